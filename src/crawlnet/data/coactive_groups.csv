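direction,group,muscle
forward,F1,2
forward,F1,6
forward,F1,10
forward,F1,11
forward,F1,14
forward,F1,30
forward,F2,3
forward,F2,4
forward,F2,5
forward,F2,9
forward,F2,12
forward,F2,13
forward,F2,18
forward,F2,19
forward,F2,25
forward,F2,26
forward,F2,29
forward,F3,1
forward,F3,8
forward,F3,15
forward,F3,16
forward,F3,17
forward,F3,20
forward,F3,28
forward,F4,21
forward,F4,22
forward,F4,23
backward,B1,10
backward,B1,15
backward,B1,16
backward,B1,17
backward,B2,1
backward,B2,3
backward,B2,4
backward,B2,6
backward,B2,9
backward,B2,12
backward,B2,13
backward,B2,28
backward,B3,2
backward,B3,5
backward,B3,8
backward,B3,19
backward,B3,20
backward,B3,26
backward,B3,29
backward,B4,11
backward,B4,18
backward,B4,21
backward,B4,22
backward,B4,23
backward,B4,24
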