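# Methods

crawlnet reimplements, end to end, the computational analysis of how one
motor-neuron population produces two crawling behaviors in the *Drosophila*
larva: alignment and clustering of muscle calcium activity into co-activated
muscle groups (CMUGs), spatial statistics on motor-neuron synapse clouds,
premotor→motor connectivity statistics, and a connectome-constrained
recurrent rate model trained to generate the forward and backward motor
sequences. All stages run on seeded synthetic data shipped with the package.

## Muscle kinetics

Raw input is two-channel fluorescence (GCaMP / mCherry) per muscle per crawl
bout. Activity is the ratiometric trace GCaMP/mCherry, with an optional
3-frame rolling median on the denominator (dropout protection; the ratio is
exact away from trace edges). ΔF/F₀ uses a ~1 s pre-event baseline.

Cycle alignment embeds each bout's frame × muscle matrix in 2D with PCA.
Each muscle is centered on its **median** rather than its mean: the median
equals the quiescent baseline whenever rest dominates the bout, so the 2D
trajectory leaves from and returns to the origin, which is what makes the
amplitude (distance from origin) a meaningful cycle marker. Mean centering
is available via `center="mean"`. The amplitude peak (plateau ties → the
earliest frame) marks the cycle midpoint; the half-height crossings, found
by linear interpolation moving outward from the peak, define cycle onset and
offset and are mapped to 25 and 75 on a normalized 0–100 axis. Traces are
linearly resampled onto the integer grid with clamped extrapolation and
range-normalized to [0, 1]; zero-range muscles are flattened to zero and
flagged.

CMUG clustering runs on the first half of the cycle only (group identity is
carried by activation onset; offsets are less coherent), using Ward linkage
on Euclidean distance. The cluster count defaults to 4; alternatively the
gap statistic (k ∈ 2..8, 10 reference draws uniform over the bounding box in
the data's principal-component basis, Tibshirani's one-reference-sd stopping
rule) chooses k. Groups are numbered 1..k by ascending mean onset time.

Differential recruitment between behaviors is scored at the cycle onset
(t = 25): `score(m) = [x_fwd,m(25) − x̄_fwd(25)] − [x_bwd,m(25) − x̄_bwd(25)]`,
where x̄ is the across-muscle mean. A muscle recruited earlier than the
population is already active at onset, so positive scores mean earlier
recruitment during forward crawling. The statistic is isolated in one
function so alternatives can be swapped.

## Synapse geometry

Synapse tables are 3D point clouds (μm) with polarity and a polyadic weight
(number of postsynaptic partners of a presynaptic site). Cross-sectional
analyses first rotate coordinates −12° about the anteroposterior (z) axis to
compensate the EM volume's roll. One-axis densities are Gaussian KDEs with a
1 μm bandwidth on a 512-point grid padded by 4 bandwidths (the padding keeps
the on-grid mass within 10⁻³ of 1; presynaptic sites can be weighted by
their polyadic count).

The pairwise similarity of two clouds combines nearest-synapse distance and
local-density agreement:

    f(i→j) = mean_s exp(−d_sk² / 2σ²) · exp(−|n_is − n_jk| / (n_is + n_jk))

with σ = ω = 2 μm; `n_is` is the fraction of neuron i's synapses within ω of
synapse s (the synapse counts itself, so single-synapse clouds give a factor
of 1), and k is the nearest synapse of j (ties → lowest index). The score is
directional; the clustering matrix averages both directions (preserves the
[0, 1] range and symmetry; `none` and `min` are retained for oracle tests).
Left/right matrices are compared by Pearson r over off-diagonal
upper-triangle entries (the unit diagonal would inflate the correlation) and
averaged for clustering, which is agglomerative with distance 1 − similarity
and average linkage. Axis distributions are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p).

## Connectivity statistics

All statistics pool bilateral homologs: left/right synapse counts are
summed on both sides of an edge. A candidate neuron qualifies as premotor
when, onto at least one MN pair, it contributes strictly more than 4 pooled
synapses that are strictly more than 1% of that pair's pooled input.
Unpaired neurons are treated as their own pair and surfaced with a warning
rather than dropped.

Degree summaries (MN pairs per PMN pair, PMN pairs per MN pair, synapse
totals and input/output fractions) default to counting any pooled connection
with ≥1 synapse as "innervates"; the premotor per-edge rule is available via
`threshold_rule="paper"` and is recorded in the output. PMN–PMN density is
the fraction of ordered pairs (autapses excluded, both hemisegments pooled)
joined by ≥1 synapse.

Group-connectivity matrices weight each connection by its share of the
target MN's input (or raw counts), sum left/right PMN counterparts, average
left/right MN pairs (a missing side counts as zero), optionally drop
pair-level connections below 1% of the MN pair's input, aggregate MNs into
muscle groups, and row- or column-normalize. These matrices are clustered
with single linkage on Euclidean distance; the count of PMN pairs with
exactly one nonzero group column measures labeled-line-like connectivity.

## The two-segment recurrent model

PMN and MN rates are rectified-linear functions of inputs with per-neuron
time constants, gains and baselines:

    τ_p ⊙ du_p/dt = −u_p + g_p ⊙ (J_p [u_p]₊) + b_p + I(t)
    τ_m ⊙ du_m/dt = −u_m + g_m ⊙ (J_m [u_p]₊) + b_m

integrated with forward Euler at the 50 ms trial bin. Two segments (A1
anterior, A2 posterior) are modeled by duplicating the reconstructed
segment; within-segment weights are hard-tied between the two diagonal
blocks throughout training, and cross-segment blocks come from the (sparser)
cross-segmental reconstruction. Each nonzero weight is a parameter with a
fixed sign from the presynaptic transmitter (excitatory +, inhibitory −);
unknown-transmitter weights are initialized inhibitory with a free sign.
Initial magnitudes are the connection's percent of the postsynaptic pair's
input (0–100 scale) times 0.005; cross-segment connections are normalized
against the target's within-segment input total so the tied blocks stay
well-defined.

Trials last 6 s (120 bins) with 1 s head / 1.5 s tail quiescence. In each
segment the four CMUGs activate sequentially — the first group is active
for 2 s, onsets staggered by 0.25 s, offsets by 0.125 s — and the two
segments are offset by the 1 s intersegmental delay, posterior first during
forward crawling and anterior first during backward. Targets are half-sine
("rectified cosine") pulses of unit amplitude (the amplitude is an isolated
constant). The descending command I(t) is a learned per-PMN amplitude
applied over the union of the trial's target windows (alternatives
selectable) and zero elsewhere; amplitudes initialize uniformly in
[0.05, 0.15]. The PMN state starts from a zero-truncated Gaussian (sd 0.1)
drawn fresh each trial; the MN state starts at zero.

The cost is `C_targ + C_A18b,A27h + C_seg + C_J`:

* `C_targ = Σ_t,i w_i (m_i(t) − m*_i(t))²` with `w_i ∝ 1/N_CMUG,i`
  normalized to sum 1 (small groups still shape the fit). The *normalized*
  target cost reported everywhere is `C_targ / Σ_t,i w_i m*_i(t)²`, a
  relative squared error.
* `C_A18b,A27h = 0.05 · (Σ_t∈FWD p_A18b + Σ_t∈BWD p_A27h)` suppresses the
  backward-specific PMN during forward trials and vice versa ("t ∈ FWD"
  means every bin of the forward trial; both segment copies are penalized).
* `C_seg = α_n Σ_t∈active ‖p_A1(t) − p_A2(t − d)‖²` aligns the two segments'
  PMN activity at the intersegmental lag d (+1 s when A2 leads, −1 s when A1
  leads; zero-padded outside the trial), over the bins where the A1 target
  is active. α_n = 0.1 (n/1000)² grows quadratically over training.
* `C_J = α_n (‖J_p − J_p⁰‖² + ‖J_m − J_m⁰‖²)` pulls weights toward the
  connectome-derived initials.

Each epoch averages one forward and one backward trial and takes an RMSProp
step with learning rate `10^(−2 − epoch/1000)` (1e-2 → 1e-3 logarithmically)
for 1000 epochs. Gradients are exact: a hand-derived adjoint (backprop
through time) over the unrolled Euler recursion, verified against central
finite differences to 1e-3 relative on a small network. The rectification's
subgradient at 0 is taken as 0. After every update, hard constraints are
enforced by projection: τ clipped to [50 ms, 1 s], gains clipped positive,
sign-constrained magnitudes clipped nonnegative; the sparsity pattern lives
in the parameterization and cannot be violated.

RMSProp's unstated hyperparameters default to smoothing 0.99 and ε = 1e-2.
The large ε bounds the size of the earliest normalized steps; with a
conventional ε ≈ 1e-8, the first epochs' suppression gradients can push a
motor unit's baseline so far negative that the unit never crosses the
rectification threshold again (its gradient is identically zero below
threshold), permanently silencing it. ε = 1e-2 removes this failure mode
without changing the schedule or the cost.

Evaluation extracts each CMUG's activation onset (first crossing of half its
peak mean rate) and each segment's onset (summed MN rate crossing 10% of
peak, which also anchors the normalized time axis used for PMN time
courses). Ensembles train independent seeds, report mean ± spread of the
normalized cost, weight correlations (Pearson r of |weights| on the nonzero
support) and divergence flags, and support an ablation that disables the
A18b/A27h selectivity penalty.

## Synthetic data

The generators are pure functions of a `GeneratorSpec` (including its seed);
identical specs give byte-identical tables.

* **Connectome** — 40 bilateral PMN pairs and 16 MN pairs per segment
  (defaults). PMN→MN out-degrees are Binomial(16, 8/16), matching the
  observed mean of 8 MN targets per PMN pair; synapse counts are geometric
  (mean 8 for PMN→MN, 3 for PMN→PMN); PMN–PMN adjacency is Bernoulli at 7%
  of ordered pairs. Left/right wiring is exactly mirrored (a stated
  contralateral fraction crosses the midline). Transmitters are 40%
  excitatory / 40% inhibitory / 20% unknown; two excitatory pairs are
  designated the direction-specific neurons (A27h-like forward, A18b-like
  backward). Every MN pair is guaranteed ≥2 excitatory premotor partners
  and a ≥30% excitatory share of its premotor input — real MNs fire every
  cycle under strong cholinergic drive, with inhibition shaping timing, and
  an MN whose net drive is negative at all times can never cross the
  rectification threshold, so it could not produce its target under the
  sign constraints regardless of training.
  A pool of weak non-premotor partners dilutes input/output fractions below
  1 while staying under the premotor selection thresholds; cross-segment
  edges are a thinned (50%-kept, half-count) copy of the within-segment
  edges. The 16 model muscles are those recorded in both behaviors,
  spanning all four CMUGs of each direction, including the six
  differentially recruited muscles.
* **Synapse clouds** — per spatial group, a 3D Gaussian (sd 2 μm) around
  centers spaced 12 μm apart; three neurons per group; the right side is the
  mediolateral mirror of the left plus 0.5 μm Gaussian jitter; polyadic
  weights are geometric ≥ 1.
* **Muscle traces** — per direction, each muscle carries a half-sine pulse
  (2.5 s) whose onset is staggered 0.5 s per CMUG, on a 100-frame 10 Hz
  bout, with multiplicative log-normal noise (sd 0.05) on both channels;
  group memberships come from the packaged reference table, so the
  differentially recruited muscles (15–17 early in backward; 2, 11, 18
  late in backward) arise from their real group assignments.

What the generators do **not** emulate: movement artifacts and bleaching in
imaging, muscles missing at random within a bout, biological variability of
cycle duration, non-mirrored left/right wiring noise, spatially organized
PMN–PMN structure, or realistic synapse-cloud anisotropy. Passing the
round-trip tests therefore shows the pipeline recovers planted structure
under the stated noise, not that it is robust to every artifact of real
recordings.

## Problem sizes and determinism

Default analysis sizes: 27/25 muscles × 4 bouts per direction for the
muscle stage; 18 neurons × 30 synapses per side for geometry; 40 PMN and 16
MN pairs for connectivity and the model. The acceptance script trains five
1000-epoch models (~7 s each on one core). Every random draw flows from an
explicit seed; rerunning any stage with the same configuration reproduces
its CSV/JSON artifacts byte for byte.

## Known limitations

Descending command circuitry, gap junctions, proprioceptive feedback and
conductance-based dynamics are out of scope. The model's weight correlations
to the initial connectome depend on the synthetic connectome's statistics
and are reported, not calibrated. The CATMAID-style JSON importer is
deliberately not included; tabular CSV/TSV exports are the supported
interchange format.
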