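"""Premotor selection and connectivity statistics on a synthetic connectome.

Applies the premotor selection rule (>4 pooled synapses and >1% of a motor
pair's input), summarizes degree statistics, measures premotor-premotor
density, and counts premotor pairs dedicated to a single co-activated group
after the 1% connection filter.
"""

import warnings

from crawlnet import connectome as cc
from crawlnet.datasets import coactive_group_map
from crawlnet.synthetic import GeneratorSpec, synth_connectome

warnings.simplefilter("ignore")

conn = synth_connectome(GeneratorSpec(seed=1))
rec, edges = conn["records"], conn["edges"]
mn_ids = set(rec.loc[rec.neuron_class == "MN", "neuron_id"])

pmn_ids = cc.select_premotor(edges, rec, mn_ids)
print(f"premotor neurons selected: {len(pmn_ids)} "
      f"({len(pmn_ids) // 2} bilateral pairs)")

stats = cc.connectivity_summary(edges, pmn_ids, mn_ids, rec)
print(f"mean MN pairs innervated per PMN pair:  {stats.mean_mn_targets_per_pmn:.1f}")
print(f"mean PMN pairs innervating each MN pair: {stats.mean_pmn_inputs_per_mn:.1f}")
print(f"total PMN->MN synapses: {stats.total_pmn_to_mn_synapses}")
print(f"PMN output onto MNs: {100 * stats.fraction_pmn_output_to_mns:.1f}%")
print(f"MN input from PMNs:  {100 * stats.fraction_mn_input_from_pmns:.1f}%")

pairs = cc.pair_map(rec, warn_unpaired=False)
pooled = cc.pool_bilateral(edges, pairs)
pmn_pairs = {pairs[n] for n in rec.loc[rec.neuron_class == "PMN", "neuron_id"]}
density = cc.pmn_pmn_density(pooled, pmn_pairs)
print(f"PMN-PMN connection density: {100 * density:.1f}% of ordered pairs")

group_map = coactive_group_map("forward")
by_id = rec.set_index("neuron_id")
mn_groups = {
    m: group_map[int(by_id.loc[m, "muscle_targets"])]
    for m in mn_ids
    if int(by_id.loc[m, "muscle_targets"]) in group_map
}
mat = cc.group_connectivity_matrix(
    edges, pmn_ids, mn_groups, rec, normalize="row", min_fraction=0.01
)
n_single = cc.count_single_group_pmns(mat)
print(f"PMN pairs connected to a single forward co-active group: {n_single} "
      f"of {len(mat)} (after the 1% connection filter)")
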