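"""Seeded generators emulating the statistical structure of the real data.

Three generators produce the inputs the analysis stages expect, so the whole
pipeline runs and is testable without any external download:

* :func:`synth_connectome` -- a bilaterally mirrored two-population
  connectome (premotor and motor pairs) with ~7% premotor-premotor density,
  a target mean of 8 motor targets per premotor pair, geometric synapse
  counts, transmitter labels, designated direction-specific premotor pairs
  (an A27h-like forward-specific and an A18b-like backward-specific pair),
  and thinned cross-segment edges.
* :func:`synth_synapse_clouds` -- mirrored left/right Gaussian synapse
  clouds organized in spatial groups (a myotopic layout).
* :func:`synth_muscle_traces` -- two-channel fluorescence traces with
  half-sine activation pulses staggered by co-activated muscle group
  (memberships from the packaged reference table) and multiplicative
  log-normal noise.

Every generator is a pure function of its spec (including the seed): the
same spec yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datasets import coactive_group_map
from .errors import ValidationError

# 16 muscles recorded in both directions, spanning all four CMUGs of each
# direction; used as the motor units of the synthetic connectome.
MODEL_MUSCLES = (1, 2, 3, 4, 5, 6, 9, 10, 11, 12, 15, 16, 17, 18, 21, 22)


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic-data generators, with study defaults."""

    seed: int = 0
    # connectome
    n_pmn_pairs: int = 40
    n_mn_pairs: int = 16
    pmn_pmn_density: float = 0.07
    mean_mn_targets: float = 8.0
    synapse_count_mean: float = 8.0
    pmn_synapse_count_mean: float = 3.0
    excitatory_fraction: float = 0.4
    unknown_fraction: float = 0.2
    min_excitatory_inputs_per_mn: int = 2
    min_excitatory_input_share: float = 0.3
    contralateral_prob: float = 0.3
    cross_segment_keep: float = 0.5
    nonmotor_output_factor: float = 6.0
    n_other_pairs: int = 10
    other_input_prob: float = 0.6
    # synapse clouds
    n_spatial_groups: int = 6
    neurons_per_group: int = 3
    synapses_per_neuron: int = 30
    cloud_sd_um: float = 2.0
    group_spacing_um: float = 12.0
    mirror_jitter_um: float = 0.5
    midline_offset_um: float = 20.0
    # muscle traces
    frame_rate_hz: float = 10.0
    bout_duration_s: float = 10.0
    cycle_start_s: float = 2.0
    group_stagger_s: float = 0.5
    pulse_duration_s: float = 2.5
    trace_noise_sd: float = 0.05
    gcamp_baseline: float = 100.0
    gcamp_amplitude: float = 4.0
    mcherry_level: float = 50.0
    n_bouts: int = 4

    def to_dict(self) -> dict:
        return asdict(self)


def _geometric_counts(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    """Synapse counts >= 1 from a geometric distribution with the given mean."""
    p = 1.0 / max(mean, 1.0)
    return rng.geometric(p, n)


def synth_connectome(spec: GeneratorSpec = GeneratorSpec()) -> dict:
    """Generate a mirrored premotor/motor connectome.

    Returns a dict with ``records`` (neuron table, individual left/right
    neurons), ``edges`` (within-segment edge table), ``cross_edges``
    (pair-level, thinned copy of the within-segment edges, both directions)
    and ``spec``.
    """
    if not 0 < spec.pmn_pmn_density < 1:
        raise ValidationError("pmn_pmn_density must be in (0, 1)")
    if spec.mean_mn_targets > spec.n_mn_pairs:
        raise ValidationError("mean_mn_targets exceeds the number of MN pairs")
    rng = np.random.default_rng(spec.seed)
    P, M = spec.n_pmn_pairs, spec.n_mn_pairs

    pmn_pair_names = [f"PMN{i:03d}" for i in range(P)]
    mn_pair_names = [f"MN-m{MODEL_MUSCLES[i % len(MODEL_MUSCLES)]:02d}" for i in range(M)]
    if M > len(MODEL_MUSCLES):
        raise ValidationError("n_mn_pairs exceeds the packaged muscle roster")

    # transmitter labels; two excitatory pairs are designated the
    # direction-specific neurons (forward-specific A27h, backward-specific A18b)
    u = rng.random(P)
    transmitter = np.where(
        u < spec.excitatory_fraction,
        "excitatory",
        np.where(u < spec.excitatory_fraction + spec.unknown_fraction, "unknown", "inhibitory"),
    )
    transmitter[0] = transmitter[1] = "excitatory"
    roles = {0: "A27h-like", 1: "A18b-like"}

    records = []
    for i, pname in enumerate(pmn_pair_names):
        for side in ("L", "R"):
            records.append(
                {
                    "neuron_id": f"{pname}_{side}",
                    "name": roles.get(i, pname),
                    "neuron_class": "PMN",
                    "segment": "A1",
                    "side": "left" if side == "L" else "right",
                    "transmitter": transmitter[i],
                    "homolog_id": f"{pname}_{'R' if side == 'L' else 'L'}",
                    "muscle_targets": "",
                }
            )
    for j, mname in enumerate(mn_pair_names):
        muscle = MODEL_MUSCLES[j % len(MODEL_MUSCLES)]
        for side in ("L", "R"):
            records.append(
                {
                    "neuron_id": f"{mname}_{side}",
                    "name": mname,
                    "neuron_class": "MN",
                    "segment": "A1",
                    "side": "left" if side == "L" else "right",
                    "transmitter": "excitatory",
                    "homolog_id": f"{mname}_{'R' if side == 'L' else 'L'}",
                    "muscle_targets": str(muscle),
                }
            )
    # a pool of weak non-premotor partners (sensory/descending stand-ins) so
    # that output/input fractions are < 1; each contributes too few synapses
    # per MN pair to pass the premotor selection rule
    other_names = [f"OTHER{i:02d}" for i in range(spec.n_other_pairs)]
    for oname in other_names:
        for side in ("L", "R"):
            records.append(
                {
                    "neuron_id": f"{oname}_{side}",
                    "name": oname,
                    "neuron_class": "other",
                    "segment": "A1",
                    "side": "left" if side == "L" else "right",
                    "transmitter": "unknown",
                    "homolog_id": f"{oname}_{'R' if side == 'L' else 'L'}",
                    "muscle_targets": "",
                }
            )
    records = pd.DataFrame(records)

    # --- pair-level edges, mirrored to L/R individuals ----------------------
    pair_edges: list[tuple[str, str, int]] = []
    # PMN -> MN: out-degrees Binomial(M, mean/M) (mean = target), >=1
    out_prob = spec.mean_mn_targets / M
    for i, pname in enumerate(pmn_pair_names):
        k = max(1, rng.binomial(M, out_prob))
        targets = rng.choice(M, size=k, replace=False)
        counts = _geometric_counts(rng, k, spec.synapse_count_mean)
        for j, c in zip(targets, counts):
            pair_edges.append((pname, mn_pair_names[j], int(c)))
    # every MN pair must receive substantial excitatory premotor drive (real
    # MNs are driven each cycle by cholinergic premotor input, with inhibition
    # shaping timing): guarantee a minimum number of excitatory partners and a
    # minimum excitatory share of the MN's premotor input
    exc_set = {pmn_pair_names[i] for i in range(P) if transmitter[i] == "excitatory"}
    exc_pmns = sorted(exc_set)
    for j, mname in enumerate(mn_pair_names):
        have = {pre for pre, post, _ in pair_edges if post == mname and pre in exc_set}
        deficit = spec.min_excitatory_inputs_per_mn - len(have)
        if deficit > 0:
            candidates = [p for p in exc_pmns if p not in have]
            picks = rng.choice(len(candidates), size=min(deficit, len(candidates)), replace=False)
            counts = _geometric_counts(rng, len(picks), spec.synapse_count_mean)
            for idx, c in zip(picks, counts):
                pair_edges.append((candidates[idx], mname, int(c)))
    share = spec.min_excitatory_input_share
    for mname in mn_pair_names:
        idxs = [k for k, (pre, post, _) in enumerate(pair_edges) if post == mname]
        exc_idx = [k for k in idxs if pair_edges[k][0] in exc_set]
        e = sum(pair_edges[k][2] for k in exc_idx)
        t = sum(pair_edges[k][2] for k in idxs)
        extra = int(np.ceil(max(0.0, (share * t - e) / (1 - share))))
        if extra > 0:
            # spread the top-up over the MN's existing excitatory edges
            add_per = np.bincount(
                rng.integers(0, len(exc_idx), extra), minlength=len(exc_idx)
            )
            for k, a in zip(exc_idx, add_per):
                pre, post, c = pair_edges[k]
                pair_edges[k] = (pre, post, c + int(a))
    # PMN -> PMN: Bernoulli(density) over ordered pairs, no autapses
    for i in range(P):
        for j in range(P):
            if i != j and rng.random() < spec.pmn_pmn_density:
                c = int(_geometric_counts(rng, 1, spec.pmn_synapse_count_mean)[0])
                pair_edges.append((pmn_pair_names[i], pmn_pair_names[j], c))
    # dilution: PMN output onto non-motor partners, non-premotor input to MNs
    mn_totals = {m: 0 for m in mn_pair_names}
    pmn_to_mn = {p: 0 for p in pmn_pair_names}
    for pre, post, c in pair_edges:
        if post in mn_totals and pre in pmn_to_mn:
            mn_totals[post] += c
            pmn_to_mn[pre] += c
    for i, pname in enumerate(pmn_pair_names):
        c = int(round(spec.nonmotor_output_factor * pmn_to_mn[pname]))
        if c > 0:
            pair_edges.append((pname, other_names[i % len(other_names)], c))
    for mname in mn_pair_names:
        for oname in other_names:
            if rng.random() < spec.other_input_prob:
                # 1-2 synapses per side: pooled count <= 4, below the rule
                pair_edges.append((oname, mname, int(rng.integers(1, 3))))

    rows = []
    for pre, post, c in pair_edges:
        contra = rng.random() < spec.contralateral_prob
        for side in ("L", "R"):
            post_side = ({"L": "R", "R": "L"}[side]) if contra else side
            rows.append(
                {
                    "pre_id": f"{pre}_{side}",
                    "post_id": f"{post}_{post_side}",
                    "synapse_count": c,
                }
            )
    edges = pd.DataFrame(rows)

    # cross-segment edges: a thinned copy of the within-segment pair edges
    cross_rows = []
    for direction in ("a1_to_a2", "a2_to_a1"):
        for pre, post, c in pair_edges:
            if pre.startswith("PMN") and not post.startswith("OTHER"):
                if rng.random() < spec.cross_segment_keep:
                    thinned = max(1, int(round(c / 2)))
                    cross_rows.append(
                        {
                            "pre_pair": f"{pre}_L",
                            "post_pair": f"{post}_L",
                            "synapse_count": thinned,
                            "direction": direction,
                        }
                    )
    cross_edges = pd.DataFrame(cross_rows)
    return {
        "records": records,
        "edges": edges,
        "cross_edges": cross_edges,
        "spec": spec,
    }


def synth_synapse_clouds(
    spec: GeneratorSpec = GeneratorSpec(),
) -> dict:
    """Mirrored left/right synapse clouds in a myotopic group layout.

    Group centers are spaced ``group_spacing_um`` apart along alternating
    axes; each neuron's synapses are Gaussian around its group center. The
    right side is the mediolateral mirror of the left plus Gaussian jitter.
    Returns ``{"left": table, "right": table, "groups": {neuron: group}}``.
    """
    if spec.n_spatial_groups < 2:
        raise ValidationError("need >=2 spatial groups")
    rng = np.random.default_rng(spec.seed + 1)
    rows_l, rows_r = [], []
    groups = {}
    for g in range(spec.n_spatial_groups):
        center = np.array(
            [
                spec.midline_offset_um + (g % 2) * spec.group_spacing_um,
                (g // 2) * spec.group_spacing_um,
                ((g * 7) % spec.n_spatial_groups) * spec.group_spacing_um,
            ]
        )
        for k in range(spec.neurons_per_group):
            nid = f"G{g}N{k}"
            groups[nid] = g
            offset = rng.normal(0, spec.cloud_sd_um / 2, 3)
            pts = rng.normal(center + offset, spec.cloud_sd_um, (spec.synapses_per_neuron, 3))
            w = rng.geometric(0.5, spec.synapses_per_neuron)
            jitter = rng.normal(0, spec.mirror_jitter_um, (spec.synapses_per_neuron, 3))
            for s in range(spec.synapses_per_neuron):
                rows_l.append(
                    {
                        "neuron_id": nid,
                        "x_um": pts[s, 0],
                        "y_um": pts[s, 1],
                        "z_um": pts[s, 2],
                        "polarity": "post",
                        "polyadic_weight": int(w[s]),
                    }
                )
                rows_r.append(
                    {
                        "neuron_id": nid,
                        "x_um": -pts[s, 0] + jitter[s, 0],
                        "y_um": pts[s, 1] + jitter[s, 1],
                        "z_um": pts[s, 2] + jitter[s, 2],
                        "polarity": "post",
                        "polyadic_weight": int(w[s]),
                    }
                )
    return {
        "left": pd.DataFrame(rows_l),
        "right": pd.DataFrame(rows_r),
        "groups": groups,
        "spec": spec,
    }


def synth_muscle_traces(spec: GeneratorSpec = GeneratorSpec()) -> pd.DataFrame:
    """Two-channel muscle fluorescence traces for forward and backward bouts.

    Each muscle's GCaMP trace carries a half-sine activation pulse whose
    onset is staggered by the muscle's co-activated group for that direction
    (group 1 earliest); both channels carry multiplicative log-normal noise.
    Returns a long-format table (bout_id, direction, muscle, frame, t_s,
    gcamp, mcherry).
    """
    rng = np.random.default_rng(spec.seed + 2)
    n_frames = int(round(spec.bout_duration_s * spec.frame_rate_hz))
    t = np.arange(n_frames) / spec.frame_rate_hz
    rows = []
    for direction in ("forward", "backward"):
        group_of = coactive_group_map(direction)
        for b in range(spec.n_bouts):
            bout_id = f"{direction[0]}{b:02d}"
            for muscle, label in sorted(group_of.items()):
                g = int(label[1]) - 1  # 'F2' -> 1
                onset = spec.cycle_start_s + g * spec.group_stagger_s
                phase = (t - onset) / spec.pulse_duration_s
                pulse = np.where(
                    (phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0
                )
                noise_g = np.exp(rng.normal(0, spec.trace_noise_sd, n_frames))
                noise_m = np.exp(rng.normal(0, spec.trace_noise_sd, n_frames))
                gcamp = spec.gcamp_baseline * (1 + spec.gcamp_amplitude * pulse) * noise_g
                mcherry = spec.mcherry_level * noise_m
                for f in range(n_frames):
                    rows.append(
                        (bout_id, direction, muscle, f, t[f], gcamp[f], mcherry[f])
                    )
    return pd.DataFrame(
        rows,
        columns=["bout_id", "direction", "muscle", "frame", "t_s", "gcamp", "mcherry"],
    )
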