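"""Assemble the two-segment network structure from connectivity tables.

The model duplicates the reconstructed segment: PMN and MN bilateral pairs
become one unit per segment, within-segment connectivity is identical in the
two segments (tied weights), and cross-segment connections come from the
cross-segmental reconstruction (typically sparser).

Initial weight magnitudes are synapse counts normalized to the percent of
input received by the postsynaptic pair (0-100 scale) times a 0.005 scaling
factor, signed by the presynaptic transmitter. Unknown-transmitter weights
are initialized inhibitory but left sign-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..connectome import pair_map, pool_bilateral
from ..datasets import coactive_group_map
from ..errors import ValidationError
from .network import TwoSegmentNetwork, WeightStructure

WEIGHT_SCALE = 0.005


def mn_cmug_indices(
    records: pd.DataFrame, mn_pairs: list[str], direction: str
) -> np.ndarray:
    """0-indexed CMUG of each MN pair, derived from its target muscles."""
    group_of_muscle = coactive_group_map(direction)
    pairs = pair_map(records, warn_unpaired=False)
    by_id = records.set_index("neuron_id")
    out = np.full(len(mn_pairs), -1, dtype=int)
    for i, pid in enumerate(mn_pairs):
        members = [n for n, p in pairs.items() if p == pid]
        muscles: list[int] = []
        for m in members:
            raw = by_id.loc[m, "muscle_targets"]
            muscles += [int(x) for x in str(raw).split(";") if x]
        labels = [group_of_muscle[m] for m in sorted(set(muscles)) if m in group_of_muscle]
        if not labels:
            raise ValidationError(
                f"MN pair {pid} has no muscle with a {direction} CMUG assignment"
            )
        out[i] = int(labels[0][1]) - 1  # 'F3' -> 2
    return out


def _percent_input(pooled: pd.DataFrame) -> dict[tuple[str, str], float]:
    totals = pooled.groupby("post_id")["synapse_count"].sum()
    return {
        (r.pre_id, r.post_id): 100.0 * r.synapse_count / totals[r.post_id]
        for r in pooled.itertuples()
    }


def build_two_segment(
    edges: pd.DataFrame,
    records: pd.DataFrame,
    cross_edges: pd.DataFrame | None = None,
    scale: float = WEIGHT_SCALE,
) -> TwoSegmentNetwork:
    """Build the tied two-segment structure and initial weights.

    ``edges`` holds the within-segment reconstruction (individual left/right
    neurons; pooled to bilateral pairs here). ``cross_edges``, if given, is a
    pair-level table with columns ``pre_pair``, ``post_pair``,
    ``synapse_count`` and ``direction`` (``a1_to_a2`` or ``a2_to_a1``).
    """
    known = set(records["neuron_id"])
    referenced = set(edges["pre_id"]) | set(edges["post_id"])
    missing = sorted(referenced - known)
    if missing:
        raise ValidationError(f"edges reference unknown neurons: {missing}")

    pairs = pair_map(records, warn_unpaired=False)
    cls = dict(zip(records["neuron_id"], records["neuron_class"]))
    trans = dict(zip(records["neuron_id"], records["transmitter"]))
    name = dict(zip(records["neuron_id"], records["name"]))

    pmn_pairs = sorted({pairs[n] for n in known if cls[n] == "PMN"})
    mn_pairs = sorted({pairs[n] for n in known if cls[n] == "MN"})
    p_idx = {p: i for i, p in enumerate(pmn_pairs)}
    m_idx = {p: i for i, p in enumerate(mn_pairs)}
    nP, nM = len(pmn_pairs), len(mn_pairs)

    pooled = pool_bilateral(edges, pairs)
    pooled = pooled.loc[pooled["synapse_count"] > 0]
    percent = _percent_input(pooled)

    pair_trans = {}
    for n, p in pairs.items():
        if cls[n] == "PMN":
            pair_trans.setdefault(p, trans[n])
            if trans[n] != pair_trans[p]:
                raise ValidationError(f"transmitter mismatch within pair {p}")

    def sign_and_init(pre_pair: str, value: float) -> tuple[float, float, bool]:
        """(sign factor, initial parameter, constrained?) for one connection."""
        t = pair_trans.get(pre_pair, "unknown")
        if t == "excitatory":
            return 1.0, scale * value, True
        if t == "inhibitory":
            return -1.0, scale * value, True
        return 1.0, -scale * value, False  # unknown: inhibitory init, free sign

    # --- collect placements -------------------------------------------------
    p_rows, p_cols, p_pidx, p_sign = [], [], [], []
    m_rows, m_cols, m_pidx, m_sign = [], [], [], []
    wp0, wp_con = [], []
    wm0, wm_con = [], []

    for r in pooled.itertuples():
        pre_p, post_p = r.pre_id, r.post_id
        if pre_p not in p_idx:
            continue  # non-PMN presynaptic partners carry no model weight
        value = percent[(pre_p, post_p)]
        s, w0, con = sign_and_init(pre_p, value)
        if post_p in p_idx:
            k = len(wp0)
            wp0.append(w0)
            wp_con.append(con)
            for seg in (0, 1):  # tied within-segment blocks
                p_rows.append(seg * nP + p_idx[post_p])
                p_cols.append(seg * nP + p_idx[pre_p])
                p_pidx.append(k)
                p_sign.append(s)
        elif post_p in m_idx:
            k = len(wm0)
            wm0.append(w0)
            wm_con.append(con)
            for seg in (0, 1):
                m_rows.append(seg * nM + m_idx[post_p])
                m_cols.append(seg * nP + p_idx[pre_p])
                m_pidx.append(k)
                m_sign.append(s)

    if cross_edges is not None:
        for r in cross_edges.itertuples():
            pre_p, post_p = r.pre_pair, r.post_pair
            if pre_p not in p_idx:
                raise ValidationError(f"cross edge from unknown PMN pair {pre_p}")
            pre_seg = 0 if r.direction == "a1_to_a2" else 1
            post_seg = 1 - pre_seg
            # normalized against the within-segment input total of the target
            total = pooled.loc[pooled["post_id"] == post_p, "synapse_count"].sum()
            value = 100.0 * r.synapse_count / total if total else r.synapse_count
            s, w0, con = sign_and_init(pre_p, value)
            if post_p in p_idx:
                k = len(wp0)
                wp0.append(w0)
                wp_con.append(con)
                p_rows.append(post_seg * nP + p_idx[post_p])
                p_cols.append(pre_seg * nP + p_idx[pre_p])
                p_pidx.append(k)
                p_sign.append(s)
            elif post_p in m_idx:
                k = len(wm0)
                wm0.append(w0)
                wm_con.append(con)
                m_rows.append(post_seg * nM + m_idx[post_p])
                m_cols.append(pre_seg * nP + p_idx[pre_p])
                m_pidx.append(k)
                m_sign.append(s)
            else:
                raise ValidationError(f"cross edge onto unknown pair {post_p}")

    struct_p = WeightStructure(
        shape=(2 * nP, 2 * nP),
        rows=np.array(p_rows, dtype=int),
        cols=np.array(p_cols, dtype=int),
        pidx=np.array(p_pidx, dtype=int),
        sign=np.array(p_sign, dtype=float),
        constrained=np.array(wp_con, dtype=bool),
        n_params=len(wp0),
    )
    struct_m = WeightStructure(
        shape=(2 * nM, 2 * nP),
        rows=np.array(m_rows, dtype=int),
        cols=np.array(m_cols, dtype=int),
        pidx=np.array(m_pidx, dtype=int),
        sign=np.array(m_sign, dtype=float),
        constrained=np.array(wm_con, dtype=bool),
        n_params=len(wm0),
    )

    cmug_f = mn_cmug_indices(records, mn_pairs, "forward")
    cmug_b = mn_cmug_indices(records, mn_pairs, "backward")

    def units_named(tag: str) -> np.ndarray:
        hits = sorted({pairs[n] for n in known if tag in str(name.get(n, ""))})
        idx = [p_idx[h] for h in hits if h in p_idx]
        return np.array([seg * nP + i for seg in (0, 1) for i in idx], dtype=int)

    return TwoSegmentNetwork(
        pmn_pairs=pmn_pairs,
        mn_pairs=mn_pairs,
        struct_p=struct_p,
        struct_m=struct_m,
        wp0=np.array(wp0),
        wm0=np.array(wm0),
        cmug_fwd=np.tile(cmug_f, 2),
        cmug_bwd=np.tile(cmug_b, 2),
        a27h_units=units_named("A27h"),
        a18b_units=units_named("A18b"),
    )
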