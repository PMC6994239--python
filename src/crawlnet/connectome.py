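"""Premotor-motor connectivity: loading, selection, statistics and clustering.

The central objects are plain pandas DataFrames:

* **neuron table** -- one row per neuron with columns ``neuron_id``, ``name``,
  ``neuron_class`` (``MN`` / ``PMN`` / ``other``), ``segment``, ``side``
  (``left`` / ``right`` / ``midline``), ``transmitter`` (``excitatory`` /
  ``inhibitory`` / ``unknown``), ``homolog_id`` (the bilateral partner, empty
  if unpaired) and ``muscle_targets`` (``;``-separated muscle labels, MNs only).
* **edge table** -- one row per directed connection with columns ``pre_id``,
  ``post_id``, ``synapse_count``.

Bilateral left/right homologs are pooled throughout, matching how premotor
neurons (PMNs) were selected in the reconstruction: a candidate qualifies as
premotor when, onto at least one left+right motor-neuron (MN) pair, it makes
more than four pooled synapses that account for more than 1% of that pair's
pooled synaptic input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import EmptyInputError, FormatError, ValidationError

EDGE_COLUMNS = ("pre_id", "post_id", "synapse_count")

NEURON_COLUMNS = (
    "neuron_id",
    "name",
    "neuron_class",
    "segment",
    "side",
    "transmitter",
    "homolog_id",
    "muscle_targets",
)


def load_edge_table(path) -> pd.DataFrame:
    """Read and validate a directed synapse-count table (CSV or TSV).

    Duplicate ``(pre_id, post_id)`` rows are aggregated by summation with a
    warning; negative counts raise :class:`ValidationError`.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"pre_id": str, "post_id": str})
    return validate_edge_table(df)


def validate_edge_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"edge table missing columns: {missing}")
    df = df.loc[:, list(EDGE_COLUMNS)].copy()
    if df["synapse_count"].isna().any():
        raise ValidationError("edge table contains blank synapse counts")
    counts = pd.to_numeric(df["synapse_count"], errors="raise")
    if (counts < 0).any():
        bad = df.loc[counts < 0]
        raise ValidationError(f"negative synapse counts in {len(bad)} rows")
    df["synapse_count"] = counts.astype(int)
    dup = df.duplicated(subset=["pre_id", "post_id"])
    if dup.any():
        warnings.warn(
            f"aggregating {int(dup.sum())} duplicate (pre, post) rows by summation",
            stacklevel=2,
        )
        df = df.groupby(["pre_id", "post_id"], as_index=False, sort=False)[
            "synapse_count"
        ].sum()
    return df.reset_index(drop=True)


def load_neuron_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in NEURON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"neuron table missing columns: {missing}")
    if df["neuron_id"].duplicated().any():
        raise ValidationError("neuron_id values are not unique")
    return df.reset_index(drop=True)


def check_no_motor_output(edges: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Drop (with a warning) edges whose presynaptic neuron is an MN.

    In the reconstruction MNs carried no presynaptic contacts onto other
    neurons, so MN->anything rows indicate a malformed table.
    """
    mn_ids = set(records.loc[records["neuron_class"] == "MN", "neuron_id"])
    bad = edges["pre_id"].isin(mn_ids)
    if bad.any():
        warnings.warn(
            f"rejecting {int(bad.sum())} edges with motor-neuron presynaptic partner",
            stacklevel=2,
        )
        edges = edges.loc[~bad].reset_index(drop=True)
    return edges


def pair_map(records: pd.DataFrame, warn_unpaired: bool = True) -> dict[str, str]:
    """Map each neuron_id to a canonical bilateral-pair id.

    The pair id is the lexicographic minimum of the two homolog ids. Neurons
    without an identifiable homolog become their own pair (surfaced with a
    warning rather than silently dropped).
    """
    ids = set(records["neuron_id"])
    homolog = dict(zip(records["neuron_id"], records["homolog_id"]))
    mapping: dict[str, str] = {}
    unpaired = []
    for nid, h in homolog.items():
        if h and h in ids:
            back = homolog.get(h, "")
            if back != nid:
                raise ValidationError(
                    f"homolog map is not an involution: {nid}->{h}->{back}"
                )
            mapping[nid] = min(nid, h)
        else:
            mapping[nid] = nid
            unpaired.append(nid)
    if unpaired and warn_unpaired:
        warnings.warn(
            f"{len(unpaired)} neurons have no bilateral homolog; treated as "
            f"their own pair: {sorted(unpaired)[:5]}...",
            stacklevel=2,
        )
    return mapping


def pool_bilateral(edges: pd.DataFrame, pairs: dict[str, str]) -> pd.DataFrame:
    """Sum synapse counts over left/right homologs on both sides of each edge."""
    pooled = edges.assign(
        pre_id=edges["pre_id"].map(lambda i: pairs.get(i, i)),
        post_id=edges["post_id"].map(lambda i: pairs.get(i, i)),
    )
    return pooled.groupby(["pre_id", "post_id"], as_index=False, sort=False)[
        "synapse_count"
    ].sum()


def input_fractions(edges: pd.DataFrame, post_id: str) -> dict[str, float]:
    """Fraction of ``post_id``'s synaptic input contributed by each partner."""
    sub = edges.loc[edges["post_id"] == post_id]
    total = sub["synapse_count"].sum()
    if len(sub) == 0 or total == 0:
        raise EmptyInputError(f"{post_id} has no incoming synapses")
    return dict(zip(sub["pre_id"], sub["synapse_count"] / total))


def select_premotor(
    edges: pd.DataFrame,
    records: pd.DataFrame,
    mn_ids: set[str],
    min_synapses: int = 4,
    min_fraction: float = 0.01,
) -> set[str]:
    """Apply the premotor selection rule and return qualifying neuron ids.

    A candidate pair qualifies if, for at least one bilateral MN pair, its
    pooled left+right synapse count is strictly greater than ``min_synapses``
    AND strictly greater than ``min_fraction`` of that MN pair's pooled input.
    Both members of a qualifying pair are returned.
    """
    if not mn_ids:
        raise EmptyInputError("mn_ids is empty")
    pairs = pair_map(records, warn_unpaired=True)
    pooled = pool_bilateral(edges, pairs)
    mn_pairs = {pairs.get(m, m) for m in mn_ids}
    onto_mn = pooled.loc[pooled["post_id"].isin(mn_pairs)]
    totals = onto_mn.groupby("post_id")["synapse_count"].sum()
    selected_pairs = set()
    for _, row in onto_mn.iterrows():
        count = row["synapse_count"]
        if count > min_synapses and count / totals[row["post_id"]] > min_fraction:
            selected_pairs.add(row["pre_id"])
    selected_pairs -= mn_pairs
    return {nid for nid, p in pairs.items() if p in selected_pairs}


@dataclass
class ConnectivityStats:
    """Degree and synapse-fraction statistics of PMN->MN connectivity.

    Counts are at the bilateral-pair level: ``mn_targets_per_pmn[p]`` is the
    number of MN pairs reached by PMN pair ``p`` under ``threshold_rule``.
    """

    mean_mn_targets_per_pmn: float
    mean_pmn_inputs_per_mn: float
    total_pmn_to_mn_synapses: int
    fraction_pmn_output_to_mns: float
    fraction_mn_input_from_pmns: float
    mn_targets_per_pmn: pd.Series = field(repr=False)
    pmn_inputs_per_mn: pd.Series = field(repr=False)
    threshold_rule: str = "raw"

    def to_dict(self) -> dict:
        return {
            "mean_mn_targets_per_pmn": self.mean_mn_targets_per_pmn,
            "mean_pmn_inputs_per_mn": self.mean_pmn_inputs_per_mn,
            "total_pmn_to_mn_synapses": self.total_pmn_to_mn_synapses,
            "fraction_pmn_output_to_mns": self.fraction_pmn_output_to_mns,
            "fraction_mn_input_from_pmns": self.fraction_mn_input_from_pmns,
            "threshold_rule": self.threshold_rule,
        }


def connectivity_summary(
    edges: pd.DataFrame,
    pmn_ids: set[str],
    mn_ids: set[str],
    records: pd.DataFrame | None = None,
    threshold_rule: str = "raw",
    min_synapses: int = 4,
    min_fraction: float = 0.01,
) -> ConnectivityStats:
    """Degree histogram summaries of PMN->MN connectivity.

    ``threshold_rule='raw'`` counts any pooled connection with >=1 synapse as
    "innervates"; ``'paper'`` applies the premotor per-edge rule (>4 pooled
    synapses and >1% of the target pair's input).
    """
    if not pmn_ids or not mn_ids:
        raise EmptyInputError("pmn_ids and mn_ids must be non-empty")
    if pmn_ids & mn_ids:
        raise ValidationError("pmn_ids and mn_ids overlap")
    if threshold_rule not in ("raw", "paper"):
        raise ValidationError(f"unknown threshold_rule {threshold_rule!r}")
    if records is not None:
        pairs = pair_map(records, warn_unpaired=False)
    else:
        pairs = {}
    pooled = pool_bilateral(edges, pairs)
    pmn_pairs = sorted({pairs.get(i, i) for i in pmn_ids})
    mn_pairs = sorted({pairs.get(i, i) for i in mn_ids})

    onto_mn = pooled.loc[
        pooled["pre_id"].isin(pmn_pairs) & pooled["post_id"].isin(mn_pairs)
    ]
    if threshold_rule == "paper":
        totals = pooled.loc[pooled["post_id"].isin(mn_pairs)].groupby("post_id")[
            "synapse_count"
        ].sum()
        keep = (onto_mn["synapse_count"] > min_synapses) & (
            onto_mn["synapse_count"]
            > min_fraction * onto_mn["post_id"].map(totals)
        )
        counted = onto_mn.loc[keep]
    else:
        counted = onto_mn

    out_deg = counted.groupby("pre_id")["post_id"].nunique()
    out_deg = out_deg.reindex(pmn_pairs, fill_value=0)
    if (out_deg == 0).any():
        warnings.warn(
            f"{int((out_deg == 0).sum())} PMN pairs have no MN targets "
            "under the chosen rule",
            stacklevel=2,
        )
    in_deg = counted.groupby("post_id")["pre_id"].nunique()
    in_deg = in_deg.reindex(mn_pairs, fill_value=0)

    total_syn = int(onto_mn["synapse_count"].sum())
    pmn_out_total = pooled.loc[pooled["pre_id"].isin(pmn_pairs), "synapse_count"].sum()
    mn_in_total = pooled.loc[pooled["post_id"].isin(mn_pairs), "synapse_count"].sum()
    return ConnectivityStats(
        mean_mn_targets_per_pmn=float(out_deg.mean()),
        mean_pmn_inputs_per_mn=float(in_deg.mean()),
        total_pmn_to_mn_synapses=total_syn,
        fraction_pmn_output_to_mns=float(total_syn / pmn_out_total)
        if pmn_out_total
        else 0.0,
        fraction_mn_input_from_pmns=float(total_syn / mn_in_total)
        if mn_in_total
        else 0.0,
        mn_targets_per_pmn=out_deg,
        pmn_inputs_per_mn=in_deg,
        threshold_rule=threshold_rule,
    )


def pmn_pmn_density(edges: pd.DataFrame, pmn_ids: set[str]) -> float:
    """Directed connection density among PMNs.

    Fraction of ordered pairs ``(i, j), i != j`` joined by >=1 synapse;
    autapses are excluded from numerator and denominator.
    """
    pmn_ids = set(pmn_ids)
    if len(pmn_ids) < 2:
        raise EmptyInputError("need >=2 PMNs to define a density")
    sub = edges.loc[
        edges["pre_id"].isin(pmn_ids)
        & edges["post_id"].isin(pmn_ids)
        & (edges["pre_id"] != edges["post_id"])
        & (edges["synapse_count"] > 0)
    ]
    n_connected = len(sub.drop_duplicates(subset=["pre_id", "post_id"]))
    n = len(pmn_ids)
    return n_connected / (n * (n - 1))


def group_connectivity_matrix(
    edges: pd.DataFrame,
    pmn_ids: set[str],
    mn_groups: dict[str, str],
    records: pd.DataFrame,
    normalize: str = "row",
    weight: str = "fraction",
    min_fraction: float | None = None,
) -> pd.DataFrame:
    """PMN-pair x muscle-group connectivity matrix.

    Left/right PMN counterparts are summed and left/right MN pairs averaged
    before MNs are aggregated into their groups. ``weight='fraction'`` uses
    each connection's share of the target MN's total input, ``'count'`` raw
    synapse counts. With ``min_fraction`` set, pair-level connections whose
    pooled weighted synapses fall below that share of the MN pair's input are
    discarded before grouping (the 1% filter used for group-specificity
    counts). ``normalize`` is ``'row'``, ``'column'`` or ``'none'``.

    ``mn_groups`` maps MN neuron ids to group labels; MNs referenced by the
    considered edges but absent from the mapping raise an error listing them.
    """
    if normalize not in ("row", "column", "none"):
        raise ValidationError(f"unknown normalize mode {normalize!r}")
    if weight not in ("fraction", "count"):
        raise ValidationError(f"unknown weight mode {weight!r}")
    pairs = pair_map(records, warn_unpaired=False)
    mn_ids = set(mn_groups)
    onto_mn = edges.loc[edges["post_id"].isin(mn_ids)].copy()
    missing = set(
        edges.loc[
            edges["post_id"].isin(
                set(records.loc[records["neuron_class"] == "MN", "neuron_id"])
            )
            & ~edges["post_id"].isin(mn_ids),
            "post_id",
        ]
    )
    if missing:
        raise ValidationError(f"MNs without a group assignment: {sorted(missing)}")
    # group labels must agree within a bilateral MN pair
    for mn, grp in mn_groups.items():
        partner = pairs.get(mn, mn)
        for other, g2 in mn_groups.items():
            if pairs.get(other, other) == partner and g2 != grp:
                raise ValidationError(
                    f"bilateral MN pair {partner} maps to two groups ({grp}, {g2})"
                )

    if weight == "fraction":
        totals = edges.groupby("post_id")["synapse_count"].sum()
        onto_mn["w"] = onto_mn["synapse_count"] / onto_mn["post_id"].map(totals)
    else:
        onto_mn["w"] = onto_mn["synapse_count"].astype(float)

    onto_mn = onto_mn.loc[onto_mn["pre_id"].isin(pmn_ids)]
    onto_mn["pre_pair"] = onto_mn["pre_id"].map(lambda i: pairs.get(i, i))
    onto_mn["post_pair"] = onto_mn["post_id"].map(lambda i: pairs.get(i, i))

    # sum over left/right PMN counterparts, average over left/right MN pairs
    # (a side with no connection counts as zero, so divide by the pair size)
    pair_size = pd.Series(pairs).groupby(pd.Series(pairs)).size()
    per_mn_pair = (
        onto_mn.groupby(["pre_pair", "post_pair"], sort=False)["w"].sum().reset_index()
    )
    per_mn_pair["w"] /= per_mn_pair["post_pair"].map(pair_size).fillna(1)

    if min_fraction is not None:
        per_mn_pair = per_mn_pair.loc[per_mn_pair["w"] >= min_fraction]

    pair_group = {pairs.get(m, m): g for m, g in mn_groups.items()}
    per_mn_pair["group"] = per_mn_pair["post_pair"].map(pair_group)
    mat = per_mn_pair.pivot_table(
        index="pre_pair", columns="group", values="w", aggfunc="sum", fill_value=0.0
    )
    all_pairs = sorted({pairs.get(i, i) for i in pmn_ids})
    groups = sorted(set(pair_group.values()))
    mat = mat.reindex(index=all_pairs, columns=groups, fill_value=0.0)

    if normalize == "row":
        sums = mat.sum(axis=1)
        mat = mat.div(sums.where(sums > 0, 1.0), axis=0)
    elif normalize == "column":
        sums = mat.sum(axis=0)
        mat = mat.div(sums.where(sums > 0, 1.0), axis=1)
    return mat


def cluster_group_connectivity(
    matrix: pd.DataFrame, n_clusters: int | None = None
) -> dict:
    """Single-linkage Euclidean hierarchical clustering of a connectivity matrix.

    Returns the scipy linkage, leaf order, and (optionally) flat labels at an
    ``n_clusters`` cut.
    """
    values = np.asarray(matrix, dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("connectivity matrix contains non-finite entries")
    if len(values) == 1:
        return {"linkage": None, "leaves": [0], "labels": np.array([1])}
    Z = linkage(pdist(values, metric="euclidean"), method="single")
    from scipy.cluster.hierarchy import leaves_list

    out = {"linkage": Z, "leaves": leaves_list(Z).tolist(), "labels": None}
    if n_clusters is not None:
        out["labels"] = fcluster(Z, t=n_clusters, criterion="maxclust")
    return out


def count_single_group_pmns(matrix: pd.DataFrame, tol: float = 0.0) -> int:
    """Number of PMN pairs whose connectivity is confined to exactly one group."""
    values = np.asarray(matrix, dtype=float)
    nonzero = (values > tol).sum(axis=1)
    return int((nonzero == 1).sum())
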