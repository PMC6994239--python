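"""Spatial statistics on synapse point clouds.

Synapse tables are DataFrames with columns ``neuron_id``, ``x_um``, ``y_um``,
``z_um``, ``polarity`` (``pre``/``post``) and ``polyadic_weight`` (>=1; for
presynaptic sites, the number of postsynaptic partners of the synapse). By
convention the z axis is the anteroposterior (AP) axis, x mediolateral (ML)
and y dorsoventral (DV).

The similarity score between two neurons' clouds combines, for every synapse
``s`` of neuron ``i``, the distance to the nearest synapse ``k`` of neuron
``j`` and the agreement of local synapse density around the two sites::

    f(i, j) = mean_s  exp(-d_sk^2 / 2 sigma^2) * exp(-|n_is - n_jk| / (n_is + n_jk))

where ``n_is`` is the fraction of neuron i's synapses within ``omega`` of
``s`` (including ``s`` itself) and ``n_jk`` the analogous fraction for neuron
j at ``k``. The score is directional; a symmetrized matrix averages both
directions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp, pearsonr

from .errors import AlignmentError, EmptyInputError, FormatError, ValidationError

SYNAPSE_COLUMNS = ("neuron_id", "x_um", "y_um", "z_um", "polarity", "polyadic_weight")

AXIS_INDEX = {"ML": 0, "DV": 1, "AP": 2}


def load_synapse_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"neuron_id": str})
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"synapse table missing columns: {missing}")
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    if not np.isfinite(coords).all():
        raise ValidationError("synapse coordinates contain non-finite values")
    if (df["polyadic_weight"] < 1).any():
        raise ValidationError("polyadic_weight must be >= 1")
    return df.reset_index(drop=True)


def rotate_about_ap_axis(table: pd.DataFrame, angle_deg: float = -12.0) -> pd.DataFrame:
    """Rotate the (x, y) coordinates about the z (AP) axis.

    The default -12 degrees compensates the slight roll of the EM volume so
    that cross-sectional (ML/DV) densities line up with anatomical axes.
    """
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    out = table.copy()
    x, y = table["x_um"].to_numpy(float), table["y_um"].to_numpy(float)
    out["x_um"] = c * x - s * y
    out["y_um"] = s * x + c * y
    return out


def axis_kde(
    table: pd.DataFrame,
    axis: str = "ML",
    bandwidth: float = 1.0,
    weighted: bool = False,
    grid_points: int = 512,
    padding_bandwidths: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of synapse positions along one anatomical axis.

    Returns ``(grid, density)``. The grid spans the data range padded by
    ``padding_bandwidths`` bandwidths so that the density integrates to 1
    (within 1e-3) over the grid. With ``weighted=True`` each site counts
    ``polyadic_weight`` times (used for presynaptic sites).
    """
    if axis not in AXIS_INDEX:
        raise ValidationError(f"axis must be one of {sorted(AXIS_INDEX)}")
    if len(table) == 0:
        raise EmptyInputError("cannot build a KDE from an empty synapse table")
    col = ["x_um", "y_um", "z_um"][AXIS_INDEX[axis]]
    x = table[col].to_numpy(float)
    w = (
        table["polyadic_weight"].to_numpy(float)
        if weighted
        else np.ones_like(x)
    )
    w = w / w.sum()
    pad = padding_bandwidths * bandwidth
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_points)
    diff = (grid[:, None] - x[None, :]) / bandwidth
    dens = (w[None, :] * np.exp(-0.5 * diff**2)).sum(axis=1) / (
        bandwidth * np.sqrt(2 * np.pi)
    )
    return grid, dens


def _coords(table: pd.DataFrame) -> np.ndarray:
    return table[["x_um", "y_um", "z_um"]].to_numpy(float)


def synapse_similarity(
    cloud_i: pd.DataFrame,
    cloud_j: pd.DataFrame,
    sigma: float = 2.0,
    omega: float = 2.0,
) -> float:
    """Directional synapse-similarity score f(i -> j) in [0, 1].

    Nearest-neighbor ties are broken by the lowest synapse index of neuron j
    (cKDTree returns the smallest index among equidistant points), making the
    score deterministic.
    """
    if len(cloud_i) == 0 or len(cloud_j) == 0:
        raise EmptyInputError("synapse similarity requires two non-empty clouds")
    xi, xj = _coords(cloud_i), _coords(cloud_j)
    tree_j = cKDTree(xj)
    d, k = tree_j.query(xi, k=1)
    # local fraction of each neuron's synapses within omega (self included)
    tree_i = cKDTree(xi)
    n_is = np.array([len(nb) for nb in tree_i.query_ball_point(xi, omega)]) / len(xi)
    n_j_all = np.array([len(nb) for nb in tree_j.query_ball_point(xj, omega)]) / len(xj)
    n_jk = n_j_all[k]
    scores = np.exp(-(d**2) / (2 * sigma**2)) * np.exp(
        -np.abs(n_is - n_jk) / (n_is + n_jk)
    )
    return float(scores.mean())


def similarity_matrix(
    clouds: dict[str, pd.DataFrame],
    sigma: float = 2.0,
    omega: float = 2.0,
    symmetrize: str = "mean",
) -> pd.DataFrame:
    """All-pairs synapse-similarity matrix over a set of neurons.

    ``symmetrize='mean'`` stores (f(i->j) + f(j->i)) / 2; ``'min'`` the
    element-wise minimum; ``'none'`` the raw directional scores with rows as
    the source neuron.
    """
    if symmetrize not in ("mean", "min", "none"):
        raise ValidationError(f"unknown symmetrize mode {symmetrize!r}")
    empty = [nid for nid, c in clouds.items() if len(c) == 0]
    if empty:
        raise EmptyInputError(f"neurons without synapses: {sorted(empty)}")
    ids = list(clouds)
    n = len(ids)
    mat = np.ones((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            mat[a, b] = synapse_similarity(
                clouds[ids[a]], clouds[ids[b]], sigma=sigma, omega=omega
            )
    if symmetrize == "mean":
        mat = 0.5 * (mat + mat.T)
    elif symmetrize == "min":
        mat = np.minimum(mat, mat.T)
    return pd.DataFrame(mat, index=ids, columns=ids)


def bilateral_average(
    sim_left: pd.DataFrame, sim_right: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Average left/right similarity matrices; report their Pearson r.

    The correlation is computed over off-diagonal upper-triangle entries only
    (the unit diagonal would inflate it).
    """
    if list(sim_left.index) != list(sim_right.index) or list(
        sim_left.columns
    ) != list(sim_right.columns):
        raise AlignmentError("left/right similarity matrices are indexed differently")
    avg = (sim_left + sim_right) / 2.0
    iu = np.triu_indices(len(sim_left), k=1)
    left = sim_left.to_numpy()[iu]
    right = sim_right.to_numpy()[iu]
    if np.std(left) == 0 or np.std(right) == 0:
        r = 1.0 if np.allclose(left, right) else float("nan")
    else:
        r = float(pearsonr(left, right)[0])
    return avg, r


def cluster_by_similarity(matrix: pd.DataFrame, n_clusters: int | None = None) -> dict:
    """Average-linkage hierarchical clustering with distance 1 - similarity."""
    values = np.asarray(matrix, dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(
        values, values.T, atol=1e-10
    ):
        raise ValidationError("similarity matrix must be symmetric; symmetrize first")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    out = {"linkage": Z, "leaves": leaves_list(Z).tolist(), "labels": None}
    if n_clusters is not None:
        out["labels"] = fcluster(Z, t=n_clusters, criterion="maxclust")
    return out


def axis_distribution_test(
    cloud_a: pd.DataFrame,
    cloud_b: pd.DataFrame,
    axis: str = "ML",
    weighted: bool = False,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on one-axis projections.

    With ``weighted=True`` each site is repeated ``polyadic_weight`` times
    before the test. Returns ``(statistic, p_value)`` (asymptotic p).
    """
    if axis not in AXIS_INDEX:
        raise ValidationError(f"axis must be one of {sorted(AXIS_INDEX)}")
    if len(cloud_a) == 0 or len(cloud_b) == 0:
        raise EmptyInputError("both clouds must be non-empty")
    col = ["x_um", "y_um", "z_um"][AXIS_INDEX[axis]]

    def proj(cloud):
        x = cloud[col].to_numpy(float)
        if weighted:
            x = np.repeat(x, cloud["polyadic_weight"].to_numpy(int))
        return x

    res = ks_2samp(proj(cloud_a), proj(cloud_b), method="asymp")
    return float(res.statistic), float(res.pvalue)
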