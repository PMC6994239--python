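"""Muscle calcium-imaging kinetics: alignment, co-activation clustering, and
forward/backward differential recruitment.

Raw input is a long-format trace table with columns ``bout_id``,
``direction`` (``forward``/``backward``), ``muscle``, ``frame``, ``t_s``,
``gcamp``, ``mcherry``. Each bout holds one crawl cycle of two-channel
fluorescence for the subset of body-wall muscles that could be recorded.

The crawl cycle is located by embedding the per-frame muscle activity in two
dimensions with PCA; the cycle appears as a trajectory that leaves and
returns to the origin, and the amplitude peak marks the time when most
muscles are maximally active. The width of that peak at half-height defines
the crawl onset and offset, which are mapped to 25 and 75 on a normalized
0-100 cycle axis. Muscles are then range-normalized and clustered (first
half-cycle only) into co-activated muscle groups (CMUGs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import EmptyInputError, ValidationError

GRID = np.arange(101)  # normalized cycle time 0..100
ONSET_T, OFFSET_T = 25.0, 75.0


def ratiometric_activity(
    gcamp: np.ndarray, mcherry: np.ndarray, smooth_window: int = 3
) -> np.ndarray:
    """GCaMP normalized to mCherry, element-wise.

    The denominator is smoothed with a rolling median (``smooth_window``
    frames) to suppress single-frame dropouts. Samples where the smoothed
    denominator is not strictly positive are masked to NaN with a warning.
    """
    gcamp = np.asarray(gcamp, dtype=float)
    mcherry = np.asarray(mcherry, dtype=float)
    if gcamp.shape != mcherry.shape:
        raise ValidationError("gcamp and mcherry traces differ in length")
    denom = (
        pd.Series(mcherry).rolling(smooth_window, center=True, min_periods=1).median()
    ).to_numpy()
    bad = denom <= 0
    if bad.any():
        warnings.warn(
            f"masking {int(bad.sum())} samples with non-positive mCherry",
            stacklevel=2,
        )
    out = np.full_like(gcamp, np.nan)
    out[~bad] = gcamp[~bad] / denom[~bad]
    return out


def delta_f_over_f(
    trace: np.ndarray,
    event_start_index: int,
    baseline_window_s: float = 1.0,
    frame_rate_hz: float = 10.0,
) -> np.ndarray:
    """(F - F0) / F0 with F0 averaged over ~1 s immediately before the event."""
    trace = np.asarray(trace, dtype=float)
    n_base = max(1, int(round(baseline_window_s * frame_rate_hz)))
    if event_start_index < n_base:
        raise ValidationError(
            f"baseline window of {n_base} frames does not fit before index "
            f"{event_start_index}"
        )
    f0 = trace[event_start_index - n_base : event_start_index].mean()
    if f0 <= 0:
        raise ValidationError(f"baseline F0 = {f0:.4g} is not positive")
    return (trace - f0) / f0


def embed_crawl_pca(
    activity: pd.DataFrame, center: str = "median"
) -> tuple[np.ndarray, np.ndarray]:
    """2D PCA embedding of a bout's frame x muscle activity matrix.

    Rows are frames, columns muscles. Each muscle is centered on its median
    (its quiescent baseline when rest dominates the bout, so the trajectory
    leaves from and returns to the origin over a crawl cycle; ``center='mean'``
    selects classical mean centering). The first two principal components
    give the trajectory; amplitude is Euclidean distance from the origin.
    """
    if activity.shape[1] < 3 or activity.shape[0] < 10:
        raise ValidationError("need >=3 muscles and >=10 frames for PCA embedding")
    if center not in ("median", "mean"):
        raise ValidationError(f"unknown centering {center!r}")
    X = activity.to_numpy(float)
    if center == "median":
        X = X - np.median(X, axis=0, keepdims=True)
    else:
        X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValidationError("activity matrix has no variance")
    # SVD-based PCA; deterministic sign convention (largest-|loading| positive)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    signs = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    traj = (U[:, :2] * S[:2]) * signs[:2]
    amplitude = np.linalg.norm(traj, axis=1)
    return traj, amplitude


def detect_cycle_window(
    amplitude: np.ndarray, floor: float = 1e-9
) -> tuple[int, float, float]:
    """Locate the crawl cycle as the amplitude peak and its half-height width.

    Returns ``(peak_index, onset, offset)`` where onset/offset are fractional
    frame indices of the first half-height crossings moving outward from the
    peak (linear interpolation). Peak ties (plateaus) resolve to the earliest
    frame. Ends of the trace clamp the window when no crossing exists.
    """
    a = np.asarray(amplitude, dtype=float)
    if (a < 0).any():
        raise ValidationError("amplitude trace must be non-negative")
    if a.max() <= floor:
        raise EmptyInputError("amplitude never exceeds the floor; no cycle found")
    peak = int(np.argmax(a))
    half = a[peak] / 2.0

    onset = 0.0
    for i in range(peak, 0, -1):
        if a[i - 1] < half <= a[i]:
            onset = (i - 1) + (half - a[i - 1]) / (a[i] - a[i - 1])
            break
    offset = float(len(a) - 1)
    for i in range(peak, len(a) - 1):
        if a[i] >= half > a[i + 1]:
            offset = i + (a[i] - half) / (a[i] - a[i + 1])
            break
    return peak, onset, offset


@dataclass
class AlignedCycle:
    """One crawl cycle on the normalized 0-100 axis.

    ``traces`` is muscle x grid (101 points); onset maps to 25 and offset to
    75. Each muscle is range-normalized to [0, 1]; muscles with zero range
    are flattened to zero and listed in ``flat_muscles``.
    """

    traces: pd.DataFrame
    peak_index: int
    onset: float
    offset: float
    flat_muscles: list[str] = field(default_factory=list)


def align_and_normalize(
    activity: pd.DataFrame, window: tuple[int, float, float]
) -> AlignedCycle:
    """Resample a bout onto the normalized cycle axis and range-normalize.

    ``activity`` is frames x muscles; ``window`` is the output of
    :func:`detect_cycle_window`. Frame f maps to normalized time
    ``25 + 50 * (f - onset) / (offset - onset)``; the result is linearly
    interpolated onto the integer grid 0..100 with clamped extrapolation.
    """
    peak, onset, offset = window
    if offset <= onset:
        raise ValidationError(f"invalid window: offset {offset} <= onset {onset}")
    frames = np.arange(activity.shape[0], dtype=float)
    norm_t = ONSET_T + (OFFSET_T - ONSET_T) * (frames - onset) / (offset - onset)
    out = {}
    flat = []
    for muscle in activity.columns:
        y = activity[muscle].to_numpy(float)
        resampled = np.interp(GRID, norm_t, y)  # clamps at both ends
        lo, hi = resampled.min(), resampled.max()
        if hi - lo <= 0:
            flat.append(muscle)
            resampled = np.zeros_like(resampled)
        else:
            resampled = (resampled - lo) / (hi - lo)
        out[muscle] = resampled
    traces = pd.DataFrame(out, index=GRID).T
    return AlignedCycle(
        traces=traces, peak_index=peak, onset=onset, offset=offset, flat_muscles=flat
    )


def _gap_statistic(
    X: np.ndarray,
    k_range: range,
    rng: np.random.Generator,
    n_ref: int = 10,
    method: str = "ward",
    metric: str = "euclidean",
) -> int:
    """Tibshirani gap statistic over hierarchical clusterings of X."""

    def within_dispersion(data, labels):
        w = 0.0
        for lab in np.unique(labels):
            pts = data[labels == lab]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        return w

    def cluster_labels(data, k):
        Z = linkage(data, method=method, metric=metric)
        return fcluster(Z, t=k, criterion="maxclust")

    # reference distribution: uniform over the data's bounding box in its
    # principal-component basis (Tibshirani's recommended null)
    mu_ = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - mu_, full_matrices=False)
    Xp = (X - mu_) @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    gaps, sks = [], []
    for k in k_range:
        logW = np.log(within_dispersion(X, cluster_labels(X, k)) + 1e-300)
        ref_logW = []
        for _ in range(n_ref):
            ref = rng.uniform(lo, hi, size=Xp.shape) @ Vt + mu_
            ref_logW.append(
                np.log(within_dispersion(ref, cluster_labels(ref, k)) + 1e-300)
            )
        gaps.append(np.mean(ref_logW) - logW)
        sks.append(np.std(ref_logW) * np.sqrt(1 + 1 / n_ref))
    # Tibshirani rule: smallest k whose gap is within one reference-sd of the
    # next k's gap
    ks = list(k_range)
    for i in range(len(ks) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return ks[i]
    return ks[-1]


@dataclass
class CoactiveAssignment:
    """Muscle -> CMUG labels with the linkage behind them.

    Groups are numbered 1..k by ascending mean onset time of their muscles
    (group 1 contains the earliest-activating muscles).
    """

    labels: dict[str, int]
    n_clusters: int
    linkage: np.ndarray
    onset_times: pd.Series


def _muscle_onsets(mean_traces: pd.DataFrame, level: float = 0.5) -> pd.Series:
    """First grid time at which each (range-normalized) trace reaches ``level``."""
    onsets = {}
    for muscle, row in mean_traces.iterrows():
        above = np.nonzero(row.to_numpy() >= level)[0]
        onsets[muscle] = float(above[0]) if len(above) else float(GRID[-1])
    return pd.Series(onsets)


def cluster_coactive(
    mean_traces: pd.DataFrame,
    n_clusters: int | None = 4,
    method: str = "ward",
    metric: str = "euclidean",
    seed: int = 0,
) -> CoactiveAssignment:
    """Cluster muscles into co-activated groups from their mean cycle traces.

    Only the first half of the cycle (normalized time 0-50) enters the
    clustering, because group identity is carried by activation onset while
    offsets are less coherent. ``n_clusters=None`` selects k in 2..8 by the
    gap statistic; the default of 4 reflects the observed number of CMUGs per
    direction.
    """
    if len(mean_traces) < 2:
        raise EmptyInputError("need at least two muscles to cluster")
    first_half = mean_traces.loc[:, mean_traces.columns <= 50]
    X = first_half.to_numpy(float)
    if np.allclose(X - X[0], 0):
        warnings.warn("all traces identical; returning a single cluster", stacklevel=2)
        Z = linkage(X, method=method, metric=metric)
        labels = {m: 1 for m in mean_traces.index}
        return CoactiveAssignment(labels, 1, Z, _muscle_onsets(mean_traces))
    if n_clusters is None:
        rng = np.random.default_rng(seed)
        k_max = min(8, len(mean_traces) - 1)
        n_clusters = _gap_statistic(X, range(2, k_max + 1), rng, method=method)
    Z = linkage(X, method=method, metric=metric)
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    onsets = _muscle_onsets(mean_traces)
    # relabel groups 1..k by ascending mean onset
    order = sorted(
        np.unique(raw), key=lambda lab: onsets[mean_traces.index[raw == lab]].mean()
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = {m: remap[r] for m, r in zip(mean_traces.index, raw)}
    return CoactiveAssignment(labels, int(n_clusters), Z, onsets)


def differential_recruitment(
    fwd_traces: pd.DataFrame, bwd_traces: pd.DataFrame, t: float = ONSET_T
) -> pd.Series:
    """Per-muscle forward-vs-backward recruitment-timing score.

    At the crawl onset (normalized t = 25), a muscle recruited earlier than
    the population shows higher activity than the population mean. The score
    is the double difference::

        score(m) = [x_fwd_m(25) - mean_fwd(25)] - [x_bwd_m(25) - mean_bwd(25)]

    Positive values mean the muscle is recruited earlier during forward
    crawling, negative earlier during backward crawling. Muscles missing in
    one direction are excluded with a warning.
    """
    col = int(t)
    common = fwd_traces.index.intersection(bwd_traces.index)
    missing = fwd_traces.index.symmetric_difference(bwd_traces.index)
    if len(missing):
        warnings.warn(
            f"excluding {len(missing)} muscles present in only one direction: "
            f"{sorted(map(str, missing))}",
            stacklevel=2,
        )
    if len(common) == 0:
        raise EmptyInputError("no muscles present in both directions")
    f = fwd_traces.loc[:, col]
    b = bwd_traces.loc[:, col]
    score = (f.loc[common] - f.mean()) - (b.loc[common] - b.mean())
    return score


def process_bout(
    bout: pd.DataFrame, smooth_window: int = 3
) -> AlignedCycle:
    """Run one bout through ratiometric normalization, PCA alignment and
    cycle normalization."""
    gcamp = bout.pivot_table(index="frame", columns="muscle", values="gcamp")
    mcherry = bout.pivot_table(index="frame", columns="muscle", values="mcherry")
    activity = pd.DataFrame(
        {
            m: ratiometric_activity(
                gcamp[m].to_numpy(), mcherry[m].to_numpy(), smooth_window
            )
            for m in gcamp.columns
        },
        index=gcamp.index,
    )
    _, amplitude = embed_crawl_pca(activity)
    window = detect_cycle_window(amplitude)
    return align_and_normalize(activity, window)


def mean_aligned_traces(bouts: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Mean normalized cycle per muscle, pooled over all bouts of a direction."""
    sub = bouts.loc[bouts["direction"] == direction]
    if len(sub) == 0:
        raise EmptyInputError(f"no bouts with direction {direction!r}")
    cycles = [process_bout(b) for _, b in sub.groupby("bout_id", sort=True)]
    stacked = pd.concat([c.traces for c in cycles])
    return stacked.groupby(stacked.index).mean().sort_index()
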