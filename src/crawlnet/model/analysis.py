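"""Evaluation of trained models: normalized time courses, CMUG activation
order, ensembles, and checkpoint I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import EmptyInputError, ValidationError
from .network import ModelParameters, TwoSegmentNetwork, simulate
from .targets import TargetPattern, TrialSpec, command_input, generate_targets
from .training import (
    TrainingConfig,
    TrainingResult,
    optimize,
    trial_cost_and_grads,
    weight_correlation,
)


def normalized_time_course(
    traces: np.ndarray,
    mn_rates: np.ndarray,
    grid: np.ndarray | None = None,
    onset_level: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample traces on an axis normalized to a segment's MN activity.

    The segment's MN onset/offset are the first/last bins where the summed MN
    rate exceeds ``onset_level`` of its peak; they map to 0 and 1. ``traces``
    is (n_bins, n_units) and ``mn_rates`` (n_bins, n_mn_of_segment). Returns
    ``(normalized_grid, resampled traces)``.
    """
    summed = np.asarray(mn_rates).sum(axis=1)
    peak = summed.max()
    if peak <= 0:
        raise EmptyInputError("no suprathreshold MN activity in the segment")
    above = np.nonzero(summed >= onset_level * peak)[0]
    onset, offset = above[0], above[-1]
    if offset <= onset:
        raise ValidationError("degenerate MN activity window")
    if grid is None:
        grid = np.linspace(-0.25, 1.25, 151)
    tnorm = (np.arange(len(summed)) - onset) / (offset - onset)
    out = np.stack(
        [np.interp(grid, tnorm, traces[:, i]) for i in range(traces.shape[1])],
        axis=1,
    )
    return grid, out


def cmug_onset_order(
    m: np.ndarray,
    target: TargetPattern,
    level: float = 0.5,
) -> dict[int, list[int]]:
    """Observed CMUG activation order per segment, from simulated MN rates.

    For each segment, each CMUG's onset is the first bin where its mean MN
    rate crosses ``level`` of its own peak; groups are returned in ascending
    onset order. Raises if a group never activates.
    """
    order: dict[int, list[int]] = {}
    for seg in (0, 1):
        onsets = {}
        for g in np.unique(target.cmug_of):
            sel = (target.cmug_of == g) & (target.segment_of == seg)
            trace = m[:, sel].mean(axis=1)
            peak = trace.max()
            if peak <= 0:
                raise EmptyInputError(f"CMUG {g} of segment {seg} never activates")
            onsets[int(g)] = int(np.nonzero(trace >= level * peak)[0][0])
        order[seg] = sorted(onsets, key=lambda g: (onsets[g], g))
    return order


def segment_onset_lag(m: np.ndarray, target: TargetPattern, level: float = 0.1) -> int:
    """Bins by which segment A2's summed MN activity leads (+) or lags (-) A1."""
    onsets = []
    for seg in (0, 1):
        trace = m[:, target.segment_of == seg].sum(axis=1)
        peak = trace.max()
        if peak <= 0:
            raise EmptyInputError(f"segment {seg} MNs never activate")
        onsets.append(int(np.nonzero(trace >= level * peak)[0][0]))
    return onsets[0] - onsets[1]


@dataclass
class EnsembleSummary:
    results: list[TrainingResult]
    diverged_seeds: list[int]
    final_c_targ_norm: np.ndarray
    r_jm: np.ndarray
    r_jp: np.ndarray

    @property
    def n_models(self) -> int:
        return len(self.results)


def run_ensemble(
    net: TwoSegmentNetwork,
    seeds: list[int],
    trial: TrialSpec = TrialSpec(),
    config: TrainingConfig = TrainingConfig(),
    selectivity_enabled: bool | None = None,
) -> EnsembleSummary:
    """Train independently initialized models, one per seed.

    Diverged members are excluded and flagged. ``selectivity_enabled=False``
    runs the ablation without the A18b/A27h penalty.
    """
    if len(seeds) < 2:
        raise ValidationError("an ensemble needs >=2 seeds")
    results, diverged = [], []
    for seed in seeds:
        cfg = TrainingConfig(**{**vars(config), "seed": seed})
        if selectivity_enabled is not None:
            cfg.selectivity_enabled = selectivity_enabled
        res = optimize(net, trial, cfg)
        if res.diverged:
            diverged.append(seed)
        else:
            results.append(res)
    jp0 = net.struct_p.matrix(net.wp0)
    jm0 = net.struct_m.matrix(net.wm0)
    r_jm = np.array(
        [weight_correlation(net.struct_m.matrix(r.params.wm), jm0) for r in results]
    )
    r_jp = np.array(
        [weight_correlation(net.struct_p.matrix(r.params.wp), jp0) for r in results]
    )
    final = np.array(
        [r.history["c_targ_norm"].iloc[-1] for r in results]
    )
    return EnsembleSummary(
        results=results,
        diverged_seeds=diverged,
        final_c_targ_norm=final,
        r_jm=r_jm,
        r_jp=r_jp,
    )


def evaluate_trial(
    params: ModelParameters,
    net: TwoSegmentNetwork,
    direction: str,
    trial: TrialSpec = TrialSpec(),
    seed: int = 0,
    alpha: float = 0.1,
    config: TrainingConfig = TrainingConfig(),
):
    """Simulate one trial with trained parameters; returns (p, m, target, costs)."""
    cmug = net.cmug_fwd if direction == "forward" else net.cmug_bwd
    target = generate_targets(cmug, net.mn_segment_of, direction, trial)
    rng = np.random.default_rng(seed)
    u0 = net.initial_state(rng)
    amps = params.i_fwd if direction == "forward" else params.i_bwd
    I = command_input(amps, target)
    p, m, _, _ = simulate(params, net, I, u0, dt=trial.dt_s)
    costs, _ = trial_cost_and_grads(
        params, net, target, u0, alpha, config, with_grads=False
    )
    return p, m, target, costs


def save_checkpoint(path, params: ModelParameters, net: TwoSegmentNetwork, **attrs):
    """Write parameters and structure to an HDF5 checkpoint."""
    import h5py

    with h5py.File(path, "w") as f:
        for k in vars(params):
            f.create_dataset(f"params/{k}", data=getattr(params, k))
        for tag, s in (("p", net.struct_p), ("m", net.struct_m)):
            for k in ("rows", "cols", "pidx", "sign", "constrained"):
                f.create_dataset(f"struct_{tag}/{k}", data=getattr(s, k))
        f.create_dataset("wp0", data=net.wp0)
        f.create_dataset("wm0", data=net.wm0)
        for k, v in attrs.items():
            f.attrs[k] = v


def load_checkpoint(path) -> ModelParameters:
    import h5py

    with h5py.File(path, "r") as f:
        return ModelParameters(**{k: f[f"params/{k}"][()] for k in f["params"]})
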