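"""Constrained optimization of the two-segment model.

Gradients are obtained by backpropagation through the unrolled forward-Euler
simulation, derived by hand (the adjoint recursion below), and the total
cost is minimized with RMSProp for 1000 epochs. The cost is

    C = C_targ + C_A18b,A27h + C_seg + C_J

* ``C_targ``   -- weighted squared deviation of MN rates from their targets,
  with per-MN weights proportional to 1 / (CMUG size), normalized to sum 1.
* ``C_A18b,A27h`` -- 0.05 times the summed activity of the backward-specific
  PMN A18b during forward trials and of the forward-specific A27h during
  backward trials.
* ``C_seg``    -- alignment of the two segments' PMN activity at the
  intersegmental lag (zero-padded outside the trial), weighted by a factor
  alpha_n that grows quadratically from 0 to 0.1 over training.
* ``C_J``      -- alpha_n-weighted squared deviation of Jp and Jm from their
  connectome-derived initial values.

Each epoch averages the costs of one forward and one backward trial. Hard
constraints (tau in [50 ms, 1 s], positive gains, fixed signs, fixed
sparsity) are enforced by projection after every update; the sparsity and
sign structure live in the weight parameterization itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import DivergenceError, ValidationError
from .network import (
    TAU_MAX,
    TAU_MIN,
    ModelParameters,
    TwoSegmentNetwork,
    simulate,
)
from .targets import SEG_A1, TargetPattern, TrialSpec, command_input, generate_targets

PARAM_KEYS = ("wp", "wm", "gp", "gm", "bp", "bm", "taup", "taum", "i_fwd", "i_bwd")


def lr_schedule(epoch: int, n_epochs: int = 1000) -> float:
    """Learning rate decaying logarithmically from 1e-2 to 1e-3."""
    if not 0 <= epoch <= n_epochs:
        raise ValidationError(f"epoch {epoch} outside [0, {n_epochs}]")
    return 10.0 ** (-2.0 - epoch / n_epochs)


def alpha_schedule(epoch: int, n_epochs: int = 1000, alpha_max: float = 0.1) -> float:
    """Regularization weight growing quadratically from 0 to ``alpha_max``."""
    if not 0 <= epoch <= n_epochs:
        raise ValidationError(f"epoch {epoch} outside [0, {n_epochs}]")
    return alpha_max * (epoch / n_epochs) ** 2


@dataclass
class TrainingConfig:
    epochs: int = 1000
    selectivity_coeff: float = 0.05
    selectivity_enabled: bool = True
    alpha_max: float = 0.1
    rmsprop_rho: float = 0.99
    rmsprop_eps: float = 1e-2
    gain_floor: float = 1e-6
    seed: int = 0
    dt: float = 0.05


def _seg_slices(net: TwoSegmentNetwork) -> tuple[slice, slice]:
    nP = net.n_pmn_per_seg
    return slice(0, nP), slice(nP, 2 * nP)


def _seg_delay_bins(direction: str, trial: TrialSpec) -> int:
    """Bin shift d such that p_A1(t) is compared with p_A2(t - d).

    Forward waves run posterior->anterior: A1 lags A2 by the intersegmental
    delay, so d = +delay; backward waves reverse the sign.
    """
    d = int(round(trial.interseg_delay_s / trial.dt_s))
    return d if direction == "forward" else -d


def trial_cost_and_grads(
    params: ModelParameters,
    net: TwoSegmentNetwork,
    target: TargetPattern,
    u_p0: np.ndarray,
    alpha: float,
    config: TrainingConfig = TrainingConfig(),
    with_grads: bool = True,
):
    """Costs (and, optionally, exact gradients) of one trial.

    Returns ``(costs, grads)`` where ``costs`` has keys ``c_targ``,
    ``c_targ_norm``, ``c_sel``, ``c_seg`` and ``grads`` maps parameter names
    to arrays (or is None). ``C_J`` is epoch-level and handled by the caller.
    """
    trial = target.trial
    dt = trial.dt_s
    direction = target.direction
    amps = params.i_fwd if direction == "forward" else params.i_bwd
    I = command_input(amps, target)
    p, m, u_p, u_m = simulate(params, net, I, u_p0, dt=dt)
    T = trial.n_bins

    w = target.weights
    dev = m - target.m_star.T  # (T, nM)
    c_targ = float((w[None, :] * dev**2).sum())
    norm = float((w[None, :] * target.m_star.T**2).sum())
    c_targ_norm = c_targ / norm if norm > 0 else np.nan

    # selectivity: suppress A18b during FWD trials, A27h during BWD trials
    sel_units = net.a18b_units if direction == "forward" else net.a27h_units
    if config.selectivity_enabled and len(sel_units):
        c_sel = config.selectivity_coeff * float(p[:, sel_units].sum())
    else:
        c_sel = 0.0
        sel_units = np.array([], dtype=int)

    # segment alignment over segment A1's active window
    sl1, sl2 = _seg_slices(net)
    d = _seg_delay_bins(direction, trial)
    on, off = trial.segment_window(target.n_groups, SEG_A1, direction)
    t_centers = trial.bin_centers
    active = np.nonzero((t_centers >= on) & (t_centers <= off))[0]
    active = active[(active - d >= 0) & (active - d < T)]  # zero-padding
    delta = p[active, sl1] - p[active - d, sl2]
    c_seg = alpha * float((delta**2).sum())

    costs = {
        "c_targ": c_targ,
        "c_targ_norm": c_targ_norm,
        "c_sel": c_sel,
        "c_seg": c_seg,
    }
    if not with_grads:
        return costs, None

    # ----- adjoint (backprop-through-time) pass -----------------------------
    Jp = net.struct_p.matrix(params.wp)
    Jm = net.struct_m.matrix(params.wm)
    ap = dt / params.taup
    am = dt / params.taum
    hp = (u_p > 0).astype(float)  # relu' with subgradient 0 at 0
    hm = (u_m > 0).astype(float)

    # direct cost derivatives w.r.t. rates
    dC_dm = 2.0 * w[None, :] * dev
    dC_dp = np.zeros_like(p)
    if len(sel_units):
        dC_dp[:, sel_units] += config.selectivity_coeff
    dC_dp[active, sl1] += 2.0 * alpha * delta
    dC_dp[active - d, sl2] -= 2.0 * alpha * delta

    lam = np.zeros_like(u_p)  # dC/du_p
    mu = np.zeros_like(u_m)  # dC/du_m
    lam[T - 1] = dC_dp[T - 1] * hp[T - 1]
    mu[T - 1] = dC_dm[T - 1] * hm[T - 1]
    apgp = ap * params.gp
    amgm = am * params.gm
    JpT, JmT = Jp.T, Jm.T
    for t in range(T - 2, -1, -1):
        mu[t] = dC_dm[t] * hm[t] + (1.0 - am) * mu[t + 1]
        lam[t] = (
            dC_dp[t] * hp[t]
            + (1.0 - ap) * lam[t + 1]
            + hp[t] * (JpT @ (apgp * lam[t + 1]) + JmT @ (amgm * mu[t + 1]))
        )

    R = p[:-1]  # presynaptic rates driving each update
    Lam = lam[1:]
    Mu = mu[1:]
    pre_p = R @ JpT  # (T-1, nP): Jp r_t
    pre_m = R @ JmT
    drive_p = -u_p[:-1] + params.gp * pre_p + params.bp + I[:-1]
    drive_m = -u_m[:-1] + params.gm * pre_m + params.bm

    dJp = (apgp * Lam).T @ R
    dJm = (amgm * Mu).T @ R
    grads = {
        "wp": net.struct_p.grad_params(dJp),
        "wm": net.struct_m.grad_params(dJm),
        "gp": ap * (Lam * pre_p).sum(axis=0),
        "gm": am * (Mu * pre_m).sum(axis=0),
        "bp": ap * Lam.sum(axis=0),
        "bm": am * Mu.sum(axis=0),
        "taup": (-dt / params.taup**2) * (Lam * drive_p).sum(axis=0),
        "taum": (-dt / params.taum**2) * (Mu * drive_m).sum(axis=0),
    }
    c_on, c_off = target.command_window
    gate = ((t_centers >= c_on) & (t_centers <= c_off))[:-1]
    dAmp = ap * (Lam * gate[:, None]).sum(axis=0)
    if direction == "forward":
        grads["i_fwd"], grads["i_bwd"] = dAmp, np.zeros_like(dAmp)
    else:
        grads["i_fwd"], grads["i_bwd"] = np.zeros_like(dAmp), dAmp
    return costs, grads


def cost_j(params: ModelParameters, net: TwoSegmentNetwork, alpha: float) -> float:
    dJp = net.struct_p.matrix(params.wp) - net.struct_p.matrix(net.wp0)
    dJm = net.struct_m.matrix(params.wm) - net.struct_m.matrix(net.wm0)
    return alpha * float((dJp**2).sum() + (dJm**2).sum())


def cost_j_grads(
    params: ModelParameters, net: TwoSegmentNetwork, alpha: float
) -> dict[str, np.ndarray]:
    dJp = net.struct_p.matrix(params.wp) - net.struct_p.matrix(net.wp0)
    dJm = net.struct_m.matrix(params.wm) - net.struct_m.matrix(net.wm0)
    return {
        "wp": net.struct_p.grad_params(2.0 * alpha * dJp),
        "wm": net.struct_m.grad_params(2.0 * alpha * dJm),
    }


@dataclass
class TrainingResult:
    params: ModelParameters
    history: pd.DataFrame
    net: TwoSegmentNetwork
    seed: int
    diverged: bool = False
    config: TrainingConfig = field(default_factory=TrainingConfig)


def optimize(
    net: TwoSegmentNetwork,
    trial: TrialSpec = TrialSpec(),
    config: TrainingConfig = TrainingConfig(),
    params0: ModelParameters | None = None,
    check_constraints_every: int | None = None,
) -> TrainingResult:
    """Train one model with RMSProp under projection constraints.

    Every epoch simulates one forward and one backward trial (fresh random
    initial PMN state each), averages their costs and gradients, adds the
    ``C_J`` pull toward the connectome weights, takes an RMSProp step, and
    projects: tau clipped to [50 ms, 1 s], gains clipped positive,
    sign-constrained magnitudes clipped nonnegative.
    """
    rng = np.random.default_rng(config.seed)
    params = params0.copy() if params0 is not None else net.initial_parameters(rng)
    tgt_f = generate_targets(net.cmug_fwd, net.mn_segment_of, "forward", trial)
    tgt_b = generate_targets(net.cmug_bwd, net.mn_segment_of, "backward", trial)

    v = {k: np.zeros_like(getattr(params, k)) for k in PARAM_KEYS}
    rows = []
    diverged = False
    for epoch in range(config.epochs):
        alpha = alpha_schedule(epoch, config.epochs, config.alpha_max)
        lr = lr_schedule(epoch, config.epochs)
        grads_sum = {k: np.zeros_like(getattr(params, k)) for k in PARAM_KEYS}
        costs_epoch = {"c_targ": 0.0, "c_targ_norm": 0.0, "c_sel": 0.0, "c_seg": 0.0}
        try:
            for tgt in (tgt_f, tgt_b):
                u0 = net.initial_state(rng)
                costs, grads = trial_cost_and_grads(
                    params, net, tgt, u0, alpha, config
                )
                for k in PARAM_KEYS:
                    grads_sum[k] += 0.5 * grads[k]
                for k in costs_epoch:
                    costs_epoch[k] += 0.5 * costs[k]
            cj = cost_j(params, net, alpha)
            for k, gj in cost_j_grads(params, net, alpha).items():
                grads_sum[k] += gj
        except DivergenceError:
            diverged = True
            break

        total = sum(costs_epoch[k] for k in ("c_targ", "c_sel", "c_seg")) + cj
        if not np.isfinite(total):
            diverged = True
            break
        rows.append(
            {"epoch": epoch, **costs_epoch, "c_j": cj, "total": total, "lr": lr}
        )

        for k in PARAM_KEYS:
            g = grads_sum[k]
            v[k] = config.rmsprop_rho * v[k] + (1 - config.rmsprop_rho) * g**2
            step = lr * g / (np.sqrt(v[k]) + config.rmsprop_eps)
            setattr(params, k, getattr(params, k) - step)

        # projections: exact constraint satisfaction after every update
        params.wp = net.struct_p.project(params.wp)
        params.wm = net.struct_m.project(params.wm)
        params.taup = np.clip(params.taup, TAU_MIN, TAU_MAX)
        params.taum = np.clip(params.taum, TAU_MIN, TAU_MAX)
        params.gp = np.maximum(params.gp, config.gain_floor)
        params.gm = np.maximum(params.gm, config.gain_floor)
        if check_constraints_every and (epoch + 1) % check_constraints_every == 0:
            params.check(net.struct_p, net.struct_m)

    history = pd.DataFrame(rows)
    return TrainingResult(
        params=params,
        history=history,
        net=net,
        seed=config.seed,
        diverged=diverged,
        config=config,
    )


def weight_correlation(J_trained: np.ndarray, J0: np.ndarray) -> float:
    """Pearson r between |weights| on the shared nonzero support of J0."""
    mask = J0 != 0
    if mask.sum() < 3:
        raise ValidationError("need >=3 nonzero entries for a correlation")
    a = np.abs(J_trained[mask])
    b = np.abs(J0[mask])
    if a.std() == 0 or b.std() == 0:
        return 1.0 if np.allclose(a / max(a.max(), 1e-300), b / max(b.max(), 1e-300)) else np.nan
    return float(np.corrcoef(a, b)[0, 1])
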