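"""Network structure, parameters and forward simulation of the rate model.

PMN and MN firing rates are rectified-linear functions of their inputs,
integrated with forward Euler at the trial bin width (50 ms)::

    tau_p * du_p/dt = -u_p + g_p * (Jp [u_p]_+) + b_p + I(t)
    tau_m * du_m/dt = -u_m + g_m * (Jm [u_p]_+) + b_m

The zero-structure of Jp (PMN->PMN) and Jm (PMN->MN) is fixed to the
connectome sparsity pattern. Each nonzero weight is a parameter ``w`` with a
fixed sign factor: sign-constrained weights (known transmitter) store a
nonnegative magnitude with sign +/-1, and free weights (unknown transmitter)
store a raw value initialized inhibitory. Within-segment weights are shared
(tied) between the two diagonal blocks, reflecting identical within-segment
wiring of the duplicated segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DivergenceError, ValidationError

TAU_MIN, TAU_MAX = 0.05, 1.0


@dataclass
class WeightStructure:
    """Placement of one weight matrix's nonzero entries.

    ``rows``/``cols``/``pidx`` give, per placement, the matrix position and
    the index into the parameter vector; tied placements share a ``pidx``.
    ``sign`` is the fixed +/-1 factor per placement and ``constrained`` marks
    parameters whose magnitude is projected to be nonnegative.
    """

    shape: tuple[int, int]
    rows: np.ndarray
    cols: np.ndarray
    pidx: np.ndarray
    sign: np.ndarray
    constrained: np.ndarray  # per parameter, not per placement
    n_params: int

    def matrix(self, w: np.ndarray) -> np.ndarray:
        J = np.zeros(self.shape)
        J[self.rows, self.cols] = self.sign * w[self.pidx]
        return J

    def grad_params(self, dJ: np.ndarray) -> np.ndarray:
        dw = np.zeros(self.n_params)
        np.add.at(dw, self.pidx, self.sign * dJ[self.rows, self.cols])
        return dw

    def project(self, w: np.ndarray) -> np.ndarray:
        out = w.copy()
        out[self.constrained] = np.maximum(out[self.constrained], 0.0)
        return out


@dataclass
class ModelParameters:
    """All trainable quantities of the two-segment model."""

    wp: np.ndarray  # Jp nonzero parameters
    wm: np.ndarray  # Jm nonzero parameters
    gp: np.ndarray
    gm: np.ndarray
    bp: np.ndarray
    bm: np.ndarray
    taup: np.ndarray
    taum: np.ndarray
    i_fwd: np.ndarray
    i_bwd: np.ndarray

    def copy(self) -> "ModelParameters":
        return ModelParameters(**{k: v.copy() for k, v in vars(self).items()})

    def check(self, struct_p: WeightStructure, struct_m: WeightStructure) -> None:
        """Assert every hard constraint; raises ValidationError on violation."""
        if not ((self.taup >= TAU_MIN - 1e-12).all() and (self.taup <= TAU_MAX + 1e-12).all()):
            raise ValidationError("taup out of [50 ms, 1 s]")
        if not ((self.taum >= TAU_MIN - 1e-12).all() and (self.taum <= TAU_MAX + 1e-12).all()):
            raise ValidationError("taum out of [50 ms, 1 s]")
        if (self.gp <= 0).any() or (self.gm <= 0).any():
            raise ValidationError("gains must be positive")
        if (self.wp[struct_p.constrained] < 0).any():
            raise ValidationError("sign-constrained Jp magnitude went negative")
        if (self.wm[struct_m.constrained] < 0).any():
            raise ValidationError("sign-constrained Jm magnitude went negative")


@dataclass
class TwoSegmentNetwork:
    """Index bookkeeping for the duplicated-segment network.

    Unit order is [segment A1 units..., segment A2 units...] for both PMNs
    and MNs; within a segment, units follow ``pmn_pairs`` / ``mn_pairs``
    (bilateral pairs, left/right pooled).
    """

    pmn_pairs: list[str]
    mn_pairs: list[str]
    struct_p: WeightStructure
    struct_m: WeightStructure
    wp0: np.ndarray
    wm0: np.ndarray
    cmug_fwd: np.ndarray  # per MN unit (both segments), 0-indexed groups
    cmug_bwd: np.ndarray
    a27h_units: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    a18b_units: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_pmn_per_seg(self) -> int:
        return len(self.pmn_pairs)

    @property
    def n_mn_per_seg(self) -> int:
        return len(self.mn_pairs)

    @property
    def n_pmn(self) -> int:
        return 2 * len(self.pmn_pairs)

    @property
    def n_mn(self) -> int:
        return 2 * len(self.mn_pairs)

    @property
    def pmn_segment_of(self) -> np.ndarray:
        return np.repeat([0, 1], self.n_pmn_per_seg)

    @property
    def mn_segment_of(self) -> np.ndarray:
        return np.repeat([0, 1], self.n_mn_per_seg)

    def initial_parameters(self, rng: np.random.Generator) -> ModelParameters:
        """Initialization: b_p=0.1, b_m=0, tau=200 ms, g=1, command
        amplitudes uniform in [0.05, 0.15], weights at the connectome-derived
        values."""
        nP, nM = self.n_pmn, self.n_mn
        return ModelParameters(
            wp=self.wp0.copy(),
            wm=self.wm0.copy(),
            gp=np.ones(nP),
            gm=np.ones(nM),
            bp=np.full(nP, 0.1),
            bm=np.zeros(nM),
            taup=np.full(nP, 0.2),
            taum=np.full(nM, 0.2),
            i_fwd=rng.uniform(0.05, 0.15, nP),
            i_bwd=rng.uniform(0.05, 0.15, nP),
        )

    def initial_state(self, rng: np.random.Generator, sd: float = 0.1) -> np.ndarray:
        """u_p(0): zero-truncated Gaussian with the given sd (u_m starts at 0)."""
        return np.abs(rng.normal(0.0, sd, self.n_pmn))


def simulate(
    params: ModelParameters,
    net: TwoSegmentNetwork,
    I: np.ndarray,
    u_p0: np.ndarray,
    dt: float = 0.05,
    return_inputs: bool = False,
):
    """Forward-Euler integration of the rate dynamics.

    ``I`` is (n_bins, n_pmn). Rates are recorded at every bin; the state at
    bin t is the result of t Euler updates from the initial condition.
    Returns ``(p, m, u_p, u_m)`` each with shape (n_bins, n_units).
    """
    T = I.shape[0]
    Jp = net.struct_p.matrix(params.wp)
    Jm = net.struct_m.matrix(params.wm)
    ap = dt / params.taup
    am = dt / params.taum
    u_p = np.empty((T, net.n_pmn))
    u_m = np.empty((T, net.n_mn))
    u_p[0] = u_p0
    u_m[0] = 0.0
    for t in range(T - 1):
        p_t = np.maximum(u_p[t], 0.0)
        drive_p = Jp @ p_t
        drive_m = Jm @ p_t
        u_p[t + 1] = u_p[t] + ap * (
            -u_p[t] + params.gp * drive_p + params.bp + I[t]
        )
        u_m[t + 1] = u_m[t] + am * (-u_m[t] + params.gm * drive_m + params.bm)
    if not (np.isfinite(u_p).all() and np.isfinite(u_m).all()):
        raise DivergenceError("simulation produced non-finite state")
    p = np.maximum(u_p, 0.0)
    m = np.maximum(u_m, 0.0)
    return p, m, u_p, u_m
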