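"""Trial layout and motor-neuron target patterns for the two-segment model.

A trial is 6 s discretized into 50 ms bins. It contains one peristaltic
sequence of co-activated muscle group (CMUG) activation in each of the two
modeled segments, with a 1 s inter-segmental delay, and begins/ends with
1 s / 1.5 s of quiescence. During forward crawling the posterior segment
(A2) activates first; during backward crawling the anterior segment (A1)
leads.

Within a segment the first CMUG is active for 2 s; subsequent CMUGs start
with a 0.25 s delay between groups and end with a 0.125 s delay between
groups. Each MN's target is a rectified-cosine (half-sine) pulse of unit
amplitude over its CMUG's window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError

SEG_A1, SEG_A2 = 0, 1  # anterior, posterior


@dataclass(frozen=True)
class TrialSpec:
    """Timing layout of one 6 s training trial."""

    duration_s: float = 6.0
    dt_s: float = 0.05
    quiescence_head_s: float = 1.0
    quiescence_tail_s: float = 1.5
    first_group_duration_s: float = 2.0
    onset_stagger_s: float = 0.25
    offset_stagger_s: float = 0.125
    interseg_delay_s: float = 1.0
    pulse_amplitude: float = 1.0

    @property
    def n_bins(self) -> int:
        return int(round(self.duration_s / self.dt_s))

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.dt_s

    def segment_start(self, segment: int, direction: str) -> float:
        """Start of CMUG activity in a segment (0=A1 anterior, 1=A2 posterior).

        Forward waves propagate posterior -> anterior, so A2 leads; backward
        waves propagate anterior -> posterior, so A1 leads.
        """
        if direction not in ("forward", "backward"):
            raise ValidationError(f"unknown direction {direction!r}")
        leads = SEG_A2 if direction == "forward" else SEG_A1
        lag = 0.0 if segment == leads else self.interseg_delay_s
        return self.quiescence_head_s + lag

    def group_window(
        self, group: int, n_groups: int, segment: int, direction: str
    ) -> tuple[float, float]:
        """(onset, offset) in seconds of CMUG ``group`` (0-indexed)."""
        t0 = self.segment_start(segment, direction)
        on = t0 + self.onset_stagger_s * group
        off = t0 + self.first_group_duration_s + self.offset_stagger_s * group
        if off > self.duration_s - self.quiescence_tail_s + 1e-9:
            raise ValidationError(
                f"CMUG {group} window [{on}, {off}] exceeds the active span of "
                f"a {self.duration_s} s trial"
            )
        return on, off

    def segment_window(
        self, n_groups: int, segment: int, direction: str
    ) -> tuple[float, float]:
        """Union of all CMUG windows in one segment."""
        on, _ = self.group_window(0, n_groups, segment, direction)
        _, off = self.group_window(n_groups - 1, n_groups, segment, direction)
        return on, off


def rectified_cosine_pulse(
    t: np.ndarray, on: float, off: float, amplitude: float = 1.0
) -> np.ndarray:
    """Half-sine bump of the given amplitude over [on, off], zero outside."""
    phase = (t - on) / (off - on)
    return amplitude * np.where(
        (phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0
    )


@dataclass
class TargetPattern:
    """Per-MN target rates and CMUG bookkeeping for one trial.

    ``m_star`` is (n_mn_total, n_bins); ``weights`` sums to 1 over MNs and is
    proportional to 1 / (CMUG size), so small groups still shape the cost.
    """

    m_star: np.ndarray
    weights: np.ndarray
    cmug_of: np.ndarray  # group index per MN unit
    segment_of: np.ndarray  # 0 (A1) or 1 (A2) per MN unit
    direction: str
    trial: TrialSpec
    n_groups: int

    @property
    def command_window(self) -> tuple[float, float]:
        """Default drive window: first target onset to last target offset."""
        ons, offs = [], []
        for seg in (SEG_A1, SEG_A2):
            on, off = self.trial.segment_window(self.n_groups, seg, self.direction)
            ons.append(on)
            offs.append(off)
        return min(ons), max(offs)


def generate_targets(
    cmug_of: np.ndarray,
    segment_of: np.ndarray,
    direction: str,
    trial: TrialSpec = TrialSpec(),
) -> TargetPattern:
    """Build the MN target matrix for one trial.

    ``cmug_of[i]`` is the 0-indexed CMUG of MN unit ``i`` for this direction
    and ``segment_of[i]`` its segment (0=A1, 1=A2). MN units of the same CMUG
    and segment receive identical rows.
    """
    cmug_of = np.asarray(cmug_of, dtype=int)
    segment_of = np.asarray(segment_of, dtype=int)
    if cmug_of.shape != segment_of.shape:
        raise ValidationError("cmug_of and segment_of must align")
    n_groups = int(cmug_of.max()) + 1
    if not 1 <= n_groups <= 4:
        raise ValidationError(f"expected 1-4 CMUGs per direction, got {n_groups}")
    t = trial.bin_centers
    m_star = np.zeros((len(cmug_of), trial.n_bins))
    for i, (g, seg) in enumerate(zip(cmug_of, segment_of)):
        on, off = trial.group_window(int(g), n_groups, int(seg), direction)
        m_star[i] = rectified_cosine_pulse(t, on, off, trial.pulse_amplitude)
    # w_i proportional to 1/N_CMUG within (group, segment), normalized to sum 1
    sizes = np.zeros(len(cmug_of))
    for seg in np.unique(segment_of):
        for g in np.unique(cmug_of):
            sel = (cmug_of == g) & (segment_of == seg)
            if sel.any():
                sizes[sel] = sel.sum()
    weights = (1.0 / sizes) / (1.0 / sizes).sum()
    return TargetPattern(
        m_star=m_star,
        weights=weights,
        cmug_of=cmug_of,
        segment_of=segment_of,
        direction=direction,
        trial=trial,
        n_groups=n_groups,
    )


def command_input(
    amplitudes: np.ndarray,
    target: TargetPattern,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Tonic descending drive matrix I(t), shape (n_bins, n_pmn).

    The per-PMN amplitude vector is applied during the command window
    (default: the union of the trial's target windows) and is zero elsewhere.
    """
    trial = target.trial
    if window is None:
        window = target.command_window
    on, off = window
    t = trial.bin_centers
    gate = ((t >= on) & (t <= off)).astype(float)
    return gate[:, None] * np.asarray(amplitudes, dtype=float)[None, :]
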