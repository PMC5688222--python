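"""Temporal stimulus encoding: trial clock, complete serial compound, eligibility traces.

Discriminative stimuli are encoded as a *complete serial compound* (CSC): a
tapped delay line in which each post-onset timestep of a trial is represented
by its own binary unit. Exactly one unit of the presented stimulus is active
per timestep, which gives the critic a distinct predictor for every moment
between cue onset and reinforcer delivery. Each unit carries an eligibility
trace that is set to 1 when the unit fires and then decays geometrically,
providing the presynaptic factor of the critic's two-factor learning rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialClock",
    "trace_coefficients",
    "csc_unit_index",
    "csc_activation",
    "EligibilityTraces",
    "trial_table",
]


class ProtocolError(ValueError):
    """Raised when a stimulus/trial specification is inconsistent."""


@dataclass(frozen=True)
class TrialClock:
    """Timing of a single discrete trial, in integer timesteps.

    Windows are half-open ``[onset, offset)``: the cue is present at
    ``cue_onset <= t < cue_offset``. The reinforcer occupies a single step
    by default (``reinforcer_onset=72``, ``reinforcer_offset=73``).
    """

    T: int = 100
    cue_onset: int = 25
    cue_offset: int = 50
    target_onset: int = 57
    target_offset: int = 72
    reinforcer_onset: int = 72
    reinforcer_offset: int = 73
    dt: float = 1.0

    def __post_init__(self) -> None:
        ok = (
            0 < self.cue_onset < self.cue_offset < self.target_onset
            <= self.target_offset <= self.reinforcer_onset
            < self.reinforcer_offset <= self.T
        )
        if not ok:
            raise ProtocolError(
                "trial clock must satisfy cue_onset < cue_offset < target_onset"
                " <= target_offset <= reinforcer_onset < reinforcer_offset <= T"
            )
        if self.dt <= 0:
            raise ProtocolError("dt must be positive")

    @property
    def decision_step(self) -> int:
        """Step at which the response is read out (end of target window)."""
        return self.target_offset - 1

    @property
    def isi_cue_to_reinforcer(self) -> int:
        """Inter-stimulus interval, counted cue offset to reinforcer onset."""
        return self.reinforcer_onset - self.cue_offset


def trace_coefficients(kappa: float, tau: float, dt: float = 1.0) -> tuple[float, float]:
    """Return the eligibility-trace pair ``(lambda, gamma)``.

    ``gamma = 1 - dt/tau`` is the per-step discount and
    ``lambda = 1 - (1 - dt/kappa) / (1 - dt/tau)`` the trace coefficient;
    their product ``lambda * gamma`` is the per-step trace decay factor.

    Parameters
    ----------
    kappa : trace time constant (steps).
    tau : value-discount time constant (steps); requires ``dt < tau``.
    """
    if not 0 < dt < tau:
        raise ValueError("dt must satisfy 0 < dt < tau (discount undefined otherwise)")
    if dt >= kappa:
        raise ValueError("dt must be smaller than kappa")
    gamma = 1.0 - dt / tau
    lam = 1.0 - (1.0 - dt / kappa) / gamma
    return lam, gamma


def csc_unit_index(clock: TrialClock, t: int) -> int | None:
    """0-based index of the delay-line unit that fires at step ``t``.

    Unit ``n`` (1-based) fires at ``t = cue_onset + (n - 1)``; before cue
    onset no unit is active and ``None`` is returned.
    """
    if t < clock.cue_onset:
        return None
    return t - clock.cue_onset


def csc_activation(
    clock: TrialClock,
    t: int,
    presented_stimulus: int,
    n_units: int = 100,
    n_stimuli: int = 2,
) -> np.ndarray:
    """Binary CSC activation map ``phi`` of shape ``(n_stimuli, n_units)``.

    For the presented stimulus, unit ``n`` is 1 iff ``t == cue_onset + (n-1)``;
    every unit of the non-presented stimulus is 0 for the whole trial.

    ``presented_stimulus`` is 1-based (1..n_stimuli) as in protocol specs.
    """
    if not 1 <= presented_stimulus <= n_stimuli:
        raise ProtocolError(
            f"invalid stimulus id {presented_stimulus!r}: must be in 1..{n_stimuli}"
        )
    phi = np.zeros((n_stimuli, n_units), dtype=np.int8)
    n = csc_unit_index(clock, t)
    if n is not None and n < n_units:
        phi[presented_stimulus - 1, n] = 1
    return phi


class EligibilityTraces:
    """Per-unit, per-stimulus eligibility traces for the CSC representation.

    A unit's trace is set to 1 at the step its CSC unit fires and thereafter
    decays by ``lambda * gamma`` per step. Traces for the non-presented
    stimulus stay at 0 because its units never fire.

    The optional ``literal_reward_onset`` mode implements the alternative
    reading in which every trace is held at 1 until reinforcer onset and only
    decays afterwards; it is provided for comparison and is off by default.
    """

    def __init__(
        self,
        clock: TrialClock,
        decay: float,
        n_units: int = 100,
        n_stimuli: int = 2,
        literal_reward_onset: bool = False,
    ) -> None:
        if not 0.0 <= decay <= 1.0:
            raise ValueError("trace decay factor must be in [0, 1]")
        self.clock = clock
        self.decay = float(decay)
        self.n_units = n_units
        self.n_stimuli = n_stimuli
        self.literal_reward_onset = literal_reward_onset
        self.values = np.zeros((n_stimuli, n_units), dtype=float)
        self._fired = np.zeros((n_stimuli, n_units), dtype=bool)

    def reset(self) -> None:
        self.values[:] = 0.0
        self._fired[:] = False

    def update(self, t: int, presented_stimulus: int) -> np.ndarray:
        """Advance traces to step ``t`` given the stimulus presented this trial."""
        if self.literal_reward_onset:
            # traces of already-fired units pinned at 1 until reward onset
            if t < self.clock.reinforcer_onset:
                n = csc_unit_index(self.clock, t)
                if n is not None and n < self.n_units:
                    self._fired[presented_stimulus - 1, n] = True
                self.values[self._fired] = 1.0
            else:
                self.values *= self.decay
            return self.values
        self.values *= self.decay
        n = csc_unit_index(self.clock, t)
        if n is not None and n < self.n_units:
            self.values[presented_stimulus - 1, n] = 1.0
        return self.values


def trial_table(
    clock: TrialClock,
    presented_stimulus: int,
    decay: float,
    n_units: int = 100,
    n_stimuli: int = 2,
    literal_reward_onset: bool = False,
):
    """Per-timestep unit activation / trace table for one trial.

    Returns a long-format :class:`pandas.DataFrame` with columns
    ``t, stimulus, unit, phi, trace`` (units and stimuli 1-based),
    restricted to units that are ever active, suitable for CSV export
    and fixture tests.
    """
    import pandas as pd

    traces = EligibilityTraces(
        clock, decay, n_units, n_stimuli, literal_reward_onset
    )
    rows = []
    for t in range(1, clock.T + 1):
        phi = csc_activation(clock, t, presented_stimulus, n_units, n_stimuli)
        tr = traces.update(t, presented_stimulus)
        active = np.nonzero((phi != 0) | (tr != 0))
        for s, n in zip(*active):
            rows.append(
                {"t": t, "stimulus": s + 1, "unit": n + 1,
                 "phi": int(phi[s, n]), "trace": float(tr[s, n])}
            )
    return pd.DataFrame(rows, columns=["t", "stimulus", "unit", "phi", "trace"])
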