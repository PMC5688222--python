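"""Dual-dimension critic: reward-magnitude and reward-omission value learning.

The critic maintains two temporal-difference value functions over the CSC
delay line. The *magnitude* dimension learns how large the reinforcer is and
never unlearns (its prediction error is clipped at zero inside the weight
update), so it remains an accurate magnitude estimate even when rewards stop.
The *omission* dimension learns, as a fraction of magnitude, how often the
reinforcer is withheld: its error is driven by the sign-flipped magnitude
error, so an omitted-but-expected reward (negative magnitude error) produces
a positive omission error, and an unexpected reward a negative one, which
lets omission expectation rise and fall with the schedule.

Prediction errors follow the continuous-time TD form with discount
``gamma = 1 - dt/tau`` and an overall gain on the temporal-difference term.
The gain written with the equations is ``tau/dt``, which the standalone
``delta_magnitude`` / ``delta_omission`` helpers use by default. With that
gain the asymptotic pre-reinforcer value of a unit reward is ``dt/tau`` (0.1
for the defaults), which leaves the [0, 1] value clamp inert and starves the
downstream expectancy sigmoids, whose thresholds span [0, 1]. The simulation
engine therefore uses a unit gain (``td_gain = 1``, plain discrete TD(0)),
under which magnitude value converges to the reinforcer magnitude and
omission value to the omission *probability* — the scale on which the rest
of the architecture operates. The gain is exposed in configuration.
"""

from __future__ import annotations

import numpy as np

from .encoding import csc_unit_index

__all__ = [
    "clamp",
    "compute_value",
    "delta_magnitude",
    "delta_omission",
    "update_critic_weights",
    "DualCritic",
]


def clamp(x: float) -> float:
    """Piecewise-linear output nonlinearity: 0 below 0, identity, 1 above 1."""
    if x < 0.0:
        return 0.0
    if x < 1.0:
        return float(x)
    return 1.0


def compute_value(theta: np.ndarray, phi: np.ndarray) -> float:
    """Clamped value ``clamp(sum_ns theta[ns] * phi[ns])`` for one dimension.

    ``theta`` and ``phi`` must share the (n_stimuli, n_units) shape.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if theta.shape != phi.shape:
        raise ValueError(
            f"dimension mismatch: weights {theta.shape} vs activations {phi.shape}"
        )
    return clamp(float(np.sum(theta * phi)))


def _gain(tau: float, dt: float, td_gain: float | None) -> float:
    return tau / dt if td_gain is None else float(td_gain)


def delta_magnitude(
    reward_prev: float,
    vm_now: float,
    vm_prev: float,
    tau: float = 10.0,
    dt: float = 1.0,
    td_gain: float | None = None,
) -> float:
    """Raw signed magnitude prediction error.

    ``reward_prev`` is the reward signal of the previous step. The returned
    value is *not* clipped; non-negativity applies only inside the magnitude
    weight update.
    """
    g = _gain(tau, dt, td_gain)
    return reward_prev + g * ((1.0 - dt / tau) * vm_now - vm_prev)


def delta_omission(
    delta_m_raw: float,
    vo_now: float,
    vo_prev: float,
    tau: float = 10.0,
    dt: float = 1.0,
    td_gain: float | None = None,
) -> float:
    """Omission prediction error: sign-flipped magnitude error plus TD term."""
    g = _gain(tau, dt, td_gain)
    return -delta_m_raw + g * ((1.0 - dt / tau) * vo_now - vo_prev)


def update_critic_weights(
    theta: np.ndarray,
    delta: float,
    traces: np.ndarray,
    beta: float,
    dimension: str,
) -> np.ndarray:
    """Two-factor weight update ``theta += beta * delta * trace`` (in place).

    For the magnitude dimension (``'m'``) the error is clipped at zero first,
    so magnitude weights never decrease; the omission dimension (``'o'``)
    uses the signed error.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("learning rate must be in [0, 1)")
    if dimension == "m":
        delta = max(0.0, delta)
    elif dimension != "o":
        raise ValueError("dimension must be 'm' or 'o'")
    theta += beta * delta * traces
    return theta


class DualCritic:
    """Vectorised dual critic for a batch of independent runs.

    State arrays carry a leading run axis so that a whole seeded batch is
    stepped in lockstep. ``step`` performs, in order: CSC read-out of both
    values, prediction errors from the previous step's values and reward,
    weight updates against the *previous* step's eligibility traces, then the
    trace advance (decay + set-to-1 of the unit firing this step). Pairing
    the error at ``t`` with the trace state of ``t - dt`` credits the unit
    whose activation produced ``V(t - dt)``, which is the contractive TD
    assignment; crediting the unit firing at ``t`` itself is unstable (the
    error then grows with the weight it updates).
    """

    def __init__(
        self,
        n_runs: int,
        clock,
        *,
        beta_m: float = 0.06,
        beta_o: float = 0.10,
        tau: float = 10.0,
        trace_decay: float = 0.0041666,
        td_gain: float = 1.0,
        n_units: int = 100,
        n_stimuli: int = 2,
        literal_reward_onset_traces: bool = False,
    ) -> None:
        for name, b in (("beta_m", beta_m), ("beta_o", beta_o)):
            if not 0.0 <= b < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        self.clock = clock
        self.R = n_runs
        self.beta_m = beta_m
        self.beta_o = beta_o
        self.tau = tau
        self.dt = clock.dt
        self.gamma = 1.0 - self.dt / tau
        self.td_gain = td_gain
        self.trace_decay = trace_decay
        self.literal_reward_onset_traces = literal_reward_onset_traces
        self.n_units = n_units
        self.n_stimuli = n_stimuli
        shape = (n_runs, n_stimuli, n_units)
        self.theta_m = np.zeros(shape)
        self.theta_o = np.zeros(shape)
        self.traces = np.zeros(shape)
        self.vm_prev = np.zeros(n_runs)
        self.vo_prev = np.zeros(n_runs)
        self._rows = np.arange(n_runs)

    def begin_trial(self) -> None:
        """Reset traces and value memory (activations reset between trials)."""
        self.traces[:] = 0.0
        self.vm_prev[:] = 0.0
        self.vo_prev[:] = 0.0

    def step(
        self, t: int, stim_idx: np.ndarray, reward_prev: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Advance one timestep; returns ``(V_m, V_o, delta_m, delta_o)``.

        ``stim_idx`` is the 0-based presented stimulus per run;
        ``reward_prev`` the reward signal delivered at ``t - dt``.
        """
        n = csc_unit_index(self.clock, t)
        if n is not None and n < self.n_units:
            vm = np.clip(self.theta_m[self._rows, stim_idx, n], 0.0, 1.0)
            vo = np.clip(self.theta_o[self._rows, stim_idx, n], 0.0, 1.0)
        else:
            vm = np.zeros(self.R)
            vo = np.zeros(self.R)

        g = self.td_gain
        dm = reward_prev + g * (self.gamma * vm - self.vm_prev)
        do = -dm + g * (self.gamma * vo - self.vo_prev)

        # two-factor update against the previous step's traces
        self.theta_m += (self.beta_m * np.maximum(dm, 0.0))[:, None, None] * self.traces
        self.theta_o += (self.beta_o * do)[:, None, None] * self.traces

        # trace advance: decay, then the unit firing now is set to 1
        # (literal mode instead pins all fired units at 1 until reward onset)
        if self.literal_reward_onset_traces and t < self.clock.reinforcer_onset:
            if n is not None and n < self.n_units:
                self.traces[self._rows, stim_idx, n] = 1.0
        else:
            self.traces *= self.trace_decay
            if n is not None and n < self.n_units:
                self.traces[self._rows, stim_idx, n] = 1.0

        self.vm_prev = vm
        self.vo_prev = vo
        return vm, vo, dm, do
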