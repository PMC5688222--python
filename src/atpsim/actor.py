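"""Neural-dynamic actor: response nodes, affective expectancies, Hebbian learning.

Four leaky-integrator nodes (S1, S2, R1, R2) follow Amari-style dynamics
integrated with a backward-Euler step. Two further read-out quantities, the
reward-acquisition expectancy ``Rew`` and the omission expectancy ``Om``,
are computed each step from the previous step's critic values through
sigmoids whose slope and threshold are themselves *meta-parameters*, pushed
around by the omission prediction error: positive omission errors sharpen
the omission classifier, negative ones (unexpected reward) sharpen the
reward classifier. ``Om`` receives inhibition from ``Rew`` and vice versa
(``Rew`` subtracts the omission sigmoid), which drives the two expectancies
toward an XOR-like classification of stimuli by expected outcome.

Response choice is mediated by two routes converging on the R nodes: the
retrospective stimulus-response route (S1/S2 -> R1/R2) and the prospective
expectancy route (Rew/Om -> R1/R2). Both weight classes learn by a
prediction-error-gated Hebbian rule; the executed response node is driven by
an execution input during the response/reinforcer window so that outcome
errors are attributed to the action actually taken.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "step_node",
    "compute_expectancies",
    "update_meta_params",
    "update_association_weights",
    "select_response",
    "AffectiveActor",
    "PRE_NODES",
    "POST_NODES",
]

PRE_NODES = ("S1", "S2", "Om", "Rew")
POST_NODES = ("R1", "R2")

# meta-parameter vector layout and error-congruence signs:
# slopes rise / thresholds fall under the congruent prediction-error sign
# (omission side under positive delta_o, reward side under negative delta_o)
META_NAMES = ("slope_vo", "slope_vm", "th_vo", "th_vm")
META_PSI = np.array([+1.0, -1.0, -1.0, +1.0])


def sigmoid(u, beta: float, th: float = 0.0):
    """Logistic transfer ``1 / (1 + exp(-beta * (u - th)))``."""
    from scipy.special import expit

    return expit(beta * (np.asarray(u, dtype=float) - th))


def step_node(
    u_prev,
    input_current,
    tau_r: float = 5.0,
    h_r: float = -1.0,
    C_r: float = 1.2,
    beta_r: float = 4.0,
    dt: float = 1.0,
):
    """One backward-Euler step of the Amari node dynamics.

    ``u(t) = u + (dt/tau_r) * (-u + h_r + C_r * sigmoid(u, beta_r) + I)``.
    """
    if tau_r <= 0:
        raise ValueError("tau_r must be positive")
    u_prev = np.asarray(u_prev, dtype=float)
    drive = -u_prev + h_r + C_r * sigmoid(u_prev, beta_r) + np.asarray(input_current)
    return u_prev + (dt / tau_r) * drive


def compute_expectancies(
    vm_prev,
    vo_prev,
    meta: np.ndarray,
    beta_om: float = 10.0,
    th_om: float = 0.25,
    *,
    mutual_inhibition: bool = True,
    rew_outer_sigmoid: bool = False,
):
    """Rew and Om outputs from the previous step's critic values.

    ``meta`` holds ``(slope_vo, slope_vm, th_vo, th_vm)`` along its last
    axis. ``Rew`` is the reward sigmoid minus the omission sigmoid,
    rectified at zero; ``Om`` passes the omission sigmoid minus ``Rew``
    through a fixed outer sigmoid. With ``mutual_inhibition=False`` the two
    subtraction terms are dropped (ablation of the XOR competition). With
    ``rew_outer_sigmoid=True`` the Rew difference is passed through the same
    outer sigmoid instead of being rectified.
    """
    meta = np.asarray(meta, dtype=float)
    s_vo, s_vm = meta[..., 0], meta[..., 1]
    t_vo, t_vm = meta[..., 2], meta[..., 3]
    lam_vm = sigmoid(np.asarray(vm_prev) - t_vm, s_vm, 0.0)
    lam_vo = sigmoid(np.asarray(vo_prev) - t_vo, s_vo, 0.0)
    if mutual_inhibition:
        rew_drive = lam_vm - lam_vo
    else:
        rew_drive = lam_vm
    if rew_outer_sigmoid:
        rew = sigmoid(rew_drive, beta_om, th_om)
    else:
        rew = np.maximum(0.0, rew_drive)
    om_drive = lam_vo - (rew if mutual_inhibition else 0.0)
    om = sigmoid(om_drive, beta_om, th_om)
    return rew, om


def update_meta_params(
    meta: np.ndarray,
    delta_o,
    input_r,
    *,
    C_j: float = 10.0,
    slope_bounds: tuple[float, float] = (0.5, 20.0),
    th_bounds: tuple[float, float] = (0.0, 1.0),
    mode: str = "congruent",
) -> np.ndarray:
    """Prediction-error-driven meta-parameter step (in place, clamped).

    Each entry moves by ``psi * error / (C_j * I_r)`` where ``I_r`` is the
    input to the executed response node at the evaluation step; runs with
    ``I_r == 0`` are skipped (no response drive, nothing to attribute).

    In the default ``'congruent'`` mode each classifier sharpens under its
    own congruent error only — the omission-side slope rises and threshold
    falls with the positive part of the omission error, the reward side
    with the positive part of the reward error ``-delta_o`` — so the
    stronger the omission (reward) surprise, the more effective omission
    (reward) classification becomes. ``'signed'`` applies the raw signed
    omission error to all four entries, letting incongruent errors
    de-sharpen a classifier.
    """
    delta_o = np.atleast_1d(np.asarray(delta_o, dtype=float))
    input_r = np.atleast_1d(np.asarray(input_r, dtype=float))
    active = input_r != 0.0
    step = np.zeros_like(delta_o)
    step[active] = delta_o[active] / (C_j * input_r[active])
    if mode == "congruent":
        step_om = np.maximum(step, 0.0)
        step_rew = np.maximum(-step, 0.0)
        drive = np.stack([step_om, step_rew, -step_om, -step_rew], axis=-1)
        meta += drive
    elif mode == "signed":
        meta += META_PSI * step[..., None]
    else:
        raise ValueError("mode must be 'congruent' or 'signed'")
    meta[..., 0:2] = np.clip(meta[..., 0:2], *slope_bounds)
    meta[..., 2:4] = np.clip(meta[..., 2:4], *th_bounds)
    return meta


def update_association_weights(
    omega: np.ndarray,
    pre: np.ndarray,
    post: np.ndarray,
    delta_m,
    delta_o,
    *,
    beta_sr: float = 0.06,
    beta_er: float = 0.06,
    gate_mode: str = "omission",
    er_unlearn_factor: float = 1.0,
    weight_floor: float | None = 0.0,
    lesion_s_r: bool = False,
    lesion_e_r: bool = False,
) -> np.ndarray:
    """Prediction-error-gated Hebbian update of the connection matrix.

    ``omega`` has shape ``(..., 4, 2)`` with pre rows ordered (S1, S2, Om,
    Rew) and post columns (R1, R2).

    With the default ``gate_mode='omission'`` every route is gated by the
    same signed reward prediction error ``-delta_o`` (the omission critic's
    error, inverted): connections onto the executed response grow when
    reward arrives under-predicted and are unlearned while omission is
    still under-predicted. What differentiates the routes is purely the
    presynaptic factor: omission-expectancy weights can only form where the
    Om node is active when a response pays off (partial schedules), and the
    total unlearning a response suffers in extinction is the sum of the
    omission-learning transients of every stimulus that drives it — which
    ties extinction persistence to the omission learning rate and to how
    many stimuli share the response. ``gate_mode='magnitude'`` instead
    gates the S-R and Rew rows by the signed magnitude error and the Om row
    by the signed omission error. Lesion flags freeze (and imply zero) the
    corresponding rows.
    """
    delta_m = np.asarray(delta_m, dtype=float)
    delta_o = np.asarray(delta_o, dtype=float)
    if gate_mode == "omission":
        rpe = -delta_o
        # expectancy routes unlearn more slowly than they learn
        # (asymmetric potentiation/depression on the prospective pathway)
        rpe_er = np.maximum(rpe, 0.0) + er_unlearn_factor * np.minimum(rpe, 0.0)
        gate = np.stack([rpe, rpe, rpe_er, rpe_er], axis=-1)
    elif gate_mode == "magnitude":
        gate = np.stack([delta_m, delta_m, delta_o, delta_m], axis=-1)
    else:
        raise ValueError("gate_mode must be 'omission' or 'magnitude'")
    rate = np.array([beta_sr, beta_sr, beta_er, beta_er])
    if lesion_s_r:
        rate = rate * np.array([0.0, 0.0, 1.0, 1.0])
    if lesion_e_r:
        rate = rate * np.array([1.0, 1.0, 0.0, 0.0])
    omega += (rate * gate)[..., :, None] * pre[..., :, None] * post[..., None, :]
    if weight_floor is not None:
        # associations extinguish at the floor rather than turning inhibitory
        np.maximum(omega, weight_floor, out=omega)
    return omega


def select_response(
    outputs: np.ndarray,
    protocol_kind: str,
    rng_guess: np.ndarray,
    rng_tie: np.ndarray,
    threshold: float = 0.5,
) -> np.ndarray:
    """Choose a response per run from sigmoided R-node outputs.

    If the larger output reaches ``threshold`` the argmax is taken (exact
    ties broken by ``rng_tie``); otherwise an undriven guess is made:
    uniform over the two levers for the two-lever protocol, response 1 with
    probability 0.25 for the single-rule (button-sequence) protocol, in
    which guessing the rewarded rule means hitting one of four button
    permutations.
    """
    outputs = np.atleast_2d(outputs)
    driven = outputs.max(axis=1) >= threshold
    choice = np.where(
        outputs[:, 0] == outputs[:, 1],
        (rng_tie < 0.5).astype(np.int64),
        np.argmax(outputs, axis=1),
    )
    if protocol_kind == "two_lever":
        guess = (rng_guess < 0.5).astype(np.int64)
    elif protocol_kind == "single_rule":
        guess = (rng_guess >= 0.25).astype(np.int64)  # P(R1) = 0.25
    else:
        raise ValueError(f"unknown protocol kind {protocol_kind!r}")
    return np.where(driven, choice, guess)


class AffectiveActor:
    """Vectorised actor state for a batch of runs.

    Holds node activations ``u`` (R, 4), the learnable connection matrix
    ``omega`` (R, 4, 2) and the meta-parameter matrix ``meta`` (R, 4).
    Between trials activations reset; weights and meta-parameters persist.
    """

    def __init__(
        self,
        n_runs: int,
        *,
        tau_r: float = 5.0,
        h_r: float = -1.0,
        C_r: float = 1.2,
        beta_r: float = 4.0,
        beta_sr: float = 0.105,
        beta_er: float = 0.06,
        gate_mode: str = "omission",
        er_unlearn_factor: float = 0.2,
        weight_floor: float | None = 0.0,
        beta_om: float = 10.0,
        th_om: float = 0.29,
        C_j: float = 3.0,
        meta_mode: str = "congruent",
        init_slope: float = 4.2,
        init_th: float = 0.5,
        slope_bounds: tuple[float, float] = (0.5, 20.0),
        th_bounds: tuple[float, float] = (0.0, 1.0),
        decision_threshold: float = 0.525,
        exec_input: float = 2.2,
        stimulus_input: float = 1.0,
        dt: float = 1.0,
        lesion_s_r: bool = False,
        lesion_e_r: bool = False,
        mutual_inhibition: bool = True,
        rew_outer_sigmoid: bool = False,
    ) -> None:
        self.R = n_runs
        self.tau_r, self.h_r, self.C_r, self.beta_r = tau_r, h_r, C_r, beta_r
        self.beta_sr, self.beta_er = beta_sr, beta_er
        self.gate_mode = gate_mode
        self.er_unlearn_factor = er_unlearn_factor
        self.weight_floor = weight_floor
        self.beta_om, self.th_om, self.C_j = beta_om, th_om, C_j
        self.meta_mode = meta_mode
        self.slope_bounds, self.th_bounds = slope_bounds, th_bounds
        self.decision_threshold = decision_threshold
        self.exec_input = exec_input
        self.stimulus_input = stimulus_input
        self.dt = dt
        self.lesion_s_r, self.lesion_e_r = lesion_s_r, lesion_e_r
        self.mutual_inhibition = mutual_inhibition
        self.rew_outer_sigmoid = rew_outer_sigmoid

        self.u = np.full((n_runs, 4), h_r, dtype=float)  # S1, S2, R1, R2
        self.omega = np.zeros((n_runs, 4, 2))
        self.meta = np.empty((n_runs, 4))
        self.meta[:, 0:2] = init_slope
        self.meta[:, 2:4] = init_th
        self.rew = np.zeros(n_runs)
        self.om = np.zeros(n_runs)
        self._rows = np.arange(n_runs)

    def begin_trial(self) -> None:
        """Reset node activations to rest (weights and meta persist)."""
        self.u[:] = self.h_r
        self.rew[:] = 0.0
        self.om[:] = 0.0

    def node_outputs(self) -> np.ndarray:
        """Sigmoided activations of all four nodes, shape (R, 4)."""
        return sigmoid(self.u, self.beta_r, 0.0)

    def response_input(self, pre: np.ndarray) -> np.ndarray:
        """Weighted input to the R nodes from the four presynaptic sources."""
        return np.einsum("rk,rkl->rl", pre, self.omega)

    def presynaptic(self) -> np.ndarray:
        """Presynaptic activity vector (S1, S2, Om, Rew) per run."""
        s_out = sigmoid(self.u[:, 0:2], self.beta_r, 0.0)
        return np.column_stack([s_out, self.om, self.rew])

    def step(
        self,
        t: int,
        stim_idx: np.ndarray,
        vm_prev: np.ndarray,
        vo_prev: np.ndarray,
        cue_on: bool,
        executing: np.ndarray | None,
    ) -> np.ndarray:
        """Advance expectancies and node dynamics one timestep.

        ``executing`` is a per-run response index (or -1) receiving the
        execution input. Returns the input that reached each R node,
        shape (R, 2), for use by the meta update at the evaluation step.
        """
        self.rew, self.om = compute_expectancies(
            vm_prev,
            vo_prev,
            self.meta,
            self.beta_om,
            self.th_om,
            mutual_inhibition=self.mutual_inhibition,
            rew_outer_sigmoid=self.rew_outer_sigmoid,
        )
        pre = self.presynaptic()
        input_r = self.response_input(pre)
        if executing is not None:
            mask = executing >= 0
            input_r[self._rows[mask], executing[mask]] += self.exec_input
        input_s = np.zeros((self.R, 2))
        if cue_on:
            input_s[self._rows, stim_idx] = self.stimulus_input
        inputs = np.concatenate([input_s, input_r], axis=1)
        self.u = step_node(
            self.u, inputs, self.tau_r, self.h_r, self.C_r, self.beta_r, self.dt
        )
        return input_r

    def learn(self, delta_m: np.ndarray, delta_o: np.ndarray) -> None:
        """Per-timestep Hebbian update of all association weights."""
        post = sigmoid(self.u[:, 2:4], self.beta_r, 0.0)
        update_association_weights(
            self.omega,
            self.presynaptic(),
            post,
            delta_m,
            delta_o,
            beta_sr=self.beta_sr,
            beta_er=self.beta_er,
            gate_mode=self.gate_mode,
            er_unlearn_factor=self.er_unlearn_factor,
            weight_floor=self.weight_floor,
            lesion_s_r=self.lesion_s_r,
            lesion_e_r=self.lesion_e_r,
        )

    def learn_meta(self, delta_o: np.ndarray, input_exec: np.ndarray) -> None:
        """Meta-parameter update at the outcome-evaluation step."""
        update_meta_params(
            self.meta,
            delta_o,
            input_exec,
            C_j=self.C_j,
            slope_bounds=self.slope_bounds,
            th_bounds=self.th_bounds,
            mode=self.meta_mode,
        )
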