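"""Trial engine coupling the dual critic to the affective actor.

A trial is ``T`` discrete timesteps. The cue is presented during the cue
window and again during the target (response-option) window; the CSC delay
line starts at cue onset and runs to the end of the trial. At the last step
of the target window the response is read out from the sigmoided R-node
activations (argmax above threshold, undriven guess otherwise). The chosen
response is *executed*: its node receives an execution input from selection
until reinforcer offset, so that the outcome prediction errors are
attributed, through the Hebbian rule, to the action actually taken. Reward
(if the response was correct and the schedule's Bernoulli draw succeeds) is
delivered at reinforcer onset and reaches the magnitude error one step
later; that step is also where the expectancy meta-parameters update.

All state arrays carry a leading run axis: a whole batch of independently
seeded runs advances in lockstep, which keeps 50-run experiments fast while
preserving per-run reproducibility (each run draws from its own generators).
"""

from __future__ import annotations

import numpy as np

from .actor import AffectiveActor, select_response
from .config import ModelConfig
from .critic import DualCritic
from .encoding import trace_coefficients

__all__ = ["TwoProcessEngine", "TrialOutcome", "timecourse_frame"]


def timecourse_frame(outcome: "TrialOutcome") -> "pd.DataFrame":
    """Long-format per-timestep trace of a recorded trial batch.

    Columns: run, t, stimulus, V_m, V_o, delta_m, delta_o, u_S1, u_S2,
    u_R1, u_R2, Rew, Om, chosen_response. Requires the trial to have been
    run with ``record_timecourse=True``.
    """
    import pandas as pd

    tc = outcome["timecourse"]
    T, R = tc["vm"].shape
    t_idx = np.repeat(np.arange(1, T + 1), R)
    run_idx = np.tile(np.arange(R), T)
    u = tc["u"].reshape(T * R, 4)
    return pd.DataFrame(
        {
            "run": run_idx,
            "t": t_idx,
            "stimulus": np.tile(outcome["stimulus"], T),
            "V_m": tc["vm"].ravel(),
            "V_o": tc["vo"].ravel(),
            "delta_m": tc["dm"].ravel(),
            "delta_o": tc["do"].ravel(),
            "u_S1": u[:, 0],
            "u_S2": u[:, 1],
            "u_R1": u[:, 2],
            "u_R2": u[:, 3],
            "Rew": tc["rew"].ravel(),
            "Om": tc["om"].ravel(),
            "chosen_response": np.tile(outcome["response"], T),
        }
    )


class TrialOutcome(dict):
    """Per-trial results keyed by field name, each an array over runs."""

    __getattr__ = dict.__getitem__


class TwoProcessEngine:
    """A batch of model instances run in lockstep.

    Parameters
    ----------
    n_runs : number of independent model instances.
    config : full model configuration; all equation constants come from it.
    """

    def __init__(self, n_runs: int, config: ModelConfig) -> None:
        config.validate()
        self.cfg = config
        self.clock = config.trial
        self.R = n_runs
        if config.critic.trace_mode == "kappa":
            # per-step decay with time constant kappa (the trace as a
            # learning-speeding device: spans ~kappa steps)
            decay = 1.0 - self.clock.dt / config.critic.kappa
        else:
            # product of the printed coefficient pair (effectively one-step)
            lam, gamma = trace_coefficients(
                config.critic.kappa, config.critic.tau, self.clock.dt
            )
            decay = lam * gamma
        self.critic = DualCritic(
            n_runs,
            self.clock,
            beta_m=config.critic.beta_m,
            beta_o=config.critic.beta_o,
            tau=config.critic.tau,
            trace_decay=decay,
            td_gain=config.critic.td_gain,
            literal_reward_onset_traces=config.critic.literal_reward_onset_traces,
        )
        a, m, les = config.actor, config.meta, config.lesion
        self.actor = AffectiveActor(
            n_runs,
            tau_r=a.tau_r,
            h_r=a.h_r,
            C_r=a.C_r,
            beta_r=a.beta_r,
            beta_sr=a.beta_sr,
            beta_er=a.beta_er,
            gate_mode=a.gate_mode,
            er_unlearn_factor=a.er_unlearn_factor,
            weight_floor=a.weight_floor,
            beta_om=a.beta_om,
            th_om=a.th_om,
            C_j=m.C_j,
            meta_mode=m.update_mode,
            init_slope=m.init_slope,
            init_th=m.init_th,
            slope_bounds=(m.n_slope, m.a_slope),
            th_bounds=(m.n_th, m.a_th),
            decision_threshold=a.decision_threshold,
            exec_input=a.exec_input,
            stimulus_input=a.stimulus_input,
            dt=self.clock.dt,
            lesion_s_r=les.s_r,
            lesion_e_r=les.e_r,
            mutual_inhibition=les.mutual_inhibition,
            rew_outer_sigmoid=a.rew_outer_sigmoid,
        )
        self._rows = np.arange(n_runs)
        self.learning_enabled = True

    # ------------------------------------------------------------------
    def run_trial(
        self,
        stimulus: np.ndarray,
        correct_response: np.ndarray,
        p_reward: np.ndarray,
        protocol_kind: str,
        reward_draw: np.ndarray,
        guess_draw: np.ndarray,
        tie_draw: np.ndarray,
        record_timecourse: bool = False,
    ) -> TrialOutcome:
        """Execute one full trial for every run in the batch.

        ``stimulus`` and ``correct_response`` are 1-based per-run arrays;
        ``p_reward`` the per-run reinforcement probability of a correct
        response this trial (0 during extinction). The three ``*_draw``
        arrays are uniform(0,1) variates from the per-run substreams for
        Bernoulli reward, undriven guessing and tie-breaking.
        """
        clk = self.clock
        cc = self.cfg.critic
        eval_step = clk.reinforcer_onset + cc.reward_lag
        stim_idx = np.asarray(stimulus) - 1
        corr_idx = np.asarray(correct_response) - 1

        self.critic.begin_trial()
        self.actor.begin_trial()

        executing = np.full(self.R, -1, dtype=np.int64)
        rewarded = np.zeros(self.R, dtype=bool)
        chosen = np.zeros(self.R, dtype=np.int64)
        rew_dec = om_dec = vm_dec = vo_dec = None
        tc: dict[str, list] = {k: [] for k in ("vm", "vo", "dm", "do", "u", "rew", "om")}

        for t in range(1, clk.T + 1):
            if t == clk.reinforcer_onset + cc.reward_lag:
                reward_prev = rewarded.astype(float)
            else:
                reward_prev = np.zeros(self.R)

            vm_p = self.critic.vm_prev
            vo_p = self.critic.vo_prev
            vm, vo, dm, do = self.critic.step(t, stim_idx, reward_prev)

            cue_on = (
                clk.cue_onset <= t < clk.cue_offset
                or clk.target_onset <= t < clk.target_offset
            )
            target_both = (
                self.cfg.actor.target_input_both
                and clk.target_onset <= t < clk.target_offset
            )
            exec_now = executing if clk.decision_step < t <= clk.reinforcer_offset else None
            input_r = self._actor_step(
                t, stim_idx, vm_p, vo_p, cue_on, target_both, exec_now
            )

            if self.learning_enabled:
                # association weights update when the outcome information
                # arrives (trial-based associative learning) or continuously
                if self.cfg.actor.learn_step == "all" or t == eval_step:
                    self.actor.learn(dm, do)
                if t == eval_step:
                    i_exec = np.where(
                        executing >= 0,
                        input_r[self._rows, np.maximum(executing, 0)],
                        0.0,
                    )
                    self.actor.learn_meta(do, i_exec)

            if t == clk.decision_step:
                outputs = self.actor.node_outputs()[:, 2:4]
                chosen = select_response(
                    outputs,
                    protocol_kind,
                    guess_draw,
                    tie_draw,
                    self.cfg.actor.decision_threshold,
                )
                correct = chosen == corr_idx
                rewarded = correct & (reward_draw < p_reward)
                executing = chosen
                rew_dec = self.actor.rew.copy()
                om_dec = self.actor.om.copy()
                vm_dec = vm.copy()
                vo_dec = vo.copy()

            if record_timecourse:
                tc["vm"].append(vm)
                tc["vo"].append(vo)
                tc["dm"].append(dm)
                tc["do"].append(do)
                tc["u"].append(self.actor.u.copy())
                tc["rew"].append(self.actor.rew.copy())
                tc["om"].append(self.actor.om.copy())

        out = TrialOutcome(
            stimulus=np.asarray(stimulus),
            response=chosen + 1,
            correct=chosen == corr_idx,
            rewarded=rewarded,
            rew=rew_dec,
            om=om_dec,
            vm=vm_dec,
            vo=vo_dec,
        )
        if record_timecourse:
            out["timecourse"] = {k: np.stack(v) for k, v in tc.items()}
        return out

    # ------------------------------------------------------------------
    def _actor_step(self, t, stim_idx, vm_p, vo_p, cue_on, target_both, executing):
        """One actor step; splits out the both-stimuli target-input variant."""
        if not target_both:
            return self.actor.step(t, stim_idx, vm_p, vo_p, cue_on, executing)
        # literal reading: both S nodes receive target input this step
        act = self.actor
        act.rew, act.om = act.rew, act.om  # recomputed inside step; delegate
        input_r = act.step(t, stim_idx, vm_p, vo_p, False, executing)
        act.u[:, 0:2] += (self.clock.dt / act.tau_r) * act.stimulus_input
        return input_r
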