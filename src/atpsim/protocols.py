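"""Experiment protocols: declarative specs, trial sequences, batch runner.

Two families of discrete-trial discrimination experiments are bundled:

* ``ko_*`` — a two-lever task in which each of two discriminative stimuli
  has its own correct lever (S1-R1, S2-R2). The within-subjects condition
  (``ko_expl``) reinforces S1-R1 continuously (p=1.0) and S2-R2 partially
  (p=0.5); the controls run both contingencies at 1.0 or both at 0.5.
  240 acquisition trials reported as 6 blocks of 40; 40 extinction trials
  as 4 blocks of 10.

* ``svartdal_*`` — a button-sequence task in which both stimuli share one
  rewarded rule (S1-R1, S2-R1) at high (0.8) / low (0.4) reinforcement
  densities in the multiple-schedule condition, or a single density in the
  between-subjects controls. 180 acquisition trials in 18 blocks of 10; 40
  extinction trials in 4 blocks of 10. Undriven responding guesses the
  rewarded rule with probability 0.25 (four button permutations).

Trial order is pseudo-random, balanced across stimuli within each block,
with no more than three successive trials of the same stimulus type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ModelConfig, ProtocolSpec
from .model import TwoProcessEngine

__all__ = [
    "PROTOCOLS",
    "get_protocol",
    "generate_trial_sequence",
    "run_experiment",
    "RunResult",
    "savings_experiment",
]


def _ko(name: str, p1: float, p2: float) -> ProtocolSpec:
    return ProtocolSpec(
        name=name,
        kind="two_lever",
        schedules={1: (1, p1), 2: (2, p2)},
        acquisition_trials=240,
        extinction_trials=40,
        acquisition_block=40,
        extinction_block=10,
    )


def _svartdal(name: str, p1: float, p2: float) -> ProtocolSpec:
    return ProtocolSpec(
        name=name,
        kind="single_rule",
        schedules={1: (1, p1), 2: (1, p2)},
        acquisition_trials=180,
        extinction_trials=40,
        acquisition_block=10,
        extinction_block=10,
    )


PROTOCOLS: dict[str, ProtocolSpec] = {
    "ko_expl": _ko("ko_expl", 1.0, 0.5),
    "ko_crf": _ko("ko_crf", 1.0, 1.0),
    "ko_prf": _ko("ko_prf", 0.5, 0.5),
    "svartdal_multi": _svartdal("svartdal_multi", 0.8, 0.4),
    "svartdal_high": _svartdal("svartdal_high", 0.8, 0.8),
    "svartdal_low": _svartdal("svartdal_low", 0.4, 0.4),
}


def get_protocol(name: str, **overrides) -> ProtocolSpec:
    """Return a bundled protocol spec, optionally with field overrides."""
    if name not in PROTOCOLS:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}"
        )
    spec = PROTOCOLS[name]
    return replace(spec, **overrides).validate() if overrides else spec


def generate_trial_sequence(
    spec: ProtocolSpec, phase: str, rng: np.random.Generator
) -> np.ndarray:
    """Pseudo-random stimulus order for one phase.

    Stimuli are exactly balanced within each reporting block and no more
    than ``max_same_type_run`` successive trials share a stimulus (the
    constraint also holds across block boundaries). Returns 1-based ids.
    """
    n_trials = (
        spec.acquisition_trials if phase == "acquisition" else spec.extinction_trials
    )
    block = spec.acquisition_block if phase == "acquisition" else spec.extinction_block
    stimuli = sorted(spec.schedules)
    if len(stimuli) == 1:
        return np.full(n_trials, stimuli[0], dtype=np.int64)
    if n_trials % block:
        raise ValueError("phase length must be a whole number of blocks")
    per = block // len(stimuli)
    base = np.repeat(stimuli, per)
    seq = np.empty(n_trials, dtype=np.int64)
    cap = spec.max_same_type_run
    for b in range(n_trials // block):
        lo = b * block
        for _ in range(1000):
            cand = rng.permutation(base)
            tail = seq[max(0, lo - cap): lo]
            if _max_run(np.concatenate([tail, cand])) <= cap:
                seq[lo: lo + block] = cand
                break
        else:  # pragma: no cover - rejection sampling essentially always succeeds
            raise RuntimeError("could not satisfy trial-order constraints")
    return seq


def _max_run(x: np.ndarray) -> int:
    best = run = 1
    for i in range(1, len(x)):
        run = run + 1 if x[i] == x[i - 1] else 1
        best = max(best, run)
    return best


@dataclass
class RunResult:
    """Batch result: per-trial records, per-block proportions, final engine."""

    spec: ProtocolSpec
    model: ModelConfig
    trials: pd.DataFrame
    blocks: pd.DataFrame
    engine: TwoProcessEngine
    seeds: list[int]


def _substreams(seed_base: int, n_runs: int):
    """Per-run named substreams (trial order, rewards, guesses, tie-breaks)."""
    streams = {"order": [], "reward": [], "guess": [], "tie": []}
    for i in range(n_runs):
        children = np.random.SeedSequence(seed_base + i).spawn(4)
        for name, child in zip(streams, children):
            streams[name].append(np.random.default_rng(child))
    return streams


def run_experiment(
    spec: ProtocolSpec,
    model: ModelConfig | None = None,
    n_runs: int | None = None,
    seed_base: int | None = None,
) -> RunResult:
    """Run acquisition then extinction for a batch of seeded model instances.

    Each run ``i`` draws every random quantity from substreams of seed
    ``seed_base + i``, so results are reproducible run-by-run and invariant
    to batch composition. Extinction forces the reinforcement probability of
    every schedule to zero; learning continues throughout.
    """
    spec.validate()
    model = (model or ModelConfig()).validate()
    R = n_runs if n_runs is not None else spec.n_runs
    seed_base = seed_base if seed_base is not None else spec.seed_base
    streams = _substreams(seed_base, R)
    engine = TwoProcessEngine(R, model)

    corr = {s: spec.schedules[s][0] for s in spec.schedules}
    prob = {s: spec.schedules[s][1] for s in spec.schedules}

    records = []
    for phase in ("acquisition", "extinction"):
        seqs = np.stack(
            [generate_trial_sequence(spec, phase, g) for g in streams["order"]]
        )  # (R, n_trials)
        block = (
            spec.acquisition_block if phase == "acquisition" else spec.extinction_block
        )
        for j in range(seqs.shape[1]):
            stim = seqs[:, j]
            correct_resp = np.vectorize(corr.get)(stim)
            p = (
                np.vectorize(prob.get)(stim).astype(float)
                if phase == "acquisition"
                else np.zeros(R)
            )
            out = engine.run_trial(
                stim,
                correct_resp,
                p,
                spec.kind,
                reward_draw=np.array([g.random() for g in streams["reward"]]),
                guess_draw=np.array([g.random() for g in streams["guess"]]),
                tie_draw=np.array([g.random() for g in streams["tie"]]),
            )
            records.append(
                pd.DataFrame(
                    {
                        "run": np.arange(R),
                        "condition": spec.name,
                        "phase": phase,
                        "trial": j,
                        "block": j // block,
                        "stimulus": stim,
                        "component": np.where(stim == 1, "A", "B"),
                        "p_sched": np.vectorize(prob.get)(stim).astype(float),
                        "response": out["response"],
                        "correct": out["correct"],
                        "rewarded": out["rewarded"],
                        "Rew": out["rew"],
                        "Om": out["om"],
                        "V_m": out["vm"],
                        "V_o": out["vo"],
                    }
                )
            )
    trials = pd.concat(records, ignore_index=True)
    blocks = blocks_from_trials(trials)
    return RunResult(
        spec=spec,
        model=model,
        trials=trials,
        blocks=blocks,
        engine=engine,
        seeds=[seed_base + i for i in range(R)],
    )


def blocks_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-run, per-block correct-choice proportions by schedule component."""
    grouped = (
        trials.groupby(
            ["run", "condition", "phase", "block", "component", "p_sched"],
            as_index=False,
        )["correct"]
        .mean()
        .rename(columns={"correct": "prop_correct"})
    )
    return grouped


def savings_experiment(
    model: ModelConfig | None = None,
    n_runs: int = 10,
    seed_base: int = 1,
    acquisition_trials: int = 200,
    extinction_trials: int = 60,
    reacquisition_trials: int = 120,
    criterion: float = 0.8,
    window: int = 10,
) -> pd.DataFrame:
    """Acquisition / extinction / re-acquisition on a single CRF contingency.

    Measures trials-to-criterion (first trial at which the trailing
    ``window``-trial correct proportion reaches ``criterion``) in initial
    acquisition and in re-acquisition after responding has extinguished.
    Because learned reinforcer magnitude is retained through extinction,
    re-acquisition only needs the omission expectation to unlearn, and is
    faster (the savings effect). Returns one row per run.
    """
    model = (model or ModelConfig()).validate()
    spec = ProtocolSpec(
        name="savings_crf",
        kind="two_lever",
        schedules={1: (1, 1.0)},
        acquisition_trials=acquisition_trials,
        extinction_trials=extinction_trials,
        acquisition_block=window,
        extinction_block=window,
    ).validate()
    streams = _substreams(seed_base, n_runs)
    engine = TwoProcessEngine(n_runs, model)
    stim = np.ones(n_runs, dtype=np.int64)
    resp = np.ones(n_runs, dtype=np.int64)

    def _phase(n_trials: int, p: float) -> np.ndarray:
        correct = np.zeros((n_trials, n_runs), dtype=bool)
        for j in range(n_trials):
            out = engine.run_trial(
                stim,
                resp,
                np.full(n_runs, p),
                spec.kind,
                reward_draw=np.array([g.random() for g in streams["reward"]]),
                guess_draw=np.array([g.random() for g in streams["guess"]]),
                tie_draw=np.array([g.random() for g in streams["tie"]]),
            )
            correct[j] = out["correct"]
        return correct

    def _trials_to_criterion(correct: np.ndarray) -> np.ndarray:
        n_trials, R = correct.shape
        ttc = np.full(R, n_trials, dtype=np.int64)
        csum = np.cumsum(correct, axis=0)
        for j in range(window - 1, n_trials):
            frac = (csum[j] - (csum[j - window] if j >= window else 0)) / window
            hit = (frac >= criterion) & (ttc == n_trials)
            ttc[hit] = j + 1
        return ttc

    acq = _phase(acquisition_trials, 1.0)
    ext = _phase(extinction_trials, 0.0)
    reacq = _phase(reacquisition_trials, 1.0)
    tail = ext[-window:].mean(axis=0)
    return pd.DataFrame(
        {
            "run": np.arange(n_runs),
            "ttc_acquisition": _trials_to_criterion(acq),
            "ttc_reacquisition": _trials_to_criterion(reacq),
            "extinction_tail_correct": tail,
        }
    )
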