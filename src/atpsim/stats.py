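"""Summary statistics and derived measures for simulated experiments.

Covers the reporting conventions of two-phase discrimination experiments:
per-block correct-choice summaries, the PREE index (a normalised
continuous-vs-partial contrast), log-proportion-to-baseline extinction
curves, mixed ANOVA and paired t tests over seeded runs, the learning-rate
sensitivity sweep and the lesion comparison table.

Conventions. The PREE index is ``(CRF - PRF) / (CRF + PRF)`` on mean correct
proportions — negative for a partial reinforcement extinction effect,
positive for a reversed one. It is evaluated on the last acquisition block
and on the first three extinction blocks. Inferential statistics on
extinction use blocks 2-3 only (after the inertial transient, before
absolute extinction): the paired t test treats each run x block proportion
as a paired observation, while the mixed ANOVA takes per-run means, one
observation per run and component.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "block_summary",
    "pree_index",
    "phase_indices",
    "log_baseline_curve",
    "mixed_anova",
    "paired_ttest",
    "extinction_pairs",
    "extinction_run_means",
    "sensitivity_sweep",
    "lesion_comparison",
    "modulation_comparison",
]

#: extinction blocks (0-based) entering inferential statistics
ANALYSIS_BLOCKS = (1, 2)
#: extinction blocks (0-based) entering the extinction PREE index
INDEX_BLOCKS = (0, 1, 2)


def block_summary(blocks: pd.DataFrame) -> pd.DataFrame:
    """Across-run mean, SEM and 95% CI of block correct proportions."""
    def agg(g: pd.Series) -> pd.Series:
        n = len(g)
        mean = g.mean()
        sem = g.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        half = sps.t.ppf(0.975, n - 1) * sem if n > 1 else 0.0
        return pd.Series(
            {"mean": mean, "sem": sem, "ci_low": mean - half, "ci_high": mean + half,
             "n_runs": n}
        )

    out = (
        blocks.groupby(["condition", "phase", "block", "component"])["prop_correct"]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    return out


def pree_index(mean_crf: float, mean_prf: float) -> float:
    """Normalised contrast ``(CRF - PRF) / (CRF + PRF)``.

    Negative values indicate a PREE (the partial schedule is more
    persistent), positive values a reversed PREE. Undefined when both means
    are zero (returns NaN with a warning).
    """
    total = mean_crf + mean_prf
    if total == 0:
        warnings.warn("PREE index undefined: both means are zero")
        return float("nan")
    return (mean_crf - mean_prf) / total


def phase_indices(
    blocks: pd.DataFrame,
    crf_component: str = "A",
    prf_component: str = "B",
    ext_blocks: tuple[int, ...] = INDEX_BLOCKS,
) -> dict[str, float]:
    """PREE index per phase from a block table of one condition.

    Acquisition uses the final block; extinction the mean over
    ``ext_blocks``. Components default to stimulus 1 = continuous/high
    density ('A') versus stimulus 2 = partial/low density ('B').
    """
    acq = blocks[blocks.phase == "acquisition"]
    last = acq.block.max()
    acq_m = acq[acq.block == last].groupby("component")["prop_correct"].mean()
    ext = blocks[(blocks.phase == "extinction") & blocks.block.isin(ext_blocks)]
    ext_m = ext.groupby("component")["prop_correct"].mean()
    return {
        "acquisition": pree_index(acq_m[crf_component], acq_m[prf_component]),
        "extinction": pree_index(ext_m[crf_component], ext_m[prf_component]),
    }


def log_baseline_curve(
    extinction_props: np.ndarray,
    baseline: float,
    eps: float = 1e-3,
    base: float = np.e,
) -> np.ndarray:
    """Per-block ``log(prop / baseline)`` extinction curve.

    ``baseline`` is the final-acquisition-block proportion; zero block
    proportions are floored at ``eps``. Natural log by default.
    """
    if baseline <= 0:
        raise ValueError("baseline proportion must be positive")
    props = np.maximum(np.asarray(extinction_props, dtype=float), eps)
    return np.log(props / baseline) / np.log(base)


def paired_ttest(a, b) -> dict:
    """Two-sided paired t test with 95% CI of the mean difference.

    Returns ``{'t', 'df', 'p', 'mean_diff', 'ci_low', 'ci_high',
    'degenerate'}``; a zero-variance difference is flagged degenerate
    (t is NaN) rather than reported as infinite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        # identical samples are a well-defined null (t = 0); a constant
        # non-zero difference has no finite t and is flagged degenerate
        t = 0.0 if md == 0 else float("nan")
        return {"t": t, "df": n - 1, "p": 1.0 if md == 0 else float("nan"),
                "mean_diff": float(md), "ci_low": float(md), "ci_high": float(md),
                "degenerate": md != 0}
    se = sd / np.sqrt(n)
    t = md / se
    p = 2 * sps.t.sf(abs(t), n - 1)
    half = sps.t.ppf(0.975, n - 1) * se
    return {"t": float(t), "df": n - 1, "p": float(p), "mean_diff": float(md),
            "ci_low": float(md - half), "ci_high": float(md + half),
            "degenerate": False}


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "prop_correct",
    within: str = "component",
    between: str = "condition",
    subject: str = "subject",
) -> pd.DataFrame:
    """Mixed (split-plot) ANOVA over seeded runs.

    Requires a balanced design: every subject measured at every within
    level, equal subject counts per between group. Returns a table with
    one row per effect (within, between, interaction) carrying F, the
    degrees of freedom, the uncorrected p value and partial eta squared.
    """
    import pingouin as pg

    counts = data.groupby([between, subject]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal observations per subject")
    per_group = data.groupby(between)[subject].nunique()
    if per_group.nunique() != 1:
        raise ValueError("unbalanced design: unequal subjects per group")
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between
    )
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    out = aov.rename(
        columns={"Source": "effect", "DF1": "df1", "DF2": "df2", pcol: "p",
                 "np2": "eta_p2"}
    )[["effect", "F", "df1", "df2", "p", "eta_p2"]]
    out["effect"] = out["effect"].map(
        {within: "within", between: "between", "Interaction": "interaction"}
    )
    return out


def extinction_pairs(
    blocks: pd.DataFrame, blocks_used: tuple[int, ...] = ANALYSIS_BLOCKS
) -> pd.DataFrame:
    """Per-run, per-block paired component proportions from extinction.

    Each run x block contributes one (A, B) pair, matching the convention
    in which two analysis blocks from each of 50 runs yield 100 pairs
    (t with 98 degrees of freedom).
    """
    e = blocks[(blocks.phase == "extinction") & blocks.block.isin(blocks_used)]
    return e.pivot_table(
        index=["run", "block"], columns="component", values="prop_correct"
    )


def extinction_run_means(
    blocks: pd.DataFrame,
    condition: str,
    blocks_used: tuple[int, ...] = ANALYSIS_BLOCKS,
) -> pd.DataFrame:
    """Per-run extinction means per component, in mixed-ANOVA long format."""
    e = blocks[(blocks.phase == "extinction") & blocks.block.isin(blocks_used)]
    m = e.groupby(["run", "component"], as_index=False)["prop_correct"].mean()
    m["condition"] = condition
    m["subject"] = condition + "_" + m["run"].astype(str)
    return m


def sensitivity_sweep(
    model,
    spec=None,
    beta_sr_values=(0.05, 0.09, 0.13, 0.17),
    beta_svo_values=(0.02, 0.04, 0.09, 0.13),
    n_seeds: int = 10,
    seed_base: int = 1,
) -> pd.DataFrame:
    """Learning-rate sensitivity grid on the two-lever within-subjects task.

    Sweeps the stimulus-response rate and the omission-value rate while the
    expectancy-response and magnitude-value rates stay fixed at 0.06, and
    classifies each cell by the sign of its extinction PREE index: cells
    with omission learning faster than the expectancy-response rate should
    be PREE-classified, slower cells RPREE-classified.
    """
    from .protocols import get_protocol, run_experiment

    spec = spec if spec is not None else get_protocol("ko_expl")
    rows = []
    for bsr in beta_sr_values:
        for bsvo in beta_svo_values:
            cfg = replace(
                model,
                actor=replace(model.actor, beta_sr=bsr, beta_er=0.06),
                critic=replace(model.critic, beta_o=bsvo, beta_m=0.06),
            )
            res = run_experiment(spec, cfg, n_runs=n_seeds, seed_base=seed_base)
            ix = phase_indices(res.blocks)
            for phase, val in ix.items():
                rows.append(
                    {"beta_sr": bsr, "beta_svo": bsvo, "phase": phase,
                     "pree_index": val,
                     "classification": "PREE" if val < 0 else "RPREE"}
                )
    return pd.DataFrame(rows)


def lesion_comparison(
    model,
    protocols=("ko_expl", "svartdal_multi"),
    n_runs: int = 50,
    seed_base: int = 1,
) -> pd.DataFrame:
    """Acquisition/extinction PREE indices for the full and lesioned models.

    Compares the full two-process model against the mediational-theory
    variant (stimulus-response route lesioned) and a plain actor-critic
    (expectancy-response route lesioned) on the given protocols. On the
    two-lever task only the full model transitions from a positive
    acquisition index to a negative extinction index; the actor-critic
    stays positive (reversed effect); on the single-rule task no model
    goes negative.
    """
    from .config import LesionConfig
    from .protocols import get_protocol, run_experiment

    variants = {
        "full_atp": LesionConfig(),
        "amt": LesionConfig(s_r=True),
        "actor_critic": LesionConfig(e_r=True),
    }
    rows = []
    for proto in protocols:
        spec = get_protocol(proto) if isinstance(proto, str) else proto
        for name, les in variants.items():
            cfg = replace(model, lesion=les)
            res = run_experiment(spec, cfg, n_runs=n_runs, seed_base=seed_base)
            ix = phase_indices(res.blocks)
            acq = res.blocks[res.blocks.phase == "acquisition"]
            final = acq[acq.block == acq.block.max()]["prop_correct"].mean()
            for phase, val in ix.items():
                rows.append(
                    {"protocol": spec.name, "model": name, "phase": phase,
                     "pree_index": val, "final_acquisition_correct": final}
                )
    return pd.DataFrame(rows)


def modulation_comparison(multi_blocks, high_blocks, low_blocks) -> dict[str, float]:
    """Within- versus between-subjects extinction persistence (blocks 2-3).

    Returns the four mean proportions needed to assess the modulation
    effect: in the multiple schedule the high-density component should be
    pulled up relative to the high-density-only control, and the
    low-density component pulled down relative to the low-density-only
    control, because the shared response pools the omission-expectancy
    support of both schedules.
    """
    def mean23(blocks, component=None):
        e = blocks[(blocks.phase == "extinction") & blocks.block.isin(ANALYSIS_BLOCKS)]
        if component is not None:
            e = e[e.component == component]
        return float(e["prop_correct"].mean())

    return {
        "within_high": mean23(multi_blocks, "A"),
        "within_low": mean23(multi_blocks, "B"),
        "between_high": mean23(high_blocks),
        "between_low": mean23(low_blocks),
    }
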