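# atpsim

A neurocomputational simulator of **partial reinforcement extinction
effects** (PREE) in discrete-trial discrimination learning, built around an
affective two-process actor–critic model: response choice is mediated both
by a retrospective stimulus→response route and by a prospective
stimulus→expectancy→response route in which learned *reward* and
*reward-omission* expectancies compete to cue responses.

It is intended for researchers in computational modelling of animal/human
learning who want to simulate, lesion and analyse two-phase
(acquisition/extinction) operant protocols in which the persistence of
responding after reward discontinuation depends on the reinforcement
schedule and on the response structure of the task.

## The model

A **dual-dimension critic** learns two temporal-difference value functions
over a complete-serial-compound (tapped delay line) stimulus
representation, one unit per post-onset timestep:

- magnitude value `V_m(t) = f'(Σ_ns θ_m,ns φ_ns(t))`, updated by
  `θ ← θ + β_m [δ_m]₊ ē_n`, where `δ_m(t) = λ(t−Δt) + γV_m(t) − V_m(t−Δt)`
  with `γ = 1 − Δt/τ`. The error is clipped at zero inside the update, so
  learned reinforcer magnitude is never unlearned and `V_m` converges to
  the full magnitude regardless of the schedule.
- omission value `V_o`, updated with the signed error
  `δ_o(t) = −δ_m(t) + γV_o(t) − V_o(t−Δt)`. Because an omitted-but-expected
  reward makes `δ_m` negative, `δ_o` is then positive: `V_o/V_m` converges
  to the experienced omission *probability*, rising and falling with the
  schedule.

A **neural-dynamic actor** (Amari-style leaky integrator nodes S1, S2, R1,
R2, backward-Euler step `u ← u + (Δt/τ_r)(−u + h + C·Λ(u) + I)`) selects a
response at the end of the target window. Two expectancy read-outs,
`Rew = [Λ(V_m; x_β, x_th) − Λ(V_o; x_β, x_th)]₊` and
`Om = Λ(Λ(V_o) − Rew; β_om, th_om)`, are mutually inhibitory, and the
slopes/thresholds of their sigmoids are *meta-parameters* sharpened by the
congruent prediction-error surprises — an XOR-like classification of
stimuli by expected outcome. All association weights (S→R, Rew→R, Om→R)
learn by a prediction-error-gated Hebbian rule driven by the signed reward
prediction error `−δ_o` of the omission critic.

Why this produces the dissociation: in a **two-lever task** (each stimulus
has its own correct lever, continuously vs partially reinforced), the
partial stimulus comes under omission-expectancy control during
acquisition. In extinction the omission expectancy spreads to the
continuous stimulus and actively cues the *other* lever — "counterfeit
extinction" — so the continuous schedule collapses below chance while the
partial one persists (a within-subjects PREE). In a **single-rule task**
(both stimuli share one rewarded response at high/low reinforcement
density), both expectancies cue the same response, the shared response
absorbs the omission-learning transients of *both* stimuli, and extinction
ordering simply follows acquired strength: the high-density component is
more persistent (a reversed PREE).

## Worked example

```python
from atpsim import ModelConfig, get_protocol, run_experiment
from atpsim.stats import phase_indices

res = run_experiment(get_protocol("ko_expl"), ModelConfig(),
                     n_runs=10, seed_base=1)
b = res.blocks
print(b[b.phase == "extinction"]
      .groupby(["block", "component"])["prop_correct"].mean().unstack())
print(phase_indices(b))
```

prints (component A = continuous schedule, B = partial; four extinction
blocks of 10 trials, mean over 10 seeded runs):

```
component     A     B
block
0          1.00  0.98
1          0.96  0.98
2          0.52  0.94
3          0.08  0.96
{'acquisition': 0.02, 'extinction': -0.078}
```

The continuous component collapses from perfect responding to 8% correct —
far below the 50% guessing level, the signature of the omission expectancy
actively cueing the wrong lever — while the partial component stays above
90%. The index `(CRF − PRF)/(CRF + PRF)` is positive in acquisition
(continuous learns faster) and negative in extinction (partial is more
persistent): a within-subjects PREE. Running the single-rule protocol
(`svartdal_multi`) the same way yields the opposite extinction sign.

The same experiments are available from the shell:

```bash
atpsim run --spec ko_expl --runs 50 --seed 1 --out results/
atpsim lesions --runs 50 --seed 1 --out results/      # full vs lesioned models
atpsim sweep --seed 1 --out results/                  # learning-rate grid
atpsim reproduce fig10 --out results/                 # data behind a figure
```

Bundled protocols: `ko_expl`, `ko_crf`, `ko_prf` (two-lever, 240
acquisition + 40 extinction trials), `svartdal_multi`, `svartdal_high`,
`svartdal_low` (single-rule, 180 + 40). YAML configuration files (see
`configs/ko_expl.yaml`) expose every equation constant, timing and
schedule; lesion flags remove the S→R route (mediational-theory variant),
the expectancy→R route (plain actor–critic) or the Rew/Om mutual
inhibition.

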