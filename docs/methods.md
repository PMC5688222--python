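# Methods

## Model

### Trial structure and stimulus representation

A trial is `T = 100` discrete steps (`Δt = 1`). The discriminative cue is
presented over steps 25–49, response options over 57–71 with the response
read out at step 71, and the reinforcer (if any) occupies step 72. The
cue-offset-to-reinforcer interval is therefore 22 steps. All timings live
in `TrialClock` and are configuration, not code.

The cue is encoded as a complete serial compound: a tapped delay line of
`N = 100` binary units per stimulus, unit *n* firing exactly at
`cue_onset + (n − 1)`. Each unit carries an eligibility trace set to 1 when
it fires and decaying geometrically thereafter. Two decay conventions are
implemented. The default uses the trace time constant κ = 9.6 directly
(per-step factor `1 − Δt/κ ≈ 0.896`, a trace spanning ~10 steps, which is
what lets value information propagate from the reinforcer back to the
decision point within a few tens of trials). The alternative
(`critic.trace_mode = "lambda_gamma"`) uses the product of the coefficient
pair `λ = 1 − (1 − Δt/κ)/(1 − Δt/τ)` and `γ = 1 − Δt/τ`, i.e. ≈ 0.0042 — an
effectively one-step trace. Under the one-step trace, backward propagation
of value advances roughly one delay-line unit per trial and decision-time
expectancies remain untrained within the protocols' trial budgets; we keep
it available for comparison but do not use it by default.

### Dual critic

Magnitude and omission values are linear read-outs of the delay line,
clamped to [0, 1]. Prediction errors take the discrete TD(0) form

    δ_m(t) = λ(t−Δt) + γ V_m(t) − V_m(t−Δt)
    δ_o(t) = −δ_m(t) + γ V_o(t) − V_o(t−Δt)

with γ = 1 − Δt/τ, τ = 10. A gain on the TD term (`critic.td_gain`) allows
the continuous-time scaling τ/Δt instead; with that scaling the asymptotic
pre-reinforcer value of a unit reward is Δt/τ = 0.1, which leaves the value
clamp inert and puts the values an order of magnitude below the range the
expectancy thresholds span, so the engine default is 1.0. At the default,
`V_m` converges to the reinforcer magnitude (here 1) and — because the
magnitude update clips its error at zero and never unlearns — stays there
through extinction, while `V_o/V_m` tracks the experienced omission
frequency. This is the division of labour that yields both the savings
effect (magnitude is retained; only omission must unlearn on
re-acquisition) and an explicit omission-probability estimate.

Weight updates pair the error at step *t* with the trace state of step
*t − Δt*, crediting the unit whose activation produced `V(t − Δt)`. The
alternative pairing (credit to the unit firing at *t* itself) closes a
positive feedback loop — the error grows with the very weight it updates —
and drives every value to the clamp; we verified this numerically and use
the contractive pairing throughout.

Learning rates: β_magnitude = 0.06, β_omission = 0.10. Omission learning
faster than magnitude (and faster than the expectancy-response rate below)
is the regime in which omission is tracked flexibly on a stable magnitude
estimate; the sensitivity sweep probes both sides of this regime.

### Actor

S1, S2, R1, R2 are Amari-style leaky integrators,
`u ← u + (Δt/τ_r)(−u + h_r + C_r Λ(u) + I)`, with sigmoidal output
`Λ(u) = 1/(1 + e^{−β_r u})`. The presented stimulus's S node receives unit
input during the cue and target windows. R nodes receive the weighted sum
of the four presynaptic sources (S1, S2, Om, Rew). At the decision step the
response with the larger output is chosen if it exceeds the decision
threshold; otherwise an undriven guess is made — uniform over the two
levers in the two-lever task, hitting the rewarded rule with probability
1/4 in the single-rule (button-sequence) task, whose four button
permutations are collapsed into a rule response and a guessing response.
The chosen response node receives an execution input from selection to
reinforcer offset, so that outcome errors are attributed to the action
actually taken; without some such efference the Hebbian rule cannot break
the symmetry between responses and acquisition never starts.

Expectancies are computed each step from the previous step's values:

    Rew = [Λ(V_m − x_th,rew; x_β,rew) − Λ(V_o − x_th,om; x_β,om)]₊
    Om  = Λ(Λ(V_o − x_th,om; x_β,om) − Rew; β_om, th_om)

The subtractions implement mutual inhibition (ablatable). The slopes and
thresholds are meta-parameters, clamped to [0.5, 20] and [0, 1], moved at
each outcome-evaluation step by `surprise/(C_j · I_r)` where `I_r` is the
input to the executed response node. Each side sharpens under the positive
part of its *congruent* error — the omission side under δ_o > 0, the
reward side under −δ_o > 0 — so classification precision grows with
surprise on that dimension. (Applying the signed error bidirectionally to
all four parameters is available as `meta.update_mode = "signed"`; there,
the surplus of omission surprises during the error-laden early phase pins
the reward-side threshold at its ceiling and the reward classifier never
forms.)

### Association learning

All learnable actor weights update at the outcome-evaluation step by

    Ω_kl ← Ω_kl + β_e · g · Λ(u_k) Λ(u_l),   g = −δ_o (signed),

the omission critic's error read as a reward prediction error: at the
critic's fixed point it is +(1 − p̂) on rewarded trials and −p̂ on omission
trials. Three consequences structure everything downstream. (1) Expectancy
weights form only where an expectancy is active when a response pays off —
omission→response associations arise on partial schedules (omission
expectancy active, response still intermittently rewarded) and never on a
never-rewarded response. (2) In extinction the total unlearning a response
suffers equals the integrated positive omission error of every stimulus
driving it, i.e. `ΔV_o/β_omission` per stimulus — which ties extinction
persistence to the omission learning rate (the sweep's regime boundary)
and makes a response shared by two stimuli extinguish roughly twice as
fast as a response owned by one. (3) Weights are floored at zero
(associations extinguish rather than turn inhibitory) and the expectancy
rows unlearn at a reduced rate (`er_unlearn_factor = 0.2`, asymmetric
potentiation/depression), which preserves the acquired omission→response
association long enough for it to take over response control in
extinction.

Lesions: `lesion.s_r` zeroes and freezes the S→R rows (the
prospective-only, mediational-theory model); `lesion.e_r` zeroes and
freezes the Om/Rew rows (a plain actor–critic);
`lesion.mutual_inhibition=False` removes the Rew/Om competition. Node
activations and traces reset between trials; weights and meta-parameters
persist.

## Parameters

| parameter | value | meaning |
|---|---|---|
| τ | 10 steps | value discount time constant (γ = 0.9) |
| κ | 9.6 steps | eligibility-trace time constant |
| β_S-Vm | 0.06 | magnitude-value learning rate |
| β_S-Vo | 0.10 | omission-value learning rate |
| β_S-R | 0.105 | stimulus-response rate |
| β_E-R | 0.06 | expectancy-response rate |
| er_unlearn_factor | 0.2 | E-R depression / potentiation ratio |
| τ_r, h_r, C_r, β_r | 5, −1, 1.2, 4 | node time constant, rest, self-excitation, gain |
| decision threshold | 0.525 | on sigmoided R output |
| exec. / stimulus input | 2.2 / 1.0 | execution and cue drives |
| β_om, th_om | 10, 0.29 | Om outer sigmoid |
| C_j | 3 | meta-learning divisor |
| init slope / threshold | 4.2 / 0.5 | fresh classifier state |

The critic constants and the two fixed rates (β_S-Vm, β_E-R = 0.06) are
standard TD values used throughout. The actor constants are free
parameters of this implementation: no reference table was available, so
they were calibrated by randomized search against the qualitative targets
the model must meet jointly — acquisition on all schedules (including
bootstrap from 25% guessing), the within-subjects PREE with its
below-chance continuous-schedule collapse on the two-lever task, the
reversed effect with extinction means near 0.64/0.58 on the single-rule
task, and stable omission/reward classification — and frozen before the
test suite was written. β_S-R = 0.105 rather than 0.06 because at 0.06 the
single-rule task cannot bootstrap acquisition within 180 trials; the
sensitivity sweep treats β_S-R as a free axis in any case.

## What the simulations do and do not emulate

Protocols are generated internally: balanced pseudo-random stimulus
orders (exact balance within each reporting block, at most three
successive same-type trials, constraint enforced across block
boundaries), Bernoulli reinforcement of correct responses, extinction as
reinforcement probability zero, 50 independently seeded model instances
per condition with named substreams (trial order, rewards, guesses,
tie-breaks) per run. They do not model pre-training, inter-trial
intervals (activations reset between trials), response-repetition
criteria (one response per trial), free-operant response rates, or
magnitude discrimination; the button-sequence task is abstracted to a
rule/guess choice with a 0.25 guessing baseline. Passing tests therefore
speak to the schedule-dependent control of *choice* under these
idealisations, not to vigour effects or to literal motor sequences.

## Statistics

Block summaries are per-run correct proportions per schedule component.
The PREE index is `(CRF − PRF)/(CRF + PRF)`, evaluated on the last
acquisition block and the first three extinction blocks. Inferential
statistics use extinction blocks 2–3 only (after the inertial transient,
before absolute extinction): the paired *t* treats each run × block pair
as an observation (100 pairs from 50 runs), while the mixed ANOVA takes
per-run means (one observation per run and component; with 50 runs per
condition this reproduces the conventional (1, 147)/(2, 147) degrees of
freedom). The ANOVA is computed by pingouin; the test suite checks it
against a closed-form split-plot oracle. Log-proportion-to-baseline
extinction curves use the natural log by default (configurable), flooring
zero proportions at a configurable epsilon.

One reporting choice deserves note: a pooled within-subjects F of ~8
alongside component SEMs of ~0.023–0.026, a component difference of 0.06
and null control asymmetries is only attainable if the run-level
correlation between components is very high (ρ ≈ 0.85). Our simulated
correlation structure is weaker, so the pooled within-factor F lands near
2–2.5 even when the component means, their CIs and the paired *t* are
reproduced closely; the acceptance suite reports this statistic as
computed rather than adjusting the simulator toward it.

## Numerical and reporting choices

- Problem sizes: experiments are 50 runs × 280 (two-lever) or 220
  (single-rule) trials of 100 steps; the sweep uses a 4 × 4 grid
  (β_S-R ∈ {0.05, 0.09, 0.13, 0.17}, β_S-Vo ∈ {0.02, 0.04, 0.09, 0.13})
  at 10 seeds per cell; savings and convergence checks use 10 seeds. A
  50-run experiment takes a few seconds (the batch advances in lockstep
  with a leading run axis).
- Exact ties between response outputs are broken by the tie-break
  substream; undriven trials fall back to the protocol's guessing
  baseline.
- The savings probe runs fixed-length acquisition (200 trials),
  extinction (60) and re-acquisition (120) phases on a single continuous
  contingency and measures trials-to-criterion (80% correct over a
  trailing 10-trial window).
- Run-level reproducibility: run *i* draws only from substreams of seed
  `seed_base + i`, so any run is bit-identical whether executed alone or
  inside a batch.

## Known limitations

- The delay-line stimulus representation is biologically coarse: constant
  relay of the cue to reinforcer onset and symmetric positive/negative
  error magnitudes. Radial-basis ("microstimuli") representations are out
  of scope.
- Negative reinforcer magnitudes and slow magnitude unlearning are not
  modelled; magnitude is strictly non-decreasing.
- The expectancy meta-parameters only sharpen (congruent mode); across
  repeated acquisition–extinction cycles a de-sharpening mechanism would
  be needed.
- The actor constants are a calibrated set, not a measured one: quantities
  that depend on their fine balance (e.g. the pooled within-subjects F
  discussed above, or exact extinction block shapes) carry that
  uncertainty, while the sign structure of the effects is robust across
  the sweep's rate grid.
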