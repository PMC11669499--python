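# Methods

## Scoring

RTS uses the Champion coded categories — GCS 13–15→4, 9–12→3, 6–8→2,
4–5→1, 3→0; SBP >89→4, 76–89→3, 50–75→2, 1–49→1, 0→0; RR 10–29→4,
>29→3, 6–9→2, 1–5→1, 0→0 — with weights 0.9368/0.7326/0.2908, giving the
familiar maximum 7.8408 (reported as 7.84).  RTS is carried at full
precision internally and only rounded for display.  ISS is the sum of
squares of the three most severe of six AIS region severities; fewer
than three injured regions contribute zeros; AIS 6 in any region sets
ISS = 75 by registry convention; an all-zero profile raises a no-injury
error so the caller decides whether such records are scorable.

Age-adjusted hypotension follows the PALS convention by default
(SBP < 60 mmHg under 1 y, < 70 + 2·age for 1–10 y, < 90 mmHg above
10 y); this definition is a convention rather than a universal standard,
so every cut point is a keyword argument.

## The pediatric refit

Survival (alive at 30 days) is the modelled outcome, so the linear
predictor is directly the TRISS `b`.  Each mechanism stratum is fit
independently by Newton–Raphson with step-halving; convergence is a
relative log-likelihood change below 1e-10 (max 100 iterations);
standard errors come from the inverse observed information at the
optimum.  Quasi-complete separation is detected as a coefficient passing
15 on the standardised scale and reported as an error naming the
predictor — no silent shrinkage.  No regularisation is applied, matching
the plain-MLE character of the original derivation.

The pooled model reports a single log-likelihood (the sum over the two
independent strata), k = 8 parameters, and AIC = 2k − 2lnL,
BIC = k·ln(n) − 2lnL with n the total records.  Treating the pair of
stratum fits as one model is an interpretation: a mechanism-interaction
model fit jointly would give the same estimates and information criteria,
so nothing hinges on it.  An age-free reduced design (k = 6) is available
for specification comparisons.

## Evaluation

* **AUROC** is the midrank Mann–Whitney estimator (ties count ½);
  survivors are the positive class for Ps, which is identical to taking
  deaths as positive for 1 − Ps.  Confidence intervals and the paired
  two-model test use the DeLong structural-components variance with a
  normal approximation, two-sided 95%.
* **Hosmer–Lemeshow** cuts records into deciles of predicted risk with
  ties kept together (quantile bins; tied boundaries merge, reducing g),
  and uses df = g − 2.  The df = g − 2 null is the one for probabilities
  *fitted* to the evaluated data — the two lost degrees of freedom charge
  the estimated parameters — so the null-uniformity test refits before
  computing the statistic; externally fixed probabilities would follow
  ~chi-square(g) instead.  Fewer than three distinct risk groups is
  treated as degenerate.
* **CITL** is the intercept of a logistic refit of the outcomes with
  logit(Ps) as a fixed offset; the **calibration slope** is the
  coefficient of logit(Ps) in a free logistic refit.  Both use a small
  internal Newton solver (1–2 parameters) so the bootstrap stays fast;
  they agree with statsmodels GLM/Logit to 1e-6 in the tests.
* **E:O** uses death as the event (the rarer outcome): expected deaths
  Σ(1 − Ps) over observed deaths.  Stated prominently because either
  orientation appears in the literature.
* Ps values of exactly 0 or 1 are clipped to machine-safe bounds with a
  warning before any logit.

## Internal validation

Harrell's optimism bootstrap: for each resample, the whole refit recipe
is re-run on the bootstrap sample and evaluated on both the bootstrap
sample and the original cohort; optimism is the mean difference and
corrected = apparent − optimism, for the C statistic, CITL, slope and
E:O.  Resampling is at the patient level, stratified by mechanism so
every resample can fit both strata (an unstratified mode exists).
Resamples whose refit fails (separation, single-class stratum) are
skipped and counted; more than 20% failures aborts with a diagnostic
rather than reporting a biased summary.  Everything is reproducible from
(cohort, n_boot, seed).

## DEF benchmarking

Z = (S − ΣPi)/√(ΣPiQi) with Qi = 1 − Pi; the ±1.96 threshold gives the
5% significance label.  The expected-count validity rule (ΣPi ≥ 5 and
ΣQi ≥ 5) is emitted as a flag plus warning, not a hard error.  The six
Ps bands follow the MTOS convention 0–0.25, 0.25–0.50, 0.50–0.75,
0.75–0.90, 0.90–0.95, 0.95–1.00, applied half-open on the lower edge
with both extremes included; the interior cut points are configurable.
M is the sum of band-wise minimum fractions between the study group and
a reference band mix, which the user supplies directly or as a
reference-scored cohort (the classical MTOS mix is not bundled).  W is
the standard DEF excess-survivor rate 100·(S − ΣPi)/n.

## Synthetic cohorts

The generator emulates a single-centre pediatric trauma registry:
age drawn from four bands (probabilities 21.2/21.8/23.9/33.1% for
0–4/5–9/10–14/15–17 y, uniform within band, giving median ≈ 11.5 y and
IQR ≈ 6–16), 73% male, 66.2% blunt.  A single latent severity
u ~ N(0,1) drives ISS = round(LogNormal(ln 9, 1.0)) clipped to [1, 75]
(median 9, quartiles ≈ 5–18, P(ISS ≥ 16) ≈ 0.29 — a two-parameter
log-normal cannot hit median, IQR and the severe fraction simultaneously,
so the median and severe fraction were prioritised).  A correlated
physiology latent (ρ = 0.7) degrades GCS, SBP and RR from healthy
age-dependent baselines once it exceeds 0.45, reproducing a registry-like
RTS profile (lower quartile ≈ 7.11, median 7.84).  Outcomes are Bernoulli
with survival probability from a chosen coefficient set;
`mortality_logit_offset` shifts the linear predictor, with the default
−0.9 calibrating overall mortality to ≈ 5.7% and 0 drawing outcomes
exactly from the named model (the setting used for coefficient-recovery
and null-benchmark experiments).  Missingness injection is
missing-completely-at-random per field.

What the generator does *not* emulate: region-specific injury patterns
(it emits ISS directly rather than AIS profiles), physiology measurement
artefacts (intubated GCS, pre-hospital intervention effects), secular
trends, and within-mechanism case-mix differences beyond the single
latent.  Passing tests therefore demonstrate the correctness of the
statistical machinery under a realistic marginal structure, not the
clinical transportability of any particular coefficient set.

## Problem sizes and numerical choices

Coefficient-recovery experiments use 200,000 records per mechanism,
where the refit's sampling error is small against the published standard
errors; null-distribution checks use 500 replicates of n = 2,000;
bootstrap validation defaults to 500 resamples.  The single-cohort |Z|
check is one standard-normal draw under the null, so ~5% of seeds
legitimately exceed 1.96; the replicate-mean check is the stable
companion.  All RNG flows through `numpy.random.default_rng` with
explicit seeds; no global state.  Cohort CSV floats are parsed with
exact shortest-repr conversion so write→read round-trips bit-exactly.
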