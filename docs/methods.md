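# Methods

## The generative model

`mpcsim` simulates a population answering a PRO at two waves and a Patient
Global Rating of Change (PGRC) at the second wave, with a fully known ground
truth for the Minimal Perceived Change (MPC).

**Latent construct.** Each subject carries a standardized antecedent
(stable disposition) A ~ N(0,1), a catalyst event C (Bernoulli, log-odds
`logit(catalyst_prob) + beta_sc1_on_catalyst·(SC_t1 − mean)`), a coping
mechanism M = `beta_sc1_on_mechanism`·(SC_t1 − mean) + C·N(0,1), and the
construct levels

```
SC_t1 ~ N(mean_sc_t1, sd_sc_t1²)
SC_t2 = rho_auto·SC_t1 + beta_catalyst_on_sc2·C + beta_antecedent_on_sc2·A
        + beta_mechanism_on_sc2·M + N(0, sd_resid_sc2²)
```

All paths are linear-Gaussian. The conceptual model underlying this package
deliberately makes no commitment to functional forms, so linearity is our
documented default, with every coefficient exposed in the configuration.
Two simplifications are built in: (i) the antecedent's influence on the
*time-1* quantities is folded into the marginal distributions of SC_t1 and
`catalyst_prob` — those paths are unidentifiable from simulated two-wave
data and do not move the MPC truth; (ii) the mechanism acts additively on
SC_t2 rather than buffering the catalyst path, which keeps the model linear.
Appraisal processes (how the construct is *construed* at each wave) have no
specified functional form and are not operationalized.

**Recall and perceived change.** The remembered baseline is

```
SC_t1mem = lam·SC_t1 + psi·SC_t2 + gamma_a·A + gamma_c·C + gamma_m·M + N(0, sd_mem²)
PC = SC_t2 − SC_t1mem        (exact, machine precision)
```

`lam = 1, psi = 0` is perfect recall (PC equals the true change);
`lam = 0, psi = 1` is pure reconstruction from the present state, the
"implicit theory of change". The relative magnitude of the two processes is
an open empirical question, so both weights are free (a `convex` preset
gives psi = 1 − lam). Recall noise `sd_mem` is the central lever for recall
bias: it attenuates the correlation between the observed change score and
the PC, which is exactly what degrades anchor-based estimation.

**PGRC and the MPC.** A k-category PGRC (k ∈ {3, 5, 7}) is answered by
discretizing PC with k−1 per-subject thresholds τ_s ~ N(μ_s, σ_s²),
independent across subjects and across s. The threshold family is normal by
convention (recorded in the config so alternatives can be added). The truth
is MPC₊ = μ of the threshold just above the middle category and MPC₋ = μ of
the one just below; the middle category must span 0, a convention we enforce
(whether MPC₋ must be negative is not settled; asymmetric values such as
(−1.0, +0.8) are the normal case). Two numerical choices matter:

* *Ordering violations* are handled by whole-vector rejection sampling, not
  coordinate sorting — sorting would distort the marginal locations and
  silently break MPC₊ = μ₁. The rejection rate is logged, a warning fires
  above 10%, and a hard cap (`max_reject_iters`) raises with advice to widen
  the μ spacing.
* *Boundary ties* (PC exactly equal to a threshold) go to the upper
  category: left-closed/right-open intervals, measure-zero under a
  continuous PC but fixed for reproducibility.

**Measurement.** CTT mode adds independent normal error per wave with
variance σ_T²·(1−ρ)/ρ, so the reliability of each wave is exactly ρ; the
true-score variance is the structural value (closed form when the catalyst
is independent of SC_t1, sample variance otherwise). IRT mode draws item
responses from Samejima's graded response model (logistic,
discrimination/location parameterization) and sums them; no latent-trait
scoring is done, matching applied MID practice. The latent-scale MPC is
mapped to score units by the identity in CTT mode and by the test
characteristic curve around the baseline mean in IRT mode,
`tcc(θ̄ + MPC) − tcc(θ̄)`. Whether PC units and score units are commensurable
at all is a modeling convention; the TCC mapping is one defensible choice
and is echoed into every summary row for transparency.

## Estimators

Anchor-based (guarded by the Spearman correlation between change score and
PGRC category; default cut-off 0.30, encoding "at least moderate"):

* `mean_change_minimal_group` — mean change among category ±1;
* `mean_diff_adjacent` — that mean minus the middle-category mean;
* `roc_threshold` — the cut-point on the change score best separating
  "changed" (all categories on the requested side) from "no change" (middle
  category only; opposite side excluded). Candidates are midpoints between
  consecutive distinct pooled values plus one beyond each extreme, so the
  classification rule is unambiguous at data points. Criteria: Euclidean
  distance to (sens, spec) = (1, 1), Youden's J, or a weighted quadratic.
  Ties break to the smallest |threshold|, then the smallest threshold.

Distribution-based, for comparison: `es_based` (0.5 × SD of baseline, Cohen's
moderate effect) and `sem_based` (SD·√(1−ρ)). They are functions of score
variability only — invariant to every PGRC parameter — which is the point:
nothing ties them to the perceived-change threshold.

Empty anchor groups yield first-class `not_estimable` results, never
exceptions, so scenario grids do not abort; summaries report `n_estimable`
per estimator and exclude those replications pairwise.

## Evaluation

A replication runs latent → recall → perceived change → measurement → PGRC →
estimators from one seeded `numpy` generator, consumed in that fixed order
(so scenarios differing only in a later stage share all earlier draws — this
is what makes the distribution-based estimates bit-identical across PGRC
variants). Replication seeds come from a `SeedSequence` on the scenario's
`base_seed`; grid children get derived distinct seeds. Per estimator ×
direction the summary reports bias = mean − truth, empirical SD, RMSE
(against truth, so RMSE² = bias² + SD²·(n−1)/n), and the Monte-Carlo SE of
the bias.

## Reference study conditions

The noise-free reference scenario (`degenerate_scenario`) fixes
SC_t1 ~ N(0,1), SC_t2 = SC_t1 + N(0,1), perfect recall, reliability 1,
σ_s = 0, and asymmetric truth (MPC₊, MPC₋) = (+0.8, −1.0); k = 5/7 variants
add outer thresholds 2 units beyond. Default problem sizes are n = 5000
subjects and R = 200 replications — enough that the Monte-Carlo SE of the
ROC mean estimate is ~10⁻⁴ in the noise-free limit while a full grid still
runs in seconds. Under these conditions the Euclidean-ROC estimator recovers
the truth up to the inter-observation gap (it is a midpoint between two
order statistics, so its resolution is one gap), the group-mean estimators
overshoot the threshold (a conditional mean beyond a cut-off exceeds the
cut-off), and raising `sd_mem` over {0, 0.5, 1.0} monotonically lowers the
change/PC correlation and inflates ROC bias.

## What the generator does and does not emulate

It emulates: recall bias of configurable strength and direction,
subject-specific change thresholds, asymmetric improvement/deterioration
truths, floor/ceiling and coarseness effects of short Likert instruments
(IRT mode), and anchor/score misalignment. It does not emulate: response
shift in the appraisal sense (reconceptualization/recalibration of the
construct), nonlinear or interactive structural effects, within-subject
correlation among thresholds or threshold dependence on traits, PGRC
measurement error beyond threshold randomness, or missing data. Passing
tests therefore demonstrate estimator behavior *under the model's
assumptions*, not performance on any real instrument.

## Known limitations

* The normal threshold family and the linear recall equation are
  conventions; both are isolated behind the config schema.
* CTT mode equates score and construct scales (unit loading); real
  instruments rarely do.
* `mean_diff_adjacent` contrasts against the middle category only; with
  k > 3 the "no change" reference could arguably pool adjacent mild
  categories — not implemented.
* Estimating the threshold *dispersion* σ₁ (not just the location) is a
  natural next step and is out of scope here.
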