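# mpcsim

Monte-Carlo simulation of the **Minimal Perceived Change** (MPC) and the
statistical properties of the estimators used to interpret change in
Patient-Reported Outcome (PRO) scores.

## The problem

PROs (pain, fatigue, health-related quality of life…) are scored on
arbitrary scales, so a change of, say, 4 points is hard to interpret. The
applied literature estimates a *Minimal Important Difference* (MID) — the
smallest score change patients perceive as change — usually by anchoring the
two-wave change score to a *Patient Global Rating of Change* (PGRC: "since
baseline, is your quality of life worse / the same / better?"). Dozens of
estimators are in use, with little knowledge of their bias, because the
target was never defined as a population parameter.

`mpcsim` operationalizes a formal definition. Answering a PGRC with k
ordered categories is modeled as discretizing a latent continuous
*Perceived Change* (PC) with k−1 per-subject random thresholds
τ_s ~ N(μ_s, σ_s²). The MPC is the **location parameter of the threshold
separating "no change" from change**:

```
MPC₊ = μ₁   (improvement side)        MPC₋ = μ₋₁   (deterioration side)
```

The perceived change itself is generated by a structural model of recall:

```
PC = SC_t2 − SC_t1mem
SC_t1mem = λ·SC_t1 + ψ·SC_t2 + γ_a·antecedent + γ_c·catalyst + γ_m·mechanism + N(0, σ_mem²)
```

where SC_t1, SC_t2 are the latent construct levels at the two waves
(linear-Gaussian structural equations with a Bernoulli catalyst event,
stable antecedents and coping mechanisms), λ is accurate memory of the
baseline and ψ is reconstruction from the present state (the "implicit
theory of change"). Observed scores add psychometric error — classical test
theory with configurable reliability, or a graded response model item bank.

Because every simulated population has a *known* MPC, the package can
measure the bias, SD and RMSE of each estimator under configurable
scenarios:

* **anchor-based** — mean change of the minimally-changed group, the
  adjacent-group mean difference, and the ROC cut-point (Euclidean distance
  to (0,1), Youden, or sensitivity/specificity-weighted), each guarded by
  the Spearman correlation between change score and anchor;
* **distribution-based** — 0.5 × SD(baseline) (effect-size rule) and
  1 × SEM = SD(baseline)·√(1−ρ), included for comparison: they never see the
  anchor, so they can match the MPC only by accident.

## Worked example

`demo.yaml`:

```yaml
scenario_id: demo
n_subjects: 1000
n_replications: 20
base_seed: 42
latent: {mean_sc_t1: 0.0, sd_sc_t1: 1.0, rho_auto: 1.0, sd_resid_sc2: 1.0}
recall: {lam: 1.0, psi: 0.0, sd_mem: 0.3}
measurement: {mode: ctt, reliability: 0.9}
pgrc:
  k: 3
  thresholds:
    - {mu: -1.0, sigma: 0.2}   # MPC₋ = −1.0
    - {mu: 0.8, sigma: 0.2}    # MPC₊ = +0.8
```

```bash
mpcsim run --config demo.yaml --out demo_out/
```

prints (excerpt):

```
             estimator_id   direction  truth  mean_estimate      bias  empirical_sd     rmse
mean_change_minimal_group improvement    0.8       1.236386  0.436386      0.040752 0.438190
       mean_diff_adjacent improvement    0.8       1.306110  0.506110      0.061039 0.509594
            roc_threshold improvement    0.8       0.566617 -0.233383      0.090952 0.249652
                 es_based improvement    0.8       0.532785 -0.267215      0.014518 0.267589
                sem_based improvement    0.8       0.336963 -0.463037      0.009182 0.463123
```

Reading: the group-mean estimators overshoot the true MPC₊ = 0.8 (the mean
of changes *beyond* a threshold exceeds the threshold), the ROC cut-point is
closest but attenuated by recall noise (sd_mem = 0.3) and measurement error
(ρ = 0.9), and the distribution-based rules land wherever the score SD puts
them. In the noise-free limit the ROC estimator recovers 0.8 to the third
decimal (see the acceptance script below). The run also writes
`replications.csv`, `summary.csv`, `summary_long.csv` and
`config_resolved.json`.

The library API mirrors the CLI: `load_config`, `expand_grid`,
`run_scenario`, `summarize_grid`, and the individual pipeline stages
(`simulate_subjects`, `observe_ctt` / `simulate_responses`, `simulate_pgrc`,
`run_all`). `mpcsim estimate --panel panel.csv --pgrc pgrc.csv --out est.csv`
runs the estimators on real two-wave data.

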