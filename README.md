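# polycompare

Information-theoretic comparison of competing polynomial hypotheses about how
two personality traits — extraversion (E) and neuroticism (N) — relate to
loneliness (L) in adolescent cohorts.  Built for personality/developmental
researchers who want to move past "is the linear effect significant?" and ask
*which* of a complete set of shapes — additive-linear, saturating,
exponential, or genuinely interactive — the data actually support.

## The method

Every hypothesis is a constrained version of the full second-order polynomial

    L = b0 + b1·E + b2·N + b3·E² + b4·E·N + b5·N²

on POMS-rescaled (1–7), mean-centered traits.  The candidate set holds 19
models: the null; {linear, saturating, exponential} effect shapes for each
trait alone and in all 3×3 combinations; two one-parameter interaction
surfaces (mutual compensation, c·(E−e_hi)(N−n_lo) with c ≤ 0; optimal
constellation, c·(E−e_lo)(N−n_hi) with c ≥ 0); and the unconstrained full
model.  Shape constraints are inequalities anchored at the observed trait
range, e.g. saturating extraversion = {b3 ≥ 0, b1 + 2·b3·e_hi ≤ 0}.

Each model is fitted by constrained Gaussian ML (exact active-set QP on the
profile likelihood; persons missing the follow-up outcome stay in the AICc
sample size but not in the conditional likelihood).  After a full-vs-null
likelihood-ratio gate, models are ranked by

    AICc = −2·LL + 2·K + 2·K(K+1)/(n − K − 1),

near-redundant nested models (LL gain < 1) are pruned, and Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) yield a 95% confidence set of models and
evidence ratios.  Full models in the confidence set are interpreted as
response surfaces (a1 = b1+b2, a2 = b3+b4+b5, a3 = b1−b2, a4 = b3−b4+b5)
restricted to the convex hull of the observed trait pairs.  A power module
and a synthetic-cohort generator make every stage testable without access to
the original questionnaire data.  See `docs/methods.md` for the details.

## Worked example

```python
from polycompare import RunConfig, SynthConfig, run_analysis

result = run_analysis(RunConfig(
    synth=SynthConfig(n=237, model="Linear Main Effects Model",
                      t2_missing_rate=0.4557, seed=20237),
))
g = result.gate
print(f"LR gate: chi2({g.df}) = {g.statistic:.2f}, p = {g.p:.2e}")
print(result.table.table.loc[result.table.table.in_confidence_set,
                             ["model", "K", "LL", "AICc", "weight"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints

```
LR gate: chi2(5) = 80.13, p = 7.89e-16
                      model  K       LL    AICc  weight
  Linear Main Effects Model  4 -267.003 542.179   0.677
Optimal Constellation Model  3 -268.872 543.847   0.294
```

Reading: the full model explains far more variance than the null (the gate
passes), and after pruning, the generating linear-main-effects model carries
68% of the evidence — it would take an evidence ratio of 0.677/0.294 ≈ 2.3 to
prefer it over the next candidate.  No other model has more than a 5% chance
of being the best in the set.

The same pipeline is available from the shell
(`polycompare simulate|prepare|fit|compare|surface|power|recover|run`), and
`analysis/01…06` run the complete study arc — cohort simulation,
cross-sectional and longitudinal comparisons, response surfaces, a-priori
power, and pipeline recovery checks — writing tables under `results/`.

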