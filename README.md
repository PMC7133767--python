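# mr2s — two-sample Mendelian randomization of serum uric acid on multiple sclerosis

Observational studies consistently find lower serum uric acid (UA) in
people with multiple sclerosis (MS), but cannot say whether low UA is a
cause of MS or a consequence of it.  `mr2s` implements the two-sample
Mendelian randomization (MR) analysis that addresses this question with
GWAS summary statistics alone: UA-associated SNPs serve as instrumental
variables, their effects on UA (mg/dl per allele, from a urate GWAS
meta-analysis of 110,347 individuals) are combined with their effects on
MS risk (log-odds, from two MS case-control studies of 38,589 and 27,148
individuals), and the ratio of the two estimates the causal effect of UA
on MS under the instrumental-variable assumptions.

The package is organised as a library (`src/mr2s/`) driven by narrative
analysis scripts (`analysis/01_…` to `05_…`); every computation lives in
the library, so each step is unit-tested and importable.

## Methods implemented

With harmonized per-SNP effects (β̂ᵢˣ, σᵢˣ) on exposure and (β̂ᵢʸ, σᵢʸ) on
outcome:

* **Wald ratio** per SNP: θ̂ᵢ = β̂ᵢʸ/β̂ᵢˣ, first-order SE σᵢʸ/|β̂ᵢˣ|.
* **IVW**: θ̂ = Σwᵢθ̂ᵢ/Σwᵢ with wᵢ = (β̂ᵢˣ)²/(σᵢʸ)²; multiplicative
  random-effects SE scales the fixed SE by max(1, √(Q/(k−1))).
* **MR-Egger**: WLS of β̂ᵢʸ on β̂ᵢˣ with free intercept; the intercept
  tests average directional pleiotropy, the slope estimates the causal
  effect under InSIDE; t inference on k−2 df.
* **Weighted median**: ratio at normalized cumulative weight 0.5
  (midpoint convention), SE by seeded parametric bootstrap.
* **Mode-based estimate**: peak of a normal-kernel density of the ratios
  (Silverman-style bandwidth × φ), consistent when the largest cluster of
  SNPs is valid.
* **Diagnostics**: Cochran's Q with per-SNP contributions, χ²(1) outlier
  flagging, leave-one-out, funnel/forest tables.
* **Instrument strength & power**: r² = 2p(1−p)β²/SD², F statistic,
  binary-outcome power Φ(|ln OR|·√(n r² f(1−f)) − z₁₋α/₂).

The front end handles the standard summary-data chores: allele
harmonization (swaps, strand complements, palindrome policy), greedy LD
pruning (r² > 0.01), and high-LD proxy substitution (r² > 0.8) across
priority-ordered outcome panels.  A seeded synthetic-data generator
produces two-sample tables with known causal effect and configurable
horizontal pleiotropy (balanced / directional / InSIDE-violating) for
calibration testing.

## Worked example

The 18-SNP study dataset ships with the package:

```bash
python analysis/01_reproduce_main_mr.py
```

prints

```
instruments: 18 analyzed (9 via proxies)

pooled causal estimates (OR of MS per 1 mg/dl uric acid):
  ivw_fixed        OR 1.05 (95% CI 0.97-1.15; p = 0.22)
  ivw_random       OR 1.05 (95% CI 0.92-1.21; p = 0.45)
  weighted_median  OR 1.00 (95% CI 0.91-1.10; p = 0.99)
  mode_based       OR 1.00 (95% CI 0.90-1.10; p = 0.97)
  egger            OR 0.99 (95% CI 0.81-1.22; p = 0.93)

Egger intercept 0.0093 (SE 0.0100, p = 0.37) — no evidence of net directional pleiotropy
Cochran's Q = 44.1 on 17 df (p = 3.3e-04)
```

Every method's confidence interval covers OR = 1: genetically raised UA
does not move MS risk.  The significant Q reflects two outlier SNPs
(rs653178, rs1165151); `analysis/02_sensitivity_subsets.py` shows the
heterogeneity disappears when they are excluded while the pooled OR stays
at 1.00.  Scripts 03–05 cover instrument strength/power, estimator
calibration on synthetic truth, and the reverse direction (MS → UA).

Or from Python:

```python
from mr2s import table1_fixture, ivw
ds, exposure = table1_fixture()
print(ivw(ds).or_scale)        # OddsRatioScale(or_=1.054..., ci_low=0.919..., ci_high=1.208...)
```

The same pipeline runs on your own TSVs via the CLI:

```bash
mr2s run --config config.yaml --out results/
mr2s power --n-outcome 38589 --case-fraction 0.3757 --r2 0.05 --target-power 0.8
```

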