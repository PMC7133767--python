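# Methods

## Model

Two-sample MR treats each SNP i as an instrument for the exposure.  The
observed summary effects are modelled as

    β̂ᵢˣ ~ N(βᵢˣ, (σᵢˣ)²)        (exposure GWAS, serum urate, mg/dl per allele)
    β̂ᵢʸ ~ N(θ βᵢˣ + αᵢ, (σᵢʸ)²)  (outcome GWAS, MS log-odds per allele)

independently across samples.  θ is the causal log-odds of MS per 1 mg/dl
urate; αᵢ is SNP i's horizontal-pleiotropy (direct) effect, zero for a
valid instrument.  The estimators differ in which assumption about {αᵢ}
they need: IVW assumes all αᵢ = 0 (or balanced, with the random-effects
SE absorbing the extra dispersion); MR-Egger allows a common nonzero mean
of αᵢ provided pleiotropy is uncorrelated with instrument strength
(InSIDE); the weighted median needs ≥ 50% of weight on valid instruments;
the mode-based estimate needs only the largest cluster to be valid.

## Estimator conventions

* **Scale.** All internal estimates are log-odds per mg/dl; `or_scale`
  exponentiates.  The 0.975 normal quantile is frozen at 1.959964 so CI
  conversions are bit-stable.
* **Wald ratio SE** is first-order (outcome error only).  The
  second-order variant (adding β̂ʸ²σˣ²/β̂ˣ⁴) is available but off by
  default; with the study's instruments the difference is < 2%.
* **IVW** uses weights (β̂ᵢˣ)²/(σᵢʸ)², i.e. the inverse first-order ratio
  variance.  The multiplicative random-effects SE multiplies the fixed SE
  by √(Q/(k−1)) floored at 1, leaving the point estimate unchanged —
  which is why the fixed and random ORs printed for the study coincide.
  Inference is normal-based.  Because the dispersion factor is estimated
  on k−1 df and the floor discards under-dispersion, the realised type-I
  error at k = 20 runs slightly above nominal (≈ 5.5% at α = 5% in the
  calibration suite); t-based inference would over-correct in the
  common no-pleiotropy case.
* **MR-Egger** first orients every pair so β̂ᵢˣ > 0 (the model is
  identified only up to that orientation), fits WLS with weights
  1/(σᵢʸ)², inflates both SEs by the residual scale floored at 1, and
  uses t(k−2) inference.
* **Weighted median**: ratios sorted ascending; cumulative weights with
  the midpoint convention pᵢ = (cumᵢ − wᵢ/2)/Σw; linear interpolation at
  p = 0.5.  With tied ratios the interpolation knots depend on the
  within-tie order, so exact antisymmetry under outcome negation holds
  only for tie-free data — a property of the convention, not a defect.
* **Mode-based estimate**: normal-kernel density of the ratios with
  bandwidth φ · 0.9 · min(sd, MAD/0.6745) · k^(−1/5) (φ = 1 by default);
  the weighted variant weights kernels by inverse ratio variance.  The
  maximizer is located on a 512-point grid spanning the ratio range, ties
  broken toward the smallest magnitude.  If > 50% of ratios coincide the
  MAD is zero; the positive member of (sd, MAD) is then used, and only
  the all-identical case short-circuits to the common ratio with the IVW
  fixed SE.
* **Bootstrap SEs** (median, mode) are parametric: each pair's exposure
  and outcome effects are redrawn from N(β̂, σ̂), the point estimator is
  recomputed, and the SE is the SD over n_boot = 1000 draws.  Seeds are
  mandatory in the pipeline config; estimators sort pairs by rsid before
  drawing, so results are invariant to input order.
* **Outlier flagging** replaces the original study's visual forest-plot
  inspection with a testable rule: each SNP's Cochran-Q contribution is
  referred to χ²(1) and flagged below the Bonferroni-corrected α/k.  On
  the study data this flags exactly rs653178 and rs1165151, the two SNPs
  the authors identified by eye.

## Harmonization

Outcome records are matched to exposure records by rsid and reoriented by
allele swap and/or strand complement; a swap negates the outcome beta and
complements its frequency.  Palindromic (A/T, G/C) SNPs are
strand-ambiguous; when palindrome dropping is active (default: off in the
forward urate→MS direction, which used a curated instrument set, on in
the reverse screen) they are dropped if the minor-allele frequency is
within 0.08 of 0.5 — the conventional "intermediate frequency" window,
configurable.  LD pruning is greedy in ascending exposure p-value
(r² > 0.01 excludes), and proxy search takes the highest-r² candidate
above 0.8, panels consulted in priority order (here: ImmunoChip first,
then WTCCC2).  Every input SNP receives exactly one audit disposition;
the selection funnel reconciles counts by construction.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `r2_prune` | 0.01 | r² | independence threshold between instruments |
| `r2_proxy` | 0.8 | r² | minimum LD for proxy substitution |
| `palindrome_window` | 0.08 | allele freq. | drop A/T,G/C SNPs with MAF in [0.42, 0.5] |
| `pheno_sd` | 1.31 | mg/dl | urate phenotype SD; source GWAS reports per-study SDs 0.92–1.68, and 1.31 makes the two leading SNPs explain 3.4% of variance as that study states |
| `phi` | 1.0 | — | mode-bandwidth multiplier |
| `n_boot` | 1000 | draws | bootstrap SE stability ≪ estimate SE |
| power r² | 0.05 | — | instrument variance explained fed to the power formula (the 18 instruments' published total) |

## Synthetic-data generator

`SyntheticTruth` defaults mirror the study scale: k = 18 instruments,
true exposure effects uniform on (0.03, 0.37) mg/dl, exposure SE 0.006,
outcome SE 0.02 log-odds, frequencies uniform on (0.05, 0.95).  Balanced
pleiotropy draws αᵢ ~ N(0, 0.01) — half a typical outcome SE, a moderate
violation; directional pleiotropy shifts the mean; the InSIDE-violating
mode makes αᵢ proportional to instrument strength.  Outcome statistics
are emitted in the OR/CI dialect so the conversion path is exercised
end-to-end.

What the generator does *not* emulate: individual-level genotypes,
realistic LD beyond block-diagonal r², winner's-curse selection of
instruments, sample overlap between the two GWAS, and case-control
ascertainment effects on the outcome scale.  Passing calibration tests
therefore demonstrate correctness of the estimators under the two-sample
summary model, not robustness to those real-data complications.

The weighted-median robustness check uses directional pleiotropy with
mean direct effect 0.05 log-odds on 30% of instruments against an
outcome SE of 0.01: the pleiotropic shift must dominate ratio noise for
the median's advantage over IVW to be detectable at all; at smaller
shifts both estimators' errors are sampling noise and their ordering is a
coin flip.

Simulation sizes in the analysis drivers (400/300/200 replicates) are
chosen to give rate SEs of about 1% while keeping each driver under a
minute; the test suite uses the full 1000/500-replicate versions of the
calibration properties.

## Degenerate inputs and tie-breaks

Zero exposure effect → explicit undefined-ratio error naming the SNP.
Fewer pairs than an estimator needs → insufficient-instruments error; the
pipeline marks such subsets "not estimable" and continues.  LD entries
absent from the table count as r² = 0.  Proxy and pruning ties break
lexicographically by rsid.  All-identical ratios give Q = 0, p = 1 and an
empty outlier list.

## Known limitations

* Per-SNP ORs printed by the original study (4.04 / 1.92 / 1.81) are not
  exactly recoverable from its published rounded inputs (direct
  arithmetic gives 4.33 / 1.97 / 1.90); the package reproduces them to
  within ~10% and matches which SNPs are individually significant.  The
  same rounding moves Cochran's Q from the printed 40.9 to ≈ 44.1 without
  affecting any significance conclusion.
* The target–proxy r² values behind the nine proxy SNPs are unpublished;
  the packaged LD table uses a synthetic 0.9 placeholder (only the
  crossing of the 0.8 threshold is consequential).
* The reverse-direction (MS → urate) instrument set is unpublished, so
  that analysis is validated structurally on synthetic data with the same
  attrition counts (110 → 81), not numerically.
* Egger CIs use t(k−2); with k = 18 they are noticeably wider than
  normal-based ones, which is intentional.
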