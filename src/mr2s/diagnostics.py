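"""Heterogeneity, outlier and sensitivity diagnostics for MR datasets.

Cochran's Q measures dispersion of the per-SNP Wald ratios about the IVW
estimate; excess Q signals heterogeneity, typically from horizontal
pleiotropy.  Per-SNP Q contributions referred to a chi-square(1) provide a
testable replacement for eyeballing the forest plot when flagging outliers.
Leave-one-out re-estimation and funnel/forest tables complete the standard
sensitivity toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EffectsModel,
    PooledResult,
    RatioEstimate,
    _arrays,
    _ivw_core,
    _require,
    ivw,
    wald_ratios,
)
from .summary_data import HarmonizedDataset

__all__ = [
    "HeterogeneityResult",
    "SensitivityReport",
    "cochran_q",
    "leave_one_out",
    "flag_outliers",
    "funnel_forest_data",
    "sensitivity_report",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q about the IVW fixed-effects estimate."""

    q: float
    df: int
    pvalue: float
    contributions: dict[str, float]


@dataclass
class SensitivityReport:
    leave_one_out: list[tuple[str, PooledResult]]
    outliers: list[tuple[str, float]]  # (rsid, contribution p-value)
    funnel: pd.DataFrame  # rsid, estimate, inv_se
    forest: pd.DataFrame  # label, kind, estimate, se, ci_low, ci_high
    heterogeneity: HeterogeneityResult | None = None


def _q_contributions(ds: HarmonizedDataset):
    pairs, bx, _, by, sy = _arrays(ds)
    est, _, _ = _ivw_core(bx, by, sy)
    w = bx**2 / sy**2
    terms = w * (by / bx - est) ** 2
    return pairs, terms


def cochran_q(ds: HarmonizedDataset) -> HeterogeneityResult:
    """Q = sum_i w_i (r_i - r_hat)², w_i = beta_exposure_i²/se_outcome_i².

    r_hat is the IVW fixed-effects estimate (identical to the random-effects
    point estimate); p is the upper chi-square tail on k-1 df.
    """
    _require(ds, 2, "cochran_q")
    pairs, terms = _q_contributions(ds)
    q = float(terms.sum())
    df = len(pairs) - 1
    return HeterogeneityResult(
        q=q,
        df=df,
        pvalue=float(stats.chi2.sf(q, df)),
        contributions={p.rsid: float(t) for p, t in zip(pairs, terms)},
    )


def leave_one_out(
    ds: HarmonizedDataset, effects_model: EffectsModel = "multiplicative_random"
) -> list[tuple[str, PooledResult]]:
    """IVW re-estimated with each SNP excluded in turn (canonical rsid order)."""
    _require(ds, 3, "leave_one_out")
    out: list[tuple[str, PooledResult]] = []
    for rsid in sorted(ds.rsids):
        out.append((rsid, ivw(ds.drop([rsid]), effects_model)))
    return out


def flag_outliers(
    ds: HarmonizedDataset,
    alpha: float = 0.05,
    correction: Literal["bonferroni", "none"] = "bonferroni",
) -> list[str]:
    """SNPs whose Q contribution is improbably large under chi-square(1).

    A SNP is flagged when its contribution's upper-tail p falls below
    alpha/k (Bonferroni) or alpha (no correction); the flagged list is
    sorted by contribution, largest first.
    """
    _require(ds, 3, "flag_outliers")
    pairs, terms = _q_contributions(ds)
    k = len(pairs)
    cut = alpha / k if correction == "bonferroni" else alpha
    pvals = stats.chi2.sf(terms, 1)
    flagged = [
        (p.rsid, float(t)) for p, t, pv in zip(pairs, terms, pvals) if pv < cut
    ]
    flagged.sort(key=lambda x: -x[1])
    return [rsid for rsid, _ in flagged]


def funnel_forest_data(
    ds: HarmonizedDataset, pooled: Sequence[PooledResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready funnel and forest tables.

    Funnel: one row per SNP (ratio estimate vs 1/se); vertical reference
    lines are the pooled estimates.  Forest: per-SNP Wald rows followed by
    one row per pooled method.
    """
    if not pooled:
        raise ValueError("pooled results must be non-empty")
    ratios = wald_ratios(ds)
    funnel = pd.DataFrame(
        [(r.rsid, r.estimate, 1.0 / r.se) for r in ratios],
        columns=["rsid", "estimate", "inv_se"],
    )
    snp_rows = [
        {
            "label": r.rsid,
            "kind": "snp",
            "estimate": r.estimate,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pvalue": r.pvalue,
        }
        for r in ratios
    ]
    pooled_rows = [
        {
            "label": p.method,
            "kind": "pooled",
            "estimate": p.estimate,
            "se": p.se,
            "ci_low": p.ci_low,
            "ci_high": p.ci_high,
            "pvalue": p.pvalue,
        }
        for p in pooled
    ]
    forest = pd.DataFrame(snp_rows + pooled_rows)
    return funnel, forest


def sensitivity_report(
    ds: HarmonizedDataset,
    pooled: Sequence[PooledResult],
    effects_model: EffectsModel = "multiplicative_random",
    alpha: float = 0.05,
    correction: Literal["bonferroni", "none"] = "bonferroni",
) -> SensitivityReport:
    """Full sensitivity bundle: LOO, outliers, funnel/forest, heterogeneity."""
    het = cochran_q(ds)
    flagged = flag_outliers(ds, alpha=alpha, correction=correction)
    outliers = [
        (rsid, float(stats.chi2.sf(het.contributions[rsid], 1))) for rsid in flagged
    ]
    funnel, forest = funnel_forest_data(ds, pooled)
    return SensitivityReport(
        leave_one_out=leave_one_out(ds, effects_model),
        outliers=outliers,
        funnel=funnel,
        forest=forest,
        heterogeneity=het,
    )
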