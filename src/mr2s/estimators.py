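"""Causal estimators for two-sample Mendelian randomization.

Four families operate on a :class:`~mr2s.summary_data.HarmonizedDataset`:

* **Wald ratio** — per-SNP causal estimate, beta_outcome / beta_exposure.
* **IVW** — inverse-variance-weighted pooling of the Wald ratios, with a
  fixed-effects SE or a multiplicative random-effects SE (fixed SE scaled
  by sqrt(Q/(k-1)), floored at 1; the point estimate is identical).
* **MR-Egger** — weighted regression of outcome on exposure effects with a
  free intercept; the intercept estimates average directional pleiotropy,
  the slope the causal effect under the InSIDE assumption.
* **Weighted median / mode-based** — order- and cluster-robust estimators,
  consistent when a weighted majority (median) or the largest cluster
  (mode) of instruments is valid; SEs by seeded parametric bootstrap.

All estimators sort pairs by rsid before computing, so results (including
bootstrap SEs) are invariant to input order.  Estimates are log-odds of
outcome per unit of exposure; ``PooledResult.or_scale`` exponentiates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .summary_data import HarmonizedDataset, HarmonizedPair, Z_95

__all__ = [
    "RatioEstimate",
    "PooledResult",
    "EggerIntercept",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_based",
]

logger = logging.getLogger(__name__)

EffectsModel = Literal["fixed", "multiplicative_random"]


class OddsRatioScale(NamedTuple):
    or_: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RatioEstimate:
    """Single-SNP Wald ratio on the log-odds-per-exposure-unit scale."""

    rsid: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float

    @property
    def or_scale(self) -> OddsRatioScale:
        return OddsRatioScale(
            float(np.exp(self.estimate)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )


@dataclass(frozen=True)
class PooledResult:
    """A method's pooled causal estimate (log scale) with CI and p."""

    method: str
    n_snps: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float

    @property
    def or_scale(self) -> OddsRatioScale:
        return OddsRatioScale(
            float(np.exp(self.estimate)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )


@dataclass(frozen=True)
class EggerIntercept:
    """Average directional pleiotropy per SNP, in outcome (log-odds) units."""

    estimate: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class EggerResult:
    slope: PooledResult
    intercept: EggerIntercept


def _sorted_pairs(ds: HarmonizedDataset) -> list[HarmonizedPair]:
    return sorted(ds.pairs, key=lambda p: p.rsid)


def _arrays(ds: HarmonizedDataset):
    pairs = _sorted_pairs(ds)
    bx = np.array([p.beta_exposure for p in pairs])
    sx = np.array([p.se_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    return pairs, bx, sx, by, sy


def _require(ds: HarmonizedDataset, k_min: int, method: str) -> None:
    if len(ds) < k_min:
        raise InsufficientInstrumentsError(
            f"{method} requires at least {k_min} SNPs, got {len(ds)}"
        )


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> RatioEstimate:
    """Per-SNP causal estimate: beta_outcome / beta_exposure.

    The default SE is the first-order delta approximation
    se_outcome / |beta_exposure|; ``second_order`` adds the exposure-error
    term beta_outcome² se_exposure² / beta_exposure⁴ under the square root.
    """
    if pair.beta_exposure == 0:
        raise UndefinedRatioError(f"{pair.rsid}: beta_exposure is zero")
    est = pair.beta_outcome / pair.beta_exposure
    var = pair.se_outcome**2 / pair.beta_exposure**2
    if second_order:
        var += (
            pair.beta_outcome**2 * pair.se_exposure**2 / pair.beta_exposure**4
        )
    se = float(np.sqrt(var))
    return RatioEstimate(
        rsid=pair.rsid,
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se),
    )


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Point estimate, fixed SE and Cochran's Q for IVW pooling."""
    ratios = by / bx
    weights = bx**2 / sy**2
    est = float(np.sum(weights * ratios) / np.sum(weights))
    se_fixed = float(np.sum(weights) ** -0.5)
    q = float(np.sum(weights * (ratios - est) ** 2))
    return est, se_fixed, q


def ivw(
    ds: HarmonizedDataset, effects_model: EffectsModel = "multiplicative_random"
) -> PooledResult:
    """Inverse-variance-weighted pooled causal estimate.

    Weights are beta_exposure²/se_outcome² (the inverse first-order Wald
    ratio variance).  Under ``multiplicative_random`` the fixed-effects SE
    is inflated by sqrt(Q/(k-1)), floored at 1, so over-dispersion widens
    the CI while the point estimate is unchanged.
    """
    k_min = 1 if effects_model == "fixed" else 2
    _require(ds, k_min, f"ivw ({effects_model})")
    _, bx, _, by, sy = _arrays(ds)
    if np.any(bx == 0):
        raise UndefinedRatioError("zero beta_exposure in dataset")
    est, se_fixed, q = _ivw_core(bx, by, sy)
    k = len(bx)
    if effects_model == "fixed" or k == 1:
        se = se_fixed
    else:
        se = se_fixed * max(1.0, float(np.sqrt(q / (k - 1))))
    return PooledResult(
        method=f"ivw_{'fixed' if effects_model == 'fixed' else 'random'}",
        n_snps=k,
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se),
    )


def egger(ds: HarmonizedDataset) -> EggerResult:
    """MR-Egger regression: WLS of beta_outcome on beta_exposure + intercept.

    Pairs are first oriented so every beta_exposure is positive (the Egger
    model is identified only up to this orientation).  Weights are
    1/se_outcome²; both SEs are inflated by the residual scale, floored at
    1; inference uses a t distribution with k-2 df.
    """
    _require(ds, 3, "egger")
    _, bx, _, by, sy = _arrays(ds)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    k = len(bx)

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    # unscaled covariance, then multiplicative residual inflation floored at 1
    se_unit = np.sqrt(np.diag(fit.normalized_cov_params))
    scale = float(np.sqrt(fit.scale)) if fit.scale > 0 else 0.0
    se = se_unit * max(1.0, scale)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_int, se_slope = float(se[0]), float(se[1])
    tq = float(stats.t.ppf(0.975, k - 2))

    def t_p(est: float, s: float) -> float:
        return float(2.0 * stats.t.sf(abs(est / s), k - 2))

    slope_res = PooledResult(
        method="egger",
        n_snps=k,
        estimate=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pvalue=t_p(slope, se_slope),
    )
    return EggerResult(
        slope=slope_res,
        intercept=EggerIntercept(intercept, se_int, t_p(intercept, se_int)),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Midpoint-convention weighted median with linear interpolation."""
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w)
    p = (cum - w / 2.0) / cum[-1]
    return float(np.interp(0.5, p, r))


def _bootstrap_se(
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: redraw each pair's effects from N(beta, se)."""
    if n_boot < 100:
        logger.warning("n_boot=%d is below 100; bootstrap SE will be noisy", n_boot)
    rng = np.random.default_rng(seed)
    k = len(bx)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + rng.standard_normal(k) * sx
        by_b = by + rng.standard_normal(k) * sy
        boots[b] = point_fn(bx_b, by_b)
    return float(np.std(boots, ddof=1))


def weighted_median(
    ds: HarmonizedDataset,
    weighting: Literal["inverse_variance", "equal"] = "inverse_variance",
    n_boot: int = 1000,
    seed: int = 0,
) -> PooledResult:
    """Weighted-median causal estimate.

    The Wald ratios are sorted and the ratio at normalized cumulative
    weight 0.5 (midpoint convention, linear interpolation) is the point
    estimate; it is consistent when valid instruments carry at least half
    of the weight.  The SE comes from a seeded parametric bootstrap.
    """
    _require(ds, 3, "weighted_median")
    _, bx, sx, by, sy = _arrays(ds)

    def point(bx_: np.ndarray, by_: np.ndarray) -> float:
        ratios = by_ / bx_
        if weighting == "inverse_variance":
            w = bx_**2 / sy**2
        else:
            w = np.ones_like(ratios)
        return _weighted_median_point(ratios, w)

    est = point(bx, by)
    se = _bootstrap_se(bx, sx, by, sy, point, n_boot, seed)
    return PooledResult(
        method="weighted_median",
        n_snps=len(bx),
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se),
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """phi x 0.9 min(sd, MAD/0.6745) k^(-1/5); guards against a zero MAD."""
    k = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * k ** (-1.0 / 5.0)


def _mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float, grid_points: int
) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0.0:
        return float(ratios[0])
    grid = np.linspace(ratios.min(), ratios.max(), grid_points)
    dens = np.sum(
        weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
        axis=1,
    )
    peaks = np.flatnonzero(dens == dens.max())
    # ties broken toward the smallest-magnitude grid value
    best = peaks[np.argmin(np.abs(grid[peaks]))]
    return float(grid[best])


def mode_based(
    ds: HarmonizedDataset,
    phi: float = 1.0,
    weighted: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    grid_points: int = 512,
) -> PooledResult:
    """Mode-based causal estimate: peak of a kernel-smoothed ratio density.

    Each Wald ratio contributes a normal kernel (bandwidth: ``phi`` times
    the Silverman-style rule over the ratios); the ``weighted`` variant
    weights kernels by the inverse ratio variance.  The estimate is the
    density maximizer on a dense grid over the ratio range, consistent when
    the largest cluster of SNPs shares the true causal effect.  If all
    ratios coincide the common ratio is returned with the IVW fixed SE.
    """
    _require(ds, 3, "mode_based")
    _, bx, sx, by, sy = _arrays(ds)
    ratios = by / bx
    if float(np.ptp(ratios)) == 0.0:
        fixed = ivw(ds, "fixed")
        est = float(ratios[0])
        return PooledResult(
            method="mode_based",
            n_snps=len(bx),
            estimate=est,
            se=fixed.se,
            ci_low=est - Z_95 * fixed.se,
            ci_high=est + Z_95 * fixed.se,
            pvalue=_normal_p(est / fixed.se),
        )

    def point(bx_: np.ndarray, by_: np.ndarray) -> float:
        r = by_ / bx_
        if weighted:
            w = bx_**2 / sy**2
        else:
            w = np.ones_like(r)
        return _mode_point(r, w / w.sum(), phi, grid_points)

    est = point(bx, by)
    se = _bootstrap_se(bx, sx, by, sy, point, n_boot, seed)
    return PooledResult(
        method="mode_based",
        n_snps=len(bx),
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=_normal_p(est / se),
    )


def all_estimates(
    ds: HarmonizedDataset,
    effects_model: EffectsModel = "multiplicative_random",
    n_boot: int = 1000,
    seed: int = 0,
    phi: float = 1.0,
) -> dict[str, PooledResult]:
    """Run IVW (both effects models), Egger, median and mode on one dataset."""
    results = {
        "ivw_fixed": ivw(ds, "fixed"),
        "ivw_random": ivw(ds, effects_model),
        "weighted_median": weighted_median(ds, n_boot=n_boot, seed=seed),
        "mode_based": mode_based(ds, phi=phi, n_boot=n_boot, seed=seed + 1),
    }
    eg = egger(ds)
    results["egger"] = eg.slope
    return results


def wald_ratios(ds: HarmonizedDataset) -> list[RatioEstimate]:
    """Wald ratio for every pair, in canonical rsid order."""
    return [wald_ratio(p) for p in _sorted_pairs(ds)]
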