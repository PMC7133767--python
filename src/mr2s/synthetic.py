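"""Synthetic two-sample GWAS data with known ground truth, plus the
packaged serum-urate / multiple-sclerosis study fixture.

The generator emulates the two-sample summary-statistic setting directly:
true per-SNP exposure effects are drawn, true outcome effects are
theta * beta_exposure plus an optional per-SNP horizontal-pleiotropy term,
and the *observed* effects in each (independent) sample are the true
effects plus normal noise with the stated standard errors.  Outcome
effects are emitted in the OR / 95%-CI dialect so the full parsing path is
exercised.  Everything is reproducible from the seed.

The fixture is the printed characteristics table of the urate-MS study:
18 SNPs (9 via proxies), exposure GWAS n = 110,347, outcome panels from
two MS case-control studies (n = 38,589 and 27,148).
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .summary_data import (
    HarmonizedDataset,
    HarmonizedPair,
    KEPT,
    LdTable,
    PROXIED,
    VariantAssociation,
    Z_95,
    ci_to_log_se,
)

__all__ = [
    "harmonized_from_tables",
    "OUTCOME_STUDY_N",
    "OUTCOME_STUDY_CASES",
    "EXPOSURE_N",
    "SyntheticTruth",
    "simulate_two_sample",
    "simulate_ld_panel",
    "table1_fixture",
    "fixture_input_tables",
    "write_fixture_inputs",
]

#: Sample sizes of the two MS outcome studies and the urate exposure GWAS.
OUTCOME_STUDY_N = {"IMSGC": 38589, "WTCCC2": 27148}
OUTCOME_STUDY_CASES = {"IMSGC": 14498, "WTCCC2": 9772}
EXPOSURE_N = 110347

PleiotropyMode = Literal["none", "balanced", "directional", "inside_violating"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative parameters for a two-sample MR simulation.

    Defaults mirror the urate-MS study scale: 18 instruments with exposure
    effects spanning 0.03-0.37 mg/dl per allele, exposure-side SEs around
    0.006 and outcome-side SEs of 0.02 log-odds.  ``pleiotropy_sd``
    defaults to 0.01 log-odds (half a typical outcome SE), a moderate
    violation; ``invalid_fraction`` is the share of SNPs receiving a
    pleiotropic direct effect.
    """

    theta: float = 0.0
    k: int = 18
    beta_exposure_range: tuple[float, float] | Sequence[float] = (0.03, 0.37)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    se_exposure: float | tuple[float, float] = 0.006
    se_outcome: float | tuple[float, float] = 0.02
    pleiotropy_mode: PleiotropyMode = "none"
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.0
    inside_slope: float = 0.05
    invalid_fraction: float = 1.0
    n_exposure: int = EXPOSURE_N
    n_outcome: int = OUTCOME_STUDY_N["IMSGC"]
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValidationError("invalid_fraction must be in [0, 1]")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        for name in ("se_exposure", "se_outcome"):
            v = getattr(self, name)
            lo = v[0] if isinstance(v, tuple) else v
            if not lo >= 0:
                raise ValidationError(f"{name} must be >= 0")


_ALLELES = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]


def _draw(rng: np.random.Generator, spec, k: int) -> np.ndarray:
    if isinstance(spec, tuple) and len(spec) == 2:
        return rng.uniform(spec[0], spec[1], k)
    if np.isscalar(spec):
        return np.full(k, float(spec))
    arr = np.asarray(spec, dtype=float)
    if len(arr) != k:
        raise ValidationError(f"explicit effect list has length {len(arr)}, expected {k}")
    return arr


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    with np.errstate(divide="ignore"):
        z = np.where(se > 0, np.abs(beta) / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.norm.sf(z)
    return np.clip(p, 1e-300, 1.0)


def simulate_two_sample(
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate matched exposure and outcome summary-statistic tables.

    Returns (exposure table in the continuous beta/se dialect, outcome
    table in the binary OR/CI dialect, truth record with the per-SNP true
    effects and pleiotropy terms).
    """
    rng = np.random.default_rng(truth.seed)
    k = truth.k
    rsids = [f"snp{i + 1:04d}" for i in range(k)]
    bx_true = _draw(rng, truth.beta_exposure_range, k)
    eaf = rng.uniform(*truth.eaf_range, k)
    sx = _draw(rng, truth.se_exposure, k)
    sy = _draw(rng, truth.se_outcome, k)

    alpha = np.zeros(k)
    n_invalid = int(round(truth.invalid_fraction * k))
    invalid = rng.choice(k, size=n_invalid, replace=False) if n_invalid else np.array([], dtype=int)
    if truth.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, truth.pleiotropy_sd, n_invalid)
    elif truth.pleiotropy_mode == "directional":
        mean = truth.pleiotropy_mean if truth.pleiotropy_mean else truth.pleiotropy_sd
        alpha[invalid] = rng.normal(mean, truth.pleiotropy_sd, n_invalid)
    elif truth.pleiotropy_mode == "inside_violating":
        # direct effects proportional to instrument strength (violates InSIDE)
        alpha[invalid] = truth.inside_slope * bx_true[invalid] + rng.normal(
            0.0, truth.pleiotropy_sd, n_invalid
        )
    by_true = truth.theta * bx_true + alpha

    bx_obs = bx_true + (rng.standard_normal(k) * sx if np.any(sx > 0) else 0.0)
    by_obs = by_true + (rng.standard_normal(k) * sy if np.any(sy > 0) else 0.0)

    allele_idx = rng.integers(0, len(_ALLELES), k)
    ea = [_ALLELES[i][0] for i in allele_idx]
    oa = [_ALLELES[i][1] for i in allele_idx]

    sx_rep = np.where(sx > 0, sx, 1e-12)  # SEs must stay positive in the tables
    sy_rep = np.where(sy > 0, sy, 1e-12)
    exposure = pd.DataFrame(
        {
            "rsid": rsids,
            "chr": "1",
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": np.round(eaf, 6),
            "beta": bx_obs,
            "se": sx_rep,
            "pvalue": _pvals(bx_obs, sx_rep),
            "n": truth.n_exposure,
        }
    )
    outcome = pd.DataFrame(
        {
            "rsid": rsids,
            "chr": "1",
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": np.round(eaf, 6),
            "or": np.exp(by_obs),
            "ci_low": np.exp(by_obs - Z_95 * sy_rep),
            "ci_high": np.exp(by_obs + Z_95 * sy_rep),
            "pvalue": _pvals(by_obs, sy_rep),
            "n": truth.n_outcome,
        }
    )
    record = {
        "truth": {
            **asdict(truth),
            "beta_exposure_range": list(np.atleast_1d(truth.beta_exposure_range)),
        },
        "beta_exposure_true": bx_true.tolist(),
        "beta_outcome_true": by_true.tolist(),
        "pleiotropy": alpha.tolist(),
        "invalid_snps": [rsids[i] for i in sorted(invalid.tolist())],
    }
    return exposure, outcome, record


def harmonized_from_tables(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    drop_palindromic: bool = False,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedDataset:
    """Parse and harmonize a simulated exposure/outcome table pair."""
    from .summary_data import associations_from_frame, harmonize

    exp = associations_from_frame(exposure, "continuous")
    out = associations_from_frame(outcome, "binary")
    return harmonize(
        exp,
        out,
        drop_palindromic=drop_palindromic,
        palindrome_eaf_window=palindrome_eaf_window,
    )


def simulate_ld_panel(
    k_targets: int,
    k_proxies_per_target: int,
    r2_levels: Sequence[float],
    seed: int = 0,
) -> tuple[LdTable, pd.DataFrame]:
    """Block-diagonal LD panel for exercising pruning and proxy search.

    Each target gets ``k_proxies_per_target`` candidate proxies whose r²
    with the target cycles through ``r2_levels``; r² across clusters is
    zero (absent).  Returns the LD table and a candidate outcome
    association table (binary dialect) covering every proxy.
    """
    if k_targets < 1 or k_proxies_per_target < 0:
        raise ValidationError("counts must be positive")
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str, float]] = []
    rows = []
    li = 0
    for t in range(k_targets):
        target = f"target{t + 1:03d}"
        for p in range(k_proxies_per_target):
            proxy = f"{target}_proxy{p + 1}"
            r2 = float(r2_levels[li % len(r2_levels)])
            li += 1
            entries.append((target, proxy, r2))
            beta = rng.normal(0.0, 0.03)
            se = 0.02
            rows.append(
                {
                    "rsid": proxy,
                    "chr": "1",
                    "effect_allele": "A",
                    "other_allele": "G",
                    "eaf": round(float(rng.uniform(0.1, 0.9)), 6),
                    "or": math.exp(beta),
                    "ci_low": math.exp(beta - Z_95 * se),
                    "ci_high": math.exp(beta + Z_95 * se),
                    "pvalue": 0.5,
                    "n": OUTCOME_STUDY_N["IMSGC"],
                }
            )
    return LdTable(entries), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged study fixture (printed characteristics table, 18 SNPs)
# ---------------------------------------------------------------------------

def _table1_frame() -> pd.DataFrame:
    with importlib.resources.files("mr2s.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"rsid": str, "chr": str, "proxy_rsid": str})
    # 'or' is not a valid identifier for itertuples; rename internally
    return df.rename(columns={"or": "or_point"})


def table1_fixture() -> tuple[HarmonizedDataset, list[VariantAssociation]]:
    """The 18-SNP urate-MS dataset, already harmonized, plus the exposure list.

    Outcome ORs/CIs are stored verbatim and converted to log-odds beta/SE at
    load time; 9 SNPs carry proxy annotations (their outcome statistics come
    from a high-LD proxy).  Byte-stable across calls.
    """
    df = _table1_frame()
    pairs: list[HarmonizedPair] = []
    exposure: list[VariantAssociation] = []
    audit: dict[str, str] = {}
    for row in df.itertuples(index=False):
        proxy = None if pd.isna(row.proxy_rsid) else str(row.proxy_rsid)
        point = float(row.or_point)
        se_out = ci_to_log_se(point, float(row.ci_low), float(row.ci_high))
        exposure.append(
            VariantAssociation(
                rsid=row.rsid,
                chrom=str(row.chr),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=EXPOSURE_N,
                trait_kind="continuous",
                source="GUGC",
            )
        )
        pairs.append(
            HarmonizedPair(
                rsid=row.rsid,
                beta_exposure=float(row.beta),
                se_exposure=float(row.se),
                beta_outcome=math.log(point),
                se_outcome=se_out,
                eaf=float(row.eaf),
                proxy_rsid=proxy,
                proxy_r2=None,
                source=str(row.study),
                flipped=False,
            )
        )
        audit[row.rsid] = PROXIED if proxy else KEPT
    return HarmonizedDataset(pairs, audit), exposure


#: Synthetic stand-in for the unpublished target-proxy LD r² values; only
#: crossing the 0.8 proxy threshold matters to the pipeline.
FIXTURE_PROXY_R2 = 0.9


def fixture_input_tables() -> dict[str, pd.DataFrame]:
    """Fixture as raw pipeline inputs: exposure table, two outcome panels
    (proxy SNPs listed under the proxy rsid), and a synthetic LD table
    linking each proxied target to its proxy at r² = 0.9.

    The real target-proxy r² values are not printed in the study; 0.9 is a
    synthetic placeholder above the 0.8 proxy threshold, and proxy rows
    reuse the target's alleles/EAF (the fixture stores already-aligned
    outcome values).
    """
    df = _table1_frame()
    exposure = pd.DataFrame(
        {
            "rsid": df.rsid,
            "chr": df.chr,
            "effect_allele": df.effect_allele,
            "other_allele": df.other_allele,
            "eaf": df.eaf,
            "beta": df.beta,
            "se": df.se,
            "pvalue": df.pvalue,
            "n": EXPOSURE_N,
        }
    )
    panels: dict[str, list[dict]] = {"IMSGC": [], "WTCCC2": []}
    ld_rows = []
    for row in df.itertuples(index=False):
        point = float(row.or_point)
        study = str(row.study)
        proxy = None if pd.isna(row.proxy_rsid) else str(row.proxy_rsid)
        rsid_out = proxy if proxy else row.rsid
        panels[study].append(
            {
                "rsid": rsid_out,
                "chr": row.chr,
                "effect_allele": row.effect_allele,
                "other_allele": row.other_allele,
                "eaf": row.eaf,
                "or": point,
                "ci_low": row.ci_low,
                "ci_high": row.ci_high,
                "pvalue": row.pvalue_outcome,
                "n": OUTCOME_STUDY_N[study],
            }
        )
        if proxy:
            ld_rows.append({"rsid_a": row.rsid, "rsid_b": proxy, "r2": FIXTURE_PROXY_R2})
    return {
        "exposure": exposure,
        "outcome_imsgc": pd.DataFrame(panels["IMSGC"]),
        "outcome_wtccc2": pd.DataFrame(panels["WTCCC2"]),
        "ld": pd.DataFrame(ld_rows),
    }


def write_fixture_inputs(out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture input tables as TSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = fixture_input_tables()
    paths: dict[str, Path] = {}
    for name, frame in tables.items():
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
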