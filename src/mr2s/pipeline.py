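"""End-to-end orchestration of a two-sample MR study.

``run_analysis`` drives the whole procedure from a :class:`RunConfig`:
parse summary tables → LD-prune the instruments → find outcome-side
proxies for SNPs missing from the outcome panels (panels searched in
priority order) → harmonize → run all estimators → heterogeneity /
outlier / leave-one-out diagnostics → repeat the estimation on the
study's sensitivity subsets (proxies excluded, outliers excluded, per
source study) → instrument strength and power → a serializable report.

The reverse direction swaps the exposure and outcome roles (outcome
log-odds become the instrument effects) and, as is conventional for a
binary-exposure screen, drops palindromic SNPs with intermediate allele
frequency.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Literal, Sequence

import pandas as pd
import yaml

from . import diagnostics, estimators, strength, summary_data
from .estimators import PooledResult
from .exceptions import ValidationError
from .summary_data import (
    HarmonizedDataset,
    LdTable,
    VariantAssociation,
    read_association_table,
)

__all__ = ["RunConfig", "AnalysisReport", "run_analysis", "selection_funnel"]


@dataclass
class RunConfig:
    exposure_path: str
    outcome_paths: list[str]
    outcome_sources: list[str] | None = None  # study tags, default: file stems
    ld_path: str | None = None
    direction: Literal["forward", "reverse", "both"] = "forward"
    exposure_trait: Literal["continuous", "binary"] = "continuous"
    outcome_trait: Literal["continuous", "binary"] = "binary"
    r2_prune: float = 0.01
    r2_proxy: float = 0.8
    palindrome_window: float = 0.08
    drop_palindromic: bool | None = None  # None: off forward, on reverse
    outlier_alpha: float = 0.05
    outlier_correction: Literal["bonferroni", "none"] = "bonferroni"
    effects_model: Literal["fixed", "multiplicative_random"] = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    phi: float = 1.0
    pheno_sd: float = strength.DEFAULT_PHENO_SD
    power_n_outcome: int | None = None
    power_case_fraction: float | None = None
    power_r2: float | None = None
    power_alpha: float = 0.05
    target_power: float = 0.8
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "exposure_path" not in d or "outcome_paths" not in d:
            raise ValidationError("config requires exposure_path and outcome_paths")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def selection_funnel(input_count: int, excluded: dict[str, int]) -> dict[str, Any]:
    """Per-stage instrument accounting; raises if the counts don't reconcile."""
    analyzed = input_count - sum(excluded.values())
    if analyzed < 0:
        raise ValidationError(
            f"selection funnel does not reconcile: input {input_count}, "
            f"excluded {excluded}"
        )
    return {"input": input_count, "excluded": dict(excluded), "analyzed": analyzed}


def _child_seed(base: int, label: str) -> int:
    return (int(base) + zlib.crc32(label.encode())) % (2**31)


def _pooled_dict(p: PooledResult) -> dict[str, Any]:
    or_, lo, hi = p.or_scale
    return {
        "method": p.method,
        "n_snps": p.n_snps,
        "estimate": p.estimate,
        "se": p.se,
        "ci_low": p.ci_low,
        "ci_high": p.ci_high,
        "pvalue": p.pvalue,
        "or": or_,
        "or_ci_low": lo,
        "or_ci_high": hi,
    }


def _estimate_suite(
    ds: HarmonizedDataset, cfg: RunConfig, label: str
) -> dict[str, Any]:
    """All five estimator variants plus Q and the Egger intercept on one set."""
    if len(ds) < 3:
        return {"n_snps": len(ds), "estimable": False}
    seed = _child_seed(cfg.seed, label)
    pooled = {
        "ivw_fixed": estimators.ivw(ds, "fixed"),
        "ivw_random": estimators.ivw(ds, "multiplicative_random"),
        "weighted_median": estimators.weighted_median(
            ds, n_boot=cfg.n_boot, seed=seed
        ),
        "mode_based": estimators.mode_based(
            ds, phi=cfg.phi, n_boot=cfg.n_boot, seed=seed + 1
        ),
    }
    eg = estimators.egger(ds)
    pooled["egger"] = eg.slope
    het = diagnostics.cochran_q(ds)
    return {
        "n_snps": len(ds),
        "estimable": True,
        "pooled": {k: _pooled_dict(v) for k, v in pooled.items()},
        "egger_intercept": asdict(eg.intercept),
        "heterogeneity": {"q": het.q, "df": het.df, "pvalue": het.pvalue},
        "_pooled_objects": pooled,
        "_dataset": ds,
    }


def _merge_panels(panels: Sequence[Sequence[VariantAssociation]]) -> list[VariantAssociation]:
    """First panel containing an rsid wins (priority order)."""
    seen: set[str] = set()
    merged: list[VariantAssociation] = []
    for panel in panels:
        for a in panel:
            if a.rsid not in seen:
                seen.add(a.rsid)
                merged.append(a)
    return merged


def _run_direction(
    label: str,
    exposure: list[VariantAssociation],
    panels: list[list[VariantAssociation]],
    ld: LdTable | None,
    cfg: RunConfig,
    drop_palindromic: bool,
) -> dict[str, Any]:
    n_input = len(exposure)
    if ld is not None:
        pruned = summary_data.prune_ld(exposure, ld, cfg.r2_prune)
    else:
        pruned = list(exposure)
    n_ld_excluded = n_input - len(pruned)

    available = {a.rsid for p in panels for a in p}
    missing = [a for a in pruned if a.rsid not in available]
    proxies = (
        summary_data.substitute_proxies(missing, ld, panels, cfg.r2_proxy)
        if ld is not None and missing
        else {}
    )
    merged = _merge_panels(panels)
    ds = summary_data.harmonize(
        pruned,
        merged,
        palindrome_eaf_window=cfg.palindrome_window,
        drop_palindromic=drop_palindromic,
        proxies=proxies,
    )
    audit = ds.audit
    counts = {
        "ld_pruned": n_ld_excluded,
        "unmatched": sum(1 for d in audit.values() if d == summary_data.UNMATCHED),
        "palindromic": sum(
            1 for d in audit.values() if d == summary_data.PALINDROMIC_DROPPED
        ),
        "incompatible": sum(
            1 for d in audit.values() if d == summary_data.INCOMPATIBLE_DROPPED
        ),
    }
    funnel = selection_funnel(n_input, counts)
    result: dict[str, Any] = {
        "direction": label,
        "selection": funnel,
        "audit": dict(audit),
        "n_proxies": sum(1 for p in ds.pairs if p.proxy_rsid),
    }

    main = _estimate_suite(ds, cfg, f"{label}/all")
    result["all_snps"] = main
    if not main["estimable"]:
        return result

    pooled_objs = main.pop("_pooled_objects")
    main.pop("_dataset")
    report = diagnostics.sensitivity_report(
        ds,
        list(pooled_objs.values()),
        effects_model=cfg.effects_model,
        alpha=cfg.outlier_alpha,
        correction=cfg.outlier_correction,
    )
    result["ratio_estimates"] = [
        {
            "rsid": r.rsid,
            "estimate": r.estimate,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pvalue": r.pvalue,
            "or": r.or_scale.or_,
            "or_ci_low": r.or_scale.ci_low,
            "or_ci_high": r.or_scale.ci_high,
        }
        for r in estimators.wald_ratios(ds)
    ]
    result["leave_one_out"] = [
        {"excluded": rsid, **_pooled_dict(p)} for rsid, p in report.leave_one_out
    ]
    result["outliers"] = [
        {"rsid": rsid, "pvalue": pv} for rsid, pv in report.outliers
    ]
    result["_tables"] = {"funnel": report.funnel, "forest": report.forest}

    subsets: dict[str, Any] = {}
    flagged = [o["rsid"] for o in result["outliers"]]
    proxied = [p.rsid for p in ds.pairs if p.proxy_rsid]
    subset_sets = {
        "proxy_excluded": ds.drop(proxied),
        "outlier_excluded": ds.drop(flagged),
    }
    for src in sorted({p.source for p in ds.pairs if p.source}):
        subset_sets[f"source:{src}"] = ds.subset(
            [p.rsid for p in ds.pairs if p.source == src]
        )
    for name, sub in subset_sets.items():
        suite = _estimate_suite(sub, cfg, f"{label}/{name}")
        suite.pop("_pooled_objects", None)
        suite.pop("_dataset", None)
        subsets[name] = suite
    result["subsets"] = subsets

    # instrument strength (continuous exposure only) and power
    exposure_by_rsid = {a.rsid: a for a in pruned}
    analyzed = [exposure_by_rsid[r] for r in ds.rsids if r in exposure_by_rsid]
    if analyzed and analyzed[0].trait_kind == "continuous":
        ss = strength.variance_explained(analyzed, pheno_sd=cfg.pheno_sd)
        result["strength"] = {
            "per_snp_r2": ss.per_snp_r2,
            "total_r2": ss.total_r2,
            "f_stat": ss.f_stat,
            "n": ss.n,
            "k": ss.k,
            "pheno_sd": ss.pheno_sd,
            "excluded": list(ss.excluded),
        }
    else:
        result["strength"] = None

    if cfg.power_n_outcome and cfg.power_case_fraction:
        r2 = cfg.power_r2
        if r2 is None and result["strength"]:
            r2 = result["strength"]["total_r2"]
        if r2:
            spec = strength.PowerSpec(
                n_outcome=cfg.power_n_outcome,
                case_fraction=cfg.power_case_fraction,
                r2=r2,
                alpha=cfg.power_alpha,
            )
            up, down = strength.detectable_or(spec, cfg.target_power)
            result["power"] = {
                "spec": asdict(spec),
                "target_power": cfg.target_power,
                "detectable_or": up,
                "detectable_or_protective": down,
            }
    return result


class AnalysisReport:
    """Structured results of a run, with TSV/JSON writers."""

    def __init__(self, config: RunConfig, directions: dict[str, dict[str, Any]]):
        self.config = config
        self.directions = directions

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"config": asdict(self.config), "directions": {}}
        for name, d in self.directions.items():
            clean = {k: v for k, v in d.items() if not k.startswith("_")}
            out["directions"][name] = clean
        return out

    def methods_table(self, direction: str | None = None) -> pd.DataFrame:
        """Estimator-by-result table mirroring the study's summary figure."""
        name = direction or next(iter(self.directions))
        d = self.directions[name]
        rows = []
        if d["all_snps"].get("estimable"):
            for m, p in d["all_snps"]["pooled"].items():
                rows.append(
                    {
                        "subset": "all",
                        "method": m,
                        "n_snps": p["n_snps"],
                        "or": p["or"],
                        "ci_low": p["or_ci_low"],
                        "ci_high": p["or_ci_high"],
                        "pvalue": p["pvalue"],
                    }
                )
            for sub, suite in d.get("subsets", {}).items():
                if not suite.get("estimable"):
                    continue
                for m, p in suite["pooled"].items():
                    rows.append(
                        {
                            "subset": sub,
                            "method": m,
                            "n_snps": p["n_snps"],
                            "or": p["or"],
                            "ci_low": p["or_ci_low"],
                            "ci_high": p["or_ci_high"],
                            "pvalue": p["pvalue"],
                        }
                    )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        for name, d in self.directions.items():
            tag = "" if len(self.directions) == 1 else f"{name}_"
            self.methods_table(name).to_csv(out / f"{tag}methods.tsv", sep="\t", index=False)
            tables = d.get("_tables")
            if tables:
                tables["funnel"].to_csv(out / f"{tag}funnel.tsv", sep="\t", index=False)
                tables["forest"].to_csv(out / f"{tag}forest.tsv", sep="\t", index=False)
            if "leave_one_out" in d:
                pd.DataFrame(d["leave_one_out"]).to_csv(
                    out / f"{tag}loo.tsv", sep="\t", index=False
                )
            with open(out / f"{tag}audit.json", "w") as fh:
                json.dump(
                    {"selection": d["selection"], "audit": d["audit"]},
                    fh,
                    indent=2,
                    sort_keys=True,
                )


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the configured study and return the full report."""
    exposure = read_association_table(config.exposure_path, config.exposure_trait)
    sources = config.outcome_sources or [Path(p).stem for p in config.outcome_paths]
    if len(sources) != len(config.outcome_paths):
        raise ValidationError("outcome_sources must match outcome_paths in length")
    panels = [
        read_association_table(p, config.outcome_trait, source=tag)
        for p, tag in zip(config.outcome_paths, sources)
    ]
    ld = LdTable.from_tsv(config.ld_path) if config.ld_path else None

    directions: dict[str, dict[str, Any]] = {}
    want = (
        ["forward", "reverse"] if config.direction == "both" else [config.direction]
    )
    for direction in want:
        if direction == "forward":
            drop = (
                config.drop_palindromic
                if config.drop_palindromic is not None
                else False
            )
            directions["forward"] = _run_direction(
                "forward", exposure, panels, ld, config, drop
            )
        else:
            # swap roles: the first outcome panel supplies the instruments
            drop = (
                config.drop_palindromic
                if config.drop_palindromic is not None
                else True
            )
            directions["reverse"] = _run_direction(
                "reverse", panels[0], [exposure], ld, config, drop
            )
    report = AnalysisReport(config, directions)
    if config.output_dir:
        report.write(config.output_dir)
    return report
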