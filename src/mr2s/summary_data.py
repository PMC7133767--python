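"""Data model and harmonization of two-sample GWAS summary statistics.

A two-sample Mendelian randomization analysis combines per-SNP summary
associations from an exposure GWAS (here: serum urate, mg/dl) and an
outcome GWAS (here: multiple sclerosis, log-odds).  Before any causal
estimator can run, the two tables must be expressed on a shared effect
allele per SNP ("harmonization"), correlated instruments must be pruned
by linkage disequilibrium, and SNPs absent from the outcome panel may be
replaced by high-LD proxies.  This module implements that front end.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, ValidationError

__all__ = [
    "Z_95",
    "VariantAssociation",
    "LdTable",
    "HarmonizedPair",
    "HarmonizedDataset",
    "ci_to_log_se",
    "read_association_table",
    "associations_from_frame",
    "harmonize",
    "prune_ld",
    "substitute_proxies",
]

#: 0.975 standard-normal quantile, frozen so CI conversions are bit-stable.
Z_95 = 1.959964

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

TraitKind = Literal["continuous", "binary"]


def _complement(allele: str) -> str:
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ValidationError(f"not a single-base allele: {allele!r}") from None


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is mg/dl per effect allele for a continuous trait and
    log-odds per effect allele for a binary one.
    """

    rsid: str
    chrom: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int
    trait_kind: TraitKind = "continuous"
    source: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.rsid}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not self.se > 0:
            raise ValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.effect_allele, self.other_allele)

    def is_palindromic(self) -> bool:
        """True for A/T and G/C variants (strand-ambiguous)."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele

    def flipped(self) -> "VariantAssociation":
        """Reorient onto the other allele: swap alleles, negate beta, 1-eaf."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
        )

    def strand_complemented(self) -> "VariantAssociation":
        return replace(
            self,
            effect_allele=_complement(self.effect_allele),
            other_allele=_complement(self.other_allele),
        )


class LdTable:
    """Sparse symmetric table of pairwise LD r² values.

    Pairs not present are treated as independent (r² = 0); a variant with
    itself has r² = 1.
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in entries:
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r² must be in [0, 1], got {r2} for ({a}, {b})")
        if a != b:
            self._r2[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path_or_stream) -> "LdTable":
        df = pd.read_csv(path_or_stream, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
        for col in ("rsid_a", "rsid_b", "r2"):
            if col not in df.columns:
                raise FormatError(f"LD table is missing required column {col!r}")
        return cls(
            (row.rsid_a, row.rsid_b, float(row.r2)) for row in df.itertuples(index=False)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None = None
    proxy_rsid: str | None = None
    proxy_r2: float | None = None
    source: str = ""
    flipped: bool = False

    def __post_init__(self) -> None:
        if not self.se_exposure > 0:
            raise ValidationError(f"{self.rsid}: se_exposure must be > 0")
        if not self.se_outcome > 0:
            raise ValidationError(f"{self.rsid}: se_outcome must be > 0")


#: Harmonization dispositions recorded in the audit.
KEPT = "kept"
FLIPPED = "flipped"
PROXIED = "proxied"
PALINDROMIC_DROPPED = "palindromic-dropped"
INCOMPATIBLE_DROPPED = "incompatible-dropped"
UNMATCHED = "unmatched"

_KEPT_STATES = {KEPT, FLIPPED, PROXIED}


@dataclass
class HarmonizedDataset:
    """Ordered harmonized pairs plus a per-input-SNP disposition audit."""

    pairs: list[HarmonizedPair]
    audit: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            if p.rsid in seen:
                raise ValidationError(f"duplicate rsid in harmonized dataset: {p.rsid}")
            seen.add(p.rsid)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [p.rsid for p in self.pairs]

    def subset(self, rsids: Iterable[str]) -> "HarmonizedDataset":
        keep = set(rsids)
        pairs = [p for p in self.pairs if p.rsid in keep]
        return HarmonizedDataset(pairs, {p.rsid: self.audit.get(p.rsid, KEPT) for p in pairs})

    def drop(self, rsids: Iterable[str]) -> "HarmonizedDataset":
        out = set(rsids)
        return self.subset([r for r in self.rsids if r not in out])

    def n_kept(self) -> int:
        return sum(1 for d in self.audit.values() if d in _KEPT_STATES)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": p.rsid,
                    "beta_exposure": p.beta_exposure,
                    "se_exposure": p.se_exposure,
                    "beta_outcome": p.beta_outcome,
                    "se_outcome": p.se_outcome,
                    "eaf": p.eaf,
                    "proxy_rsid": p.proxy_rsid or "",
                    "proxy_r2": p.proxy_r2,
                    "source": p.source,
                    "flipped": p.flipped,
                }
                for p in self.pairs
            ]
        )


def ci_to_log_se(
    point_or: float, ci_low: float, ci_high: float, level: float = 0.95
) -> float:
    """Standard error on the log-odds scale from an OR and its CI.

    se = (ln ci_high - ln ci_low) / (2 z), z the (1+level)/2 normal quantile.
    """
    if min(point_or, ci_low, ci_high) <= 0:
        raise ValidationError("odds ratio and CI bounds must be positive")
    if not (ci_low <= point_or <= ci_high):
        raise ValidationError(
            f"inverted CI: expected ci_low <= OR <= ci_high, got "
            f"({ci_low}, {point_or}, {ci_high})"
        )
    if ci_low == ci_high:
        raise ValidationError("degenerate CI: ci_low == ci_high gives se = 0")
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf((1.0 + level) / 2.0))
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


_COMMON_COLS = ["rsid", "chr", "effect_allele", "other_allele", "eaf", "pvalue", "n"]


def read_association_table(
    path_or_stream, trait_kind: TraitKind, source: str = ""
) -> list[VariantAssociation]:
    """Parse a TSV of per-SNP summary statistics.

    Continuous-trait tables carry ``beta``/``se`` columns; binary-trait
    tables may instead (or additionally) carry ``or``/``ci_low``/``ci_high``,
    which are converted to log-odds beta and SE.  Row order is preserved.
    """
    if isinstance(path_or_stream, str) and "\n" in path_or_stream:
        path_or_stream = io.StringIO(path_or_stream)
    df = pd.read_csv(path_or_stream, sep="\t", dtype={"rsid": str, "chr": str})
    return associations_from_frame(df, trait_kind, source=source)


def associations_from_frame(
    df: pd.DataFrame, trait_kind: TraitKind, source: str = ""
) -> list[VariantAssociation]:
    """Build associations from an in-memory table (same contract as
    :func:`read_association_table`)."""
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]

    for col in _COMMON_COLS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    has_beta = "beta" in df.columns and "se" in df.columns
    has_or = {"or", "ci_low", "ci_high"} <= set(df.columns)
    if trait_kind == "continuous" and not has_beta:
        raise FormatError("missing required column 'beta'/'se' for a continuous trait")
    if trait_kind == "binary" and not (has_beta or has_or):
        raise FormatError(
            "binary trait requires either 'beta'/'se' or 'or'/'ci_low'/'ci_high' columns"
        )

    out: list[VariantAssociation] = []
    for row in df.to_dict("records"):
        rsid = row["rsid"]
        if has_beta and not (pd.isna(row.get("beta")) or pd.isna(row.get("se"))):
            beta, se = float(row["beta"]), float(row["se"])
        elif trait_kind == "binary" and has_or:
            point, lo, hi = (float(row["or"]), float(row["ci_low"]), float(row["ci_high"]))
            if min(point, lo, hi) <= 0:
                raise ValidationError(f"{rsid}: OR/CI values must be positive")
            beta = math.log(point)
            se = ci_to_log_se(point, lo, hi)
        else:
            raise ValidationError(f"{rsid}: no usable effect columns in row")
        if not se > 0:
            raise ValidationError(f"{rsid}: non-positive standard error {se}")
        eaf = None if pd.isna(row["eaf"]) else float(row["eaf"])
        out.append(
            VariantAssociation(
                rsid=rsid,
                chrom=str(row["chr"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                eaf=eaf,
                beta=beta,
                se=se,
                pvalue=float(row["pvalue"]),
                n=int(row["n"]),
                trait_kind=trait_kind,
                source=source or str(row.get("source", "") or ""),
            )
        )
    return out


def write_association_table(assocs: Sequence[VariantAssociation], path) -> None:
    """Write associations back to the continuous-dialect TSV."""
    pd.DataFrame(
        [
            {
                "rsid": a.rsid,
                "chr": a.chrom,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "eaf": a.eaf,
                "beta": a.beta,
                "se": a.se,
                "pvalue": a.pvalue,
                "n": a.n,
            }
            for a in assocs
        ]
    ).to_csv(path, sep="\t", index=False)


def _check_unique(assocs: Sequence[VariantAssociation], label: str) -> None:
    seen: set[str] = set()
    for a in assocs:
        if a.rsid in seen:
            raise ValidationError(f"duplicate rsid {a.rsid!r} in {label} input")
        seen.add(a.rsid)


def _orient_outcome(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[VariantAssociation, bool] | None:
    """Express an outcome record on the exposure's effect allele.

    Returns (oriented record, flipped flag), or None when the allele pairs
    are irreconcilable even under strand complement.
    """
    for candidate in (out, out.strand_complemented()):
        if candidate.alleles == exp.alleles:
            return candidate, False
        if candidate.alleles == (exp.other_allele, exp.effect_allele):
            return candidate.flipped(), True
    return None


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_eaf_window: float = 0.08,
    drop_palindromic: bool = True,
    proxies: Mapping[str, tuple[VariantAssociation, float]] | None = None,
) -> HarmonizedDataset:
    """Align exposure and outcome effects onto a shared effect allele per SNP.

    For each exposure SNP present in the outcome panel (directly or through
    ``proxies``), the outcome record is reoriented — by allele swap and/or
    strand complement — onto the exposure effect allele, negating its beta
    and complementing its frequency when swapped.  Palindromic (A/T, G/C)
    SNPs whose minor-allele frequency lies within ``palindrome_eaf_window``
    of 0.5 are strand-ambiguous and dropped when ``drop_palindromic``.
    Every input exposure SNP receives exactly one audit disposition.
    """
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")
    by_rsid = {a.rsid: a for a in outcome}
    proxies = proxies or {}

    pairs: list[HarmonizedPair] = []
    audit: dict[str, str] = {}
    for exp in exposure:
        proxy_rsid: str | None = None
        proxy_r2: float | None = None
        out = by_rsid.get(exp.rsid)
        if out is None and exp.rsid in proxies:
            out, proxy_r2 = proxies[exp.rsid]
            proxy_rsid = out.rsid
        if out is None:
            audit[exp.rsid] = UNMATCHED
            continue

        if drop_palindromic and exp.is_palindromic():
            eaf = exp.eaf if exp.eaf is not None else out.eaf
            maf = 0.5 if eaf is None else min(eaf, 1.0 - eaf)
            if 0.5 - maf <= palindrome_eaf_window:
                audit[exp.rsid] = PALINDROMIC_DROPPED
                continue

        oriented = _orient_outcome(exp, out)
        if oriented is None:
            audit[exp.rsid] = INCOMPATIBLE_DROPPED
            continue
        out_aligned, flipped = oriented
        pairs.append(
            HarmonizedPair(
                rsid=exp.rsid,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=out_aligned.beta,
                se_outcome=out_aligned.se,
                eaf=exp.eaf if exp.eaf is not None else out_aligned.eaf,
                proxy_rsid=proxy_rsid,
                proxy_r2=proxy_r2,
                source=out.source,
                flipped=flipped,
            )
        )
        if proxy_rsid is not None:
            audit[exp.rsid] = PROXIED
        elif flipped:
            audit[exp.rsid] = FLIPPED
        else:
            audit[exp.rsid] = KEPT
    return HarmonizedDataset(pairs, audit)


def prune_ld(
    assocs: Sequence[VariantAssociation],
    ld: LdTable,
    r2_max: float = 0.01,
) -> list[VariantAssociation]:
    """Greedy LD pruning: keep the most significant SNP of each LD cluster.

    Candidates are visited in ascending exposure p-value order (ties broken
    lexicographically by rsid) and retained iff their r² with every SNP
    already retained is <= ``r2_max``.  The returned list preserves the
    input's relative order; absent LD entries count as independent.
    """
    order = sorted(assocs, key=lambda a: (a.pvalue, a.rsid))
    retained: list[str] = []
    for a in order:
        if all(ld.r2(a.rsid, kept) <= r2_max for kept in retained):
            retained.append(a.rsid)
    keep = set(retained)
    return [a for a in assocs if a.rsid in keep]


def substitute_proxies(
    missing: Sequence[VariantAssociation],
    ld: LdTable,
    outcome_panels: Sequence[VariantAssociation] | Sequence[Sequence[VariantAssociation]],
    r2_min: float = 0.8,
) -> dict[str, tuple[VariantAssociation, float]]:
    """Find an outcome-panel proxy for each target SNP absent from it.

    Panels are searched in priority order; within a panel the candidate with
    maximal r² >= ``r2_min`` wins (ties broken lexicographically by rsid),
    and the first panel yielding a qualifying proxy is used.  Targets with
    no qualifying candidate are simply absent from the returned mapping.
    """
    if len(outcome_panels) > 0 and isinstance(outcome_panels[0], VariantAssociation):
        panels: list[Sequence[VariantAssociation]] = [outcome_panels]  # type: ignore[list-item]
    else:
        panels = list(outcome_panels)  # type: ignore[arg-type]

    mapping: dict[str, tuple[VariantAssociation, float]] = {}
    for target in missing:
        for panel in panels:
            best: tuple[float, str, VariantAssociation] | None = None
            for cand in panel:
                if cand.rsid == target.rsid:
                    continue
                r2 = ld.r2(target.rsid, cand.rsid)
                if r2 < r2_min:
                    continue
                # max r2, ties to lexicographically smallest rsid
                key = (-r2, cand.rsid)
                if best is None or key < (-best[0], best[1]):
                    best = (r2, cand.rsid, cand)
            if best is not None:
                mapping[target.rsid] = (best[2], best[0])
                break
    return mapping
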