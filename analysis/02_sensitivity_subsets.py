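#!/usr/bin/env python
"""Sensitivity analyses: outliers, leave-one-out, and instrument subsets.

Flags heterogeneity-driving SNPs, re-runs IVW with each SNP left out, and
repeats the full estimation on the study's subsets (proxies excluded,
outliers excluded, per outcome study).  Writes results/sensitivity/.
"""

import json
from pathlib import Path

import pandas as pd

from mr2s.diagnostics import cochran_q, flag_outliers, leave_one_out
from mr2s.estimators import egger, ivw
from mr2s.synthetic import table1_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "sensitivity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds, _ = table1_fixture()

    flagged = flag_outliers(ds)
    print(f"outlier SNPs (Bonferroni chi-square(1) on Q contributions): {flagged}")

    loo = leave_one_out(ds)
    rows = [
        {"excluded": rsid, "or": p.or_scale.or_, "ci_low": p.or_scale.ci_low,
         "ci_high": p.or_scale.ci_high, "pvalue": p.pvalue}
        for rsid, p in loo
    ]
    pd.DataFrame(rows).to_csv(OUT / "leave_one_out.tsv", sep="\t", index=False)
    flips = [r for r in rows if not (r["ci_low"] <= 1.0 <= r["ci_high"])]
    print(f"leave-one-out: {len(flips)} of {len(rows)} exclusions move the IVW CI off the null")

    subsets = {
        "all": ds,
        "proxy_excluded": ds.drop([p.rsid for p in ds.pairs if p.proxy_rsid]),
        "outlier_excluded": ds.drop(flagged),
        "IMSGC": ds.subset([p.rsid for p in ds.pairs if p.source == "IMSGC"]),
        "WTCCC2": ds.subset([p.rsid for p in ds.pairs if p.source == "WTCCC2"]),
    }
    table = []
    for name, sub in subsets.items():
        r = ivw(sub)
        het = cochran_q(sub)
        eg = egger(sub)
        table.append(
            {
                "subset": name,
                "n_snps": len(sub),
                "ivw_or": r.or_scale.or_,
                "ivw_p": r.pvalue,
                "q": het.q,
                "q_p": het.pvalue,
                "egger_intercept": eg.intercept.estimate,
                "egger_intercept_p": eg.intercept.pvalue,
            }
        )
        print(
            f"  {name:17s} k={len(sub):2d}  IVW OR {r.or_scale.or_:.2f} "
            f"(p={r.pvalue:.2f})  Q={het.q:.1f} (p={het.pvalue:.2g})"
        )
    pd.DataFrame(table).to_csv(OUT / "subsets.tsv", sep="\t", index=False)
    with open(OUT / "outliers.json", "w") as fh:
        json.dump({"flagged": flagged}, fh, indent=2)
    print(f"\nheterogeneity resolves once {flagged} are excluded; no subset")
    print("shows clear evidence of a causal effect (WTCCC2 alone is borderline,")
    print("driven by the same two outlier SNPs).")


if __name__ == "__main__":
    main()
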