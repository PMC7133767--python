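import numpy as np
import pytest

from mr2s.summary_data import HarmonizedDataset, HarmonizedPair, VariantAssociation
from mr2s.synthetic import table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged 18-SNP urate-MS dataset (harmonized + exposure list)."""
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_ds(table1):
    return table1[0]


def make_pair(
    rsid="snp1",
    beta_exposure=0.1,
    se_exposure=0.006,
    beta_outcome=0.01,
    se_outcome=0.02,
    **kw,
):
    return HarmonizedPair(
        rsid=rsid,
        beta_exposure=beta_exposure,
        se_exposure=se_exposure,
        beta_outcome=beta_outcome,
        se_outcome=se_outcome,
        **kw,
    )


def make_dataset(ratios, weights=None, se_outcome=0.02, se_exposure=0.006):
    """Dataset whose Wald ratios and IVW weights are exactly as requested.

    With beta_exposure_i = sqrt(w_i) * se_outcome the IVW weight
    beta_exposure²/se_outcome² equals w_i, and beta_outcome = ratio * beta_exposure.
    """
    if weights is None:
        weights = [1.0] * len(ratios)
    pairs = []
    for i, (r, w) in enumerate(zip(ratios, weights)):
        bx = float(np.sqrt(w) * se_outcome)
        pairs.append(
            make_pair(
                rsid=f"snp{i + 1:03d}",
                beta_exposure=bx,
                se_exposure=se_exposure,
                beta_outcome=r * bx,
                se_outcome=se_outcome,
            )
        )
    return HarmonizedDataset(pairs, {p.rsid: "kept" for p in pairs})


def random_dataset(rng, k=10):
    """Random harmonized dataset for oracle-equivalence checks."""
    pairs = []
    for i in range(k):
        bx = rng.uniform(0.03, 0.4) * rng.choice([-1.0, 1.0])
        pairs.append(
            make_pair(
                rsid=f"r{i:03d}",
                beta_exposure=float(bx),
                se_exposure=float(rng.uniform(0.004, 0.01)),
                beta_outcome=float(rng.normal(0.0, 0.03)),
                se_outcome=float(rng.uniform(0.01, 0.04)),
            )
        )
    return HarmonizedDataset(pairs, {p.rsid: "kept" for p in pairs})


def make_assoc(
    rsid="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-8,
    n=10000,
    trait_kind="continuous",
    **kw,
):
    return VariantAssociation(
        rsid=rsid,
        chrom=kw.pop("chrom", "1"),
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        trait_kind=trait_kind,
        **kw,
    )
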