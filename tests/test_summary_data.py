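"""Parsing, CI conversion, harmonization, LD pruning and proxy search."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mr2s.exceptions import FormatError, ValidationError
from mr2s.summary_data import (
    LdTable,
    Z_95,
    ci_to_log_se,
    harmonize,
    prune_ld,
    read_association_table,
    substitute_proxies,
)

from conftest import make_assoc


class TestCiToLogSe:
    @pytest.mark.parametrize(
        "point, lo, hi, expected",
        [
            (0.95, 0.92, 0.98, (math.log(0.98) - math.log(0.92)) / 3.919928),
            (1.00, 0.96, 1.04, (math.log(1.04) - math.log(0.96)) / 3.919928),
            (1.0, math.exp(-Z_95), math.exp(Z_95), 1.0),
        ],
    )
    def test_known_values(self, point, lo, hi, expected):
        assert ci_to_log_se(point, lo, hi) == pytest.approx(expected, rel=1e-12)

    def test_inverted_ci_rejected(self):
        with pytest.raises(ValidationError):
            ci_to_log_se(1.0, 1.04, 0.96)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            ci_to_log_se(1.0, 0.0, 1.1)

    def test_other_level(self):
        # 90% CI spans 2 * z_0.95
        se = ci_to_log_se(1.0, math.exp(-1.6448536269514722), math.exp(1.6448536269514722), level=0.90)
        assert se == pytest.approx(1.0, rel=1e-9)


EXPOSURE_TSV = (
    "rsid\tchr\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
    "rs2231142\t4\tT\tG\t0.11\t0.217\t0.009\t1e-134\t110347\n"
)

OUTCOME_TSV = (
    "rsid\tchr\teffect_allele\tother_allele\teaf\tor\tci_low\tci_high\tpvalue\tn\n"
    "rs12498742\t4\tA\tG\t0.77\t1.00\t0.96\t1.04\t0.961\t38589\n"
)


class TestReadAssociationTable:
    def test_continuous_row(self):
        (a,) = read_association_table(io.StringIO(EXPOSURE_TSV), "continuous")
        assert (a.rsid, a.beta, a.se) == ("rs2231142", 0.217, 0.009)
        assert a.trait_kind == "continuous"

    def test_binary_or_ci_converted(self):
        (a,) = read_association_table(io.StringIO(OUTCOME_TSV), "binary")
        assert a.beta == pytest.approx(0.0)
        assert a.se == pytest.approx(
            (math.log(1.04) - math.log(0.96)) / (2 * Z_95), rel=1e-9
        )

    def test_empty_data_section(self):
        header = EXPOSURE_TSV.splitlines()[0] + "\n"
        assert read_association_table(io.StringIO(header), "continuous") == []

    def test_missing_column_named(self):
        bad = EXPOSURE_TSV.replace("\tse", "\tsx")
        with pytest.raises(FormatError, match="se"):
            read_association_table(io.StringIO(bad), "continuous")

    def test_bad_ci_names_rsid(self):
        bad = OUTCOME_TSV.replace("0.96\t1.04", "-0.96\t1.04")
        with pytest.raises(ValidationError, match="rs12498742"):
            read_association_table(io.StringIO(bad), "binary")

    def test_row_order_preserved(self):
        two = EXPOSURE_TSV + "rs1260326\t2\tT\tC\t0.41\t0.074\t0.005\t1.2e-44\t110347\n"
        rows = read_association_table(io.StringIO(two), "continuous")
        assert [a.rsid for a in rows] == ["rs2231142", "rs1260326"]


def _outcome(rsid="rs1", ea="A", oa="G", beta=0.05, eaf=0.3, **kw):
    return make_assoc(
        rsid=rsid,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        eaf=eaf,
        se=0.02,
        trait_kind="binary",
        **kw,
    )


class TestHarmonize:
    def test_same_orientation_kept(self):
        ds = harmonize([make_assoc()], [_outcome()])
        assert ds.audit == {"rs1": "kept"}
        assert ds.pairs[0].beta_outcome == 0.05
        assert not ds.pairs[0].flipped

    def test_swapped_orientation_flips_beta(self):
        ds = harmonize([make_assoc()], [_outcome(ea="G", oa="A")])
        (p,) = ds.pairs
        assert p.beta_outcome == -0.05
        assert p.flipped
        assert ds.audit["rs1"] == "flipped"

    def test_strand_complement_resolved(self):
        # exposure A/G, outcome reported on the other strand as T/C
        ds = harmonize([make_assoc()], [_outcome(ea="T", oa="C")])
        (p,) = ds.pairs
        assert p.beta_outcome == 0.05
        assert not p.flipped

    def test_strand_complement_swapped(self):
        ds = harmonize([make_assoc()], [_outcome(ea="C", oa="T")])
        assert ds.pairs[0].beta_outcome == -0.05
        assert ds.pairs[0].flipped

    def test_palindromic_intermediate_dropped(self):
        exp = make_assoc(effect_allele="A", other_allele="T", eaf=0.47)
        ds = harmonize([exp], [_outcome(ea="A", oa="T", eaf=0.47)], palindrome_eaf_window=0.08)
        assert ds.audit == {"rs1": "palindromic-dropped"}
        assert len(ds) == 0

    def test_palindromic_extreme_frequency_kept(self):
        exp = make_assoc(effect_allele="G", other_allele="C", eaf=0.10)
        ds = harmonize([exp], [_outcome(ea="G", oa="C", eaf=0.10)])
        assert ds.audit == {"rs1": "kept"}

    def test_palindromic_kept_when_not_dropping(self):
        exp = make_assoc(effect_allele="A", other_allele="T", eaf=0.47)
        ds = harmonize(
            [exp], [_outcome(ea="A", oa="T", eaf=0.47)], drop_palindromic=False
        )
        assert len(ds) == 1

    def test_incompatible_alleles_dropped(self):
        ds = harmonize([make_assoc()], [_outcome(ea="A", oa="C")])
        assert ds.audit == {"rs1": "incompatible-dropped"}

    def test_unmatched_recorded(self):
        ds = harmonize([make_assoc()], [_outcome(rsid="rs9")])
        assert ds.audit == {"rs1": "unmatched"}

    def test_duplicate_rsid_rejected(self):
        with pytest.raises(ValidationError):
            harmonize([make_assoc(), make_assoc()], [_outcome()])

    def test_proxy_substitution_recorded(self):
        proxy = _outcome(rsid="rs1_proxy")
        ds = harmonize([make_assoc()], [], proxies={"rs1": (proxy, 0.92)})
        (p,) = ds.pairs
        assert (p.proxy_rsid, p.proxy_r2) == ("rs1_proxy", 0.92)
        assert ds.audit == {"rs1": "proxied"}

    def test_idempotent(self):
        """Re-harmonizing an already-aligned dataset changes nothing."""
        exposure = [make_assoc(), make_assoc(rsid="rs2", effect_allele="T", other_allele="C", beta=-0.04)]
        outcome = [_outcome(), _outcome(rsid="rs2", ea="C", oa="T", beta=0.03)]
        first = harmonize(exposure, outcome)
        aligned = [
            _outcome(rsid=p.rsid, ea=e.effect_allele, oa=e.other_allele, beta=p.beta_outcome, eaf=p.eaf)
            for p, e in zip(first.pairs, exposure)
        ]
        second = harmonize(exposure, aligned)
        assert [
            (p.rsid, p.beta_outcome, p.se_outcome) for p in second.pairs
        ] == [(p.rsid, p.beta_outcome, p.se_outcome) for p in first.pairs]
        assert all(not p.flipped for p in second.pairs)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_orientation_involution_and_audit_conservation(self, data):
        """Flipping every outcome record leaves the harmonized effects
        identical (up to the flipped flags), and every exposure SNP in the
        outcome panel is either kept or dropped — never lost."""
        k = data.draw(st.integers(2, 8))
        pairs = [("A", "G"), ("T", "C"), ("A", "C"), ("A", "T"), ("G", "C")]
        exposure, outcome = [], []
        for i in range(k):
            ea, oa = data.draw(st.sampled_from(pairs))
            eaf = data.draw(st.floats(0.05, 0.95))
            beta_o = data.draw(st.floats(-0.1, 0.1))
            exposure.append(
                make_assoc(rsid=f"rs{i}", effect_allele=ea, other_allele=oa, eaf=eaf)
            )
            if data.draw(st.booleans()):
                outcome.append(
                    _outcome(rsid=f"rs{i}", ea=ea, oa=oa, beta=beta_o, eaf=eaf)
                )
        ds = harmonize(exposure, outcome)
        flipped_outcome = [a.flipped() for a in outcome]
        ds2 = harmonize(exposure, flipped_outcome)
        def key(d):
            return [
                (p.rsid, p.beta_exposure, p.beta_outcome, p.se_outcome) for p in d.pairs
            ]

        assert key(ds) == key(ds2)
        matched = {a.rsid for a in outcome}
        kept = sum(1 for d in ds.audit.values() if d in {"kept", "flipped", "proxied"})
        dropped = sum(
            1
            for r, d in ds.audit.items()
            if d in {"palindromic-dropped", "incompatible-dropped"} and r in matched
        )
        assert kept + dropped == len(matched)


class TestPruneLd:
    def test_correlated_pair_keeps_most_significant(self):
        a = make_assoc(rsid="rsA", pvalue=1e-40)
        b = make_assoc(rsid="rsB", pvalue=1e-9)
        ld = LdTable([("rsA", "rsB", 0.02)])
        assert [x.rsid for x in prune_ld([a, b], ld)] == ["rsA"]

    def test_below_threshold_keeps_both(self):
        a = make_assoc(rsid="rsA", pvalue=1e-40)
        b = make_assoc(rsid="rsB", pvalue=1e-9)
        ld = LdTable([("rsA", "rsB", 0.005)])
        assert [x.rsid for x in prune_ld([a, b], ld)] == ["rsA", "rsB"]

    def test_greedy_chain(self):
        """A-B and B-C correlated, A-C not: greedy keeps {A, C}."""
        a = make_assoc(rsid="rsA", pvalue=1e-30)
        b = make_assoc(rsid="rsB", pvalue=1e-20)
        c = make_assoc(rsid="rsC", pvalue=1e-10)
        ld = LdTable([("rsA", "rsB", 0.5), ("rsB", "rsC", 0.5)])
        assert [x.rsid for x in prune_ld([a, b, c], ld)] == ["rsA", "rsC"]

    def test_output_independent_of_input_order(self):
        rng = np.random.default_rng(3)
        assocs = [
            make_assoc(rsid=f"rs{i}", pvalue=float(rng.uniform(1e-20, 1e-8)))
            for i in range(8)
        ]
        entries = [
            (f"rs{i}", f"rs{j}", float(rng.uniform(0, 0.3)))
            for i in range(8)
            for j in range(i + 1, 8)
        ]
        ld = LdTable(entries)
        base = {a.rsid for a in prune_ld(assocs, ld)}
        for _ in range(5):
            perm = list(assocs)
            rng.shuffle(perm)
            assert {a.rsid for a in prune_ld(perm, ld)} == base


class TestSubstituteProxies:
    def test_best_candidate_selected(self):
        target = make_assoc(rsid="rs12498742")
        cands = [
            _outcome(rsid="rs7442295"),
            _outcome(rsid="rs0weak"),
        ]
        ld = LdTable([("rs12498742", "rs7442295", 0.95), ("rs12498742", "rs0weak", 0.85)])
        got = substitute_proxies([target], ld, cands)
        assert got["rs12498742"][0].rsid == "rs7442295"
        assert got["rs12498742"][1] == 0.95

    def test_below_threshold_unproxied(self):
        target = make_assoc(rsid="rsT")
        ld = LdTable([("rsT", "rsP", 0.5)])
        assert substitute_proxies([target], ld, [_outcome(rsid="rsP")]) == {}

    def test_panel_priority_order(self):
        target = make_assoc(rsid="rsT")
        p1 = [_outcome(rsid="rsP1")]
        p2 = [_outcome(rsid="rsP2")]
        ld = LdTable([("rsT", "rsP1", 0.85), ("rsT", "rsP2", 0.99)])
        got = substitute_proxies([target], ld, [p1, p2])
        # first panel with a qualifying proxy wins despite the higher r2 later
        assert got["rsT"][0].rsid == "rsP1"

    def test_tie_broken_lexicographically(self):
        target = make_assoc(rsid="rsT")
        cands = [_outcome(rsid="rsB"), _outcome(rsid="rsA")]
        ld = LdTable([("rsT", "rsA", 0.9), ("rsT", "rsB", 0.9)])
        assert substitute_proxies([target], ld, cands)["rsT"][0].rsid == "rsA"


class TestFixtureHarmonization:
    def test_all_18_pairs_survive(self, table1):
        from mr2s.synthetic import fixture_input_tables
        from mr2s.summary_data import associations_from_frame

        tables = fixture_input_tables()
        exposure = associations_from_frame(tables["exposure"], "continuous")
        panels = [
            associations_from_frame(tables["outcome_imsgc"], "binary", source="IMSGC"),
            associations_from_frame(tables["outcome_wtccc2"], "binary", source="WTCCC2"),
        ]
        ld = LdTable(
            (r.rsid_a, r.rsid_b, r.r2) for r in tables["ld"].itertuples(index=False)
        )
        missing = [
            a for a in exposure if a.rsid not in {o.rsid for p in panels for o in p}
        ]
        proxies = substitute_proxies(missing, ld, panels)
        ds = harmonize(exposure, panels[0] + panels[1], proxies=proxies)
        assert len(ds) == 18
        assert sum(1 for p in ds.pairs if p.proxy_rsid) == 9
        assert all(d in {"kept", "proxied"} for d in ds.audit.values())
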