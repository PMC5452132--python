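import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chloredit import edit_call as ec
from chloredit import synthetic_data as synth
from chloredit.align_filter import CdsAlignment
from chloredit.synthetic_data import EditingSiteRecord


def exact_binomial_tail(k: int, n: int, p: float) -> float:
    """Independent oracle: P(X >= k), X ~ Bin(n, p), in exact rational
    arithmetic on the binary float value of p."""
    if k <= 0:
        return 1.0
    pf = Fraction(p)
    q = 1 - pf
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * pf**i * q ** (n - i)
    return float(total)


def _site(gene="g1", pos=10, score=0.9, fracs=None):
    return EditingSiteRecord(gene, pos, score, true_fraction_by_condition=fracs or {})


class TestPileupSites:
    def test_counts_from_constructed_alignments(self):
        site = _site(pos=5)
        cds = {"g1": "A" * 4 + "C" + "A" * 15}
        reads = [CdsAlignment(f"r{i}", "g1", 0, "AAAAT" + "A" * 10, 0) for i in range(11)]
        reads += [CdsAlignment(f"s{i}", "g1", 0, "AAAAC" + "A" * 10, 0) for i in range(9)]
        piles = ec.pileup_sites({"lib": reads}, [site], cds)
        assert len(piles) == 1
        assert (piles[0].n_edited, piles[0].n_unedited, piles[0].n_other) == (11, 9, 0)

    def test_truth_table_oracle(self, genome_set):
        sites = synth.generate_site_table(genome_set, 2, {"control": 0.55}, seed=3)
        prof = synth.LibraryProfile("lib", "control", 8000, seed=8, error_rate=0.0)
        reads = synth.simulate_read_library(genome_set, sites, prof)
        alns = [
            CdsAlignment(r.read_id, r.target_id, r.start, r.sequence, 0)
            for r in reads
            if r.origin == "cds"
        ]
        piles = ec.pileup_sites({"lib": alns}, sites, genome_set.cds_sequences())
        expected = {
            (s.gene_id, s.cds_position): [0, 0] for s in sites
        }  # [edited, unedited]
        for r in reads:
            for g, p, e in r.edited_sites:
                expected[(g, p)][e] += 0  # placeholder keeps keys
                if e:
                    expected[(g, p)][0] += 1
                else:
                    expected[(g, p)][1] += 1
        for p in piles:
            e, u = expected[(p.gene_id, p.cds_position)]
            assert (p.n_edited, p.n_unedited) == (e, u)

    def test_no_coverage_site_is_nd(self):
        site = _site(pos=5)
        piles = ec.pileup_sites({"lib": []}, [site], {"g1": "C" * 10})
        assert piles[0].coverage == 0
        assert ec.editing_fraction(piles[0]) is None

    def test_n_base_counts_as_other(self):
        site = _site(pos=3)
        reads = [CdsAlignment("r", "g1", 0, "AANAA" + "A" * 10, 0)]
        piles = ec.pileup_sites({"lib": reads}, [site], {"g1": "AACAA" + "A" * 10})
        assert piles[0].n_other == 1
        assert piles[0].n_edited == 0

    def test_site_beyond_cds_raises(self):
        with pytest.raises(IndexError, match="g1:500"):
            ec.pileup_sites({"lib": []}, [_site(pos=500)], {"g1": "C" * 20})


class TestVariantTest:
    def test_zero_edited_gives_p_one(self):
        p, det = ec.variant_test(ec.SitePileup("g", 1, "l", 0, 50, 0))
        assert p == 1.0
        assert not det

    def test_min_coverage_gate(self):
        p, det = ec.variant_test(ec.SitePileup("g", 1, "l", 4, 0, 0))
        assert not det  # coverage 4 < 5 regardless of p
        p5, det5 = ec.variant_test(ec.SitePileup("g", 1, "l", 5, 0, 0))
        assert det5

    def test_exact_enumeration_oracle(self):
        pile = ec.SitePileup("g", 1, "l", 11, 9, 0)
        p, det = ec.variant_test(pile, error_rate=0.01)
        assert p == pytest.approx(exact_binomial_tail(11, 20, 0.01), abs=1e-12)
        assert det

    @pytest.mark.parametrize("n,k", [(5, 1), (20, 3), (100, 2), (250, 10)])
    def test_matches_enumeration_grid(self, n, k):
        pile = ec.SitePileup("g", 1, "l", k, n - k, 0)
        p, _ = ec.variant_test(pile, error_rate=0.01)
        assert p == pytest.approx(exact_binomial_tail(k, n, 0.01), abs=1e-12)

    def test_monotone_in_edited_count(self):
        last = 1.1
        for k in range(0, 21):
            p, _ = ec.variant_test(ec.SitePileup("g", 1, "l", k, 20 - k, 0))
            assert p <= last + 1e-15
            last = p

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            ec.variant_test(ec.SitePileup("g", 1, "l", 1, 1, 0), error_rate=0.7)


class TestEditingFraction:
    @pytest.mark.parametrize(
        "edited,unedited,expected",
        [
            (11, 9, 0.55),  # printed fraction for an 11-of-20 pileup
            (8, 0, 1.0),  # fully edited site
            (4, 1, 0.80),
            (1, 19, 0.05),
        ],
    )
    def test_values(self, edited, unedited, expected):
        pile = ec.SitePileup("g", 1, "l", edited, unedited, 0)
        assert round(ec.editing_fraction(pile), 2) == expected

    def test_nd_when_no_informative_reads(self):
        assert ec.editing_fraction(ec.SitePileup("g", 1, "l", 0, 0, 5)) is None

    def test_other_bases_excluded_from_denominator(self):
        pile = ec.SitePileup("g", 1, "l", 3, 1, 6)
        assert ec.editing_fraction(pile) == 0.75


class TestCompareConditions:
    COND = {"c1": "control", "c2": "control", "s1": "salt", "s2": "salt"}

    def test_identical_constant_groups(self):
        res = ec.compare_conditions(
            {"c1": 0.5, "c2": 0.5, "s1": 0.5, "s2": 0.5}, self.COND
        )
        assert res.p_value == 1.0
        assert res.degenerate

    def test_textbook_t_oracle(self):
        res = ec.compare_conditions(
            {"c1": 0.9, "c2": 0.8, "s1": 0.3, "s2": 0.4}, self.COND
        )
        # independent closed form: pooled SS = 4*(0.05^2) = 0.01,
        # pooled var = 0.005, se = sqrt(0.005*(1/2+1/2)), t = 0.5/se;
        # two-sided p for df=2 is 1 - t/sqrt(2 + t^2)
        t = 0.5 / math.sqrt(0.005)
        expected = 1.0 - t / math.sqrt(2.0 + t * t)
        assert res.p_value == pytest.approx(expected, rel=1e-10)

    def test_single_value_group_degenerate(self):
        res = ec.compare_conditions({"c1": 0.8, "s1": 0.2, "s2": 0.3}, self.COND)
        assert res.degenerate
        assert res.p_value is not None

    def test_nd_excluded_and_incomparable(self):
        res = ec.compare_conditions(
            {"c1": None, "c2": None, "s1": 0.5, "s2": 0.6}, self.COND
        )
        assert res.incomparable
        assert res.p_value is None

    def test_zero_variance_unequal_means(self):
        res = ec.compare_conditions(
            {"c1": 0.8, "c2": 0.8, "s1": 0.2, "s2": 0.2}, self.COND
        )
        assert res.p_value == 0.0
        assert res.degenerate


class TestSelectSites:
    COND = {"c1": "control", "c2": "control", "s1": "salt", "s2": "salt"}

    def _stats(self, coverages, edited):
        site = _site()
        piles = [
            ec.SitePileup("g1", 10, lib, e, c - e, 0)
            for lib, c, e in zip(self.COND, coverages, edited)
        ]
        return ec.compute_site_stats(piles, [site], self.COND)

    def test_low_total_coverage_not_selected(self):
        stats = self._stats([1, 1, 0, 1], [1, 1, 0, 1])
        df = ec.select_sites(stats, min_total_coverage=4)
        assert not df.loc[0, "selected"]

    def test_high_coverage_detected_selected(self):
        stats = self._stats([24, 17, 14, 19], [18, 14, 12, 17])
        df = ec.select_sites(stats, min_total_coverage=4)
        assert bool(df.loc[0, "selected"])
        assert df.loc[0, "total_coverage"] == 74

    def test_covered_but_undetected_not_selected(self):
        stats = self._stats([24, 17, 14, 19], [0, 0, 0, 0])
        df = ec.select_sites(stats)
        assert not df.loc[0, "selected"]

    def test_empty_stats(self):
        df = ec.select_sites([])
        assert len(df) == 0
        assert "gene_id" in df.columns

    def test_report_tsv_uses_nd(self, tmp_path):
        stats = self._stats([0, 0, 5, 5], [0, 0, 5, 5])
        df = ec.select_sites(stats, library_order=list(self.COND))
        out = tmp_path / "report.tsv"
        ec.write_report(df, out)
        text = out.read_text()
        assert "nd" in text
        assert "1.00" in text

    def test_bh_option(self):
        all_stats = []
        for i, (cov, ed) in enumerate([([9, 9, 9, 9], [9, 9, 1, 1]), ([9, 9, 9, 9], [5, 5, 5, 5])]):
            site = _site(pos=10 + i)
            piles = [
                ec.SitePileup("g1", 10 + i, lib, e, c - e, 0)
                for lib, c, e in zip(self.COND, cov, ed)
            ]
            all_stats.extend(ec.compute_site_stats(piles, [site], self.COND))
        df = ec.select_sites(all_stats, bh_adjust=True)
        assert "q_value" in df.columns
        order = df.sort_values("p_value")
        assert order["q_value"].is_monotonic_increasing


class TestParameterRecovery:
    def test_fraction_recovery_high_coverage(self, genome_set):
        # moderate-scale version of the recovery property
        sites = synth.generate_site_table(
            genome_set, 10, {"control": 0.35}, seed=44
        )
        prof = synth.LibraryProfile(
            "lib", "control", 6000, seed=45,
            read_length_range=(40, 60), error_rate=0.005,
        )
        reads = synth.simulate_read_library(genome_set, sites, prof)
        alns = [
            CdsAlignment(r.read_id, r.target_id, r.start, r.sequence, 0)
            for r in reads
            if r.origin == "cds"
        ]
        piles = ec.pileup_sites({"lib": alns}, sites, genome_set.cds_sequences())
        ok = 0
        for p in piles:
            n = p.n_edited + p.n_unedited
            assert n >= 50
            f = 0.35
            se = math.sqrt(f * (1 - f) / n)
            if abs(p.n_edited / n - f) <= 3 * se:
                ok += 1
        assert ok >= 9


@settings(max_examples=50, deadline=None)
@given(
    n=st.integers(1, 200),
    k=st.integers(0, 200),
    err=st.floats(0.001, 0.2),
)
def test_variant_p_in_unit_interval_and_monotone(n, k, err):
    k = min(k, n)
    p, _ = ec.variant_test(ec.SitePileup("g", 1, "l", k, n - k, 0), error_rate=err)
    assert 0.0 <= p <= 1.0
    if k > 0:
        p_less, _ = ec.variant_test(
            ec.SitePileup("g", 1, "l", k - 1, n - k + 1, 0), error_rate=err
        )
        assert p <= p_less + 1e-15
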