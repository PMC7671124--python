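"""Panel diagnostics: frequencies, heterozygosity, HWE, nulls, exclusion."""

import math

import numpy as np
import pytest

import poolpat as pp
from poolpat.locus_stats import (
    AlleleFrequencies,
    NoDataAtLocusError,
    combined_exclusion,
    exclusion_probabilities,
    exclusion_probabilities_enumeration,
)

from conftest import make_adults


def af(freqs, locus=None, n=50):
    locus = locus or pp.Locus(name="L01", repeat_motif="AC")
    return AlleleFrequencies(locus=locus, freqs=freqs, n_adults_typed=n)


class TestAlleleFrequencies:
    def test_direct_counts(self, single_locus):
        adults = make_adults([(57, 57), (57, 59)])
        out = pp.allele_frequencies(adults, single_locus)
        assert out.freqs == {57: 0.75, 59: 0.25}
        assert out.n_adults_typed == 2

    def test_single_heterozygote(self, single_locus):
        out = pp.allele_frequencies(make_adults([(113, 115)]), single_locus)
        assert out.freqs == {113: 0.5, 115: 0.5}

    def test_untyped_adults_excluded(self, single_locus):
        adults = make_adults([(57, 57)]) + [pp.AdultGenotype(adult_id="Z", calls={})]
        out = pp.allele_frequencies(adults, single_locus)
        assert out.n_adults_typed == 1

    def test_no_data_raises(self, single_locus):
        with pytest.raises(NoDataAtLocusError):
            pp.allele_frequencies([pp.AdultGenotype(adult_id="Z", calls={})], single_locus)


class TestHeterozygosity:
    def test_all_heterozygous(self, single_locus):
        ho, _ = pp.heterozygosities(make_adults([(1, 2), (3, 4), (5, 6)]), single_locus)
        assert ho == 1.0

    def test_fixed_allele(self, single_locus):
        ho, he = pp.heterozygosities(make_adults([(1, 1), (1, 1)]), single_locus)
        assert ho == 0.0 and he == 0.0

    def test_unbiased_estimator_hand_value(self, single_locus):
        # {(1,2),(1,1),(2,2),(1,2)}: p1 = p2 = 0.5, Ho = 2/4,
        # He = (8/7) * (1 - 0.5) = 4/7
        ho, he = pp.heterozygosities(
            make_adults([(1, 2), (1, 1), (2, 2), (1, 2)]), single_locus
        )
        assert ho == 0.5
        assert he == pytest.approx(4 / 7, abs=1e-12)


class TestHweTest:
    def test_counts_at_hwe_proportions_give_high_p(self, single_locus):
        # 2 alleles at 0.5: expected 4 AA, 8 AB, 4 BB out of 16
        adults = make_adults([(1, 1)] * 4 + [(1, 2)] * 8 + [(2, 2)] * 4)
        chi2, df, p = pp.hwe_test(adults, single_locus)
        assert chi2 == pytest.approx(0.0, abs=1e-9) or p > 0.9

    def test_all_homozygotes_hand_computed_chi2(self, single_locus):
        # 20 adults, 10 (1,1) and 10 (2,2); p1 = p2 = 0.5.
        # Expected: 5 / 10 / 5.  Observed: 10 / 0 / 10.  df = 3 - 2 = 1,
        # Yates: (4.5^2/5) + (9.5^2/10) + (4.5^2/5) = 17.125
        adults = make_adults([(1, 1)] * 10 + [(2, 2)] * 10)
        chi2, df, p = pp.hwe_test(adults, single_locus)
        assert df == 1
        assert chi2 == pytest.approx(17.125, abs=1e-9)
        assert p < 0.001

    def test_bundled_loci_all_consistent_with_hwe(self, bundled_panel):
        for locus in bundled_panel.loci:
            _, _, p = pp.hwe_test(list(bundled_panel.adults), locus)
            assert p > 0.05

    def test_requires_minimum_sample(self, single_locus):
        with pytest.raises(ValueError):
            pp.hwe_test(make_adults([(1, 2)] * 4), single_locus)


class TestNullAlleleFrequency:
    def test_zero_when_ho_equals_he(self, single_locus):
        adults = make_adults([(1, 2), (1, 2), (1, 2), (1, 2)])
        ho, he = pp.heterozygosities(adults, single_locus)
        if ho == he:  # guard: construct may not balance exactly
            assert pp.null_allele_frequency(adults, single_locus) == 0.0

    def test_direct_formula(self, single_locus):
        adults = make_adults([(1, 1), (1, 2), (2, 2), (1, 2), (1, 1)])
        ho, he = pp.heterozygosities(adults, single_locus)
        expected = (he - ho) / (he + ho)
        assert pp.null_allele_frequency(adults, single_locus) == pytest.approx(expected)

    def test_recovers_simulated_null_frequency(self, single_locus):
        # 4 visible equifrequent alleles plus a null at r = 0.15; a null/x
        # carrier types as homozygous x, a null/null fails (dropped).
        rng = np.random.default_rng(42)
        r, n = 0.15, 500
        p = [(1 - r) / 4] * 4 + [r]
        labels = [1, 2, 3, 4, None]
        pairs = []
        while len(pairs) < n:
            a, b = rng.choice(5, size=2, p=p)
            if labels[a] is None and labels[b] is None:
                continue
            if labels[a] is None:
                pairs.append((labels[b], labels[b]))
            elif labels[b] is None:
                pairs.append((labels[a], labels[a]))
            else:
                pairs.append((labels[a], labels[b]))
        est = pp.null_allele_frequency(make_adults(pairs), single_locus)
        assert est == pytest.approx(r, abs=0.05)

    def test_near_zero_under_clean_hwe(self, single_locus):
        # mean estimate over replicates of a clean HWE sample is ~0
        rng = np.random.default_rng(7)
        p = [0.4, 0.3, 0.2, 0.1]
        ests = []
        for _ in range(200):
            draws = rng.choice([1, 2, 3, 4], size=(500, 2), p=p)
            ests.append(
                pp.null_allele_frequency(make_adults([tuple(d) for d in draws]), single_locus)
            )
        assert abs(np.mean(ests)) < 0.02


class TestExclusionProbabilities:
    def test_single_allele_excludes_nobody(self):
        assert exclusion_probabilities(af({10: 1.0})) == (0.0, 0.0)
        assert exclusion_probabilities_enumeration(af({10: 1.0})) == (0.0, 0.0)

    def test_two_equifrequent_alleles_hand_values(self):
        # P1 = 2 * (1/4)(1/4) = 1/8; P2 = 3/16 (hand enumeration over
        # mother x paternal allele x candidate)
        f = af({1: 0.5, 2: 0.5})
        p1, p2 = exclusion_probabilities(f)
        assert p1 == pytest.approx(0.125, abs=1e-12)
        assert p2 == pytest.approx(0.1875, abs=1e-12)
        assert exclusion_probabilities_enumeration(f) == (
            pytest.approx(p1, abs=1e-12),
            pytest.approx(p2, abs=1e-12),
        )

    def test_closed_form_matches_enumeration_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 9))
            p = rng.dirichlet(np.ones(k) * rng.uniform(0.3, 3.0))
            f = af({100 + 2 * i: float(x) for i, x in enumerate(p)})
            a1, a2 = exclusion_probabilities(f)
            b1, b2 = exclusion_probabilities_enumeration(f)
            assert a1 == pytest.approx(b1, abs=1e-12)
            assert a2 == pytest.approx(b2, abs=1e-12)
            assert a2 >= a1 - 1e-12  # knowing the mother never hurts

    def test_combined_two_loci_half_each(self):
        assert combined_exclusion([0.5, 0.5]) == pytest.approx(0.75)

    def test_combined_nondecreasing_in_loci(self):
        vals = [0.3, 0.1, 0.45, 0.2]
        acc = [combined_exclusion(vals[: i + 1]) for i in range(len(vals))]
        assert all(b >= a for a, b in zip(acc, acc[1:]))
        assert acc[-1] >= max(vals)


class TestPanelSummary:
    def test_single_locus_combined_equals_per_locus(self, bundled_panel):
        locus = bundled_panel.loci[0]
        summ = pp.panel_summary(list(bundled_panel.adults), [locus])
        assert summ.combined_Pexcl_no_parent == pytest.approx(
            summ.per_locus[0].Pexcl_no_parent
        )

    def test_bundled_panel_structure(self, bundled_panel):
        summ = pp.panel_summary(list(bundled_panel.adults), list(bundled_panel.loci))
        for row in summ.per_locus:
            assert 4 <= row.Na <= 7
            assert 0 <= row.Ho <= 1 and 0 <= row.He <= 1
            assert row.Pexcl_one_parent >= row.Pexcl_no_parent
        assert summ.combined_Pexcl_no_parent >= max(
            r.Pexcl_no_parent for r in summ.per_locus
        )
        assert summ.combined_Pexcl_one_parent > summ.combined_Pexcl_no_parent

    def test_failing_locus_reported_as_na_not_fatal(self, bundled_panel):
        ghost = pp.Locus(name="GHOST", repeat_motif="AC")
        loci = list(bundled_panel.loci) + [ghost]
        adults = [
            pp.AdultGenotype(
                adult_id=a.adult_id, social_status=a.social_status,
                shell_length_mm=a.shell_length_mm, calls=a.calls,
            )
            for a in bundled_panel.adults
        ]
        summ = pp.panel_summary(adults, loci)
        ghost_row = summ.per_locus[-1]
        assert ghost_row.Na == 0 and math.isnan(ghost_row.Ho)
        assert summ.combined_Pexcl_no_parent > 0  # other loci still combined
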