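"""Minimum-sires estimation and monogamy classification."""

import pytest
from hypothesis import given, settings, strategies as st

import poolpat as pp
from poolpat.parentage import UNKNOWN, PairCall

# the published minimum-sires column for the bundled worked example
EXPECTED_MIN_SIRES = {
    "20": 1, "21": 1, "23": 1, "25": 1, "26": 2, "27": 1, "28": 1, "29": 1,
    "30": 1, "31": 1, "32": 2, "33": 1, "34": 1, "35": 1, "36": 1, "37": 2,
}


class TestNonmaternalAlleles:
    def test_homozygous_mother_five_allele_set(self):
        # brood {53,57,59,61,63} vs mother (57,57): four sire-derived alleles
        assert pp.nonmaternal_alleles(frozenset({53, 57, 59, 61, 63}), (57, 57)) == 4

    def test_set_equal_to_maternal_pair(self):
        assert pp.nonmaternal_alleles(frozenset({115, 117}), (115, 117)) == 0

    def test_unknown_mother_subtracts_two(self):
        assert pp.nonmaternal_alleles(frozenset({115, 117, 121}), UNKNOWN) == 1
        assert pp.nonmaternal_alleles(frozenset({115}), UNKNOWN) == 0

    def test_no_data_is_na(self):
        assert pp.nonmaternal_alleles(None, (57, 57)) is None


class TestEstimateSires:
    def test_reproduces_published_column_exactly(self, bundled_panel):
        estimates = {e.mass_id: e for e in pp.estimate_sires_for_panel(bundled_panel)}
        got = {mid: e.min_sires_conservative for mid, e in estimates.items()}
        assert got == EXPECTED_MIN_SIRES

    def test_liberal_estimates(self, bundled_panel):
        estimates = {e.mass_id: e for e in pp.estimate_sires_for_panel(bundled_panel)}
        assert estimates["26"].sires_liberal == 4  # the largest in the dataset
        assert estimates["27"].min_sires_conservative == 1
        assert estimates["27"].sires_liberal == 1
        assert max(e.sires_liberal for e in estimates.values()) == 4
        assert min(e.sires_liberal for e in estimates.values()) == 1

    def test_unknown_mother_masses_flagged(self, bundled_panel):
        estimates = {e.mass_id: e for e in pp.estimate_sires_for_panel(bundled_panel)}
        assert not estimates["23"].maternal_known
        assert not estimates["36"].maternal_known
        assert estimates["20"].maternal_known

    def test_all_no_data_mass_rejected(self):
        mass = pp.EggMassRecord(mass_id="X", maternal_id="NS", alleles={"L01": None})
        with pytest.raises(ValueError, match="uninformative"):
            pp.estimate_sires(mass, UNKNOWN)

    def test_floor_of_one_when_all_alleles_maternal(self):
        mother = pp.AdultGenotype(adult_id="MOM", calls={"L01": (1, 2)})
        mass = pp.EggMassRecord(
            mass_id="X", maternal_id="MOM", alleles={"L01": frozenset({1, 2})}
        )
        est = pp.estimate_sires(mass, mother)
        assert est.min_sires_conservative == 1 and est.sires_liberal == 1

    @given(
        st.lists(
            st.frozensets(st.integers(100, 130), min_size=1, max_size=8),
            min_size=1,
            max_size=4,
        ),
        st.tuples(st.integers(100, 130), st.integers(100, 130)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conservative_liberal_bounds(self, allele_sets, mother_pair):
        """1 <= conservative <= liberal <= 2*conservative for any brood."""
        mother = pp.AdultGenotype(
            adult_id="MOM", calls={f"L{i:02d}": mother_pair for i in range(len(allele_sets))}
        )
        mass = pp.EggMassRecord(
            mass_id="X",
            maternal_id="MOM",
            alleles={f"L{i:02d}": s for i, s in enumerate(allele_sets)},
        )
        est = pp.estimate_sires(mass, mother)
        assert 1 <= est.min_sires_conservative <= est.sires_liberal
        assert est.sires_liberal <= 2 * est.min_sires_conservative

    @given(
        st.frozensets(st.integers(100, 130), min_size=1, max_size=6),
        st.frozensets(st.integers(100, 130), min_size=1, max_size=4),
        st.tuples(st.integers(100, 130), st.integers(100, 130)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adding_alleles_never_decreases_estimates(self, base, extra, mother_pair):
        mother = pp.AdultGenotype(adult_id="MOM", calls={"L01": mother_pair})

        def est(alleles):
            mass = pp.EggMassRecord(
                mass_id="X", maternal_id="MOM", alleles={"L01": alleles}
            )
            return pp.estimate_sires(mass, mother)

        small, large = est(base), est(base | extra)
        assert large.min_sires_conservative >= small.min_sires_conservative
        assert large.sires_liberal >= small.sires_liberal


class TestMultiplePaternityCounts:
    def test_conservative_three_of_sixteen(self, bundled_panel):
        assert pp.count_multiple_paternity(bundled_panel, "conservative") == (3, 16, 0.1875)

    def test_liberal_eight_of_sixteen(self, bundled_panel):
        assert pp.count_multiple_paternity(bundled_panel, "liberal") == (8, 16, 0.5)

    def test_multiply_sired_masses_all_solitary(self, bundled_panel):
        estimates = pp.estimate_sires_for_panel(bundled_panel)
        by_id = {m.mass_id: m for m in bundled_panel.masses}
        multi = [e.mass_id for e in estimates if e.min_sires_conservative >= 2]
        assert multi and all(
            by_id[mid].maternal_status is pp.SocialStatus.SOLITARY for mid in multi
        )


class TestClassifyPair:
    def test_reproduces_published_calls(self, bundled_panel):
        calls = {c.mass_id: c.call.value for c in pp.classify_pairs_for_panel(bundled_panel)}
        assert calls == {"20": "EP", "27": "MO", "30": "EP", "33": "EP"}

    def test_mass_20_evidence_loci(self, bundled_panel):
        calls = {c.mass_id: c for c in pp.classify_pairs_for_panel(bundled_panel)}
        assert {"MS-31", "MS-34"} <= calls["20"].evidence_loci

    def test_undetermined_without_sire_genotype(self):
        mother = pp.AdultGenotype(adult_id="MOM", calls={"L01": (1, 2)})
        mass = pp.EggMassRecord(
            mass_id="X", maternal_id="MOM", putative_sire_id="GHOST",
            alleles={"L01": frozenset({1, 3})},
        )
        out = pp.classify_pair(mass, mother, None)
        assert out.call is PairCall.UNDETERMINED

    def test_subset_of_mother_and_sire_is_mo(self):
        mother = pp.AdultGenotype(adult_id="MOM", calls={"L01": (1, 2)})
        sire = pp.AdultGenotype(adult_id="DAD", calls={"L01": (3, 4)})
        mass = pp.EggMassRecord(
            mass_id="X", maternal_id="MOM", putative_sire_id="DAD",
            alleles={"L01": frozenset({1, 3, 4})},
        )
        assert pp.classify_pair(mass, mother, sire).call is PairCall.MO

    def test_sire_exclusion_reported(self):
        # non-maternal allele exists but the partner carries none of them
        mother = pp.AdultGenotype(adult_id="MOM", calls={"L01": (1, 2)})
        sire = pp.AdultGenotype(adult_id="DAD", calls={"L01": (3, 3)})
        mass = pp.EggMassRecord(
            mass_id="X", maternal_id="MOM", putative_sire_id="DAD",
            alleles={"L01": frozenset({1, 5})},
        )
        out = pp.classify_pair(mass, mother, sire)
        assert out.call is PairCall.EP
        assert out.sire_excluded_loci == frozenset({"L01"})

    def test_pair_summary(self, bundled_panel):
        assert pp.pair_summary(bundled_panel) == (3, 1, 0)

    def test_panel_without_putative_sires(self, bundled_panel):
        stripped = pp.Panel(
            loci=bundled_panel.loci,
            adults=bundled_panel.adults,
            masses=tuple(
                pp.EggMassRecord(
                    mass_id=m.mass_id, maternal_id=m.maternal_id,
                    maternal_status=m.maternal_status, putative_sire_id=None,
                    alleles=m.alleles,
                )
                for m in bundled_panel.masses
            ),
        )
        assert pp.pair_summary(stripped) == (0, 0, 0)
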