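"""Cohort ingestion, filtering, and recurrence-spectrum construction."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdnscan.cohort_io import (
    MutationRecord,
    PatientLoad,
    RecurrenceSpectrum,
    as_ratio,
    build_spectrum,
    filter_cohort,
    load_zscores,
    read_mutations,
    scale_panel_load,
)
from cdnscan.opportunity import SiteOpportunity


def rec(patient, pos, ref="G", alt="A", csq="missense", chrom="chr1", freq=None):
    return MutationRecord(patient_id=patient, chrom=chrom, pos=pos, ref=ref,
                          alt=alt, consequence=csq, pop_freq=freq)


def flat_opportunity(L_S=100.0, L_A=200.0):
    return SiteOpportunity.from_totals(L_S=L_S, L_A=L_A)


class TestReader:
    def test_toy_file_counts_and_skips(self, cohort_writer):
        path = cohort_writer([
            ("P1", "chr1", 100, "G", "A", "TP53", "Missense_Mutation"),
            ("P2", "chr1", 100, "G", "A", "TP53", "Missense_Mutation"),
            ("P3", "chr2", 7, "C", "T", "KRAS", "Missense_Mutation"),
            ("P1", "chr2", 9, "A", "G", "KRAS", "Silent"),
            ("P2", "chr3", 5, "T", "C", "EGFR", "Intron"),
        ])
        records = read_mutations(path)
        assert len(records) == 4
        assert sum(r.consequence == "missense" for r in records) == 3
        assert sum(r.consequence == "synonymous" for r in records) == 1
        assert records[0].pos == 100  # 1-based, preserved

    def test_empty_file_with_header(self, cohort_writer):
        path = cohort_writer([])
        assert read_mutations(path) == []

    def test_permuted_columns_with_dialect(self, cohort_writer):
        canonical = cohort_writer([
            ("P1", "chr1", 100, "G", "A", "TP53", "Missense_Mutation"),
        ])
        permuted = cohort_writer(
            [("chr1", "P1", "Missense_Mutation", 100, "A", "G", "TP53")],
            name="permuted.tsv",
            header=["c", "sample", "cls", "position", "altb", "refb", "sym"],
        )
        dialect = {"patient": "sample", "chrom": "c", "pos": "position",
                   "ref": "refb", "alt": "altb", "gene": "sym", "consequence": "cls"}
        assert read_mutations(permuted, dialect=dialect) == read_mutations(canonical)

    def test_missing_column_names_the_column(self, cohort_writer):
        path = cohort_writer([("P1", "chr1", 100, "G", "A")],
                             header=["Tumor_Sample_Barcode", "Chromosome",
                                     "Start_Position", "Reference_Allele",
                                     "Tumor_Seq_Allele2"])
        with pytest.raises(ValueError, match="Variant_Classification"):
            read_mutations(path)

    def test_non_acgt_allele_collected_into_rejects(self, cohort_writer):
        path = cohort_writer([
            ("P1", "chr1", 100, "G", "A", "TP53", "Missense_Mutation"),
            ("P2", "chr1", 101, "GG", "A", "TP53", "Missense_Mutation"),
        ])
        rejects = []
        records = read_mutations(path, rejects=rejects)
        assert len(records) == 1 and len(rejects) == 1
        assert "reason" in rejects[0]

    def test_max_over_subpopulation_frequencies(self, cohort_writer):
        path = cohort_writer(
            [("P1", "chr1", 100, "G", "A", "TP53", "Missense_Mutation", 0.0001, 0.002)],
            header=["Tumor_Sample_Barcode", "Chromosome", "Start_Position",
                    "Reference_Allele", "Tumor_Seq_Allele2", "Hugo_Symbol",
                    "Variant_Classification", "freq_afr", "freq_eur"])
        records = read_mutations(path, dialect={"pop_freq": ["freq_afr", "freq_eur"]})
        assert records[0].pop_freq == 0.002


class TestFilterCohort:
    def test_hypermutator_excluded_entirely(self):
        records = [rec("P1", pos) for pos in range(1, 3002)]
        kept, loads, excluded = filter_cohort(records)
        assert excluded == ["P1"]
        assert kept == [] and loads == []

    def test_zero_frequencies_pass_germline_filter(self):
        records = [rec("P1", p, freq=0.0) for p in (1, 2, 3)]
        kept, loads, _ = filter_cohort(records)
        assert len(kept) == 3 and loads[0].load == 3

    def test_one_of_two_patients_excluded(self):
        records = [rec("P1", p) for p in range(1, 11)]
        records += [rec("P2", p) for p in range(1, 4001)]
        kept, loads, excluded = filter_cohort(records)
        assert excluded == ["P2"]
        assert len(kept) == 10
        assert [pl.load for pl in loads] == [10]

    def test_germline_filter_applied_before_load(self):
        # 3001 records, one of them germline: after germline removal the load is 3000
        records = [rec("P1", p) for p in range(1, 3001)] + [rec("P1", 9999, freq=0.5)]
        kept, _, excluded = filter_cohort(records)
        assert excluded == [] and len(kept) == 3000


class TestScalePanelLoad:
    @pytest.mark.parametrize("n_l,l,L,expected", [
        (100, 5.0, 5.0, 100.0),
        (100, 3.0, 30.0, 1000.0),
        (31, 1.2e6, 3.0e7, 775.0),
    ])
    def test_linear_scaling(self, n_l, l, L, expected):
        assert scale_panel_load(n_l, l, L) == pytest.approx(expected)

    def test_zero_covered_length_rejected(self):
        with pytest.raises(ValueError):
            scale_panel_load(10, 0.0, 100.0)


class TestBuildSpectrum:
    def test_three_patients_same_change_is_one_triple_hit(self):
        records = [rec(p, 100) for p in ("P1", "P2", "P3")]
        sp = build_spectrum(records, flat_opportunity())
        assert sp.a == {3: 1} and sp.s == {}

    def test_different_alts_are_different_sites(self):
        records = [rec("P1", 100, alt="A"), rec("P2", 100, alt="A"),
                   rec("P3", 100, alt="T")]
        sp = build_spectrum(records, flat_opportunity())
        assert sp.a == {1: 1, 2: 1}

    def test_duplicate_call_in_one_patient_counts_once(self):
        records = [rec("P1", 100), rec("P1", 100), rec("P2", 200)]
        sp = build_spectrum(records, flat_opportunity())
        assert sp.a == {1: 2}

    def test_nonsense_kept_out_of_a_by_default_but_mergeable(self):
        records = [rec("P1", 100, csq="nonsense"), rec("P2", 100, csq="nonsense"),
                   rec("P1", 200, csq="missense")]
        sp = build_spectrum(records, flat_opportunity())
        assert sp.a == {1: 1} and sp.nonsense == {2: 1}
        merged = build_spectrum(records, flat_opportunity(), merge_nonsense=True)
        assert merged.a == {1: 1, 2: 1}

    def test_closure_against_opportunity(self):
        records = [rec("P1", 100), rec("P2", 100), rec("P1", 5, csq="synonymous")]
        sp = build_spectrum(records, flat_opportunity(L_S=50, L_A=80))
        assert sp.a0 == 80 - 1 and sp.s0 == 50 - 1

    def test_opportunity_too_small_is_an_inconsistency(self):
        records = [rec("P1", p) for p in range(1, 10)]
        with pytest.raises(ValueError, match="opportunity"):
            build_spectrum(records, flat_opportunity(L_S=1, L_A=3))

    def test_cpg_strata_partition_all_sites(self):
        cpg = np.array([True, False, True, False, False])
        opp = SiteOpportunity(
            L=5, L_S=2, L_A=3, L_N=0,
            strata={"all": {"L": 5, "L_S": 2, "L_A": 3, "L_N": 0},
                    "cpg_only": {"L": 2, "L_S": 1, "L_A": 1, "L_N": 0},
                    "cpg_removed": {"L": 3, "L_S": 1, "L_A": 2, "L_N": 0}},
            cpg_mask={"chr1": cpg})
        records = [rec("P1", 1), rec("P2", 1), rec("P1", 2), rec("P2", 4, csq="synonymous")]
        full = build_spectrum(records, opp, stratum="all")
        only = build_spectrum(records, opp, stratum="cpg_only")
        removed = build_spectrum(records, opp, stratum="cpg_removed")
        for i in range(1, 3):
            assert full.a.get(i, 0) == only.a.get(i, 0) + removed.a.get(i, 0)
            assert full.s.get(i, 0) == only.s.get(i, 0) + removed.s.get(i, 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(1, 8)),
                    min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_and_duplication_invariance(self, raw, rnd):
        """Shuffling record order or duplicating every record leaves the spectrum unchanged."""
        records = [rec(f"P{p}", pos,
                       csq="synonymous" if pos % 2 else "missense")
                   for p, pos in raw]
        base = build_spectrum(records, flat_opportunity())
        shuffled = list(records)
        rnd.shuffle(shuffled)
        assert build_spectrum(shuffled, flat_opportunity()).a == base.a
        doubled = build_spectrum(records + records, flat_opportunity())
        assert (doubled.a, doubled.s) == (base.a, base.s)

    def test_recurrence_cannot_exceed_cohort_size(self):
        with pytest.raises(ValueError, match="exceeds cohort size"):
            RecurrenceSpectrum(n=2, a={3: 1}, s={}, a0=10, s0=10)


class TestAsRatio:
    def test_single_bin_ratio(self):
        sp = RecurrenceSpectrum.from_counts(n=10, a={3: 99}, s={3: 21},
                                            L_A=1e6, L_S=1e6)
        out = as_ratio(sp, [(3, 3)])
        assert out[(3, 3)].ratio == pytest.approx(99 / 21)

    def test_open_bin_aggregates_the_tail(self):
        sp = RecurrenceSpectrum.from_counts(
            n=30, a={3: 99, 4: 23, 5: 16, 9: 40}, s={3: 21, 4: 1}, L_A=1e6, L_S=1e6)
        out = as_ratio(sp, [(3, None)])
        assert out[(3, None)].A == 178 and out[(3, None)].S == 22

    def test_zero_denominator_flagged_not_divided(self):
        sp = RecurrenceSpectrum.from_counts(n=10, a={5: 16}, s={}, L_A=1e6, L_S=1e6)
        result = as_ratio(sp, [(5, 5)])[(5, 5)]
        assert result.undefined and result.A == 16 and result.ratio is None

    def test_overlapping_bins_rejected(self):
        sp = RecurrenceSpectrum.from_counts(n=10, a={1: 1}, s={1: 1}, L_A=10, L_S=10)
        with pytest.raises(ValueError, match="disjoint"):
            as_ratio(sp, [(1, 3), (2, None)])


class TestLoadZscores:
    def test_symmetric_loads_give_unit_zscores(self):
        loads = [PatientLoad("a", 10), PatientLoad("b", 20), PatientLoad("c", 30)]
        load_zscores(loads)
        assert [pl.zscore for pl in loads] == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_sd_group_gets_zeros(self):
        loads = [PatientLoad("a", 5), PatientLoad("b", 5), PatientLoad("c", 5)]
        load_zscores(loads)
        assert all(pl.zscore == 0.0 for pl in loads)

    def test_groups_standardized_independently(self):
        loads = [PatientLoad(p, v) for p, v in
                 [("a", 10), ("b", 30), ("c", 1000), ("d", 3000)]]
        grouping = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        load_zscores(loads, grouping)
        z = np.array([pl.zscore for pl in loads])
        assert z[:2].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[2:].mean() == pytest.approx(0.0, abs=1e-12)
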