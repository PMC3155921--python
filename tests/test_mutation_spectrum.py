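from itertools import product

import numpy as np
import pytest

from cenpop.alignment_io import reduce_to_haplotypes
from cenpop.mutation_spectrum import (
    COLLAPSED_CLASSES,
    SpectrumCounts,
    SpectrumRow,
    classify_indels,
    collapsed_class,
    polarize_unique_changes,
    pool_rows,
    pooled_counts,
    published_spectra,
    relative_rates_with_ci,
    source_pair,
    spectrum_counts,
)
from cenpop.popgen_stats import polymorphism_summary

from conftest import make_alignment


class TestPolarizeUniqueChanges:
    def test_unique_allele_is_derived(self):
        a = make_alignment(["A", "A", "A", "G"])
        (ch,) = polarize_unique_changes(a)
        assert (ch.from_base, ch.to_base) == ("A", "G")
        assert ch.kind == "transition"
        assert ch.carrier_haplotype == "s4"

    @pytest.mark.parametrize(
        "column",
        [
            ["A", "A", "G", "G"],  # two-way tie
            ["A", "A", "C", "G"],  # two unique alleles
            ["A", "G", "N", "N"],  # <3 valid haplotypes
            ["A", "A", "A", "A"],  # monomorphic
        ],
    )
    def test_unpolarizable_columns_skipped(self, column):
        a = make_alignment(column)
        assert polarize_unique_changes(a) == []

    def test_exhaustive_column_patterns_match_rule(self):
        """Brute-force re-statement of the rule over all 4-haplotype columns
        on {A,C,G,N}: polarized iff exactly two alleles, one carried once."""
        for col in product("ACGN", repeat=4):
            a = make_alignment(list(col))
            got = polarize_unique_changes(a)
            valid = [b for b in col if b != "N"]
            alleles = {b: valid.count(b) for b in set(valid)}
            expect = (
                len(valid) >= 3
                and len(alleles) == 2
                and sorted(alleles.values())[0] == 1
                and sorted(alleles.values())[1] >= 2
            )
            assert bool(got) == expect, col

    def test_changes_bounded_by_segregating_sites(self):
        rng = np.random.default_rng(5)
        seqs = [
            "".join(rng.choice(list("AACGT"), size=40)) for _ in range(6)
        ]
        a = make_alignment(seqs)
        assert len(polarize_unique_changes(a)) <= polymorphism_summary(a).S


class TestSpectrumCounts:
    def test_counts_and_alpha(self):
        a = make_alignment(["AAGA", "AAGA", "AGGA"])
        changes = polarize_unique_changes(a)
        sc = spectrum_counts(a, changes)
        assert sc.n[("A", "G")] == 1
        assert sc.total == 1
        assert sc.alpha == {"A": 8, "C": 0, "G": 4, "T": 0}

    def test_zero_changes_alpha_still_populated(self):
        a = make_alignment(["ACGT", "ACGT"])
        sc = spectrum_counts(a, [])
        assert sc.total == 0
        assert sum(sc.alpha.values()) == 8

    def test_locus_mismatch_rejected(self):
        a = make_alignment(["AAA", "AAG", "AAA"], locus_id="x")
        b = make_alignment(["AAA", "AAG", "AAA"], locus_id="y")
        with pytest.raises(ValueError):
            spectrum_counts(a, polarize_unique_changes(b))

    def test_composition_fractions(self):
        a = make_alignment(["AATT", "AATT"])
        sc = spectrum_counts(a, [])
        assert sc.p["A:T"] == pytest.approx(1.0)
        assert sc.p["C:G"] == pytest.approx(0.0)

    def test_ts_tv_partition_of_directed_types(self):
        # 4 of the 12 directed types are transitions
        sc = SpectrumCounts()
        for t in sc.n:
            sc.n[t] = 1
        ts, tv = sc.ts_tv()
        assert (ts, tv) == (4, 8)


class TestRelativeRates:
    def _counts(self, class_counts, alpha):
        sc = SpectrumCounts()
        for cls, k in class_counts.items():
            for (i, j), c in sc.n.items():
                if collapsed_class(i, j) == cls:
                    sc.n[(i, j)] += k / 2  # split evenly between the 2 types
        sc.n = {t: int(v) for t, v in sc.n.items()}
        sc.alpha = alpha
        return sc

    def test_single_class_gets_rate_one(self):
        sc = self._counts(
            {"C:G>T:A": 4}, {"A": 40, "T": 40, "C": 10, "G": 10}
        )
        rr = relative_rates_with_ci([sc], n_reps=10, seed=0)
        assert rr.r["C:G>T:A"] == pytest.approx(1.0)
        assert all(v == 0 for c, v in rr.r.items() if c != "C:G>T:A")

    def test_equal_counts_equal_composition_symmetric(self):
        sc = self._counts(
            {"A:T>G:C": 4, "C:G>A:T": 4}, {"A": 25, "T": 25, "C": 25, "G": 25}
        )
        rr = relative_rates_with_ci([sc], n_reps=10, seed=0)
        assert rr.r["A:T>G:C"] == pytest.approx(0.5)
        assert rr.r["C:G>A:T"] == pytest.approx(0.5)

    def test_formula_matches_stepwise_recomputation(self):
        """Point rates equal an independent divide/normalize/rescale pass."""
        rng = np.random.default_rng(2)
        per_locus = []
        for _ in range(5):
            sc = SpectrumCounts()
            for t in sc.n:
                sc.n[t] = int(rng.integers(0, 5))
            sc.alpha = {b: int(rng.integers(10, 60)) for b in "ACGT"}
            per_locus.append(sc)
        rr = relative_rates_with_ci(per_locus, n_reps=10, seed=0)
        pool = pooled_counts(per_locus)
        coll, p = pool.collapsed(), pool.p
        total = sum(coll.values())
        raw = {
            c: (coll[c] / total) / p[source_pair(c)] for c in COLLAPSED_CLASSES
        }
        z = sum(raw.values())
        for c in COLLAPSED_CLASSES:
            assert rr.r[c] == pytest.approx(raw[c] / z)

    def test_rates_sum_to_one_including_replicates(self):
        rng = np.random.default_rng(4)
        per_locus = []
        for _ in range(8):
            sc = SpectrumCounts()
            for t in sc.n:
                sc.n[t] = int(rng.integers(0, 4))
            sc.alpha = {b: int(rng.integers(5, 50)) for b in "ACGT"}
            per_locus.append(sc)
        rr = relative_rates_with_ci(per_locus, n_reps=200, seed=1)
        assert sum(rr.r.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_counts_rejected(self):
        sc = SpectrumCounts()
        sc.alpha = {"A": 10, "C": 10, "G": 10, "T": 10}
        with pytest.raises(ValueError):
            relative_rates_with_ci([sc], n_reps=10, seed=0)


class TestClassifyIndels:
    def test_one_bp_deletion_outside_run(self):
        a = make_alignment(["ACGTACGT", "ACGTACGT", "ACG-ACGT"])
        s = classify_indels(a)
        assert (s.one_bp_deletions, s.one_bp_insertions, s.other) == (1, 0, 0)
        assert s.events[0].kind == "deletion"

    def test_deletion_inside_homopolymer_run_is_other(self):
        a = make_alignment(["CAAAAAC", "CAAAAAC", "CAA-AAC"])
        s = classify_indels(a)
        assert (s.one_bp_deletions, s.other, s.in_run) == (0, 1, 1)

    def test_multi_base_deletion_is_other(self):
        a = make_alignment(["ACGTCGTG", "ACGTCGTG", "AC---GTG"])
        s = classify_indels(a)
        assert (s.one_bp_deletions, s.other, s.multi_bp) == (0, 1, 1)

    def test_one_bp_insertion(self):
        a = make_alignment(["ACG-TC", "ACG-TC", "ACGCTC"])
        s = classify_indels(a)
        assert (s.one_bp_insertions, s.one_bp_deletions) == (1, 0)

    def test_shared_indel_not_unique(self):
        a = make_alignment(["ACG-ACGT", "ACG-ACGT", "ACGTACGT"])
        # the gap is carried by two haplotypes: not unique, not counted
        # (and the T in s3 is itself unique -> insertion is counted instead)
        s = classify_indels(a)
        assert s.one_bp_deletions == 0

    def test_every_event_in_exactly_one_bucket(self):
        a = make_alignment(
            ["ACGTACGTAAAAAG", "ACGTACGTAAAAAG", "AC-TACGTAA-AAG"]
        )
        s = classify_indels(a)
        assert s.total == len(s.events)


class TestPublishedSpectraArithmetic:
    def test_ts_tv_frequency_reproduction(self):
        rows = {r.study: r for r in published_spectra()}
        assert rows["CDEII"].ts_tv_freq == pytest.approx(0.68, abs=0.005)
        assert rows["Genome-wide (WT)"].ts_tv_freq == pytest.approx(0.63, abs=0.005)
        assert rows["URA3 Hicks (GC)"].ts_tv_freq == pytest.approx(1.33, abs=0.005)

    def test_total_polarized_and_pooled_wt(self):
        rows = published_spectra()
        cdeii = next(r for r in rows if r.study == "CDEII")
        assert cdeii.total_bps == 114
        wt = pool_rows(r for r in rows if r.group == "wild-type")
        assert (wt.transitions, wt.transversions) == (142, 252)

    def test_end_to_end_ts_tv_from_summary_counts(self):
        # Ts/Tv from a SpectrumCounts equals the ratio of its Ts and Tv tallies
        sc = SpectrumCounts()
        sc.n[("C", "T")] = 3
        sc.n[("A", "C")] = 2
        ts, tv = sc.ts_tv()
        row = SpectrumRow("synthetic", ts, tv, 0, 0, 0)
        assert row.ts_tv_freq == pytest.approx(3 / 2)
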