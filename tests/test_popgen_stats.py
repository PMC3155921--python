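import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenpop.popgen_stats import (
    DegenerateInputError,
    binomial_exact_test,
    bootstrap_ci,
    homopolymer_runs,
    pairwise_divergence_dxy,
    polymorphism_summary,
)
from cenpop.alignment_io import PopulationMap

from conftest import brute_force_pi, make_alignment, random_alignment


class TestPolymorphismSummary:
    def test_monomorphic(self):
        s = polymorphism_summary(make_alignment(["ACGTACGTAC"] * 4))
        assert (s.S, s.pi, s.theta_w, s.n_sites_analysed) == (0, 0.0, 0.0, 10)

    def test_two_sequences_one_difference(self):
        s = polymorphism_summary(make_alignment(["AAAAAAAAAA", "AAAAAAAAAT"]))
        assert s.S == 1
        assert s.pi == pytest.approx(0.1)
        assert s.theta_w == pytest.approx(0.1)  # a(2) = 1 so pi == theta_w

    def test_four_sequences_intermediate_frequency(self):
        # alleles (A,A,C,C) at one site of 10: per-site h = (4/3)(1-0.5) = 2/3
        seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "CAAAAAAAAA", "CAAAAAAAAA"]
        s = polymorphism_summary(make_alignment(seqs))
        assert s.pi == pytest.approx((2 / 3) / 10)
        assert s.pi == pytest.approx(brute_force_pi(make_alignment(seqs)))

    def test_sites_with_fewer_than_two_valid_bases_skipped(self):
        base = make_alignment(["ACGT", "AGGT", "ACGT"])
        padded = make_alignment(["ACGTNN", "AGGTN-", "ACGTNA"])
        a, b = polymorphism_summary(base), polymorphism_summary(padded)
        assert (a.S, a.pi, a.theta_w) == (b.S, b.pi, b.theta_w)
        assert b.n_sites_analysed == 4

    def test_region_slice(self):
        a = make_alignment(["AAAA", "AAAT"])
        assert polymorphism_summary(a, (0, 3)).S == 0
        assert polymorphism_summary(a, (3, 4)).S == 1

    def test_local_sample_size_watterson(self):
        # site 0: n=4 segregating; site 1: n=2 (two N) segregating
        a = make_alignment(["AC", "AG", "TN", "TN"])
        s = polymorphism_summary(a)
        expected = (1 / (1 + 1 / 2 + 1 / 3) + 1 / 1) / 2
        assert s.theta_w == pytest.approx(expected)

    def test_invariant_to_strain_and_column_order(self):
        rng = np.random.default_rng(0)
        a = random_alignment(rng, 6, 20)
        perm_rows = make_alignment([seq for _, seq in reversed(a.records)])
        cols = rng.permutation(a.length)
        perm_cols = make_alignment(
            ["".join(seq[c] for c in cols) for _, seq in a.records]
        )
        s0, s1, s2 = map(polymorphism_summary, (a, perm_rows, perm_cols))
        for s in (s1, s2):
            assert s.pi == pytest.approx(s0.pi)
            assert s.theta_w == pytest.approx(s0.theta_w)
            assert s.S == s0.S

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_pi_matches_brute_force_pairwise(self, seed):
        """The per-site allele-count formula equals brute-force mean pairwise
        difference over valid pairs on random alignments with N and gaps."""
        rng = np.random.default_rng(seed)
        a = random_alignment(rng, int(rng.integers(2, 9)), int(rng.integers(1, 51)))
        s = polymorphism_summary(a)
        assert s.pi == pytest.approx(brute_force_pi(a), abs=1e-12)


class TestDxy:
    def _pm(self, n_a, n_b):
        d = {f"s{i+1}": "A" for i in range(n_a)}
        d.update({f"s{n_a+i+1}": "B" for i in range(n_b)})
        return PopulationMap(d)

    def test_identical_populations(self):
        a = make_alignment(["ACGT", "ACGT"])
        assert pairwise_divergence_dxy(a, self._pm(1, 1), "A", "B").dxy == 0.0

    def test_single_pair_quarter(self):
        a = make_alignment(["AAAA", "AAAT"])
        assert pairwise_divergence_dxy(a, self._pm(1, 1), "A", "B").dxy == 0.25

    def test_matches_pair_enumeration(self):
        # 2 vs 2, hand enumeration over the 4 cross pairs per site
        a = make_alignment(["AAAA", "AATA", "AAAT", "TAAA"])
        pm = self._pm(2, 2)
        got = pairwise_divergence_dxy(a, pm, "A", "B").dxy
        seqs = {sid: s for sid, s in a.records}
        pairs = [("s1", "s3"), ("s1", "s4"), ("s2", "s3"), ("s2", "s4")]
        per_site = []
        for c in range(4):
            diffs = [seqs[x][c] != seqs[y][c] for x, y in pairs]
            per_site.append(sum(diffs) / len(diffs))
        assert got == pytest.approx(sum(per_site) / 4)

    def test_missing_population_raises(self):
        a = make_alignment(["ACGT", "ACGT"])
        pm = PopulationMap({"s1": "A", "s2": "A"})
        with pytest.raises(DegenerateInputError):
            pairwise_divergence_dxy(a, pm, "A", "B")


class TestBootstrapCI:
    def test_constant_values(self):
        est = bootstrap_ci([3.0, 3.0, 3.0], "mean", n_reps=100, seed=0)
        assert est.point == est.ci_low == est.ci_high == 3.0

    def test_deterministic_under_seed(self):
        a = bootstrap_ci([0.0, 1.0, 0.5], "median", n_reps=10, seed=42)
        b = bootstrap_ci([0.0, 1.0, 0.5], "median", n_reps=10, seed=42)
        assert a == b

    def test_matches_independent_resampler(self):
        """Percentile endpoints agree with a second, loop-based resampler
        using the same generator protocol."""
        rng = np.random.default_rng(7)
        values = rng.uniform(0.0, 0.1, size=16)
        est = bootstrap_ci(values, "mean", n_reps=10_000, seed=123)
        rng2 = np.random.default_rng(123)
        reps = []
        for _ in range(10_000):
            idx = rng2.integers(0, 16, size=16)
            reps.append(float(np.mean([values[i] for i in idx])))
        lo, hi = np.percentile(reps, [2.5, 97.5])
        assert est.ci_low == pytest.approx(lo)
        assert est.ci_high == pytest.approx(hi)

    def test_too_few_loci(self):
        with pytest.raises(DegenerateInputError):
            bootstrap_ci([1.0], "mean", n_reps=10, seed=0)


class TestHomopolymerRuns:
    @pytest.mark.parametrize(
        "seq,min_len,expected",
        [
            ("AAAAA", 5, [("A", 0, 5)]),
            ("AAAANAAAA", 5, []),  # N breaks a run
            ("TTTTCCCCCAA", 4, [("T", 0, 4), ("C", 4, 9)]),
            ("AAAA-AAAA", 5, []),  # gap breaks a run
            ("", 5, []),
        ],
    )
    def test_maximal_runs(self, seq, min_len, expected):
        prof = homopolymer_runs(seq, min_len=min_len)
        assert list(prof.runs) == expected

    def test_exact_length_selection(self):
        prof = homopolymer_runs("AAAATTTTTGGGG", exact_len=4)
        assert [r[0] for r in prof.runs] == ["A", "G"]

    def test_runs_non_overlapping_and_maximal(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("AT"), size=200))
        prof = homopolymer_runs(seq, min_len=3)
        for base, s, e in prof.runs:
            assert set(seq[s:e]) == {base}
            assert s == 0 or seq[s - 1] != base
            assert e == len(seq) or seq[e] != base
        for (_, _, e1), (_, s2, _) in zip(prof.runs, prof.runs[1:]):
            assert e1 <= s2


class TestBinomialExactTest:
    def test_full_enumeration_oracle(self):
        # n=3, p0=0.5, x=3: only {0,3} have probability <= P(3); p = 2/8
        assert binomial_exact_test(3, 3, 0.5) == pytest.approx(0.25)

    def test_symmetric_midpoint_is_one(self):
        assert binomial_exact_test(2, 4, 0.5) == pytest.approx(
            sum(
                math.comb(4, k) / 16
                for k in range(5)
                if math.comb(4, k) / 16 <= math.comb(4, 2) / 16
            )
        )

    def test_matches_minlike_enumeration(self):
        # independent minimum-likelihood enumeration at small n
        from scipy.stats import binom

        x, n, p0 = 7, 20, 1 / 3
        pmf = binom.pmf(np.arange(n + 1), n, p0)
        expected = pmf[pmf <= pmf[x] * (1 + 1e-12)].sum()
        assert binomial_exact_test(x, n, p0) == pytest.approx(expected)

    @pytest.mark.parametrize("x,n,p0", [(-1, 5, 0.5), (6, 5, 0.5), (2, 5, 0.0)])
    def test_invalid_inputs(self, x, n, p0):
        with pytest.raises(ValueError):
            binomial_exact_test(x, n, p0)
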