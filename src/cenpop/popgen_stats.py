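"""Missing-data-aware polymorphism and divergence statistics.

Shotgun population data leave most alignment columns with only a handful of
called bases, so every estimator here works per site on the *local* sample of
valid bases (``A C G T``; ``N`` and gaps excluded), and a site enters the
analysis only if at least two valid bases are present:

* nucleotide diversity ``pi`` uses the unbiased per-site heterozygosity
  ``h = n/(n-1) * (1 - sum_b p_b^2)`` at local sample size ``n``, averaged
  over analysed sites;
* Watterson's ``theta_W`` scores each analysed site as segregating (0/1) and
  divides by the harmonic sum ``a(n) = sum_{k<n} 1/k`` at that site's local
  ``n``, again averaged over analysed sites;
* between-population divergence ``dxy`` averages the per-site difference
  proportion over valid between-population pairs.

Insertions/deletions are treated as missing data throughout, so estimates are
insensitive to gap placement inside the AT homopolymer runs that dominate
CDEII.  Also here: locus-set bootstrap confidence intervals, homopolymer-run
profiling, and the two-sided exact binomial test (minimum-likelihood
convention) used for transition:transversion comparisons against the 1/3 null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binomtest

from .alignment_io import Alignment

_BASES = "ACGT"


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class PolymorphismSummary:
    locus_id: str
    n_sites_analysed: int
    S: int
    pi: float
    theta_w: float


@dataclass(frozen=True)
class DivergenceSummary:
    locus_id: str
    pop_a: str
    pop_b: str
    dxy: float
    n_sites_analysed: int


@dataclass(frozen=True)
class LocusSetEstimate:
    statistic: str
    point: float
    ci_low: float
    ci_high: float
    n_loci: int
    n_reps: int
    seed: int


def _base_count_matrix(aln: Alignment) -> np.ndarray:
    """(4, L) matrix of per-column counts of A, C, G, T."""
    arr = np.frombuffer(
        "".join(seq for _, seq in aln.records).encode(), dtype="S1"
    ).reshape(aln.n_strains, aln.length)
    return np.stack([(arr == b.encode()).sum(axis=0) for b in _BASES])


def _harmonic(n: int) -> float:
    return sum(1.0 / k for k in range(1, n))


def polymorphism_summary(
    aln: Alignment, region: tuple[int, int] | None = None
) -> PolymorphismSummary:
    """Per-site ``S``, ``pi`` and ``theta_W`` over ``region`` (0-based
    half-open; whole alignment if omitted).

    Sites with fewer than two valid bases are skipped entirely; the per-site
    denominator is the number of analysed sites, not the alignment length.
    """
    sub = aln if region is None else aln.slice(*region)
    counts = _base_count_matrix(sub)  # (4, L)
    n = counts.sum(axis=0)  # valid sample size per site
    analysed = n >= 2
    n_sites = int(analysed.sum())
    if n_sites == 0:
        return PolymorphismSummary(aln.locus_id, 0, 0, 0.0, 0.0)

    c = counts[:, analysed].astype(float)
    nloc = n[analysed].astype(float)
    n_alleles = (c > 0).sum(axis=0)
    seg = n_alleles >= 2
    S = int(seg.sum())

    # unbiased heterozygosity at local sample size
    p2 = (c / nloc) ** 2
    h = nloc / (nloc - 1.0) * (1.0 - p2.sum(axis=0))
    pi = float(h.sum() / n_sites)

    max_n = int(nloc.max())
    a_table = np.zeros(max_n + 1)
    for k in range(2, max_n + 1):
        a_table[k] = a_table[k - 1] + 1.0 / (k - 1)
    theta_w = float((seg / a_table[nloc.astype(int)]).sum() / n_sites)

    return PolymorphismSummary(aln.locus_id, n_sites, S, pi, theta_w)


def pairwise_divergence_dxy(
    aln: Alignment,
    pops,
    pop_a: str,
    pop_b: str,
    region: tuple[int, int] | None = None,
) -> DivergenceSummary:
    """Mean per-site distance between all valid between-population pairs.

    A site is analysed if each population contributes at least one valid
    base there; within an analysed site the difference proportion is averaged
    over the valid cross pairs, then over analysed sites.
    """
    sub = aln if region is None else aln.slice(*region)
    ids = set(sub.strain_ids)
    strains_a = [s for s in pops.strains_in(pop_a) if s in ids]
    strains_b = [s for s in pops.strains_in(pop_b) if s in ids]
    if not strains_a or not strains_b:
        missing = pop_a if not strains_a else pop_b
        raise DegenerateInputError(
            f"{aln.locus_id}: population {missing!r} absent from alignment"
        )

    def mat(strains: list[str]) -> np.ndarray:
        return np.frombuffer(
            "".join(sub.sequence(s) for s in strains).encode(), dtype="S1"
        ).reshape(len(strains), sub.length)

    A, B = mat(strains_a), mat(strains_b)
    validA = np.isin(A, [b.encode() for b in _BASES])
    validB = np.isin(B, [b.encode() for b in _BASES])
    # per site: number of valid cross pairs and differing cross pairs
    pair_valid = validA[:, None, :] & validB[None, :, :]
    pair_diff = pair_valid & (A[:, None, :] != B[None, :, :])
    n_pairs = pair_valid.sum(axis=(0, 1))
    analysed = n_pairs > 0
    n_sites = int(analysed.sum())
    if n_sites == 0:
        return DivergenceSummary(aln.locus_id, pop_a, pop_b, 0.0, 0)
    per_site = pair_diff.sum(axis=(0, 1))[analysed] / n_pairs[analysed]
    return DivergenceSummary(
        aln.locus_id, pop_a, pop_b, float(per_site.mean()), n_sites
    )


def bootstrap_ci(
    values: Sequence[float],
    statistic: str = "mean",
    n_reps: int = 10_000,
    seed: int = 0,
) -> LocusSetEstimate:
    """Percentile bootstrap CI for the mean or median of per-locus statistics.

    Loci are resampled with replacement ``n_reps`` times; the interval is the
    2.5/97.5 percentile of the replicate statistics.  Deterministic under
    ``seed``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise DegenerateInputError("bootstrap needs at least 2 loci")
    if n_reps < 1:
        raise DegenerateInputError("n_reps must be >= 1")
    stat = {"mean": np.mean, "median": np.median}[statistic]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_reps, vals.size))
    reps = stat(vals[idx], axis=1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return LocusSetEstimate(
        statistic=statistic,
        point=float(stat(vals)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_loci=int(vals.size),
        n_reps=n_reps,
        seed=seed,
    )


@dataclass(frozen=True)
class HomopolymerProfile:
    """Maximal single-base runs in a sequence; ``N`` or a gap breaks a run."""

    runs: tuple[tuple[str, int, int], ...]  # (base, start, end) 0-based half-open
    min_len: int

    def count(self) -> int:
        return len(self.runs)

    def counts_by_length(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for _, s, e in self.runs:
            out[e - s] = out.get(e - s, 0) + 1
        return out

    def covers(self, pos: int) -> bool:
        return any(s <= pos < e for _, s, e in self.runs)


def homopolymer_runs(
    seq: str, min_len: int = 5, exact_len: int | None = None
) -> HomopolymerProfile:
    """Maximal runs of one repeated valid base with length >= ``min_len``.

    ``exact_len`` instead selects runs of exactly that length (used to count
    the 4-bp runs that remain once runs of 5+ are excluded).
    """
    seq = seq.upper()
    runs: list[tuple[str, int, int]] = []
    i, L = 0, len(seq)
    while i < L:
        ch = seq[i]
        if ch not in _BASES:
            i += 1
            continue
        j = i + 1
        while j < L and seq[j] == ch:
            j += 1
        length = j - i
        if (exact_len is None and length >= min_len) or (
            exact_len is not None and length == exact_len
        ):
            runs.append((ch, i, j))
        i = j
    return HomopolymerProfile(tuple(runs), min_len)


def binomial_exact_test(x: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood tail convention):
    the sum of probabilities of all outcomes no more likely than the one
    observed, under Binomial(n, p0)."""
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    if not 0 < p0 < 1:
        raise ValueError(f"p0={p0} outside (0, 1)")
    return float(binomtest(x, n, p0, alternative="two-sided").pvalue)
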