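"""Four-gamete recombination testing with a repeat-mutation (homoplasy) null.

Two biallelic sites at which all four allele combinations occur cannot be
explained by unique mutations on a single genealogy: either a crossover fell
between them or one of the sites mutated twice (homoplasy).  In a short,
hypermutable region like CDEII, homoplasy is expected, so an incompatibility
is not by itself evidence of recombination.  This module provides:

* ``incompatible_pairs`` — the four-gamete test over every pair of biallelic
  sites, with ``N``/gaps excluded per strain per site;
* ``hudson_kaplan_rmin`` — the interval-removal lower bound on the number of
  recombination events (R_min);
* ``min_homoplasy_set`` — the smallest set of sites whose removal explains
  all incompatibilities, i.e. an exact minimum vertex cover of the conflict
  graph (sites = vertices, incompatible pairs = edges);
* ``homoplasy_null_pvalue`` — an empirical p-value for the observed minimum
  homoplasy count under repeat mutation alone: mutations are placed uniformly
  at random among L sites until S distinct sites are hit, and sites hit twice
  or more are homoplasious (a same-total-mutations variant is available);
* ``retest_after_removal`` — masks the removed sites and re-runs the test,
  mirroring the remove-and-retest check on full (core + flank) loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import Alignment

_BASES = "ACGT"


class TractabilityError(RuntimeError):
    """Conflict graph too large for exact minimum-cover search."""


@dataclass(frozen=True)
class IncompatiblePair:
    site_a: int
    site_b: int
    #: two-site haplotype -> count among strains valid at both sites
    gametes_observed: tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class HomoplasyResult:
    locus_id: str
    incompatible_pairs: tuple[IncompatiblePair, ...]
    rmin: int
    min_homoplasy_set: tuple[int, ...]
    k_obs: int
    p_value: float
    n_reps: int
    seed: int


def _site_matrix(aln: Alignment) -> np.ndarray:
    return np.frombuffer(
        "".join(seq for _, seq in aln.records).encode(), dtype="S1"
    ).reshape(aln.n_strains, aln.length)


def biallelic_sites(
    aln: Alignment, region: tuple[int, int] | None = None
) -> tuple[list[int], list[int]]:
    """Columns with exactly 2 distinct valid bases, and (logged separately)
    columns with 3+ alleles — themselves direct evidence of repeat mutation."""
    start = 0 if region is None else region[0]
    sub = aln if region is None else aln.slice(*region)
    arr = _site_matrix(sub)
    biallelic, multiallelic = [], []
    for j in range(sub.length):
        col = arr[:, j]
        alleles = {b for b in col.tobytes().decode() if b in _BASES}
        if len(alleles) == 2:
            biallelic.append(start + j)
        elif len(alleles) > 2:
            multiallelic.append(start + j)
    return biallelic, multiallelic


def incompatible_pairs(
    aln: Alignment, region: tuple[int, int] | None = None
) -> list[IncompatiblePair]:
    """Four-gamete test over all pairs of biallelic sites in ``region``.

    A pair is incompatible iff, among strains carrying a valid base at both
    sites, all four two-site haplotypes occur.  With three or fewer such
    strains at most three gametes are observable, so small samples can never
    be incompatible.
    """
    sites, _ = biallelic_sites(aln, region)
    arr = _site_matrix(aln)
    valid = np.isin(arr, [b.encode() for b in _BASES])
    out: list[IncompatiblePair] = []
    for a, b in combinations(sites, 2):
        both = valid[:, a] & valid[:, b]
        if both.sum() < 4:
            continue
        ga = arr[both, a].tobytes().decode()
        gb = arr[both, b].tobytes().decode()
        gametes: dict[str, int] = {}
        for x, y in zip(ga, gb):
            gametes[x + y] = gametes.get(x + y, 0) + 1
        # restricted to the two alleles seen at each site among jointly valid
        if len({g[0] for g in gametes}) == 2 and len({g[1] for g in gametes}) == 2:
            if len(gametes) == 4:
                out.append(
                    IncompatiblePair(a, b, tuple(sorted(gametes.items())))
                )
    return out


def hudson_kaplan_rmin(pairs: Iterable[IncompatiblePair]) -> int:
    """Lower bound on recombination events: the maximum number of pairwise
    disjoint open intervals ``(site_a, site_b)`` among the incompatible
    pairs, found greedily by earliest right endpoint."""
    intervals = sorted((p.site_a, p.site_b) for p in pairs)
    intervals.sort(key=lambda iv: iv[1])
    count = 0
    last_end = -1
    for a, b in intervals:
        if a >= last_end:
            count += 1
            last_end = b
    return count


# ---------------------------------------------------------------------------
# Minimum homoplasy set = exact minimum vertex cover of the conflict graph
# ---------------------------------------------------------------------------

def _min_vertex_cover(
    vertices: Sequence[int], edges: Sequence[tuple[int, int]]
) -> tuple[int, ...]:
    """Exact minimum vertex cover, lexicographically smallest among minima.

    Branch and bound on the highest-degree endpoint of an uncovered edge;
    candidate covers are compared by (size, sorted vertex tuple) so the
    tie-break is deterministic.
    """
    verts = sorted(vertices)
    best: list[tuple[int, ...]] = [tuple(verts)]  # trivially a cover

    def recurse(chosen: frozenset[int], remaining: list[tuple[int, int]]) -> None:
        remaining = [e for e in remaining if e[0] not in chosen and e[1] not in chosen]
        cand = tuple(sorted(chosen))
        if not remaining:
            if (len(cand), cand) < (len(best[0]), best[0]):
                best[0] = cand
            return
        if len(chosen) + 1 > len(best[0]):
            return
        # lower bound: a greedy matching is vertex-disjoint, each edge needs a cover vertex
        matched: set[int] = set()
        lb = 0
        for u, v in remaining:
            if u not in matched and v not in matched:
                matched.update((u, v))
                lb += 1
        if len(chosen) + lb > len(best[0]):
            return
        u, v = remaining[0]
        for pick in sorted((u, v)):
            recurse(chosen | {pick}, remaining)

    recurse(frozenset(), list(edges))
    return best[0]


def min_homoplasy_set(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    max_vertices: int = 32,
) -> tuple[tuple[int, ...], int]:
    """Smallest set of sites whose removal leaves no incompatible pair.

    Returns the cover (column indices, lexicographically smallest among
    minimum covers) and its size ``k_obs``.  Raises ``TractabilityError``
    when the conflict graph has more than ``max_vertices`` vertices; split
    the region and analyse the parts in that case.
    """
    pairs = incompatible_pairs(aln, region)
    if not pairs:
        return (), 0
    edges = [(p.site_a, p.site_b) for p in pairs]
    vertices = sorted({v for e in edges for v in e})
    if len(vertices) > max_vertices:
        raise TractabilityError(
            f"{aln.locus_id}: conflict graph has {len(vertices)} vertices "
            f"(cap {max_vertices}); split the region"
        )
    cover = _min_vertex_cover(vertices, edges)
    return cover, len(cover)


def homoplasy_null_pvalue(
    L: int,
    S: int,
    k_obs: int,
    n_reps: int = 1000,
    seed: int = 0,
    condition: str = "distinct",
) -> float:
    """Empirical p-value for ``k_obs`` homoplasious sites under repeat
    mutation alone.

    Each replicate drops mutations uniformly at random on ``L`` sites; under
    ``condition='distinct'`` (default) mutations accumulate until ``S``
    distinct sites have been hit, under ``condition='total'`` exactly ``S``
    mutations are placed.  A replicate's homoplasy count is the number of
    sites hit at least twice.  The p-value uses add-one smoothing:
    ``(1 + #{count >= k_obs}) / (n_reps + 1)``.
    """
    if S > L:
        raise ValueError(f"S={S} exceeds L={L}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if S < 0 or L < 1:
        raise ValueError("need L >= 1 and S >= 0")
    if condition not in ("total", "distinct"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    chunk = max(2 * S, 16)
    exceed = 0
    for _ in range(n_reps):
        if condition == "total" or S == 0:
            draws = rng.integers(0, L, size=S)
        else:
            draws = rng.integers(0, L, size=chunk)
            while True:
                uniq, first = np.unique(draws, return_index=True)
                if uniq.size >= S:
                    # truncate at the draw that hit the S-th distinct site
                    cutoff = int(np.sort(first)[S - 1])
                    draws = draws[: cutoff + 1]
                    break
                draws = np.concatenate([draws, rng.integers(0, L, size=chunk)])
        _, counts = np.unique(draws, return_counts=True)
        if int((counts >= 2).sum()) >= k_obs:
            exceed += 1
    return (1 + exceed) / (n_reps + 1)


def retest_after_removal(
    aln: Alignment,
    removed: Iterable[int],
    region: tuple[int, int] | None = None,
) -> list[IncompatiblePair]:
    """Four-gamete test with ``removed`` columns masked to ``N``.

    Used on the full locus (core plus flanks) after removing the per-region
    minimum homoplasy sets, to check whether any recombination signal
    survives."""
    return incompatible_pairs(aln.mask_columns(removed), region)


def analyse_region(
    aln: Alignment,
    region: tuple[int, int] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    max_vertices: int = 32,
    condition: str = "distinct",
) -> HomoplasyResult:
    """Full four-gamete analysis of one region: incompatibilities, R_min,
    minimum homoplasy set, and the randomization-null p-value."""
    from .popgen_stats import polymorphism_summary

    pairs = incompatible_pairs(aln, region)
    rmin = hudson_kaplan_rmin(pairs)
    cover, k_obs = min_homoplasy_set(aln, region, max_vertices=max_vertices)
    summ = polymorphism_summary(aln, region)
    p = homoplasy_null_pvalue(
        L=max(summ.n_sites_analysed, 1),
        S=min(summ.S, max(summ.n_sites_analysed, 1)),
        k_obs=k_obs,
        n_reps=n_reps,
        seed=seed,
        condition=condition,
    )
    return HomoplasyResult(
        locus_id=aln.locus_id,
        incompatible_pairs=tuple(pairs),
        rmin=rmin,
        min_homoplasy_set=cover,
        k_obs=k_obs,
        p_value=p,
        n_reps=n_reps,
        seed=seed,
    )
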