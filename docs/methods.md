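# Methods

## Data model

Every analysis operates on per-locus multiple alignments over
`{A, C, G, T, N, -}`.  `N` is a missing or sub-quality call; `-` is an
alignment gap.  Indels are treated as missing data by all site statistics,
so estimates do not depend on gap placement inside homopolymer runs.
Internally all coordinates are 0-based half-open; every report and config
surface is 1-based inclusive.

## Polymorphism estimators under missing data

With shotgun-derived population data most columns carry only a few valid
bases, so all estimators are computed per site on the local valid sample and
a column enters the analysis only when it has ≥2 valid bases (`N` and gaps
excluded per strain per site):

* π: per-site unbiased heterozygosity `h = n/(n−1) · (1 − Σ_b p_b²)` at
  local sample size `n`, summed over analysed sites and divided by the
  number of analysed sites.  This identity equals the mean pairwise
  difference over valid pairs, which the test suite verifies by brute force
  on random alignments.
* θ_W: each analysed site contributes `s/a(n)` with `s ∈ {0,1}` marking
  segregation and `a(n) = Σ_{k=1}^{n−1} 1/k` at that site's local `n`.
* D_xy: per-site mean difference proportion over valid between-population
  pairs, averaged over sites where each population has ≥1 valid base.

Denominators use analysed sites, not alignment length: appending all-`N`
columns changes nothing.  Locus-set uncertainty is a percentile bootstrap
(resample loci with replacement; 2.5/97.5 percentiles; 10,000 replicates by
default; deterministic under a seed).

The exact binomial test is two-sided by the minimum-likelihood convention
(sum of all outcome probabilities ≤ that of the observed outcome), the
convention under which the transition-count checks in the test suite are
meaningful.  It delegates to `scipy.stats.binomtest` and is verified against
full enumeration at small n.

## Haplotype reduction and polarization

No outgroup aligns to CDEII, so polarity is inferred from haplotype
structure.  First the alignment is collapsed so each haplotype appears once:

* Two sequences belong to one haplotype class iff they agree at every column
  where both carry a determinate state; `-` is a matchable fifth state (so
  indel haplotypes stay distinct) and `N` is a wildcard.  This wildcard
  relation is not transitive; classes are therefore formed greedily —
  sequences sorted by non-`N` count (descending, ties by strain id), each
  assigned to the first compatible existing representative — which is
  deterministic and makes "the longest unambiguous sequence represents the
  class" well defined.
* At each column of the reduced alignment, if exactly one haplotype carries
  base `j` and all other valid haplotypes carry one identical base `i`, the
  column yields a polarized change `i → j`.  Columns with <3 valid
  haplotypes are skipped because with two, both alleles are unique and
  polarity is undefined; columns with ≥3 alleles or two singletons are
  likewise unpolarizable.  This is conservative: genealogy-based polarization
  would recover more events.

Unique indels (maximal gap runs present in — or absent from — exactly one
haplotype) are classified by length and direction; an indel whose context in
a gap-free representative lies inside a homopolymer run of ≥5 bp goes to the
"other" bucket regardless of length, because slippage makes in-run indel
rates incomparable across sequence contexts.  Multi-base and in-run
sub-tallies are kept separately.  The 1 bp-deletions-per-substitution ratio
reported by the summary tables is defined as `one_bp_deletions/(Ts+Tv)`.

## Relative-rate spectrum

Directed counts `n[i→j]` and availabilities `α_i` (base content summed over
the reduced alignment's sequences; a switch allows using all strains) are
pooled over loci and collapsed to six complement classes (e.g. `C:G>T:A` =
C→T plus G→A).  Rates are

    r_c = ((n_c / Σn) / p_src(c)) / Σ_c' ((n_c' / Σn) / p_src(c'))

with `p_src` the composition fraction of the source pair (`p_AT` or
`p_CG`), so Σ r = 1 exactly, for the point estimate and for every bootstrap
replicate (loci resampled with replacement, re-pooled, re-normalized;
1000 replicates by default).

## Recombination versus repeat mutation

A four-gamete incompatibility between two biallelic sites means either a
crossover between them or a repeat mutation (homoplasy) at one of them.  In
a short hypermutable region homoplasy is expected, so the analysis
quantifies both readings:

* `hudson_kaplan_rmin`: the standard interval-removal lower bound on
  crossovers — the maximum number of pairwise-disjoint open intervals among
  incompatible pairs, found greedily by earliest right endpoint (verified
  against exhaustive subset search).
* `min_homoplasy_set`: the smallest site set explaining all
  incompatibilities = exact minimum vertex cover of the conflict graph,
  by branch and bound with a greedy-matching lower bound; ties broken to the
  lexicographically smallest cover.  Exact search is capped (default 32
  conflict vertices) with an explicit error advising region splitting.
* `homoplasy_null_pvalue`: mutations are placed uniformly at random on `L`
  analysed sites until `S` distinct sites are hit; a replicate's homoplasy
  count is the number of sites hit ≥2 times; `p = (1 + #{count ≥ k_obs}) /
  (n_reps + 1)` (add-one smoothing; 1000 replicates by default).  Whether
  the null should condition on `S` distinct sites or `S` total placements is
  genuinely open; `condition="total"` switches to the latter.  Because the
  simulated null counts *all* repeat-hit sites while `k_obs` counts only
  detectable ones, the test errs conservative.
* Cores and flanks are analysed separately (the null assumes a uniform
  mutation rate, which fails across the core/flank boundary); the minimum
  homoplasy sets are then removed and the full locus re-tested.  Sites with
  >2 valid bases are excluded from pair testing — they are themselves direct
  homoplasy evidence and are reported separately.

## Centromere annotation

CDEI and CDEIII are scanned as IUPAC-degenerate motifs on both strands
(`N` in the subject never matches); every same-strand pair whose gap length
falls in the configured CDEII range (default 75–100 bp, bracketing the
canonical ~87 bp) is reported, CDEII being the gap.  The consensus strings
are configuration with shipped defaults (CDEI `RTCACRTG`; CDEIII a
permissive 25-base consensus anchored on the conserved CCCGA core), echoed
into every report: published consensi vary, and annotation should be
reproducible from the report alone.  Overlapping candidates are all
reported; selection is the caller's.

## Synthetic data

The generator produces data with the structure the analysis assumes, plus
full ground truth:

* Genealogies are single-population haploid coalescent trees (msprime,
  population size 1, so a lineage pair coalesces on average 1 time unit in
  the past).  Mutations are a Poisson process on branches at per-site rate
  θ/2, so E[π] = θ; sites are finite (length L), repeat hits allowed —
  homoplasy arises naturally.
* The 12-entry directed substitution matrix is interpreted as relative
  rates: proposals arrive at the maximum row total and are thinned by the
  current base's row total, then the target is drawn within the row.  With a
  uniform matrix nothing is thinned and E[π] = θ exactly; a skewed matrix
  lowers realized diversity by the mean acceptance ratio (e.g. a 5× C:G→T:A
  matrix on 95% A+T sequence realizes ≈0.46·θ).
* Crossovers are modelled as independent genealogies per block (breakpoints
  uniform), not an ancestral recombination graph: sufficient to create
  four-gamete-detectable discordance, and much simpler.  Linkage between
  blocks is therefore zero rather than decaying — a documented limitation.
* Indels are ±1 bp slippage events at a per-site rate multiplied (default
  10×) inside homopolymer runs ≥5 bp of the consensus; deletions mark
  carriers with `-`, insertions add a column gapped in non-carriers.
* Missing data are applied last: each valid base masked to `N` independently
  (default fraction 0.6, emulating shotgun data where only ~40% of
  centromere sites carry calls).

Default study conditions: 35 strains, 87 bp, AT-rich composition
(p_AT = 0.95), θ = 0.02 (within the empirical per-locus range 0.006–0.04).

What the generator does not emulate: population structure and admixture,
rate variation along the sequence within a block, gene-conversion tracts,
sequencing-error substitution signatures, and realistic (autocorrelated)
coverage patterns — masking is independent per base.  Passing calibration
tests therefore shows the estimators are correct under the stated model,
not that real strain panels satisfy that model.

## Problem sizes and test conditions

Chosen once as realistic study-scale conditions:

* π calibration: 200 replicates at n = 50, L = 10,000, θ = 0.01, no
  masking; mean π is required within 3 standard errors of θ.
* Null calibration: 500 recombination-free loci (n = 20, L = 500,
  θ = 0.01), 1000 null replicates each; rejection at 5% must stay ≤ ~7%.
* Crossover power: 100 replicates (n = 30, L = 400, θ = 0.05, one
  crossover); incompatibilities must appear in ≥80%.
* Spectrum recovery: 50 batches of 16 loci (n = 32, L = 87, θ = 0.08
  nominal → realized π ≈ 0.04, masking 0.1), matrix with C:G→T:A at 5×.
  Composition is set moderately AT-rich (p_AT = 0.75) so the favoured class
  is observed tens of times per batch (pooled polarized counts ≈110,
  matching the scale at which spectrum estimation is attempted in practice).
  At the CDEII extreme (p_AT = 0.95) the same estimator runs but a
  16-locus bootstrap cannot resolve rare-source classes — the known
  limitation that C:G-source rates at extreme AT content carry very wide
  intervals.

## Numerical and degenerate-input conventions

Bootstrap and simulation stages are deterministic under integer seeds
(numpy `default_rng`); the pipeline derives independent named per-stage
seeds from one master seed via `SeedSequence`.  Degenerate inputs fail
loudly: <2 loci for a bootstrap, an all-zero spectrum, S > L for the null,
populations absent from an alignment, conflict graphs beyond the exact-
search cap.  Empty annotation results and monomorphic loci are valid
outputs, not errors.
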