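"""Polarized mutation-spectrum analysis.

With no usable outgroup (CDEII is unalignable even between sibling species),
polarity is inferred from haplotype structure: a variant carried by exactly
one haplotype in the haplotype-reduced alignment is assumed derived, all
other haplotypes carrying the shared (ancestral) base.  This is conservative
— columns with two-way ties, three or more alleles, or fewer than three valid
haplotypes are unpolarizable and skipped.

From the polarized changes the module tabulates the 12 directed substitution
counts ``n[i->j]``, base availabilities ``alpha[i]`` (how much of each base
exists to mutate, summed over the reduced alignments), and the
composition-normalized relative-rate spectrum over the 6 complement-collapsed
classes::

    r_c = ((n_c / sum(n)) / p_src(c)) / sum_c' ((n_c' / sum(n)) / p_src(c'))

where ``p_src`` is the composition fraction of the source base pair (A:T or
C:G).  Rates sum to one by construction; confidence intervals come from
resampling loci with replacement.  Indels unique to one haplotype are
classified by length and direction, with indels inside homopolymer runs of
5+ bp bucketed separately (slippage in such runs inflates indel rates and
would otherwise confound comparisons between sequence contexts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import Alignment, HaplotypeClasses
from .popgen_stats import homopolymer_runs

_BASES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
#: the 12 directed substitution types
DIRECTED_TYPES = [(i, j) for i in _BASES for j in _BASES if i != j]
#: 6 complement-collapsed classes; the label pairs elements positionally,
#: e.g. "C:G>T:A" collapses C>T with G>A
COLLAPSED_CLASSES = [
    "A:T>G:C",  # A>G + T>C   (transition)
    "A:T>C:G",  # A>C + T>G
    "A:T>T:A",  # A>T + T>A
    "C:G>T:A",  # C>T + G>A   (transition)
    "C:G>A:T",  # C>A + G>T
    "C:G>G:C",  # C>G + G>C
]
_CLASS_OF = {
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("C", "T"): "C:G>T:A", ("G", "A"): "C:G>T:A",
    ("C", "A"): "C:G>A:T", ("G", "T"): "C:G>A:T",
    ("C", "G"): "C:G>G:C", ("G", "C"): "C:G>G:C",
}


def collapsed_class(from_base: str, to_base: str) -> str:
    return _CLASS_OF[(from_base, to_base)]


def source_pair(cls: str) -> str:
    return cls.split(">")[0]


@dataclass(frozen=True)
class PolarizedChange:
    locus_id: str
    column: int
    from_base: str
    to_base: str
    carrier_haplotype: str

    @property
    def kind(self) -> str:
        return (
            "transition"
            if (self.from_base, self.to_base) in TRANSITIONS
            else "transversion"
        )


@dataclass
class SpectrumCounts:
    """Directed substitution counts and base availabilities for a locus set."""

    n: dict[tuple[str, str], int] = field(
        default_factory=lambda: {t: 0 for t in DIRECTED_TYPES}
    )
    alpha: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in _BASES}
    )

    @property
    def total(self) -> int:
        return sum(self.n.values())

    @property
    def p(self) -> dict[str, float]:
        """Composition fractions per base and per complement pair."""
        tot = sum(self.alpha.values())
        if tot == 0:
            return {}
        out = {b: self.alpha[b] / tot for b in _BASES}
        out["A:T"] = out["A"] + out["T"]
        out["C:G"] = out["C"] + out["G"]
        return out

    def collapsed(self) -> dict[str, int]:
        out = {c: 0 for c in COLLAPSED_CLASSES}
        for (i, j), k in self.n.items():
            out[_CLASS_OF[(i, j)]] += k
        return out

    def ts_tv(self) -> tuple[int, int]:
        ts = sum(k for t, k in self.n.items() if t in TRANSITIONS)
        return ts, self.total - ts

    def __add__(self, other: "SpectrumCounts") -> "SpectrumCounts":
        out = SpectrumCounts()
        for t in DIRECTED_TYPES:
            out.n[t] = self.n[t] + other.n[t]
        for b in _BASES:
            out.alpha[b] = self.alpha[b] + other.alpha[b]
        return out


@dataclass(frozen=True)
class RelativeRates:
    r: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_reps: int
    seed: int


@dataclass(frozen=True)
class IndelEvent:
    locus_id: str
    start: int
    end: int  # half-open columns of the gap run
    carrier_haplotype: str
    kind: str  # 'deletion' | 'insertion'
    in_homopolymer: bool


@dataclass
class IndelSummary:
    one_bp_deletions: int = 0
    one_bp_insertions: int = 0
    other: int = 0
    #: sub-tallies of the 'other' bucket
    multi_bp: int = 0
    in_run: int = 0
    events: list[IndelEvent] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.one_bp_deletions + self.one_bp_insertions + self.other


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize_unique_changes(reduced: Alignment) -> list[PolarizedChange]:
    """Derived changes under the unique-haplotype rule.

    At each column of the haplotype-reduced alignment: if exactly one
    haplotype carries base ``j`` while every other haplotype with a valid
    base carries one identical base ``i``, the column contributes ``i -> j``.
    Requires at least 3 valid haplotypes at the column (with only 2, both
    alleles are unique and polarity is undefined).
    """
    changes: list[PolarizedChange] = []
    for col in range(reduced.length):
        carriers: dict[str, list[str]] = {}
        for (sid, seq) in reduced.records:
            b = seq[col]
            if b in _BASES:
                carriers.setdefault(b, []).append(sid)
        if sum(len(v) for v in carriers.values()) < 3 or len(carriers) != 2:
            continue
        (b1, s1), (b2, s2) = carriers.items()
        if len(s1) == 1 and len(s2) > 1:
            derived, ancestral, who = b1, b2, s1[0]
        elif len(s2) == 1 and len(s1) > 1:
            derived, ancestral, who = b2, b1, s2[0]
        else:
            continue  # two-way tie: unpolarizable
        changes.append(
            PolarizedChange(
                locus_id=reduced.locus_id,
                column=col,
                from_base=ancestral,
                to_base=derived,
                carrier_haplotype=who,
            )
        )
    return changes


def spectrum_counts(
    reduced: Alignment,
    changes: Sequence[PolarizedChange] | None = None,
    alpha_source: Alignment | None = None,
) -> SpectrumCounts:
    """``n[i->j]`` and ``alpha[i]`` for one haplotype-reduced locus.

    ``alpha`` sums literal base content over all sequences of the reduced
    alignment by default; pass the unreduced alignment as ``alpha_source``
    to count availability over every strain instead."""
    if changes is None:
        changes = polarize_unique_changes(reduced)
    out = SpectrumCounts()
    for ch in changes:
        if ch.locus_id != reduced.locus_id:
            raise ValueError(
                f"changes from {ch.locus_id!r} paired with {reduced.locus_id!r}"
            )
        out.n[(ch.from_base, ch.to_base)] += 1
    for _, seq in (alpha_source or reduced).records:
        for b in _BASES:
            out.alpha[b] += seq.count(b)
    return out


def pooled_counts(per_locus: Iterable[SpectrumCounts]) -> SpectrumCounts:
    out = SpectrumCounts()
    for c in per_locus:
        out = out + c
    return out


# ---------------------------------------------------------------------------
# Relative rates (composition-normalized, rescaled to sum to one)
# ---------------------------------------------------------------------------

def _point_rates(counts: SpectrumCounts) -> dict[str, float]:
    coll = counts.collapsed()
    total = sum(coll.values())
    if total == 0:
        raise ValueError("undefined spectrum: no polarized changes")
    p = counts.p
    raw = {}
    for c in COLLAPSED_CLASSES:
        psrc = p.get(source_pair(c), 0.0)
        raw[c] = (coll[c] / total) / psrc if psrc > 0 else 0.0
    z = sum(raw.values())
    return {c: raw[c] / z for c in COLLAPSED_CLASSES}


def relative_rates_with_ci(
    per_locus: Sequence[SpectrumCounts],
    n_reps: int = 1000,
    seed: int = 0,
) -> RelativeRates:
    """Point spectrum from pooled counts, with percentile CIs from resampling
    loci with replacement (each replicate re-pools and re-normalizes, so every
    replicate spectrum also sums to one)."""
    if not per_locus or pooled_counts(per_locus).total == 0:
        raise ValueError("undefined spectrum: no polarized changes in any locus")
    point = _point_rates(pooled_counts(per_locus))
    rng = np.random.default_rng(seed)
    n_loci = len(per_locus)
    reps = {c: np.empty(n_reps) for c in COLLAPSED_CLASSES}
    for rep in range(n_reps):
        idx = rng.integers(0, n_loci, size=n_loci)
        pool = pooled_counts([per_locus[i] for i in idx])
        if pool.total == 0:
            r = {c: np.nan for c in COLLAPSED_CLASSES}
        else:
            r = _point_rates(pool)
        for c in COLLAPSED_CLASSES:
            reps[c][rep] = r[c]
    lo, hi = {}, {}
    for c in COLLAPSED_CLASSES:
        vals = reps[c][~np.isnan(reps[c])]
        lo[c], hi[c] = (
            (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
            if vals.size
            else (np.nan, np.nan)
        )
    return RelativeRates(r=point, ci_low=lo, ci_high=hi, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# Indels
# ---------------------------------------------------------------------------

def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs, i, L = [], 0, len(seq)
    while i < L:
        if seq[i] == "-":
            j = i + 1
            while j < L and seq[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def classify_indels(
    reduced: Alignment, run_min_len: int = 5
) -> IndelSummary:
    """Unique indels in a haplotype-reduced alignment, Ts/Tv-style polarized.

    An indel event is a maximal gap run present in exactly one haplotype
    (deletion in the carrier) or absent from exactly one haplotype while all
    other valid haplotypes are gapped there (insertion in the carrier); the
    uniqueness rule mirrors substitution polarization.  Events of length
    1 bp outside homopolymer runs of ``run_min_len``+ are counted in the two
    headline buckets; longer events and events inside such runs go to
    ``other`` (sub-tallies kept separately).
    """
    out = IndelSummary()
    n_hap = reduced.n_strains
    # homopolymer context from each non-carrier representative's gap-free seq
    seen: set[tuple[int, int, str]] = set()
    for sid, seq in reduced.records:
        for (s, e) in _gap_runs(seq):
            # deletion unique to this haplotype: all others have valid bases
            others = [
                (osid, oseq) for osid, oseq in reduced.records if osid != sid
            ]
            other_states = [oseq[s:e] for _, oseq in others]
            if all(all(c in _BASES for c in st) for st in other_states) and n_hap >= 3:
                key = (s, e, "deletion")
                if key in seen:
                    continue
                seen.add(key)
                in_run = _in_homopolymer_context(others[0][1], s, e, run_min_len)
                _record(out, reduced.locus_id, s, e, sid, "deletion", in_run)
    # insertions: column block where exactly one haplotype has bases, rest gaps
    for sid, seq in reduced.records:
        others = [(osid, oseq) for osid, oseq in reduced.records if osid != sid]
        blocks = _insertion_blocks(seq, [oseq for _, oseq in others])
        for (s, e) in blocks:
            if n_hap < 3:
                continue
            key = (s, e, "insertion")
            if key in seen:
                continue
            seen.add(key)
            in_run = _in_homopolymer_context(seq, s, e, run_min_len)
            _record(out, reduced.locus_id, s, e, sid, "insertion", in_run)
    return out


def _insertion_blocks(seq: str, other_seqs: list[str]) -> list[tuple[int, int]]:
    """Maximal column runs where ``seq`` has valid bases and every other
    sequence is gapped."""
    flags = [
        seq[i] in _BASES and all(o[i] == "-" for o in other_seqs)
        for i in range(len(seq))
    ]
    blocks, i = [], 0
    while i < len(flags):
        if flags[i]:
            j = i + 1
            while j < len(flags) and flags[j]:
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def _in_homopolymer_context(
    context_seq: str, s: int, e: int, run_min_len: int
) -> bool:
    """Whether alignment columns [s, e) fall inside a homopolymer run of
    ``run_min_len``+ in the gap-free version of ``context_seq``."""
    degapped = context_seq.replace("-", "")
    # map alignment column s to degapped coordinate
    pos = sum(1 for c in context_seq[:s] if c != "-")
    prof = homopolymer_runs(degapped, min_len=run_min_len)
    return prof.covers(pos) or (pos > 0 and prof.covers(pos - 1))


def _record(
    out: IndelSummary,
    locus_id: str,
    s: int,
    e: int,
    sid: str,
    kind: str,
    in_run: bool,
) -> None:
    out.events.append(IndelEvent(locus_id, s, e, sid, kind, in_run))
    if e - s == 1 and not in_run:
        if kind == "deletion":
            out.one_bp_deletions += 1
        else:
            out.one_bp_insertions += 1
    else:
        out.other += 1
        if e - s > 1:
            out.multi_bp += 1
        if in_run:
            out.in_run += 1


# ---------------------------------------------------------------------------
# Published-table summary arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumRow:
    """One study's headline mutation-spectrum counts."""

    study: str
    transitions: int
    transversions: int
    one_bp_deletions: int
    one_bp_insertions: int
    other: int
    group: str = ""

    @property
    def ts_tv_freq(self) -> float:
        return self.transitions / self.transversions

    @property
    def total_bps(self) -> int:
        return self.transitions + self.transversions

    @property
    def del_bps_freq(self) -> float:
        """1 bp deletions per base substitution."""
        return self.one_bp_deletions / self.total_bps


def pool_rows(rows: Iterable[SpectrumRow], study: str = "pooled") -> SpectrumRow:
    rows = list(rows)
    return SpectrumRow(
        study=study,
        transitions=sum(r.transitions for r in rows),
        transversions=sum(r.transversions for r in rows),
        one_bp_deletions=sum(r.one_bp_deletions for r in rows),
        one_bp_insertions=sum(r.one_bp_insertions for r in rows),
        other=sum(r.other for r in rows),
    )


def read_spectrum_table(path) -> list[SpectrumRow]:
    """Read a TSV of study spectra (study, transitions, transversions,
    one_bp_deletions, one_bp_insertions, other)."""
    import csv
    from pathlib import Path

    rows = []
    with Path(path).open() as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                SpectrumRow(
                    study=rec["study"],
                    transitions=int(rec["transitions"]),
                    transversions=int(rec["transversions"]),
                    one_bp_deletions=int(rec["one_bp_deletions"]),
                    one_bp_insertions=int(rec["one_bp_insertions"]),
                    other=int(rec["other"]),
                    group=rec.get("class", ""),
                )
            )
    return rows


def published_spectra() -> list[SpectrumRow]:
    """The shipped table of published mutation-spectrum counts: the CDEII
    polarized counts plus literature wild-type (spontaneous) and
    gene-conversion spectra used for comparison."""
    from importlib.resources import files

    return read_spectrum_table(files("cenpop.data") / "published_spectra.tsv")
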