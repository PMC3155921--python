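"""Per-locus multiple-sequence-alignment handling.

Alignments are over the six-letter alphabet ``A C G T N -``: ``N`` encodes a
missing or sub-quality base (in shotgun population data most of the matrix can
be ``N``), ``-`` an alignment gap.  Every downstream statistic excludes ``N``
per strain per site, so the container keeps the raw matrix and exposes
column-wise views that already apply the missing-data rules.

The module also implements haplotype reduction: collapsing the alignment so
each distinct haplotype is represented once, by its least-ambiguous member.
Because missing data make "same haplotype" a wildcard relation (``N`` matches
anything), the relation is not transitive; classes are therefore formed
greedily against class representatives in a deterministic order (most
unambiguous characters first, ties broken by strain id).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
VALID_BASES = frozenset("ACGT")
#: states that participate in haplotype identity ('-' is a matchable fifth
#: state so indel haplotypes stay distinct; 'N' is a wildcard)
MATCHABLE = frozenset("ACGT-")


class AlignmentError(ValueError):
    """Raised for malformed alignment input (shape, duplicates, emptiness)."""


@dataclass(frozen=True)
class Alignment:
    """An immutable per-locus alignment matrix.

    Parameters
    ----------
    locus_id:
        Name of the locus (e.g. ``CEN1``).
    records:
        Ordered ``(strain_id, sequence)`` pairs; sequences are upper-case
        strings over ``ACGTN-`` of identical length.
    """

    locus_id: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"{self.locus_id}: alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError(f"{self.locus_id}: zero-length alignment")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = [s for s, c in Counter(ids).items() if c > 1]
            raise AlignmentError(f"{self.locus_id}: duplicate strain ids {dupes}")
        for sid, seq in self.records:
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"{self.locus_id}/{sid}: invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_strains(self) -> int:
        return len(self.records)

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    def sequence(self, strain_id: str) -> str:
        for sid, seq in self.records:
            if sid == strain_id:
                return seq
        raise KeyError(strain_id)

    def column(self, i: int) -> tuple[str, ...]:
        if not 0 <= i < self.length:
            raise IndexError(f"column {i} out of range [0, {self.length})")
        return tuple(seq[i] for _, seq in self.records)

    def slice(self, start: int, end: int) -> "Alignment":
        """Sub-alignment over columns ``[start, end)`` (0-based half-open)."""
        if not (0 <= start < end <= self.length):
            raise AlignmentError(
                f"{self.locus_id}: bad region [{start}, {end}) for length {self.length}"
            )
        return Alignment(
            self.locus_id,
            tuple((sid, seq[start:end]) for sid, seq in self.records),
        )

    def mask_columns(self, columns: Iterable[int]) -> "Alignment":
        """Return a copy with the given columns set to ``N`` in every strain."""
        cols = set(columns)
        out = []
        for sid, seq in self.records:
            chars = list(seq)
            for c in cols:
                chars[c] = "N"
            out.append((sid, "".join(chars)))
        return Alignment(self.locus_id, tuple(out))


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Upper-case a sequence and map anything outside ``ACGT-`` to ``N``.

    Returns the normalized string and the number of characters that were
    coerced to ``N`` (excluding characters that already were ``N``/``n``).
    """
    up = raw.upper()
    coerced = 0
    out = []
    for ch in up:
        if ch in ALPHABET:
            out.append(ch)
        else:
            out.append("N")
            coerced += 1
    return "".join(out), coerced


def read_alignment(path: str | Path, locus_id: str | None = None) -> Alignment:
    """Read a FASTA alignment; sequences are case-folded and any character
    outside ``ACGT-`` (other than ``N``) becomes ``N`` (count is logged)."""
    path = Path(path)
    records = []
    n_coerced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, c = normalize_sequence(str(rec.seq))
        n_coerced += c
        records.append((rec.id, seq))
    if not records:
        raise AlignmentError(f"{path}: empty FASTA")
    if n_coerced:
        logger.warning("%s: coerced %d non-ACGTN- characters to N", path, n_coerced)
    return Alignment(locus_id or path.stem, tuple(records))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment as FASTA wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def site_states(aln: Alignment, column: int) -> Counter:
    """Multiset of valid bases (``ACGT``) at a column; ``N`` and gaps excluded."""
    return Counter(b for b in aln.column(column) if b in VALID_BASES)


def site_states_by_strain(aln: Alignment, column: int) -> dict[str, str]:
    """Per-strain valid base at a column (strains with ``N``/gap omitted)."""
    col = aln.column(column)
    return {
        sid: b for (sid, _), b in zip(aln.records, col) if b in VALID_BASES
    }


# ---------------------------------------------------------------------------
# Haplotype reduction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeClasses:
    """Result of collapsing an alignment to distinct haplotypes."""

    reduced: Alignment
    #: representative strain id -> member strain ids (representative included)
    members: dict[str, list[str]] = field(default_factory=dict)

    def to_table(self) -> list[dict]:
        rows = []
        for i, (rep, mem) in enumerate(self.members.items(), start=1):
            rows.append(
                {
                    "haplotype_id": f"hap{i}",
                    "representative": rep,
                    "members": ",".join(mem),
                    "n_unambiguous": sum(
                        1 for ch in self.reduced.sequence(rep) if ch != "N"
                    ),
                }
            )
        return rows


def _compatible(a: str, b: str) -> bool:
    """True iff a and b agree wherever both are in ``ACGT-`` (N is wildcard)."""
    for x, y in zip(a, b):
        if x in MATCHABLE and y in MATCHABLE and x != y:
            return False
    return True


def reduce_to_haplotypes(aln: Alignment) -> HaplotypeClasses:
    """Collapse the alignment so each haplotype is represented once.

    Two sequences belong to one haplotype class iff they agree at every column
    where both carry a determinate state (``ACGT`` or ``-``); ``N`` matches
    anything.  The representative of a class is the member with the most
    non-``N`` characters (ties: lexicographically smallest strain id), i.e.
    the longest unambiguous sequence of the class.  Because wildcard
    compatibility is not transitive, sequences are assigned greedily, in
    representative order, to the first compatible existing representative.
    """
    order = sorted(
        aln.records,
        key=lambda r: (-sum(1 for ch in r[1] if ch != "N"), r[0]),
    )
    reps: list[tuple[str, str]] = []  # (strain_id, seq) in creation order
    members: dict[str, list[str]] = {}
    for sid, seq in order:
        for rep_id, rep_seq in reps:
            if _compatible(seq, rep_seq):
                members[rep_id].append(sid)
                break
        else:
            reps.append((sid, seq))
            members[sid] = [sid]
    reduced = Alignment(aln.locus_id, tuple(reps))
    return HaplotypeClasses(reduced=reduced, members={k: sorted(v) for k, v in members.items()})


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationMap:
    """Mapping from strain id to population label."""

    assignments: Mapping[str, str]

    def population(self, strain_id: str) -> str:
        try:
            return self.assignments[strain_id]
        except KeyError:
            raise KeyError(f"strain {strain_id!r} has no population assignment")

    def strains_in(self, population: str) -> list[str]:
        return sorted(s for s, p in self.assignments.items() if p == population)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a two-column TSV (strain_id, population)."""
        assignments = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AlignmentError(f"{path}: malformed population line {line!r}")
            assignments[parts[0]] = parts[1]
        return cls(assignments)
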