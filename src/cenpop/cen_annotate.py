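"""Annotation of budding-yeast point centromeres.

A *Saccharomyces* point centromere is ~120 bp of sequence comprising two
conserved protein-binding motifs — CDEI (8 bp) and CDEIII (25 bp) — separated
by the AT-rich CDEII core, whose length (~80–90 bp, typically 87 bp) is
conserved but whose sequence is essentially unconstrained.  Annotation
therefore reduces to motif finding: scan both strands for IUPAC-degenerate
CDEI and CDEIII consensus matches and report every same-strand pair whose gap
(the CDEII candidate) has a plausible length.

The consensus strings themselves are configuration, not hard-coded truth:
they are shipped as editable defaults and echoed into every report, because
different references print slightly different degenerate consensi.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

# Default consensus motifs (IUPAC).  CDEI is the canonical 8-mer; the CDEIII
# default is a permissive 25-base consensus centred on the essential CCG core,
# written mostly as N so that annotation is driven by CDEI, the gap-length
# constraint, and the conserved central positions.
DEFAULT_CDEI = "RTCACRTG"
DEFAULT_CDEIII = "TGNNNNNNGNNNNNNAAANNCCCGA"  # 25 bp
DEFAULT_CDEII_RANGE = (75, 100)


class MotifPatternError(ValueError):
    """Invalid IUPAC pattern."""


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise MotifPatternError(f"{self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(ambiguous_dna_values)
        if bad:
            raise MotifPatternError(
                f"{self.name}: invalid IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    def to_regex(self) -> re.Pattern:
        # N in the *subject* never matches, so every character class is built
        # from concrete bases only (IUPAC N expands to ACGT, not to N).
        parts = []
        for ch in self.pattern.upper():
            bases = ambiguous_dna_values[ch]
            parts.append(bases if len(bases) == 1 else f"[{bases}]")
        return re.compile("".join(parts))


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CentromereAnnotation:
    source_id: str
    strand: str  # '+' or '-'
    cdei: Interval
    cdeii: Interval
    cdeiii: Interval


def find_motif_matches(
    seq: str, motif: MotifPattern
) -> list[tuple[Interval, str]]:
    """All exact IUPAC matches of ``motif`` on both strands of ``seq``.

    Reverse-strand matches are reported in forward coordinates.  Matches are
    sorted by start position.  ``N`` in the subject never matches any code.
    """
    seq = seq.upper()
    rx = motif.to_regex()
    hits: list[tuple[Interval, str]] = []
    for m in _overlapping_finditer(rx, seq):
        hits.append((Interval(m[0], m[1]), "+"))
    rc = str(Seq(seq).reverse_complement())
    L = len(seq)
    for m in _overlapping_finditer(rx, rc):
        hits.append((Interval(L - m[1], L - m[0]), "-"))
    hits.sort(key=lambda h: (h[0].start, h[1]))
    return hits


def _overlapping_finditer(rx: re.Pattern, s: str) -> Iterable[tuple[int, int]]:
    pos = 0
    while True:
        m = rx.search(s, pos)
        if m is None:
            return
        yield m.start(), m.end()
        pos = m.start() + 1


def annotate_point_centromere(
    seq: str,
    source_id: str = "seq",
    cdei: MotifPattern | None = None,
    cdeiii: MotifPattern | None = None,
    cdeii_len_range: tuple[int, int] = DEFAULT_CDEII_RANGE,
) -> list[CentromereAnnotation]:
    """Locate candidate point centromeres in a raw sequence.

    Every same-strand CDEI/CDEIII match pair whose intervening gap length lies
    within ``cdeii_len_range`` is reported, with CDEII defined as that gap.
    On the minus strand the element order along the forward coordinate is
    CDEIII — CDEII — CDEI.  An empty list is a valid result (a locus may
    simply lack a recognisable centromere).
    """
    cdei = cdei or MotifPattern("CDEI", DEFAULT_CDEI)
    cdeiii = cdeiii or MotifPattern("CDEIII", DEFAULT_CDEIII)
    lo, hi = cdeii_len_range
    if lo > hi:
        raise ValueError(f"bad CDEII length range ({lo}, {hi})")
    m1 = find_motif_matches(seq, cdei)
    m3 = find_motif_matches(seq, cdeiii)
    out: list[CentromereAnnotation] = []
    for iv1, s1 in m1:
        for iv3, s3 in m3:
            if s1 != s3:
                continue
            if s1 == "+":
                gap = Interval(iv1.end, iv3.start) if iv1.end <= iv3.start else None
            else:
                gap = Interval(iv3.end, iv1.start) if iv3.end <= iv1.start else None
            if gap is None or not lo <= len(gap) <= hi:
                continue
            out.append(
                CentromereAnnotation(
                    source_id=source_id, strand=s1, cdei=iv1, cdeii=gap, cdeiii=iv3
                )
            )
    out.sort(key=lambda a: (a.cdei.start, a.strand))
    return out


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def annotations_to_gff3(
    annotations: Iterable[CentromereAnnotation],
    cdei_pattern: str = DEFAULT_CDEI,
    cdeiii_pattern: str = DEFAULT_CDEIII,
) -> str:
    """GFF3 (1-based inclusive) with the consensus patterns echoed for provenance."""
    lines = [
        "##gff-version 3",
        f"#cdei_pattern={cdei_pattern}",
        f"#cdeiii_pattern={cdeiii_pattern}",
    ]
    for i, a in enumerate(annotations, start=1):
        for name, iv in (("CDEI", a.cdei), ("CDEII", a.cdeii), ("CDEIII", a.cdeiii)):
            lines.append(
                "\t".join(
                    [
                        a.source_id,
                        "cenpop",
                        name,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        a.strand,
                        ".",
                        f"ID=cen{i}_{name.lower()}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def annotations_to_bed(annotations: Iterable[CentromereAnnotation]) -> str:
    """BED (0-based half-open)."""
    lines = []
    for a in annotations:
        for name, iv in (("CDEI", a.cdei), ("CDEII", a.cdeii), ("CDEIII", a.cdeiii)):
            lines.append(
                "\t".join(
                    [a.source_id, str(iv.start), str(iv.end), name, "0", a.strand]
                )
            )
    return "\n".join(lines) + "\n"


def write_annotation_reports(
    annotations: list[CentromereAnnotation],
    gff_path: str | Path,
    bed_path: str | Path,
    cdei_pattern: str = DEFAULT_CDEI,
    cdeiii_pattern: str = DEFAULT_CDEIII,
) -> None:
    Path(gff_path).write_text(
        annotations_to_gff3(annotations, cdei_pattern, cdeiii_pattern)
    )
    Path(bed_path).write_text(annotations_to_bed(annotations))
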