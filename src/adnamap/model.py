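"""Core domain types for ancient-DNA read mapping analyses.

The toolkit operates on three kinds of objects: sequencing reads
(:class:`SequenceRead`), individual SAM alignments (:class:`AlignmentHit`)
and per-position read-vs-reference comparisons reconstructed from CIGAR and
MD information (:class:`AlignedColumnSeries`).

Conventions
-----------
* SAM coordinates are 1-based inclusive, matching the format itself.
* All per-position damage statistics are expressed in *read orientation*:
  position 1 is the first base sequenced (the 5' terminus of the read as it
  came off the instrument).  For reverse-strand alignments both read and
  reconstructed reference bases are complemented accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The 12 ordered substitution classes (reference base -> read base).
SUBSTITUTION_CLASSES: tuple[str, ...] = tuple(
    f"{r}>{q}" for r in "ACGT" for q in "ACGT" if r != q
)


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Platform(str, Enum):
    HELICOS = "helicos"
    ILLUMINA = "illumina"


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"


class Uniqueness(str, Enum):
    """Mapping uniqueness as encoded by BWA's XT tag."""

    UNIQUE = "unique"
    REPEAT = "repeat"
    UNMAPPED = "unmapped"


class ColumnEvent(str, Enum):
    MATCH = "match"
    MISMATCH = "mismatch"
    INSERTION = "insertion"
    DELETION = "deletion"
    SOFTCLIP = "softclip"


@dataclass(frozen=True)
class SequenceRead:
    """A sequencing read.

    Helicos (tSMS) reads carry no per-base quality scores; Illumina reads do.
    ``qualities`` are PHRED scores, one per base, in sequencing order.
    """

    read_id: str
    bases: str
    qualities: Optional[tuple[int, ...]] = None
    platform: Platform = Platform.ILLUMINA

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentHit:
    """One SAM alignment record.

    ``cigar`` is restricted to the M/I/D/S operations produced by BWA's
    ``aln`` mode.  ``md``, ``nm``, ``alt_hits`` (X1), ``best_hits`` (X0) and
    ``uniqueness`` (XT) are ``None`` when the corresponding tag is absent;
    they are never silently defaulted.  ``sam_seq`` stores SEQ exactly as in
    the file (forward-reference orientation) so profiling can run from a SAM
    alone.
    """

    read_id: str
    reference_name: Optional[str]
    position: Optional[int]  # 1-based leftmost reference coordinate
    strand: Strand
    cigar: tuple[tuple[str, int], ...]
    md: Optional[str] = None
    nm: Optional[int] = None
    mapq: int = 0
    uniqueness: Optional[Uniqueness] = None
    alt_hits: Optional[int] = None
    best_hits: Optional[int] = None
    is_duplicate: bool = False
    sam_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mapped:
            if self.position is None or self.position < 1:
                raise ValueError(f"hit {self.read_id!r}: position must be >= 1")
        if self.nm is not None and self.nm < 0:
            raise ValueError(f"hit {self.read_id!r}: NM must be >= 0")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"hit {self.read_id!r}: MAPQ out of [0, 255]")
        bad = [op for op, _ in self.cigar if op not in "MIDS"]
        if bad:
            raise ValueError(f"hit {self.read_id!r}: unsupported CIGAR ops {bad}")
        if self.sam_seq is not None and self.cigar:
            if self.read_length != len(self.sam_seq):
                raise ValueError(
                    f"hit {self.read_id!r}: CIGAR read length {self.read_length} "
                    f"!= sequence length {len(self.sam_seq)}"
                )

    @property
    def mapped(self) -> bool:
        return self.uniqueness is not Uniqueness.UNMAPPED

    @property
    def read_length(self) -> int:
        """Read length implied by the CIGAR (sum of M/I/S lengths)."""
        return sum(n for op, n in self.cigar if op in "MIS")

    @property
    def reference_span(self) -> int:
        """Number of reference bases covered (sum of M/D lengths)."""
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost reference coordinate."""
        if self.position is None:
            raise ValueError("unmapped hit has no reference end")
        return self.position + self.reference_span - 1


@dataclass(frozen=True)
class AlignedColumn:
    """One read-vs-reference column, in read orientation.

    ``read_pos`` is 1-based from the sequencing 5' end.  Deletion columns
    carry a reference base and no read base; insertion and softclip columns
    carry a read base and no reference base.
    """

    read_pos: int
    ref_base: Optional[str]
    read_base: Optional[str]
    event: ColumnEvent
    base_quality: Optional[int] = None


@dataclass
class AlignedColumnSeries:
    """All columns of one alignment, ordered in read orientation."""

    read_id: str
    read_length: int
    columns: tuple[AlignedColumn, ...]

    def __iter__(self):
        return iter(self.columns)

    def nm(self) -> int:
        """Edit distance under the mismatches + inserted + deleted bases
        convention (soft clips excluded)."""
        return sum(
            1
            for c in self.columns
            if c.event
            in (ColumnEvent.MISMATCH, ColumnEvent.INSERTION, ColumnEvent.DELETION)
        )


def phred_to_string(qualities: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in qualities)


def string_to_phred(text: str) -> tuple[int, ...]:
    return tuple(ord(c) - 33 for c in text)
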