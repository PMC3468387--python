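"""Reconstruction of per-position read-vs-reference comparisons.

The MD tag encodes the reference bases at mismatches and deletions, so the
full column-by-column comparison of a read against the reference can be
recovered from a SAM record alone, without the reference FASTA.  This walk
is the substrate for all misincorporation statistics in the toolkit.

Columns are returned in *read orientation*: position 1 is the sequencing 5'
terminus.  For reverse-strand alignments both read and reference bases are
complemented and positions re-indexed, matching the mapDamage convention.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .model import (
    AlignedColumn,
    AlignedColumnSeries,
    AlignmentHit,
    ColumnEvent,
    SequenceRead,
    Strand,
    complement,
    revcomp,
)

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def parse_md(md: str) -> list[tuple[str, object]]:
    """Tokenize an MD string into ('match', n) / ('del', bases) /
    ('mismatch', ref_base) items."""
    tokens: list[tuple[str, object]] = []
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise ValueError(f"invalid MD string {md!r}")
        pos = m.end()
        if m.group(1) is not None:
            n = int(m.group(1))
            if n > 0:
                tokens.append(("match", n))
        elif m.group(2) is not None:
            tokens.append(("del", m.group(2)[1:].upper()))
        else:
            tokens.append(("mismatch", m.group(3).upper()))
    if pos != len(md):
        raise ValueError(f"invalid MD string {md!r}")
    return tokens


class _MdWalker:
    """Consumes MD tokens in step with the CIGAR walk."""

    def __init__(self, md: str):
        self.tokens = parse_md(md)
        self.index = 0
        self.match_left = 0

    def next_aligned(self) -> Optional[str]:
        """Advance one aligned (M) column; returns the reference base for a
        mismatch, or None for a match."""
        while self.match_left == 0:
            if self.index >= len(self.tokens):
                raise ValueError("MD string exhausted before CIGAR")
            kind, value = self.tokens[self.index]
            self.index += 1
            if kind == "match":
                self.match_left = value
            elif kind == "mismatch":
                return value
            else:
                raise ValueError("MD deletion where CIGAR expects an aligned base")
        self.match_left -= 1
        return None

    def next_deletion(self, length: int) -> str:
        while self.match_left == 0 and self.index < len(self.tokens):
            kind, value = self.tokens[self.index]
            if kind == "del":
                self.index += 1
                if len(value) != length:
                    raise ValueError(
                        f"MD deletion of {len(value)} bases where CIGAR has {length}"
                    )
                return value
            if kind == "match" and value == 0:
                self.index += 1
                continue
            break
        raise ValueError("MD inconsistent with CIGAR deletion")

    def finished(self) -> bool:
        if self.match_left:
            return False
        return all(k == "match" and v == 0 for k, v in self.tokens[self.index :])


def reconstruct_columns(
    hit: AlignmentHit,
    read: Optional[SequenceRead] = None,
    qualities: Optional[Sequence[int]] = None,
) -> AlignedColumnSeries:
    """Recover the aligned column series of ``hit`` from CIGAR + MD.

    ``read`` is the read as sequenced (5'->3'); if omitted, the SEQ stored
    on the hit (forward-reference orientation) is used.  ``qualities``
    override the read's own scores and are taken in SAM orientation (as
    stored in the file).
    """
    if hit.md is None:
        raise ValueError(f"hit {hit.read_id!r} lacks an MD tag; cannot profile")
    if not hit.cigar:
        raise ValueError(f"hit {hit.read_id!r} has no CIGAR")

    reverse = hit.strand is Strand.REVERSE
    if read is not None:
        sam_seq = revcomp(read.bases) if reverse else read.bases
        sam_quals: Optional[Sequence[int]] = None
        if read.qualities is not None:
            sam_quals = read.qualities[::-1] if reverse else read.qualities
    elif hit.sam_seq is not None:
        sam_seq = hit.sam_seq
        sam_quals = None
    else:
        raise ValueError(f"hit {hit.read_id!r}: no read sequence available")
    if qualities is not None:
        sam_quals = qualities

    length = hit.read_length
    if len(sam_seq) != length:
        raise ValueError(
            f"hit {hit.read_id!r}: read length {len(sam_seq)} does not match "
            f"CIGAR ({length})"
        )
    if sam_quals is not None and len(sam_quals) != length:
        raise ValueError(f"hit {hit.read_id!r}: quality/sequence length mismatch")

    md = _MdWalker(hit.md)
    # Build columns in SAM orientation first.  Deletions store both flanking
    # read cursors so the strand-dependent "position following the deleted
    # bases in read orientation" can be resolved afterwards.
    raw: list[tuple] = []  # (sam_pos or (before, after), event, ref, base, qual)
    cursor = 0  # 0-based index into sam_seq of the next base
    for op, n in hit.cigar:
        if op == "S":
            for _ in range(n):
                base = sam_seq[cursor]
                q = sam_quals[cursor] if sam_quals is not None else None
                raw.append((cursor + 1, ColumnEvent.SOFTCLIP, None, base, q))
                cursor += 1
        elif op == "M":
            for _ in range(n):
                base = sam_seq[cursor]
                q = sam_quals[cursor] if sam_quals is not None else None
                mismatch_ref = md.next_aligned()
                if mismatch_ref is None:
                    raw.append((cursor + 1, ColumnEvent.MATCH, base, base, q))
                else:
                    raw.append((cursor + 1, ColumnEvent.MISMATCH, mismatch_ref, base, q))
                cursor += 1
        elif op == "I":
            for _ in range(n):
                base = sam_seq[cursor]
                q = sam_quals[cursor] if sam_quals is not None else None
                raw.append((cursor + 1, ColumnEvent.INSERTION, None, base, q))
                cursor += 1
        elif op == "D":
            ref_bases = md.next_deletion(n)
            for ref_base in ref_bases:
                raw.append(((cursor, cursor + 1), ColumnEvent.DELETION, ref_base, None, None))
    if cursor != length:
        raise ValueError(f"hit {hit.read_id!r}: CIGAR walk consumed {cursor}/{length} bases")
    if not md.finished():
        raise ValueError(f"hit {hit.read_id!r}: MD not exhausted by CIGAR walk")

    columns: list[AlignedColumn] = []
    for pos, event, ref, base, qual in raw:
        if event is ColumnEvent.DELETION:
            before, after = pos
            # Read position of the base following the deletion *in read
            # orientation*: the next SAM base when forward, the previous one
            # (flipped) when reverse.
            read_pos = after if not reverse else length - before + 1
        else:
            read_pos = pos if not reverse else length - pos + 1
        if reverse:
            ref = complement(ref) if ref is not None else None
            base = complement(base) if base is not None else None
        columns.append(AlignedColumn(read_pos, ref, base, event, qual))
    if reverse:
        columns.reverse()
    return AlignedColumnSeries(hit.read_id, length, tuple(columns))
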