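"""Readers and writers for FASTA, FASTQ and SAM.

FASTA/FASTQ parsing is delegated to Biopython, SAM I/O to pysam; this module
only maps records onto the toolkit's domain types.  SAM files are handled as
text (the toolkit's deliverables are all plain-text formats); pysam reads
BAM transparently should one be supplied.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping, Optional

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import (
    AlignmentHit,
    Platform,
    SequenceRead,
    Strand,
    Uniqueness,
    phred_to_string,
    string_to_phred,
)

_XT_MAP = {"U": Uniqueness.UNIQUE, "R": Uniqueness.REPEAT, "N": None, "M": None}
_CIGAR_OPS = "MIDNSHP=X"


def read_fastq(path: str, platform: Platform = Platform.ILLUMINA) -> Iterator[SequenceRead]:
    """Yield reads from a PHRED+33 FASTQ file in file order.

    Malformed records raise a ``ValueError`` naming the (0-based) record
    index at which parsing failed.
    """
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc
            if len(qual) != len(seq):
                raise ValueError(
                    f"malformed FASTQ record {index}: quality length "
                    f"{len(qual)} != sequence length {len(seq)}"
                )
            yield SequenceRead(
                read_id=title.split()[0],
                bases=seq.upper(),
                qualities=string_to_phred(qual),
                platform=platform,
            )
            index += 1


def write_fastq(reads: Iterable[SequenceRead], path: str) -> None:
    with open(path, "w") as handle:
        for read in reads:
            if read.qualities is None:
                raise ValueError(f"read {read.read_id!r} has no qualities; use FASTA")
            handle.write(
                f"@{read.read_id}\n{read.bases}\n+\n{phred_to_string(read.qualities)}\n"
            )


def read_fasta_reads(path: str, platform: Platform = Platform.HELICOS) -> Iterator[SequenceRead]:
    """Read quality-free reads (the Helicos case) from FASTA."""
    for record in SeqIO.parse(path, "fasta"):
        yield SequenceRead(record.id, str(record.seq).upper(), None, platform)


def read_reads(path: str, platform: Platform) -> Iterator[SequenceRead]:
    """Dispatch on extension: .fastq/.fq -> FASTQ, otherwise FASTA."""
    if path.endswith((".fastq", ".fq")):
        return read_fastq(path, platform)
    return read_fasta_reads(path, platform)


def write_fasta(sequences: Mapping[str, str] | Iterable[SequenceRead], path: str, width: int = 70) -> None:
    with open(path, "w") as handle:
        items = (
            sequences.items()
            if isinstance(sequences, Mapping)
            else ((r.read_id, r.bases) for r in sequences)
        )
        for name, seq in items:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load reference sequences into a name -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _hit_from_pysam(rec: pysam.AlignedSegment) -> AlignmentHit:
    if rec.is_unmapped:
        return AlignmentHit(
            read_id=rec.query_name,
            reference_name=None,
            position=None,
            strand=Strand.FORWARD,
            cigar=(),
            mapq=rec.mapping_quality,
            uniqueness=Uniqueness.UNMAPPED,
            is_duplicate=rec.is_duplicate,
            sam_seq=rec.query_sequence,
        )
    cigar = tuple((_CIGAR_OPS[op], n) for op, n in rec.cigartuples or ())
    seq = rec.query_sequence
    if seq is not None:
        implied = sum(n for op, n in cigar if op in "MIS")
        if implied != len(seq):
            raise ValueError(
                f"record {rec.query_name!r}: CIGAR implies read length "
                f"{implied} but SEQ has {len(seq)} bases"
            )
    xt = rec.get_tag("XT") if rec.has_tag("XT") else None
    return AlignmentHit(
        read_id=rec.query_name,
        reference_name=rec.reference_name,
        position=rec.reference_start + 1,
        strand=Strand.REVERSE if rec.is_reverse else Strand.FORWARD,
        cigar=cigar,
        md=rec.get_tag("MD") if rec.has_tag("MD") else None,
        nm=rec.get_tag("NM") if rec.has_tag("NM") else None,
        mapq=rec.mapping_quality,
        uniqueness=_XT_MAP.get(xt) if xt is not None else None,
        alt_hits=rec.get_tag("X1") if rec.has_tag("X1") else None,
        best_hits=rec.get_tag("X0") if rec.has_tag("X0") else None,
        is_duplicate=rec.is_duplicate,
        sam_seq=seq,
    )


def read_sam(path: str) -> Iterator[AlignmentHit]:
    """Yield one :class:`AlignmentHit` per SAM record (unmapped included).

    Records pysam cannot parse (e.g. CIGAR/sequence length disagreement)
    surface as ``ValueError``.
    """
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        iterator = iter(sam)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                return
            except OSError as exc:
                raise ValueError(f"malformed SAM record in {path}: {exc}") from exc
            yield _hit_from_pysam(rec)


def read_sam_with_quals(path: str) -> Iterator[tuple[AlignmentHit, Optional[tuple[int, ...]]]]:
    """Like :func:`read_sam` but also yields per-base qualities (SAM
    orientation, as stored), for divergence estimation."""
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            quals = tuple(rec.query_qualities) if rec.query_qualities is not None else None
            yield _hit_from_pysam(rec), quals


def write_sam(
    hits: Iterable[AlignmentHit],
    path: str,
    references: Mapping[str, int],
    qualities: Optional[Mapping[str, tuple[int, ...]]] = None,
) -> None:
    """Write hits as a text SAM with @SQ lines from ``references``
    (name -> length).  Re-reading reproduces every field bit-exactly."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for hit in hits:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = hit.read_id
            flag = 0
            if hit.uniqueness is Uniqueness.UNMAPPED:
                flag |= 0x4
            if hit.strand is Strand.REVERSE:
                flag |= 0x10
            if hit.is_duplicate:
                flag |= 0x400
            rec.flag = flag
            rec.mapping_quality = hit.mapq
            if hit.reference_name is not None:
                rec.reference_id = out.header.get_tid(hit.reference_name)
                rec.reference_start = hit.position - 1
                rec.cigartuples = [(_CIGAR_OPS.index(op), n) for op, n in hit.cigar]
            if hit.sam_seq is not None:
                rec.query_sequence = hit.sam_seq
                if qualities is not None and hit.read_id in qualities:
                    rec.query_qualities = list(qualities[hit.read_id])
            tags = []
            if hit.nm is not None:
                tags.append(("NM", hit.nm))
            if hit.md is not None:
                tags.append(("MD", hit.md))
            if hit.uniqueness is Uniqueness.UNIQUE:
                tags.append(("XT", "U"))
            elif hit.uniqueness is Uniqueness.REPEAT:
                tags.append(("XT", "R"))
            if hit.best_hits is not None:
                tags.append(("X0", hit.best_hits))
            if hit.alt_hits is not None:
                tags.append(("X1", hit.alt_hits))
            rec.set_tags(tags)
            out.write(rec)


def ensure_exists(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"[{stage}] required input missing: {path}")
    return path
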