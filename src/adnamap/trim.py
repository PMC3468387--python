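"""Selective 5'-end trimming of previously unmapped reads.

Cytosine deamination concentrates in the first one or two read positions,
so reads that failed high-quality classification are trimmed of one or two
5' bases and re-aligned.  Only reads of at least 30 nt before trimming are
considered, to bound the spurious-alignment risk of shortening queries.
After re-alignment, the reference sequence upstream of the new hit reveals
the mismatch each trimmed base *would have caused*, so recovered reads can
be binned by mismatch class (damage class C>T for Illumina, G>A for
Helicos, vs all other classes as controls).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import AlignmentHit, SequenceRead, Strand, complement

DEFAULT_MIN_LENGTH = 30

MATCH = "match"
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class TrimRecord:
    read_id: str
    n_trimmed: int
    trimmed_bases: str
    inferred_ref_bases: Optional[str] = None
    mismatch_classes: Optional[tuple[str, ...]] = None  # per trimmed base

    def __post_init__(self) -> None:
        if self.n_trimmed not in (1, 2):
            raise ValueError("n_trimmed must be 1 or 2")
        if len(self.trimmed_bases) != self.n_trimmed:
            raise ValueError("trimmed_bases length != n_trimmed")
        if self.mismatch_classes is not None and len(self.mismatch_classes) != self.n_trimmed:
            raise ValueError("one mismatch class required per trimmed base")


def trim_candidates(
    unmapped_reads: Iterable[SequenceRead],
    n_bases: int,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[SequenceRead], dict[str, TrimRecord]]:
    """Trim ``n_bases`` from the 5' end of each read of pre-trim length >=
    ``min_length``; shorter reads are dropped.  Returns the trimmed reads
    and stub records carrying the removed bases."""
    if n_bases not in (1, 2):
        raise ValueError("n_bases must be 1 or 2")
    trimmed: list[SequenceRead] = []
    stubs: dict[str, TrimRecord] = {}
    for read in unmapped_reads:
        if len(read) < min_length:
            continue
        quals = read.qualities[n_bases:] if read.qualities is not None else None
        trimmed.append(SequenceRead(read.read_id, read.bases[n_bases:], quals, read.platform))
        stubs[read.read_id] = TrimRecord(read.read_id, n_bases, read.bases[:n_bases])
    return trimmed, stubs


def classify_trimmed(
    stub: TrimRecord,
    post_trim_hit: AlignmentHit,
    reference: Mapping[str, str],
) -> TrimRecord:
    """Determine the mismatch class each trimmed base would have caused.

    The alignment is extended upstream of the read's 5' end by
    ``n_trimmed`` reference bases: positions [pos-k, pos-1] for a forward
    hit; [end+1, end+k] complemented and reversed for a reverse hit, so the
    inferred reference bases line up with the trimmed bases in sequencing
    order.  Positions off the contig edge are unclassifiable.
    """
    name = post_trim_hit.reference_name
    if name not in reference:
        raise KeyError(f"reference sequence {name!r} not found")
    seq = reference[name]
    k = stub.n_trimmed
    if post_trim_hit.strand is Strand.FORWARD:
        start = post_trim_hit.position - k  # 1-based
        if start < 1:
            ref_bases = None
        else:
            ref_bases = seq[start - 1 : start - 1 + k]
    else:
        end = post_trim_hit.reference_end
        if end + k > len(seq):
            ref_bases = None
        else:
            ref_bases = complement(seq[end : end + k])[::-1]
    if ref_bases is None or len(ref_bases) != k:
        classes = tuple([UNCLASSIFIABLE] * k)
        inferred = None
    else:
        classes = []
        for ref_base, read_base in zip(ref_bases, stub.trimmed_bases):
            if ref_base not in "ACGT" or read_base not in "ACGT":
                classes.append(UNCLASSIFIABLE)
            elif ref_base == read_base:
                classes.append(MATCH)
            else:
                classes.append(f"{ref_base}>{read_base}")
        classes = tuple(classes)
        inferred = ref_bases
    return TrimRecord(stub.read_id, k, stub.trimmed_bases, inferred, classes)


def _bin_of(record: TrimRecord) -> str:
    """Bin key for a classified record: the shared class when all trimmed
    bases agree (the 'two consecutive identical mismatches' reading),
    otherwise 'mixed'."""
    if record.mismatch_classes is None:
        return UNCLASSIFIABLE
    classes = set(record.mismatch_classes)
    return record.mismatch_classes[0] if len(classes) == 1 else "mixed"


def gain_report(
    trim_records: Iterable[TrimRecord],
    hq_after_trim: set[str],
    baseline_hq_count: int,
    damage_class: str = "C>T",
    require_all: bool = True,
) -> pd.DataFrame:
    """Bin newly-hq reads by the mismatch class their trimmed bases would
    have caused.

    One row per bin with the count of recovered reads and its fraction of
    the baseline hq count.  ``require_all`` demands every trimmed base be
    the damage class for the damage bin (default, per the consecutive-
    mismatch reading); with ``require_all=False`` records where at least
    one trimmed base is the damage class land in the damage bin instead.
    """
    bins: Counter = Counter()
    for record in trim_records:
        if record.read_id not in hq_after_trim:
            continue
        if not require_all and record.mismatch_classes is not None:
            if damage_class in record.mismatch_classes:
                bins[damage_class] += 1
                continue
        bins[_bin_of(record)] += 1
    rows = [
        (cls, cls == damage_class, count, count / baseline_hq_count if baseline_hq_count else 0.0)
        for cls, count in sorted(bins.items())
    ]
    return pd.DataFrame(rows, columns=["bin", "is_damage_class", "count", "gain_fraction"])


def conservative_posttrim_filter(
    untrimmed_contaminant_hits: Iterable[AlignmentHit],
    trimmed_contaminant_hits: Iterable[AlignmentHit],
    candidates: Iterable[str],
) -> set[str]:
    """Exclude a candidate when either its untrimmed or trimmed version
    maps to the contaminant genome."""
    mapped = {h.read_id for h in untrimmed_contaminant_hits if h.mapped}
    mapped |= {h.read_id for h in trimmed_contaminant_hits if h.mapped}
    return {rid for rid in candidates if rid not in mapped}
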