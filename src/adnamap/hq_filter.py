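"""High-quality-hit classification and two-genome contamination filtering.

A *high-quality (hq) endogenous hit* maps to a unique location (XT:A:U),
has no suboptimal alternative hits (X1:i:0), mapping quality >= 25 and is
not a flagged PCR duplicate.  Putative contamination is removed either by
the strict criterion (discard any read that also yields a qualifying hit on
the contaminant genome) or by the best-hit criterion (discard only when the
edit distance to the target genome is greater than or equal to the edit
distance to the contaminant genome).  Spurious-alignment levels are
monitored by mapping against a distant outgroup genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

from .model import AlignmentHit, SequenceRead, Uniqueness

DEFAULT_MAPQ_MIN = 25


class HitStatus(str, Enum):
    HQ_ENDOGENOUS = "hq_endogenous"
    FILTERED_CONTAMINANT = "filtered_contaminant"
    NON_UNIQUE = "non_unique"
    LOW_MAPQ = "low_mapq"
    DUPLICATE = "duplicate"
    UNMAPPED = "unmapped"


class ContaminantMode(str, Enum):
    #: any mapped contaminant hit disqualifies, even repeats/paralogs
    #: (the conservative mode used for Illumina data)
    ANY_HIT = "any_hit"
    #: only contaminant hits that are themselves high-quality disqualify
    HQ_HIT = "hq_hit"


@dataclass
class HitClassification:
    read_id: str
    status: HitStatus
    reason: str
    target_nm: Optional[int] = None
    contaminant_nm: Optional[int] = None


def classify_hit(
    hit: AlignmentHit,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    exclude_duplicates: bool = True,
) -> HitClassification:
    """Classify a single alignment against the hq-endogenous definition."""
    if hit.uniqueness is Uniqueness.UNMAPPED:
        return HitClassification(hit.read_id, HitStatus.UNMAPPED, "unmapped")
    if exclude_duplicates and hit.is_duplicate:
        return HitClassification(hit.read_id, HitStatus.DUPLICATE, "flagged PCR duplicate")
    if hit.uniqueness is not Uniqueness.UNIQUE:
        label = "XT tag absent" if hit.uniqueness is None else f"XT={hit.uniqueness.value}"
        return HitClassification(hit.read_id, HitStatus.NON_UNIQUE, label, hit.nm)
    if hit.alt_hits is None:
        # absent X1 cannot confirm "no suboptimal alternative hits"
        return HitClassification(hit.read_id, HitStatus.NON_UNIQUE, "X1 tag absent", hit.nm)
    if hit.alt_hits != 0:
        return HitClassification(
            hit.read_id, HitStatus.NON_UNIQUE, f"X1={hit.alt_hits} suboptimal hits", hit.nm
        )
    if hit.mapq < mapq_min:
        return HitClassification(
            hit.read_id, HitStatus.LOW_MAPQ, f"MAPQ {hit.mapq} < {mapq_min}", hit.nm
        )
    return HitClassification(hit.read_id, HitStatus.HQ_ENDOGENOUS, "hq", hit.nm)


def _index_hits(hits: Iterable[AlignmentHit], label: str) -> dict[str, AlignmentHit]:
    index: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.read_id in index:
            raise ValueError(f"duplicate read id {hit.read_id!r} in {label} alignments")
        index[hit.read_id] = hit
    return index


def _hq_ids(
    hits: Mapping[str, AlignmentHit], mapq_min: int, exclude_duplicates: bool
) -> set[str]:
    return {
        rid
        for rid, hit in hits.items()
        if classify_hit(hit, mapq_min, exclude_duplicates).status is HitStatus.HQ_ENDOGENOUS
    }


def strict_filter(
    target_hits: Iterable[AlignmentHit],
    contaminant_hits: Iterable[AlignmentHit],
    contaminant_mode: ContaminantMode | str = ContaminantMode.ANY_HIT,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    exclude_duplicates: bool = True,
) -> set[str]:
    """Target-hq reads with no qualifying hit on the contaminant genome.

    Duplicate flags on contaminant alignments are ignored (they are only
    trusted on the merged target alignments).
    """
    contaminant_mode = ContaminantMode(contaminant_mode)
    target = _index_hits(target_hits, "target")
    contaminant = _index_hits(contaminant_hits, "contaminant")
    hq = _hq_ids(target, mapq_min, exclude_duplicates)
    if contaminant_mode is ContaminantMode.ANY_HIT:
        disqualifying = {rid for rid, hit in contaminant.items() if hit.mapped}
    else:
        disqualifying = _hq_ids(contaminant, mapq_min, exclude_duplicates=False)
    return hq - disqualifying


def besthit_filter(
    target_hits: Iterable[AlignmentHit],
    contaminant_hits: Iterable[AlignmentHit],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    exclude_duplicates: bool = True,
) -> set[str]:
    """Target-hq reads retained unless their edit distance to the target is
    greater than or equal to their edit distance to the contaminant.

    Ties are filtered (conservative).  Reads with no mapped contaminant hit
    are always retained.  NM must be present on every compared hit.
    """
    target = _index_hits(target_hits, "target")
    contaminant = _index_hits(contaminant_hits, "contaminant")
    hq = _hq_ids(target, mapq_min, exclude_duplicates)
    retained: set[str] = set()
    for rid in hq:
        chit = contaminant.get(rid)
        if chit is None or not chit.mapped:
            retained.add(rid)
            continue
        tnm = target[rid].nm
        cnm = chit.nm
        if tnm is None or cnm is None:
            raise ValueError(f"read {rid!r}: NM missing on a compared hit")
        if tnm < cnm:
            retained.add(rid)
    return retained


def classify_against_contaminant(
    target_hits: Iterable[AlignmentHit],
    contaminant_hits: Iterable[AlignmentHit],
    contaminant_mode: ContaminantMode | str = ContaminantMode.ANY_HIT,
    best_hit: bool = False,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    exclude_duplicates: bool = True,
) -> list[HitClassification]:
    """Per-read classifications including contaminant filtering, for the
    per-read TSV report."""
    contaminant_mode = ContaminantMode(contaminant_mode)
    target = _index_hits(target_hits, "target")
    contaminant = _index_hits(contaminant_hits, "contaminant")
    if best_hit:
        retained = besthit_filter(
            target.values(), contaminant.values(), mapq_min, exclude_duplicates
        )
    else:
        retained = strict_filter(
            target.values(), contaminant.values(), contaminant_mode, mapq_min, exclude_duplicates
        )
    out: list[HitClassification] = []
    for rid, hit in target.items():
        cls = classify_hit(hit, mapq_min, exclude_duplicates)
        chit = contaminant.get(rid)
        cls.contaminant_nm = chit.nm if chit is not None and chit.mapped else None
        if cls.status is HitStatus.HQ_ENDOGENOUS and rid not in retained:
            cls.status = HitStatus.FILTERED_CONTAMINANT
            cls.reason = (
                "edit distance to contaminant <= target"
                if best_hit
                else "qualifying contaminant hit"
            )
        out.append(cls)
    return out


def spurious_rate(
    reads: Iterable[SequenceRead],
    outgroup_hits: Iterable[AlignmentHit],
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> tuple[int, float, Counter]:
    """Fraction of reads yielding hq hits on a distant outgroup genome,
    with the length histogram of those reads (spurious-alignment monitor)."""
    lengths = {r.read_id: len(r) for r in reads}
    hq = {
        hit.read_id
        for hit in outgroup_hits
        if classify_hit(hit, mapq_min, exclude_duplicates=False).status
        is HitStatus.HQ_ENDOGENOUS
    }
    hq &= set(lengths)
    count = len(hq)
    rate = count / len(lengths) if lengths else 0.0
    histogram = Counter(lengths[rid] for rid in hq)
    return count, rate, histogram
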