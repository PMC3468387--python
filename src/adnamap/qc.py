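"""Pre-mapping read quality control (Illumina-style).

Residual 3' adapter removal, terminal low-quality trimming, first-base
filtering and a minimum-length cut.  Reads shorter than 25 nt are discarded
by default to limit spurious alignments downstream.  Quality-free (Helicos)
reads pass through the quality-based steps unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .model import SequenceRead


@dataclass
class QcConfig:
    min_length: int = 25
    min_start_quality: int = 10
    trim_end_quality: int = 2
    adapters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_start_quality < 0 or self.trim_end_quality < 0:
            raise ValueError("quality thresholds must be >= 0")


def _find_adapter(bases: str, adapter: str, min_overlap: int = 8) -> int:
    """Leftmost position i such that bases[i:] equals a prefix of the
    adapter of length >= min_overlap; len(bases) if none."""
    n = len(bases)
    for i in range(0, n - min_overlap + 1):
        tail = n - i
        if tail <= len(adapter) and bases[i:] == adapter[:tail]:
            return i
    return n


def quality_trim(read: SequenceRead, cfg: QcConfig) -> SequenceRead:
    """Remove a 3' adapter occurrence then strip terminal bases with
    BQ <= trim_end_quality from both ends.  Quality-free reads are returned
    unchanged (adapter trimming still applies)."""
    bases = read.bases
    quals = read.qualities
    cut = min((_find_adapter(bases, a) for a in cfg.adapters), default=len(bases))
    bases = bases[:cut]
    if quals is not None:
        quals = quals[:cut]
        lo, hi = 0, len(bases)
        while lo < hi and quals[lo] <= cfg.trim_end_quality:
            lo += 1
        while hi > lo and quals[hi - 1] <= cfg.trim_end_quality:
            hi -= 1
        bases, quals = bases[lo:hi], quals[lo:hi]
    return SequenceRead(read.read_id, bases, quals, read.platform)


def start_filter(read: SequenceRead, cfg: QcConfig) -> bool:
    """Accept the read unless its first base is undetermined (N) or below
    the minimum start quality.  Quality-free reads are judged on N only."""
    if not read.bases:
        return False
    if read.bases[0] == "N":
        return False
    if read.qualities is not None and read.qualities[0] < cfg.min_start_quality:
        return False
    return True


def length_filter(reads: Iterable[SequenceRead], min_length: int) -> Iterator[SequenceRead]:
    """Retain reads with length >= min_length, preserving order."""
    return (r for r in reads if len(r) >= min_length)


@dataclass
class QcSummary:
    n_input: int = 0
    n_failed_start: int = 0
    n_too_short: int = 0
    n_passed: int = 0

    def to_tsv(self) -> str:
        rows = [
            ("input", self.n_input),
            ("failed_start_filter", self.n_failed_start),
            ("shorter_than_minimum", self.n_too_short),
            ("passed", self.n_passed),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def qc_pass(
    reads: Iterable[SequenceRead], cfg: QcConfig, summary: QcSummary | None = None
) -> Iterator[SequenceRead]:
    """Full QC pass: adapter/quality trim, start filter, length filter.

    Idempotent: a second application leaves survivors unchanged.
    """
    for read in reads:
        if summary is not None:
            summary.n_input += 1
        trimmed = quality_trim(read, cfg)
        if not start_filter(trimmed, cfg):
            if summary is not None:
                summary.n_failed_start += 1
            continue
        if len(trimmed) < cfg.min_length:
            if summary is not None:
                summary.n_too_short += 1
            continue
        if summary is not None:
            summary.n_passed += 1
        yield trimmed
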