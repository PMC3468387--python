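"""Damage-aware divergence estimation against a modern reference.

Raw mismatch counts between ancient reads and a reference conflate true
lineage divergence with sequencing error and post-mortem deamination
(GC->AT).  Restricting to high-base-quality sites suppresses sequencing
error; damage is excluded by dropping the GC->AT transition classes and
doubling the reciprocal AT->GC classes, which true divergence produces
symmetrically:

    divergence = (transversions + indel bases + 2 * AT->GC) / n_sites

computed per base-quality threshold, optionally masking positions near the
read ends where damage concentrates.  Helicos reads carry no base
qualities and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .model import AlignedColumnSeries, ColumnEvent

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
AT_TO_GC = {("A", "G"), ("T", "C")}
GC_TO_AT = {("C", "T"), ("G", "A")}


@dataclass
class DivergenceEstimate:
    bq_threshold: int
    end_mask: int
    n_sites: int
    n_transversions: int
    n_indel_bases: int
    n_AT_to_GC: int
    n_GC_to_AT: int

    @property
    def divergence(self) -> float:
        return (self.n_transversions + self.n_indel_bases + 2 * self.n_AT_to_GC) / self.n_sites

    @property
    def gc_to_at_rate(self) -> float:
        return self.n_GC_to_AT / self.n_sites


def estimate_divergence(
    column_series_stream: Iterable[AlignedColumnSeries],
    bq_threshold: int = 35,
    end_mask: int = 0,
    bq_upper: Optional[int] = None,
) -> Optional[DivergenceEstimate]:
    """Estimate divergence over columns with BQ >= ``bq_threshold``,
    excluding positions within ``end_mask`` of either read end.

    ``bq_upper`` restricts to BQ < bq_upper (per-bin curves); the default
    cumulative-threshold semantics leave it unset.  Indel bases are counted
    per inserted/deleted base when outside the mask, without a BQ condition
    (deleted bases carry none).  Returns None when no site qualifies.
    """
    n_sites = n_tv = n_indel = n_at_gc = n_gc_at = 0
    for series in column_series_stream:
        length = series.read_length
        for col in series.columns:
            if col.read_pos <= end_mask or col.read_pos > length - end_mask:
                continue
            if col.event in (ColumnEvent.INSERTION, ColumnEvent.DELETION):
                n_indel += 1
                continue
            if col.event is ColumnEvent.SOFTCLIP:
                continue
            if col.ref_base not in "ACGT" or col.read_base not in "ACGT":
                continue
            if col.base_quality is None:
                raise ValueError(
                    f"read {series.read_id!r}: aligned column without base "
                    "quality; quality-free (Helicos) input cannot be used"
                )
            if col.base_quality < bq_threshold:
                continue
            if bq_upper is not None and col.base_quality >= bq_upper:
                continue
            n_sites += 1
            if col.event is ColumnEvent.MISMATCH:
                pair = (col.ref_base, col.read_base)
                if pair not in TRANSITIONS:
                    n_tv += 1
                elif pair in AT_TO_GC:
                    n_at_gc += 1
                else:
                    n_gc_at += 1
    if n_sites == 0:
        return None
    return DivergenceEstimate(bq_threshold, end_mask, n_sites, n_tv, n_indel, n_at_gc, n_gc_at)


def divergence_curve(
    column_series: Sequence[AlignedColumnSeries],
    bq_grid: Sequence[int],
    end_mask: int = 0,
    mode: str = "cumulative",
) -> list[Optional[DivergenceEstimate]]:
    """One estimate per threshold of an ascending BQ grid (the paired
    divergence / GC->AT-rate curves).

    ``mode='cumulative'`` uses BQ >= threshold; ``mode='bin'`` uses
    threshold <= BQ < next grid value.
    """
    if not bq_grid:
        raise ValueError("bq_grid must be non-empty")
    if list(bq_grid) != sorted(bq_grid):
        raise ValueError("bq_grid must be ascending")
    series = list(column_series)
    estimates = []
    for i, threshold in enumerate(bq_grid):
        upper = None
        if mode == "bin":
            upper = bq_grid[i + 1] if i + 1 < len(bq_grid) else None
        elif mode != "cumulative":
            raise ValueError(f"unknown mode {mode!r}")
        estimates.append(estimate_divergence(series, threshold, end_mask, bq_upper=upper))
    return estimates


def mapping_count_test(counts: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table
    of read counts, e.g. parameter set x reference genome."""
    (a, b), (c, d) = counts
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be >= 0")
    n = sum(cells)
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("both margins must be positive")
    chi2 = 0.0
    for obs, (row, col) in zip(cells, [(0, 0), (0, 1), (1, 0), (1, 1)]):
        expected = margins[row] * margins[2 + col] / n
        chi2 += (obs - expected) ** 2 / expected
    return chi2, float(stats.chi2.sf(chi2, df=1))
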