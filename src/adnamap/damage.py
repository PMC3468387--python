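"""Position-specific misincorporation, indel and clip rates at read termini.

Post-mortem cytosine deamination leaves a characteristic excess of C->T
mismatches at the 5' ends of Illumina reads (read as G->A at 5' ends of
Helicos tSMS reads, whose chemistry sequences the complementary strand),
mirrored by G->A at Illumina 3' ends.  Rates follow the mapDamage
methodology: substitution rates divide the mismatches observed at each
position by the number of reference bases of the substituted class observed
there; insertion, deletion and soft-clip rates divide the affected bases by
the total read depth at the position.  15 positions are profiled from each
end by default.

All positions are in read orientation (position 1 = sequencing 5' end); the
3' block is indexed 1..window counting inward from the 3' terminus and
reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlignedColumnSeries, ColumnEvent, Platform

DEFAULT_WINDOW = 15

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Damage classes by platform: (5' class, 3' class or None).
PLATFORM_DAMAGE_CLASS = {
    Platform.ILLUMINA: (("C", "T"), ("G", "A")),
    Platform.HELICOS: (("G", "A"), None),
}


@dataclass
class MisincorporationTable:
    """Terminal misincorporation counts and rates.

    Arrays are indexed [end][position-1][...] with end 0 = 5', end 1 = 3'.
    ``sub_counts[e, p, r, q]`` counts aligned columns with reference base r
    read as q; ``ref_counts[e, p, r]`` is the substitution-rate denominator;
    ``depth[e, p]`` the indel/clip denominator.  N-containing columns are
    excluded throughout.  A (pos5, pos3) joint histogram of mismatch columns
    supports double-count-free cumulative terminal statistics, alongside
    whole-read totals per substitution class.
    """

    window: int = DEFAULT_WINDOW
    n_reads: int = 0
    sub_counts: np.ndarray = field(default=None)  # (2, window, 4, 4)
    ref_counts: np.ndarray = field(default=None)  # (2, window, 4)
    depth: np.ndarray = field(default=None)  # (2, window)
    ins_counts: np.ndarray = field(default=None)  # (2, window)
    del_counts: np.ndarray = field(default=None)  # (2, window)
    clip_counts: np.ndarray = field(default=None)  # (2, window)
    # mismatch columns binned by (min(pos5, window+1), min(pos3, window+1)),
    # split into GC->AT (C>T or G>A) vs other classes
    joint_gc_at: np.ndarray = field(default=None)  # (window+1, window+1)
    joint_other: np.ndarray = field(default=None)  # (window+1, window+1)
    class_totals: dict = field(default_factory=dict)  # "C>T" -> whole-read count

    def __post_init__(self) -> None:
        w = self.window
        if self.sub_counts is None:
            self.sub_counts = np.zeros((2, w, 4, 4), dtype=np.int64)
            self.ref_counts = np.zeros((2, w, 4), dtype=np.int64)
            self.depth = np.zeros((2, w), dtype=np.int64)
            self.ins_counts = np.zeros((2, w), dtype=np.int64)
            self.del_counts = np.zeros((2, w), dtype=np.int64)
            self.clip_counts = np.zeros((2, w), dtype=np.int64)
            self.joint_gc_at = np.zeros((w + 1, w + 1), dtype=np.int64)
            self.joint_other = np.zeros((w + 1, w + 1), dtype=np.int64)

    # -- accessors ---------------------------------------------------------
    def substitution_rate(self, end: str, pos: int, ref: str, read: str) -> Optional[float]:
        e = _end_index(end)
        denom = self.ref_counts[e, pos - 1, _BASE_INDEX[ref]]
        if denom == 0:
            return None
        return float(self.sub_counts[e, pos - 1, _BASE_INDEX[ref], _BASE_INDEX[read]] / denom)

    def _depth_rate(self, counts: np.ndarray, end: str, pos: int) -> Optional[float]:
        e = _end_index(end)
        denom = self.depth[e, pos - 1]
        if denom == 0:
            return None
        return float(counts[e, pos - 1] / denom)

    def insertion_rate(self, end: str, pos: int) -> Optional[float]:
        return self._depth_rate(self.ins_counts, end, pos)

    def deletion_rate(self, end: str, pos: int) -> Optional[float]:
        return self._depth_rate(self.del_counts, end, pos)

    def softclip_rate(self, end: str, pos: int) -> Optional[float]:
        return self._depth_rate(self.clip_counts, end, pos)

    def damage_rate(self, platform: Platform, pos: int = 1, end: str = "5p") -> Optional[float]:
        """Platform damage-class rate: Illumina 5' C>T / 3' G>A; Helicos 5'
        G>A."""
        five, three = PLATFORM_DAMAGE_CLASS[Platform(platform)]
        cls = five if end == "5p" else three
        if cls is None:
            raise ValueError(f"no {end} damage class for platform {platform}")
        return self.substitution_rate(end, pos, *cls)

    def total_mismatches(self) -> int:
        return int(self.joint_gc_at.sum() + self.joint_other.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per end x position x rate class."""
        rows = []
        for e, end in enumerate(("5p", "3p")):
            for p in range(1, self.window + 1):
                for r in _BASES:
                    for q in _BASES:
                        if r == q:
                            continue
                        denom = int(self.ref_counts[e, p - 1, _BASE_INDEX[r]])
                        count = int(self.sub_counts[e, p - 1, _BASE_INDEX[r], _BASE_INDEX[q]])
                        rows.append(
                            (end, p, f"{r}>{q}", count, denom, count / denom if denom else np.nan)
                        )
                depth = int(self.depth[e, p - 1])
                for name, arr in (
                    ("insertion", self.ins_counts),
                    ("deletion", self.del_counts),
                    ("softclip", self.clip_counts),
                ):
                    count = int(arr[e, p - 1])
                    rows.append((end, p, name, count, depth, count / depth if depth else np.nan))
        return pd.DataFrame(
            rows, columns=["end", "position", "class", "count", "denominator", "rate"]
        )


def _end_index(end: str) -> int:
    if end in ("5p", "5'", "5"):
        return 0
    if end in ("3p", "3'", "3"):
        return 1
    raise ValueError(f"unknown end {end!r}")


def accumulate_profile(
    series_stream: Iterable[AlignedColumnSeries], window: int = DEFAULT_WINDOW
) -> MisincorporationTable:
    """Accumulate a misincorporation table over aligned column series.

    Columns must already be in read orientation (the reconstruction
    contract).  Soft clips are excluded from substitution denominators and
    tracked as their own rate class; columns with N in read or reference are
    excluded from numerators and denominators alike.  Deletion columns do
    not contribute to read depth (no read base exists at the position).
    """
    table = MisincorporationTable(window=window)
    for series in series_stream:
        table.n_reads += 1
        length = series.read_length
        for p in range(1, min(window, length) + 1):
            table.depth[0, p - 1] += 1
        for p in range(1, min(window, length) + 1):
            table.depth[1, p - 1] += 1
        for col in series.columns:
            pos5 = col.read_pos
            pos3 = length - col.read_pos + 1
            ends = []
            if pos5 <= window:
                ends.append((0, pos5))
            if pos3 <= window:
                ends.append((1, pos3))
            if col.event is ColumnEvent.DELETION:
                # read_pos of a deletion is the following read base; depth
                # denominators count read bases, deletions only numerators
                for e, p in ends:
                    if 1 <= p <= window:
                        table.del_counts[e, p - 1] += 1
                continue
            if col.event is ColumnEvent.INSERTION:
                for e, p in ends:
                    table.ins_counts[e, p - 1] += 1
                continue
            if col.event is ColumnEvent.SOFTCLIP:
                for e, p in ends:
                    table.clip_counts[e, p - 1] += 1
                continue
            # aligned column (match or mismatch)
            if col.ref_base not in _BASE_INDEX or col.read_base not in _BASE_INDEX:
                continue  # N in read or reconstructed reference
            r = _BASE_INDEX[col.ref_base]
            q = _BASE_INDEX[col.read_base]
            for e, p in ends:
                table.ref_counts[e, p - 1, r] += 1
                table.sub_counts[e, p - 1, r, q] += 1
            if col.event is ColumnEvent.MISMATCH:
                cls = f"{col.ref_base}>{col.read_base}"
                table.class_totals[cls] = table.class_totals.get(cls, 0) + 1
                i5 = min(pos5, window + 1) - 1
                i3 = min(pos3, window + 1) - 1
                if cls in ("C>T", "G>A"):
                    table.joint_gc_at[i5, i3] += 1
                else:
                    table.joint_other[i5, i3] += 1
    return table


def cumulative_terminal_damage(
    table: MisincorporationTable, n_terminal: int = 5, ends: str = "both"
) -> Optional[float]:
    """Fraction of all mismatches that are GC->AT (C>T or G>A) within the
    terminal ``n_terminal`` positions.

    ``ends='both'`` pools the 5' and 3' windows (each mismatch counted
    once); ``ends='5p'`` restricts to the 5' window.  Returns None when no
    mismatches were observed.
    """
    if n_terminal > table.window:
        raise ValueError("n_terminal exceeds the profiled window")
    total = table.total_mismatches()
    if total == 0:
        return None
    j = table.joint_gc_at
    if ends == "both":
        terminal = int(j[:n_terminal, :].sum() + j[n_terminal:, :n_terminal].sum())
    elif ends == "5p":
        terminal = int(j[:n_terminal, :].sum())
    else:
        raise ValueError(f"unknown ends {ends!r}")
    return terminal / total


@dataclass
class LengthCorrelation:
    pearson_r: Optional[float]
    p_value: Optional[float]
    per_length: pd.DataFrame  # columns: length, mismatches, ref_bases, rate
    degenerate: bool = False


def damage_length_correlation(
    series_stream: Iterable[AlignedColumnSeries],
    damage_class: tuple[str, str] = ("G", "A"),
) -> LengthCorrelation:
    """Correlation between 5'-position-1 damage-class rate and read length.

    Damaged reads map less readily when short, so mapped short reads are
    depleted of damage and the rate rises with length.  Requires >= 3
    distinct lengths with defined rates; degenerate (zero-variance) rates
    yield an undefined correlation, flagged rather than fabricated.
    """
    ref, alt = damage_class
    counts: dict[int, list[int]] = {}
    for series in series_stream:
        for col in series.columns:
            if col.read_pos != 1 or col.event not in (ColumnEvent.MATCH, ColumnEvent.MISMATCH):
                continue
            if col.ref_base != ref:
                continue
            entry = counts.setdefault(series.read_length, [0, 0])
            entry[1] += 1
            if col.read_base == alt:
                entry[0] += 1
            break
    rows = [
        (length, mm, n, mm / n)
        for length, (mm, n) in sorted(counts.items())
        if n > 0
    ]
    frame = pd.DataFrame(rows, columns=["length", "mismatches", "ref_bases", "rate"])
    if len(frame) < 3:
        raise ValueError("need >= 3 distinct read lengths with defined rates")
    rates = frame["rate"].to_numpy()
    if np.allclose(rates, rates[0]) or np.allclose(frame["length"], frame["length"][0]):
        return LengthCorrelation(None, None, frame, degenerate=True)
    r, p = stats.pearsonr(frame["length"], frame["rate"])
    return LengthCorrelation(float(r), float(p), frame)


def plot_profile(table: MisincorporationTable, path: str, platform: Platform | None = None) -> None:
    """Dual-panel terminal misincorporation plot (5' left, 3' right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = {
        "C>T": "red",
        "G>A": "blue",
        "insertion": "magenta",
        "deletion": "green",
        "softclip": "orange",
    }
    frame = table.to_frame()
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, end in zip(axes, ("5p", "3p")):
        sub = frame[frame["end"] == end]
        others = (
            sub[~sub["class"].isin(classes)]
            .groupby("position")[["count", "denominator"]]
            .sum()
        )
        for cls, color in classes.items():
            block = sub[sub["class"] == cls].set_index("position")
            ax.plot(block.index, block["rate"], color=color, label=cls)
        with np.errstate(invalid="ignore", divide="ignore"):
            ax.plot(
                others.index,
                others["count"] / others["denominator"],
                color="grey",
                label="other",
            )
        if end == "3p":
            ax.invert_xaxis()
        ax.set_xlabel(f"position from {end} end")
    axes[0].set_ylabel("rate")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
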