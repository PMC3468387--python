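"""BWA ``aln`` parameter modelling for ancient-DNA reads.

BWA caps the edit distance of an alignment as a function of read length:
for a per-base error rate e (0.02 by default) it accepts the smallest k >= 1
such that the upper tail P(X > k) of a Poisson variable with mean e*L falls
below the missing-alignment fraction given by ``-n``.  This module exposes
that construction, the read-length breakpoints it induces, and the
platform-specific parameter sets recommended for ancient-DNA mapping:
seed disabled (``-l 1024``) for Illumina; seed disabled, terminal indels
allowed (``-i 0``), two gap opens (``-o 2``) and a relaxed edit distance
(``-n 0.03``) for Helicos tSMS.  Alignment penalties stay at BWA defaults
(mismatch 3, gap open 11, gap extension 4), which outperformed the
alternatives tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from scipy import stats

from .model import Platform

#: BWA's internal per-base error rate used by the maxdiff construction.
DEFAULT_PER_BASE_ERROR = 0.02

# BWA aln defaults the recommendations are expressed against.
_BWA_DEFAULTS = {
    "seed_length": 32,
    "indel_end_distance": 5,
    "max_gap_opens": 1,
    "gap_open_penalty": 11,
    "gap_extend_penalty": 4,
    "mismatch_penalty": 3,
    "missing_fraction": 0.04,
}


@dataclass(frozen=True)
class AlnParameterSet:
    """A ``bwa aln`` parameter vector.  seed_length 1024 encodes a disabled
    seed (longer than any query)."""

    seed_length: int = 32  # -l
    indel_end_distance: int = 5  # -i
    max_gap_opens: int = 1  # -o
    gap_open_penalty: int = 11  # -O
    gap_extend_penalty: int = 4  # -E
    mismatch_penalty: int = 3  # -M
    missing_fraction: float = 0.04  # -n
    platform: Platform | None = None

    def __post_init__(self) -> None:
        if min(self.gap_open_penalty, self.gap_extend_penalty, self.mismatch_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if not 0 < self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in (0, 1)")
        if self.max_gap_opens < 0:
            raise ValueError("max_gap_opens must be >= 0")

    def command_line(self) -> str:
        """``bwa aln`` invocation carrying every non-default flag exactly
        once."""
        flags = [
            ("-l", self.seed_length, _BWA_DEFAULTS["seed_length"]),
            ("-i", self.indel_end_distance, _BWA_DEFAULTS["indel_end_distance"]),
            ("-o", self.max_gap_opens, _BWA_DEFAULTS["max_gap_opens"]),
            ("-O", self.gap_open_penalty, _BWA_DEFAULTS["gap_open_penalty"]),
            ("-E", self.gap_extend_penalty, _BWA_DEFAULTS["gap_extend_penalty"]),
            ("-M", self.mismatch_penalty, _BWA_DEFAULTS["mismatch_penalty"]),
            ("-n", self.missing_fraction, _BWA_DEFAULTS["missing_fraction"]),
        ]
        parts = ["bwa aln"]
        for flag, value, default in flags:
            if value != default:
                parts.append(f"{flag} {value:g}" if isinstance(value, float) else f"{flag} {value}")
        return " ".join(parts)


def max_edit_distance(
    read_length: int,
    per_base_error: float = DEFAULT_PER_BASE_ERROR,
    missing_fraction: float = 0.04,
) -> int:
    """Maximum edit distance BWA allows for a read of the given length.

    Smallest k >= 1 with P(Poisson(read_length * per_base_error) > k)
    strictly below ``missing_fraction``.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not (0 < per_base_error < 1 and 0 < missing_fraction < 1):
        raise ValueError("probabilities must be in (0, 1)")
    lam = read_length * per_base_error
    for k in range(1, 1000):
        if stats.poisson.sf(k, lam) < missing_fraction:
            return k
    raise RuntimeError("maxdiff search did not converge below k = 1000")


def threshold_table(
    per_base_error: float = DEFAULT_PER_BASE_ERROR,
    missing_fraction: float = 0.04,
    min_len: int = 17,
    max_len: int = 250,
) -> list[tuple[int, int]]:
    """Breakpoints of the maximum edit distance over [min_len, max_len].

    Returns (first_length, max_diff) pairs: the value at min_len followed by
    every length at which the cap increases.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    table: list[tuple[int, int]] = []
    previous: int | None = None
    for length in range(min_len, max_len + 1):
        k = max_edit_distance(length, per_base_error, missing_fraction)
        if k != previous:
            table.append((length, k))
            previous = k
    return table


def recommend_parameters(platform: Platform | str) -> AlnParameterSet:
    """Recommended ancient-DNA mapping parameters for a platform."""
    platform = Platform(platform)
    if platform is Platform.ILLUMINA:
        return AlnParameterSet(seed_length=1024, platform=platform)
    if platform is Platform.HELICOS:
        return AlnParameterSet(
            seed_length=1024,
            indel_end_distance=0,
            max_gap_opens=2,
            missing_fraction=0.03,
            platform=platform,
        )
    raise ValueError(f"unknown platform: {platform}")
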