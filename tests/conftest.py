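"""Shared fixtures: synthetic genomes and alignment-hit factories.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import pytest

from adnamap.model import AlignmentHit, SequenceRead, Strand, Uniqueness
from adnamap.sim import fixture_genomes


@pytest.fixture(scope="session")
def genomes() -> dict[str, str]:
    """Target genome, homologous contaminant (12% diverged outside a
    conserved block) and unrelated outgroup."""
    return fixture_genomes(
        seed=0, target_length=20_000, divergence=0.12, conserved_block=(2_000, 5_000)
    )


def make_hit(
    read_id: str = "r1",
    length: int = 30,
    nm: int = 0,
    mapq: int = 37,
    uniqueness: Uniqueness | None = Uniqueness.UNIQUE,
    alt_hits: int | None = 0,
    is_duplicate: bool = False,
    position: int = 100,
    strand: Strand = Strand.FORWARD,
    reference_name: str = "target",
) -> AlignmentHit:
    """Minimal mapped hit for filter-semantics tests."""
    if uniqueness is Uniqueness.UNMAPPED:
        return AlignmentHit(read_id, None, None, Strand.FORWARD, (), uniqueness=uniqueness)
    return AlignmentHit(
        read_id=read_id,
        reference_name=reference_name,
        position=position,
        strand=strand,
        cigar=(("M", length),),
        md=str(length) if nm == 0 else None,
        nm=nm,
        mapq=mapq,
        uniqueness=uniqueness,
        alt_hits=alt_hits,
        best_hits=1,
        is_duplicate=is_duplicate,
    )


def make_read(
    read_id: str = "r1",
    bases: str = "ACGT" * 8,
    qualities: tuple[int, ...] | int | None = None,
) -> SequenceRead:
    if isinstance(qualities, int):
        qualities = tuple([qualities] * len(bases))
    return SequenceRead(read_id, bases, qualities)
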