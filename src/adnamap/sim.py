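"""Read simulator with platform error profiles and truth alignments.

Reads are sampled from a reference (both strands of each sequence merged,
as a concatenation of the forward sequence and its reverse complement),
with start sites drawn either uniformly or according to a position weight
matrix over the -5..+5 context of observed read starts.  Bases are then
emitted from the start site until the drawn read length is reached, with
fixed per-base rates of insertions (1.5%) and deletions (3%) — the
indel-dominated Helicos tSMS error profile — plus an optional substitution
error rate (0, 0.5, 1.0 or 1.5%), substituting/inserted bases drawn from
the underlying base composition.  Reads containing N, or that would run
off the sampled strand sequence, are discarded and resampled.

An ancient-damage overlay is available as an extension beyond the
error-only model: template C bases within ``max_overhang`` of the 5' end
are read as T with probability p0 * decay**(i-1) at position i, emulating
post-mortem cytosine deamination at overhanging ends (default off).

Every injected event is recorded in a truth record, and truth alignments
can be written as SAM with CIGAR/MD/NM computed from the event list —
against the source genome or against a homologous (substitution-only
diverged) genome, which turns the simulator into a ground-truth oracle for
the profiling, filtering and divergence modules.

Random-stream discipline: every sampling function takes a seed or a
``random.Random`` and touches no other randomness, so output is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import io as adio
from .model import (
    AlignmentHit,
    Platform,
    SequenceRead,
    Strand,
    Uniqueness,
    revcomp,
)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

TRUTH_MAPQ = 37


@dataclass(frozen=True)
class DamageConfig:
    """Geometric 5'-deamination overlay: P(C read as T at position i) =
    p0 * decay**(i-1) for i <= max_overhang."""

    p0: float = 0.0
    decay: float = 0.5
    max_overhang: int = 5

    def probability(self, position: int) -> float:
        if position > self.max_overhang:
            return 0.0
        return self.p0 * self.decay ** (position - 1)


@dataclass
class SimConfig:
    #: uniform [length_min, length_max] unless an empirical histogram
    #: {length: probability} is given
    length_min: int = 25
    length_max: int = 57
    length_distribution: Optional[Mapping[int, float]] = None
    insertion_rate: float = 0.015
    deletion_rate: float = 0.03
    substitution_rate: float = 0.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pwm: Optional[np.ndarray] = None  # (11, 4); None = uniform start sites
    pwm_score: str = "product"  # or "log_odds"
    damage: DamageConfig = field(default_factory=DamageConfig)
    polyT_trim: bool = False  # Helicos TT-start emulation
    platform: Platform = Platform.HELICOS
    quality_high: int = 40  # Illumina two-level quality model
    quality_low: int = 15
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for rate in (self.insertion_rate, self.deletion_rate, self.substitution_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.length_distribution is not None:
            if abs(sum(self.length_distribution.values()) - 1.0) > 1e-9:
                raise ValueError("length_distribution masses must sum to 1")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape != (11, 4):
                raise ValueError("pwm must be 11x4")
            if not np.allclose(self.pwm.sum(axis=1), 1.0):
                raise ValueError("pwm rows must sum to 1")


@dataclass
class SimEvent:
    read_pos: int  # 1-based, read orientation; deletions: following base
    type: str  # substitution | insertion | deletion | deamination
    ref_base: Optional[str]
    read_base: Optional[str]


@dataclass
class SimTruthRecord:
    read_id: str
    source_sequence: str
    strand: Strand
    start: int  # 1-based inclusive, forward reference coordinates
    end: int
    events: tuple[SimEvent, ...]


def random_sequence(length: int, rng: random.Random, gc: float = 0.5) -> str:
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices(_BASES, weights=weights, k=length))


def mutate_sequence(
    seq: str,
    rate: float,
    rng: random.Random,
    protect: Optional[tuple[int, int]] = None,
) -> str:
    """Substitution-only mutation at per-base ``rate``, the alternative
    drawn uniformly from the other three bases.  ``protect`` keeps a
    0-based half-open block identical (a conserved region)."""
    out = list(seq)
    for i, base in enumerate(out):
        if protect is not None and protect[0] <= i < protect[1]:
            continue
        if base in _BASE_INDEX and rng.random() < rate:
            out[i] = rng.choice([b for b in _BASES if b != base])
    return "".join(out)


def fixture_genomes(
    seed: int,
    target_length: int = 20_000,
    divergence: float = 0.10,
    conserved_block: tuple[int, int] = (2_000, 4_000),
    outgroup_length: int = 20_000,
) -> dict[str, str]:
    """Standard test fixture: a target genome, a homologous contaminant at
    controlled divergence containing one conserved (identical) block, and
    an unrelated distant outgroup."""
    rng = random.Random(seed)
    target = random_sequence(target_length, rng)
    contaminant = mutate_sequence(target, divergence, rng, protect=conserved_block)
    outgroup = random_sequence(outgroup_length, rng)
    return {"target": target, "contaminant": contaminant, "outgroup": outgroup}


def diverge_sequence(
    seq: str, divergence: float, rng: random.Random
) -> str:
    """Derive a homologue at an exactly controlled divergence.

    round(L * divergence) distinct sites are substituted: half receive a
    transversion (uniform over the two), half the transition available at
    the site.  With a balanced base composition the two transition
    directions (AT->GC vs GC->AT) occur equally often, matching the
    symmetry the damage-aware divergence statistic assumes.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}
    candidates = [i for i, b in enumerate(seq) if b in _BASE_INDEX]
    n_mut = round(len(seq) * divergence)
    sites = rng.sample(candidates, n_mut)
    out = list(seq)
    for j, i in enumerate(sites):
        base = out[i]
        if j % 2 == 0:
            out[i] = rng.choice(transversions[base])
        else:
            out[i] = transitions[base]
    return "".join(out)


def realized_error_rates(
    reads: Sequence[SequenceRead], truths: Sequence[SimTruthRecord]
) -> dict[str, float]:
    """Realized per-base event frequencies of a simulated read set.

    insertion: inserted bases over emitted bases (every emitted base is one
    insertion draw).  deletion: deleted reference bases over deletion draw
    opportunities — each traversed reference base except the first of every
    read, which anchors the alignment and is not subject to the deletion
    process, plus the deleted bases themselves.  substitution /
    deamination: events over the template-derived read bases eligible for
    the respective draw.
    """
    n_ins = n_del = n_sub = n_deam = 0
    n_emitted = 0
    n_template = 0  # template-derived read bases
    for read, truth in zip(reads, truths):
        n_emitted += len(read.bases)
        ins = sum(1 for e in truth.events if e.type == "insertion")
        n_ins += ins
        n_del += sum(1 for e in truth.events if e.type == "deletion")
        n_sub += sum(1 for e in truth.events if e.type == "substitution")
        n_deam += sum(1 for e in truth.events if e.type == "deamination")
        n_template += len(read.bases) - ins
    kept_draws = n_template - len(reads)  # first consumed base: no draw
    return {
        "insertion": n_ins / n_emitted if n_emitted else 0.0,
        "deletion": n_del / (n_del + kept_draws) if (n_del + kept_draws) else 0.0,
        "substitution": n_sub / (n_template - n_deam) if n_template > n_deam else 0.0,
        "deamination_events": float(n_deam),
        "emitted_bases": float(n_emitted),
        "deletion_opportunities": float(n_del + kept_draws),
    }


# -- PWM start-site model -------------------------------------------------


def build_pwm(contexts: Iterable[str], pseudocount: float = 0.0) -> np.ndarray:
    """Column-wise base frequencies of 11-mer (-5..+5) read-start contexts,
    with an additive pseudocount."""
    counts = np.full((11, 4), float(pseudocount))
    n = 0
    for context in contexts:
        if len(context) != 11 or any(b not in _BASE_INDEX for b in context):
            raise ValueError(f"contexts must be 11-mers over ACGT, got {context!r}")
        for i, base in enumerate(context):
            counts[i, _BASE_INDEX[base]] += 1
        n += 1
    if n == 0 and pseudocount == 0:
        raise ValueError("empty context set with zero pseudocount")
    return counts / counts.sum(axis=1, keepdims=True)


def _context_score(pwm: np.ndarray, context: str, mode: str) -> float:
    score = 1.0
    for i, base in enumerate(context):
        f = pwm[i, _BASE_INDEX[base]]
        score *= (f / 0.25) if mode == "log_odds" else f
    return score


def _max_score(pwm: np.ndarray, mode: str) -> float:
    best = pwm.max(axis=1)
    if mode == "log_odds":
        best = best / 0.25
    return float(np.prod(best))


def sample_start_sites(
    reference: str,
    pwm: Optional[np.ndarray],
    n: int,
    seed: int | random.Random = 0,
    score: str = "product",
) -> list[tuple[int, Strand]]:
    """Sample ``n`` read start sites on a single sequence (both strands),
    with probability proportional to the PWM likelihood of the 11-mer
    context centred on the site.

    Rejection sampling against the maximum attainable score bounds memory;
    a uniform (or None) PWM reduces to uniform sampling.  Returns 1-based
    forward coordinates of the 5' terminus with the strand.
    """
    if len(reference) < 11:
        raise ValueError("reference shorter than the 11-mer PWM context")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    merged = reference + revcomp(reference)
    L = len(reference)
    top = _max_score(pwm, score) if pwm is not None else 1.0
    sites: list[tuple[int, Strand]] = []
    while len(sites) < n:
        p0 = rng.randrange(5, 2 * L - 5)  # 0-based in merged coordinates
        context = merged[p0 - 5 : p0 + 6]
        if "N" in context:
            continue
        if pwm is not None:
            if rng.random() * top >= _context_score(pwm, context, score):
                continue
        if p0 < L:
            sites.append((p0 + 1, Strand.FORWARD))
        else:
            sites.append((2 * L - p0, Strand.REVERSE))
    return sites


# -- read emission --------------------------------------------------------


def _draw_length(cfg: SimConfig, rng: random.Random) -> int:
    if cfg.length_distribution is not None:
        lengths = list(cfg.length_distribution)
        weights = [cfg.length_distribution[l] for l in lengths]
        return rng.choices(lengths, weights=weights, k=1)[0]
    return rng.randint(cfg.length_min, cfg.length_max)


def _draw_base(cfg: SimConfig, rng: random.Random, exclude: Optional[str] = None) -> str:
    while True:
        base = rng.choices(_BASES, weights=cfg.base_composition, k=1)[0]
        if base != exclude:
            return base


def _emit_read(
    template: str, length: int, cfg: SimConfig, rng: random.Random
) -> Optional[tuple[str, list[SimEvent], int]]:
    """Emit one read of ``length`` bases along ``template`` (read
    orientation).  Returns (bases, events, ref_consumed) or None when the
    template is exhausted or an N is met (reject-and-resample).

    Per emitted base, an insertion is decided first (exactly
    Bernoulli(insertion_rate) per read base); otherwise a geometric run of
    deletion draws precedes the consumed template base (exactly
    Bernoulli(deletion_rate) per traversed template base).  Deletions are
    suppressed before the first consumed base: the start site defines the
    first aligned reference position.  The damage overlay is applied to the
    consumed base before the substitution-error draw, and a deaminated base
    is exempt from it, so each read base carries at most one event.
    """
    read: list[str] = []
    events: list[SimEvent] = []
    ref_cursor = 0
    consumed_any = False
    damage_on = cfg.damage.p0 > 0
    while len(read) < length:
        pos = len(read) + 1
        if rng.random() < cfg.insertion_rate:
            base = _draw_base(cfg, rng)
            events.append(SimEvent(pos, "insertion", None, base))
            read.append(base)
            continue
        if consumed_any:
            while rng.random() < cfg.deletion_rate:
                if ref_cursor >= len(template):
                    return None
                ref_base = template[ref_cursor]
                if ref_base == "N":
                    return None
                ref_cursor += 1
                events.append(SimEvent(pos, "deletion", ref_base, None))
        if ref_cursor >= len(template):
            return None
        ref_base = template[ref_cursor]
        ref_cursor += 1
        if ref_base == "N":
            return None
        consumed_any = True
        base = ref_base
        if damage_on and base == "C" and rng.random() < cfg.damage.probability(pos):
            base = "T"
            events.append(SimEvent(pos, "deamination", "C", "T"))
        elif cfg.substitution_rate and rng.random() < cfg.substitution_rate:
            base = _draw_base(cfg, rng, exclude=ref_base)
            events.append(SimEvent(pos, "substitution", ref_base, base))
        read.append(base)
    return "".join(read), events, ref_cursor


def _polyT_trim(
    bases: str, events: list[SimEvent], ref_consumed: int
) -> Optional[tuple[str, list[SimEvent], int, int]]:
    """Emulate the instrument-side trimming of Helicos reads starting with
    two or more thymines (poly-A tail read-through).  Returns the trimmed
    read, shifted events, remaining ref consumption and the reference
    shift of the alignment start; None when nothing is left."""
    k = 0
    while k < len(bases) and bases[k] == "T":
        k += 1
    if k < 2:
        return bases, events, ref_consumed, 0
    if k >= len(bases):
        return None
    insertions_trimmed = 0
    deletions_dropped = 0
    kept: list[SimEvent] = []
    for ev in events:
        if ev.read_pos <= k:
            if ev.type == "insertion":
                insertions_trimmed += 1
            elif ev.type == "deletion":
                deletions_dropped += 1
            continue  # substitution/deamination on a trimmed base: dropped
        if ev.type == "deletion" and ev.read_pos == k + 1:
            deletions_dropped += 1  # would become a leading deletion
            continue
        kept.append(SimEvent(ev.read_pos - k, ev.type, ev.ref_base, ev.read_base))
    # reference consumed by the trimmed prefix: its template-derived bases
    # plus any deletions inside or immediately after it
    ref_shift = (k - insertions_trimmed) + deletions_dropped
    return bases[k:], kept, ref_consumed - ref_shift, ref_shift


def simulate_reads(
    reference: Mapping[str, str] | str,
    cfg: SimConfig,
    n: int,
    seed: Optional[int] = None,
    read_prefix: str = "sim",
) -> tuple[list[SequenceRead], list[SimTruthRecord]]:
    """Simulate ``n`` reads with truth records.

    ``reference`` is a name -> sequence mapping (or a single sequence,
    named 'ref'); multi-sequence references are sampled proportionally to
    length.  Deterministic under a fixed seed.
    """
    if isinstance(reference, str):
        reference = {"ref": reference}
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(cfg.seed if seed is None else seed)
    names = list(reference)
    lengths = [len(reference[name]) for name in names]
    if min(lengths) < 11:
        raise ValueError("reference sequences must be at least 11 bases")
    max_len = (
        max(cfg.length_distribution) if cfg.length_distribution else cfg.length_max
    )
    if max_len > min(lengths):
        raise ValueError("requested read lengths exceed the reference length")
    reads: list[SequenceRead] = []
    truths: list[SimTruthRecord] = []
    attempts = 0
    while len(reads) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise RuntimeError("simulation rejection rate too high; check inputs")
        name = rng.choices(names, weights=lengths, k=1)[0]
        seq = reference[name]
        L = len(seq)
        ((site, strand),) = sample_start_sites(seq, cfg.pwm, 1, rng, cfg.pwm_score)
        length = _draw_length(cfg, rng)
        if strand is Strand.FORWARD:
            template = seq[site - 1 : site - 1 + 2 * length + 16]
        else:
            q = L - site  # 0-based offset into the reverse-complement strand
            template = revcomp(seq)[q : q + 2 * length + 16]
        emitted = _emit_read(template, length, cfg, rng)
        if emitted is None:
            continue
        bases, events, ref_consumed = emitted
        ref_shift = 0
        if cfg.polyT_trim:
            trimmed = _polyT_trim(bases, events, ref_consumed)
            if trimmed is None or len(trimmed[0]) == 0:
                continue
            bases, events, ref_consumed, ref_shift = trimmed
        if strand is Strand.FORWARD:
            start = site + ref_shift
            end = start + ref_consumed - 1
        else:
            end = site - ref_shift
            start = end - ref_consumed + 1
        if start < 1 or end > L:
            continue
        read_id = f"{read_prefix}_{len(reads):07d}"
        qualities = None
        if cfg.platform is Platform.ILLUMINA:
            error_positions = {
                ev.read_pos for ev in events if ev.type in ("insertion", "substitution")
            }
            qualities = tuple(
                cfg.quality_low if pos in error_positions else cfg.quality_high
                for pos in range(1, len(bases) + 1)
            )
        reads.append(SequenceRead(read_id, bases, qualities, cfg.platform))
        truths.append(SimTruthRecord(read_id, name, strand, start, end, tuple(events)))
    return reads, truths


def simulate_random_reads(
    base_composition: Sequence[float],
    length_distribution: Mapping[int, float] | tuple[int, int],
    n: int,
    seed: int = 0,
    platform: Platform = Platform.HELICOS,
) -> list[SequenceRead]:
    """Null model: i.i.d. reads from a base composition, lengths from an
    empirical distribution with support above 24 bp."""
    rng = random.Random(seed)
    if isinstance(length_distribution, tuple):
        lengths_support = list(range(length_distribution[0], length_distribution[1] + 1))
        weights = [1.0] * len(lengths_support)
    else:
        lengths_support = list(length_distribution)
        weights = [length_distribution[l] for l in lengths_support]
    if min(lengths_support) <= 24:
        raise ValueError("length distribution must be supported above 24 bp")
    reads = []
    for i in range(n):
        length = rng.choices(lengths_support, weights=weights, k=1)[0]
        bases = "".join(rng.choices(_BASES, weights=list(base_composition), k=length))
        reads.append(SequenceRead(f"rand_{i:07d}", bases, None, platform))
    return reads


# -- truth alignments -----------------------------------------------------


def _ops_from_events(length: int, events: Sequence[SimEvent]) -> list[str]:
    """Template-orientation op string per column: M/I per read base with
    deletions interleaved before the read base they precede."""
    deletions = Counter(ev.read_pos for ev in events if ev.type == "deletion")
    insert_at = {ev.read_pos for ev in events if ev.type == "insertion"}
    ops: list[str] = []
    for pos in range(1, length + 1):
        ops.extend(["D"] * deletions.get(pos, 0))
        ops.append("I" if pos in insert_at else "M")
    if deletions.get(length + 1, 0):
        raise ValueError("deletion event beyond the read end")
    return ops


def truth_hits(
    truth_records: Iterable[SimTruthRecord],
    reads: Mapping[str, SequenceRead] | Iterable[SequenceRead],
    reference: Mapping[str, str],
    mapq: int = TRUTH_MAPQ,
) -> list[AlignmentHit]:
    """Construct truth alignments with CIGAR/MD/NM computed from the event
    lists against ``reference``.

    ``reference`` may be the source genome or a homologous genome with
    identical coordinates (substitution-only divergence), which yields
    contamination-fixture hits whose NM reflects the extra divergence.
    """
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r for r in reads}
    hits = []
    for truth in truth_records:
        read = reads[truth.read_id]
        seq = reference[truth.source_sequence]
        reverse = truth.strand is Strand.REVERSE
        fwd = revcomp(read.bases) if reverse else read.bases
        ops = _ops_from_events(len(read.bases), truth.events)
        if reverse:
            ops = ops[::-1]
        cigar: list[tuple[str, int]] = []
        md_parts: list[str] = []
        match_run = 0
        nm = 0
        ref_i = truth.start - 1
        read_i = 0
        i = 0
        while i < len(ops):
            op = ops[i]
            if op == "D":
                j = i
                deleted = []
                while j < len(ops) and ops[j] == "D":
                    deleted.append(seq[ref_i])
                    ref_i += 1
                    j += 1
                md_parts.append(f"{match_run}^{''.join(deleted)}")
                match_run = 0
                nm += len(deleted)
                cigar.append(("D", j - i))
                i = j
                continue
            if op == "I":
                cigar.append(("I", 1))
                nm += 1
                read_i += 1
                i += 1
                continue
            ref_base = seq[ref_i]
            if fwd[read_i] == ref_base:
                match_run += 1
            else:
                md_parts.append(f"{match_run}{ref_base}")
                match_run = 0
                nm += 1
            cigar.append(("M", 1))
            ref_i += 1
            read_i += 1
            i += 1
        md_parts.append(str(match_run))
        if ref_i != truth.end:
            raise ValueError(
                f"read {truth.read_id!r}: event list inconsistent with "
                f"coordinates (ref walk ends at {ref_i}, expected {truth.end})"
            )
        merged: list[tuple[str, int]] = []
        for op, n_op in cigar:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n_op)
            else:
                merged.append((op, n_op))
        hits.append(
            AlignmentHit(
                read_id=truth.read_id,
                reference_name=truth.source_sequence,
                position=truth.start,
                strand=truth.strand,
                cigar=tuple(merged),
                md="".join(md_parts),
                nm=nm,
                mapq=mapq,
                uniqueness=Uniqueness.UNIQUE,
                alt_hits=0,
                best_hits=1,
                sam_seq=fwd,
            )
        )
    return hits


def write_truth_sam(
    truth_records: Iterable[SimTruthRecord],
    reads: Iterable[SequenceRead],
    reference: Mapping[str, str],
    path: str,
    mapq: int = TRUTH_MAPQ,
) -> list[AlignmentHit]:
    """Write truth alignments as SAM (XT:A:U, X0:i:1, X1:i:0, MAPQ 37);
    returns the hits."""
    reads = {r.read_id: r for r in reads}
    hits = truth_hits(truth_records, reads, reference, mapq)
    qualities = {}
    for hit in hits:
        read = reads[hit.read_id]
        if read.qualities is not None:
            quals = read.qualities
            if hit.strand is Strand.REVERSE:
                quals = quals[::-1]
            qualities[hit.read_id] = quals
    adio.write_sam(hits, path, {name: len(s) for name, s in reference.items()}, qualities)
    return hits
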