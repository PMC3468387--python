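"""Read simulator: PWM start sites, error/damage injection, truth SAM."""

from __future__ import annotations

import random
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from adnamap.model import Platform, Strand, revcomp
from adnamap.sim import (
    DamageConfig,
    SimConfig,
    SimEvent,
    SimTruthRecord,
    build_pwm,
    diverge_sequence,
    random_sequence,
    realized_error_rates,
    sample_start_sites,
    simulate_random_reads,
    simulate_reads,
    truth_hits,
)


class TestBuildPwm:
    def test_identical_contexts_concentrate_mass(self):
        pwm = build_pwm(["ACGTACGTACG"] * 20)
        assert pwm[0, 0] == pytest.approx(1.0)  # column 0 all A
        assert np.allclose(pwm.sum(axis=1), 1.0)

    def test_uniform_contexts_approach_quarter(self):
        rng = random.Random(0)
        contexts = ["".join(rng.choices("ACGT", k=11)) for _ in range(10_000)]
        pwm = build_pwm(contexts)
        assert np.allclose(pwm, 0.25, atol=0.02)

    def test_pseudocount_on_empty_input_gives_uniform(self):
        assert np.allclose(build_pwm([], pseudocount=1.0), 0.25)

    def test_empty_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])

    def test_malformed_context_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT"])


class TestSampleStartSites:
    def test_uniform_pwm_uniform_starts(self):
        rng = random.Random(1)
        reference = random_sequence(2_000, rng)
        pwm = np.full((11, 4), 0.25)
        sites = sample_start_sites(reference, pwm, 50_000, seed=2)
        positions = [p for p, _ in sites]
        observed, _ = np.histogram(positions, bins=20, range=(1, len(reference) + 1))
        chi2, p = stats.chisquare(observed)
        assert p > 0.01

    def test_degenerate_pwm_forces_terminal_base(self):
        rng = random.Random(3)
        reference = random_sequence(3_000, rng)
        pwm = np.full((11, 4), 0.25)
        pwm[5] = [0.0, 0.0, 0.0, 1.0]  # position 0 of the read must be T
        merged = reference + revcomp(reference)
        for pos, strand in sample_start_sites(reference, pwm, 200, seed=4):
            if strand is Strand.FORWARD:
                assert reference[pos - 1] == "T"
            else:
                assert merged[2 * len(reference) - pos] == "T"

    def test_determinism_under_seed(self):
        reference = random_sequence(1_000, random.Random(5))
        a = sample_start_sites(reference, None, 100, seed=6)
        b = sample_start_sites(reference, None, 100, seed=6)
        assert a == b

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            sample_start_sites("ACGT", None, 1, seed=0)


class TestSimulateReads:
    def test_error_free_reads_are_reference_substrings(self, genomes):
        cfg = SimConfig(insertion_rate=0.0, deletion_rate=0.0, substitution_rate=0.0)
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 200, seed=1)
        merged = genomes["target"] + revcomp(genomes["target"])
        for read, truth in zip(reads, truths):
            assert truth.events == ()
            assert read.bases in merged
            segment = genomes["target"][truth.start - 1 : truth.end]
            expected = segment if truth.strand is Strand.FORWARD else revcomp(segment)
            assert read.bases == expected

    def test_determinism_under_seed(self, genomes):
        cfg = SimConfig(substitution_rate=0.01)
        a = simulate_reads({"target": genomes["target"]}, cfg, 50, seed=2)
        b = simulate_reads({"target": genomes["target"]}, cfg, 50, seed=2)
        assert a == b

    def test_realized_rates_within_three_sds(self, genomes):
        cfg = SimConfig(substitution_rate=0.005)
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 10_000, seed=3)
        rates = realized_error_rates(reads, truths)
        for key, expected, n in (
            ("insertion", cfg.insertion_rate, rates["emitted_bases"]),
            ("deletion", cfg.deletion_rate, rates["deletion_opportunities"]),
        ):
            sd = (expected * (1 - expected) / n) ** 0.5
            assert abs(rates[key] - expected) < 3 * sd, key

    def test_damage_events_are_ct_on_sequenced_strand(self, genomes):
        cfg = SimConfig(damage=DamageConfig(p0=0.4, decay=0.5, max_overhang=3))
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 500, seed=4)
        deaminations = [
            ev for t in truths for ev in t.events if ev.type == "deamination"
        ]
        assert deaminations
        assert all((ev.ref_base, ev.read_base) == ("C", "T") for ev in deaminations)
        assert all(ev.read_pos <= 3 for ev in deaminations)

    def test_illumina_quality_model_marks_errors_low(self, genomes):
        cfg = SimConfig(substitution_rate=0.02, platform=Platform.ILLUMINA)
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 300, seed=5)
        index = {r.read_id: r for r in reads}
        for truth in truths:
            read = index[truth.read_id]
            error_positions = {
                ev.read_pos for ev in truth.events if ev.type in ("insertion", "substitution")
            }
            for pos, quality in enumerate(read.qualities, start=1):
                assert quality == (cfg.quality_low if pos in error_positions else cfg.quality_high)

    def test_polyT_trim_removes_leading_thymine_runs(self, genomes):
        cfg = SimConfig(polyT_trim=True)
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 400, seed=6)
        assert all(not r.bases.startswith("TT") for r in reads)
        # truth alignments remain consistent after the trim
        hits = truth_hits(truths, reads, {"target": genomes["target"]})
        assert all(h.nm >= 0 for h in hits)

    def test_infeasible_length_rejected(self):
        cfg = SimConfig(length_min=100, length_max=100)
        with pytest.raises(ValueError):
            simulate_reads({"tiny": "ACGTACGTACGTACGT"}, cfg, 1, seed=0)


class TestSimulateRandomReads:
    def test_degenerate_composition(self):
        reads = simulate_random_reads((1, 0, 0, 0), (25, 30), 50, seed=0)
        assert all(set(r.bases) == {"A"} for r in reads)

    def test_lengths_above_24(self):
        reads = simulate_random_reads((0.25, 0.25, 0.25, 0.25), (25, 57), 500, seed=1)
        assert all(len(r) > 24 for r in reads)
        with pytest.raises(ValueError):
            simulate_random_reads((0.25, 0.25, 0.25, 0.25), (20, 57), 1, seed=1)

    def test_composition_converges(self):
        composition = (0.1, 0.4, 0.3, 0.2)
        reads = simulate_random_reads(composition, (25, 57), 5_000, seed=2)
        counts = Counter(b for r in reads for b in r.bases)
        total = sum(counts.values())
        observed = [counts[b] for b in "ACGT"]
        _, p = stats.chisquare(observed, [c * total for c in composition])
        assert p > 0.001


class TestTruthSam:
    def test_event_free_read_plain_cigar_md(self, genomes):
        cfg = SimConfig(insertion_rate=0.0, deletion_rate=0.0)
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 20, seed=7)
        for hit, read in zip(truth_hits(truths, reads, {"target": genomes["target"]}), reads):
            assert hit.cigar == (("M", len(read.bases)),)
            assert hit.md == str(len(read.bases))
            assert hit.nm == 0

    def test_single_substitution_encoded_in_md(self, genomes):
        target = genomes["target"]
        read_bases = target[99:129]
        mutated = "A" if read_bases[9] != "A" else "G"
        read_bases = read_bases[:9] + mutated + read_bases[10:]
        from conftest import make_read

        read = make_read("r", read_bases)
        truth = SimTruthRecord(
            "r", "target", Strand.FORWARD, 100, 129,
            (SimEvent(10, "substitution", target[108], mutated),),
        )
        (hit,) = truth_hits([truth], [read], {"target": target})
        assert hit.nm == 1
        assert hit.md == f"9{target[108]}20"

    def test_inconsistent_coordinates_rejected(self, genomes):
        from conftest import make_read

        read = make_read("r", genomes["target"][:30])
        truth = SimTruthRecord("r", "target", Strand.FORWARD, 1, 31, ())  # end off by one
        with pytest.raises(ValueError, match="inconsistent"):
            truth_hits([truth], [read], {"target": genomes["target"]})


class TestDivergeSequence:
    def test_exact_mutation_count(self):
        seq = random_sequence(10_000, random.Random(8))
        diverged = diverge_sequence(seq, 0.01, random.Random(9))
        differences = sum(1 for a, b in zip(seq, diverged) if a != b)
        assert differences == 100

    def test_transition_transversion_balance(self):
        seq = random_sequence(50_000, random.Random(10))
        diverged = diverge_sequence(seq, 0.02, random.Random(11))
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        n_ts = sum(
            1 for a, b in zip(seq, diverged) if a != b and (a, b) in transitions
        )
        n_mut = sum(1 for a, b in zip(seq, diverged) if a != b)
        assert n_ts == n_mut // 2
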