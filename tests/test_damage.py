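"""Terminal misincorporation profiling and derived damage statistics."""

from __future__ import annotations

import random

import numpy as np
import pytest
from scipy import stats

from adnamap.damage import (
    accumulate_profile,
    cumulative_terminal_damage,
    damage_length_correlation,
)
from adnamap.model import (
    AlignedColumn,
    AlignedColumnSeries,
    ColumnEvent,
    Platform,
)
from adnamap.sim import DamageConfig, SimConfig, simulate_reads, truth_hits
from adnamap.columns import reconstruct_columns


def series_from_strings(read_id, ref, read, quals=None):
    """Build a column series from aligned ref/read strings ('-' = gap)."""
    columns = []
    pos = 0
    for i, (r, q) in enumerate(zip(ref, read)):
        if q == "-":
            columns.append(AlignedColumn(pos + 1, r, None, ColumnEvent.DELETION))
            continue
        pos += 1
        bq = quals[pos - 1] if quals is not None else None
        if r == "-":
            columns.append(AlignedColumn(pos, None, q, ColumnEvent.INSERTION, bq))
        elif r == q:
            columns.append(AlignedColumn(pos, r, q, ColumnEvent.MATCH, bq))
        else:
            columns.append(AlignedColumn(pos, r, q, ColumnEvent.MISMATCH, bq))
    return AlignedColumnSeries(read_id, pos, tuple(columns))


class TestAccumulateProfile:
    def test_substitution_rate_uses_reference_base_denominator(self):
        # 10 reads; position 1 references: 4 C (one read T), 6 A
        series = []
        for i in range(4):
            read = "T" + "A" * 19 if i == 0 else "C" + "A" * 19
            series.append(series_from_strings(f"c{i}", "C" + "A" * 19, read))
        for i in range(6):
            series.append(series_from_strings(f"a{i}", "A" * 20, "A" * 20))
        table = accumulate_profile(series)
        assert table.substitution_rate("5p", 1, "C", "T") == pytest.approx(1 / 4)
        assert table.ref_counts[0, 0, 1] == 4  # C denominator at 5' position 1

    def test_no_mismatches_all_rates_zero(self):
        series = [series_from_strings(f"r{i}", "ACGT" * 8, "ACGT" * 8) for i in range(5)]
        table = accumulate_profile(series)
        assert table.sub_counts.sum() == table.sub_counts.trace(axis1=2, axis2=3).sum()
        assert table.total_mismatches() == 0
        assert cumulative_terminal_damage(table) is None  # absent, not zero

    def test_insertion_rate_is_depth_normalized(self):
        # 2 of 10 reads carry an insertion at read position 3
        series = []
        for i in range(2):
            series.append(series_from_strings(f"i{i}", "AC-GTACGTA", "ACGGTACGTA"))
        for i in range(8):
            series.append(series_from_strings(f"m{i}", "ACGTACGTA", "ACGTACGTA"))
        table = accumulate_profile(series)
        assert table.insertion_rate("5p", 3) == pytest.approx(0.2)
        assert table.depth[0, 2] == 10

    def test_three_prime_block_indexed_inward(self):
        # mismatch at the last base of a 30-nt read: 3' position 1
        ref = "A" * 29 + "G"
        read = "A" * 29 + "T"
        table = accumulate_profile([series_from_strings("r", ref, read)])
        assert table.substitution_rate("3p", 1, "G", "T") == pytest.approx(1.0)
        assert table.substitution_rate("5p", 1, "A", "A") == pytest.approx(1.0)

    def test_n_columns_excluded_everywhere(self):
        table = accumulate_profile([series_from_strings("r", "NCGT", "ACGT")])
        assert table.ref_counts[0, 0].sum() == 0
        assert table.total_mismatches() == 0

    def test_conservation_of_reference_base_counts(self, genomes):
        cfg = SimConfig(substitution_rate=0.01, damage=DamageConfig(p0=0.3))
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 300, seed=3)
        hits = truth_hits(truths, reads, {"target": genomes["target"]})
        index = {r.read_id: r for r in reads}
        table = accumulate_profile(reconstruct_columns(h, index[h.read_id]) for h in hits)
        # at each position, counts conditioned on a reference base sum to
        # that base's denominator
        assert np.array_equal(table.sub_counts.sum(axis=3), table.ref_counts)

    def test_order_invariance(self, genomes):
        cfg = SimConfig(substitution_rate=0.01)
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 100, seed=4)
        hits = truth_hits(truths, reads, {"target": genomes["target"]})
        index = {r.read_id: r for r in reads}
        series = [reconstruct_columns(h, index[h.read_id]) for h in hits]
        shuffled = series[:]
        random.Random(0).shuffle(shuffled)
        a, b = accumulate_profile(series), accumulate_profile(shuffled)
        assert np.array_equal(a.sub_counts, b.sub_counts)
        assert np.array_equal(a.depth, b.depth)


class TestCumulativeTerminalDamage:
    def test_all_terminal_ct(self):
        series = [series_from_strings("r", "C" + "A" * 29, "T" + "A" * 29)]
        assert cumulative_terminal_damage(accumulate_profile(series)) == 1.0

    def test_no_gc_at_among_mismatches(self):
        series = [series_from_strings("r", "A" + "C" * 29, "C" + "C" * 29)]
        assert cumulative_terminal_damage(accumulate_profile(series)) == 0.0

    def test_fraction_of_total_mismatches(self):
        # 8 terminal C>T of 25 total mismatches -> 0.32
        series = []
        for i in range(8):
            series.append(series_from_strings(f"d{i}", "C" + "A" * 29, "T" + "A" * 29))
        for i in range(17):
            ref = "A" * 10 + "A" + "A" * 19
            read = "A" * 10 + "G" + "A" * 19  # interior non-damage mismatch
            series.append(series_from_strings(f"o{i}", ref, read))
        table = accumulate_profile(series)
        assert table.total_mismatches() == 25
        assert cumulative_terminal_damage(table, n_terminal=5) == pytest.approx(8 / 25)

    def test_five_prime_only_option(self):
        series = [
            series_from_strings("a", "C" + "A" * 29, "T" + "A" * 29),
            series_from_strings("b", "A" * 29 + "G", "A" * 29 + "A"),  # 3' G>A
        ]
        table = accumulate_profile(series)
        assert cumulative_terminal_damage(table, ends="both") == 1.0
        assert cumulative_terminal_damage(table, ends="5p") == pytest.approx(0.5)


class TestDamageRecovery:
    def test_deamination_probability_recovered_at_position_1(self, genomes):
        """C>T rate at 5' position 1 estimates the configured p0 within a
        wide sampling band (fine-grained CI checks live with the larger
        acceptance runs)."""
        p0 = 0.25
        cfg = SimConfig(damage=DamageConfig(p0=p0, decay=0.5, max_overhang=3))
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 4000, seed=8)
        hits = truth_hits(truths, reads, {"target": genomes["target"]})
        index = {r.read_id: r for r in reads}
        table = accumulate_profile(reconstruct_columns(h, index[h.read_id]) for h in hits)
        n_c = int(table.ref_counts[0, 0, 1])
        rate = table.substitution_rate("5p", 1, "C", "T")
        assert n_c > 500
        margin = 4 * (p0 * (1 - p0) / n_c) ** 0.5
        assert rate == pytest.approx(p0, abs=margin)

    def test_helicos_damage_class_accessor(self):
        series = [series_from_strings("r", "G" + "A" * 29, "A" + "A" * 29)]
        table = accumulate_profile(series)
        assert table.damage_rate(Platform.HELICOS, pos=1, end="5p") == 1.0
        assert table.damage_rate(Platform.ILLUMINA, pos=1, end="5p") is None  # no C seen


class TestDamageLengthCorrelation:
    @staticmethod
    def _series_with_rates(rates_by_length, n_per_length=100):
        series = []
        for length, rate in rates_by_length.items():
            n_damaged = round(rate * n_per_length)
            for i in range(n_per_length):
                first = "A" if i < n_damaged else "G"
                ref = "G" + "C" * (length - 1)
                read = first + "C" * (length - 1)
                series.append(series_from_strings(f"L{length}_{i}", ref, read))
        return series

    def test_linear_rates_give_r_one(self):
        series = self._series_with_rates({30: 0.10, 40: 0.20, 50: 0.30, 60: 0.40})
        result = damage_length_correlation(series, damage_class=("G", "A"))
        assert result.pearson_r == pytest.approx(1.0)
        assert result.p_value < 0.05

    def test_constant_rates_flagged_degenerate(self):
        series = self._series_with_rates({30: 0.2, 40: 0.2, 50: 0.2})
        result = damage_length_correlation(series, damage_class=("G", "A"))
        assert result.degenerate and result.pearson_r is None

    def test_requires_three_lengths(self):
        series = self._series_with_rates({30: 0.1, 40: 0.2})
        with pytest.raises(ValueError, match="3 distinct"):
            damage_length_correlation(series, damage_class=("G", "A"))

    def test_mapping_bias_fixture_positive_correlation(self, genomes):
        """When short damaged reads are preferentially lost (the edit-
        distance cap bites hardest at short lengths), the observed damage
        rate rises with read length."""
        cfg = SimConfig(
            length_min=25, length_max=60, damage=DamageConfig(p0=0.5, decay=0.3, max_overhang=2)
        )
        reads, truths = simulate_reads({"target": genomes["target"]}, cfg, 4000, seed=9)
        index = {r.read_id: r for r in reads}
        kept = []
        for truth in truths:
            n_events = len(truth.events)
            # mimic a severe length-dependent mismatch budget: 1 mismatch
            # allowed below 40 nt, unlimited above
            if len(index[truth.read_id].bases) < 40 and n_events > 1:
                continue
            kept.append(truth)
        hits = truth_hits(kept, index, {"target": genomes["target"]})
        series = [reconstruct_columns(h, index[h.read_id]) for h in hits]
        result = damage_length_correlation(series, damage_class=("C", "T"))
        assert result.pearson_r is not None and result.pearson_r > 0
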