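"""Burden arithmetic, chromosome distributions and the rank statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scna_atlas.classify import EVENT_COLUMNS
from scna_atlas.errors import DataError
from scna_atlas.genome import ArmInterval, GenomeBuild
from scna_atlas.stats import (
    amp_del_correlations,
    burden_table,
    chrom_distribution,
    class_mix,
    cohort_tables,
    group_comparisons,
    interval_union_bp,
    sample_burden,
    scna_length_stats,
    spearman,
    stars,
    wilcoxon_two_sided,
)

from conftest import raster_union_bp


def events_frame(rows):
    """rows: (sample, chrom, start, end, ratio, direction, cls)"""
    return pd.DataFrame(
        [(s, c, st, en, en - st, r, d, cl) for s, c, st, en, r, d, cl in rows],
        columns=list(EVENT_COLUMNS),
    )


@pytest.fixture()
def flat_build():
    # two chromosomes, 500 Mb each -> analysis length 1000 Mb
    return GenomeBuild(
        chromosomes=[("chr1", 500_000_000), ("chr2", 500_000_000)],
        arms=[
            ArmInterval("chr1", "p", 0, 240_000_000),
            ArmInterval("chr1", "q", 260_000_000, 500_000_000),
            ArmInterval("chr2", "p", 0, 240_000_000),
            ArmInterval("chr2", "q", 260_000_000, 500_000_000),
        ],
    )


class TestSampleBurden:
    def test_empty_sample(self, flat_build):
        b = sample_burden(events_frame([]), flat_build, "S1")
        assert b.pct_genome_amp == 0 and b.pct_genome_del == 0
        assert all(v == 0 for v in b.counts.values())
        assert math.isnan(b.mean_scna_len_amp)

    def test_single_event_percentage(self, flat_build):
        ev = events_frame([("S1", "chr1", 0, 10_000_000, 1.0, "AMP", "SCNA")])
        b = sample_burden(ev, flat_build, "S1")
        assert b.pct_genome_amp == pytest.approx(1.0)  # 10 Mb of 1000 Mb
        assert b.pct_genome_del == 0.0

    def test_overlapping_events_use_union(self, flat_build):
        ev = events_frame(
            [
                ("S1", "chr1", 0, 10_000_000, 1.0, "AMP", "SCNA"),
                ("S1", "chr1", 5_000_000, 15_000_000, 0.9, "AMP", "SCNA"),
            ]
        )
        b = sample_burden(ev, flat_build, "S1")
        assert b.pct_genome_amp == pytest.approx(1.5)  # union 15 Mb, not 20

    def test_union_matches_raster_oracle(self, rng):
        lengths = {"chr1": 100_000, "chr2": 100_000}
        spans = []
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            start = int(rng.integers(0, 99_000))
            end = start + int(rng.integers(1, 1000))
            spans.append((chrom, start, end))
        assert interval_union_bp(spans) == raster_union_bp(spans, lengths)

    def test_percentages_bounded(self, flat_build, rng):
        rows = []
        pos = 0
        for _ in range(50):
            start = pos
            pos += int(rng.integers(1_000_000, 20_000_000))
            end = min(pos, 500_000_000)
            if start >= end:
                break
            rows.append(("S1", "chr1", start, end, 1.0, "AMP", "SCNA"))
            pos += 1000
        b = sample_burden(events_frame(rows), flat_build, "S1")
        assert 0 <= b.pct_genome_amp <= 100


class TestCohortTables:
    def annotate(self, *pairs):
        return dict(pairs)

    def test_single_sample_type_mean_is_value(self, flat_build):
        ev = events_frame([("S1", "chr1", 0, 10_000_000, 1.0, "AMP", "SCNA")])
        burdens = burden_table(ev, flat_build, {"S1": "OV"})
        table = cohort_tables(burdens)
        row = table[table["tumor_type"] == "OV"].iloc[0]
        assert row["n"] == 1
        assert row["mean_n_amp"] == 1.0

    def test_two_sample_mean(self, flat_build):
        rows = [("S1", "chr1", i * 2_000_000, i * 2_000_000 + 1_000_000, 1.0, "AMP", "SCNA") for i in range(2)]
        rows += [("S2", "chr1", i * 2_000_000, i * 2_000_000 + 1_000_000, 1.0, "AMP", "SCNA") for i in range(4)]
        burdens = burden_table(events_frame(rows), flat_build, {"S1": "OV", "S2": "OV"})
        table = cohort_tables(burdens)
        assert table.loc[table["tumor_type"] == "OV", "mean_n_scna"].iloc[0] == 3.0

    def test_pooled_length_stats_match_flat_recomputation(self, rng):
        rows = []
        for i in range(100):
            length = int(rng.integers(10_000, 5_000_000))
            start = i * 6_000_000
            d = "AMP" if rng.random() < 0.5 else "DEL"
            cls = "SCNA" if rng.random() < 0.8 else "INDEL"
            rows.append((f"S{i % 7}", "chr1", start, start + length, 1.0, d, cls))
        ev = events_frame(rows)
        stats_df = scna_length_stats(ev)
        lens = [en - st for _, _, st, en, _, _, cls in rows if cls == "SCNA"]
        row = stats_df[stats_df["direction"] == "ALL"].iloc[0]
        assert row["mean_bp"] == pytest.approx(np.mean(lens))
        assert row["sd_bp"] == pytest.approx(np.std(lens, ddof=1))


class TestClassMix:
    def test_only_scnas(self):
        ev = events_frame([("S1", "chr1", 0, 1_000_000, 1.0, "AMP", "SCNA")])
        mix = class_mix(ev, {"S1": "OV"})
        row = mix[mix["tumor_type"] == "OV"].iloc[0]
        assert (row["pct_indel"], row["pct_scna"], row["pct_aneuploidy"]) == (0, 100, 0)

    def test_planted_mix_recovered_exactly(self):
        rows = []
        for i in range(50):
            rows.append((f"S{i}", "chr1", 0, 5_000, 1.0, "AMP", "INDEL"))
        for i in range(30):
            rows.append((f"S{i}", "chr1", 10_000, 1_000_000, 1.0, "AMP", "SCNA"))
        for i in range(20):
            rows.append((f"S{i}", "chr1", 2_000_000, 90_000_000, 1.0, "AMP", "ANEUPLOIDY"))
        ann = {f"S{i}": "OV" for i in range(50)}
        mix = class_mix(events_frame(rows), ann)
        row = mix[mix["tumor_type"] == "OV"].iloc[0]
        assert (row["pct_indel"], row["pct_scna"], row["pct_aneuploidy"]) == (50, 30, 20)

    def test_empty_type_reports_missing(self):
        ev = events_frame([])
        mix = class_mix(ev, {"S1": "OV"})
        row = mix.iloc[0]
        assert math.isnan(row["pct_scna"])


class TestChromDistribution:
    def build2(self):
        return GenomeBuild(
            chromosomes=[("chr1", 100_000_000), ("chr2", 50_000_000)],
            arms=[
                ArmInterval("chr1", "q", 0, 100_000_000),
                ArmInterval("chr2", "q", 0, 50_000_000),
            ],
        )

    def test_all_on_one_chromosome(self):
        ev = events_frame(
            [("S1", "chr1", i * 2_000_000, i * 2_000_000 + 1_000_000, 1.0, "AMP", "SCNA") for i in range(4)]
        )
        dist = chrom_distribution(ev, {"S1": "OV"}, self.build2())
        raw = dict(zip(dist["chrom"], dist["raw_proportion"]))
        assert raw["chr1"] == 1.0 and raw["chr2"] == 0.0

    def test_divide_and_literal_modes(self):
        rows = [
            ("S1", "chr1", 0, 1_000_000, 1.0, "AMP", "SCNA"),
            ("S1", "chr2", 0, 1_000_000, 1.0, "AMP", "SCNA"),
        ]
        ev = events_frame(rows)
        div = chrom_distribution(ev, {"S1": "OV"}, self.build2(), mode="divide")
        vals = dict(zip(div["chrom"], div["normalized"]))
        assert vals["chr1"] == pytest.approx(0.005)
        assert vals["chr2"] == pytest.approx(0.010)
        lit = chrom_distribution(ev, {"S1": "OV"}, self.build2(), mode="literal")
        vals = dict(zip(lit["chrom"], lit["normalized"]))
        assert vals["chr1"] == pytest.approx(50.0)
        assert vals["chr2"] == pytest.approx(25.0)

    def test_raw_proportions_sum_to_one(self, rng):
        rows = []
        for i in range(60):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            start = i * 1_500_000
            rows.append((f"S{i % 4}", chrom, start, start + 1_000_000, 1.0, "AMP", "SCNA"))
        ann = {f"S{i}": "OV" for i in range(4)}
        dist = chrom_distribution(events_frame(rows), ann, self.build2())
        assert dist.groupby("tumor_type")["raw_proportion"].sum().iloc[0] == pytest.approx(1.0)


class TestWilcoxon:
    def test_exact_small_sample_enumeration(self):
        """p for {1,2} vs {3,4} equals 1/3 by full enumeration of rank splits."""
        # independent oracle: enumerate all C(4,2) assignments of ranks to x
        values = [1, 2, 3, 4]
        observed_u = 0  # x={1,2}: no y smaller than any x
        count_as_extreme = 0
        total = 0
        for combo in itertools.combinations(range(4), 2):
            x = [values[i] for i in combo]
            y = [values[i] for i in range(4) if i not in combo]
            u = sum(1 for xi in x for yi in y if xi > yi)
            # two-sided: as extreme in either direction
            if min(u, 4 - u) <= min(observed_u, 4 - observed_u):
                count_as_extreme += 1
            total += 1
        oracle_p = count_as_extreme / total
        assert oracle_p == pytest.approx(1 / 3)
        assert wilcoxon_two_sided([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_symmetry(self):
        x, y = [1.0, 5.0, 2.5], [3.0, 4.0, 0.5, 6.0]
        assert wilcoxon_two_sided(x, y) == pytest.approx(wilcoxon_two_sided(y, x))

    def test_identical_tied_groups_give_p_one(self):
        assert wilcoxon_two_sided([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            wilcoxon_two_sided([], [1.0])

    def test_null_calibration_smoke(self, rng):
        """At nominal 0.05, a null simulation rejects at roughly 5%."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            if wilcoxon_two_sided(x, y) < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.10


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        rho, _ = spearman(x, [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_tied_values_match_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [5.0, 7.0, 6.0, 8.0]
        # hand mid-ranks: x -> 1, 2.5, 2.5, 4 ; y -> 1, 3, 2, 4
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([1, 3, 2, 4.0])
        oracle = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(oracle)

    def test_constant_vector_reported_missing(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.20, "ns"),
            (0.05, "ns"),     # boundary takes the weaker label
            (0.049, "*"),
            (0.01, "*"),
            (0.0099, "**"),
            (0.001, "**"),
            (0.0005, "***"),
            (0.0001, "***"),
            (0.00009, "****"),
            (0.0, "****"),
            (1.0, "ns"),
        ],
    )
    def test_mapping(self, p, label):
        assert stars(p) == label


class TestComparisons:
    def test_group_comparison_shape_and_stars(self, flat_build, rng):
        rows = []
        for i in range(20):
            start = i * 20_000_000
            rows.append((f"S{i}", "chr1", start, start + 10_000_000, 1.0, "AMP", "SCNA"))
            if i < 3:
                rows.append((f"S{i}", "chr2", start, start + 100_000, -1.0, "DEL", "SCNA"))
        ann = {f"S{i}": "OV" for i in range(20)}
        burdens = burden_table(events_frame(rows), flat_build, ann)
        comp = group_comparisons(burdens)
        assert set(comp["metric"]) == {"n_events", "pct_genome", "mean_scna_len"}
        n_events = comp[(comp["tumor_type"] == "OV") & (comp["metric"] == "n_events")].iloc[0]
        assert n_events["p_value"] < 0.05

    def test_amp_del_correlation_levels_labelled(self, flat_build):
        rows = []
        for i in range(9):
            for j in range(i % 3 + 1):
                start = j * 20_000_000
                rows.append((f"S{i}", "chr1", start, start + 10_000_000, 1.0, "AMP", "SCNA"))
                rows.append((f"S{i}", "chr2", start, start + 10_000_000, -1.0, "DEL", "SCNA"))
        ann = {f"S{i}": ["OV", "BRCA", "LUAD"][i % 3] for i in range(9)}
        burdens = burden_table(events_frame(rows), flat_build, ann)
        corr = amp_del_correlations(burdens)
        assert set(corr["level"]) == {"per_sample_within_type", "across_type_means"}
        within = corr[corr["level"] == "per_sample_within_type"]
        assert (within["rho"].dropna() == 1.0).all()
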