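"""Gene-pair co-alteration counting, filtering and hub participation."""

import itertools

import pandas as pd
import pytest

from scna_atlas.genome import ArmInterval, GenomeBuild, GenomicInterval
from scna_atlas.io import GeneRecord
from scna_atlas.pairs import (
    AMP_AMP,
    AMP_DEL,
    DEL_DEL,
    filter_pairs,
    pair_events,
    pair_frequency,
    participation,
)


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "direction", "overlap_fraction"])


@pytest.fixture()
def pair_build():
    return GenomeBuild(
        chromosomes=[("chr1", 10_000_000), ("chr2", 10_000_000)],
        arms=[
            ArmInterval("chr1", "p", 0, 4_000_000),
            ArmInterval("chr1", "q", 5_000_000, 10_000_000),
            ArmInterval("chr2", "q", 0, 10_000_000),
        ],
    )


@pytest.fixture()
def pair_genes():
    return [
        GeneRecord("A", GenomicInterval("chr1", 1_000_000, 1_100_000)),   # chr1 p
        GeneRecord("B", GenomicInterval("chr1", 6_000_000, 6_100_000)),   # chr1 q
        GeneRecord("C", GenomicInterval("chr1", 7_000_000, 7_100_000)),   # chr1 q
        GeneRecord("D", GenomicInterval("chr2", 1_000_000, 1_100_000)),   # chr2 q
    ]


class TestPairEvents:
    def test_two_amplified_genes(self):
        assert pair_events([("A", "AMP"), ("B", "AMP")]) == {("A", "B", AMP_AMP, "")}

    def test_opposite_directions_record_amplified_member(self):
        assert pair_events([("A", "AMP"), ("B", "DEL")]) == {("A", "B", AMP_DEL, "A")}
        assert pair_events([("A", "DEL"), ("B", "AMP")]) == {("A", "B", AMP_DEL, "B")}

    def test_three_amplified_genes_give_all_pairs(self):
        events = pair_events([("A", "AMP"), ("B", "AMP"), ("C", "AMP")])
        assert events == {
            ("A", "B", AMP_AMP, ""),
            ("A", "C", AMP_AMP, ""),
            ("B", "C", AMP_AMP, ""),
        }

    def test_gene_with_both_calls_contributes_both_types(self):
        events = pair_events([("A", "AMP"), ("A", "DEL"), ("B", "AMP")])
        assert events == {("A", "B", AMP_AMP, ""), ("A", "B", AMP_DEL, "B")}

    def test_matches_combinatorial_oracle(self, rng):
        """Against brute-force enumeration over all gene pairs and directions."""
        genes = [f"G{i}" for i in range(8)]
        for _ in range(50):
            callset = set()
            for g in genes:
                for d in ("AMP", "DEL"):
                    if rng.random() < 0.3:
                        callset.add((g, d))
            got = pair_events(sorted(callset))
            expected = set()
            for (g1, d1), (g2, d2) in itertools.combinations(sorted(callset), 2):
                if g1 == g2:
                    continue
                a, b = sorted([g1, g2])
                da = d1 if a == g1 else d2
                db = d2 if b == g2 else d1
                if da == "AMP" and db == "AMP":
                    expected.add((a, b, AMP_AMP, ""))
                elif da == "DEL" and db == "DEL":
                    expected.add((a, b, DEL_DEL, ""))
                else:
                    expected.add((a, b, AMP_DEL, a if da == "AMP" else b))
            assert got == expected


class TestPairFrequency:
    def test_two_of_ten_samples(self, pair_build, pair_genes):
        ann = {f"S{i}": "OV" for i in range(10)}
        rows = []
        for s in ("S0", "S1"):
            rows += [(s, "A", "AMP", 1.0), (s, "D", "AMP", 1.0)]
        pf = pair_frequency(calls_frame(rows), ann, pair_genes, pair_build)
        row = pf.iloc[0]
        assert (row["gene_a"], row["gene_b"], row["event_type"]) == ("A", "D", AMP_AMP)
        assert row["frequency"] == pytest.approx(0.2)
        assert not row["same_chromosome"]

    def test_single_type_pan_equals_per_type(self, pair_build, pair_genes):
        ann = {f"S{i}": "OV" for i in range(5)}
        rows = [("S0", "B", "DEL", 1.0), ("S0", "C", "DEL", 1.0)]
        pan = pair_frequency(calls_frame(rows), ann, pair_genes, pair_build, scope="pan")
        per = pair_frequency(calls_frame(rows), ann, pair_genes, pair_build, scope="per_type")
        assert pan["frequency"].iloc[0] == per["frequency"].iloc[0]

    def test_same_chromosome_and_arm_flags(self, pair_build, pair_genes):
        ann = {"S0": "OV"}
        rows = [("S0", g, "AMP", 1.0) for g in ("A", "B", "C")]
        pf = pair_frequency(calls_frame(rows), ann, pair_genes, pair_build)
        flags = {
            (r.gene_a, r.gene_b): (r.same_chromosome, r.same_arm) for r in pf.itertuples()
        }
        assert flags[("A", "B")] == (True, False)   # p vs q
        assert flags[("B", "C")] == (True, True)    # both q
        assert ("A", "D") not in flags              # D not called

    def test_cooccurrence_bounded_by_marginals(self, pair_build, pair_genes, rng):
        ann = {f"S{i}": "OV" for i in range(30)}
        rows = []
        for i in range(30):
            for g in ("A", "B", "D"):
                if rng.random() < 0.4:
                    rows.append((f"S{i}", g, "AMP", 1.0))
        calls = calls_frame(rows)
        pf = pair_frequency(calls, ann, pair_genes, pair_build)
        marg = calls.groupby("gene")["sample"].nunique() / 30
        for r in pf[pf["event_type"] == AMP_AMP].itertuples():
            assert r.frequency <= min(marg[r.gene_a], marg[r.gene_b]) + 1e-12

    def test_symmetry_under_input_relabelling(self, pair_build, pair_genes):
        ann = {"S0": "OV", "S1": "OV"}
        rows1 = [("S0", "A", "AMP", 1.0), ("S0", "D", "DEL", 1.0)]
        rows2 = [("S0", "D", "DEL", 1.0), ("S0", "A", "AMP", 1.0)]
        pf1 = pair_frequency(calls_frame(rows1), ann, pair_genes, pair_build)
        pf2 = pair_frequency(calls_frame(rows2), ann, pair_genes, pair_build)
        pd.testing.assert_frame_equal(pf1, pf2)


class TestFilterPairs:
    def frame(self):
        return pd.DataFrame(
            {
                "gene_a": ["A", "A", "B", "C"],
                "gene_b": ["B", "C", "C", "D"],
                "event_type": [AMP_AMP, AMP_AMP, DEL_DEL, AMP_DEL],
                "amp_gene": ["", "", "", "C"],
                "frequency": [0.05, 0.04, 0.5, 0.9],
                "same_chromosome": [True, False, False, False],
            }
        )

    def test_threshold_inclusive(self):
        out = filter_pairs(self.frame(), 0.05)
        assert set(zip(out["gene_a"], out["gene_b"])) == {("A", "B"), ("B", "C")}

    def test_inter_chromosomal_masking(self):
        out = filter_pairs(self.frame(), 0.05, inter_chromosomal_only=True)
        assert set(zip(out["gene_a"], out["gene_b"])) == {("B", "C")}

    def test_amp_del_excluded_by_default_but_selectable(self):
        out = filter_pairs(self.frame(), 0.0, event_types=[AMP_DEL])
        assert list(out["event_type"]) == [AMP_DEL]

    def test_empty_input(self):
        out = filter_pairs(self.frame().iloc[0:0], 0.05)
        assert len(out) == 0


class TestParticipation:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "event_type", "frequency"])

    def test_hub_gene_in_every_pair(self):
        rows = [("HUB", f"G{i}", AMP_AMP, 0.5 - i * 0.01) for i in range(10)]
        part = participation(self.frame(rows), 10)
        assert part[part["gene"] == "HUB"]["n_pairs_involving_gene"].iloc[0] == 10

    def test_absent_gene_not_listed(self):
        rows = [("A", "B", AMP_AMP, 0.9), ("C", "D", AMP_AMP, 0.1)]
        part = participation(self.frame(rows), 1)
        assert set(part["gene"]) == {"A", "B"}

    def test_counts_sum_to_twice_k(self):
        rows = [(f"A{i}", f"B{i}", AMP_AMP, 0.9 - i * 0.01) for i in range(20)]
        part = participation(self.frame(rows), 15)
        assert part["n_pairs_involving_gene"].sum() == 30
        assert (part["k_used"] == 15).all()

    def test_fewer_pairs_than_k_records_actual(self):
        rows = [("A", "B", AMP_AMP, 0.9)]
        part = participation(self.frame(rows), 100)
        assert (part["k_used"] == 1).all()

    def test_tie_breaking_deterministic(self):
        rows = [("X", "Y", AMP_AMP, 0.5), ("A", "B", AMP_AMP, 0.5), ("M", "N", AMP_AMP, 0.5)]
        part = participation(self.frame(rows), 2)
        # lexicographic tie-break keeps (A,B) and (M,N)
        assert set(part["gene"]) == {"A", "B", "M", "N"}
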