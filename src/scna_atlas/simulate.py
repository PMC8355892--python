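"""Seeded synthetic copy-number cohorts with planted ground truth.

The generator emulates the statistical structure of a pan-cancer segmented
copy-number release at desk scale: several tumor types, negative-binomial
per-sample event counts (optionally sharing a per-sample intensity between
amplifications and deletions, which induces the amp/del correlation seen in
real tumors), a log-normal SCNA length distribution, and log2 ratios drawn
with a guard margin away from every calling threshold so that each event's
direction and class are unambiguous by construction.

Specific census genes and gene pairs can be planted at exact per-type or
cohort frequencies; background events never touch census genes, so the
planted gene-call and pair incidence is the complete truth for the default
(SCNA-class, union-overlap) gene-calling configuration.  Every random draw
flows from a single seed, and identical specs produce byte-identical files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    AMP,
    ANEUPLOIDY,
    CLASSES,
    DEL,
    EVENT_COLUMNS,
    INDEL,
    SCNA,
    ClassificationParams,
)
from .errors import SimulationError
from .genome import ArmInterval, GenomeBuild, GenomicInterval, write_arm_table, write_chrom_sizes
from .io import (
    GeneRecord,
    SampleAnnotation,
    SegmentRecord,
    write_annotations,
    write_gene_bed,
    write_seg,
    write_table,
)

logger = logging.getLogger(__name__)

_MAX_TRIES = 200


# -- specification --------------------------------------------------------


@dataclass(frozen=True)
class TumorTypeSpec:
    """Event-rate parameters of one synthetic tumor type.

    Per-sample amplification and deletion counts are negative-binomial with
    the given means and a common dispersion (gamma-Poisson mixture; larger
    ``dispersion`` means closer to Poisson).
    """

    label: str
    n_samples: int
    amp_mean: float
    del_mean: float
    dispersion: float = 3.0


@dataclass(frozen=True)
class PlantedGene:
    """Plant an alteration of one census gene at a fixed frequency.

    ``frequency`` is either a single fraction applied to every tumor type or
    a mapping from type label to fraction (missing labels get ``default``).
    """

    symbol: str
    direction: str
    frequency: float | Mapping[str, float]
    default: float = 0.0

    def freq_for(self, ttype: str) -> float:
        if isinstance(self.frequency, Mapping):
            return float(self.frequency.get(ttype, self.default))
        return float(self.frequency)


@dataclass(frozen=True)
class PlantedPair:
    """Plant a co-altered gene pair at a fixed pan-cohort frequency.

    With ``shared_event`` the pair is realised by a single event spanning
    both genes (they must sit on the same arm); otherwise by two independent
    events, one per gene.  For AMP-DEL pairs ``gene_a`` is the amplified
    member.
    """

    gene_a: str
    gene_b: str
    event_type: str  # AMP-AMP | DEL-DEL | AMP-DEL
    frequency: float
    shared_event: bool = False


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort.

    Defaults describe the desk-scale study cohort: five tumor types of 50
    samples each with distinct burden levels, a 25/70/5 indel/SCNA/
    aneuploidy class mix, log-normal SCNA lengths around 2 Mb, coupled
    amp/del intensities, three planted genes and three planted pairs.
    """

    seed: int = 0
    tumor_types: list[TumorTypeSpec] = field(default_factory=list)
    class_mix: tuple[float, float, float] = (0.25, 0.70, 0.05)  # INDEL, SCNA, ANEUPLOIDY
    scna_len_log_mean: float = math.log(2_000_000)
    scna_len_log_sd: float = 1.0
    margin_log2: float = 0.02
    margin_bp: int = 100
    neutral_per_sample: int = 4
    amp_del_coupling: bool = True
    coupling_shape: float = 3.0
    planted_genes: list[PlantedGene] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    params: ClassificationParams = field(default_factory=ClassificationParams)

    def validate(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise SimulationError("class_mix proportions must sum to 1")
        if self.margin_log2 <= 0 or self.margin_bp <= 0:
            raise SimulationError("guard margins must be positive")
        used: set[str] = set()
        for pg in self.planted_genes:
            if not (0 <= pg.freq_for("?") <= 1) and not isinstance(pg.frequency, Mapping):
                raise SimulationError(f"planted frequency out of [0,1] for {pg.symbol}")
            if pg.symbol in used:
                raise SimulationError(f"gene {pg.symbol} planted more than once")
            used.add(pg.symbol)
        for pp in self.planted_pairs:
            if not (0 <= pp.frequency <= 1):
                raise SimulationError(f"planted pair frequency out of [0,1]")
            for sym in (pp.gene_a, pp.gene_b):
                if sym in used:
                    raise SimulationError(f"gene {sym} planted more than once")
                used.add(sym)


# -- toy genome and census ------------------------------------------------


def make_toy_genome(
    n_chroms: int = 8,
    chrom_length: int = 100_000_000,
    p_fraction: float = 0.45,
    gap_fraction: float = 0.05,
    acrocentric: Sequence[str] = (),
    out_dir: str | Path | None = None,
) -> GenomeBuild:
    """Build a toy genome of equal chromosomes with p/gap/q arm layout.

    Chromosomes are named chr1..chrN; chromosomes listed in ``acrocentric``
    get their p arm flagged as an acrocentric short arm.  When ``out_dir``
    is given, chrom.sizes and arms.tsv are written there.
    """
    if n_chroms < 1:
        raise SimulationError("n_chroms must be >= 1")
    if p_fraction <= 0 or gap_fraction < 0 or p_fraction + gap_fraction >= 1:
        raise SimulationError("arm layout inconsistent with chromosome length")
    acro = set(acrocentric)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chroms)]
    arms: list[ArmInterval] = []
    p_len = int(chrom_length * p_fraction)
    gap = int(chrom_length * gap_fraction)
    for name, length in chroms:
        arms.append(ArmInterval(name, "p", 0, p_len, acrocentric_short=name in acro))
        arms.append(ArmInterval(name, "q", p_len + gap, length))
    build = GenomeBuild(chromosomes=chroms, arms=arms)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(build, out_dir / "chrom.sizes")
        write_arm_table(build, out_dir / "arms.tsv")
    return build


def default_gene_census(
    build: GenomeBuild, genes_per_chrom: int = 2, gene_length: int = 100_000
) -> list[GeneRecord]:
    """Evenly spaced toy census genes placed on each chromosome's q arm."""
    genes: list[GeneRecord] = []
    idx = 1
    for name, _ in build.chromosomes:
        q_arms = [a for a in build.arms_of(name) if a.arm == "q"]
        if not q_arms:
            continue
        q = q_arms[0]
        step = q.length // (genes_per_chrom + 1)
        for j in range(genes_per_chrom):
            start = q.start + (j + 1) * step
            genes.append(
                GeneRecord(f"G{idx:03d}", GenomicInterval(name, start, start + gene_length))
            )
            idx += 1
    return genes


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default desk-scale study cohort: 5 types x 50 samples."""
    return CohortSpec(
        seed=seed,
        tumor_types=[
            TumorTypeSpec("TTA", 50, amp_mean=4.0, del_mean=3.0),
            TumorTypeSpec("TTB", 50, amp_mean=6.0, del_mean=5.0),
            TumorTypeSpec("TTC", 50, amp_mean=8.0, del_mean=6.0),
            TumorTypeSpec("TTD", 50, amp_mean=10.0, del_mean=8.0),
            TumorTypeSpec("TTE", 50, amp_mean=5.0, del_mean=4.0),
        ],
        planted_genes=[
            PlantedGene("G001", AMP, 0.4),
            PlantedGene("G014", DEL, 0.3),
            PlantedGene("G005", AMP, {"TTA": 0.6, "TTB": 0.2}, default=0.1),
        ],
        planted_pairs=[
            PlantedPair("G003", "G011", "AMP-AMP", 0.2),
            PlantedPair("G006", "G016", "DEL-DEL", 0.1),
            PlantedPair("G009", "G010", "AMP-AMP", 0.24, shared_event=True),
        ],
    )


# -- truth table ----------------------------------------------------------


@dataclass
class TruthTable:
    """Ground truth consistent with the emitted segments by construction."""

    events: pd.DataFrame          # classified-events schema
    sample_counts: pd.DataFrame   # per-sample burden truth
    gene_calls: pd.DataFrame      # sample, gene, direction
    pair_incidence: pd.DataFrame  # gene_a, gene_b, event_type, amp_gene, n, frequency
    planted_gene_freq: pd.DataFrame


@dataclass
class SyntheticCohort:
    build: GenomeBuild
    genes: list[GeneRecord]
    segments: list[SegmentRecord]
    annotations: list[SampleAnnotation]
    truth: TruthTable
    spec: CohortSpec

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all inputs and truth tables; returns name -> path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": out / "chrom.sizes",
            "arms": out / "arms.tsv",
            "genes": out / "genes.bed",
            "segments": out / "segments.seg",
            "annotations": out / "annotations.tsv",
            "truth_events": out / "truth_events.tsv",
            "truth_sample_counts": out / "truth_sample_counts.tsv",
            "truth_gene_calls": out / "truth_gene_calls.tsv",
            "truth_pairs": out / "truth_pairs.tsv",
            "truth_planted_gene_freq": out / "truth_planted_gene_freq.tsv",
        }
        write_chrom_sizes(self.build, paths["chrom_sizes"])
        write_arm_table(self.build, paths["arms"])
        write_gene_bed(self.genes, paths["genes"])
        write_seg(self.segments, paths["segments"])
        write_annotations(self.annotations, paths["annotations"])
        self.truth.events.to_csv(
            paths["truth_events"], sep="\t", index=False, float_format="%.6g",
            lineterminator="\n",
        )
        write_table(self.truth.sample_counts, paths["truth_sample_counts"], ["sample"])
        write_table(self.truth.gene_calls, paths["truth_gene_calls"],
                    ["sample", "gene", "direction"])
        write_table(self.truth.pair_incidence, paths["truth_pairs"],
                    ["event_type", "gene_a", "gene_b", "amp_gene"])
        write_table(self.truth.planted_gene_freq, paths["truth_planted_gene_freq"],
                    ["gene", "direction", "tumor_type"])
        return paths


# -- internal helpers -----------------------------------------------------


def _union_bp(spans: list[tuple[str, int, int]]) -> int:
    # independent of stats.interval_union_bp on purpose: truth bookkeeping
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in spans:
        per_chrom.setdefault(chrom, []).append((s, e))
    total = 0
    for vals in per_chrom.values():
        covered: list[tuple[int, int]] = []
        for s, e in sorted(vals):
            if covered and s <= covered[-1][1]:
                covered[-1] = (covered[-1][0], max(covered[-1][1], e))
            else:
                covered.append((s, e))
        total += sum(e - s for s, e in covered)
    return total


class _SampleLayout:
    """Tracks placed segments of one sample to keep them non-overlapping."""

    def __init__(self) -> None:
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def clashes(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.spans.get(chrom, []))

    def add(self, chrom: str, start: int, end: int) -> None:
        self.spans.setdefault(chrom, []).append((start, end))


def _overlaps_any_gene(chrom: str, start: int, end: int, genes: Sequence[GeneRecord]) -> bool:
    return any(
        g.interval.chrom == chrom and g.interval.start < end and start < g.interval.end
        for g in genes
    )


def _ratio(rng: np.random.Generator, direction: str, spec: CohortSpec) -> float:
    p, m = spec.params, spec.margin_log2
    if direction == AMP:
        return float(rng.uniform(p.amp_log2 + m, p.amp_log2 + m + 1.0))
    if direction == DEL:
        return float(rng.uniform(p.del_log2 - m - 1.0, p.del_log2 - m))
    return float(rng.uniform(p.del_log2 + m, p.amp_log2 - m))


# -- the generator --------------------------------------------------------


class _Generator:
    def __init__(self, spec: CohortSpec, build: GenomeBuild, genes: list[GeneRecord]):
        spec.validate()
        self.spec = spec
        self.build = build
        self.genes = genes
        self.gene_by_symbol = {g.symbol: g for g in genes}
        self.rng = np.random.default_rng(spec.seed)
        self.samples: list[tuple[str, str]] = [
            (f"{tt.label}-{i + 1:03d}", tt.label)
            for tt in spec.tumor_types
            for i in range(tt.n_samples)
        ]
        self.layouts = {s: _SampleLayout() for s, _ in self.samples}
        # event rows: (sample, chrom, start, end, ratio, direction, class)
        self.event_rows: list[tuple] = []
        self.neutral_rows: list[tuple] = []
        self.gene_truth: set[tuple[str, str, str]] = set()  # sample, gene, direction

        for pp in spec.planted_pairs:
            for sym in (pp.gene_a, pp.gene_b):
                if sym not in self.gene_by_symbol:
                    raise SimulationError(f"planted gene {sym} not in the census")
        for pg in spec.planted_genes:
            if pg.symbol not in self.gene_by_symbol:
                raise SimulationError(f"planted gene {pg.symbol} not in the census")

    # .. placement primitives .............................................

    def _arm_of_gene(self, gene: GeneRecord) -> ArmInterval:
        for arm in self.build.arms_of(gene.interval.chrom):
            if arm.start <= gene.interval.start and gene.interval.end <= arm.end:
                return arm
        raise SimulationError(f"gene {gene.symbol} does not sit inside one arm")

    def _scna_bounds(self, arm: ArmInterval) -> tuple[int, int]:
        p, mbp = self.spec.params, self.spec.margin_bp
        lo = p.indel_max_bp + mbp
        hi = int(p.arm_frac * arm.length) - mbp
        if lo >= hi:
            raise SimulationError(f"arm {arm.chrom}{arm.arm} too short for SCNA events")
        return lo, hi

    def _place_gene_event(self, sample: str, gene: GeneRecord, direction: str) -> None:
        """One SCNA-class event fully covering ``gene``, clear of other genes."""
        arm = self._arm_of_gene(gene)
        lo, hi = self._scna_bounds(arm)
        g = gene.interval
        layout = self.layouts[sample]
        others = [x for x in self.genes if x.symbol != gene.symbol]
        for _ in range(_MAX_TRIES):
            pad_l = int(self.rng.integers(2_000, 200_000))
            pad_r = int(self.rng.integers(2_000, 200_000))
            start, end = g.start - pad_l, g.end + pad_r
            if start < arm.start or end > arm.end:
                continue
            if not (lo <= end - start <= hi):
                continue
            if _overlaps_any_gene(g.chrom, start, end, others):
                continue
            if layout.clashes(g.chrom, start, end):
                continue
            self._commit(sample, g.chrom, start, end, direction, SCNA)
            self.gene_truth.add((sample, gene.symbol, direction))
            return
        raise SimulationError(
            f"could not place event for gene {gene.symbol} in sample {sample}"
        )

    def _place_span_event(
        self, sample: str, gene_a: GeneRecord, gene_b: GeneRecord, direction: str
    ) -> None:
        """One SCNA-class event spanning two genes on the same arm."""
        arm_a, arm_b = self._arm_of_gene(gene_a), self._arm_of_gene(gene_b)
        if (arm_a.chrom, arm_a.arm) != (arm_b.chrom, arm_b.arm):
            raise SimulationError(
                f"shared event requires {gene_a.symbol} and {gene_b.symbol} on one arm"
            )
        lo, hi = self._scna_bounds(arm_a)
        left = min(gene_a.interval.start, gene_b.interval.start)
        right = max(gene_a.interval.end, gene_b.interval.end)
        others = [
            x for x in self.genes if x.symbol not in (gene_a.symbol, gene_b.symbol)
        ]
        layout = self.layouts[sample]
        for _ in range(_MAX_TRIES):
            pad_l = int(self.rng.integers(2_000, 200_000))
            pad_r = int(self.rng.integers(2_000, 200_000))
            start, end = left - pad_l, right + pad_r
            if start < arm_a.start or end > arm_a.end or not (lo <= end - start <= hi):
                continue
            if _overlaps_any_gene(arm_a.chrom, start, end, others):
                continue
            if layout.clashes(arm_a.chrom, start, end):
                continue
            self._commit(sample, arm_a.chrom, start, end, direction, SCNA)
            self.gene_truth.add((sample, gene_a.symbol, direction))
            self.gene_truth.add((sample, gene_b.symbol, direction))
            return
        raise SimulationError(
            f"could not place shared event for {gene_a.symbol}/{gene_b.symbol} "
            f"in sample {sample}"
        )

    def _place_background(self, sample: str, direction: str, cls: str) -> None:
        spec, build = self.spec, self.build
        layout = self.layouts[sample]
        mbp = spec.margin_bp
        for _ in range(_MAX_TRIES):
            if cls == INDEL:
                chrom, length = build.chromosomes[
                    int(self.rng.integers(len(build.chromosomes)))
                ]
                ev_len = int(self.rng.integers(mbp, spec.params.indel_max_bp - mbp))
                start = int(self.rng.integers(0, length - ev_len))
                end = start + ev_len
                if _overlaps_any_gene(chrom, start, end, self.genes):
                    continue
            elif cls == SCNA:
                arms = [a for a in build.arms if not a.acrocentric_short]
                arm = arms[int(self.rng.integers(len(arms)))]
                lo, hi = self._scna_bounds(arm)
                ev_len = int(
                    np.clip(self.rng.lognormal(spec.scna_len_log_mean, spec.scna_len_log_sd),
                            lo, hi)
                )
                start = int(self.rng.integers(arm.start, arm.end - ev_len))
                end = start + ev_len
                chrom = arm.chrom
                if _overlaps_any_gene(chrom, start, end, self.genes):
                    continue
            else:  # ANEUPLOIDY
                arms = [a for a in build.arms if not a.acrocentric_short]
                arm = arms[int(self.rng.integers(len(arms)))]
                frac = float(self.rng.uniform(spec.params.arm_frac + 0.01, 1.0))
                ev_len = int(frac * arm.length)
                start = int(self.rng.integers(arm.start, arm.end - ev_len + 1))
                end = start + ev_len
                chrom = arm.chrom
            if layout.clashes(chrom, start, end):
                continue
            self._commit(sample, chrom, start, end, direction, cls)
            return
        raise SimulationError(
            f"could not place a background {direction} {cls} event in sample {sample}"
        )

    def _place_neutral(self, sample: str) -> None:
        build = self.build
        layout = self.layouts[sample]
        for _ in range(_MAX_TRIES):
            chrom, length = build.chromosomes[
                int(self.rng.integers(len(build.chromosomes)))
            ]
            ev_len = int(self.rng.integers(50_000, 2_000_000))
            if ev_len >= length:
                continue
            start = int(self.rng.integers(0, length - ev_len))
            end = start + ev_len
            if layout.clashes(chrom, start, end):
                continue
            ratio = _ratio(self.rng, "NEUTRAL", self.spec)
            layout.add(chrom, start, end)
            self.neutral_rows.append((sample, chrom, start, end, ratio))
            return
        raise SimulationError(f"could not place a neutral segment in sample {sample}")

    def _commit(
        self, sample: str, chrom: str, start: int, end: int, direction: str, cls: str
    ) -> None:
        ratio = _ratio(self.rng, direction, self.spec)
        self.layouts[sample].add(chrom, start, end)
        self.event_rows.append((sample, chrom, start, end, ratio, direction, cls))

    # .. phases ...........................................................

    def _plant_genes(self) -> None:
        by_type: dict[str, list[str]] = {}
        for sample, ttype in self.samples:
            by_type.setdefault(ttype, []).append(sample)
        for pg in self.spec.planted_genes:
            gene = self.gene_by_symbol[pg.symbol]
            for tt in self.spec.tumor_types:
                freq = pg.freq_for(tt.label)
                n = int(round(freq * tt.n_samples))
                if n == 0:
                    continue
                chosen = self.rng.choice(by_type[tt.label], size=n, replace=False)
                for sample in chosen:
                    self._place_gene_event(str(sample), gene, pg.direction)

    def _plant_pairs(self) -> None:
        all_samples = [s for s, _ in self.samples]
        for pp in self.spec.planted_pairs:
            n = int(round(pp.frequency * len(all_samples)))
            if n == 0:
                continue
            chosen = self.rng.choice(all_samples, size=n, replace=False)
            a = self.gene_by_symbol[pp.gene_a]
            b = self.gene_by_symbol[pp.gene_b]
            if pp.event_type == "AMP-AMP":
                dirs = (AMP, AMP)
            elif pp.event_type == "DEL-DEL":
                dirs = (DEL, DEL)
            elif pp.event_type == "AMP-DEL":
                dirs = (AMP, DEL)
            else:
                raise SimulationError(f"unknown pair event type {pp.event_type}")
            for sample in chosen:
                sample = str(sample)
                if pp.shared_event:
                    if dirs[0] != dirs[1]:
                        raise SimulationError("a shared event cannot realise AMP-DEL")
                    self._place_span_event(sample, a, b, dirs[0])
                else:
                    self._place_gene_event(sample, a, dirs[0])
                    self._place_gene_event(sample, b, dirs[1])

    def _background(self) -> None:
        mix = np.asarray(self.spec.class_mix, dtype=float)
        for tt in self.spec.tumor_types:
            r = tt.dispersion
            for sample, ttype in self.samples:
                if ttype != tt.label:
                    continue
                if self.spec.amp_del_coupling:
                    # one shared intensity drives both directions -> correlated counts
                    g = self.rng.gamma(self.spec.coupling_shape, 1.0 / self.spec.coupling_shape)
                    g_amp = g_del = g
                else:
                    g_amp = self.rng.gamma(r, 1.0 / r)
                    g_del = self.rng.gamma(r, 1.0 / r)
                n_amp = int(self.rng.poisson(tt.amp_mean * g_amp))
                n_del = int(self.rng.poisson(tt.del_mean * g_del))
                queue: list[tuple[str, str]] = []
                for direction, n in ((AMP, n_amp), (DEL, n_del)):
                    for _ in range(n):
                        cls = CLASSES[int(self.rng.choice(3, p=mix))]
                        queue.append((direction, cls))
                # place arm-scale events before focal ones so they can still
                # find an unobstructed arm
                size_rank = {ANEUPLOIDY: 0, SCNA: 1, INDEL: 2}
                queue.sort(key=lambda dc: size_rank[dc[1]])
                for direction, cls in queue:
                    self._place_background(sample, direction, cls)

    def _neutrals(self) -> None:
        for sample, _ in self.samples:
            for _ in range(self.spec.neutral_per_sample):
                self._place_neutral(sample)

    # .. truth assembly ...................................................

    def _truth(self) -> TruthTable:
        order = {name: i for i, (name, _) in enumerate(self.build.chromosomes)}
        ev = sorted(self.event_rows, key=lambda r: (r[0], order[r[1]], r[2]))
        events = pd.DataFrame(
            [(s, c, st, en, en - st, ra, d, cl) for s, c, st, en, ra, d, cl in ev],
            columns=list(EVENT_COLUMNS),
        )

        denom = self.build.analysis_length
        rows = []
        for sample, ttype in self.samples:
            mine = [r for r in self.event_rows if r[0] == sample]
            row = {"sample": sample, "tumor_type": ttype}
            for direction in (AMP, DEL):
                spans = [(c, st, en) for _, c, st, en, _, d, _ in mine if d == direction]
                row[f"n_{direction.lower()}"] = len(spans)
                row[f"pct_genome_{direction.lower()}"] = 100.0 * _union_bp(spans) / denom
            for cls in CLASSES:
                row[f"n_{cls.lower()}"] = sum(1 for r in mine if r[6] == cls)
            rows.append(row)
        sample_counts = pd.DataFrame(rows)

        gene_calls = pd.DataFrame(
            sorted(self.gene_truth), columns=["sample", "gene", "direction"]
        )

        # per-sample pair enumeration (generator-side bookkeeping)
        pair_counts: dict[tuple[str, str, str, str], int] = {}
        per_sample: dict[str, dict[str, set[str]]] = {}
        for sample, gene, direction in self.gene_truth:
            per_sample.setdefault(sample, {}).setdefault(gene, set()).add(direction)
        for sample, gdirs in per_sample.items():
            keys: set[tuple[str, str, str, str]] = set()
            symbols = sorted(gdirs)
            for i in range(len(symbols)):
                for j in range(i + 1, len(symbols)):
                    a, b = symbols[i], symbols[j]
                    for da in gdirs[a]:
                        for db in gdirs[b]:
                            if da == AMP and db == AMP:
                                keys.add((a, b, "AMP-AMP", ""))
                            elif da == DEL and db == DEL:
                                keys.add((a, b, "DEL-DEL", ""))
                            else:
                                keys.add((a, b, "AMP-DEL", a if da == AMP else b))
            for key in keys:
                pair_counts[key] = pair_counts.get(key, 0) + 1
        n_total = len(self.samples)
        pair_incidence = pd.DataFrame(
            [
                {
                    "gene_a": a,
                    "gene_b": b,
                    "event_type": et,
                    "amp_gene": ag,
                    "n_samples_co_altered": n,
                    "frequency": n / n_total,
                }
                for (a, b, et, ag), n in sorted(pair_counts.items())
            ],
            columns=[
                "gene_a", "gene_b", "event_type", "amp_gene",
                "n_samples_co_altered", "frequency",
            ],
        )

        planted_rows = []
        for pg in self.spec.planted_genes:
            for tt in self.spec.tumor_types:
                n = int(round(pg.freq_for(tt.label) * tt.n_samples))
                planted_rows.append(
                    {
                        "gene": pg.symbol,
                        "direction": pg.direction,
                        "tumor_type": tt.label,
                        "n_planted": n,
                        "frequency": n / tt.n_samples,
                    }
                )
        planted = pd.DataFrame(
            planted_rows,
            columns=["gene", "direction", "tumor_type", "n_planted", "frequency"],
        )
        return TruthTable(events, sample_counts, gene_calls, pair_incidence, planted)

    # .. driver ...........................................................

    def run(self) -> SyntheticCohort:
        self._plant_genes()
        self._plant_pairs()
        self._background()
        self._neutrals()
        order = {name: i for i, (name, _) in enumerate(self.build.chromosomes)}
        all_rows = [
            (s, c, st, en, ra) for s, c, st, en, ra, _, _ in self.event_rows
        ] + self.neutral_rows
        all_rows.sort(key=lambda r: (r[0], order[r[1]], r[2]))
        # ratios are rounded to 4 decimals at generation so every downstream
        # serialisation (6 significant digits) is lossless and truth == files
        segments = [
            SegmentRecord(s, GenomicInterval(c, st, en), round(ra, 4))
            for s, c, st, en, ra in all_rows
        ]
        annotations = [SampleAnnotation(s, t) for s, t in self.samples]
        truth = self._truth()
        truth.events["log2_ratio"] = truth.events["log2_ratio"].astype(float).round(4)
        logger.info(
            "generated cohort: %d samples, %d events, %d neutral segments",
            len(self.samples), len(self.event_rows), len(self.neutral_rows),
        )
        return SyntheticCohort(self.build, self.genes, segments, annotations, truth, self.spec)


def generate_cohort(
    spec: CohortSpec,
    build: GenomeBuild | None = None,
    genes: list[GeneRecord] | None = None,
) -> SyntheticCohort:
    """Generate a synthetic cohort with planted ground truth.

    Uses the default toy genome and census when not supplied.  Raises
    :class:`SimulationError` before writing anything if the spec cannot be
    realised (e.g. a planted event would not fit its arm).
    """
    if build is None:
        build = make_toy_genome()
    if genes is None:
        genes = default_gene_census(build)
    return _Generator(spec, build, genes).run()
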