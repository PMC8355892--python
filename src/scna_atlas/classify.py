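"""Copy-number event calling and classification.

Direction is called from the segment's log2 tumor/normal ratio: amplified
above ``amp_log2`` (default 0.32), deleted below ``del_log2`` (default
-0.42), neutral otherwise — both inequalities strict, so a ratio sitting
exactly on a threshold is neutral.

Each called event is then assigned exactly one class:

* ``INDEL``      — length strictly below ``indel_max_bp`` (default 10 kb);
* ``ANEUPLOIDY`` — it covers strictly more than ``arm_frac`` (default 75%)
  of some chromosome arm, the short arms of acrocentric chromosomes being
  ineligible;
* ``SCNA``       — everything else.

A segment spanning the centromere is tested per arm and the maximum
fraction over eligible arms decides: a whole-chromosome gain is one
aneuploidy, never two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .genome import GenomeBuild, GenomicInterval, arm_fractions
from .io import SegmentRecord

logger = logging.getLogger(__name__)

AMP = "AMP"
DEL = "DEL"
NEUTRAL = "NEUTRAL"
INDEL = "INDEL"
SCNA = "SCNA"
ANEUPLOIDY = "ANEUPLOIDY"

DIRECTIONS = (AMP, DEL)
CLASSES = (INDEL, SCNA, ANEUPLOIDY)

#: Columns of the classified-events table, in output order.
EVENT_COLUMNS = ("sample", "chrom", "start", "end", "length", "log2_ratio", "direction", "class")


@dataclass(frozen=True)
class ClassificationParams:
    """The five calling constants, all overridable from config.

    ``amp_log2``/``del_log2`` are strict log2-ratio thresholds;
    ``indel_max_bp`` is the exclusive upper length bound for indels;
    ``arm_frac`` is the exclusive arm-coverage lower bound for aneuploidy;
    ``gene_overlap_frac`` is the inclusive gene-coverage lower bound for
    gene-level calls.
    """

    amp_log2: float = 0.32
    del_log2: float = -0.42
    indel_max_bp: int = 10_000
    arm_frac: float = 0.75
    gene_overlap_frac: float = 0.50

    def __post_init__(self) -> None:
        if not (self.del_log2 < 0 < self.amp_log2):
            raise ConfigError("require del_log2 < 0 < amp_log2")
        if not (0 < self.arm_frac <= 1):
            raise ConfigError("arm_frac must be in (0, 1]")
        if not (0 < self.gene_overlap_frac <= 1):
            raise ConfigError("gene_overlap_frac must be in (0, 1]")
        if self.indel_max_bp <= 0:
            raise ConfigError("indel_max_bp must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "ClassificationParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown classification parameters: {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data.get("params", data))


DEFAULT_PARAMS = ClassificationParams()


@dataclass(frozen=True)
class Alteration:
    """A called copy-number event with its direction and class."""

    sample_id: str
    interval: GenomicInterval
    direction: str
    alt_class: str
    log2_ratio: float

    @property
    def length(self) -> int:
        return self.interval.length


def call_direction(log2_ratio: float, params: ClassificationParams = DEFAULT_PARAMS) -> str:
    """AMP / DEL / NEUTRAL from the log2 ratio (strict thresholds)."""
    if not math.isfinite(log2_ratio):
        raise DataError(f"non-finite log2 ratio: {log2_ratio}")
    if log2_ratio > params.amp_log2:
        return AMP
    if log2_ratio < params.del_log2:
        return DEL
    return NEUTRAL


def classify_event(
    interval: GenomicInterval,
    direction: str,
    build: GenomeBuild,
    params: ClassificationParams = DEFAULT_PARAMS,
) -> str:
    """Assign a called event to INDEL, ANEUPLOIDY or SCNA.

    The length rule is tested first; aneuploidy then requires coverage of
    strictly more than ``arm_frac`` of at least one eligible arm (acrocentric
    short arms are excluded from the test, but their sequence still counts
    toward event length).
    """
    if direction not in DIRECTIONS:
        raise DataError(f"direction must be AMP or DEL, got {direction!r}")
    if interval.length < params.indel_max_bp:
        return INDEL
    fractions = arm_fractions(interval, build)  # raises if arms missing
    eligible = [frac for arm, frac in fractions if not arm.acrocentric_short]
    if eligible and max(eligible) > params.arm_frac:
        return ANEUPLOIDY
    return SCNA


def classify_sample(
    segments: Sequence[SegmentRecord],
    build: GenomeBuild,
    params: ClassificationParams = DEFAULT_PARAMS,
    *,
    merge_adjacent: bool = False,
    merge_gap_bp: int = 0,
) -> list[Alteration]:
    """Call and classify every segment of one sample.

    Neutral segments are dropped; segments on chromosomes outside the
    analysis set are dropped with a logged count.  Output is sorted by
    chromosome (build order) then start.  With ``merge_adjacent``, called
    same-direction segments separated by at most ``merge_gap_bp`` are fused
    (length-weighted mean ratio) before classification; off by default
    because merging changes event counts.
    """
    samples = {s.sample_id for s in segments}
    if len(samples) > 1:
        raise DataError(f"classify_sample received mixed sample ids: {sorted(samples)}")

    called: list[tuple[SegmentRecord, str]] = []
    dropped = 0
    for seg in segments:
        if seg.interval.chrom not in build.analysis_set:
            dropped += 1
            continue
        direction = call_direction(seg.log2_ratio, params)
        if direction != NEUTRAL:
            called.append((seg, direction))
    if dropped:
        logger.info(
            "sample %s: dropped %d segments outside the analysis set",
            next(iter(samples), "?"),
            dropped,
        )

    if merge_adjacent:
        called = _merge_called(called, merge_gap_bp)

    alterations = [
        Alteration(
            sample_id=seg.sample_id,
            interval=seg.interval,
            direction=direction,
            alt_class=classify_event(seg.interval, direction, build, params),
            log2_ratio=seg.log2_ratio,
        )
        for seg, direction in called
    ]
    alterations.sort(key=lambda a: (build.chrom_order(a.interval.chrom), a.interval.start))
    return alterations


def _merge_called(
    called: list[tuple[SegmentRecord, str]], gap_bp: int
) -> list[tuple[SegmentRecord, str]]:
    by_key: dict[tuple[str, str], list[tuple[SegmentRecord, str]]] = {}
    for seg, direction in called:
        by_key.setdefault((seg.interval.chrom, direction), []).append((seg, direction))
    out: list[tuple[SegmentRecord, str]] = []
    for (chrom, direction), group in sorted(by_key.items()):
        group.sort(key=lambda sd: sd[0].interval.start)
        run = [group[0][0]]
        for seg, _ in group[1:]:
            if seg.interval.start - run[-1].interval.end <= gap_bp:
                run.append(seg)
            else:
                out.append((_fuse(run, chrom), direction))
                run = [seg]
        out.append((_fuse(run, chrom), direction))
    return out


def _fuse(run: list[SegmentRecord], chrom: str) -> SegmentRecord:
    if len(run) == 1:
        return run[0]
    start = min(s.interval.start for s in run)
    end = max(s.interval.end for s in run)
    total = sum(s.interval.length for s in run)
    ratio = sum(s.log2_ratio * s.interval.length for s in run) / total
    return SegmentRecord(run[0].sample_id, GenomicInterval(chrom, start, end), ratio)


def classify_cohort(
    segments: Iterable[SegmentRecord],
    build: GenomeBuild,
    params: ClassificationParams = DEFAULT_PARAMS,
    **kwargs,
) -> pd.DataFrame:
    """Classify every sample's segments; returns the classified-events table.

    Columns: sample, chrom, start, end, length, log2_ratio, direction, class.
    Samples appear in sorted order for deterministic output.
    """
    by_sample: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    rows: list[tuple] = []
    for sample in sorted(by_sample):
        for alt in classify_sample(by_sample[sample], build, params, **kwargs):
            rows.append(
                (
                    alt.sample_id,
                    alt.interval.chrom,
                    alt.interval.start,
                    alt.interval.end,
                    alt.length,
                    alt.log2_ratio,
                    alt.direction,
                    alt.alt_class,
                )
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a classified-events TSV, checking the schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: classified-events table missing columns {missing}")
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df = df.loc[:, list(EVENT_COLUMNS)]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
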