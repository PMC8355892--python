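"""Readers and writers for the tabular formats the pipeline touches.

Segmented copy-number tables (SEG dialect, 1-based inclusive on disk),
BED/TSV gene lists, sample annotations and deterministic TSV result tables.
Readers reject malformed coordinates rather than coercing them; coordinate
conventions are converted at this boundary so everything downstream is
zero-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import DataError
from .genome import GenomeBuild, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentRecord:
    """One row of a segmented copy-number profile for one sample."""

    sample_id: str
    interval: GenomicInterval
    log2_ratio: float
    num_probes: Optional[int] = None


@dataclass(frozen=True)
class GeneRecord:
    """A gene with genomic coordinates, as in a cancer-gene census."""

    symbol: str
    interval: GenomicInterval


@dataclass(frozen=True)
class SampleAnnotation:
    """Maps one sample to its tumor-type cohort label."""

    sample_id: str
    tumor_type: str


# Column-name synonyms for SEG headers, keyed by canonical name.  Lookup is
# case-insensitive after stripping dots, underscores and spaces.
SEG_SYNONYMS: dict[str, set[str]] = {
    "sample": {"sample", "id", "sampleid", "samplename"},
    "chrom": {"chromosome", "chrom", "chr"},
    "start": {"start", "locstart", "chromstart"},
    "end": {"end", "locend", "chromend", "stop"},
    "num_probes": {"numprobes", "nummark", "nummarkers", "probes"},
    "log2_ratio": {"segmentmean", "segmean", "log2ratio", "log2", "mean"},
}


def _canonical_columns(columns: Sequence[str]) -> dict[str, str]:
    found: dict[str, str] = {}
    for col in columns:
        key = col.strip().lower().replace(".", "").replace("_", "").replace(" ", "")
        for canon, synonyms in SEG_SYNONYMS.items():
            if key in synonyms and canon not in found:
                found[canon] = col
    return found


def read_seg(
    path: str | Path,
    build: GenomeBuild | None = None,
    *,
    unknown_chrom: str = "error",
    overlap_policy: str = "reject",
) -> list[SegmentRecord]:
    """Read a SEG file into :class:`SegmentRecord` objects.

    On-disk coordinates are 1-based inclusive and are converted to internal
    half-open intervals (row ``start=1001 end=2000`` becomes ``[1000, 2000)``,
    length 1000).  Row order is preserved.

    Parameters
    ----------
    build
        When given, segment coordinates are validated against it;
        ``unknown_chrom`` selects whether rows on unlisted chromosomes raise
        (``"error"``) or are dropped with a logged count (``"skip"``).
    overlap_policy
        Within one sample, ``"reject"`` (default) raises on overlapping
        segments; ``"merge"`` unions overlapping runs, averaging the log2
        ratio weighted by length.
    """
    if unknown_chrom not in ("error", "skip"):
        raise ValueError("unknown_chrom must be 'error' or 'skip'")
    if overlap_policy not in ("reject", "merge"):
        raise ValueError("overlap_policy must be 'reject' or 'merge'")

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _canonical_columns(df.columns)
    for required in ("sample", "chrom", "start", "end", "log2_ratio"):
        if required not in cols:
            raise DataError(f"{path}: SEG header lacks a {required!r} column")

    # re-key to canonical names so dotted/renamed headers don't matter
    canon_df = df[[cols[c] for c in cols]]
    canon_df.columns = list(cols)

    records: list[SegmentRecord] = []
    skipped = 0
    for i, row in enumerate(canon_df.itertuples(index=False), start=2):
        row = dict(zip(canon_df.columns, row))
        get = lambda canon: row[canon]  # noqa: E731
        sample = str(get("sample")).strip()
        chrom = normalize_chrom(get("chrom"))
        try:
            start = int(get("start"))
            end = int(get("end"))
        except (TypeError, ValueError):
            raise DataError(f"{path}, row {i}: unparseable coordinates") from None
        try:
            ratio = float(get("log2_ratio"))
        except (TypeError, ValueError):
            raise DataError(
                f"{path}, row {i}: unparseable segment mean {get('log2_ratio')!r}"
            ) from None
        if not math.isfinite(ratio):
            raise DataError(f"{path}, row {i}: non-finite segment mean")
        if start - 1 >= end:
            raise DataError(
                f"{path}, row {i}: start >= end after coordinate conversion"
            )
        if build is not None and not build.has_chrom(chrom):
            if unknown_chrom == "error":
                raise DataError(f"{path}, row {i}: unknown chromosome {chrom}")
            skipped += 1
            continue
        num_probes: Optional[int] = None
        if "num_probes" in cols:
            raw = get("num_probes")
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                num_probes = int(float(raw))
        records.append(
            SegmentRecord(sample, GenomicInterval(chrom, start - 1, end), ratio, num_probes)
        )
    if skipped:
        logger.warning("%s: skipped %d rows on unknown chromosomes", path, skipped)

    _check_sample_overlaps(records, overlap_policy, str(path))
    if overlap_policy == "merge":
        records = _merge_overlapping(records)
    return records


def _check_sample_overlaps(
    records: list[SegmentRecord], policy: str, source: str
) -> None:
    if policy != "reject":
        return
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sample_id, rec.interval.chrom), []).append(rec)
    for (sample, chrom), group in by_key.items():
        group = sorted(group, key=lambda r: r.interval.start)
        for left, right in zip(group, group[1:]):
            if left.interval.end > right.interval.start:
                raise DataError(
                    f"{source}: overlapping segments for sample {sample} on {chrom} "
                    f"({left.interval.start}-{left.interval.end} vs "
                    f"{right.interval.start}-{right.interval.end})"
                )


def _merge_overlapping(records: list[SegmentRecord]) -> list[SegmentRecord]:
    """Union overlapping same-sample runs; ratio is length-weighted mean."""
    out: list[SegmentRecord] = []
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sample_id, rec.interval.chrom), []).append(rec)
    for (sample, chrom), group in sorted(by_key.items()):
        group = sorted(group, key=lambda r: r.interval.start)
        run = [group[0]]
        for rec in group[1:]:
            if rec.interval.start < run[-1].interval.end:
                run.append(rec)
            else:
                out.append(_collapse(run, sample, chrom))
                run = [rec]
        out.append(_collapse(run, sample, chrom))
    return out


def _collapse(run: list[SegmentRecord], sample: str, chrom: str) -> SegmentRecord:
    if len(run) == 1:
        return run[0]
    start = min(r.interval.start for r in run)
    end = max(r.interval.end for r in run)
    total = sum(r.interval.length for r in run)
    ratio = sum(r.log2_ratio * r.interval.length for r in run) / total
    return SegmentRecord(sample, GenomicInterval(chrom, start, end), ratio)


def write_seg(records: Sequence[SegmentRecord], path: str | Path) -> None:
    """Write segments in the SEG dialect (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for rec in records:
            probes = "" if rec.num_probes is None else str(rec.num_probes)
            fh.write(
                f"{rec.sample_id}\t{rec.interval.chrom}\t{rec.interval.start + 1}\t"
                f"{rec.interval.end}\t{probes}\t{rec.log2_ratio:.6g}\n"
            )


def read_gene_census(
    path: str | Path,
    build: GenomeBuild | None = None,
    dialect: str = "bed",
) -> list[GeneRecord]:
    """Read a gene list in BED4 (default) or headered-TSV dialect.

    BED is 0-based half-open with no header (chrom, start, end, symbol); the
    TSV dialect has a header (symbol, chrom, start, end) with 1-based
    inclusive coordinates.  Both land on identical internal intervals.
    Duplicate symbols and zero-length genes are rejected.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()

    def add(symbol: str, chrom: str, start: int, end: int, lineno: int) -> None:
        if symbol in seen:
            raise DataError(f"{path}, line {lineno}: duplicate gene symbol {symbol}")
        seen.add(symbol)
        if start >= end:
            raise DataError(f"{path}, line {lineno}: zero-length gene {symbol}")
        chrom = normalize_chrom(chrom)
        if build is not None:
            if not build.has_chrom(chrom):
                raise DataError(f"{path}, line {lineno}: unknown chromosome {chrom}")
            if end > build.chrom_length(chrom):
                raise DataError(
                    f"{path}, line {lineno}: gene {symbol} extends beyond {chrom}"
                )
        genes.append(GeneRecord(symbol, GenomicInterval(chrom, start, end)))

    with open(path) as fh:
        if dialect == "bed":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise DataError(f"{path}, line {lineno}: BED4 needs four columns")
                add(fields[3], fields[0], int(fields[1]), int(fields[2]), lineno)
        elif dialect == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c.strip().lower(): i for i, c in enumerate(header)}
            for key in ("symbol", "chrom", "start", "end"):
                if key not in cols:
                    raise DataError(f"{path}: TSV gene table missing column {key!r}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                add(
                    f[cols["symbol"]].strip(),
                    f[cols["chrom"]],
                    int(f[cols["start"]]) - 1,
                    int(f[cols["end"]]),
                    lineno,
                )
        else:
            raise ValueError("dialect must be 'bed' or 'tsv'")
    return genes


def write_gene_bed(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.symbol}\n")


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample -> tumor-type map (two-column TSV with header).

    A sample listed twice with conflicting tumor types is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    sample_col = next((cols[k] for k in ("sample", "sample_id", "id") if k in cols), None)
    type_col = next(
        (cols[k] for k in ("tumor_type", "type", "cohort", "tumortype") if k in cols),
        None,
    )
    if sample_col is None or type_col is None:
        raise DataError(f"{path}: annotation table needs sample and tumor_type columns")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        sample = str(row[sample_col]).strip()
        ttype = str(row[type_col]).strip()
        if sample in mapping and mapping[sample] != ttype:
            raise DataError(
                f"{path}: sample {sample} annotated with conflicting tumor types "
                f"{mapping[sample]!r} and {ttype!r}"
            )
        mapping[sample] = ttype
    return [SampleAnnotation(s, t) for s, t in mapping.items()]


def annotations_to_map(annotations: Sequence[SampleAnnotation]) -> dict[str, str]:
    return {a.sample_id: a.tumor_type for a in annotations}


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttumor_type\n")
        for a in annotations:
            fh.write(f"{a.sample_id}\t{a.tumor_type}\n")


def write_table(
    df: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None
) -> None:
    """Write a result table as deterministic TSV.

    Rows are sorted by ``sort_by`` (default: all columns, left to right) so
    output bytes do not depend on input order; floats are serialised with 6
    significant digits.
    """
    if sort_by is None:
        sort_by = list(df.columns)
    if len(df) and sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
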