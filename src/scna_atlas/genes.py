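"""Gene-level amplification/deletion calls via the 50% overlap rule.

A census gene is called amplified (deleted) in a sample when at least
``gene_overlap_frac`` (default 50%, inclusive) of the gene body is covered
by that sample's amplification (deletion) events of the included classes —
SCNA-class events only by default.  Coverage is the union over events
(``mode="union"``), so one biological event split by segmentation still
produces the call; ``mode="single"`` requires the threshold to be met by
one event alone.  A gene may carry both an AMP and a DEL call in the same
sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classify import AMP, DEL, DIRECTIONS, SCNA, ClassificationParams, DEFAULT_PARAMS
from .errors import DataError

from .io import GeneRecord
from .stats import interval_union_bp

logger = logging.getLogger(__name__)

GENE_CALL_COLUMNS = ("sample", "gene", "direction", "overlap_fraction")


@dataclass(frozen=True)
class GeneCall:
    sample_id: str
    symbol: str
    direction: str
    overlap_fraction: float


def _gene_coverage(
    gene: GeneRecord, events: pd.DataFrame, mode: str
) -> float:
    """Fraction of the gene body covered by the given events."""
    g = gene.interval
    sub = events[events["chrom"] == g.chrom]
    if not len(sub):
        return 0.0
    if mode == "union":
        clipped = [
            (g.chrom, max(int(s), g.start), min(int(e), g.end))
            for s, e in zip(sub["start"], sub["end"])
            if min(int(e), g.end) > max(int(s), g.start)
        ]
        covered = interval_union_bp(clipped) if clipped else 0
        return covered / g.length
    # single-event mode: best single overlap
    best = 0
    for s, e in zip(sub["start"], sub["end"]):
        ov = max(0, min(int(e), g.end) - max(int(s), g.start))
        best = max(best, ov)
    return best / g.length


def call_genes(
    sample_events: pd.DataFrame,
    genes: Sequence[GeneRecord],
    params: ClassificationParams = DEFAULT_PARAMS,
    include_classes: frozenset[str] | set[str] = frozenset({SCNA}),
    mode: str = "union",
) -> list[GeneCall]:
    """Gene calls for one sample's classified events.

    Returns at most one call per (gene, direction); AMP and DEL coverage are
    computed independently.
    """
    if mode not in ("union", "single"):
        raise ValueError("mode must be 'union' or 'single'")
    if len(sample_events) and sample_events["sample"].nunique() > 1:
        raise DataError("call_genes received events from multiple samples")
    sample_id = str(sample_events["sample"].iloc[0]) if len(sample_events) else ""
    events = sample_events[sample_events["class"].isin(include_classes)]
    calls: list[GeneCall] = []
    for direction in DIRECTIONS:
        dir_events = events[events["direction"] == direction]
        if not len(dir_events):
            continue
        for gene in genes:
            frac = _gene_coverage(gene, dir_events, mode)
            if frac >= params.gene_overlap_frac:
                calls.append(GeneCall(sample_id, gene.symbol, direction, frac))
    return calls


def call_genes_cohort(
    events: pd.DataFrame,
    genes: Sequence[GeneRecord],
    params: ClassificationParams = DEFAULT_PARAMS,
    include_classes: frozenset[str] | set[str] = frozenset({SCNA}),
    mode: str = "union",
) -> pd.DataFrame:
    """Gene-call table over the whole cohort (sample, gene, direction, fraction)."""
    rows = []
    for sample, sub in events.groupby("sample"):
        for call in call_genes(sub, genes, params, include_classes, mode):
            rows.append(
                (call.sample_id, call.symbol, call.direction, call.overlap_fraction)
            )
    return pd.DataFrame(rows, columns=GENE_CALL_COLUMNS)


def gene_frequency(
    calls: pd.DataFrame,
    annotations: Mapping[str, str],
    genes: Sequence[GeneRecord] | None = None,
) -> pd.DataFrame:
    """Alteration frequency of each (gene, direction) per tumor type and pan-cohort.

    The denominator of each tumor type is the number of annotated samples of
    that type; the pan-cohort row (tumor_type ``PAN``) uses every sample.
    Rows are ordered by descending pan-cohort frequency then symbol, so the
    table is deterministic regardless of input order.  When ``genes`` is
    given, never-called genes appear with zero frequency.
    """
    type_sizes: dict[str, int] = {}
    for ttype in annotations.values():
        type_sizes[ttype] = type_sizes.get(ttype, 0) + 1
    n_total = len(annotations)
    if n_total == 0:
        raise DataError("gene_frequency requires a non-empty sample annotation map")

    symbols = sorted({g.symbol for g in genes}) if genes is not None else sorted(
        calls["gene"].unique()
    )
    calls = calls.assign(
        tumor_type=calls["sample"].map(lambda s: annotations.get(s, "UNKNOWN"))
    )
    rows = []
    for symbol in symbols:
        for direction in DIRECTIONS:
            sub = calls[(calls["gene"] == symbol) & (calls["direction"] == direction)]
            n_pan = sub["sample"].nunique()
            pan_freq = n_pan / n_total
            rows.append(
                {
                    "gene": symbol,
                    "direction": direction,
                    "tumor_type": "PAN",
                    "n_called": n_pan,
                    "n_samples": n_total,
                    "frequency": pan_freq,
                    "pan_frequency": pan_freq,
                }
            )
            for ttype, size in sorted(type_sizes.items()):
                n_t = sub.loc[sub["tumor_type"] == ttype, "sample"].nunique()
                rows.append(
                    {
                        "gene": symbol,
                        "direction": direction,
                        "tumor_type": ttype,
                        "n_called": n_t,
                        "n_samples": size,
                        "frequency": n_t / size,
                        "pan_frequency": pan_freq,
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["pan_frequency", "gene", "direction", "tumor_type"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def top_genes(freq: pd.DataFrame, k: int, direction: str) -> pd.DataFrame:
    """Top ``k`` genes of one direction by pan-cohort frequency.

    Ties break alphabetically by symbol.  When fewer than ``k`` genes exist,
    all are returned with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pan = freq[(freq["tumor_type"] == "PAN") & (freq["direction"] == direction)]
    pan = pan.sort_values(
        ["frequency", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if len(pan) < k:
        logger.warning("top_genes: only %d genes available for k=%d", len(pan), k)
    out = pan.head(k).copy()
    out.insert(0, "rank", range(1, len(out) + 1))
    return out[["rank", "gene", "direction", "n_called", "n_samples", "frequency"]]
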