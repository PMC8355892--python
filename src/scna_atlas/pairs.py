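"""Co-amplification / co-deletion of census gene pairs across a cohort.

A sample contributes at most once to each (pair, event type): AMP-AMP when
both genes carry an amplification call, DEL-DEL when both carry a deletion
call, AMP-DEL when the directions differ (the amplified member is recorded
explicitly).  Frequencies are fractions of samples, pan-cohort or per tumor
type.  Only observed (nonzero) pairs are materialised.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .classify import AMP, DEL
from .errors import DataError
from .genome import GenomeBuild, overlap_bp
from .io import GeneRecord

AMP_AMP = "AMP-AMP"
DEL_DEL = "DEL-DEL"
AMP_DEL = "AMP-DEL"
EVENT_TYPES = (AMP_AMP, DEL_DEL, AMP_DEL)

PAIR_COLUMNS = (
    "gene_a",
    "gene_b",
    "event_type",
    "amp_gene",
    "tumor_type",
    "n_samples_co_altered",
    "n_samples",
    "frequency",
    "same_chromosome",
    "same_arm",
)


def pair_events(
    calls: pd.DataFrame | Sequence[tuple[str, str]],
) -> set[tuple[str, str, str, str]]:
    """Pair events of one sample: set of (gene_a, gene_b, event_type, amp_gene).

    ``calls`` is either a gene-call DataFrame slice for one sample or an
    iterable of (gene, direction) tuples.  Gene pairs are unordered with
    ``gene_a < gene_b``; self-pairs are excluded.  ``amp_gene`` names the
    amplified member of an AMP-DEL pair and is empty otherwise.  A pair can
    contribute several event types for one sample only when a gene carries
    both an AMP and a DEL call.
    """
    if isinstance(calls, pd.DataFrame):
        if len(calls) and calls["sample"].nunique() > 1:
            raise DataError("pair_events expects the calls of a single sample")
        items = list(zip(calls["gene"], calls["direction"]))
    else:
        items = list(calls)
    directions: dict[str, set[str]] = {}
    for gene, direction in items:
        directions.setdefault(gene, set()).add(direction)
    events: set[tuple[str, str, str, str]] = set()
    for a, b in combinations(sorted(directions), 2):
        for da in directions[a]:
            for db in directions[b]:
                if da == AMP and db == AMP:
                    events.add((a, b, AMP_AMP, ""))
                elif da == DEL and db == DEL:
                    events.add((a, b, DEL_DEL, ""))
                else:
                    events.add((a, b, AMP_DEL, a if da == AMP else b))
    return events


def _gene_arms(
    genes: Sequence[GeneRecord], build: GenomeBuild
) -> dict[str, tuple[str, str]]:
    """Map symbol -> (chrom, arm label); arm by maximum overlap, '' if none."""
    out: dict[str, tuple[str, str]] = {}
    for gene in genes:
        arms = build.arms_of(gene.interval.chrom)
        best, best_ov = "", 0
        for arm in arms:
            ov = overlap_bp(gene.interval, arm)
            if ov > best_ov:
                best, best_ov = arm.arm, ov
        out[gene.symbol] = (gene.interval.chrom, best)
    return out


def pair_frequency(
    calls: pd.DataFrame,
    annotations: Mapping[str, str],
    genes: Sequence[GeneRecord],
    build: GenomeBuild,
    scope: str = "pan",
) -> pd.DataFrame:
    """Co-alteration frequency of every observed gene pair.

    Counts samples, not events.  ``scope="pan"`` uses the whole cohort
    (tumor_type column ``PAN``); ``scope="per_type"`` emits one block per
    tumor type with that type's sample count as denominator.
    """
    if scope not in ("pan", "per_type"):
        raise ValueError("scope must be 'pan' or 'per_type'")
    if not annotations:
        raise DataError("pair_frequency requires a non-empty annotation map")
    locations = _gene_arms(genes, build)

    sample_types = dict(annotations)
    type_sizes: dict[str, int] = {}
    for ttype in sample_types.values():
        type_sizes[ttype] = type_sizes.get(ttype, 0) + 1

    # (tumor_type, pair-key) -> sample count
    counts: dict[tuple[str, tuple[str, str, str, str]], int] = {}
    for sample, sub in calls.groupby("sample"):
        ttype = sample_types.get(str(sample), "UNKNOWN")
        for key in pair_events(sub):
            if scope == "pan":
                counts[("PAN", key)] = counts.get(("PAN", key), 0) + 1
            else:
                counts[(ttype, key)] = counts.get((ttype, key), 0) + 1

    n_total = len(sample_types)
    rows = []
    for (ttype, (a, b, etype, amp_gene)), n in sorted(counts.items()):
        denom = n_total if ttype == "PAN" else type_sizes.get(ttype, 0)
        if denom == 0:
            continue
        chrom_a, arm_a = locations.get(a, ("", ""))
        chrom_b, arm_b = locations.get(b, ("", ""))
        same_chrom = bool(chrom_a) and chrom_a == chrom_b
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "event_type": etype,
                "amp_gene": amp_gene,
                "tumor_type": ttype,
                "n_samples_co_altered": n,
                "n_samples": denom,
                "frequency": n / denom,
                "same_chromosome": same_chrom,
                "same_arm": same_chrom and bool(arm_a) and arm_a == arm_b,
            }
        )
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS))


def filter_pairs(
    pairs: pd.DataFrame,
    min_frequency: float = 0.05,
    inter_chromosomal_only: bool = False,
    event_types: Sequence[str] = (AMP_AMP, DEL_DEL),
) -> pd.DataFrame:
    """Keep pairs at or above ``min_frequency`` (inclusive).

    ``inter_chromosomal_only`` masks same-chromosome pairs; AMP-DEL pairs
    are excluded by default to match the co-amplification/co-deletion view.
    """
    if not (0 <= min_frequency <= 1):
        raise ValueError("min_frequency must be in [0, 1]")
    out = pairs[
        (pairs["frequency"] >= min_frequency)
        & pairs["event_type"].isin(event_types)
    ]
    if inter_chromosomal_only:
        out = out[~out["same_chromosome"]]
    return out.reset_index(drop=True)


def participation(pairs: pd.DataFrame, k: int) -> pd.DataFrame:
    """Per-gene membership counts among the top ``k`` pairs by frequency.

    Pairs are ranked by descending frequency with lexicographic
    (gene_a, gene_b) tie-breaking; with fewer than ``k`` pairs, all are used
    and the actual count is recorded in ``k_used``.  Pass a single event
    type (pre-filtered) for the conventional hub-gene counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = pairs.sort_values(
        ["frequency", "gene_a", "gene_b"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(k)
    k_used = len(ranked)
    tally: dict[str, int] = {}
    for a, b in zip(ranked["gene_a"], ranked["gene_b"]):
        tally[a] = tally.get(a, 0) + 1
        tally[b] = tally.get(b, 0) + 1
    rows = [
        {"gene": g, "k_used": k_used, "n_pairs_involving_gene": n}
        for g, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["gene", "k_used", "n_pairs_involving_gene"])
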