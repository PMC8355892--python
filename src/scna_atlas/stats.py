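"""Per-sample and per-tumor-type burden statistics.

Covers the fraction of genome altered, event counts by direction and class,
SCNA length summaries, per-chromosome SCNA distributions and the two-group
comparisons (two-sided Wilcoxon rank-sum, Spearman correlation) with the
conventional star labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .classify import AMP, ANEUPLOIDY, CLASSES, DEL, DIRECTIONS, INDEL, SCNA
from .errors import DataError
from .genome import GenomeBuild

logger = logging.getLogger(__name__)

#: Per-sample burden metrics emitted by :func:`burden_table`.
BURDEN_METRICS = (
    "n_amp",
    "n_del",
    "n_indel",
    "n_scna",
    "n_aneuploidy",
    "pct_genome_amp",
    "pct_genome_del",
    "mean_scna_len_amp",
    "mean_scna_len_del",
)


@dataclass
class SampleBurden:
    """Alteration burden of one sample.

    Percentages are of the analysis-set genome length covered by the union
    of the sample's called events, separately for amplifications and
    deletions.  Mean lengths cover SCNA-class events only and are NaN when
    no such event exists.
    """

    sample_id: str
    tumor_type: str
    counts: dict[tuple[str, str], int]
    pct_genome_amp: float
    pct_genome_del: float
    mean_scna_len_amp: float
    mean_scna_len_del: float


def interval_union_bp(intervals: Iterable[tuple[str, int, int]]) -> int:
    """Total base pairs covered by the union of (chrom, start, end) intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        total += cur_end - cur_start
    return total


def sample_burden(
    alts: pd.DataFrame,
    build: GenomeBuild,
    sample_id: str,
    tumor_type: str = "UNKNOWN",
) -> SampleBurden:
    """Burden statistics for one sample's classified events.

    ``alts`` uses the classified-events schema and must contain rows of a
    single sample (or be empty).
    """
    if len(alts) and alts["sample"].nunique() > 1:
        raise DataError("sample_burden received events from multiple samples")
    counts = {(d, c): 0 for d in DIRECTIONS for c in CLASSES}
    for (d, c), n in alts.groupby(["direction", "class"]).size().items():
        counts[(d, c)] = int(n)
    denom = build.analysis_length
    pct = {}
    mean_len = {}
    for direction in DIRECTIONS:
        sub = alts[alts["direction"] == direction]
        covered = interval_union_bp(
            zip(sub["chrom"], sub["start"], sub["end"])
        ) if len(sub) else 0
        pct[direction] = 100.0 * covered / denom
        scna_lens = sub.loc[sub["class"] == SCNA, "length"]
        mean_len[direction] = float(scna_lens.mean()) if len(scna_lens) else float("nan")
    return SampleBurden(
        sample_id=sample_id,
        tumor_type=tumor_type,
        counts=counts,
        pct_genome_amp=pct[AMP],
        pct_genome_del=pct[DEL],
        mean_scna_len_amp=mean_len[AMP],
        mean_scna_len_del=mean_len[DEL],
    )


def burden_table(
    events: pd.DataFrame,
    build: GenomeBuild,
    annotations: Mapping[str, str],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample burden table over the whole cohort.

    The sample roster is the union of ``samples`` (if given), the annotation
    keys and the samples present in ``events``, so samples with no called
    event still contribute zero burden.  Samples missing from the
    annotations get tumor_type ``UNKNOWN`` with a logged warning.
    """
    roster = set(annotations) | set(events["sample"].unique())
    if samples is not None:
        roster |= set(samples)
    unknown = sorted(s for s in roster if s not in annotations)
    if unknown:
        logger.warning(
            "%d samples lack a tumor-type annotation; assigned UNKNOWN", len(unknown)
        )
    rows = []
    grouped = dict(tuple(events.groupby("sample"))) if len(events) else {}
    empty = events.iloc[0:0]
    for sample in sorted(roster):
        b = sample_burden(
            grouped.get(sample, empty), build, sample, annotations.get(sample, "UNKNOWN")
        )
        rows.append(
            {
                "sample": b.sample_id,
                "tumor_type": b.tumor_type,
                "n_amp": sum(b.counts[(AMP, c)] for c in CLASSES),
                "n_del": sum(b.counts[(DEL, c)] for c in CLASSES),
                "n_indel": b.counts[(AMP, INDEL)] + b.counts[(DEL, INDEL)],
                "n_scna": b.counts[(AMP, SCNA)] + b.counts[(DEL, SCNA)],
                "n_aneuploidy": b.counts[(AMP, ANEUPLOIDY)] + b.counts[(DEL, ANEUPLOIDY)],
                "n_scna_amp": b.counts[(AMP, SCNA)],
                "n_scna_del": b.counts[(DEL, SCNA)],
                "pct_genome_amp": b.pct_genome_amp,
                "pct_genome_del": b.pct_genome_del,
                "mean_scna_len_amp": b.mean_scna_len_amp,
                "mean_scna_len_del": b.mean_scna_len_del,
            }
        )
    return pd.DataFrame(rows)


def cohort_tables(burdens: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor-type summary of the burden metrics, plus a pooled ALL row.

    One row per tumor type with sample count ``n`` and mean/sd of each
    metric (NaN-aware for the mean-length columns).
    """
    def summarize(group: pd.DataFrame, label: str) -> dict:
        row: dict = {"tumor_type": label, "n": len(group)}
        for metric in BURDEN_METRICS:
            vals = group[metric].dropna()
            row[f"mean_{metric}"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"sd_{metric}"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        return row

    rows = [summarize(g, t) for t, g in burdens.groupby("tumor_type")]
    rows.append(summarize(burdens, "ALL"))
    return pd.DataFrame(rows)


def scna_length_stats(events: pd.DataFrame) -> pd.DataFrame:
    """Pooled event-level SCNA length mean/sd, overall and per direction."""
    scna = events[events["class"] == SCNA]
    rows = []
    for label, sub in (("ALL", scna), (AMP, scna[scna["direction"] == AMP]),
                       (DEL, scna[scna["direction"] == DEL])):
        lens = sub["length"].to_numpy(dtype=float)
        rows.append(
            {
                "direction": label,
                "n_events": len(lens),
                "mean_bp": float(lens.mean()) if len(lens) else float("nan"),
                "sd_bp": float(lens.std(ddof=1)) if len(lens) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def class_mix(events: pd.DataFrame, annotations: Mapping[str, str]) -> pd.DataFrame:
    """Percentage of indels, SCNAs and aneuploidies among called events, per type.

    Tumor types with no called event report NaN (missing), not zero.
    """
    events = events.assign(
        tumor_type=events["sample"].map(lambda s: annotations.get(s, "UNKNOWN"))
    )
    types = sorted(set(annotations.values()) | set(events["tumor_type"].unique()))
    rows = []
    for ttype in types:
        sub = events[events["tumor_type"] == ttype]
        n = len(sub)
        row = {"tumor_type": ttype, "n_events": n}
        for cls in CLASSES:
            row[f"pct_{cls.lower()}"] = (
                100.0 * (sub["class"] == cls).sum() / n if n else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def chrom_distribution(
    events: pd.DataFrame,
    annotations: Mapping[str, str],
    build: GenomeBuild,
    mode: str = "divide",
) -> pd.DataFrame:
    """Per-chromosome SCNA distribution for each tumor type.

    Raw proportion is ``n_c / N`` over SCNA-class events.  The normalised
    value divides by the chromosome length in Mb (``mode="divide"``) or
    multiplies by it (``mode="literal"``); both conventions are in
    circulation, hence the explicit mode.  With no SCNA in a type, all
    values are missing.
    """
    if mode not in ("divide", "literal"):
        raise ValueError("mode must be 'divide' or 'literal'")
    scna = events[events["class"] == SCNA]
    scna = scna.assign(
        tumor_type=scna["sample"].map(lambda s: annotations.get(s, "UNKNOWN"))
    )
    types = sorted(set(annotations.values()) | set(scna["tumor_type"].unique()))
    rows = []
    for ttype in types:
        sub = scna[scna["tumor_type"] == ttype]
        counts = sub.groupby("chrom").size()
        total = int(counts.sum())
        for chrom in build.analysis_set:
            n_c = int(counts.get(chrom, 0))
            length_mb = build.chrom_length(chrom) / 1e6
            if total == 0:
                raw = value = float("nan")
            else:
                raw = n_c / total
                value = raw / length_mb if mode == "divide" else raw * length_mb
            rows.append(
                {
                    "tumor_type": ttype,
                    "chrom": chrom,
                    "n_scna": n_c,
                    "raw_proportion": raw,
                    "normalized": value,
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)


# -- hypothesis tests -----------------------------------------------------


def wilcoxon_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration when both groups have at most 25 observations
    and there are no ties, and otherwise the normal approximation with tie
    and continuity corrections — mirroring R's ``wilcox.test`` defaults.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("wilcoxon_two_sided requires two non-empty groups")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and x.size <= 25 and y.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sp_stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with its t-approximation p-value.

    Returns ``(nan, nan)`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("spearman requires >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    rho, p = sp_stats.spearmanr(x, y)
    return float(rho), float(p)


def stars(p_value: float) -> str:
    """Significance label: * <0.05, ** <0.01, *** <0.001, **** <0.0001.

    Boundary values take the weaker label (p = 0.05 is ``ns``).
    """
    if not (0 <= p_value <= 1):
        raise DataError(f"p-value out of [0, 1]: {p_value}")
    if p_value < 0.0001:
        return "****"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


#: Burden metric pairs compared AMP vs DEL within each tumor type.
COMPARISON_METRICS = (
    ("n_events", "n_amp", "n_del"),
    ("pct_genome", "pct_genome_amp", "pct_genome_del"),
    ("mean_scna_len", "mean_scna_len_amp", "mean_scna_len_del"),
)


def group_comparisons(burdens: pd.DataFrame) -> pd.DataFrame:
    """AMP-vs-DEL Wilcoxon comparisons per tumor type (and pooled).

    One row per (tumor type, metric) with the two-sided p-value and star
    label; a comparison with an empty group reports a missing p-value and
    the label ``na``.
    """
    rows = []
    groups = [(t, g) for t, g in burdens.groupby("tumor_type")]
    groups.append(("ALL", burdens))
    for ttype, group in groups:
        for label, amp_col, del_col in COMPARISON_METRICS:
            x = group[amp_col].dropna().to_numpy()
            y = group[del_col].dropna().to_numpy()
            if x.size and y.size:
                p = wilcoxon_two_sided(x, y)
                star = stars(p)
            else:
                p, star = float("nan"), "na"
            rows.append(
                {"tumor_type": ttype, "metric": label, "p_value": p, "stars": star}
            )
    return pd.DataFrame(rows)


def amp_del_correlations(burdens: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between amplification and deletion burden.

    Emitted at two levels, labelled distinctly: across samples within each
    tumor type, and across tumor types on the per-type means.
    """
    rows = []
    for ttype, group in burdens.groupby("tumor_type"):
        if len(group) >= 3:
            rho, p = spearman(group["n_amp"], group["n_del"])
        else:
            rho, p = float("nan"), float("nan")
        rows.append(
            {
                "level": "per_sample_within_type",
                "tumor_type": ttype,
                "metric": "n_amp_vs_n_del",
                "rho": rho,
                "p_value": p,
                "n": len(group),
            }
        )
    means = burdens.groupby("tumor_type")[["n_amp", "n_del"]].mean()
    if len(means) >= 3:
        rho, p = spearman(means["n_amp"], means["n_del"])
    else:
        rho, p = float("nan"), float("nan")
    rows.append(
        {
            "level": "across_type_means",
            "tumor_type": "ALL",
            "metric": "n_amp_vs_n_del",
            "rho": rho,
            "p_value": p,
            "n": len(means),
        }
    )
    return pd.DataFrame(rows)
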