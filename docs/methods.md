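# Methods

## Event model

The unit of analysis is a segmented copy-number row: one sample, one
genomic interval, one log2 tumor/normal copy ratio. The pipeline takes the
segment mean as given — no re-centering, ploidy correction, GC correction
or re-segmentation — because the taxonomy it implements is defined directly
on thresholded segment means.

Direction calling uses two strict thresholds: amplified when
`log2_ratio > amp_log2` (default 0.32, ≈ 2.5 copies in a diploid genome),
deleted when `log2_ratio < del_log2` (default −0.42, ≈ 1.5 copies). Values
at a threshold are neutral. "Above", "below", "more than" and "smaller
than" are all read as strict inequalities; the gene-call rule's "at least"
is inclusive. All five constants are configuration-visible, so the
opposite convention is reproducible if a dataset requires it.

Each called event receives exactly one class, tested in this order:

1. **indel** — `length < indel_max_bp` (default 10,000; an event of exactly
   10 kb is not an indel);
2. **aneuploidy** — the maximum covered fraction over the *eligible* arms of
   the event's chromosome exceeds `arm_frac` (default 0.75, strict).
   Acrocentric short arms are ineligible for this test only: their sequence
   still counts toward event length and genome-fraction denominators;
3. **SCNA** — everything else.

For a centromere-spanning event the arm fraction is evaluated per arm and
the maximum decides, so a whole-chromosome gain is a single aneuploidy,
never one event per arm. This per-arm-maximum rule is a declared design
choice: with p+q pooling, a segment covering 40% of each arm would count as
covering 80% of "an arm", which contradicts the arm-level definition.

Adjacent same-direction segments are **not** merged before classification;
segmentation output is classified as provided. A gap-tolerant merge is
available behind a flag (`merge_adjacent`) because merging changes event
counts and therefore must be opt-in.

## Coordinate conventions

Internal coordinates are zero-based half-open everywhere, so
`length = end − start` with no ±1 bookkeeping. Conversions happen only at
file boundaries: SEG and the arm table are 1-based inclusive on disk (the
common convention for those formats), BED is 0-based half-open. Chromosome
names are normalised to carry the `chr` prefix on read. A centromeric gap —
a region belonging to neither arm — is permitted, since many cytoband
sources leave centromeres outside the p/q extents; event length, not
arm-assigned length, drives the indel rule.

The analysis set (the chromosomes entering genome-fraction denominators and
per-chromosome tables) defaults to all listed chromosomes except chrY;
chrX is included. Events on chromosomes outside the analysis set are
dropped with a logged count so numerators and denominators stay consistent.

## Burden statistics

Percent genome amplified (deleted) is 100 × the union of a sample's called
amplification (deletion) events — all three classes — divided by the total
analysis-set length. The union guards against double counting when events
overlap after, e.g., permissive reading modes. Mean SCNA length covers
SCNA-class events only (indels and aneuploidies excluded) and is reported
missing, not zero, when a sample has no SCNA of that direction. Class-mix
percentages are likewise missing for a tumor type with no called events.

Per-chromosome SCNA distributions report the raw proportion
`n_c / N` over SCNA-class events and a length-normalised value. Two
normalisation conventions circulate for this quantity — dividing the
proportion by the chromosome length in Mb, or multiplying by it — and they
answer different questions (rate per Mb vs. a length-weighted share). Both
are implemented; `divide` is the default and `literal` selects the
multiplicative form. Neither is silently chosen: the mode is echoed in the
output table.

## Hypothesis tests

The amplification-vs-deletion comparisons use the two-sided unpaired
Wilcoxon rank-sum test, computed via `scipy.stats.mannwhitneyu`: exact
enumeration when both groups have ≤ 25 observations and no ties, otherwise
the normal approximation with tie and continuity corrections — the same
dispatch R's `wilcox.test` applies. Star labels follow the conventional
cutoffs (* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001; boundary values
take the weaker label). No multiple-testing correction is applied by
default; per-type stars are reported as-is, and Benjamini–Hochberg can be
layered on by the caller if rigor across 30+ types is needed.

Spearman correlations between per-sample amplification and deletion counts
are emitted at two labelled levels — across samples within each tumor type,
and across tumor types on per-type means — because the two aggregations
answer different questions and are easily conflated. A constant input
vector yields a missing correlation rather than an arbitrary value.

## Gene calls and pairs

A census gene is called amplified (deleted) when the union of the sample's
amplification (deletion) events of the included classes covers at least
`gene_overlap_frac` (default 0.50) of the gene body. Union-of-events is the
default because segmentation can split one biological event into several
rows; a single-event mode exists for the stricter reading. Only SCNA-class
events count by default (configurable), so an arm-level aneuploidy does not
flood the gene table. AMP and DEL coverage are computed independently and a
gene may carry both calls in one sample; dropping either would bias the
direction-specific frequencies.

Pair counting is at sample granularity: a sample contributes 0 or 1 to each
(pair, event type), so frequencies are fractions of tumors. AMP-DEL pairs
record which member is amplified; they are computed and written but
excluded from the filtered co-amplification/co-deletion view by default.
The frequency filter (default 5%) is inclusive. Top-pair participation
ranks pairs by descending frequency with lexicographic (gene_a, gene_b)
tie-breaking — without a documented tie rule the top-k list is not
reproducible. Only observed pairs are materialised; the full
quadratic pair matrix is never built densely.

## Synthetic cohorts

The generator emulates the statistical structure of a pan-cancer segmented
release at desk scale. The default cohort is five tumor types × 50 samples
with per-type mean amplification counts 4–10 and deletion counts 3–8 per
sample, negative-binomial via a gamma-Poisson mixture. By default one
gamma intensity (shape 3.0, mean 1) is shared between a sample's
amplification and deletion rates, producing the positive within-sample
amp/del correlation observed in real tumors; switching the coupling off
makes the counts independent. The class mix defaults to 25% indels, 70%
SCNAs, 5% aneuploidies — SCNAs dominant, indels second, arm events rare, as
in real cohorts. SCNA lengths are log-normal (median 2 Mb, σ = 1 on the log
scale) truncated to the legal SCNA range for the target arm.

Every decision boundary carries a guard margin (0.02 log2 units, 100 bp on
lengths) so no generated event is ambiguous under the default thresholds:
ratios are drawn uniformly in [amp + m, amp + m + 1] for amplifications and
[del − m − 1, del − m] for deletions; neutral filler segments sit strictly
inside the neutral band. Log2 ratios are rounded to four decimals at
generation so every downstream serialisation (6 significant digits) is
lossless and the truth tables equal the files bit-for-bit.

Events within a sample are placed without overlap by bounded rejection
sampling (200 attempts); exhaustion raises an error before any file is
written — never a silent truncation, which would corrupt the union
arithmetic the truth tables guarantee. Within a sample, arm-scale events
are placed before focal ones so they can still find an unobstructed arm.
Background (non-planted) indel and SCNA events never touch census genes;
with the default SCNA-only gene-calling configuration the planted gene
incidence is therefore the complete gene-call truth. Planted genes are
realised by an SCNA fully covering the gene in `round(freq × n)` samples of
each type, so planted frequencies are exact, and planted pairs either by
two independent events or by one shared event spanning both genes of a
same-arm pair (the mechanism behind the elevated intra-arm co-alteration
frequency). The pair-incidence truth is enumerated per sample from the
gene-incidence truth, including any co-occurrence that arises from
independent plantings, so it is consistent with the emitted segments by
construction.

The default toy genome is eight 100-Mb chromosomes (p arm 45 Mb, 5-Mb
centromeric gap, q arm 50 Mb) with two 100-kb census genes per q arm;
acrocentric-flagged arms are supported for testing the aneuploidy
exclusion. What the generator does **not** emulate: probe-level noise,
segmentation error, real per-cancer-type burden profiles, wavy GC artifacts
or subclonal fractions. Tests passing on these cohorts therefore validate
the *arithmetic and contracts* of the pipeline, not its robustness to
noisy real-world segmentation.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical specs produce byte-identical files.

## Problem sizes and determinism

The test suite runs the full pipeline on cohorts of 250 samples
(~3,000–3,500 events) and exercises the oracle comparisons on ≥ 1,000
random events over ≤ 10-Mb toy genomes; the Wilcoxon calibration uses
2,000 null replicates at n = 12 per group. These sizes were chosen so the
whole suite completes in well under a minute of compute per module while
keeping Monte-Carlo standard errors far below the asserted tolerances.
Result tables are written with sorted rows and fixed float precision
(6 significant digits), so reruns with identical inputs are byte-identical
and diffable.

## Known limitations

- No purity/ploidy inference: thresholds on the provided segment means
  implicitly assume comparable tumor purity across samples.
- Arm resolution is p/q only; no sub-arm cytoband logic.
- No liftover: all inputs must share one assembly, supplied explicitly as
  chromosome sizes plus arm coordinates.
- No significance testing of pair co-occurrence beyond raw frequencies
  (no permutation null), and no GISTIC-style focal-peak significance.
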