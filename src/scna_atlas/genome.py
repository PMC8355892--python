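"""Reference-genome coordinate frame.

Chromosome sizes, p/q arm intervals (with acrocentric short-arm flags) and
the overlap / arm-fraction arithmetic that the event classifier and the
gene-overlap caller are built on.

All internal coordinates are zero-based half-open, so ``length = end - start``
everywhere.  Conversions from the 1-based inclusive on-disk conventions
happen at file boundaries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataError

logger = logging.getLogger(__name__)

#: Human chromosomes whose p arm is a short acrocentric stalk; these arms are
#: excluded from the arm-level aneuploidy definition.
ACROCENTRIC_DEFAULT: tuple[str, ...] = ("chr13", "chr14", "chr15", "chr21", "chr22")

#: Chromosomes dropped from the default analysis set.
EXCLUDE_DEFAULT: tuple[str, ...] = ("chrY",)


def normalize_chrom(name: str) -> str:
    """Return a chromosome label with the ``chr`` prefix (``"1"`` -> ``"chr1"``)."""
    name = str(name).strip()
    return name if name.startswith("chr") else f"chr{name}"


@dataclass(frozen=True)
class GenomicInterval:
    """A zero-based half-open genomic interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmInterval:
    """A chromosome arm (p or q) as a half-open interval.

    ``acrocentric_short`` marks the vestigial p arms of acrocentric
    chromosomes, which never count towards arm-level aneuploidy calls.
    """

    chrom: str
    arm: str
    start: int
    end: int
    acrocentric_short: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise DataError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"invalid arm interval {self.chrom}{self.arm}:{self.start}-{self.end}"
            )
        if self.acrocentric_short and self.arm != "p":
            raise DataError(
                f"acrocentric_short may only flag p arms ({self.chrom}{self.arm})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class GenomeBuild:
    """Chromosome lengths, arm geometry and the analysis set.

    ``chromosomes`` preserves file order, which defines the canonical sort
    order for all outputs.  ``analysis_set`` is the subset of chromosomes
    entering genome-fraction denominators and per-chromosome tables.
    """

    chromosomes: list[tuple[str, int]]
    arms: list[ArmInterval] = field(default_factory=list)
    analysis_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, length in self.chromosomes:
            if name in seen:
                raise DataError(f"duplicate chromosome name: {name}")
            seen.add(name)
            if length <= 0:
                raise DataError(f"non-positive length for chromosome {name}: {length}")
        if not self.analysis_set:
            self.analysis_set = tuple(
                n for n, _ in self.chromosomes if n not in EXCLUDE_DEFAULT
            )
        self._lengths = dict(self.chromosomes)
        self._order = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        self._validate_arms()

    def _validate_arms(self) -> None:
        by_chrom: dict[str, list[ArmInterval]] = {}
        for arm in self.arms:
            if arm.chrom not in self._lengths:
                raise DataError(f"arm references unknown chromosome {arm.chrom}")
            if arm.end > self._lengths[arm.chrom]:
                raise DataError(
                    f"arm {arm.chrom}{arm.arm} ends at {arm.end}, beyond "
                    f"chromosome length {self._lengths[arm.chrom]}"
                )
            by_chrom.setdefault(arm.chrom, []).append(arm)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            for left, right in zip(arms, arms[1:]):
                if left.end > right.start:
                    raise DataError(f"overlapping arms on {chrom}")

    # -- queries ---------------------------------------------------------

    def has_chrom(self, name: str) -> bool:
        return name in self._lengths

    def chrom_length(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise DataError(f"unknown chromosome {name}") from None

    def chrom_order(self, name: str) -> int:
        """Sort key for canonical (file-order) chromosome sorting."""
        return self._order.get(name, len(self._order))

    def arms_of(self, chrom: str) -> list[ArmInterval]:
        return [a for a in self.arms if a.chrom == chrom]

    @property
    def analysis_length(self) -> int:
        """Total base pairs over the analysis set (genome-fraction denominator)."""
        return sum(self._lengths[c] for c in self.analysis_set)

    def with_arms(self, arms: Sequence[ArmInterval]) -> "GenomeBuild":
        return replace(self, arms=list(arms))


# -- overlap arithmetic ---------------------------------------------------


def overlap_bp(a, b) -> int:
    """Base pairs shared by two half-open intervals; 0 across chromosomes.

    Accepts any objects with ``chrom``, ``start`` and ``end`` attributes.
    Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def arm_fractions(
    seg: GenomicInterval, build: GenomeBuild
) -> list[tuple[ArmInterval, float]]:
    """Fraction of each arm of ``seg.chrom`` covered by ``seg``.

    One entry per arm, in arm-start order; each fraction lies in [0, 1].
    """
    if not build.has_chrom(seg.chrom):
        raise DataError(f"segment on unknown chromosome {seg.chrom}")
    arms = sorted(build.arms_of(seg.chrom), key=lambda a: a.start)
    if not arms:
        raise DataError(
            f"no arm intervals loaded for {seg.chrom}; load an arm table "
            "(load_arms) before arm-fraction queries"
        )
    return [(arm, overlap_bp(seg, arm) / arm.length) for arm in arms]


# -- file I/O -------------------------------------------------------------


def load_chrom_sizes(
    path: str | Path,
    analysis_set: Iterable[str] | None = None,
    exclude: Iterable[str] = EXCLUDE_DEFAULT,
) -> GenomeBuild:
    """Read a two-column ``chrom.sizes`` file (name, length; no header).

    Chromosome names are normalised to carry the ``chr`` prefix and file
    order is preserved.  Unless ``analysis_set`` is given, every chromosome
    except those in ``exclude`` (default chrY) enters the analysis set.
    """
    chromosomes: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise DataError(f"{path}, line {lineno}: expected two columns")
            name = normalize_chrom(fields[0])
            try:
                length = int(fields[1])
            except ValueError:
                raise DataError(
                    f"{path}, line {lineno}: length {fields[1]!r} is not an integer"
                ) from None
            if length <= 0:
                raise DataError(
                    f"{path}, line {lineno}: non-positive length for {name}"
                )
            if name in seen:
                raise DataError(f"{path}, line {lineno}: duplicate chromosome {name}")
            seen.add(name)
            chromosomes.append((name, length))
    if not chromosomes:
        raise DataError(f"{path}: empty chrom.sizes file")
    if analysis_set is None:
        exclude = set(normalize_chrom(c) for c in exclude)
        aset = tuple(n for n, _ in chromosomes if n not in exclude)
    else:
        aset = tuple(normalize_chrom(c) for c in analysis_set)
    return GenomeBuild(chromosomes=chromosomes, analysis_set=aset)


_TRUE = {"1", "true", "yes"}


def load_arms(
    path: str | Path,
    build: GenomeBuild,
    acrocentric: Iterable[str] = ACROCENTRIC_DEFAULT,
) -> GenomeBuild:
    """Attach arm intervals from an explicit arm table.

    The table is tab-separated with a header (chrom, arm, start, end and an
    optional acrocentric column) and uses 1-based inclusive coordinates on
    disk.  When the acrocentric column is absent, p arms of chromosomes in
    ``acrocentric`` (default: the human acrocentrics chr13/14/15/21/22) are
    flagged.
    """
    acro = {normalize_chrom(c) for c in acrocentric}
    arms: list[ArmInterval] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c.strip().lower(): i for i, c in enumerate(header)}
        for key in ("chrom", "arm", "start", "end"):
            if key not in cols:
                raise DataError(f"{path}: arm table missing column {key!r}")
        has_flag = "acrocentric" in cols
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom = normalize_chrom(fields[cols["chrom"]])
            arm = fields[cols["arm"]].strip().lower()
            start = int(fields[cols["start"]]) - 1  # 1-based inclusive -> half-open
            end = int(fields[cols["end"]])
            if has_flag:
                flag = fields[cols["acrocentric"]].strip().lower() in _TRUE
            else:
                flag = arm == "p" and chrom in acro
            if not build.has_chrom(chrom):
                raise DataError(f"{path}, line {lineno}: unknown chromosome {chrom}")
            arms.append(ArmInterval(chrom, arm, start, end, acrocentric_short=flag))
    out = build.with_arms(arms)
    armed = {a.chrom for a in arms}
    for chrom in out.analysis_set:
        if chrom not in armed:
            logger.warning("chromosome %s is in the analysis set but has no arms", chrom)
    return out


def arms_from_cytoband(
    path: str | Path,
    build: GenomeBuild,
    acrocentric: Iterable[str] = ACROCENTRIC_DEFAULT,
) -> GenomeBuild:
    """Derive p/q arms from a UCSC ``cytoBand.txt`` file (0-based half-open).

    Each arm spans the extent of its ``p*`` (resp. ``q*``) bands.
    """
    acro = {normalize_chrom(c) for c in acrocentric}
    extents: dict[tuple[str, str], list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, band = line.split("\t")[:4]
            chrom = normalize_chrom(chrom)
            if not build.has_chrom(chrom) or not band or band[0] not in "pq":
                continue
            key = (chrom, band[0])
            cur = extents.setdefault(key, [int(start), int(end)])
            cur[0] = min(cur[0], int(start))
            cur[1] = max(cur[1], int(end))
    arms = [
        ArmInterval(c, a, s, e, acrocentric_short=(a == "p" and c in acro))
        for (c, a), (s, e) in sorted(extents.items())
    ]
    return build.with_arms(arms)


def write_chrom_sizes(build: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in build.chromosomes:
            fh.write(f"{name}\t{length}\n")


def write_arm_table(build: GenomeBuild, path: str | Path) -> None:
    """Write the arm table in the on-disk (1-based inclusive) convention."""
    with open(path, "w") as fh:
        fh.write("chrom\tarm\tstart\tend\tacrocentric\n")
        for arm in build.arms:
            flag = "true" if arm.acrocentric_short else "false"
            fh.write(f"{arm.chrom}\t{arm.arm}\t{arm.start + 1}\t{arm.end}\t{flag}\n")
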