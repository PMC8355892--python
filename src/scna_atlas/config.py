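"""Run configuration: paths, parameter overrides and mode flags.

A single YAML file configures every pipeline stage; all keys are optional
and fall back to the documented defaults, so ``scna-atlas all --config
cfg.yaml`` with a minimal file runs the whole default analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .classify import SCNA, ClassificationParams
from .errors import ConfigError
from .simulate import CohortSpec, PlantedGene, PlantedPair, TumorTypeSpec, default_cohort_spec


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    ``paths`` hold the stage inputs (segments, genes, genome, arms,
    annotations) and the output directory; ``params`` the five calling
    constants; the mode flags mirror the analysis conventions (chromosome
    normalisation mode, gene-overlap mode, included classes, the 5% pair
    filter and the top-25 / top-100 list sizes).
    """

    outdir: Path = Path("scna_out")
    segments: Optional[Path] = None
    genes: Optional[Path] = None
    genome: Optional[Path] = None
    arms: Optional[Path] = None
    annotations: Optional[Path] = None
    params: ClassificationParams = field(default_factory=ClassificationParams)
    chrom_norm_mode: str = "divide"
    gene_overlap_mode: str = "union"
    include_classes: tuple[str, ...] = (SCNA,)
    pair_min_frequency: float = 0.05
    top_k_genes: int = 25
    top_k_pairs: int = 100
    log_level: str = "INFO"
    seed: int = 0
    simulate: Optional[CohortSpec] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw, base_dir=Path(path).parent)

    @classmethod
    def from_mapping(
        cls, raw: Mapping, base_dir: Path | None = None
    ) -> "RunConfig":
        def path_of(value) -> Optional[Path]:
            if value is None:
                return None
            p = Path(value)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            return p

        cfg = cls()
        paths = raw.get("paths", {})
        unknown = set(paths) - {"segments", "genes", "genome", "arms", "annotations", "outdir"}
        if unknown:
            raise ConfigError(f"unknown path keys: {sorted(unknown)}")
        for key in ("segments", "genes", "genome", "arms", "annotations"):
            setattr(cfg, key, path_of(paths.get(key)))
        if "outdir" in paths:
            cfg.outdir = path_of(paths["outdir"])  # type: ignore[assignment]
        if "params" in raw:
            cfg.params = ClassificationParams.from_mapping(raw["params"])
        modes = raw.get("modes", {})
        cfg.chrom_norm_mode = modes.get("chrom_norm", cfg.chrom_norm_mode)
        cfg.gene_overlap_mode = modes.get("gene_overlap", cfg.gene_overlap_mode)
        if "include_classes" in modes:
            cfg.include_classes = tuple(modes["include_classes"])
        cfg.pair_min_frequency = float(modes.get("pair_min_frequency", cfg.pair_min_frequency))
        cfg.top_k_genes = int(modes.get("top_k_genes", cfg.top_k_genes))
        cfg.top_k_pairs = int(modes.get("top_k_pairs", cfg.top_k_pairs))
        cfg.log_level = str(raw.get("log_level", cfg.log_level))
        cfg.seed = int(raw.get("seed", cfg.seed))
        if "simulate" in raw:
            cfg.simulate = _cohort_spec_from_mapping(raw["simulate"] or {}, cfg)
        return cfg

    def echo(self) -> dict:
        """A JSON-serialisable snapshot for the run manifest."""
        return {
            "paths": {
                k: (str(getattr(self, k)) if getattr(self, k) is not None else None)
                for k in ("segments", "genes", "genome", "arms", "annotations", "outdir")
            },
            "params": {
                f: getattr(self.params, f)
                for f in ClassificationParams.__dataclass_fields__
            },
            "modes": {
                "chrom_norm": self.chrom_norm_mode,
                "gene_overlap": self.gene_overlap_mode,
                "include_classes": list(self.include_classes),
                "pair_min_frequency": self.pair_min_frequency,
                "top_k_genes": self.top_k_genes,
                "top_k_pairs": self.top_k_pairs,
            },
            "seed": self.seed,
            "simulate": self.simulate is not None,
        }


def _cohort_spec_from_mapping(raw: Mapping, cfg: RunConfig) -> CohortSpec:
    spec = default_cohort_spec(seed=cfg.seed)
    if "tumor_types" in raw:
        spec.tumor_types = [
            TumorTypeSpec(
                label=t["label"],
                n_samples=int(t["n_samples"]),
                amp_mean=float(t.get("amp_mean", 5.0)),
                del_mean=float(t.get("del_mean", 4.0)),
                dispersion=float(t.get("dispersion", 3.0)),
            )
            for t in raw["tumor_types"]
        ]
    if "class_mix" in raw:
        spec.class_mix = tuple(float(x) for x in raw["class_mix"])  # type: ignore[assignment]
    for key in ("scna_len_log_mean", "scna_len_log_sd", "margin_log2"):
        if key in raw:
            setattr(spec, key, float(raw[key]))
    for key in ("margin_bp", "neutral_per_sample"):
        if key in raw:
            setattr(spec, key, int(raw[key]))
    if "amp_del_coupling" in raw:
        spec.amp_del_coupling = bool(raw["amp_del_coupling"])
    if "planted_genes" in raw:
        spec.planted_genes = [
            PlantedGene(
                symbol=g["symbol"],
                direction=g["direction"],
                frequency=g["frequency"],
                default=float(g.get("default", 0.0)),
            )
            for g in raw["planted_genes"]
        ]
    if "planted_pairs" in raw:
        spec.planted_pairs = [
            PlantedPair(
                gene_a=p["gene_a"],
                gene_b=p["gene_b"],
                event_type=p["event_type"],
                frequency=float(p["frequency"]),
                shared_event=bool(p.get("shared_event", False)),
            )
            for p in raw["planted_pairs"]
        ]
    spec.params = cfg.params
    spec.seed = cfg.seed
    return spec
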