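"""Pipeline configuration: every threshold in one serializable object."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ValidationError

__all__ = ["PipelineConfig", "DEFAULT_PLANTED"]

# default simulated truth: one hypermethylated block per collection run
DEFAULT_PLANTED = [
    {
        "chrom": "chr7",
        "start": 27_150_000,
        "end": 27_151_400,
        "n_probes": 23,
        "delta_beta": 0.3,
        "affected_cohort_fraction": 1.0,
    }
]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, with the study's default thresholds.

    Thresholds: per-cohort FDR gate ``q_threshold`` (default 0.01),
    cross-cancer mean AUROC gate ``mean_auc_threshold`` (default 0.75),
    region gates ``min_sites`` (10 contiguous DMSs) and
    ``min_density_per_kb`` (3 CpG/kb), merge distance ``max_gap_bp``,
    cohort-size filter ``min_group_size`` (30 per group) and significance
    level ``alpha`` (0.05) for distal associations.
    """

    seed: int = 0
    out_dir: str = "pandmr_run"

    # --- simulation ---
    collections: tuple[str, ...] = ("discovery", "validation")
    n_cohorts: int = 3
    n_normal: int = 40
    n_tumor: int = 40
    n_background_probes: int = 2000
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr5", "chr6", "chr7")
    mean_spacing_bp: int = 500
    baseline_params: tuple[float, float] = (0.8, 0.8)
    planted_baseline_params: tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 0.4
    cohort_sd: float = 0.02
    planted: list[dict] = field(default_factory=lambda: [dict(d) for d in DEFAULT_PLANTED])

    # --- normalization ---
    qn_mode: str = "rank-mean"
    normalize_scope: str = "joint"
    min_group_size: int = 30

    # --- site statistics / DMS aggregation ---
    use_logit_test: bool = False
    q_threshold: float = 0.01
    mean_auc_threshold: float = 0.75
    min_significant_fraction: float = 1.0
    direction_mode: str = "hyper"

    # --- regions ---
    min_sites: int = 10
    min_density_per_kb: float = 3.0
    max_gap_bp: int = 1000
    min_overlap_bp: int = 1

    # --- co-expression ---
    expr_n_normal: int = 200
    expr_n_tumor: int = 200
    r_within_normal: float = 0.8
    r_within_tumor: float = 0.2
    r_between: float = 0.1
    distal_gene: str = "TAX1BP1"
    distal_gene_r_tumor: float = 0.3
    alpha: float = 0.05

    def __post_init__(self):
        for name, lo, hi in (
            ("q_threshold", 0.0, 1.0),
            ("mean_auc_threshold", 0.0, 1.0),
            ("min_significant_fraction", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValidationError(f"{name} must lie in ({lo}, {hi}], got {v}")
        if self.min_sites < 2:
            raise ValidationError("min_sites must be >= 2")
        if self.min_density_per_kb < 0 or self.max_gap_bp < 0:
            raise ValidationError("density and gap thresholds must be non-negative")
        if self.min_group_size < 1:
            raise ValidationError("min_group_size must be >= 1")
        if self.qn_mode not in ("rank-mean", "classic"):
            raise ValidationError(f"unknown qn_mode {self.qn_mode!r}")
        if self.normalize_scope not in ("joint", "cohort"):
            raise ValidationError(f"unknown normalize_scope {self.normalize_scope!r}")
        if self.direction_mode not in ("hyper", "symmetric"):
            raise ValidationError(f"unknown direction_mode {self.direction_mode!r}")
        self.collections = tuple(self.collections)
        self.chroms = tuple(self.chroms)
        self.baseline_params = tuple(self.baseline_params)
        self.planted_baseline_params = tuple(self.planted_baseline_params)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["collections"] = list(self.collections)
        out["chroms"] = list(self.chroms)
        out["baseline_params"] = list(self.baseline_params)
        out["planted_baseline_params"] = list(self.planted_baseline_params)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
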