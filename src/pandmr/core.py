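"""Core data containers shared across the pipeline.

The central objects are:

* :class:`ProbeManifest` — the ordered genomic catalogue of CpG probes.
  Probe order within a chromosome defines what "coordinately contiguous"
  means for region calling.
* :class:`BetaCohortSet` — per-cancer-type paired normal/tumor beta-value
  matrices sharing one manifest.
* :class:`ExpressionCohortSet` — per-cohort, per-group log-scale expression
  matrices for an ordered gene cluster with a block assignment.
* :class:`PlantedDMR` — description of a simulated contiguous methylation
  shift, used both to generate data and as ground truth when checking
  recovery.

All coordinates are 1-based inclusive throughout, matching Illumina
manifest conventions; BED export converts at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ProbeManifest",
    "PlantedDMR",
    "BetaCohortSet",
    "ExpressionCohortSet",
    "GROUP_LABELS",
]

GROUP_LABELS = ("normal", "tumor")


class ValidationError(ValueError):
    """Raised when an input object violates a documented contract."""


class ProbeManifest:
    """Ordered catalogue of CpG probes: (probe_id, chrom, pos).

    Records are sorted by (chrom, pos) on construction. Probe ids are
    unique and no two probes share a genomic position. Positions are
    1-based.
    """

    COLUMNS = ("probe_id", "chrom", "pos")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["probe_id"] = df["probe_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            bad = df.loc[df["pos"] < 1].index[0]
            raise ValidationError(f"non-positive position at input row {bad}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id: {dup!r}")
        if df.duplicated(subset=["chrom", "pos"]).any():
            row = df.loc[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ValidationError(
                f"two probes share position {row['chrom']}:{row['pos']}"
            )
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self._df = df
        self._pos_by_probe = df.set_index("probe_id")[["chrom", "pos"]]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int]]
    ) -> "ProbeManifest":
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        return cls(df)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self._df["probe_id"])

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._pos_by_probe.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeManifest):
            return NotImplemented
        return self._df.equals(other._df)

    def position_of(self, probe_id: str) -> tuple[str, int]:
        if probe_id not in self._pos_by_probe.index:
            raise ValidationError(f"probe {probe_id!r} not in manifest")
        row = self._pos_by_probe.loc[probe_id]
        return str(row["chrom"]), int(row["pos"])

    def probes_in_span(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """All probes with chrom == ``chrom`` and start <= pos <= end, in order."""
        df = self._df
        sel = (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)
        return df.loc[sel].reset_index(drop=True)


@dataclass(frozen=True)
class PlantedDMR:
    """A simulated contiguous tumor-vs-normal methylation shift.

    ``start`` and ``end`` are the positions of the first and last planted
    probe (1-based inclusive). ``delta_beta`` is the tumor-minus-normal
    mean shift; positive values model hypermethylation. The shift is
    applied in ``ceil(affected_cohort_fraction * n_cohorts)`` cohorts.
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    delta_beta: float
    affected_cohort_fraction: float = 1.0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"end ({self.end}) must exceed start ({self.start})")
        if self.n_probes < 2:
            raise ValidationError("a planted region needs at least 2 probes")
        if self.n_probes > self.end - self.start + 1:
            raise ValidationError(
                f"{self.n_probes} probes cannot fit in span "
                f"[{self.start}, {self.end}]"
            )
        if not -1.0 < self.delta_beta < 1.0:
            raise ValidationError("delta_beta must lie in (-1, 1)")
        if not 0.0 < self.affected_cohort_fraction <= 1.0:
            raise ValidationError("affected_cohort_fraction must lie in (0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    def n_affected_cohorts(self, n_cohorts: int) -> int:
        return math.ceil(self.affected_cohort_fraction * n_cohorts)


def _check_beta_matrix(name: str, matrix: pd.DataFrame, probe_ids: pd.Index) -> None:
    if not matrix.index.equals(probe_ids):
        raise ValidationError(f"{name}: row index does not match the shared manifest")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{name}: missing value at probe {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}"
        )
    if (values < 0).any() or (values > 1).any():
        i, j = np.argwhere((values < 0) | (values > 1))[0]
        raise ValidationError(
            f"{name}: beta value {values[i, j]} outside [0, 1] at probe "
            f"{matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )


class BetaCohortSet:
    """Per-cohort paired normal/tumor beta matrices sharing one manifest.

    ``cohorts`` maps cohort name -> (normal_matrix, tumor_matrix); each
    matrix is probes x samples with the manifest's probe order as its row
    index. A sample sheet (sample_id, cohort, group) is derived from the
    matrices and kept consistent by construction.
    """

    def __init__(
        self,
        manifest: ProbeManifest,
        cohorts: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    ):
        if not cohorts:
            raise ValidationError("cohort set must contain at least one cohort")
        probe_ids = manifest.probe_ids
        seen_samples: dict[str, str] = {}
        for name, (normal, tumor) in cohorts.items():
            _check_beta_matrix(f"{name}/normal", normal, probe_ids)
            _check_beta_matrix(f"{name}/tumor", tumor, probe_ids)
            for sid in list(normal.columns) + list(tumor.columns):
                if sid in seen_samples:
                    raise ValidationError(
                        f"sample {sid!r} appears in both {seen_samples[sid]!r} "
                        f"and {name!r}"
                    )
                seen_samples[sid] = name
        self.manifest = manifest
        self.cohorts = dict(cohorts)

    @property
    def cohort_names(self) -> list[str]:
        return list(self.cohorts)

    def group_sizes(self) -> dict[str, tuple[int, int]]:
        return {
            name: (normal.shape[1], tumor.shape[1])
            for name, (normal, tumor) in self.cohorts.items()
        }

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for name, (normal, tumor) in self.cohorts.items():
            rows.extend((sid, name, "normal") for sid in normal.columns)
            rows.extend((sid, name, "tumor") for sid in tumor.columns)
        return pd.DataFrame(rows, columns=["sample_id", "cohort", "group"])

    def map_matrices(self, func) -> "BetaCohortSet":
        """Apply ``func`` (DataFrame -> DataFrame) to every matrix."""
        return BetaCohortSet(
            self.manifest,
            {
                name: (func(normal), func(tumor))
                for name, (normal, tumor) in self.cohorts.items()
            },
        )


@dataclass
class ExpressionCohortSet:
    """Per-cohort, per-group log-scale expression matrices.

    ``genes`` is the ordered gene list (locus order); ``block_assignment``
    maps each clustered gene to a block label. A distal gene, if present,
    is part of ``genes`` but carries no block label.
    """

    genes: list[str]
    block_assignment: dict[str, str]
    cohorts: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene names must be unique")
        unknown = set(self.block_assignment) - set(self.genes)
        if unknown:
            raise ValidationError(f"block assignment names unknown genes: {sorted(unknown)}")
        for cname, groups in self.cohorts.items():
            for gname, matrix in groups.items():
                if gname not in GROUP_LABELS:
                    raise ValidationError(
                        f"unknown group {gname!r} in cohort {cname!r}; "
                        f"allowed: {GROUP_LABELS}"
                    )
                if list(matrix.index) != self.genes:
                    raise ValidationError(
                        f"{cname}/{gname}: gene index does not match the shared gene list"
                    )

    @property
    def cluster_genes(self) -> list[str]:
        return [g for g in self.genes if g in self.block_assignment]

    @property
    def distal_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.block_assignment]
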