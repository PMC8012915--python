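"""DMR calling from a pan-cancer DMS set.

A candidate region is a *maximal run of coordinately contiguous DMS
probes*: consecutive probes in manifest order on one chromosome, all
flagged as DMS — any intervening non-DMS probe breaks the run. A run
becomes a DMR when it contains at least ``min_sites`` probes and its
probe density clears ``min_density_per_kb``. Length is the distance
between the first and last member probe (end - start); density is
stored per bp (n_dms / length) and the per-kb threshold is converted
accordingly.

Coordinately close regions on the same chromosome can be merged, and two
region collections (e.g. a discovery and a validation set) intersected
by genomic overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ProbeManifest, ValidationError

__all__ = [
    "DMRRecord",
    "call_dmrs",
    "merge_dmrs",
    "dmr_table",
    "intersect_collections",
    "dmrs_to_bed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DMRRecord:
    """A called differentially methylated region.

    ``start``/``end`` are the 1-based positions of the first and last
    member DMS probe. ``length`` is end - start and ``density`` is
    n_dms / length (per bp).
    """

    chrom: str
    start: int
    end: int
    member_probes: tuple[str, ...]

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"end ({self.end}) must exceed start ({self.start})")
        if len(self.member_probes) < 2:
            raise ValidationError("a region needs at least 2 member probes")

    @property
    def n_dms(self) -> int:
        return len(self.member_probes)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        return self.n_dms / self.length

    @property
    def coordinate(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _dms_probe_ids(dms) -> set[str]:
    if isinstance(dms, pd.DataFrame):
        return set(dms["probe_id"].astype(str))
    return set(map(str, dms))


def call_dmrs(
    dms,
    manifest: ProbeManifest,
    min_sites: int = 10,
    min_density_per_kb: float = 3.0,
) -> list[DMRRecord]:
    """Call DMRs from a DMS set by manifest contiguity.

    Parameters
    ----------
    dms
        The pan-cancer DMS set — a frame with a ``probe_id`` column (as
        produced by :func:`pandmr.sitestats.pan_cancer_dms`) or any
        iterable of probe ids. Order is irrelevant.
    manifest
        The probe catalogue defining contiguity.
    min_sites
        Minimum member count for a run to become a DMR (inclusive).
    min_density_per_kb
        Minimum probe density in DMS per kilobase (inclusive);
        equivalently n_dms / length >= min_density_per_kb / 1000.

    Returns records sorted by (chrom, start); runs are maximal, so the
    output is pairwise disjoint.
    """
    if min_sites < 2:
        raise ValidationError("min_sites must be >= 2")
    if min_density_per_kb < 0:
        raise ValidationError("min_density_per_kb must be non-negative")
    ids = _dms_probe_ids(dms)
    frame = manifest.to_frame()
    known = set(frame["probe_id"])
    missing = ids - known
    if missing:
        raise ValidationError(
            f"DMS probes absent from manifest: {sorted(missing)[:5]}"
        )
    flagged = frame["probe_id"].isin(ids).to_numpy()
    chroms = frame["chrom"].to_numpy()
    positions = frame["pos"].to_numpy()
    probe_ids = frame["probe_id"].to_numpy()

    records: list[DMRRecord] = []
    n_rejected_sites = n_rejected_density = 0
    i, n = 0, len(frame)
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        run_len = j - i + 1
        if run_len >= min_sites:
            start, end = int(positions[i]), int(positions[j])
            if run_len / (end - start) >= min_density_per_kb / 1000.0:
                records.append(
                    DMRRecord(
                        chrom=str(chroms[i]),
                        start=start,
                        end=end,
                        member_probes=tuple(probe_ids[i : j + 1]),
                    )
                )
            else:
                n_rejected_density += 1
        else:
            n_rejected_sites += 1
        i = j + 1
    if n_rejected_sites or n_rejected_density:
        logger.info(
            "rejected %d run(s) below %d sites and %d below %.3g DMS/kb",
            n_rejected_sites, min_sites, n_rejected_density, min_density_per_kb,
        )
    return sorted(records, key=lambda r: (r.chrom, r.start))


def merge_dmrs(dmrs: list[DMRRecord], max_gap_bp: int = 1000) -> list[DMRRecord]:
    """Merge same-chromosome regions separated by at most ``max_gap_bp``.

    The gap between consecutive sorted records is next.start - prev.end;
    merged records pool member probes and recompute span, length and
    density. Idempotent.
    """
    if max_gap_bp < 0:
        raise ValidationError("max_gap_bp must be non-negative")
    ordered = sorted(dmrs, key=lambda r: (r.chrom, r.start))
    merged: list[DMRRecord] = []
    for record in ordered:
        if (
            merged
            and record.chrom == merged[-1].chrom
            and record.start - merged[-1].end <= max_gap_bp
        ):
            prev = merged[-1]
            merged[-1] = DMRRecord(
                chrom=prev.chrom,
                start=min(prev.start, record.start),
                end=max(prev.end, record.end),
                member_probes=prev.member_probes + record.member_probes,
            )
        else:
            merged.append(record)
    return merged


def dmr_table(dmrs: list[DMRRecord], density_decimals: int = 5) -> pd.DataFrame:
    """Tabulate regions: chrom, DMS count, density, coordinate, length.

    Density is rounded half-even to ``density_decimals`` decimal places;
    the unrounded value is n_dms / length per bp.
    """
    rows = [
        {
            "chrom": r.chrom,
            "n_dms": r.n_dms,
            "density": float(np.round(r.density, density_decimals)),
            "coordinate": r.coordinate,
            "length": r.length,
        }
        for r in dmrs
    ]
    return pd.DataFrame(rows, columns=["chrom", "n_dms", "density", "coordinate", "length"])


def intersect_collections(
    dmrs_a: list[DMRRecord],
    dmrs_b: list[DMRRecord],
    min_overlap_bp: int = 1,
) -> list[DMRRecord]:
    """Regions from A overlapping >= ``min_overlap_bp`` with any region in B.

    Overlap is computed on the half-open interpretation [start, end) of
    each region's span.
    """
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    out = []
    for a in dmrs_a:
        for b in dmrs_b:
            if a.chrom != b.chrom:
                continue
            overlap = min(a.end, b.end) - max(a.start, b.start)
            if overlap >= min_overlap_bp:
                out.append(a)
                break
    return out


def dmrs_to_bed(dmrs: list[DMRRecord]) -> pd.DataFrame:
    """BED-style frame (0-based half-open): start - 1, end."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start - 1,
                "end": r.end,
                "name": f"DMR_{r.coordinate}",
                "score": r.n_dms,
            }
            for r in dmrs
        ],
        columns=["chrom", "start", "end", "name", "score"],
    )
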