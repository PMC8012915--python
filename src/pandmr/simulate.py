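"""Synthetic-cohort generators.

Emulates the kind of data a pan-cancer 450K methylation study works
with, so every downstream stage is testable without downloading
anything:

* probe manifests with realistic inter-probe spacing,
* multi-cancer-type beta-value cohorts with probe-specific bimodal
  baselines and planted contiguous hypermethylated blocks,
* expression cohorts for an ordered gene cluster whose block-correlation
  structure is present in normal samples and attenuated in tumors, with
  an optional distal gene that couples to the cluster in tumors only.

Beta-value noise is applied on the logit scale and back-transformed, so
simulated values stay inside (0, 1) without piling up at the clip
bounds. All generators are deterministic under a fixed master seed;
sub-streams are derived with ``numpy.random.SeedSequence.spawn`` so
adding a cohort never perturbs the draws of another.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import (
    BetaCohortSet,
    ExpressionCohortSet,
    PlantedDMR,
    ProbeManifest,
    ValidationError,
)

__all__ = [
    "generate_manifest",
    "build_manifest_with_runs",
    "generate_beta_cohorts",
    "generate_expression_cohorts",
    "HOXA_GENES",
    "DEFAULT_BLOCKS",
]

# The HOXA cluster in locus order (HOXA8/HOXA12 have no 450K-era RSEM
# entry and are conventionally dropped), split into the two co-expression
# blocks that flank the intra-locus hypermethylated region.
HOXA_GENES = [
    "HOXA1", "HOXA2", "HOXA3", "HOXA4", "HOXA5", "HOXA6",
    "HOXA7", "HOXA9", "HOXA10", "HOXA11", "HOXA13",
]
DEFAULT_BLOCKS = {g: ("block1" if i < 6 else "block2") for i, g in enumerate(HOXA_GENES)}

_EPS = 1e-6  # hard clip for beta values
_MEAN_CLIP = 1e-3  # keep target means away from 0/1 so logit stays finite


def generate_manifest(
    n_probes: int,
    chroms: Sequence[str],
    mean_spacing_bp: int = 500,
    seed: int = 0,
    start_pos: int = 1,
) -> ProbeManifest:
    """Generate a sorted probe manifest with geometric inter-probe gaps.

    Probes are split as evenly as possible across ``chroms`` in order;
    within a chromosome, gaps are drawn from a geometric distribution
    with mean ``mean_spacing_bp`` (support >= 1 bp), so positions are
    strictly increasing.
    """
    if n_probes < 1:
        raise ValidationError("n_probes must be >= 1")
    if mean_spacing_bp < 1:
        raise ValidationError("mean_spacing_bp must be >= 1")
    if not chroms:
        raise ValidationError("at least one chromosome is required")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = [n_probes // len(chroms)] * len(chroms)
    for i in range(n_probes % len(chroms)):
        counts[i] += 1
    records = []
    probe_no = 0
    for chrom, count in zip(chroms, counts):
        if count == 0:
            continue
        gaps = rng.geometric(1.0 / mean_spacing_bp, size=count)
        positions = start_pos - 1 + np.cumsum(gaps)
        for pos in positions:
            records.append((f"cg{probe_no:08d}", chrom, int(pos)))
            probe_no += 1
    return ProbeManifest.from_records(records)


def _run_positions(start: int, end: int, n_probes: int, rng: np.random.Generator) -> np.ndarray:
    """n_probes strictly increasing integer positions with fixed endpoints."""
    if n_probes == 2:
        return np.array([start, end], dtype=np.int64)
    interior = rng.choice(
        np.arange(start + 1, end, dtype=np.int64), size=n_probes - 2, replace=False
    )
    return np.concatenate([[start], np.sort(interior), [end]]).astype(np.int64)


def build_manifest_with_runs(
    runs: Iterable[PlantedDMR],
    n_background_probes: int,
    chroms: Sequence[str],
    mean_spacing_bp: int = 500,
    seed: int = 0,
    flank_bp: int = 10_000,
) -> ProbeManifest:
    """Build a manifest that contains each planted run as consecutive probes.

    Background probes are generated first; any background probe that
    falls inside a planted span is removed (an intervening probe would
    break run contiguity) and each run contributes ``n_probes`` probes
    whose first/last positions equal the run's stated start/end. Each run
    is additionally flanked by ``flank_bp`` of background probes at the
    stated mean spacing — as on a real array, where probes surround every
    region — so that distinct runs on one chromosome stay separated by
    non-run probes in manifest order.
    """
    runs = list(runs)
    ss = np.random.SeedSequence(seed)
    bg_seed, run_seed = ss.spawn(2)
    rng = np.random.default_rng(run_seed)
    if n_background_probes > 0:
        background = generate_manifest(
            n_background_probes, chroms, mean_spacing_bp,
            seed=int(bg_seed.generate_state(1)[0] % (2**31)),
        ).to_frame()
    else:
        background = pd.DataFrame(columns=["probe_id", "chrom", "pos"])
    zones = [(run.chrom, run.start - 1, run.end + 1) for run in runs]

    def excluded(chrom: str, pos: int) -> bool:
        return any(c == chrom and lo <= pos <= hi for c, lo, hi in zones)

    keep = np.ones(len(background), dtype=bool)
    records: list[tuple[str, str, int]] = []
    for run in runs:
        inside = (
            (background["chrom"] == run.chrom)
            & (background["pos"] >= run.start - 1)
            & (background["pos"] <= run.end + 1)
        )
        keep &= ~inside.to_numpy()
        for pos in _run_positions(run.start, run.end, run.n_probes, rng):
            records.append(("placeholder", run.chrom, int(pos)))
        # flanking background on both sides of the run
        pos = run.start
        while pos > max(1, run.start - flank_bp):
            pos -= int(rng.geometric(1.0 / mean_spacing_bp))
            if pos >= 1 and not excluded(run.chrom, pos):
                records.append(("placeholder", run.chrom, int(pos)))
        pos = run.end
        while pos < run.end + flank_bp:
            pos += int(rng.geometric(1.0 / mean_spacing_bp))
            if not excluded(run.chrom, pos):
                records.append(("placeholder", run.chrom, int(pos)))
    frame = pd.concat(
        [
            background.loc[keep, ["chrom", "pos"]],
            pd.DataFrame(records, columns=["probe_id", "chrom", "pos"])[["chrom", "pos"]],
        ],
        ignore_index=True,
    ).sort_values(["chrom", "pos"], kind="mergesort")
    frame = frame.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    frame.insert(0, "probe_id", [f"cg{i:08d}" for i in range(len(frame))])
    return ProbeManifest(frame)


def _planted_probe_index(
    manifest: ProbeManifest, planted: Sequence[PlantedDMR]
) -> dict[PlantedDMR, np.ndarray]:
    """Map each planted run to the manifest row positions it covers."""
    frame = manifest.to_frame()
    out: dict[PlantedDMR, np.ndarray] = {}
    for run in planted:
        sel = (
            (frame["chrom"] == run.chrom)
            & (frame["pos"] >= run.start)
            & (frame["pos"] <= run.end)
        )
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx) != run.n_probes:
            raise ValidationError(
                f"planted run {run.chrom}:{run.start}-{run.end} expects "
                f"{run.n_probes} manifest probes, found {len(idx)}"
            )
        positions = frame.loc[idx, "pos"].to_numpy()
        if positions[0] != run.start or positions[-1] != run.end:
            raise ValidationError(
                f"planted run {run.chrom}:{run.start}-{run.end} endpoints "
                "do not lie on manifest probes"
            )
        out[run] = idx
    return out


def generate_beta_cohorts(
    manifest: ProbeManifest,
    n_cohorts: int,
    n_normal: int,
    n_tumor: int,
    planted: Sequence[PlantedDMR] = (),
    baseline_params: tuple[float, float] = (0.8, 0.8),
    noise_sd: float = 0.4,
    seed: int = 0,
    cohort_sd: float = 0.02,
    planted_baseline_params: tuple[float, float] = (2.0, 8.0),
    cohort_names: Sequence[str] | None = None,
    sample_prefix: str = "",
) -> BetaCohortSet:
    """Simulate per-cancer-type normal/tumor beta matrices.

    Each probe draws one baseline mean from Beta(*baseline_params*) —
    bimodal by default, as 450K beta values are — shared across cohorts
    to model methylation maintenance from the tissue of origin. Probes
    inside a planted run instead draw from Beta(*planted_baseline_params*)
    (default low-methylation mode, as for CpG-island probes that gain
    methylation in tumors; mirrored for hypomethylated runs). Each cohort
    adds a small baseline offset (sd ``cohort_sd``) emulating batch and
    tissue heterogeneity. Tumor samples at planted probes have their mean
    shifted by ``delta_beta`` in ``ceil(fraction * n_cohorts)`` cohorts;
    shifted means are clipped into (0, 1). Per-sample noise with sd
    ``noise_sd`` is added on the logit scale and back-transformed;
    final values are clipped to [1e-6, 1 - 1e-6].
    """
    if n_cohorts < 1:
        raise ValidationError("n_cohorts must be >= 1")
    if n_normal < 1 or n_tumor < 1:
        raise ValidationError("group sizes must be >= 1")
    if noise_sd < 0 or cohort_sd < 0:
        raise ValidationError("noise_sd and cohort_sd must be non-negative")
    planted = list(planted)
    planted_idx = _planted_probe_index(manifest, planted)
    n_probes = len(manifest)
    if cohort_names is None:
        cohort_names = [f"cohort{i + 1:02d}" for i in range(n_cohorts)]
    elif len(cohort_names) != n_cohorts:
        raise ValidationError("cohort_names length must equal n_cohorts")

    ss = np.random.SeedSequence(seed)
    base_ss, assign_ss, *cohort_ss = ss.spawn(2 + n_cohorts)
    base_rng = np.random.default_rng(base_ss)
    a, b = baseline_params
    baseline = base_rng.beta(a, b, size=n_probes)
    pa, pb = planted_baseline_params
    for run, idx in planted_idx.items():
        if run.delta_beta >= 0:
            baseline[idx] = base_rng.beta(pa, pb, size=len(idx))
        else:
            baseline[idx] = base_rng.beta(pb, pa, size=len(idx))

    # which cohorts carry each planted shift
    assign_rng = np.random.default_rng(assign_ss)
    affected: dict[PlantedDMR, set[int]] = {}
    for run in planted:
        k = run.n_affected_cohorts(n_cohorts)
        affected[run] = set(
            assign_rng.choice(n_cohorts, size=k, replace=False).tolist()
        )

    probe_ids = manifest.probe_ids
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for c, (cname, css) in enumerate(zip(cohort_names, cohort_ss)):
        rng = np.random.default_rng(css)
        offset = rng.normal(0.0, cohort_sd)
        mean_normal = np.clip(baseline + offset, _MEAN_CLIP, 1 - _MEAN_CLIP)
        mean_tumor = mean_normal.copy()
        for run, idx in planted_idx.items():
            if c in affected[run]:
                mean_tumor[idx] = np.clip(
                    mean_tumor[idx] + run.delta_beta, _MEAN_CLIP, 1 - _MEAN_CLIP
                )
        matrices = {}
        for gname, mean, size in (
            ("normal", mean_normal, n_normal),
            ("tumor", mean_tumor, n_tumor),
        ):
            noise = rng.normal(0.0, noise_sd, size=(n_probes, size))
            values = expit(logit(mean)[:, None] + noise)
            values = np.clip(values, _EPS, 1 - _EPS)
            tag = "N" if gname == "normal" else "T"
            columns = [f"{sample_prefix}{cname}_{tag}{j + 1:03d}" for j in range(size)]
            matrices[gname] = pd.DataFrame(values, index=probe_ids, columns=columns)
        cohorts[cname] = (matrices["normal"], matrices["tumor"])
    return BetaCohortSet(manifest, cohorts)


def _target_correlation(
    genes: Sequence[str],
    block_assignment: Mapping[str, str],
    r_within: float,
    r_between: float,
    distal_gene: str | None,
    distal_r: float,
) -> np.ndarray:
    n = len(genes)
    corr = np.full((n, n), r_between, dtype=float)
    labels = [block_assignment.get(g) for g in genes]
    for i in range(n):
        for j in range(n):
            if labels[i] is not None and labels[i] == labels[j]:
                corr[i, j] = r_within
    if distal_gene is not None:
        d = genes.index(distal_gene)
        corr[d, :] = distal_r
        corr[:, d] = distal_r
    np.fill_diagonal(corr, 1.0)
    return corr


def _validate_psd(corr: np.ndarray, genes: Sequence[str], context: str) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-10:
        off = np.abs(corr - np.eye(len(corr)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValidationError(
            f"{context}: target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals[0]:.4g}; largest off-diagonal entry "
            f"r[{genes[i]},{genes[j]}]={corr[i, j]:.3g})"
        )
    return corr


def _sample_mvn(
    corr: np.ndarray, means: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    # eigen route tolerates exactly-singular targets (e.g. r = 1)
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    z = rng.standard_normal(size=(corr.shape[0], n_samples))
    return means[:, None] + factor @ z


def generate_expression_cohorts(
    genes: Sequence[str] | None = None,
    block_assignment: Mapping[str, str] | None = None,
    n_cohorts: int = 1,
    n_normal: int = 200,
    n_tumor: int = 200,
    r_within_normal: float = 0.8,
    r_within_tumor: float = 0.2,
    r_between: float = 0.1,
    distal_gene: str | None = None,
    distal_gene_r_tumor: float = 0.0,
    seed: int = 0,
    cohort_names: Sequence[str] | None = None,
) -> ExpressionCohortSet:
    """Simulate log-scale expression with group-dependent block correlation.

    Normal samples are drawn from a multivariate normal whose correlation
    is ``r_within_normal`` inside each block and ``r_between`` across
    blocks; tumor samples use ``r_within_tumor`` within blocks. The
    optional distal gene is uncorrelated with the cluster in normal
    samples and correlated at ``distal_gene_r_tumor`` with every cluster
    gene in tumor samples. Per-gene mean log-expression is drawn once
    (shared across cohorts and groups); the per-gene sd is 1 on the log
    scale. Target matrices are validated for positive semi-definiteness.
    """
    if genes is None:
        genes = list(HOXA_GENES)
        if block_assignment is None:
            block_assignment = dict(DEFAULT_BLOCKS)
    genes = list(genes)
    if block_assignment is None:
        raise ValidationError("block_assignment is required for custom gene lists")
    for r, name in (
        (r_within_normal, "r_within_normal"),
        (r_within_tumor, "r_within_tumor"),
        (r_between, "r_between"),
        (distal_gene_r_tumor, "distal_gene_r_tumor"),
    ):
        if not -1.0 <= r <= 1.0:
            raise ValidationError(f"{name} must lie in [-1, 1], got {r}")
    if distal_gene is not None and distal_gene not in genes:
        genes = genes + [distal_gene]
    if n_normal < 2 or n_tumor < 2:
        raise ValidationError("group sizes must be >= 2")

    corr_normal = _validate_psd(
        _target_correlation(
            genes, block_assignment, r_within_normal, r_between,
            distal_gene, 0.0 if distal_gene else 0.0,
        ),
        genes, "normal",
    )
    corr_tumor = _validate_psd(
        _target_correlation(
            genes, block_assignment, r_within_tumor, r_between,
            distal_gene, distal_gene_r_tumor if distal_gene else 0.0,
        ),
        genes, "tumor",
    )

    if cohort_names is None:
        cohort_names = [f"cohort{i + 1:02d}" for i in range(n_cohorts)]
    ss = np.random.SeedSequence(seed)
    mean_ss, *cohort_ss = ss.spawn(1 + n_cohorts)
    means = np.random.default_rng(mean_ss).normal(5.0, 1.0, size=len(genes))

    cohorts: dict[str, dict[str, pd.DataFrame]] = {}
    for cname, css in zip(cohort_names, cohort_ss):
        rng = np.random.default_rng(css)
        groups = {}
        for gname, corr, size in (
            ("normal", corr_normal, n_normal),
            ("tumor", corr_tumor, n_tumor),
        ):
            values = _sample_mvn(corr, means, size, rng)
            tag = "N" if gname == "normal" else "T"
            columns = [f"{cname}_{tag}{j + 1:03d}" for j in range(size)]
            groups[gname] = pd.DataFrame(values, index=list(genes), columns=columns)
        cohorts[cname] = groups
    return ExpressionCohortSet(
        genes=list(genes),
        block_assignment=dict(block_assignment),
        cohorts=cohorts,
    )
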