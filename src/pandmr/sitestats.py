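"""Per-probe differential methylation statistics and pan-cancer aggregation.

For each cohort every probe gets a two-sided Welch t-test p-value
(tumor vs normal beta values), a Benjamini-Hochberg q-value (adjusted
within the cohort across all probes), an AUROC with tumor as the
positive class and the beta value as the score, and the tumor-minus-
normal mean difference (delta beta). Probes are then aggregated across
cohorts: a probe is a pan-cancer differentially methylated site (DMS)
when its q-value clears the FDR gate in a required fraction of cohorts
and its mean AUROC across cohorts clears the discrimination gate.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
from statsmodels.stats.multitest import multipletests

from .core import ProbeManifest, ValidationError

__all__ = [
    "site_test",
    "adjust_fdr",
    "auroc",
    "per_cohort_stats",
    "cohort_stats_tables",
    "pan_cancer_dms",
]

logger = logging.getLogger(__name__)

STATS_COLUMNS = ["probe_id", "chrom", "pos", "p_value", "q_value", "auc", "delta_beta"]


def _welch_p(normal: np.ndarray, tumor: np.ndarray, axis: int | None = None) -> np.ndarray:
    res = stats.ttest_ind(tumor, normal, axis=axis, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: t is undefined; equal means -> no evidence (p=1),
    # distinct means -> complete separation (p=0)
    var_n = np.var(normal, axis=axis, ddof=1)
    var_t = np.var(tumor, axis=axis, ddof=1)
    degenerate = (var_n == 0) & (var_t == 0)
    if np.any(degenerate):
        equal = np.mean(normal, axis=axis) == np.mean(tumor, axis=axis)
        n_flat = np.sum(degenerate & equal)
        if n_flat:
            logger.info("%d probe(s) constant in both groups; p set to 1", int(n_flat))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return p


def site_test(normal_values: Sequence[float], tumor_values: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value for one probe (tumor vs normal)."""
    normal = np.asarray(normal_values, dtype=float)
    tumor = np.asarray(tumor_values, dtype=float)
    if normal.size < 2 or tumor.size < 2:
        raise ValidationError("site_test needs at least 2 values per group")
    return float(_welch_p(normal, tumor))


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("adjust_fdr needs at least one p-value")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        bad = int(np.flatnonzero(np.isnan(p) | (p < 0) | (p > 1))[0])
        raise ValidationError(f"p-value out of [0, 1] at index {bad}: {p[bad]}")
    return multipletests(p, method="fdr_bh")[1]


def auroc(normal_values: Sequence[float], tumor_values: Sequence[float]) -> float:
    """AUROC for tumor (positive class) vs normal, with half credit for ties.

    Equals the normalized Mann-Whitney U statistic computed from midranks:
    P(tumor score > normal score) + 0.5 * P(tie).
    """
    normal = np.asarray(normal_values, dtype=float)
    tumor = np.asarray(tumor_values, dtype=float)
    if normal.size == 0 or tumor.size == 0:
        raise ValidationError("auroc needs at least one value per group")
    ranks = stats.rankdata(np.concatenate([normal, tumor]))
    rank_sum = ranks[normal.size :].sum()
    u = rank_sum - tumor.size * (tumor.size + 1) / 2.0
    return float(u / (normal.size * tumor.size))


def _auroc_rows(normal: np.ndarray, tumor: np.ndarray) -> np.ndarray:
    combined = np.concatenate([normal, tumor], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    n_t = tumor.shape[1]
    rank_sum = ranks[:, normal.shape[1] :].sum(axis=1)
    u = rank_sum - n_t * (n_t + 1) / 2.0
    return u / (normal.shape[1] * n_t)


def per_cohort_stats(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    manifest: ProbeManifest,
    use_logit: bool = False,
) -> pd.DataFrame:
    """Per-probe p, BH q, AUROC, and delta beta for one cohort.

    ``use_logit`` runs the Welch test on logit-transformed beta values
    (M-value-like scale); AUROC and delta beta always use the beta scale.
    BH adjustment is applied within the cohort across all probes.
    """
    if not normal.index.equals(tumor.index):
        raise ValidationError("normal and tumor matrices must share the probe index")
    if normal.shape[1] < 2 or tumor.shape[1] < 2:
        raise ValidationError("per_cohort_stats needs >= 2 samples per group")
    values_n = normal.to_numpy(dtype=float)
    values_t = tumor.to_numpy(dtype=float)
    if use_logit:
        p = _welch_p(logit(values_n), logit(values_t), axis=1)
    else:
        p = _welch_p(values_n, values_t, axis=1)
    probes = pd.Index(normal.index, name="probe_id")
    table = manifest.to_frame().set_index("probe_id").loc[probes].reset_index()
    table["p_value"] = p
    table["q_value"] = adjust_fdr(p)
    table["auc"] = _auroc_rows(values_n, values_t)
    table["delta_beta"] = values_t.mean(axis=1) - values_n.mean(axis=1)
    return table[STATS_COLUMNS]


def cohort_stats_tables(cohort_set, use_logit: bool = False) -> dict[str, pd.DataFrame]:
    """Per-cohort stats for every cohort of a :class:`BetaCohortSet`."""
    return {
        name: per_cohort_stats(normal, tumor, cohort_set.manifest, use_logit=use_logit)
        for name, (normal, tumor) in cohort_set.cohorts.items()
    }


def pan_cancer_dms(
    tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    q_threshold: float = 0.01,
    mean_auc_threshold: float = 0.75,
    min_significant_fraction: float = 1.0,
    direction_mode: str = "hyper",
) -> pd.DataFrame:
    """Aggregate per-cohort tables into the pan-cancer DMS set.

    A probe is included iff its q-value is below ``q_threshold`` in at
    least ``min_significant_fraction`` of the cohorts where it is
    measured, and its mean AUROC across those cohorts is at least
    ``mean_auc_threshold`` (``direction_mode="hyper"``, tumor-positive) or
    ``max(mean_auc, 1 - mean_auc)`` clears the gate
    (``direction_mode="symmetric"``). Both boundaries are inclusive for
    the AUROC gate and strict for the q-value gate.

    Returns a frame sorted by (chrom, pos) with columns probe_id, chrom,
    pos, direction, mean_auc, mean_delta_beta, n_cohorts_significant.
    """
    if hasattr(tables, "values") and not isinstance(tables, pd.DataFrame):
        table_list = list(tables.values())
    else:
        table_list = list(tables)
    if not table_list:
        raise ValidationError("pan_cancer_dms needs at least one stats table")
    if not 0.0 < q_threshold <= 1.0 or not 0.0 < mean_auc_threshold <= 1.0:
        raise ValidationError("thresholds must lie in (0, 1]")
    if not 0.0 < min_significant_fraction <= 1.0:
        raise ValidationError("min_significant_fraction must lie in (0, 1]")
    if direction_mode not in ("hyper", "symmetric"):
        raise ValidationError(
            f"unknown direction_mode {direction_mode!r}; allowed: hyper, symmetric"
        )

    stacked = pd.concat(table_list, ignore_index=True)
    grouped = stacked.groupby("probe_id", sort=False)
    summary = grouped.agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        mean_auc=("auc", "mean"),
        mean_delta_beta=("delta_beta", "mean"),
        n_cohorts=("q_value", "size"),
        n_cohorts_significant=("q_value", lambda q: int((q < q_threshold).sum())),
    ).reset_index()

    frac = summary["n_cohorts_significant"] / summary["n_cohorts"]
    fdr_pass = frac >= min_significant_fraction
    if direction_mode == "hyper":
        auc_pass = summary["mean_auc"] >= mean_auc_threshold
    else:
        auc_pass = np.maximum(summary["mean_auc"], 1 - summary["mean_auc"]) >= mean_auc_threshold
    dms = summary.loc[fdr_pass & auc_pass].copy()
    dms["direction"] = np.where(dms["mean_delta_beta"] >= 0, "hyper", "hypo")
    dms = dms.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    logger.info("pan-cancer DMS set: %d of %d probes", len(dms), len(summary))
    return dms[
        [
            "probe_id", "chrom", "pos", "direction",
            "mean_auc", "mean_delta_beta", "n_cohorts_significant",
        ]
    ]
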