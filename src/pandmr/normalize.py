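"""Rank-based quantile normalization and cohort-size filtering.

Two reference conventions are provided:

* ``"rank-mean"`` (default): the reference vector is the *sorted vector of
  per-probe means* across samples; within each sample the value of
  within-sample rank k is replaced by the k-th smallest reference value.
* ``"classic"``: the usual quantile normalization reference — the mean of
  the per-sample sorted columns.

Both make every output column share one multiset of values and preserve
within-sample rank order. Ties within a sample all receive the mean of
the reference values over the tied rank positions, so the result does not
depend on input row order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import BetaCohortSet, ValidationError

__all__ = ["quantile_normalize", "normalize_cohorts", "filter_cohorts", "drop_missing_probes"]

logger = logging.getLogger(__name__)

QN_MODES = ("rank-mean", "classic")


def quantile_normalize(matrix: pd.DataFrame, mode: str = "rank-mean") -> pd.DataFrame:
    """Quantile-normalize a probes x samples matrix.

    Parameters
    ----------
    matrix
        Probes x samples values; no missing values allowed (apply
        :func:`drop_missing_probes` first).
    mode
        ``"rank-mean"`` or ``"classic"``; see module docstring.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValidationError("matrix must have at least one probe and one sample")
    if mode not in QN_MODES:
        raise ValidationError(f"unknown qn mode {mode!r}; allowed: {QN_MODES}")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(
            "matrix contains missing values; drop or impute before normalizing"
        )
    if mode == "rank-mean":
        reference = np.sort(values.mean(axis=1))
    else:
        reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        assigned = reference.copy()
        # ties share the mean reference value over their rank span
        _, first, counts = np.unique(sorted_vals, return_index=True, return_counts=True)
        for i, c in zip(first, counts):
            if c > 1:
                assigned[i : i + c] = reference[i : i + c].mean()
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_cohorts(
    cohorts: BetaCohortSet, mode: str = "rank-mean", scope: str = "joint"
) -> BetaCohortSet:
    """Quantile-normalize a cohort set.

    ``scope="joint"`` normalizes all samples of the set together (one
    shared reference, the default, matching normalization of all enrolled
    samples at once); ``scope="cohort"`` normalizes each cohort's pooled
    normal+tumor samples separately.
    """
    if scope not in ("joint", "cohort"):
        raise ValidationError(f"unknown scope {scope!r}; allowed: joint, cohort")
    if scope == "joint":
        blocks = []
        for name, (normal, tumor) in cohorts.cohorts.items():
            blocks.append(normal)
            blocks.append(tumor)
        combined = quantile_normalize(pd.concat(blocks, axis=1), mode=mode)
        return cohorts.map_matrices(lambda m: combined.loc[:, m.columns])
    out = {}
    for name, (normal, tumor) in cohorts.cohorts.items():
        combined = quantile_normalize(pd.concat([normal, tumor], axis=1), mode=mode)
        out[name] = (
            combined.loc[:, normal.columns],
            combined.loc[:, tumor.columns],
        )
    return BetaCohortSet(cohorts.manifest, out)


def filter_cohorts(cohorts: BetaCohortSet, min_group_size: int = 30) -> BetaCohortSet:
    """Drop cohorts whose normal or tumor group is smaller than the threshold.

    A cohort is retained iff both groups have at least ``min_group_size``
    samples (a cohort with exactly the threshold passes). Removals are
    logged; removing every cohort is an error rather than an empty result.
    """
    if min_group_size < 1:
        raise ValidationError("min_group_size must be >= 1")
    kept = {}
    for name, (normal, tumor) in cohorts.cohorts.items():
        n, t = normal.shape[1], tumor.shape[1]
        if n < min_group_size or t < min_group_size:
            logger.info(
                "excluding cohort %s: group sizes (normal=%d, tumor=%d) below %d",
                name, n, t, min_group_size,
            )
            continue
        kept[name] = (normal, tumor)
    if not kept:
        raise ValidationError(
            f"every cohort fell below the minimum group size of {min_group_size}"
        )
    return BetaCohortSet(cohorts.manifest, kept)


def drop_missing_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop probes with any missing value, logging how many were removed."""
    mask = matrix.isna().any(axis=1)
    if mask.any():
        logger.info("dropping %d probes with missing values", int(mask.sum()))
    return matrix.loc[~mask]
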