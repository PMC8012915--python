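"""Co-expression block structure and its disruption.

For an ordered gene cluster (the motivating case is HOXA1..HOXA13 split
into two blocks around an intra-locus hypermethylated region) the module
computes per-group Pearson correlation matrices, a *block contrast* —
mean within-block correlation minus mean between-block correlation, a
scalar summary of the modular structure a clustered heatmap shows — and
the association between a distal gene and each cluster gene (Pearson r
with the two-sided t-transform p-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = ["CorrMatrix", "BlockContrast", "correlation_matrix", "block_contrast", "distal_association"]


@dataclass
class CorrMatrix:
    """Symmetric Pearson correlation matrix over a gene list.

    Genes with zero variance cannot carry a correlation; they are
    excluded from the matrix and recorded in ``errors`` instead of
    being reported as silent NaNs.
    """

    matrix: pd.DataFrame
    n_samples: int
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class BlockContrast:
    """Within-block minus between-block mean correlation."""

    within_mean: float
    between_mean: float
    n_within_pairs: int
    n_between_pairs: int
    permutation_p: float | None = None

    @property
    def contrast(self) -> float:
        return self.within_mean - self.between_mean


def correlation_matrix(expr: pd.DataFrame) -> CorrMatrix:
    """Pairwise Pearson correlations of a genes x samples matrix."""
    n_samples = expr.shape[1]
    if n_samples < 3:
        raise ValidationError("correlation_matrix needs at least 3 samples")
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        gene = expr.index[np.flatnonzero(np.isnan(values).any(axis=1))[0]]
        raise ValidationError(f"missing expression values for gene {gene!r}")
    variances = values.var(axis=1)
    errors = {
        str(expr.index[i]): "zero variance" for i in np.flatnonzero(variances == 0)
    }
    keep = variances > 0
    kept_values = values[keep]
    corr = np.corrcoef(kept_values)
    corr = np.atleast_2d(corr)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, 1.0)
    genes = expr.index[keep]
    return CorrMatrix(
        matrix=pd.DataFrame(corr, index=genes, columns=genes),
        n_samples=n_samples,
        errors=errors,
    )


def _contrast_value(corr: np.ndarray, labels: np.ndarray) -> tuple[float, float, int, int]:
    same = labels[:, None] == labels[None, :]
    upper = np.triu(np.ones_like(same, dtype=bool), k=1)
    within = same & upper
    between = ~same & upper
    n_within = int(within.sum())
    n_between = int(between.sum())
    if n_within == 0:
        raise ValidationError("no block has two or more genes; within-block mean undefined")
    if n_between == 0:
        raise ValidationError("need at least two blocks for a between-block mean")
    return float(corr[within].mean()), float(corr[between].mean()), n_within, n_between


def block_contrast(
    corr: CorrMatrix,
    blocks: dict[str, str],
    n_permutations: int = 0,
    seed: int = 0,
) -> BlockContrast:
    """Block contrast of a correlation matrix.

    ``blocks`` maps gene -> block label; only genes present in both the
    matrix and the assignment enter. The optional permutation p-value
    shuffles gene -> block labels ``n_permutations`` times and is
    one-sided (permuted contrast >= observed), with the +1 correction.
    """
    genes = [g for g in corr.genes if g in blocks]
    if len(genes) < 3:
        raise ValidationError("need at least 3 block-assigned genes in the matrix")
    labels = np.asarray([blocks[g] for g in genes])
    if len(set(labels)) < 2:
        raise ValidationError("need at least 2 blocks")
    sub = corr.matrix.loc[genes, genes].to_numpy()
    within, between, n_w, n_b = _contrast_value(sub, labels)
    result = BlockContrast(
        within_mean=within,
        between_mean=between,
        n_within_pairs=n_w,
        n_between_pairs=n_b,
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        observed = result.contrast
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            try:
                w, b, *_ = _contrast_value(sub, perm)
            except ValidationError:
                continue
            if w - b >= observed:
                hits += 1
        result.permutation_p = (hits + 1) / (n_permutations + 1)
    return result


def distal_association(
    expr: pd.DataFrame,
    distal_gene: str,
    cluster_genes: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson association between a distal gene and each cluster gene.

    Returns a frame (gene, r, p_value, significant) where the two-sided
    p-value comes from the t transform with n - 2 degrees of freedom and
    significance is p < alpha.
    """
    if expr.shape[1] < 4:
        raise ValidationError("distal_association needs at least 4 samples")
    if distal_gene not in expr.index:
        raise ValidationError(f"distal gene {distal_gene!r} absent from the matrix")
    missing = [g for g in cluster_genes if g not in expr.index]
    if missing:
        raise ValidationError(f"cluster genes absent from the matrix: {missing}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    x = expr.loc[distal_gene].to_numpy(dtype=float)
    rows = []
    for gene in cluster_genes:
        y = expr.loc[gene].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        rows.append({"gene": gene, "r": float(r), "p_value": float(p), "significant": bool(p < alpha)})
    return pd.DataFrame(rows, columns=["gene", "r", "p_value", "significant"])
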