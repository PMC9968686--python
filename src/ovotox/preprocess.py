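"""Cell-level QC, bulk normalization, and PCA summary.

Bulk normalization uses median-of-ratios size factors followed by a
shifted log2 transform (tag "mor-log2"): a monotone, variance-stabilizing
transform that preserves the semantics of the downstream detectability and
fold-change filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyAtlasError, ValidationError
from .io import CountMatrix

logger = logging.getLogger("ovotox")


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression (genes x samples)."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    normalization: str = "mor-log2"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("expression shape does not match identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def qc_cells(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    min_umi: int = 1000,
    min_genes: int = 500,
    max_pct_mito: float = 15.0,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Remove low-quality cells from a cells x genes matrix.

    A cell is removed iff total UMI < ``min_umi`` OR detected genes <
    ``min_genes`` OR mitochondrial percentage > ``max_pct_mito`` (strict
    inequalities; a cell exactly at every threshold is retained). Metrics
    are recomputed from the matrix; the mitochondrial gene set is all
    genes whose identifier starts with ``mito_prefix``. The report counts
    removals per criterion (a cell can fail several).
    """
    if counts.orientation != "cells_by_genes":
        raise ValidationError("qc_cells expects a cells_by_genes matrix")
    values = counts.values
    mito_mask = np.array([g.startswith(mito_prefix) for g in counts.col_ids])
    total = values.sum(axis=1)
    n_genes = (values > 0).sum(axis=1)
    pct_mito = np.where(
        total > 0, 100.0 * values[:, mito_mask].sum(axis=1) / np.maximum(total, 1), 0.0
    )
    fail_umi = total < min_umi
    fail_genes = n_genes < min_genes
    fail_mito = pct_mito > max_pct_mito
    keep = ~(fail_umi | fail_genes | fail_mito)
    report = {
        "n_input": int(len(keep)),
        "n_removed": int((~keep).sum()),
        "removed_low_umi": int(fail_umi.sum()),
        "removed_low_genes": int(fail_genes.sum()),
        "removed_high_mito": int(fail_mito.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise EmptyAtlasError("QC removed every cell")
    kept_ids = [c for c, k in zip(counts.row_ids, keep) if k]
    out_counts = counts.subset_rows(kept_ids)
    out_meta = metadata[metadata["cell_id"].isin(kept_ids)].reset_index(drop=True)
    logger.info("qc_cells: kept %d/%d cells", report["n_kept"], report["n_input"])
    return out_counts, out_meta, report


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, restricted
    to genes positive in every sample; each sample's factor is the median
    ratio of its counts to the reference. When no gene is positive in all
    samples the estimator falls back to library-size factors (with a
    logged warning).
    """
    if counts.orientation != "genes_by_samples":
        raise ValidationError("size_factors expects a genes_by_samples matrix")
    values = counts.values.astype(float)
    n_genes, n_samples = values.shape
    if n_samples == 1:
        return np.array([1.0])
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValidationError("a sample has no nonzero counts")
    all_pos = np.all(values > 0, axis=1)
    if not all_pos.any():
        logger.warning("size_factors: no gene positive in all samples; library-size fallback")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return factors
    sub = values[all_pos]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalize_log(
    counts: CountMatrix, factors: np.ndarray | None = None, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount), per sample."""
    if factors is None:
        factors = size_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValidationError("size factors must be positive")
    if factors.shape != (len(counts.col_ids),):
        raise ValidationError("one size factor per sample required")
    values = np.log2(counts.values / factors[None, :] + pseudocount)
    return ExpressionMatrix(values, list(counts.row_ids), list(counts.col_ids), "mor-log2")


def pca_summary(expr: ExpressionMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates and variance fractions via SVD of gene-centered data.

    Genes are centered but not scaled (expression is already on log scale).
    Returns (samples x components DataFrame, variance fractions).
    """
    n_samples = len(expr.col_ids)
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_comp = min(len(expr.row_ids), n_samples)
    if n_components > max_comp:
        logger.warning("pca_summary: clipping n_components %d -> %d", n_components, max_comp)
        n_components = max_comp
    x = expr.values - expr.values.mean(axis=1, keepdims=True)  # center genes
    # samples are observations: SVD of x.T
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    total_var = np.sum(s**2)
    if total_var <= 0:
        coords = np.zeros((n_samples, n_components))
        fracs = np.zeros(n_components)
    else:
        coords = u[:, :n_components] * s[:n_components]
        fracs = (s[:n_components] ** 2) / total_var
    df = pd.DataFrame(
        coords, index=expr.col_ids, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return df, fracs
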