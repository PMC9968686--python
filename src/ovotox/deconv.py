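"""Cross-species bulk deconvolution against a single-cell reference.

Model: a bulk sample's relative expression x_g is approximated by
sum_k beta_k * theta_gk with beta_k proportional to p_k * S_k (cell-size
weighted abundance). Coefficients are estimated per sample by iteratively
re-weighted non-negative least squares: gene weights shrink with the
cross-subject variance of the reference profile (w_g = 1 / (nu +
sum_k beta_k^2 * tau2_gk)), so genes whose cluster profiles are unstable
across reference subjects count less. Proportions are recovered as
p_k = (beta_k / S_k) / sum_j (beta_j / S_j) and summed within broad cell
types for group comparisons (two-sided Wilcoxon rank-sum, exact for small
groups).

Genes enter the design only if they are one-to-one orthologs between the
reference and bulk species, present in both matrices, and in the
reference's variable-gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as spo
from sklearn.base import BaseEstimator

from .atlas import ReferenceSignature
from .errors import UnderdeterminedError, ValidationError
from .io import CountMatrix
from .stats import rank_sum_test

logger = logging.getLogger("ovotox")


def nnls(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Non-negative least squares: argmin ||a @ beta - b||^2 s.t. beta >= 0.

    Thin validating wrapper around the Lawson-Hanson active-set solver.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("nnls inputs must be finite")
    zero_cols = np.where(~np.any(a != 0, axis=0))[0]
    if zero_cols.size:
        raise ValidationError(f"all-zero design column at index {zero_cols[0]}")
    beta, _ = spo.nnls(a, b)
    return beta


def restrict_orthologs(
    signature: ReferenceSignature,
    bulk: CountMatrix,
    ortholog_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Align reference and bulk on one-to-one orthologs and variable genes.

    Keeps exactly the genes that are (i) one2one in the map, (ii) present
    in both matrices after renaming source -> target, and (iii) in the
    reference's variable-gene list (all shared genes when the reference
    has none). Returns (theta', tau2', bulk', col_mass) indexed by
    target-space gene ids. theta' columns are renormalized to sum 1 and
    tau2' is rescaled accordingly; ``col_mass`` is each cluster's captured
    expression mass (the pre-renormalization column sum), by which cell
    sizes must be multiplied so that proportions refer to whole cells
    rather than to the restricted gene space.
    """
    if len(ortholog_map) == 0:
        raise ValidationError("empty ortholog map")
    one2one = ortholog_map[ortholog_map["relationship"] == "one2one"]
    src_to_tgt = dict(zip(one2one["source_gene"], one2one["target_gene"]))
    ref_genes = list(signature.theta.index)
    allowed = set(signature.variable_genes) if signature.variable_genes else set(ref_genes)
    bulk_genes = set(bulk.row_ids)
    kept_src = [
        g
        for g in ref_genes
        if g in allowed and g in src_to_tgt and src_to_tgt[g] in bulk_genes
    ]
    n_clusters = signature.theta.shape[1]
    if len(kept_src) < 2 * n_clusters:
        raise UnderdeterminedError(
            f"only {len(kept_src)} genes survive ortholog/variable restriction "
            f"(need >= {2 * n_clusters})"
        )
    kept_tgt = [src_to_tgt[g] for g in kept_src]
    theta = signature.theta.loc[kept_src].copy()
    theta.index = kept_tgt
    col_mass = theta.sum(axis=0)
    theta = theta / col_mass
    tau2 = signature.tau2.loc[kept_src].copy()
    tau2.index = kept_tgt
    tau2 = tau2 / col_mass**2
    bulk_df = bulk.to_frame().loc[kept_tgt]
    logger.info("restrict_orthologs: %d genes used", len(kept_tgt))
    return theta, tau2, bulk_df, col_mass


@dataclass
class SampleDeconvolution:
    """Per-sample deconvolution outcome."""

    proportions: pd.Series  # per cluster, sums to 1
    broad_proportions: pd.Series
    residual_norm: float
    iterations: int
    converged: bool
    n_genes_used: int


def weighted_nnls_proportions(
    x: np.ndarray,
    theta: np.ndarray,
    tau2: np.ndarray,
    cell_size: np.ndarray,
    nu: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Iteratively re-weighted NNLS for one sample.

    ``x`` is the bulk column normalized to sum 1. Returns
    (proportions, beta, weighted residual norm, iterations, converged).
    With tau2 identically zero the weights stay constant, so the result
    equals a single plain NNLS solve.
    """
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValidationError("bulk column has no signal")
    x = x / total
    if nu is None:
        nu = 1e-8 * float(np.mean(x**2))
    w = np.ones_like(x)
    beta = np.zeros(theta.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sw = np.sqrt(w)
        beta_new = nnls(theta * sw[:, None], x * sw)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        # damp the weight update with the previous iterate: the plain
        # fixed-point map can settle into a two-point limit cycle
        beta_mid = 0.5 * (beta_new + beta)
        beta = beta_new
        w = 1.0 / (nu + tau2 @ (beta_mid**2))
    if not converged:
        logger.warning("weighted NNLS did not converge in %d iterations", max_iter)
    resid = np.sqrt(np.sum(w * (x - theta @ beta) ** 2))
    scaled = beta / cell_size
    s = scaled.sum()
    props = scaled / s if s > 0 else np.full_like(scaled, 1.0 / len(scaled))
    return props, beta, float(resid), it, converged


def aggregate_broad_types(
    proportions: pd.Series, cluster_broad: dict[str, str]
) -> pd.Series:
    """Sum cluster proportions within broad types; total is conserved."""
    unmapped = set(proportions.index) - set(cluster_broad)
    if unmapped:
        raise ValidationError(f"clusters without broad type: {sorted(unmapped)}")
    out: dict[str, float] = {}
    for k, v in proportions.items():
        out[cluster_broad[k]] = out.get(cluster_broad[k], 0.0) + float(v)
    return pd.Series(out).sort_index()


class CellTypeDeconvolver(BaseEstimator):
    """Estimate cell-cluster proportions of bulk samples from a reference.

    Parameters
    ----------
    nu : float or None
        Weight regularizer; None picks 1e-8 * mean(x^2) per sample.
    tol, max_iter : float, int
        Convergence control of the re-weighting iteration (max |d beta|).
    use_cell_size : bool
        If False, S_k is taken as 1 for every cluster (pure
        relative-abundance mode; the cross-species cell size is an
        assumption, not an observation).

    After ``fit`` the aligned design is available as ``theta_``, ``tau2_``,
    ``cell_size_`` and ``cluster_broad_``; ``predict`` returns a samples x
    clusters proportions DataFrame and stores per-sample diagnostics in
    ``details_``.
    """

    def __init__(
        self,
        nu: float | None = None,
        tol: float = 1e-6,
        max_iter: int = 1000,
        use_cell_size: bool = True,
    ):
        self.nu = nu
        self.tol = tol
        self.max_iter = max_iter
        self.use_cell_size = use_cell_size

    def fit(self, reference: ReferenceSignature, y=None):
        self.theta_ = reference.theta.copy()
        self.tau2_ = reference.tau2.copy()
        if self.use_cell_size:
            self.cell_size_ = reference.cell_size.copy()
        else:
            self.cell_size_ = pd.Series(1.0, index=reference.theta.columns)
        self.cluster_broad_ = dict(reference.cluster_broad)
        self.variable_genes_ = (
            list(reference.variable_genes) if reference.variable_genes else None
        )
        return self

    def align(self, bulk: CountMatrix, ortholog_map: pd.DataFrame):
        """Restrict the fitted design and the bulk matrix to usable genes."""
        ref = ReferenceSignature(
            self.theta_, self.tau2_, self.cell_size_, self.cluster_broad_, self.variable_genes_
        )
        theta, tau2, _, col_mass = restrict_orthologs(ref, bulk, ortholog_map)
        self.theta_ = theta
        self.tau2_ = tau2
        # whole-cell size in the restricted gene space
        self.cell_size_ = self.cell_size_ * col_mass
        return self

    def predict(self, bulk) -> pd.DataFrame:
        """Deconvolve each bulk column independently.

        ``bulk`` is a CountMatrix or genes x samples DataFrame whose index
        must cover the fitted design's genes.
        """
        if not hasattr(self, "theta_"):
            raise ValidationError("deconvolver is not fitted")
        bulk_df = bulk.to_frame() if isinstance(bulk, CountMatrix) else pd.DataFrame(bulk)
        missing = set(self.theta_.index) - set(bulk_df.index)
        if missing:
            raise ValidationError(f"bulk matrix lacks design genes: {sorted(missing)[:5]}")
        bulk_df = bulk_df.loc[self.theta_.index]
        theta = self.theta_.to_numpy()
        tau2 = self.tau2_.to_numpy()
        sizes = self.cell_size_.reindex(self.theta_.columns).to_numpy(float)
        clusters = list(self.theta_.columns)
        rows, details = {}, {}
        for sid in bulk_df.columns:
            props, beta, resid, it, conv = weighted_nnls_proportions(
                bulk_df[sid].to_numpy(float), theta, tau2, sizes,
                nu=self.nu, tol=self.tol, max_iter=self.max_iter,
            )
            p = pd.Series(props, index=clusters)
            rows[sid] = p
            details[sid] = SampleDeconvolution(
                proportions=p,
                broad_proportions=aggregate_broad_types(p, self.cluster_broad_),
                residual_norm=resid,
                iterations=it,
                converged=conv,
                n_genes_used=len(self.theta_.index),
            )
        self.details_ = details
        return pd.DataFrame(rows).T.loc[list(bulk_df.columns)]

    def predict_broad(self, bulk) -> pd.DataFrame:
        props = self.predict(bulk)
        return props.T.groupby(
            pd.Series(self.cluster_broad_).reindex(props.columns)
        ).sum().T


def deconvolve_sample(
    bulk_column,
    theta: pd.DataFrame,
    tau2: pd.DataFrame,
    cell_size: pd.Series,
    cluster_broad: dict[str, str],
    nu: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SampleDeconvolution:
    """Functional single-sample interface over the estimator's core solver."""
    x = np.asarray(bulk_column, dtype=float)
    props, _, resid, it, conv = weighted_nnls_proportions(
        x, theta.to_numpy(), tau2.to_numpy(),
        cell_size.reindex(theta.columns).to_numpy(float), nu=nu, tol=tol, max_iter=max_iter,
    )
    p = pd.Series(props, index=theta.columns)
    return SampleDeconvolution(
        p, aggregate_broad_types(p, cluster_broad), resid, it, conv, len(theta.index)
    )


def compare_proportions(
    broad_props: pd.DataFrame,
    metadata: pd.DataFrame,
    contrasts: list[tuple[str, pd.Series, pd.Series]] | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum comparisons of broad-type proportions.

    ``broad_props`` is samples x broad types. ``contrasts`` is a list of
    (label, reference sample mask, test sample mask); when None, the
    standard panel is built from metadata: stage-vs-stage within controls
    (per plate), and each dose vs its stage-matched control within
    compound. Percent change is on group means; it is NaN when the
    reference mean is 0.
    """
    meta = metadata.set_index("sample_id").loc[broad_props.index]
    if contrasts is None:
        contrasts = []
        for plate in sorted(meta["plate"].unique()):
            ctrl = (meta["compound"] == "control") & (meta["plate"] == plate)
            stages = [s for s in ("PND6", "PND14", "PND22") if ((meta["stage"] == s) & ctrl).any()]
            for a, b in zip(stages[:-1], stages[1:]):
                contrasts.append(
                    (f"{plate}:control:{a}_vs_{b}", ctrl & (meta["stage"] == a), ctrl & (meta["stage"] == b))
                )
            if len(stages) > 2:
                contrasts.append(
                    (
                        f"{plate}:control:{stages[0]}_vs_{stages[-1]}",
                        ctrl & (meta["stage"] == stages[0]),
                        ctrl & (meta["stage"] == stages[-1]),
                    )
                )
        for compound in sorted(set(meta["compound"]) - {"control"}):
            plate = meta.loc[meta["compound"] == compound, "plate"].iloc[0]
            for stage in sorted(meta["stage"].unique()):
                ref = (
                    (meta["compound"] == "control")
                    & (meta["plate"] == plate)
                    & (meta["stage"] == stage)
                )
                for dose in ("low", "medium", "high"):
                    test = (
                        (meta["compound"] == compound)
                        & (meta["stage"] == stage)
                        & (meta["dose_level"] == dose)
                    )
                    if test.any():
                        contrasts.append((f"{compound}:{stage}:{dose}_vs_control", ref, test))

    records = []
    for label, ref_mask, test_mask in contrasts:
        ref_ids = meta.index[np.asarray(ref_mask)]
        test_ids = meta.index[np.asarray(test_mask)]
        if len(ref_ids) < 2 or len(test_ids) < 2:
            raise ValidationError(f"contrast {label!r} has a group with < 2 samples")
        for bt in broad_props.columns:
            ref_vals = broad_props.loc[ref_ids, bt].to_numpy()
            test_vals = broad_props.loc[test_ids, bt].to_numpy()
            stat, p = rank_sum_test(test_vals, ref_vals)
            mref, mtest = float(ref_vals.mean()), float(test_vals.mean())
            pct = (mtest - mref) / mref * 100.0 if mref > 0 else float("nan")
            records.append(
                {
                    "contrast": label,
                    "broad_type": bt,
                    "n1": len(ref_ids),
                    "n2": len(test_ids),
                    "mean_ref": mref,
                    "mean_test": mtest,
                    "pct_change": pct,
                    "stat": stat,
                    "p": p,
                }
            )
    return pd.DataFrame(records)
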