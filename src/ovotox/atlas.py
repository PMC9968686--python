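"""Deconvolution reference and marker detection from a labeled atlas.

``build_reference`` turns a QC'd, labeled cells x genes matrix into the
three ingredients of the deconvolution design: per-cluster mean relative
expression (Theta), its cross-subject variance (T2), and per-cluster cell
size (mean total UMI per cell). ``find_markers`` scores genes one-vs-rest
per cluster with the Wilcoxon rank-sum statistic and AUC on log-normalized
per-cell expression; marker sets feed both cell-type enrichment and the
variable-gene list used by the deconvolver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import CountMatrix, GeneSetCollection
from .stats import bh_adjust

logger = logging.getLogger("ovotox")


@dataclass
class ReferenceSignature:
    """Deconvolution reference: Theta, T2 (cross-subject variance), S."""

    theta: pd.DataFrame  # genes x clusters, columns sum to 1
    tau2: pd.DataFrame  # genes x clusters
    cell_size: pd.Series  # per cluster
    cluster_broad: dict[str, str]
    variable_genes: list[str] | None = None

    def __post_init__(self):
        cols = list(self.theta.columns)
        if list(self.tau2.columns) != cols or list(self.cell_size.index) != cols:
            raise ValidationError("Theta, T2 and S must share the cluster set")
        sums = self.theta.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("each Theta column must sum to 1")
        if (self.tau2.to_numpy() < 0).any():
            raise ValidationError("T2 must be nonnegative")
        if (self.cell_size.to_numpy() <= 0).any():
            raise ValidationError("cell sizes must be positive")
        missing = set(cols) - set(self.cluster_broad)
        if missing:
            raise ValidationError(f"clusters without broad type: {sorted(missing)}")


def build_reference(counts: CountMatrix, metadata: pd.DataFrame) -> ReferenceSignature:
    """Build the reference signature from a labeled cells x genes matrix.

    For each subject s and cluster k, theta^s_gk is the cluster's pooled
    relative expression within that subject; Theta is the across-subject
    mean and T2 the across-subject variance (ddof=1; zero, with a warning,
    for clusters seen in a single subject). S_k is the mean total UMI per
    cell of cluster k pooled over subjects.
    """
    if counts.orientation != "cells_by_genes":
        raise ValidationError("build_reference expects a cells_by_genes matrix")
    if metadata["subject_id"].nunique() < 2:
        raise ValidationError("build_reference needs at least 2 subjects")
    meta = metadata.set_index("cell_id").loc[counts.row_ids]
    clusters = sorted(meta["cluster_id"].unique())
    genes = list(counts.col_ids)
    values = counts.values.astype(float)

    theta_cols, tau_cols, sizes = {}, {}, {}
    for k in clusters:
        in_k = (meta["cluster_id"] == k).to_numpy()
        total_k = values[in_k].sum()
        if total_k <= 0:
            raise ValidationError(f"cluster {k!r} has zero total counts")
        profiles = []
        for s in sorted(meta["subject_id"].unique()):
            sel = in_k & (meta["subject_id"] == s).to_numpy()
            if not sel.any():
                continue
            colsum = values[sel].sum(axis=0)
            tot = colsum.sum()
            if tot > 0:
                profiles.append(colsum / tot)
        profiles = np.array(profiles)
        theta_cols[k] = profiles.mean(axis=0)
        if len(profiles) > 1:
            tau_cols[k] = profiles.var(axis=0, ddof=1)
        else:
            logger.warning("cluster %s present in a single subject; T2 set to 0", k)
            tau_cols[k] = np.zeros(len(genes))
        sizes[k] = values[in_k].sum() / in_k.sum()

    theta = pd.DataFrame(theta_cols, index=genes)
    theta = theta / theta.sum(axis=0)
    tau2 = pd.DataFrame(tau_cols, index=genes)
    cell_size = pd.Series(sizes).loc[theta.columns]
    broad = dict(zip(meta["cluster_id"], meta["broad_type"]))
    return ReferenceSignature(theta, tau2, cell_size, {k: broad[k] for k in clusters})


def _lognorm(values: np.ndarray, scale: float = 1e4) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return np.log2(values / totals * scale + 1.0)


def find_markers(
    counts: CountMatrix,
    cluster_labels: pd.Series | np.ndarray,
    adj_p_max: float = 0.05,
    top_n: int = 200,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker statistics per gene and cluster.

    Expression is library-size log-normalized per cell. For each cluster
    the Wilcoxon rank-sum statistic (normal approximation, tie-corrected,
    continuity-corrected), the AUC = U/(n1*n2) and the difference of group
    means on the log scale (log2FC) are computed per gene; p values are
    BH-adjusted across genes within each cluster. The ``marker`` flag
    selects adjusted p <= ``adj_p_max`` and log2FC > 0, keeping the
    ``top_n`` genes by AUC per cluster.
    """
    if counts.orientation != "cells_by_genes":
        raise ValidationError("find_markers expects a cells_by_genes matrix")
    labels = np.asarray(cluster_labels)
    if len(labels) != len(counts.row_ids):
        raise ValidationError("one cluster label per cell required")
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValidationError("find_markers needs at least 2 clusters")
    ln = _lognorm(counts.values)
    n_cells, n_genes = ln.shape
    ranks = np.apply_along_axis(lambda col: sps.rankdata(col, method="average"), 0, ln)

    # per-gene tie correction term: sum(t^3 - t) over tied groups
    tie_term = np.zeros(n_genes)
    for j in range(n_genes):
        _, cnt = np.unique(ln[:, j], return_counts=True)
        tie_term[j] = np.sum(cnt.astype(float) ** 3 - cnt)

    records = []
    for k in clusters:
        mask = labels == k
        n1 = int(mask.sum())
        n2 = n_cells - n1
        if n1 < min_cells:
            logger.warning("find_markers: cluster %s has < %d cells; excluded", k, min_cells)
            continue
        r1 = ranks[mask].sum(axis=0)
        u = r1 - n1 * (n1 + 1) / 2.0
        auc = u / (n1 * n2)
        var = n1 * n2 / 12.0 * ((n_cells + 1) - tie_term / (n_cells * (n_cells - 1)))
        var = np.maximum(var, 0.0)
        dev = np.maximum(np.abs(u - n1 * n2 / 2.0) - 0.5, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, dev / np.sqrt(var), 0.0)
        p = 2.0 * sps.norm.sf(z)
        p = np.minimum(p, 1.0)
        lfc = ln[mask].mean(axis=0) - ln[~mask].mean(axis=0)
        adj = bh_adjust(p)
        sub = pd.DataFrame(
            {
                "gene": counts.col_ids,
                "cluster": k,
                "log2fc": lfc,
                "auc": auc,
                "p": p,
                "adj_p": adj,
            }
        )
        cand = sub[(sub["adj_p"] <= adj_p_max) & (sub["log2fc"] > 0)]
        top = set(cand.sort_values("auc", ascending=False).head(top_n)["gene"])
        sub["marker"] = sub["gene"].isin(top)
        records.append(sub)
    out = pd.concat(records, ignore_index=True)
    return out


def marker_sets(
    markers: pd.DataFrame, cluster_broad: dict[str, str] | None = None
) -> GeneSetCollection:
    """Marker gene sets per cluster and (optionally) per broad type.

    The broad-type set is the union of its member clusters' sets.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for k, sub in markers[markers["marker"]].groupby("cluster"):
        sets[f"cluster:{k}"] = set(sub["gene"])
        desc[f"cluster:{k}"] = f"markers of cluster {k}"
    if cluster_broad:
        for k, bt in cluster_broad.items():
            key = f"broad:{bt}"
            members = sets.get(f"cluster:{k}", set())
            if members:
                sets.setdefault(key, set()).update(members)
                desc[key] = f"markers of broad type {bt}"
    sets = {t: g for t, g in sets.items() if g}
    return GeneSetCollection(sets, desc)


def variable_genes(markers: pd.DataFrame, cap: int = 3000) -> list[str]:
    """Variable-gene list: union of marker sets, best-AUC-first, capped."""
    mk = markers[markers["marker"]].sort_values("auc", ascending=False)
    seen: list[str] = []
    for g in mk["gene"]:
        if g not in seen:
            seen.append(g)
        if len(seen) >= cap:
            break
    return seen
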