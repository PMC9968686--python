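"""Synthetic data with complete ground truth.

Generators emulate the study design this package models: a labeled
single-cell reference atlas of the developing ovary (clusters nested in
broad cell types, per-cluster marker genes, cross-subject variability,
injected QC-failing cells) and a bulk cohort of 3 postnatal stages x
(control + 3 doses) x 2 compounds with negative-binomial UMI noise, where
bulk expression arises as a cell-type mixture whose proportions shift
across stages (germ-cell decline, granulosa/steroidogenic-granulosa rise)
and where dose-responsive differential expression is planted on chosen
genes.

The negative binomial is parameterized by mean and a single size
(inverse-dispersion) parameter, the standard UMI noise model; default
size 10. Every generator is deterministic given its seed, and every truth
object serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    CountMatrix,
    GeneSetCollection,
    STAGES,
    validate_cell_metadata,
    validate_ortholog_map,
    validate_sample_metadata,
)

# ---------------------------------------------------------------------------
# atlas


@dataclass
class ClusterSpec:
    name: str
    broad_type: str
    n_cells: int
    n_markers: int = 5
    size_mult: float = 1.0  # multiplies mean total UMI per cell


def default_clusters_spec(n_cells: int = 120) -> list[ClusterSpec]:
    """Eight clusters covering the eight most prominent ovarian cell types.

    Germ cells get a larger cell size (oocytes are large, RNA-rich cells);
    erythrocytes and perivascular cells, rare in the tissue, are omitted so
    eight of the ten broad types are present.
    """
    return [
        ClusterSpec("c1", "germ", n_cells, size_mult=2.0),
        ClusterSpec("c2", "coelomic_surface_epithelial", n_cells),
        ClusterSpec("c3", "granulosa", n_cells),
        ClusterSpec("c4", "steroidogenic_granulosa", n_cells),
        ClusterSpec("c5", "interstitial", n_cells),
        ClusterSpec("c6", "theca", n_cells),
        ClusterSpec("c7", "endothelial", n_cells, size_mult=0.7),
        ClusterSpec("c8", "immune", n_cells, size_mult=0.7),
    ]


@dataclass
class AtlasTruth:
    """Ground truth behind a generated atlas.

    theta: genes x clusters relative expression (columns sum to 1);
    cluster_broad: cluster -> broad type; cell_size: mean total UMI per
    cell and cluster; markers: cluster -> designated marker genes;
    qc_fail_cells: injected cells that violate the QC thresholds.
    """

    theta: pd.DataFrame
    cluster_broad: dict[str, str]
    cell_size: pd.Series
    subject_sigma: float
    markers: dict[str, list[str]]
    qc_fail_cells: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "theta": {c: self.theta[c].round(10).to_dict() for c in self.theta},
                    "cluster_broad": self.cluster_broad,
                    "cell_size": self.cell_size.to_dict(),
                    "subject_sigma": self.subject_sigma,
                    "markers": self.markers,
                    "qc_fail_cells": self.qc_fail_cells,
                },
                indent=1,
            )
        )


def _gene_ids(n_genes: int, n_mito: int, mito_prefix: str) -> list[str]:
    mito = [f"{mito_prefix}{i + 1}" for i in range(n_mito)]
    rest = [f"g{i + 1:04d}" for i in range(n_genes - n_mito)]
    return mito + rest


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_atlas(
    n_genes: int = 600,
    clusters_spec: list[ClusterSpec] | None = None,
    n_subjects: int = 3,
    seed: int = 0,
    marker_fold: float = 8.0,
    dispersion: float = 10.0,
    mean_umi: float = 6000.0,
    subject_sigma: float = 0.3,
    qc_fail_frac: float = 0.05,
    n_mito: int = 10,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, pd.DataFrame, AtlasTruth]:
    """Generate a labeled single-cell atlas (cells x genes) with truth.

    Per-cluster relative expression profiles share a common gamma baseline
    modulated per cluster; each cluster's designated marker genes are
    elevated ``marker_fold``-fold in that cluster only. Subjects perturb
    profiles by a per-gene log-normal factor of scale ``subject_sigma``.
    A ``qc_fail_frac`` fraction of extra cells violating the QC thresholds
    (low UMI, low gene count, or high mitochondrial content) is appended
    and recorded in the truth.
    """
    if n_subjects < 2:
        raise ValidationError("cross-subject variance needs at least 2 subjects")
    if clusters_spec is None:
        clusters_spec = default_clusters_spec()
    if n_genes <= n_mito + sum(c.n_markers for c in clusters_spec):
        raise ValidationError("n_genes too small for requested markers and mito genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes, n_mito, mito_prefix)
    clusters = [c.name for c in clusters_spec]

    base = rng.gamma(2.0, 1.0, size=n_genes)
    base[:n_mito] = base[:n_mito].mean() * 0.5  # modest mito share in healthy cells
    theta = {}
    markers: dict[str, list[str]] = {}
    next_marker = n_mito
    for cs in clusters_spec:
        prof = base * rng.lognormal(0.0, 0.5, size=n_genes)
        mk = genes[next_marker : next_marker + cs.n_markers]
        next_marker += cs.n_markers
        markers[cs.name] = mk
        theta[cs.name] = prof
    # elevate markers in their own cluster only, relative to the gene's
    # maximum across clusters so the fold survives per-cluster variation
    gene_index = {g: i for i, g in enumerate(genes)}
    gene_max = np.max(np.column_stack(list(theta.values())), axis=1)
    for cname, mk in markers.items():
        idx = [gene_index[g] for g in mk]
        theta[cname][idx] = marker_fold * gene_max[idx]
    theta_df = pd.DataFrame(theta, index=genes)
    theta_df = theta_df / theta_df.sum(axis=0)

    cell_size = pd.Series(
        {cs.name: mean_umi * cs.size_mult for cs in clusters_spec}, name="cell_size"
    )
    subjects = [f"sub{j + 1}" for j in range(n_subjects)]
    subj_factor = {
        s: rng.lognormal(0.0, subject_sigma, size=n_genes) for s in subjects
    }

    rows, meta_rows = [], []
    cell_no = 0
    for cs in clusters_spec:
        th = theta_df[cs.name].to_numpy()
        for i in range(cs.n_cells):
            subj = subjects[i % n_subjects]
            th_s = th * subj_factor[subj]
            th_s = th_s / th_s.sum()
            total = rng.lognormal(np.log(mean_umi * cs.size_mult), 0.3)
            counts = _nb_draw(rng, total * th_s, dispersion)
            cell_no += 1
            cid = f"cell{cell_no:05d}"
            rows.append(counts)
            meta_rows.append((cid, subj, STAGES[i % len(STAGES)], cs.name, cs.broad_type))

    # injected QC failures, cycling through the three failure modes
    n_fail = int(round(qc_fail_frac * cell_no))
    qc_fail: list[str] = []
    mito_idx = np.arange(n_mito)
    for j in range(n_fail):
        cs = clusters_spec[j % len(clusters_spec)]
        th = theta_df[cs.name].to_numpy()
        mode = j % 3
        if mode == 0:  # low total UMI
            counts = _nb_draw(rng, 400.0 * th, dispersion)
        elif mode == 1:  # few detected genes: all mass on a tiny gene subset
            counts = np.zeros(n_genes, dtype=np.int64)
            chosen = rng.choice(n_genes, size=50, replace=False)
            counts[chosen] = _nb_draw(rng, np.full(50, 2000.0 / 50), dispersion)
        else:  # high mitochondrial content
            th_m = th.copy()
            th_m[mito_idx] = 0.0
            th_m = 0.6 * th_m / th_m.sum()
            th_m[mito_idx] = 0.4 / n_mito
            counts = _nb_draw(rng, 2500.0 * th_m, dispersion)
        cell_no += 1
        cid = f"cell{cell_no:05d}"
        qc_fail.append(cid)
        rows.append(counts)
        meta_rows.append((cid, subjects[j % n_subjects], STAGES[j % 3], cs.name, cs.broad_type))

    values = np.vstack(rows)
    cell_ids = [m[0] for m in meta_rows]
    counts_cm = CountMatrix(values, cell_ids, genes, orientation="cells_by_genes")

    total_umi = values.sum(axis=1)
    n_genes_det = (values > 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct_mito = 100.0 * values[:, :n_mito].sum(axis=1) / np.maximum(total_umi, 1)
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "subject_id", "stage", "cluster_id", "broad_type"])
    meta["total_umi"] = total_umi
    meta["n_genes"] = n_genes_det
    meta["pct_mito"] = pct_mito
    meta = validate_cell_metadata(meta)

    truth = AtlasTruth(theta_df, {c.name: c.broad_type for c in clusters_spec},
                       cell_size, subject_sigma, markers, qc_fail)
    return counts_cm, meta, truth


# ---------------------------------------------------------------------------
# bulk cohort


@dataclass
class DesignSpec:
    """Cohort layout: stages x (control + doses) x compounds, with plates.

    Mirrors the modeled study: each compound occupies one plate together
    with its own control groups (DES on plate #2, KTZ on plate #1); doses
    3/6/12 ug per kg bw per day for DES and 3/6/12 mg for KTZ.
    """

    stages: tuple = STAGES
    compounds: tuple = ("DES", "KTZ")
    dose_levels: tuple = ("low", "medium", "high")
    n_replicates: int = 6
    plate_of: dict = field(default_factory=lambda: {"DES": "plate2", "KTZ": "plate1"})
    dose_values: dict = field(
        default_factory=lambda: {
            "DES": {"low": "3 ug/kg bw/day", "medium": "6 ug/kg bw/day", "high": "12 ug/kg bw/day"},
            "KTZ": {"low": "3 mg/kg bw/day", "medium": "6 mg/kg bw/day", "high": "12 mg/kg bw/day"},
        }
    )


@dataclass
class PlantedEffect:
    """A planted differential-expression effect on one gene.

    ``stage`` / ``dose_level`` of None mean the effect applies at every
    stage / dose of the compound.
    """

    gene: str
    compound: str
    log2fc: float
    stage: str | None = None
    dose_level: str | None = None

    def applies(self, compound: str, stage: str, dose_level: str) -> bool:
        return (
            compound == self.compound
            and (self.stage is None or stage == self.stage)
            and (self.dose_level is None or dose_level == self.dose_level)
        )


DEFAULT_TRAJECTORIES = {
    # broad type -> proportion at (PND6, PND14, PND22); germ cells fall
    # sharply (-80% first to last stage), granulosa and steroidogenic
    # granulosa rise, matching the qualitative developmental pattern.
    "germ": (0.40, 0.22, 0.08),
    "coelomic_surface_epithelial": (0.12, 0.08, 0.05),
    "granulosa": (0.18, 0.28, 0.35),
    "steroidogenic_granulosa": (0.02, 0.06, 0.14),
    "interstitial": (0.18, 0.14, 0.12),
    "theca": (0.04, 0.06, 0.08),
    "endothelial": (0.02, 0.08, 0.10),
    "immune": (0.04, 0.08, 0.08),
}


@dataclass
class CohortTruth:
    """Ground truth behind a generated bulk cohort."""

    proportions: pd.DataFrame  # samples x clusters, rows sum to 1
    effects: list[PlantedEffect]
    lib_sizes: pd.Series
    dispersion: float | None
    expected: pd.DataFrame  # genes x samples relative expression after planted effects

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "proportions": {s: self.proportions.loc[s].round(10).to_dict()
                                    for s in self.proportions.index},
                    "effects": [vars(e) for e in self.effects],
                    "lib_sizes": self.lib_sizes.to_dict(),
                    "dispersion": self.dispersion,
                },
                indent=1,
            )
        )


def stage_proportions(
    truth: AtlasTruth, trajectories: dict[str, tuple] | None = None
) -> pd.DataFrame:
    """Per-stage target cluster proportions from broad-type trajectories.

    The broad-type proportion is split evenly across that type's clusters;
    the result is renormalized per stage over the broad types present.
    """
    trajectories = trajectories or DEFAULT_TRAJECTORIES
    clusters = list(truth.theta.columns)
    members: dict[str, list[str]] = {}
    for c in clusters:
        members.setdefault(truth.cluster_broad[c], []).append(c)
    rows = {}
    for si, stage in enumerate(STAGES):
        p = {}
        for bt, cl in members.items():
            if bt not in trajectories:
                raise ValidationError(f"no proportion trajectory for broad type {bt!r}")
            for c in cl:
                p[c] = trajectories[bt][si] / len(cl)
        vec = pd.Series(p).reindex(clusters)
        rows[stage] = vec / vec.sum()
    return pd.DataFrame(rows).T  # stages x clusters


def mixture_expectation(truth: AtlasTruth, proportions: pd.Series) -> pd.Series:
    """Exact relative bulk expression for given cluster proportions.

    x_g proportional to sum_k p_k * S_k * theta_gk, normalized to sum 1 —
    the noiseless limit of a cohort sample.
    """
    p = proportions.reindex(truth.theta.columns).to_numpy(float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValidationError("proportions must be nonnegative and sum to 1")
    s = truth.cell_size.reindex(truth.theta.columns).to_numpy(float)
    x = truth.theta.to_numpy() @ (p * s)
    return pd.Series(x / x.sum(), index=truth.theta.index)


def generate_bulk_cohort(
    atlas_truth: AtlasTruth,
    design_spec: DesignSpec | None = None,
    effects_spec: list[PlantedEffect] | None = None,
    seed: int = 0,
    lib_size: float = 200_000.0,
    dispersion: float | None = 10.0,
    proportion_concentration: float = 300.0,
    trajectories: dict[str, tuple] | None = None,
    rename: dict[str, str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame, CohortTruth]:
    """Generate a bulk cohort (genes x samples) from the atlas truth.

    Each sample's expectation is the cell-size-weighted mixture of cluster
    profiles at its true proportions (drawn from a Dirichlet around the
    stage trajectory), multiplied by 2**log2fc on genes with a planted
    effect in its condition, then sampled negative-binomially at the
    sample's library size. ``dispersion=None`` is the noiseless limit: the
    returned counts are the rounded expectations and ``truth.expected``
    holds the exact relative values.

    ``rename`` maps atlas gene ids to the bulk namespace (e.g. the target
    side of an ortholog map); unmapped genes keep their atlas ids.
    """
    design = design_spec or DesignSpec()
    effects = list(effects_spec or [])
    gene_index = set(atlas_truth.theta.index)
    for e in effects:
        if e.gene not in gene_index:
            raise ValidationError(f"planted effect on gene absent from atlas: {e.gene!r}")
    rng = np.random.default_rng(seed)
    targets = stage_proportions(atlas_truth, trajectories)
    clusters = list(atlas_truth.theta.columns)
    genes = list(atlas_truth.theta.index)
    gpos = {g: i for i, g in enumerate(genes)}

    cols, meta_rows, props, expected = [], [], {}, {}
    for compound in design.compounds:
        plate = design.plate_of[compound]
        for stage in design.stages:
            for dose in ("none",) + tuple(design.dose_levels):
                cgroup = "control" if dose == "none" else compound
                for r in range(design.n_replicates):
                    sid = f"{plate}_{stage}_{cgroup}_{dose}_r{r + 1}"
                    alpha = targets.loc[stage].to_numpy() * proportion_concentration
                    p = rng.dirichlet(alpha)
                    props[sid] = p
                    x = mixture_expectation(atlas_truth, pd.Series(p, index=clusters)).to_numpy()
                    for e in effects:
                        if cgroup != "control" and e.applies(cgroup, stage, dose):
                            x = x.copy()
                            x[gpos[e.gene]] *= 2.0 ** e.log2fc
                    expected[sid] = x
                    mean = lib_size * x
                    if dispersion is None:
                        counts = np.rint(mean).astype(np.int64)
                    else:
                        counts = _nb_draw(rng, mean, dispersion)
                    cols.append(counts)
                    dose_value = (
                        "0" if dose == "none" else design.dose_values[compound][dose]
                    )
                    meta_rows.append((sid, stage, cgroup, dose, dose_value, plate))

    values = np.column_stack(cols)
    sample_ids = [m[0] for m in meta_rows]
    out_genes = [rename.get(g, g) for g in genes] if rename else genes
    cm = CountMatrix(values, out_genes, sample_ids, orientation="genes_by_samples")
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "stage", "compound", "dose_level", "dose_value", "plate"]
    )
    meta = validate_sample_metadata(meta, cm)
    truth = CohortTruth(
        proportions=pd.DataFrame(props, index=clusters).T,
        effects=effects,
        lib_sizes=pd.Series(lib_size, index=sample_ids),
        dispersion=dispersion,
        expected=pd.DataFrame(expected, index=out_genes),
    )
    return cm, meta, truth


# ---------------------------------------------------------------------------
# ortholog map and gene sets


def generate_ortholog_map(
    gene_ids,
    frac_one2one: float = 0.8,
    frac_one2many: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Generate a source->target ortholog table; returns (map, one2one sources).

    one2one sources map to a uniquely renamed target ("R" prefix);
    one2many sources get two targets; remaining genes stay unmapped.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValidationError("empty gene list")
    if frac_one2one + frac_one2many > 1 + 1e-12:
        raise ValidationError("ortholog fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(gene_ids)))
    n11 = int(round(frac_one2one * len(gene_ids)))
    n1m = int(round(frac_one2many * len(gene_ids)))
    one2one = [gene_ids[i] for i in order[:n11]]
    one2many = [gene_ids[i] for i in order[n11 : n11 + n1m]]
    records = [(g, f"R{g}", "one2one") for g in one2one]
    for g in one2many:
        records.append((g, f"R{g}a", "one2many"))
        records.append((g, f"R{g}b", "one2many"))
    df = pd.DataFrame(records, columns=["source_gene", "target_gene", "relationship"])
    df = df.sort_values(["source_gene", "target_gene"], ignore_index=True)
    return validate_ortholog_map(df), sorted(one2one)


def generate_gene_sets(
    gene_ids,
    n_terms: int = 10,
    enriched_spec: dict[str, list[str]] | None = None,
    seed: int = 0,
    frac_from_target: float = 0.6,
    term_size_range: tuple[int, int] = (10, 40),
) -> tuple[GeneSetCollection, dict[str, list[str]]]:
    """Generate gene sets; enriched terms draw members from target groups.

    ``enriched_spec`` maps term ids to target gene groups (e.g. planted
    DEGs); those terms draw ``frac_from_target`` of their members from the
    group and the rest uniformly. ``n_terms`` additional background terms
    draw uniformly. Returns the collection and the truth (term -> target
    members actually included).
    """
    universe = list(gene_ids)
    rng = np.random.default_rng(seed)
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValidationError("term size exceeds gene universe")
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    truth: dict[str, list[str]] = {}
    for term, target in (enriched_spec or {}).items():
        target = [g for g in target if g in set(universe)]
        if not target:
            raise ValidationError(f"enriched term {term!r} has no target genes in universe")
        size = int(rng.integers(lo, hi + 1))
        n_t = min(len(target), max(1, int(round(frac_from_target * size))))
        chosen = set(rng.choice(target, size=n_t, replace=False))
        rest = [g for g in universe if g not in chosen]
        chosen |= set(rng.choice(rest, size=max(0, size - n_t), replace=False))
        sets[term] = chosen
        desc[term] = "enriched term (synthetic)"
        truth[term] = sorted(set(target) & chosen)
    for i in range(n_terms):
        term = f"BG{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        sets[term] = set(rng.choice(universe, size=size, replace=False))
        desc[term] = "background term (synthetic)"
    return GeneSetCollection(sets, desc), truth
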