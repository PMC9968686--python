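"""Expression-pattern clustering, enrichment, intersection and biomarkers.

DEG profiles (per-stage mean expression for the development analysis;
per-stage x dose log2 fold changes for exposure analyses; concatenated
z-scored profiles of both compounds for the shared analysis) are z-scored
per gene and partitioned by K-means. Patterns are tested against gene-set
collections with the one-sided Fisher/hypergeometric test, BH-adjusted
jointly across all (pattern, term) pairs of an analysis, with the
enrichment call requiring adjusted p <= 0.05 and at least 2 overlapping
genes. Signature intersection and the >= 2-dose direction-consistency rule
nominate biomarker candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .dge import SignatureSet
from .errors import ValidationError
from .io import GeneSetCollection
from .stats import bh_adjust, hypergeom_upper_tail

logger = logging.getLogger("ovotox")

ANALYSIS_PREFIX = {"development": "O", "DES": "D", "KTZ": "K", "shared": "P"}


@dataclass
class ExpressionPattern:
    pattern_id: str
    genes: list[str]
    centroid: pd.Series
    analysis: str


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score; constant rows become all-zero."""
    vals = profiles.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=profiles.index, columns=profiles.columns)


class ExpressionPatternKMeans(BaseEstimator):
    """K-means over z-scored gene profiles with deterministic labeling.

    k-means++ initialization, ``n_init`` restarts, best inertia kept (all
    delegated to scikit-learn). Clusters are relabeled by the column index
    of their centroid's peak (then by centroid mean as tie-break) and
    numbered 1..k with the analysis prefix (O/D/K/P), so labels are stable
    given the seed.
    """

    def __init__(self, k: int = 3, analysis: str = "development", seed: int = 0, n_init: int = 10):
        self.k = k
        self.analysis = analysis
        self.seed = seed
        self.n_init = n_init

    def fit(self, X: pd.DataFrame, y=None):
        profiles = pd.DataFrame(X)
        if self.k > len(profiles.index):
            raise ValidationError("k exceeds the number of genes")
        z = zscore_profiles(profiles)
        km = KMeans(n_clusters=self.k, init="k-means++", n_init=self.n_init,
                    random_state=self.seed)
        raw = km.fit_predict(z.to_numpy())
        centroids = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
        # order clusters by peak column position, then by descending mean
        order = sorted(
            range(self.k),
            key=lambda c: (int(np.argmax(centroids.iloc[c].to_numpy())),
                           -float(centroids.iloc[c].mean())),
        )
        prefix = ANALYSIS_PREFIX.get(self.analysis, self.analysis[:1].upper())
        relabel = {old: f"{prefix}{new + 1}" for new, old in enumerate(order)}
        labels = pd.Series([relabel[c] for c in raw], index=profiles.index, name="pattern_id")
        self.labels_ = labels
        self.patterns_ = [
            ExpressionPattern(
                pattern_id=relabel[c],
                genes=sorted(labels.index[labels == relabel[c]]),
                centroid=centroids.iloc[c],
                analysis=self.analysis,
            )
            for c in order
        ]
        self.inertia_ = km.inertia_
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).labels_


def kmeans_patterns(
    profiles: pd.DataFrame, k: int, seed: int = 0, analysis: str = "development"
) -> list[ExpressionPattern]:
    """Partition gene profiles into k expression patterns (see estimator)."""
    return ExpressionPatternKMeans(k=k, analysis=analysis, seed=seed).fit(profiles).patterns_


def fisher_enrichment(
    members,
    universe,
    gene_sets: GeneSetCollection,
    min_genes: int = 2,
    pattern_id: str = "",
) -> pd.DataFrame:
    """One-sided Fisher/hypergeometric enrichment of one gene group.

    P values are raw here; BH adjustment is applied jointly across all
    (pattern, term) pairs of an analysis by ``enrich_patterns``. The
    ``enriched`` flag requires adjusted p <= 0.05 and overlap >=
    ``min_genes`` and is therefore only final after adjustment.
    """
    members = set(members)
    universe = set(universe)
    if not members <= universe:
        raise ValidationError("pattern members must lie within the universe")
    rows = []
    for term, genes in gene_sets.items():
        term_in_universe = genes & universe
        if not term_in_universe:
            logger.warning("term %s disjoint from universe; skipped", term)
            continue
        overlap = len(term_in_universe & members)
        p = hypergeom_upper_tail(overlap, len(universe), len(term_in_universe), len(members))
        rows.append(
            {
                "pattern_id": pattern_id,
                "term_id": term,
                "overlap": overlap,
                "pattern_size": len(members),
                "term_size": len(term_in_universe),
                "universe_size": len(universe),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def enrich_patterns(
    patterns: list[ExpressionPattern],
    universe,
    gene_sets: GeneSetCollection,
    min_genes: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of every pattern, BH-adjusted across all pairs jointly."""
    tables = [
        fisher_enrichment(p.genes, universe, gene_sets, min_genes, p.pattern_id)
        for p in patterns
    ]
    out = pd.concat([t for t in tables if len(t)], ignore_index=True) if tables else pd.DataFrame()
    if len(out) == 0:
        return out
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = (out["adj_p"] <= alpha) & (out["overlap"] >= min_genes)
    return out.sort_values(["pattern_id", "adj_p", "term_id"], ignore_index=True)


def intersect_signatures(sig_a: SignatureSet, sig_b: SignatureSet) -> tuple[set[str], pd.DataFrame]:
    """Shared genes of two compound signatures and a direction concordance table.

    Shared = union of A's genes (over all conditions) intersected with
    union of B's. The concordance table cross-tabulates each shared gene's
    direction class (over / under / mixed) in A against its class in B.
    """
    comps_a = sig_a.compounds()
    comps_b = sig_b.compounds()
    genes_a = {g for c in comps_a for g in sig_a.union(c)}
    genes_b = {g for c in comps_b for g in sig_b.union(c)}
    shared = genes_a & genes_b

    def classify(sig: SignatureSet, comps: list[str], gene: str) -> str:
        classes = {sig.direction_class(c, gene) for c in comps if gene in sig.union(c)}
        if classes == {"over"}:
            return "over"
        if classes == {"under"}:
            return "under"
        return "mixed"

    rows = [
        {"gene": g, "class_a": classify(sig_a, comps_a, g), "class_b": classify(sig_b, comps_b, g)}
        for g in sorted(shared)
    ]
    table = pd.DataFrame(rows, columns=["gene", "class_a", "class_b"])
    return shared, table


@dataclass
class BiomarkerCall:
    gene: str
    compound: str
    stage: str
    supporting_doses: list[str] = field(default_factory=list)
    direction: str = ""
    rule: str = ""
    all_dose: bool = False


def biomarker_candidates(
    sig: SignatureSet, min_doses: int = 2, n_dose_levels: int = 3
) -> list[BiomarkerCall]:
    """Nominate genes called with one direction in >= ``min_doses`` doses.

    The rule is evaluated per (gene, compound, stage); direction conflicts
    across supporting doses disqualify the gene. Calls supported by every
    dose level carry the ``all_dose`` flag.
    """
    per_key: dict[tuple[str, str, str], dict[str, str]] = {}
    for (c, s, d), gd in sig.calls.items():
        for g, direction in gd.items():
            per_key.setdefault((g, c, s), {})[d] = direction
    calls = []
    for (g, c, s), doses in sorted(per_key.items()):
        if len(doses) < min_doses:
            continue
        directions = set(doses.values())
        if len(directions) != 1:
            continue
        direction = directions.pop()
        calls.append(
            BiomarkerCall(
                gene=g,
                compound=c,
                stage=s,
                supporting_doses=sorted(doses),
                direction=direction,
                rule=f"{direction} at {s} in {len(doses)}/{n_dose_levels} doses",
                all_dose=len(doses) == n_dose_levels,
            )
        )
    return calls


def biomarker_table(calls: list[BiomarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "compound": c.compound,
                "stage": c.stage,
                "direction": c.direction,
                "n_doses": len(c.supporting_doses),
                "doses": ",".join(c.supporting_doses),
                "all_dose": c.all_dose,
                "rule": c.rule,
            }
            for c in calls
        ],
        columns=["gene", "compound", "stage", "direction", "n_doses", "doses", "all_dose", "rule"],
    )
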