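"""Reproducible performance benchmarks on synthetic ground truth.

Each benchmark regenerates its inputs from a seed, runs the relevant part
of the pipeline, and measures recovery against the generator's truth:

- deconvolution: broad-type proportion error on noisy cohorts and exact
  recovery in the noiseless limit, through the full ortholog-restriction
  path (atlas of 8 clusters, ~300 one-to-one orthologs, NB noise);
- the DE cascade: realized false-discovery proportion on null cohorts and
  recovery ("power") of planted |log2FC| = 1.5 effects;
- the empirical-Bayes moment estimator: relative error of (d0, s0^2) on
  variances simulated from the prior;
- pattern K-means: adjusted Rand index against planted stage-peak
  archetypes.

Problem sizes are chosen so the full battery runs in well under two
minutes on one CPU; they are stated in the package documentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import preprocess, simdata
from .atlas import build_reference
from .deconv import CellTypeDeconvolver
from .dge import ContrastSpec, fit_ebayes, run_cascade
from .io import one2one_pairs
from .patterns import kmeans_patterns


def _small_cluster_spec(n_cells: int = 120) -> list[simdata.ClusterSpec]:
    return [
        simdata.ClusterSpec(c.name, c.broad_type, n_cells, c.n_markers, c.size_mult)
        for c in simdata.default_clusters_spec()
    ]


def deconvolution_recovery(
    n_seeds: int = 20, n_genes: int = 375, seed: int = 0
) -> dict[str, float]:
    """Broad-type proportion recovery through the full cross-species path.

    Per seed: a fresh atlas (8 clusters over 8 broad types), a QC'd
    estimated reference, an 80% one-to-one ortholog map (~300 usable
    genes), and a 12-sample NB-noise cohort with stage-varying true
    proportions. Reports the mean absolute error of broad-type proportions
    and, for the truth reference on exact mixture expectations, the
    maximum absolute error (noiseless limit).
    """
    maes, noiseless_errs, sign_hits = [], [], []
    design = simdata.DesignSpec(compounds=("DES",), dose_levels=("high",), n_replicates=2)
    for i in range(n_seeds):
        s = seed + 1000 * i
        sc, meta, truth = simdata.generate_atlas(
            n_genes=n_genes, clusters_spec=_small_cluster_spec(), seed=s
        )
        # gene-count threshold scaled to the reduced gene space
        scq, metaq, _ = preprocess.qc_cells(sc, meta, min_genes=n_genes // 3)
        ref = build_reference(scq, metaq)
        omap, _ = simdata.generate_ortholog_map(
            list(truth.theta.index), frac_one2one=0.8, frac_one2many=0.1, seed=s + 1
        )
        rename = one2one_pairs(omap)
        bulk, smeta, ctruth = simdata.generate_bulk_cohort(
            truth, design, seed=s + 2, rename=rename
        )
        model = CellTypeDeconvolver().fit(ref)
        model.align(bulk, omap)
        broad = model.predict_broad(bulk)
        cb = pd.Series(truth.cluster_broad)
        truth_broad = ctruth.proportions.T.groupby(cb).sum().T.loc[broad.index]
        err = broad - truth_broad[broad.columns]
        maes.append(float(err.abs().mean().mean()))

        # sign of stage-to-stage changes for strongly-changing types
        est_stage = broad.groupby(smeta.set_index("sample_id")["stage"]).mean()
        true_stage = truth_broad.groupby(smeta.set_index("sample_id")["stage"]).mean()
        for bt in broad.columns:
            t6, t22 = true_stage.loc["PND6", bt], true_stage.loc["PND22", bt]
            if t6 > 0 and abs(t22 - t6) / t6 >= 0.2:
                e6, e22 = est_stage.loc["PND6", bt], est_stage.loc["PND22", bt]
                sign_hits.append(float(np.sign(e22 - e6) == np.sign(t22 - t6)))

        # noiseless limit: exact mixture expectations, truth reference
        truth_ref = CellTypeDeconvolver().fit(_truth_signature(truth))
        truth_ref.align(_expected_bulk(ctruth, truth), omap)
        props = truth_ref.predict(ctruth.expected)
        noiseless_errs.append(
            float((props - ctruth.proportions.loc[props.index]).abs().max().max())
        )
    return {
        "mean_broad_mae": float(np.mean(maes)),
        "noiseless_max_abs_err": float(np.max(noiseless_errs)),
        "sign_recovery_rate": float(np.mean(sign_hits)) if sign_hits else float("nan"),
        "n_seeds": n_seeds,
    }


def _truth_signature(truth: simdata.AtlasTruth):
    from .atlas import ReferenceSignature

    return ReferenceSignature(
        truth.theta, truth.theta * 0.0, truth.cell_size, truth.cluster_broad
    )


def _expected_bulk(ctruth: simdata.CohortTruth, truth: simdata.AtlasTruth):
    from .io import CountMatrix

    scaled = np.rint(ctruth.expected.to_numpy() * 1e9).astype(np.int64)
    return CountMatrix(
        scaled, list(ctruth.expected.index), list(ctruth.expected.columns)
    )


def null_cascade_fdp(
    n_reps: int = 100, n_genes: int = 2000, n_replicates: int = 6, seed: int = 0
) -> dict[str, float]:
    """Mean realized false-discovery proportion on effect-free cohorts."""
    truth = simdata.generate_atlas(
        n_genes=n_genes, clusters_spec=_small_cluster_spec(5), seed=seed
    )[2]
    design = simdata.DesignSpec(
        compounds=("DES",), dose_levels=("high",), stages=("PND6",), n_replicates=n_replicates
    )
    contrast = ContrastSpec("exposure", compound="DES", stage="PND6", dose_level="high")
    fdps, n_degs = [], []
    for i in range(n_reps):
        bulk, meta, _ = simdata.generate_bulk_cohort(truth, design, seed=seed + 17 + i)
        expr = preprocess.normalize_log(bulk)
        res = run_cascade(expr, meta, contrast)
        n = int(res["deg"].sum())
        n_degs.append(n)
        fdps.append(n / n if n else 0.0)  # every discovery is false under the null
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_false_discoveries": float(np.mean(n_degs)),
        "n_reps": n_reps,
    }


def cascade_power(
    n_seeds: int = 10,
    n_genes: int = 2000,
    n_planted: int = 50,
    log2fc: float = 1.5,
    n_replicates: int = 8,
    seed: int = 0,
) -> dict[str, float]:
    """Recovery rate of planted |log2FC| effects on expressed genes."""
    truth = simdata.generate_atlas(
        n_genes=n_genes, clusters_spec=_small_cluster_spec(5), seed=seed
    )[2]
    rng = np.random.default_rng(seed + 1)
    expr_level = simdata.mixture_expectation(
        truth, simdata.stage_proportions(truth).loc["PND6"]
    )
    pool = [
        g
        for g in truth.theta.index
        if not g.startswith("mt-") and expr_level[g] > expr_level.median()
    ]
    planted = list(rng.choice(pool, size=n_planted, replace=False))
    effects = [
        simdata.PlantedEffect(
            g, "DES", log2fc * float(rng.choice([-1.0, 1.0])), stage="PND6", dose_level="high"
        )
        for g in planted
    ]
    design = simdata.DesignSpec(
        compounds=("DES",), dose_levels=("high",), stages=("PND6",), n_replicates=n_replicates
    )
    contrast = ContrastSpec("exposure", compound="DES", stage="PND6", dose_level="high")
    recoveries = []
    for i in range(n_seeds):
        bulk, meta, _ = simdata.generate_bulk_cohort(truth, design, effects, seed=seed + 29 + i)
        expr = preprocess.normalize_log(bulk)
        res = run_cascade(expr, meta, contrast)
        degs = set(res.index[res["deg"]])
        recoveries.append(float(np.mean([g in degs for g in planted])))
    return {
        "mean_recovery": float(np.mean(recoveries)),
        "min_recovery": float(np.min(recoveries)),
        "n_seeds": n_seeds,
    }


def ebayes_recovery(
    d0: float = 4.0, s0_sq: float = 2.0, d_g: int = 4, n_genes: int = 5000, seed: int = 0
) -> dict[str, float]:
    """Relative error of the moment estimator on prior-simulated variances."""
    rng = np.random.default_rng(seed)
    sigma2 = s0_sq * d0 / rng.chisquare(d0, n_genes)
    s2 = sigma2 * rng.chisquare(d_g, n_genes) / d_g
    est = fit_ebayes(s2, d_g)
    return {
        "d0_rel_err": float(abs(est.d0 - d0) / d0),
        "s0_sq_rel_err": float(abs(est.s0_sq - s0_sq) / s0_sq),
        "n_genes": n_genes,
    }


def pattern_recovery(
    n_seeds: int = 20, n_per_archetype: int = 30, noise: float = 0.3, seed: int = 0
) -> dict[str, float]:
    """ARI of K-means against three planted stage-peak archetypes."""
    aris = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        genes, profs, labels = [], [], []
        for a, arch in enumerate([(2, 0, 0), (0, 2, 0), (0, 0, 2)]):
            for j in range(n_per_archetype):
                genes.append(f"a{a}_g{j}")
                labels.append(a)
                profs.append(np.array(arch, dtype=float) + rng.normal(0, noise, 3))
        df = pd.DataFrame(profs, index=genes, columns=["PND6", "PND14", "PND22"])
        pats = kmeans_patterns(df, 3, seed=seed + i, analysis="development")
        assignment = {g: p.pattern_id for p in pats for g in p.genes}
        aris.append(adjusted_rand_score(labels, [assignment[g] for g in genes]))
    return {
        "min_ari": float(np.min(aris)),
        "mean_ari": float(np.mean(aris)),
        "n_seeds": n_seeds,
    }
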