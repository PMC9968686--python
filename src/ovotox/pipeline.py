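"""End-to-end orchestration: simulate -> qc -> normalize -> dge -> patterns
-> enrichment -> deconvolution -> intersection -> biomarkers.

Every stage writes its outputs as TSV/JSON into the output directory with
fixed orderings and float formatting, so identical configurations (seed
included) produce byte-identical files. Logging goes to standard error
with stage-tagged lines; stdout stays reserved for CLI status.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import deconv as deconv_mod
from . import dge as dge_mod
from . import patterns as patterns_mod
from . import preprocess
from . import simdata
from .errors import OvotoxError
from .io import (
    CountMatrix,
    GeneSetCollection,
    PipelineConfig,
    STAGES,
    one2one_pairs,
    read_cell_metadata,
    read_count_matrix,
    read_gmt,
    read_ortholog_map,
    read_sample_metadata,
    write_count_matrix,
    write_gmt,
    write_ortholog_map,
)

logger = logging.getLogger("ovotox")

FLOAT_FMT = "%.6g"
STAGE_ORDER = (
    "qc",
    "normalize",
    "dge",
    "patterns",
    "enrich",
    "deconvolve",
    "intersect",
    "report",
)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)


@dataclass
class Bundle:
    """Everything a pipeline run consumes."""

    bulk: CountMatrix
    sample_meta: pd.DataFrame
    sc_counts: CountMatrix
    cell_meta: pd.DataFrame
    orthologs: pd.DataFrame
    gene_sets: GeneSetCollection


def default_effects(atlas_truth: simdata.AtlasTruth, seed: int = 0) -> list[simdata.PlantedEffect]:
    """Planted exposure effects used by the simulate stage.

    A mix of all-dose and two-dose effects per compound, magnitudes
    |log2FC| in 0.6-2, with a handful of genes affected by both compounds
    so the intersection stage has signal. Genes are drawn from the
    non-marker portion of the atlas.
    """
    rng = np.random.default_rng(seed)
    marker_genes = {g for mk in atlas_truth.markers.values() for g in mk}
    # plant on expressed, non-marker genes: exposure effects on genes below
    # the detection background are invisible by construction
    expr = simdata.mixture_expectation(
        atlas_truth, simdata.stage_proportions(atlas_truth).loc["PND6"]
    )
    pool = [
        g
        for g in atlas_truth.theta.index
        if g not in marker_genes and not g.startswith("mt-") and expr[g] > expr.median()
    ]
    chosen = list(rng.choice(pool, size=52, replace=False))
    effects: list[simdata.PlantedEffect] = []

    def lfc(sign):
        return float(sign * rng.uniform(0.8, 2.0))

    # DES: all-dose effects at PND6, two-dose at PND14, high-dose at all stages
    for g in chosen[0:4]:
        effects.append(simdata.PlantedEffect(g, "DES", lfc(+1), stage="PND6"))
    for g in chosen[4:8]:
        effects.append(simdata.PlantedEffect(g, "DES", lfc(-1), stage="PND6"))
    for g in chosen[8:16]:
        s = lfc(rng.choice([-1, 1]))
        for d in ("medium", "high"):
            effects.append(simdata.PlantedEffect(g, "DES", s, stage="PND14", dose_level=d))
    for g in chosen[16:24]:
        effects.append(
            simdata.PlantedEffect(g, "DES", lfc(rng.choice([-1, 1])), dose_level="high")
        )
    # KTZ: all-dose up at PND6, all-dose down at PND14, two-dose at PND22
    for g in chosen[24:28]:
        effects.append(simdata.PlantedEffect(g, "KTZ", lfc(+1), stage="PND6"))
    for g in chosen[28:32]:
        effects.append(simdata.PlantedEffect(g, "KTZ", lfc(-1), stage="PND14"))
    for g in chosen[32:40]:
        s = lfc(rng.choice([-1, 1]))
        for d in ("medium", "high"):
            effects.append(simdata.PlantedEffect(g, "KTZ", s, stage="PND22", dose_level=d))
    # shared: affected by both compounds (downregulated, as for steroidogenic genes)
    for g in chosen[40:52]:
        s = lfc(-1)
        effects.append(simdata.PlantedEffect(g, "DES", s, stage="PND6"))
        effects.append(simdata.PlantedEffect(g, "KTZ", s, stage="PND6"))
    return effects


def simulate_bundle(config: PipelineConfig, out_dir) -> Path:
    """Generate a complete synthetic bundle plus ground truth on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sc_counts, cell_meta, atlas_truth = simdata.generate_atlas(seed=seed)
    effects = default_effects(atlas_truth, seed=seed + 1)
    omap, _ = simdata.generate_ortholog_map(
        [g for g in atlas_truth.theta.index], frac_one2one=0.8, frac_one2many=0.1, seed=seed + 2
    )
    rename = one2one_pairs(omap)
    bulk, sample_meta, cohort_truth = simdata.generate_bulk_cohort(
        atlas_truth, effects_spec=effects, seed=seed + 3, rename=rename
    )
    deg_targets: dict[str, list[str]] = {}
    for e in effects:
        deg_targets.setdefault(f"PLANTED_{e.compound}", []).append(rename.get(e.gene, e.gene))
    # terms tied to cluster markers: clusters with shifting proportions make
    # their markers development-responsive in the bulk mixture
    for cluster, mk in atlas_truth.markers.items():
        deg_targets[f"MARKERS_{cluster}"] = [rename.get(g, g) for g in mk]
    gsc, _ = simdata.generate_gene_sets(
        list(bulk.row_ids), n_terms=15, enriched_spec=deg_targets, seed=seed + 4
    )

    write_count_matrix(bulk, out / "bulk_counts.tsv")
    sample_meta.to_csv(out / "sample_metadata.tsv", sep="\t", index=False)
    write_count_matrix(sc_counts, out / "sc_counts.mtx", out / "sc_rows.txt", out / "sc_cols.txt")
    cell_meta.to_csv(out / "cell_metadata.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    write_ortholog_map(omap, out / "orthologs.tsv")
    write_gmt(gsc, out / "gene_sets.gmt")
    atlas_truth.to_json(out / "atlas_truth.json")
    cohort_truth.to_json(out / "cohort_truth.json")
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    logger.info("simulate: bundle written to %s", out)
    return out


def load_bundle(in_dir) -> Bundle:
    d = Path(in_dir)
    bulk = read_count_matrix(d / "bulk_counts.tsv", orientation="genes_by_samples")
    sample_meta = read_sample_metadata(d / "sample_metadata.tsv", bulk)
    sc_counts = read_count_matrix(
        d / "sc_counts.mtx", d / "sc_rows.txt", d / "sc_cols.txt", orientation="cells_by_genes"
    )
    cell_meta = read_cell_metadata(d / "cell_metadata.tsv")
    orthologs = read_ortholog_map(d / "orthologs.tsv")
    gene_sets = read_gmt(d / "gene_sets.gmt")
    return Bundle(bulk, sample_meta, sc_counts, cell_meta, orthologs, gene_sets)


def _exposure_contrasts(meta: pd.DataFrame) -> list[dge_mod.ContrastSpec]:
    out = []
    for compound in sorted(set(meta["compound"]) - {"control"}):
        for stage in STAGES:
            for dose in ("low", "medium", "high"):
                sel = (
                    (meta["compound"] == compound)
                    & (meta["stage"] == stage)
                    & (meta["dose_level"] == dose)
                )
                if sel.any():
                    out.append(
                        dge_mod.ContrastSpec("exposure", compound=compound, stage=stage, dose_level=dose)
                    )
    return out


def _lfc_profiles(
    results: dict[dge_mod.ContrastSpec, pd.DataFrame], compound: str, genes: list[str]
) -> pd.DataFrame:
    """Genes x (stage, dose) log2FC matrix for one compound; absent -> 0."""
    cols = {}
    for contrast, res in sorted(results.items(), key=lambda kv: kv[0].label()):
        if contrast.kind != "exposure" or contrast.compound != compound:
            continue
        name = f"{contrast.stage}_{contrast.dose_level}"
        cols[name] = res["log2fc"].reindex(genes).fillna(0.0)
    return pd.DataFrame(cols, index=genes)


def run_pipeline(config: PipelineConfig, in_dir, out_dir, stages=None) -> dict:
    """Execute the pipeline stages on a bundle directory.

    ``stages`` selects a subset (in the canonical order); None runs all.
    Returns a summary dictionary; outputs land in ``out_dir``.
    """
    wanted = list(STAGE_ORDER) if stages is None else [s for s in STAGE_ORDER if s in set(stages)]
    deps = {
        "qc": set(),
        "normalize": set(),
        "dge": {"normalize"},
        "patterns": {"normalize", "dge"},
        "enrich": {"normalize", "dge", "patterns"},
        "deconvolve": {"qc", "normalize"},
        "intersect": {"normalize", "dge"},
        "report": {"qc", "normalize", "dge", "patterns", "enrich", "deconvolve", "intersect"},
    }
    needed = set(wanted)
    for s in wanted:
        needed |= deps[s]
    needed.add("qc")  # the atlas is always QC'd before use
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}
    current = "load"
    try:
        bundle = load_bundle(in_dir)

        current = "qc"
        sc_counts, cell_meta, qc_report = preprocess.qc_cells(
            bundle.sc_counts,
            bundle.cell_meta,
            config.qc_min_umi,
            config.qc_min_genes,
            config.qc_max_pct_mito,
            config.mito_prefix,
        )
        if "qc" in wanted:
            (out / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
        summary["qc"] = qc_report

        current = "normalize"
        factors = preprocess.size_factors(bundle.bulk)
        expr = preprocess.normalize_log(bundle.bulk, factors)
        pca_coords, pca_fracs = preprocess.pca_summary(expr, n_components=2)
        if "normalize" in wanted:
            expr.to_frame().to_csv(out / "normalized.tsv", sep="\t", float_format=FLOAT_FMT)
            with open(out / "pca.tsv", "w") as fh:
                fh.write("# variance_fractions\t" + "\t".join(FLOAT_FMT % f for f in pca_fracs) + "\n")
                pca_coords.to_csv(fh, sep="\t", float_format=FLOAT_FMT)
        summary["pca_variance_fractions"] = [float(f) for f in pca_fracs]

        current = "dge"
        meta = bundle.sample_meta
        results: dict[dge_mod.ContrastSpec, pd.DataFrame] = {}
        sig = dge_mod.SignatureSet()
        contrast_list: list[dge_mod.ContrastSpec] = []
        dev_plate = (
            meta.loc[meta["compound"] == "control", "plate"].value_counts().idxmax()
        )
        if "dge" in needed:
            contrast_list = [dge_mod.ContrastSpec("development", plate=dev_plate)]
            contrast_list += _exposure_contrasts(meta)
            for contrast in contrast_list:
                results[contrast] = dge_mod.run_cascade(expr, meta, contrast, config)
            sig = dge_mod.build_signatures(results)
            if "dge" in wanted:
                table = pd.concat(
                    [r.rename_axis("gene").reset_index() for r in results.values()],
                    ignore_index=True,
                ).sort_values(["contrast", "gene"], ignore_index=True)
                table.to_csv(out / "deg_results.tsv", sep="\t", index=False,
                             float_format=FLOAT_FMT)
                sig.to_json(out / "signatures.json")
            summary["signature_counts"] = dge_mod.signature_summary(sig)

        current = "patterns"
        all_patterns: list[patterns_mod.ExpressionPattern] = []
        pattern_rows = []
        dev_genes: list[str] = []
        if "patterns" in needed:
            dev_res = results[contrast_list[0]]
            dev_genes = sorted(dev_res.index[dev_res["deg"]])
        if dev_genes:
            ctrl = meta[(meta["compound"] == "control") & (meta["plate"] == dev_plate)]
            profiles = pd.DataFrame(
                {
                    s: expr.to_frame()[ctrl.loc[ctrl["stage"] == s, "sample_id"]].mean(axis=1)
                    for s in STAGES
                }
            ).loc[dev_genes]
            k = min(config.kmeans_k["development"], len(dev_genes))
            pats = patterns_mod.kmeans_patterns(profiles, k, config.seed, "development")
            all_patterns += pats
        compound_z = {}
        compounds_present = (
            sorted(set(meta["compound"]) - {"control"}) if "patterns" in needed else []
        )
        for compound in compounds_present:
            genes = sorted(sig.union(compound))
            if not genes:
                continue
            prof = _lfc_profiles(results, compound, genes)
            compound_z[compound] = patterns_mod.zscore_profiles(prof)
            k = min(config.kmeans_k.get(compound, 4), len(genes))
            all_patterns += patterns_mod.kmeans_patterns(prof, k, config.seed, compound)
        shared_genes = set()
        if len(compound_z) == 2:
            (ca, za), (cb, zb) = sorted(compound_z.items())
            shared_genes = set(za.index) & set(zb.index)
            if shared_genes:
                shared_sorted = sorted(shared_genes)
                concat = pd.concat(
                    [za.loc[shared_sorted].add_prefix(f"{ca}_"),
                     zb.loc[shared_sorted].add_prefix(f"{cb}_")],
                    axis=1,
                )
                k = min(config.kmeans_k["shared"], len(shared_sorted))
                all_patterns += patterns_mod.kmeans_patterns(concat, k, config.seed, "shared")
        for p in all_patterns:
            for g in p.genes:
                pattern_rows.append({"gene": g, "analysis": p.analysis, "pattern_id": p.pattern_id})
        patterns_df = pd.DataFrame(pattern_rows, columns=["gene", "analysis", "pattern_id"])
        if "patterns" in wanted:
            patterns_df.sort_values(["analysis", "pattern_id", "gene"], ignore_index=True).to_csv(
                out / "patterns.tsv", sep="\t", index=False
            )
        summary["n_patterns"] = len(all_patterns)

        current = "enrich"
        if "enrich" in needed:
            detectable_universe = sorted(
                set().union(*(set(r.index[r["pass_detectable"]]) for r in results.values()))
            )
            enr = patterns_mod.enrich_patterns(
                all_patterns, detectable_universe, bundle.gene_sets,
                config.enrichment_min_genes, config.alpha,
            )
            if "enrich" in wanted:
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
            summary["n_enriched"] = int(enr["enriched"].sum()) if len(enr) else 0

        current = "deconvolve"
        if "deconvolve" in needed:
            reference = atlas_mod.build_reference(sc_counts, cell_meta)
            markers = atlas_mod.find_markers(
                sc_counts, cell_meta.set_index("cell_id").loc[sc_counts.row_ids, "cluster_id"],
                top_n=config.marker_top_n,
            )
            reference.variable_genes = atlas_mod.variable_genes(markers, config.variable_gene_cap)
            model = deconv_mod.CellTypeDeconvolver(
                nu=config.deconv_nu, tol=config.deconv_tol, max_iter=config.deconv_max_iter
            )
            model.fit(reference).align(bundle.bulk, bundle.orthologs)
            props = model.predict(bundle.bulk)
            broad = model.predict_broad(bundle.bulk)
            comparisons = deconv_mod.compare_proportions(broad, meta)
            if "deconvolve" in wanted:
                reference.theta.to_csv(out / "reference.tsv", sep="\t", float_format=FLOAT_FMT)
                reference.tau2.to_csv(out / "reference_var.tsv", sep="\t", float_format=FLOAT_FMT)
                reference.cell_size.rename("cell_size").to_csv(
                    out / "cellsizes.tsv", sep="\t", float_format=FLOAT_FMT
                )
                write_gmt(
                    atlas_mod.marker_sets(markers, reference.cluster_broad), out / "markers.gmt"
                )
                pd.concat([props, broad], axis=1).rename_axis("sample_id").to_csv(
                    out / "proportions.tsv", sep="\t", float_format=FLOAT_FMT
                )
                comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False,
                                   float_format=FLOAT_FMT)
            summary["deconv_mean_broad"] = {
                bt: float(broad[bt].mean()) for bt in broad.columns
            }

        current = "intersect"
        if "intersect" in needed:
            compounds = sig.compounds()
            shared_table = pd.DataFrame(columns=["gene", "class_a", "class_b"])
            if len(compounds) == 2:
                sig_a = SignatureView(sig, compounds[0])
                sig_b = SignatureView(sig, compounds[1])
                shared, shared_table = patterns_mod.intersect_signatures(sig_a, sig_b)
                summary["n_shared"] = len(shared)
            calls = patterns_mod.biomarker_candidates(sig)
            bio = patterns_mod.biomarker_table(calls)
            if "intersect" in wanted:
                shared_table.to_csv(out / "shared.tsv", sep="\t", index=False)
                bio.sort_values(["compound", "stage", "gene"], ignore_index=True).to_csv(
                    out / "biomarkers.tsv", sep="\t", index=False
                )
            summary["n_biomarker_calls"] = len(bio)

        current = "report"
        if "report" in wanted:
            (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    except OvotoxError as exc:
        logger.error("stage %s failed: %s [%s]", current, exc, exc.code)
        raise OvotoxError(f"stage {current}: {exc}", code=exc.code) from exc
    return summary


def SignatureView(sig: dge_mod.SignatureSet, compound: str) -> dge_mod.SignatureSet:
    """A SignatureSet restricted to one compound's calls."""
    view = dge_mod.SignatureSet()
    for (c, s, d), gd in sig.calls.items():
        if c == compound:
            view.add(c, s, d, gd)
    return view
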