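"""Three-filter differential-expression cascade with moderated statistics.

For every contrast, genes pass through (i) a detectability filter — the
global median of the comparison's normalized submatrix is the background
cutoff, and a gene passes when its mean within at least one comparison
group reaches it; (ii) a fold-change filter at 1.5; (iii) empirical-Bayes
moderated significance, BH-adjusted at 0.05. Statistics are computed only
on detectable genes, so the BH universe is the detectable set.

The moderated statistics squeeze each gene's residual variance s2_g
(pooled within groups, d_g residual df) toward a prior s0^2 with prior df
d0, both estimated from the ensemble of s2_g by matching the mean and
variance of log s2_g against digamma/trigamma expressions (the classic
moment estimator for a scaled inverse-chi-square prior). Pairwise
contrasts use a moderated t with d0 + d_g df; the three-stage development
contrast uses a moderated F with (k - 1, d0 + d_g) df.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from math import log2, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special as spsp
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .errors import MetadataError, PlateError, ValidationError
from .io import PipelineConfig
from .preprocess import ExpressionMatrix
from .stats import bh_adjust

logger = logging.getLogger("ovotox")


# ---------------------------------------------------------------------------
# filters


def detectable_filter(
    expr: pd.DataFrame, groups: dict[str, list[str]], quantile: float = 0.5
) -> tuple[set[str], float]:
    """Background-detectability filter.

    The cutoff is the ``quantile`` (default: median) of all entries of the
    submatrix over the comparison's samples; a gene passes iff its mean
    within at least one group is >= the cutoff.
    """
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValidationError("detectable_filter needs non-empty groups")
    samples = [s for v in groups.values() for s in v]
    sub = expr[samples]
    cutoff = float(np.quantile(sub.to_numpy(), quantile))
    passing: set[str] = set()
    for ids in groups.values():
        means = sub[ids].mean(axis=1)
        passing |= set(means.index[means >= cutoff])
    return passing, cutoff


def fold_change(expr: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.Series:
    """Per-gene log2 fold change: mean(group_b) - mean(group_a) on log2 scale."""
    if not group_a or not group_b:
        raise ValidationError("fold_change needs non-empty groups")
    if set(group_a) & set(group_b):
        raise ValidationError("fold_change groups overlap")
    return expr[group_b].mean(axis=1) - expr[group_a].mean(axis=1)


def max_pairwise_fold_change(expr: pd.DataFrame, groups: dict[str, list[str]]) -> pd.Series:
    """Largest absolute pairwise difference among group means (multi-group FC)."""
    means = pd.DataFrame({g: expr[ids].mean(axis=1) for g, ids in groups.items()})
    return means.max(axis=1) - means.min(axis=1)


# ---------------------------------------------------------------------------
# empirical Bayes


@dataclass
class EBayesParams:
    """Scaled inverse-chi-square prior on gene variances."""

    d0: float  # prior df, may be inf
    s0_sq: float  # prior variance

    def __post_init__(self):
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ValidationError("require d0 >= 0 and s0_sq > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs positive input")
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = spsp.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / spsp.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def fit_ebayes(s2, d_g) -> EBayesParams:
    """Estimate (d0, s0^2) from the ensemble of gene variances.

    Moment matching on z_g = log s2_g: with e_g = z_g - digamma(d_g/2) +
    log(d_g/2), the prior satisfies E[e] = log s0^2 + digamma(d0/2) -
    log(d0/2) and Var[e] = trigamma(d_g/2) + trigamma(d0/2). The excess of
    the empirical variance of e over mean trigamma(d_g/2) yields d0 by
    trigamma inversion (d0 = +inf when there is no excess dispersion),
    then s0^2 in closed form. Genes with s2 <= 0 are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d_g, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d >= 1)
    if not ok.any():
        raise ValidationError("no positive gene variances to fit")
    if ok.sum() < 10:
        raise ValidationError("fit_ebayes needs at least 10 genes with positive variance")
    s2, d = s2[ok], d[ok]
    e = np.log(s2) - spsp.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(np.mean(spsp.polygamma(1, d / 2.0)))
    if excess <= 0:
        # no excess dispersion: point-mass prior, plain moment estimate
        return EBayesParams(d0=float("inf"), s0_sq=float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + spsp.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def squeeze_var(s2: np.ndarray, d_g, params: EBayesParams) -> np.ndarray:
    """Posterior (moderated) variance s~2 = (d0 s0^2 + d_g s2) / (d0 + d_g)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    return (params.d0 * params.s0_sq + d_g * s2) / (params.d0 + d_g)


def _group_stats(expr: pd.DataFrame, groups: dict[str, list[str]]):
    """Group means, pooled within-group variance and residual df."""
    means = pd.DataFrame({g: expr[ids].mean(axis=1) for g, ids in groups.items()})
    n_total = sum(len(ids) for ids in groups.values())
    k = len(groups)
    d_g = n_total - k
    if d_g < 1:
        raise ValidationError("residual df must be >= 1")
    ss = np.zeros(len(expr.index))
    for g, ids in groups.items():
        sub = expr[ids].to_numpy()
        ss += ((sub - means[g].to_numpy()[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_g
    return means, s2, d_g


def moderated_stats(
    expr: pd.DataFrame, groups: dict[str, list[str]], params: EBayesParams
) -> pd.DataFrame:
    """Moderated t (2 groups) or moderated F (k groups) with raw p values.

    At d0 = 0 the moderated t is exactly the ordinary pooled two-sample t;
    at d0 = +inf every gene's denominator uses s0^2.
    """
    means, s2, d_g = _group_stats(expr, groups)
    s2_mod = squeeze_var(s2, d_g, params)
    df_total = params.d0 + d_g  # may be inf
    k = len(groups)
    out = pd.DataFrame(index=expr.index)
    for g in means:
        out[f"mean_{g}"] = means[g]
    out["s2"] = s2
    out["df_residual"] = d_g
    out["s2_moderated"] = s2_mod
    zero = s2_mod <= 0
    if zero.any():
        logger.warning("%d genes with zero moderated variance; p set to 0", int(zero.sum()))
    if k == 2:
        ga, gb = list(groups)
        lfc = means[gb] - means[ga]
        c = sqrt(1.0 / len(groups[ga]) + 1.0 / len(groups[gb]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc.to_numpy() / (np.sqrt(s2_mod) * c)
        t = np.where(zero, np.sign(lfc) * np.inf, t)
        if np.isinf(df_total):
            p = 2.0 * sps.norm.sf(np.abs(t))
        else:
            p = 2.0 * sps.t.sf(np.abs(t), df_total)
        p = np.where(zero, 0.0, p)
        out["log2fc"] = lfc
        out["stat"] = t
        out["p"] = p
    else:
        grand = np.zeros(len(expr.index))
        n_total = sum(len(ids) for ids in groups.values())
        for g, ids in groups.items():
            grand += means[g].to_numpy() * len(ids)
        grand /= n_total
        ms_between = np.zeros(len(expr.index))
        for g, ids in groups.items():
            ms_between += len(ids) * (means[g].to_numpy() - grand) ** 2
        ms_between /= k - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ms_between / s2_mod
        f = np.where(zero, np.inf, f)
        if np.isinf(df_total):
            p = sps.chi2.sf((k - 1) * f, k - 1)
        else:
            p = sps.f.sf(f, k - 1, df_total)
        p = np.where(zero, 0.0, p)
        out["stat"] = f
        out["p"] = p
    return out


# ---------------------------------------------------------------------------
# cascade


@dataclass(frozen=True)
class ContrastSpec:
    """One statistical comparison.

    ``kind='development'``: the 3-stage comparison of control samples
    within one plate. ``kind='exposure'``: one dose of one compound vs its
    stage-matched controls on the compound's plate.
    """

    kind: str
    plate: str | None = None
    compound: str | None = None
    stage: str | None = None
    dose_level: str | None = None

    def label(self) -> str:
        if self.kind == "development":
            return f"development:{self.plate}"
        return f"{self.compound}:{self.stage}:{self.dose_level}"


class CascadeDE(BaseEstimator):
    """Three-filter differential-expression cascade as an estimator.

    Parameters mirror the pipeline configuration: ``detectable_quantile``
    (cutoff quantile of the comparison submatrix), ``fc_cutoff`` (linear
    fold change, filter at |log2FC| >= log2(fc_cutoff)), ``alpha``
    (BH-adjusted significance level).

    ``fit(X, y)`` takes a genes x samples log2-expression DataFrame and a
    group label per sample. Fitted attributes: ``results_`` (per-gene
    table with all statistics and pass flags), ``cutoff_``, ``ebayes_``,
    ``deg_genes_``.
    """

    def __init__(self, detectable_quantile: float = 0.5, fc_cutoff: float = 1.5, alpha: float = 0.05):
        self.detectable_quantile = detectable_quantile
        self.fc_cutoff = fc_cutoff
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y):
        expr = pd.DataFrame(X)
        labels = pd.Series(np.asarray(y), index=expr.columns)
        groups = {g: list(labels.index[labels == g]) for g in pd.unique(labels)}
        if any(len(v) < 2 for v in groups.values()):
            raise ValidationError("every comparison group needs >= 2 replicates")
        detectable, cutoff = detectable_filter(expr, groups, self.detectable_quantile)
        self.cutoff_ = cutoff
        det_genes = [g for g in expr.index if g in detectable]
        lfc_threshold = log2(self.fc_cutoff)

        res = pd.DataFrame(index=expr.index)
        res["pass_detectable"] = res.index.isin(detectable)

        det_expr = expr.loc[det_genes]
        self.ebayes_ = None
        if det_genes:
            _, s2, d_g = _group_stats(det_expr, groups)
            self.ebayes_ = fit_ebayes(s2, d_g)
            stats = moderated_stats(det_expr, groups, self.ebayes_)
            stats["adj_p"] = bh_adjust(stats["p"].to_numpy())
            if len(groups) == 2:
                fc_abs = stats["log2fc"].abs()
            else:
                fc_abs = max_pairwise_fold_change(det_expr, groups)
                stats["log2fc_max"] = fc_abs
            stats["pass_fc"] = fc_abs >= lfc_threshold
            stats["pass_stat"] = stats["adj_p"] <= self.alpha
            res = res.join(stats)
        for col in ("pass_fc", "pass_stat"):
            if col not in res:
                res[col] = False
            res[col] = res[col].map(lambda v: bool(v) if pd.notna(v) else False)
        res["deg"] = res["pass_detectable"] & res["pass_fc"] & res["pass_stat"]
        if "log2fc" in res:
            res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
            res.loc[~res["deg"], "direction"] = ""
        self.results_ = res
        self.deg_genes_ = list(res.index[res["deg"]])
        return self

    def fit_transform(self, X, y):
        """Fit and return the expression restricted to DEGs."""
        self.fit(X, y)
        return pd.DataFrame(X).loc[self.deg_genes_]


def run_cascade(
    expr: ExpressionMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: ContrastSpec,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the cascade for one contrast; returns the per-gene result table.

    Refuses contrasts whose samples span more than one plate (batch
    confound), with error code E_PLATE.
    """
    config = config or PipelineConfig()
    expr_df = expr.to_frame() if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    meta = metadata.set_index("sample_id")
    if contrast.kind == "development":
        sel = (meta["compound"] == "control") & (meta["plate"] == contrast.plate)
        sub = meta[sel]
        labels = sub["stage"]
    elif contrast.kind == "exposure":
        plates = meta.loc[meta["compound"] == contrast.compound, "plate"].unique()
        if len(plates) == 0:
            raise MetadataError(f"no samples for compound {contrast.compound!r}")
        if len(plates) > 1:
            raise PlateError(f"compound {contrast.compound!r} spans plates {sorted(plates)}")
        plate = plates[0]
        sel = (meta["stage"] == contrast.stage) & (meta["plate"] == plate) & (
            ((meta["compound"] == "control"))
            | ((meta["compound"] == contrast.compound) & (meta["dose_level"] == contrast.dose_level))
        )
        sub = meta[sel]
        labels = np.where(sub["compound"] == "control", "control", "exposed")
        labels = pd.Series(labels, index=sub.index)
    else:
        raise ValidationError(f"unknown contrast kind {contrast.kind!r}")
    if sub["plate"].nunique() > 1:
        raise PlateError(f"contrast {contrast.label()} crosses plates")
    samples = [s for s in sub.index if s in expr_df.columns]
    if len(samples) != len(sub):
        raise MetadataError("metadata samples missing from expression matrix")
    # fixed group order: control first so log2FC is exposed-vs-control
    if contrast.kind == "exposure":
        order = ["control", "exposed"]
        labels = labels[samples]
        samples = sorted(samples, key=lambda s: order.index(labels[s]))
    model = CascadeDE(config.detectable_quantile, config.fc_cutoff, config.alpha)
    model.fit(expr_df[samples], [labels[s] for s in samples])
    res = model.results_
    res.insert(0, "contrast", contrast.label())
    res.attrs["cutoff"] = model.cutoff_
    res.attrs["ebayes"] = model.ebayes_
    return res


# ---------------------------------------------------------------------------
# signatures


@dataclass
class SignatureSet:
    """Directional DEG calls indexed by (compound, stage, dose_level).

    Development DEGs (the 3-stage contrast has no single direction) are
    kept in the ``development`` set.
    """

    calls: dict[tuple[str, str, str], dict[str, str]] = field(default_factory=dict)
    development: set[str] = field(default_factory=set)

    def add(self, compound: str, stage: str, dose_level: str, gene_directions: dict[str, str]):
        bad = {d for d in gene_directions.values()} - {"up", "down"}
        if bad:
            raise ValidationError(f"unknown directions: {sorted(bad)}")
        self.calls[(compound, stage, dose_level)] = dict(gene_directions)

    def compounds(self) -> list[str]:
        return sorted({c for c, _, _ in self.calls})

    def union(self, compound: str) -> set[str]:
        return {
            g for (c, _, _), gd in self.calls.items() if c == compound for g in gd
        }

    def genes_by(self, compound: str | None = None, stage: str | None = None,
                 dose_level: str | None = None) -> set[str]:
        out: set[str] = set()
        for (c, s, d), gd in self.calls.items():
            if (compound is None or c == compound) and (stage is None or s == stage) \
                    and (dose_level is None or d == dose_level):
                out |= set(gd)
        return out

    def direction_class(self, compound: str, gene: str) -> str:
        """'over' if all significant calls are up, 'under' if all down, else 'mixed'."""
        dirs = {
            gd[gene]
            for (c, _, _), gd in self.calls.items()
            if c == compound and gene in gd
        }
        if dirs == {"up"}:
            return "over"
        if dirs == {"down"}:
            return "under"
        return "mixed"

    def all_genes(self) -> set[str]:
        out = set(self.development)
        for gd in self.calls.values():
            out |= set(gd)
        return out

    def counts(self) -> pd.DataFrame:
        rows = []
        for (c, s, d), gd in sorted(self.calls.items()):
            up = sum(1 for v in gd.values() if v == "up")
            down = len(gd) - up
            rows.append({"compound": c, "stage": s, "dose_level": d,
                         "n_up": up, "n_down": down, "n_total": len(gd)})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "development": sorted(self.development),
            "calls": [
                {"compound": c, "stage": s, "dose_level": d,
                 "genes": {g: gd[g] for g in sorted(gd)}}
                for (c, s, d), gd in sorted(self.calls.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SignatureSet":
        data = json.loads(Path(path).read_text())
        sig = cls(development=set(data.get("development", [])))
        for rec in data.get("calls", []):
            sig.add(rec["compound"], rec["stage"], rec["dose_level"], rec["genes"])
        return sig

    @classmethod
    def from_table(cls, path) -> "SignatureSet":
        """Parse a deposited-style signature table.

        Expected TSV columns: gene, compound, stage, dose_level, direction
        (direction in {up, down}); compound 'development' rows carry the
        stage-course DEGs and may leave direction empty.
        """
        df = pd.read_csv(path, sep="\t")
        needed = {"gene", "compound", "stage", "dose_level", "direction"}
        missing = needed - set(df.columns)
        if missing:
            raise MetadataError(f"signature table missing columns: {sorted(missing)}")
        sig = cls()
        dev = df[df["compound"] == "development"]
        sig.development = set(dev["gene"])
        for (c, s, d), sub in df[df["compound"] != "development"].groupby(
            ["compound", "stage", "dose_level"]
        ):
            sig.add(c, s, d, dict(zip(sub["gene"], sub["direction"])))
        return sig


def build_signatures(results: dict[ContrastSpec, pd.DataFrame]) -> SignatureSet:
    """Collect directional DEG calls from cascade results into a SignatureSet."""
    sig = SignatureSet()
    for contrast, res in results.items():
        degs = res[res["deg"]]
        if contrast.kind == "development":
            sig.development |= set(degs.index)
        else:
            sig.add(
                contrast.compound,
                contrast.stage,
                contrast.dose_level,
                dict(zip(degs.index, degs["direction"])),
            )
    return sig


def signature_summary(sig: SignatureSet) -> dict[str, int]:
    """The headline signature arithmetic: totals, per-dose and per-stage splits."""
    out: dict[str, int] = {
        "total": len(sig.all_genes()),
        "development": len(sig.development),
    }
    unions = {c: sig.union(c) for c in sig.compounds()}
    for c, genes in unions.items():
        out[c] = len(genes)
        for d in ("low", "medium", "high"):
            out[f"{c}_{d}"] = len(sig.genes_by(compound=c, dose_level=d))
        for s in ("PND6", "PND14", "PND22"):
            out[f"{c}_{s}"] = len(sig.genes_by(compound=c, stage=s))
    comps = sorted(unions)
    if len(comps) == 2:
        out["shared"] = len(unions[comps[0]] & unions[comps[1]])
    return out
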