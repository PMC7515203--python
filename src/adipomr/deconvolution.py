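"""Cell-type deconvolution of bulk RNA-seq from a single-nucleus reference.

The reference is built from multi-subject single-nucleus counts: nuclei with
<300 expressed genes are dropped, then genes expressed in <3 nuclei; signature
genes are one-vs-rest Wilcoxon markers; per-subject pseudo-bulk profiles give
cell-type mean relative expression with cross-subject variances.  Because
nuclear libraries over-represent pre-mRNA, genes whose mean log expression
diverges between bulk and pseudo-bulk are removed by a chi-square concordance
filter (z-scored log difference, keep z^2 <= 1) before estimating proportions
with an iteratively re-weighted nonnegative least squares in the style of
multi-subject deconvolution (MuSiC): genes with high cross-subject variance
or large residuals are down-weighted, and the cell-size-scaled coefficients
are converted to cell-count proportions.  Leave-one-out validation rebuilds
the reference without the target subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.optimize import nnls

MIN_GENES_PER_CELL = 300
MIN_CELLS_PER_GENE = 3


class DeconvolutionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reference QC and ground-truth proportions
# ---------------------------------------------------------------------------

def qc_reference(adata: AnnData, min_genes: int = MIN_GENES_PER_CELL,
                 min_cells: int = MIN_CELLS_PER_GENE) -> tuple[AnnData, dict]:
    """Apply nucleus- then gene-level QC; returns (filtered, report).

    Cells with fewer than ``min_genes`` expressed genes are removed first;
    genes expressed in fewer than ``min_cells`` of the remaining cells are
    removed second (the order matters at the boundaries).
    """
    for col in ("subject", "cluster"):
        if col not in adata.obs.columns:
            raise DeconvolutionError(f"cell metadata missing column {col!r}")
    X = np.asarray(adata.X)
    genes_per_cell = (X > 0).sum(axis=1)
    keep_cells = genes_per_cell >= min_genes
    X2 = X[keep_cells]
    cells_per_gene = (X2 > 0).sum(axis=0)
    keep_genes = cells_per_gene >= min_cells
    out = adata[keep_cells, keep_genes].copy()
    if out.n_obs == 0 or out.n_vars == 0:
        raise DeconvolutionError("QC removed everything: no cells or genes remain")
    report = {
        "cells_in": int(adata.n_obs),
        "cells_removed": int((~keep_cells).sum()),
        "genes_in": int(adata.n_vars),
        "genes_removed": int((~keep_genes).sum()),
        "min_genes_per_cell": min_genes,
        "min_cells_per_gene": min_cells,
    }
    return out, report


def true_proportions(cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-subject cell-type label frequencies (rows sum to 1)."""
    props = (
        cell_meta.groupby("subject", observed=True)["cluster"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    props.columns.name = None
    return props


# ---------------------------------------------------------------------------
# Signature genes and reference profiles
# ---------------------------------------------------------------------------

def select_signature_genes(
    adata: AnnData,
    min_logfc: float = 1.0,
    max_p: float = 0.05,
    min_cells_per_cluster: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker genes per cluster.

    Expression is library-normalized and log1p-transformed; genes with
    Benjamini-Hochberg q < ``max_p`` and log2 fold-change > ``min_logfc`` in
    a focal cluster are its signature genes.  A gene passing in several
    clusters is attributed to the cluster with the largest fold-change.
    Returns a table with columns ``gene``, ``cluster``, ``log2fc``, ``qval``.
    """
    import scanpy as sc

    counts = adata.obs["cluster"].value_counts()
    small = counts[counts < min_cells_per_cluster]
    work = adata
    if len(small):
        warnings.warn(
            f"clusters with <{min_cells_per_cluster} cells excluded from "
            f"signature selection: {list(small.index)}",
            stacklevel=2,
        )
        work = adata[~adata.obs["cluster"].isin(small.index)].copy()
    if work.obs["cluster"].nunique() < 2:
        raise DeconvolutionError("need at least 2 clusters for marker selection")
    tmp = work.copy()
    tmp.obs["cluster"] = tmp.obs["cluster"].astype(str).astype("category")
    sc.pp.normalize_total(tmp, target_sum=1e4)
    sc.pp.log1p(tmp)
    sc.tl.rank_genes_groups(tmp, "cluster", method="wilcoxon", tie_correct=False)
    frames = []
    for grp in tmp.obs["cluster"].cat.categories:
        df = sc.get.rank_genes_groups_df(tmp, group=str(grp))
        df = df.rename(columns={"names": "gene", "logfoldchanges": "log2fc",
                                "pvals_adj": "qval"})
        df["cluster"] = str(grp)
        frames.append(df[["gene", "cluster", "log2fc", "qval"]])
    allres = pd.concat(frames, ignore_index=True)
    hits = allres[(allres["qval"] < max_p) & (allres["log2fc"] > min_logfc)]
    if hits.empty:
        return hits.reset_index(drop=True)
    # attribute each gene to its strongest cluster
    best = hits.sort_values("log2fc", ascending=False).drop_duplicates("gene")
    return best.sort_values(["cluster", "gene"]).reset_index(drop=True)


@dataclass
class ReferenceProfiles:
    """Per-cell-type mean relative expression with cross-subject variance.

    ``mean_rel``/``var_rel`` are cell-type x gene DataFrames of relative
    expression (each subject's within-type profile normalized to sum 1);
    ``cell_size`` is the mean per-cell library size of each type (the total
    RNA content used to convert RNA-fraction coefficients to cell counts).
    """

    mean_rel: pd.DataFrame
    var_rel: pd.DataFrame
    cell_size: pd.Series
    subjects: list[str] = field(default_factory=list)

    @property
    def celltypes(self) -> list[str]:
        return list(self.mean_rel.index)

    @property
    def genes(self) -> pd.Index:
        return self.mean_rel.columns


def build_pseudobulk(adata: AnnData) -> tuple[pd.DataFrame, ReferenceProfiles]:
    """Per-subject pseudo-bulk plus the cell-type reference profiles.

    Pseudo-bulk sums each subject's counts and scales to counts-per-million
    (aggregate-read semantics, matching a bulk library).  Profiles average
    the subject-level within-type relative expression across subjects.
    """
    X = np.asarray(adata.X, dtype=float)
    genes = adata.var_names
    subjects = sorted(adata.obs["subject"].unique())
    celltypes = sorted(adata.obs["cluster"].unique())

    pb = {}
    for s in subjects:
        total = X[(adata.obs["subject"] == s).to_numpy()].sum(axis=0)
        pb[s] = total / total.sum() * 1e6
    pseudobulk = pd.DataFrame(pb, index=genes).T

    rel = np.full((len(subjects), len(celltypes), len(genes)), np.nan)
    sizes = np.full((len(subjects), len(celltypes)), np.nan)
    subj_arr = adata.obs["subject"].to_numpy()
    clus_arr = adata.obs["cluster"].to_numpy()
    for i, s in enumerate(subjects):
        for k, ct in enumerate(celltypes):
            mask = (subj_arr == s) & (clus_arr == ct)
            if not mask.any():
                continue
            block = X[mask]
            total = block.sum()
            if total == 0:
                continue
            rel[i, k] = block.sum(axis=0) / total
            sizes[i, k] = block.sum(axis=1).mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_rel = np.nanmean(rel, axis=0)
        var_rel = np.nanvar(rel, axis=0, ddof=1)
        cell_size = np.nanmean(sizes, axis=0)
    var_rel = np.nan_to_num(var_rel)
    if np.isnan(mean_rel).any() or np.isnan(cell_size).any():
        empty = [celltypes[k] for k in np.flatnonzero(np.isnan(cell_size))]
        raise DeconvolutionError(f"cell types absent from every subject: {empty}")
    profiles = ReferenceProfiles(
        mean_rel=pd.DataFrame(mean_rel, index=celltypes, columns=genes),
        var_rel=pd.DataFrame(var_rel, index=celltypes, columns=genes),
        cell_size=pd.Series(cell_size, index=celltypes, name="cell_size"),
        subjects=subjects,
    )
    return pseudobulk, profiles


# ---------------------------------------------------------------------------
# Bulk / pseudo-bulk concordance filter
# ---------------------------------------------------------------------------

def concordance_filter(
    bulk_expr: pd.DataFrame, pseudobulk_expr: pd.DataFrame, max_chi2: float = 1.0
) -> tuple[pd.Index, pd.DataFrame]:
    """Keep genes whose bulk and pseudo-bulk mean log expression agree.

    d_g = mean_samples log(bulk+1) - mean_subjects log(pseudo+1) is z-scored
    across genes; genes with chi-square statistic z^2 <= ``max_chi2`` are
    kept.  ``bulk_expr`` is gene x sample, ``pseudobulk_expr`` subject x gene
    (as returned by :func:`build_pseudobulk`).  Returns (kept gene index,
    per-gene statistic table).
    """
    shared = bulk_expr.index.intersection(pseudobulk_expr.columns)
    if shared.empty:
        raise DeconvolutionError("no shared genes between bulk and pseudo-bulk")
    d = (
        np.log1p(bulk_expr.loc[shared]).mean(axis=1)
        - np.log1p(pseudobulk_expr[shared]).mean(axis=0)
    )
    sd = d.std(ddof=1)
    table = pd.DataFrame({"d": d})
    if sd == 0 or np.isnan(sd):
        warnings.warn(
            "degenerate concordance filter (zero spread in log differences); "
            "keeping all genes",
            stacklevel=2,
        )
        table["z"] = 0.0
        table["chi2"] = 0.0
        table["kept"] = True
        return shared, table
    z = (d - d.mean()) / sd
    table["z"] = z
    table["chi2"] = z**2
    table["kept"] = table["chi2"] <= max_chi2
    return shared[table["kept"].to_numpy()], table


# ---------------------------------------------------------------------------
# Weighted NNLS deconvolution
# ---------------------------------------------------------------------------

@dataclass
class DeconvOptions:
    tol: float = 1e-6
    max_iter: int = 300
    weight_floor_scale: float = 1e-6  # variance floor, relative to the median
    weight_cap: float = 100.0  # leverage cap: max weight / median weight
    condition_limit: float = 1e8


@dataclass
class DeconvResult:
    proportions: pd.Series
    converged: bool
    n_iter: int
    identifiable: bool


def wnnls_deconvolve(
    bulk_sample: pd.Series,
    profiles: ReferenceProfiles,
    genes: pd.Index | list[str] | None = None,
    options: DeconvOptions | None = None,
) -> DeconvResult:
    """Estimate cell-type proportions of one bulk sample.

    Iteratively re-weighted NNLS on relative expression: an initial
    unweighted NNLS of the bulk profile on the cell-size-scaled reference is
    refined by per-gene weights 1/(floor + residual^2 + propagated
    cross-subject variance), capped to bound leverage, until the proportion
    vector moves less than ``tol`` in the max norm.  Coefficients estimate
    RNA fractions p_k*S_k; dividing by the cell sizes S_k and renormalizing
    yields cell-count proportions.
    """
    opts = options or DeconvOptions()
    if genes is None:
        genes = profiles.genes
    genes = pd.Index(genes)
    if genes.empty:
        raise DeconvolutionError("empty gene list")
    missing = genes.difference(profiles.genes)
    if len(missing):
        raise DeconvolutionError(f"profiles do not cover genes: {list(missing[:5])}...")
    y = bulk_sample.reindex(genes).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise DeconvolutionError("bulk sample missing some requested genes")
    total = y.sum()
    if total <= 0:
        raise DeconvolutionError("all-zero bulk sample")
    y = y / total  # scale invariance to bulk library size

    # Regress bulk relative expression on the cell-type relative profiles;
    # the coefficient of type k estimates its RNA fraction p_k*S_k (up to a
    # common scale), converted to cell-count proportions by dividing by the
    # per-type cell size S_k.
    M = profiles.mean_rel[genes].to_numpy().T  # genes x celltypes
    V = profiles.var_rel[genes].to_numpy().T
    sizes = profiles.cell_size.to_numpy()
    D = M

    # Identifiability: (near-)duplicate profiles make the split arbitrary.
    col_norm = np.linalg.norm(D, axis=0)
    Dn = D / np.where(col_norm > 0, col_norm, 1.0)
    cond = np.linalg.cond(Dn)
    identifiable = bool(cond < opts.condition_limit)
    if not identifiable:
        warnings.warn(
            f"reference profiles are near-collinear (condition number {cond:.3g}); "
            "proportions are not identifiable",
            stacklevel=2,
        )

    coef, _ = nnls(D, y)
    p_prev = _to_proportions(coef, sizes, profiles.celltypes)
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        resid = y - D @ coef
        var_prop = (V * coef[None, :] ** 2).sum(axis=1)
        denom = resid**2 + var_prop
        positive = denom[denom > 0]
        floor = opts.weight_floor_scale * (np.median(positive) if len(positive) else 1.0)
        floor = max(floor, 1e-300)
        w = 1.0 / (denom + floor)
        w = np.minimum(w, opts.weight_cap * np.median(w))
        sw = np.sqrt(w)
        coef, _ = nnls(D * sw[:, None], y * sw)
        p_new = _to_proportions(coef, sizes, profiles.celltypes)
        if np.max(np.abs(p_new - p_prev)) < opts.tol:
            converged = True
            p_prev = p_new
            break
        p_prev = p_new
    if not converged:
        warnings.warn("weighted NNLS did not converge; returning last iterate",
                      stacklevel=2)
    return DeconvResult(
        proportions=p_prev, converged=converged, n_iter=it, identifiable=identifiable
    )


def _to_proportions(coef: np.ndarray, sizes: np.ndarray, celltypes) -> pd.Series:
    p = coef / sizes
    s = p.sum()
    if s <= 0:
        p = np.full_like(p, 1.0 / len(p))
    else:
        p = p / s
    return pd.Series(p, index=celltypes)


def deconvolve_samples(
    bulk_tpm: pd.DataFrame,
    profiles: ReferenceProfiles,
    genes: pd.Index | list[str] | None = None,
    options: DeconvOptions | None = None,
) -> pd.DataFrame:
    """Deconvolve every bulk sample (columns of ``bulk_tpm``)."""
    rows = {
        s: wnnls_deconvolve(bulk_tpm[s], profiles, genes, options).proportions
        for s in bulk_tpm.columns
    }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Leave-one-out validation and proportion adjustment
# ---------------------------------------------------------------------------

@dataclass
class LOOResult:
    estimated: pd.DataFrame
    true: pd.DataFrame
    per_celltype: pd.DataFrame  # columns: pearson_r, rmse
    overall_r: float
    overall_rmse: float


def loo_validate(
    adata: AnnData,
    bulk_tpm: pd.DataFrame,
    sample_of_subject: dict[str, str] | None = None,
    min_logfc: float = 1.0,
    max_p: float = 0.05,
    use_concordance_filter: bool = True,
    use_signature_genes: bool = True,
    options: DeconvOptions | None = None,
) -> LOOResult:
    """Leave-one-subject-out validation of the deconvolution pipeline.

    For each subject the reference (signature genes, profiles, concordance
    filter) is rebuilt from the other subjects only, the subject's bulk
    sample is deconvolved, and the estimate is compared to the subject's
    true nucleus label frequencies.  Setting both ``use_signature_genes``
    and ``use_concordance_filter`` to False deconvolves on every shared
    gene, the condition under which nucleus-retained (discordant)
    transcripts bias the estimates.
    """
    subjects = sorted(adata.obs["subject"].unique())
    if len(subjects) < 3:
        raise DeconvolutionError("leave-one-out needs at least 3 subjects")
    if sample_of_subject is None:
        sample_of_subject = _match_samples(subjects, bulk_tpm.columns)
    truth = true_proportions(adata.obs)
    est_rows = {}
    for subj in subjects:
        ref = adata[adata.obs["subject"] != subj].copy()
        pseudo, profiles = build_pseudobulk(ref)
        if use_signature_genes:
            sig = select_signature_genes(ref, min_logfc=min_logfc, max_p=max_p)
            if sig.empty:
                raise DeconvolutionError(f"fold {subj}: no signature genes selected")
            genes = pd.Index(sig["gene"].unique())
        else:
            genes = pd.Index(ref.var_names)
        if use_concordance_filter:
            kept, _ = concordance_filter(bulk_tpm, pseudo)
            genes = genes.intersection(kept)
        genes = genes.intersection(bulk_tpm.index)
        if genes.empty:
            raise DeconvolutionError(
                f"fold {subj}: every candidate gene was filtered out"
            )
        res = wnnls_deconvolve(bulk_tpm[sample_of_subject[subj]], profiles,
                               genes, options)
        est_rows[subj] = res.proportions
    estimated = pd.DataFrame(est_rows).T.reindex(columns=truth.columns).fillna(0.0)
    true_df = truth.loc[estimated.index]
    per_ct = {}
    for ct in truth.columns:
        e, t = estimated[ct].to_numpy(), true_df[ct].to_numpy()
        r = np.corrcoef(e, t)[0, 1] if np.std(e) > 0 and np.std(t) > 0 else np.nan
        per_ct[ct] = {"pearson_r": r, "rmse": float(np.sqrt(np.mean((e - t) ** 2)))}
    e_all = estimated.to_numpy().ravel()
    t_all = true_df.to_numpy().ravel()
    return LOOResult(
        estimated=estimated,
        true=true_df,
        per_celltype=pd.DataFrame(per_ct).T,
        overall_r=float(np.corrcoef(e_all, t_all)[0, 1]),
        overall_rmse=float(np.sqrt(np.mean((e_all - t_all) ** 2))),
    )


def _match_samples(subjects, sample_names) -> dict[str, str]:
    mapping = {}
    for subj in subjects:
        hits = [s for s in sample_names if s == subj or s.startswith(f"{subj}_")]
        if len(hits) != 1:
            raise DeconvolutionError(
                f"cannot match a unique bulk sample for subject {subj!r}: {hits}"
            )
        mapping[subj] = hits[0]
    return mapping


def adjust_proportions(props: pd.DataFrame, technical: pd.DataFrame) -> pd.DataFrame:
    """Residualize each cell-type proportion on technical factors.

    Residuals are re-centred at the original column means; adjusted values
    may leave [0, 1] and are intended for association testing only.
    """
    from .expression import residualize

    if len(props) != len(technical):
        raise DeconvolutionError("proportions and technical table must align")
    out = {}
    for ct in props.columns:
        out[ct] = residualize(props[ct].to_numpy(), technical) + props[ct].mean()
    return pd.DataFrame(out, index=props.index)
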