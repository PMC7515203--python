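"""Synthetic data with the statistical structure the downstream analyses assume.

Four generators provide ground truth for every pipeline stage:

* :func:`simulate_mr_summary` — per-variant two-sample GWAS summary
  statistics with a linear instrument -> exposure -> outcome structure and
  optional horizontal pleiotropy (balanced or directional).
* :func:`simulate_sc_reference` — a single-nucleus counts matrix over
  subjects and cell types with marker genes and a pre-mRNA-discordant gene
  subset whose nuclear expression is inflated relative to bulk (the
  MALAT1-like mismatch between nuclear and cytoplasmic transcripts).
* :func:`simulate_bulk_mixtures` — bulk RNA-seq samples as Dirichlet
  mixtures of the subject-specific cell-type profiles (discordant inflation
  absent on the bulk side).
* :func:`simulate_cohort` — per-individual phenotypes in which a latent
  insulin-sensitivity (Matsuda) index is a linear function of body fat
  percent, mitochondrial (MT) expression, age and cell-type proportions,
  with noise calibrated analytically to a target total R^2; HbA1c defines
  prediabetes (5.7-6.4%) and diabetes (>6.4%), and RNA-seq technical factors
  are confounded with the MT read fraction.

Every generator takes an explicit seed, draws from one local
``numpy.random.Generator``, and returns a truth record alongside the data;
recovery tests fit the data without reading the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .mr import LDMatrix

CELL_TYPE_NAMES = [
    "adipocytes", "preadipocytes", "macrophages", "dendritic",
    "fibroblasts", "endothelial", "smooth_muscle", "tnk_cells",
]

#: Baseline adipose composition: adipocytes ~44% of nuclei, the rest spread
#: over stromal, vascular and immune types.
ADIPOSE_BASE_PROPORTIONS = np.array([0.44, 0.15, 0.10, 0.08, 0.07, 0.06, 0.05, 0.05])

N_MT_GENES = 37  # protein-coding + rRNA + tRNA genes encoded on the MT genome


def _validate_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# MR summary statistics
# ---------------------------------------------------------------------------

@dataclass
class MRSimConfig:
    """Generative model for two-sample MR summary statistics.

    Exposure betas are drawn N(0, exposure_beta_sd^2); the outcome beta of
    variant i is ``causal_effect * beta_exp_i`` plus, for a random
    ``pleiotropy_frac`` subset, a pleiotropic effect (mean zero when
    ``balanced``, half-normal — all same sign — when ``directional``), plus
    N(0, outcome_se^2) sampling noise.  Defaults mirror a large-biobank
    exposure GWAS (a few hundred thousand samples: per-variant SEs of a few
    thousandths on an inverse-normal scale) instrumenting a smaller outcome
    GWAS.
    """

    n_variants: int = 100
    causal_effect: float = 0.0
    exposure_beta_sd: float = 0.05
    exposure_se: float = 0.0025
    outcome_se: float = 0.01
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.05
    pleiotropy_mode: str = "balanced"
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 2:
            raise ValueError(f"n_variants must be >= 2, got {self.n_variants}")
        _validate_fraction("pleiotropy_frac", self.pleiotropy_frac)
        for name in ("exposure_beta_sd", "exposure_se", "outcome_se", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


@dataclass
class MRTruth:
    causal_effect: float
    pleiotropic_ids: list[str]
    pleiotropic_effects: np.ndarray


def simulate_mr_summary(cfg: MRSimConfig) -> tuple[pd.DataFrame, MRTruth]:
    """Draw an IVTable from the linear IV -> exposure -> outcome model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_variants
    ids = [f"rs{i:06d}" for i in range(1, n + 1)]
    beta_exp = rng.normal(0.0, cfg.exposure_beta_sd, size=n)
    n_pleio = int(round(cfg.pleiotropy_frac * n))
    pleio_idx = rng.choice(n, size=n_pleio, replace=False)
    pleio = np.zeros(n)
    if n_pleio:
        if cfg.pleiotropy_mode == "balanced":
            pleio[pleio_idx] = rng.normal(0.0, cfg.pleiotropy_sd, size=n_pleio)
        else:  # directional: one-sided (half-normal) pleiotropic shifts
            pleio[pleio_idx] = np.abs(rng.normal(0.0, cfg.pleiotropy_sd, size=n_pleio))
    beta_out = cfg.causal_effect * beta_exp + pleio + rng.normal(
        0.0, cfg.outcome_se, size=n
    )
    se_exp = np.full(n, max(cfg.exposure_se, 1e-12))
    se_out = np.full(n, max(cfg.outcome_se, 1e-12))
    from scipy import stats as _st

    p_exp = np.clip(2.0 * _st.norm.sf(np.abs(beta_exp / se_exp)), 1e-300, 1.0)
    ivs = pd.DataFrame(
        {
            "variant_id": ids,
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "p_exp": p_exp,
            "beta_out": beta_out,
            "se_out": se_out,
        }
    )
    truth = MRTruth(
        causal_effect=cfg.causal_effect,
        pleiotropic_ids=[ids[i] for i in sorted(pleio_idx)],
        pleiotropic_effects=pleio[np.sort(pleio_idx)] if n_pleio else np.array([]),
    )
    return ivs, truth


def simulate_ld_blocks(
    n_variants: int, block_size: int, within_r2: float, seed: int = 0
) -> LDMatrix:
    """Block-diagonal LD: r^2 = ``within_r2`` inside blocks, 0 between.

    The last block is truncated when ``block_size`` does not divide
    ``n_variants``.  The result is symmetric positive semi-definite for any
    ``within_r2`` in [0, 1).
    """
    if not 0.0 <= within_r2 < 1.0:
        raise ValueError(f"within_r2 must lie in [0, 1), got {within_r2}")
    if block_size < 1:
        raise ValueError("block_size must be positive")
    ids = [f"rs{i:06d}" for i in range(1, n_variants + 1)]
    r2 = np.zeros((n_variants, n_variants))
    for start in range(0, n_variants, block_size):
        stop = min(start + block_size, n_variants)
        r2[start:stop, start:stop] = within_r2
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(ids, r2)


# ---------------------------------------------------------------------------
# Single-nucleus reference and bulk mixtures
# ---------------------------------------------------------------------------

@dataclass
class CellSimConfig:
    """Generative model for a multi-subject single-nucleus reference.

    Per-subject cell-type proportions are Dirichlet; per-gene base rates are
    gamma-distributed with subject-level multiplicative jitter (so cell-type
    profiles genuinely vary across subjects); ``marker_frac`` of the genes
    are upregulated ``marker_fold``-fold in one cell type each; and
    ``discordant_frac`` of the genes are inflated ``discordant_fold``-fold
    in nuclei only, emulating pre-mRNA-driven nucleus-vs-bulk mismatch.
    """

    n_subjects: int = 6
    n_celltypes: int = 8
    n_genes: int = 2000
    cells_per_subject: int = 2600
    dirichlet_alpha: np.ndarray | None = None  # default: 25 * adipose base mix
    marker_frac: float = 0.10
    marker_fold: float = 8.0
    discordant_frac: float = 0.05
    discordant_fold: float = 30.0
    libsize_mean: float = 1200.0  # gives a median ~500 expressed genes/cell on a 2000-gene panel
    subject_jitter_sd: float = 0.15
    rna_content: np.ndarray | None = None  # per-cell-type total-RNA multipliers
    seed: int = 0

    def validate(self) -> np.ndarray:
        for name in ("n_subjects", "n_celltypes", "n_genes", "cells_per_subject"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        _validate_fraction("marker_frac", self.marker_frac)
        _validate_fraction("discordant_frac", self.discordant_frac)
        if self.marker_fold < 1 or self.discordant_fold < 1:
            raise ValueError("fold changes must be >= 1")
        if self.dirichlet_alpha is None:
            if self.n_celltypes == 8:
                alpha = 25.0 * ADIPOSE_BASE_PROPORTIONS
            else:
                alpha = np.full(self.n_celltypes, 25.0 / self.n_celltypes)
        else:
            alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if len(alpha) != self.n_celltypes or np.any(alpha <= 0):
            raise ValueError("dirichlet_alpha must be strictly positive, one per cell type")
        return alpha

    def celltype_names(self) -> list[str]:
        if self.n_celltypes == len(CELL_TYPE_NAMES):
            return list(CELL_TYPE_NAMES)
        return [f"type{k + 1}" for k in range(self.n_celltypes)]


@dataclass
class CellTruth:
    """Ground truth emitted with a simulated reference."""

    true_proportions: pd.DataFrame  # subject x cell type label frequencies
    profiles: np.ndarray  # (subject, celltype, gene) bulk-side relative expression
    rna_content: np.ndarray  # per-cell-type total-RNA multipliers
    marker_of: pd.Series  # gene -> cell type name or ""
    is_discordant: pd.Series  # gene -> bool


def simulate_sc_reference(cfg: CellSimConfig) -> tuple[AnnData, CellTruth]:
    """Simulate nucleus x gene counts with subject and cell-type labels."""
    alpha = cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    S, K, G = cfg.n_subjects, cfg.n_celltypes, cfg.n_genes
    celltypes = cfg.celltype_names()
    subjects = [f"S{s + 1}" for s in range(S)]
    genes = [f"GENE{g + 1:05d}" for g in range(G)]

    base = rng.gamma(shape=0.6, scale=1.0, size=G)
    base /= base.sum()

    n_markers = int(round(cfg.marker_frac * G))
    marker_idx = rng.choice(G, size=n_markers, replace=False)
    marker_of = np.full(G, "", dtype=object)
    marker_of[marker_idx] = [celltypes[i % K] for i in range(n_markers)]

    n_disc = int(round(cfg.discordant_frac * G))
    non_marker = np.setdiff1d(np.arange(G), marker_idx)
    disc_idx = rng.choice(non_marker, size=n_disc, replace=False)
    is_discordant = np.zeros(G, dtype=bool)
    is_discordant[disc_idx] = True

    # Cell-type rates: base profile with marker upregulation.
    type_rates = np.tile(base, (K, 1))
    for k, ct in enumerate(celltypes):
        mask = marker_of == ct
        type_rates[k, mask] *= cfg.marker_fold
    # Subject-level multiplicative jitter (lognormal), shared across types.
    jitter = rng.lognormal(0.0, cfg.subject_jitter_sd, size=(S, 1, G))
    rates = type_rates[None, :, :] * jitter  # (S, K, G)
    rates /= rates.sum(axis=2, keepdims=True)

    rna_content = (
        np.ones(K) if cfg.rna_content is None
        else np.asarray(cfg.rna_content, dtype=float)
    )
    if len(rna_content) != K or np.any(rna_content <= 0):
        raise ValueError("rna_content must be positive, one per cell type")

    # Nuclear rates add the discordant (pre-mRNA-like) inflation.
    nuc_rates = rates.copy()
    nuc_rates[:, :, is_discordant] *= cfg.discordant_fold
    nuc_rates /= nuc_rates.sum(axis=2, keepdims=True)

    props = rng.dirichlet(alpha, size=S)  # (S, K)
    counts_blocks, subj_col, type_col = [], [], []
    for s in range(S):
        n_per_type = rng.multinomial(cfg.cells_per_subject, props[s])
        for k in range(K):
            nk = int(n_per_type[k])
            if nk == 0:
                continue
            libs = rng.lognormal(
                np.log(cfg.libsize_mean * rna_content[k]), 0.3, size=nk
            )
            lam = libs[:, None] * nuc_rates[s, k][None, :]
            counts_blocks.append(rng.poisson(lam).astype(np.int32))
            subj_col.extend([subjects[s]] * nk)
            type_col.extend([celltypes[k]] * nk)
    X = np.vstack(counts_blocks)
    obs = pd.DataFrame(
        {
            "barcode": [f"CELL{i + 1:06d}" for i in range(X.shape[0])],
            "subject": pd.Categorical(subj_col, categories=subjects),
            "cluster": pd.Categorical(type_col, categories=celltypes),
        }
    ).set_index("barcode")
    lengths = np.round(rng.lognormal(np.log(1500.0), 0.5, size=G)).astype(int)
    var = pd.DataFrame(
        {
            "gene_id": genes,
            "length": np.maximum(lengths, 100),
            "marker_of": pd.Categorical(marker_of),
            "is_discordant": is_discordant,
        }
    ).set_index("gene_id")
    adata = AnnData(X=X, obs=obs, var=var)

    realized = (
        obs.groupby("subject", observed=True)["cluster"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(index=subjects, columns=celltypes, fill_value=0.0)
    )
    truth = CellTruth(
        true_proportions=realized,
        profiles=rates,
        rna_content=rna_content,
        marker_of=pd.Series(marker_of, index=genes, name="marker_of"),
        is_discordant=pd.Series(is_discordant, index=genes, name="is_discordant"),
    )
    return adata, truth


def simulate_bulk_mixtures(
    truth: CellTruth,
    proportions: pd.DataFrame,
    libsize: float = 2e6,
    noise_cv: float = 0.1,
    seed: int = 0,
    gene_lengths: pd.Series | None = None,
):
    """Bulk samples as proportion-weighted mixtures of cell-type profiles.

    Expected bulk relative expression of sample s is
    ``sum_k p_sk * S_k * theta_skg`` (S_k = per-type total-RNA content,
    theta the subject's bulk-side profiles, without discordant inflation),
    perturbed by multiplicative lognormal noise with coefficient of
    variation ``noise_cv``, then sampled as Poisson counts at depth
    ``libsize`` with read probability proportional to expression x gene
    length.  Returns an :class:`~adipomr.expression.ExpressionSet`.
    """
    from .expression import ExpressionSet

    if libsize <= 0:
        raise ValueError(f"libsize must be positive, got {libsize}")
    if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("proportion rows must sum to 1")
    rng = np.random.default_rng(seed)
    S, K, G = truth.profiles.shape
    genes = list(truth.marker_of.index)
    if list(proportions.index) != list(truth.true_proportions.index):
        raise ValueError("proportions rows must align with the reference subjects")
    p = proportions.to_numpy()  # (S, K)
    weights = p * truth.rna_content[None, :]
    expected = np.einsum("sk,skg->sg", weights, truth.profiles)
    expected /= expected.sum(axis=1, keepdims=True)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        expected = expected * rng.lognormal(-sigma**2 / 2, sigma, size=expected.shape)
        expected /= expected.sum(axis=1, keepdims=True)
    if gene_lengths is None:
        lengths = pd.Series(1500, index=genes, name="length")
    else:
        lengths = gene_lengths.reindex(genes)
    read_p = expected * lengths.to_numpy()[None, :]
    read_p /= read_p.sum(axis=1, keepdims=True)
    counts = rng.poisson(libsize * read_p).astype(np.int64)
    samples = [f"{s}_bulk" for s in proportions.index]
    counts_df = pd.DataFrame(counts.T, index=genes, columns=samples)
    gene_meta = pd.DataFrame(
        {"length": lengths, "is_MT": False}, index=pd.Index(genes, name="gene_id")
    )
    return ExpressionSet(counts=counts_df, gene_meta=gene_meta)


# ---------------------------------------------------------------------------
# Phenotype cohort
# ---------------------------------------------------------------------------

@dataclass
class PhenoSimConfig:
    """Generative twin of the multivariable insulin-sensitivity model.

    The latent Matsuda index is
    ``beta_bodyfat*bodyfat% + beta_mt*MT + sum_k beta_celltypes[k]*CT_k
    + beta_age*(age-55) + noise``; when ``target_r2_total`` is set the noise
    SD is calibrated analytically (variance matching against the realized
    linear predictor) so the model R^2 hits the target.  HbA1c rises with
    body fat; prediabetes is HbA1c in ``hba1c_prediabetes_band`` and a
    ``t2d_frac`` subset is assigned diabetes (HbA1c > band upper).  MT read
    fraction tracks MT expression, and the "biased" technical factors are
    contaminated by it with strength ``mt_confounding_strength``.

    The default endothelial coefficient is 0 so that the 7-proportion model
    (endothelial excluded, proportions summing to 1) identifies the
    generator betas directly rather than a reparameterization.
    """

    n_individuals: int = 324
    beta_bodyfat: float = -0.08  # per percentage point of body fat
    beta_mt: float = 0.40  # per SD of adjusted MT expression
    beta_celltypes: np.ndarray | None = None
    beta_age: float = -0.01  # per year, centred at 55
    noise_sd: float = 1.0
    target_r2_total: float | None = 0.44
    hba1c_prediabetes_band: tuple[float, float] = (5.7, 6.4)
    t2d_frac: float = 0.033
    mt_confounding_strength: float = 0.8
    n_technical_factors: int = 11
    bodyfat_mean: float = 27.0
    bodyfat_sd: float = 7.0
    bmi_noise_sd: float = 0.4
    seed: int = 0

    def validate(self) -> np.ndarray:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.target_r2_total is not None and not 0 < self.target_r2_total < 1:
            raise ValueError("target_r2_total must lie in (0, 1)")
        lo, hi = self.hba1c_prediabetes_band
        if not lo < hi:
            raise ValueError("HbA1c band lower bound must be below the upper bound")
        _validate_fraction("t2d_frac", self.t2d_frac)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.beta_celltypes is None:
            beta_c = dict(zip(CELL_TYPE_NAMES, [2.0, 3.0, -6.0, -6.0, 4.0, 0.0, 1.0, -2.0]))
            return np.array([beta_c[ct] for ct in CELL_TYPE_NAMES])
        return np.asarray(self.beta_celltypes, dtype=float)


@dataclass
class CohortTruth:
    beta_bodyfat: float
    beta_mt: float
    beta_celltypes: pd.Series
    beta_age: float
    noise_sd: float
    latent_sd: float
    realized_r2: float


def simulate_cohort(
    cfg: PhenoSimConfig,
    proportions: pd.DataFrame | None = None,
    mt_expression: pd.Series | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a phenotype cohort table (one row per individual)."""
    beta_c = cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    ids = [f"IND{i + 1:05d}" for i in range(n)]

    bodyfat = rng.normal(cfg.bodyfat_mean, cfg.bodyfat_sd, size=n)
    bodyfat = np.clip(bodyfat, 5.0, 60.0)
    z_bf = (bodyfat - bodyfat.mean()) / bodyfat.std()
    bmi = 20.0 + 0.25 * bodyfat + rng.normal(0.0, cfg.bmi_noise_sd, size=n)
    age = rng.normal(55.0, 6.0, size=n)

    if proportions is None:
        names = CELL_TYPE_NAMES if len(beta_c) == 8 else [
            f"type{k + 1}" for k in range(len(beta_c))
        ]
        alpha = 25.0 * (
            ADIPOSE_BASE_PROPORTIONS if len(beta_c) == 8
            else np.full(len(beta_c), 1.0 / len(beta_c))
        )
        props = pd.DataFrame(rng.dirichlet(alpha, size=n), index=ids, columns=names)
    else:
        if len(proportions) != n:
            raise ValueError("proportions rows must align with n_individuals")
        props = proportions.copy()
        props.index = ids
    if len(props.columns) != len(beta_c):
        raise ValueError("beta_celltypes length must match the proportion columns")

    if mt_expression is None:
        # MT expression declines with adiposity (shared biology), unit SD.
        mt = -0.3 * z_bf + np.sqrt(1 - 0.3**2) * rng.normal(size=n)
    else:
        if len(mt_expression) != n:
            raise ValueError("mt_expression must align with n_individuals")
        mt = np.asarray(mt_expression, dtype=float)

    lp = (
        cfg.beta_bodyfat * bodyfat
        + cfg.beta_mt * mt
        + props.to_numpy() @ beta_c
        + cfg.beta_age * (age - 55.0)
    )
    if cfg.target_r2_total is not None:
        var_lp = float(np.var(lp))
        noise_sd = np.sqrt(var_lp * (1.0 - cfg.target_r2_total) / cfg.target_r2_total)
    else:
        noise_sd = cfg.noise_sd
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    latent = lp + noise
    matsuda = np.exp(0.35 * (latent - latent.mean()) + np.log(5.0))

    hba1c = np.maximum(4.5, 5.4 + 0.02 * bodyfat + rng.normal(0.0, 0.3, size=n))
    lo, hi = cfg.hba1c_prediabetes_band
    n_t2d = int(round(cfg.t2d_frac * n))
    t2d = np.zeros(n, dtype=bool)
    if n_t2d:
        t2d_idx = rng.choice(n, size=n_t2d, replace=False)
        t2d[t2d_idx] = True
        hba1c[t2d_idx] = hi + 0.1 + rng.exponential(0.8, size=n_t2d)
    prediab = (hba1c >= lo) & (hba1c <= hi) & ~t2d

    # Read categories and technical factors confounded with MT read fraction.
    z_mt = (mt - mt.mean()) / (mt.std() if mt.std() > 0 else 1.0)
    mt_frac = np.clip(0.15 + 0.05 * z_mt, 0.01, 0.6)
    total = rng.poisson(3e7, size=n).astype(np.int64)
    reads_mt = np.round(total * mt_frac).astype(np.int64)
    nuclear = total - reads_mt
    frac_ex = np.clip(rng.normal(0.60, 0.03, size=n), 0.4, 0.8)
    frac_in = np.clip(rng.normal(0.25, 0.02, size=n), 0.1, 0.4)
    reads_ex = np.round(nuclear * frac_ex).astype(np.int64)
    reads_in = np.round(nuclear * frac_in).astype(np.int64)
    reads_ig = nuclear - reads_ex - reads_in

    z_mtfrac = (mt_frac - mt_frac.mean()) / mt_frac.std()
    tech = {
        f"tech_{j + 1:02d}": cfg.mt_confounding_strength * z_mtfrac
        + rng.normal(size=n)
        for j in range(cfg.n_technical_factors)
    }
    pcs = {f"pc{j + 1}": rng.normal(size=n) for j in range(3)}

    table = pd.DataFrame(
        {
            "individual_id": ids,
            "matsuda": matsuda,
            "matsuda_latent": latent,
            "bodyfat_pct": bodyfat,
            "bmi": bmi,
            "age": age,
            "hba1c": hba1c,
            "t2d_flag": t2d,
            "prediabetes_flag": prediab,
            "mt_expression": mt,
            "mt_read_frac": mt_frac,
            "reads_total": total,
            "reads_mt": reads_mt,
            "reads_exonic": reads_ex,
            "reads_intronic": reads_in,
            "reads_intergenic": reads_ig,
            **{f"prop_{c}": props[c].to_numpy() for c in props.columns},
            **tech,
            **pcs,
        }
    )
    var_noise = float(np.var(noise))
    var_latent = float(np.var(latent))
    truth = CohortTruth(
        beta_bodyfat=cfg.beta_bodyfat,
        beta_mt=cfg.beta_mt,
        beta_celltypes=pd.Series(beta_c, index=props.columns),
        beta_age=cfg.beta_age,
        noise_sd=noise_sd,
        latent_sd=float(np.std(latent)),
        realized_r2=1.0 - var_noise / var_latent if var_latent > 0 else 1.0,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_ivtable(ivs: pd.DataFrame, path) -> None:
    ivs.to_csv(path, sep="\t", index=False)


def read_ivtable(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ld_matrix(ld: LDMatrix, path) -> None:
    ld.to_dataframe().to_csv(path, sep="\t")


def read_ld_matrix(path) -> LDMatrix:
    return LDMatrix.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))


def write_sc_reference(adata: AnnData, outdir) -> None:
    """Write a reference as MTX plus cell/gene metadata TSVs."""
    from pathlib import Path

    from scipy import io as sio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(adata.X))
    adata.obs.reset_index().to_csv(outdir / "cells.tsv", sep="\t", index=False)
    adata.var.reset_index().to_csv(outdir / "genes.tsv", sep="\t", index=False)


def read_sc_reference(indir) -> AnnData:
    from pathlib import Path

    from scipy import io as sio

    indir = Path(indir)
    X = np.asarray(sio.mmread(indir / "matrix.mtx").todense()).astype(np.int32)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("barcode")
    var = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene_id")
    return AnnData(X=X, obs=obs, var=var)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
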