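"""Two-sample Mendelian randomization.

Instrument selection by LD pruning, confounder screening, inverse-variance
weighted (IVW) and MR-Egger estimation, Cochran's Q heterogeneity, and
MR-PRESSO resampling for global-pleiotropy testing and outlier removal.

All estimators operate on a per-variant summary-statistics table (the
``IVTable``): for every variant, its effect on the exposure (``beta_exp``,
``se_exp``, ``p_exp``) and its effect on the outcome (``beta_out``,
``se_out``), obtained from two non-overlapping GWAS samples.  The causal
slope of the outcome on the exposure is estimated by weighted regression of
``beta_out`` on ``beta_exp``, through the origin (IVW) or with a free
intercept (Egger), using weights 1/se_out^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

IV_COLUMNS = ["variant_id", "beta_exp", "se_exp", "p_exp", "beta_out", "se_out"]

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class MRError(ValueError):
    """Raised for invalid MR inputs (too few instruments, bad SEs, ...)."""


def validate_ivtable(ivs: pd.DataFrame, min_variants: int = 2) -> pd.DataFrame:
    """Check an IVTable's structural invariants and return it unchanged."""
    missing = [c for c in IV_COLUMNS if c not in ivs.columns]
    if missing:
        raise MRError(f"IVTable missing columns: {missing}")
    if len(ivs) < min_variants:
        raise MRError(f"need at least {min_variants} instruments, got {len(ivs)}")
    if ivs["variant_id"].duplicated().any():
        dups = ivs.loc[ivs["variant_id"].duplicated(), "variant_id"].tolist()
        raise MRError(f"duplicated variant ids: {dups}")
    for col in ("se_exp", "se_out"):
        if not (ivs[col] > 0).all():
            raise MRError(f"{col} must be strictly positive")
    if not ((ivs["p_exp"] > 0) & (ivs["p_exp"] <= 1)).all():
        raise MRError("p_exp must lie in (0, 1]")
    return ivs


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise MRError(f"r2 shape {self.r2.shape} does not match {n} variants")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise MRError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise MRError("LD matrix diagonal must be 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def submatrix(self, variant_ids: list[str]) -> np.ndarray:
        missing = [v for v in variant_ids if v not in self._index]
        if missing:
            raise MRError(f"variants missing from LD matrix: {missing}")
        idx = np.array([self._index[v] for v in variant_ids])
        return self.r2[np.ix_(idx, idx)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LDMatrix":
        return cls(list(df.index), df.to_numpy())


@dataclass
class MRResult:
    """A single causal estimate with its diagnostics.

    ``estimate`` is the causal slope of outcome on exposure; ``Q``/``Q_p``
    the Cochran heterogeneity test; ``egger_intercept``/``intercept_p`` the
    directional-pleiotropy test (Egger only); ``presso_global_p`` the
    MR-PRESSO global residual-sum-of-squares exceedance test.
    """

    method: str
    estimate: float
    se: float
    p: float
    n_iv_used: int
    p_adjusted: float | None = None
    egger_intercept: float | None = None
    intercept_p: float | None = None
    Q: float | None = None
    Q_p: float | None = None
    presso_global_p: float | None = None
    outlier_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in self.__dict__.items()
        }


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------

def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Merge exposure and outcome summary statistics into one IVTable.

    Matches on ``variant_id``; if both tables carry ``effect_allele`` (and
    optionally ``other_allele``), outcome effects measured on the opposite
    allele are sign-flipped and strand-ambiguous palindromic variants
    (A/T, C/G) are dropped.
    """
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"))
    if "effect_allele_exp" in merged.columns and "effect_allele_out" in merged.columns:
        other = next(
            (c for c in ("other_allele_exp", "other_allele") if c in merged.columns),
            None,
        )
        if other is not None:
            pal = [
                (a, b) in PALINDROMIC
                for a, b in zip(merged["effect_allele_exp"], merged[other])
            ]
            merged = merged.loc[~np.asarray(pal)].copy()
        flip = merged["effect_allele_exp"] != merged["effect_allele_out"]
        merged.loc[flip, "beta_out"] = -merged.loc[flip, "beta_out"]
    keep = [c for c in merged.columns if c in IV_COLUMNS or c.startswith("p_")]
    return merged[keep].reset_index(drop=True)


def select_ivs(
    gwas: pd.DataFrame,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
) -> pd.DataFrame:
    """Select independent genome-wide-significant instruments.

    Keeps variants with exposure p-value below ``p_threshold`` and greedily
    prunes them in ascending p-value order (ties broken by variant id) so
    that every retained pair has r^2 below ``r2_threshold``.
    """
    validate_ivtable(gwas, min_variants=1)
    sig = gwas.loc[gwas["p_exp"] < p_threshold].copy()
    if sig.empty:
        warnings.warn(
            f"no variants pass the exposure p-value threshold {p_threshold:g}",
            stacklevel=2,
        )
        return sig.reset_index(drop=True)
    sig = sig.sort_values(["p_exp", "variant_id"], kind="mergesort").reset_index(drop=True)
    r2 = ld.submatrix(list(sig["variant_id"]))
    keep: list[int] = []
    dropped = np.zeros(len(sig), dtype=bool)
    for i in range(len(sig)):
        if dropped[i]:
            continue
        keep.append(i)
        dropped |= r2[i] >= r2_threshold
        dropped[i] = True  # self already kept
    out = sig.iloc[keep]
    return out.sort_values("variant_id", kind="mergesort").reset_index(drop=True)


def exclude_confounded_ivs(
    ivs: pd.DataFrame,
    confounders: list[str],
    p_threshold: float = 5e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop instruments significantly associated with any named confounder.

    Confounder associations are read from ``p_<name>`` columns.  Returns the
    filtered table and a report listing each removed variant with the
    confounder(s) that triggered its removal.
    """
    cols = {}
    for name in confounders:
        col = f"p_{name}"
        if col not in ivs.columns:
            raise MRError(f"unknown confounder {name!r}: column {col!r} not present")
        cols[name] = col
    flagged: dict[str, list[str]] = {}
    for name, col in cols.items():
        for vid in ivs.loc[ivs[col] < p_threshold, "variant_id"]:
            flagged.setdefault(vid, []).append(name)
    report = pd.DataFrame(
        {
            "variant_id": list(flagged),
            "confounders": [",".join(v) for v in flagged.values()],
        }
    )
    kept = ivs.loc[~ivs["variant_id"].isin(flagged)].reset_index(drop=True)
    return kept, report


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _arrays(ivs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = ivs["beta_exp"].to_numpy(dtype=float)
    y = ivs["beta_out"].to_numpy(dtype=float)
    se = ivs["se_out"].to_numpy(dtype=float)
    return x, y, se


def ivw_estimate(ivs: pd.DataFrame, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted causal estimate (regression through origin).

    estimate = sum(w x y) / sum(w x^2) with w = 1/se_out^2.  Under excess
    heterogeneity (Q/(n-1) > 1) the SE is inflated multiplicatively
    (random-effects IVW); p-value from the normal distribution.
    """
    validate_ivtable(ivs, min_variants=2)
    x, y, se = _arrays(ivs)
    w = 1.0 / se**2
    sxx = float(np.sum(w * x * x))
    if sxx == 0:
        raise MRError("all exposure betas are zero")
    estimate = float(np.sum(w * x * y)) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    n = len(x)
    q, q_p = cochran_q(ivs, estimate, df=n - 1)
    scale = 1.0
    if random_effects and n > 1 and q / (n - 1) > 1.0:
        scale = np.sqrt(q / (n - 1))
    se_hat = se_fixed * scale
    p = 2.0 * stats.norm.sf(abs(estimate / se_hat))
    return MRResult(
        method="IVW", estimate=estimate, se=float(se_hat), p=float(p),
        n_iv_used=n, Q=q, Q_p=q_p,
    )


def egger_regression(ivs: pd.DataFrame) -> MRResult:
    """MR-Egger weighted regression with a free intercept.

    Variants are re-signed so every exposure beta is positive (Egger's
    orientation convention), then beta_out is regressed on beta_exp with
    weights 1/se_out^2.  The intercept estimates the average directional
    pleiotropy; its p-value is the pleiotropy test.  SEs use the
    multiplicative overdispersion scale max(1, sqrt(Q'/(n-2))) and
    t-distributed p-values with n-2 degrees of freedom.
    """
    validate_ivtable(ivs, min_variants=3)
    x, y, se = _arrays(ivs)
    sign = np.where(x < 0, -1.0, 1.0)
    x, y = x * sign, y * sign
    w = 1.0 / se**2
    X = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    coef, _, _, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    n = len(x)
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (n - 2))
    xtx_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    se_int = float(np.sqrt(phi * xtx_inv[0, 0]))
    se_slope = float(np.sqrt(phi * xtx_inv[1, 1]))
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df=n - 2)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), df=n - 2)
    q_p = float(stats.chi2.sf(q, df=n - 2))
    return MRResult(
        method="Egger", estimate=slope, se=se_slope, p=float(p_slope),
        n_iv_used=n, egger_intercept=intercept, intercept_p=float(p_int),
        Q=q, Q_p=q_p,
    )


def cochran_q(ivs: pd.DataFrame, slope: float, df: int | None = None) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic around a given causal slope.

    Q = sum w (beta_out - slope*beta_exp)^2, compared to chi-square with
    ``df`` degrees of freedom (default n-1, the IVW convention; pass n-2
    after an Egger fit).
    """
    validate_ivtable(ivs, min_variants=2)
    x, y, se = _arrays(ivs)
    w = 1.0 / se**2
    q = float(np.sum(w * (y - slope * x) ** 2))
    if df is None:
        df = len(x) - 1
    return q, float(stats.chi2.sf(q, df=df))


def _loo_ivw_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, one per variant (vectorized)."""
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    ivs: pd.DataFrame,
    n_sim: int = 5000,
    outlier_alpha: float = 0.05,
    seed: int | None = 0,
) -> MRResult:
    """MR-PRESSO: global pleiotropy test, outlier detection, corrected IVW.

    The observed weighted residual sum of squares, with each variant's
    expectation taken from the leave-one-out IVW fit, is compared against a
    null distribution built by redrawing outcome betas from the fitted model
    at their reported SEs (``n_sim`` parametric draws); the global p-value is
    the exceedance fraction.  Per-variant squared residuals get the same
    treatment, Bonferroni-corrected over the instruments at
    ``outlier_alpha``; the corrected estimate is IVW on the non-outliers.
    """
    validate_ivtable(ivs, min_variants=4)
    if n_sim < 1000:
        raise MRError(f"n_sim must be >= 1000, got {n_sim}")
    rng = np.random.default_rng(seed)
    x, y, se = _arrays(ivs)
    w = 1.0 / se**2
    n = len(x)

    b_loo = _loo_ivw_slopes(x, y, w)
    res_obs = y - b_loo * x
    rss_obs = float(np.sum(w * res_obs**2))

    # Parametric null: redraw outcome betas around the LOO-fitted values.
    y_sim = rng.normal(loc=b_loo * x, scale=se, size=(n_sim, n))
    sxy_sim = y_sim @ (w * x)
    sxx = np.sum(w * x * x)
    b_loo_sim = (sxy_sim[:, None] - (w * x) * y_sim) / (sxx - w * x * x)
    res_sim = y_sim - b_loo_sim * x
    wres2_sim = w * res_sim**2
    rss_sim = wres2_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    wres2_obs = w * res_obs**2
    p_outlier = (1 + np.sum(wres2_sim >= wres2_obs, axis=0)) / (n_sim + 1)
    is_outlier = p_outlier < outlier_alpha / n
    outlier_ids = list(ivs.loc[is_outlier, "variant_id"])

    if is_outlier.all():
        raise MRError("no instruments remain: every variant flagged as outlier")
    if is_outlier.any():
        corrected = ivw_estimate(ivs.loc[~is_outlier])
    else:
        corrected = ivw_estimate(ivs)
    return MRResult(
        method="PRESSO-corrected",
        estimate=corrected.estimate, se=corrected.se, p=corrected.p,
        n_iv_used=corrected.n_iv_used, Q=corrected.Q, Q_p=corrected.Q_p,
        presso_global_p=global_p, outlier_ids=outlier_ids,
    )


def bonferroni_adjust(p_values, m: int = 3) -> np.ndarray:
    """Bonferroni correction: p -> min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise MRError("p-values must lie in (0, 1]")
    return np.minimum(1.0, m * p)


def run_mr_battery(
    ivs: pd.DataFrame | None,
    n_sim: int = 5000,
    outlier_alpha: float = 0.05,
    seed: int | None = 0,
    n_tests: int = 3,
    min_instruments: int = 4,
) -> dict:
    """Run the full estimator battery on one MR direction.

    Returns a structured report with the MR-PRESSO-corrected estimate, the
    Egger fit (slope + pleiotropy intercept) and the heterogeneity test, with
    causal-effect p-values Bonferroni-adjusted over ``n_tests`` analyses.
    A direction without enough genome-wide-significant instruments is
    reported as not assessable (the instrument-relevance assumption of MR
    cannot be fulfilled).
    """
    if ivs is None or len(ivs) < min_instruments:
        return {
            "assessable": False,
            "n_iv": 0 if ivs is None else len(ivs),
            "reason": "insufficient genome-wide-significant instruments",
        }
    presso = mr_presso(ivs, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
    kept = ivs.loc[~ivs["variant_id"].isin(presso.outlier_ids)]
    egger = egger_regression(kept)
    presso.p_adjusted = float(bonferroni_adjust([presso.p], m=n_tests)[0])
    egger.p_adjusted = float(bonferroni_adjust([egger.p], m=n_tests)[0])
    q, q_p = cochran_q(kept, presso.estimate)
    return {
        "assessable": True,
        "n_iv": len(ivs),
        "n_iv_after_presso": len(kept),
        "presso": presso.to_dict(),
        "egger": egger.to_dict(),
        "heterogeneity": {"Q": q, "Q_p": q_p},
    }
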