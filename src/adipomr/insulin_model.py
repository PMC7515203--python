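"""Insulin-sensitivity modelling from adipose features.

The multivariable linear model ("Model 1") regresses the inverse-normal
transformed Matsuda index on body fat percent, adjusted MT expression and 7
cell-type proportions (one type — endothelial by default — excluded because
the 8 proportions sum to 1).  Variance partitioning refits OLS on predictor
subsets.  The elastic-net predictor minimizes

    (1/2n)||y - Xb||^2 + lambda * (a ||b||_1 + (1-a)/2 ||b||_2^2)

by cyclic coordinate descent on standardized predictors, with lambda chosen
at the minimum mean k-fold cross-validated error, and is evaluated by a
100-group out-of-fold scheme in which lambda is re-selected inside every
training set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .expression import inverse_normal_transform, residualize
from .synthetic import CELL_TYPE_NAMES

EXCLUDED_CELLTYPE = "endothelial"


class ModelError(ValueError):
    pass


def _prop_columns(table: pd.DataFrame, exclude: str | None = EXCLUDED_CELLTYPE) -> list[str]:
    cols = [c for c in table.columns if c.startswith("prop_")]
    if exclude is not None:
        cols = [c for c in cols if c != f"prop_{exclude}"]
    return cols


# ---------------------------------------------------------------------------
# Cohort preparation and Model 1
# ---------------------------------------------------------------------------

def prepare_cohort(
    raw: pd.DataFrame,
    proportions: pd.DataFrame | None = None,
    mt_adjusted: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the analysis table: drop T2D, transform, age-correct.

    Individuals with diabetes are removed from every Matsuda analysis; the
    Matsuda index and MT expression are inverse-normal transformed, and the
    transformed Matsuda is residualized on age and age^2.
    """
    table = raw.copy()
    if table["individual_id"].duplicated().any():
        dups = table.loc[table["individual_id"].duplicated(), "individual_id"]
        raise ModelError(f"duplicate individual ids: {list(dups)}")
    if proportions is not None:
        for ct in proportions.columns:
            table[f"prop_{ct}"] = proportions[ct].to_numpy()
    if mt_adjusted is not None:
        table["mt_expression"] = np.asarray(mt_adjusted, dtype=float)
    table = table.loc[~table["t2d_flag"].astype(bool)].reset_index(drop=True)
    matsuda_int = inverse_normal_transform(table["matsuda"].to_numpy())
    age_cov = pd.DataFrame({"age": table["age"], "age2": table["age"] ** 2})
    table["matsuda"] = residualize(matsuda_int, age_cov)
    table["mt_expression"] = inverse_normal_transform(
        table["mt_expression"].to_numpy()
    )
    return table


@dataclass
class Model1Fit:
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    r2: float
    n: int
    excluded_celltype: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.params, "se": self.se, "p": self.pvalues})


def fit_model1(
    cohort: pd.DataFrame,
    response: str = "matsuda",
    obesity_col: str = "bodyfat_pct",
    exclude_celltype: str | None = EXCLUDED_CELLTYPE,
) -> Model1Fit:
    """OLS of the (transformed) Matsuda index on body fat, MT and cell types."""
    props = _prop_columns(cohort, exclude=exclude_celltype)
    predictors = [obesity_col, "mt_expression"] + props
    X = cohort[predictors].to_numpy(dtype=float)
    y = cohort[response].to_numpy(dtype=float)
    if len(y) <= len(predictors) + 2:
        raise ModelError("too few individuals for the number of predictors")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        all_props = [c for c in cohort.columns if c.startswith("prop_")]
        if exclude_celltype is None and len(all_props) == len(props):
            raise ModelError(
                "design is collinear: the cell-type proportions sum to 1, so one "
                "type must be excluded (pass exclude_celltype)"
            )
        raise ModelError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    names = ["intercept"] + predictors
    return Model1Fit(
        params=pd.Series(fit.params, index=names),
        se=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        r2=float(fit.rsquared),
        n=len(y),
        excluded_celltype=exclude_celltype or "",
    )


def celltype_association_scan(
    cohort: pd.DataFrame, response: str = "matsuda", n_tests: int | None = None
) -> pd.DataFrame:
    """Per-cell-type linear association with the Matsuda index, age-adjusted.

    One regression per cell type (all 8 tested marginally), Bonferroni
    corrected over the number of cell types.
    """
    props = [c for c in cohort.columns if c.startswith("prop_")]
    if not props:
        raise ModelError("no cell-type proportion columns (prop_*) found")
    m = n_tests or len(props)
    rows = {}
    y = cohort[response].to_numpy(dtype=float)
    for col in props:
        x = cohort[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ModelError(f"constant proportion column {col}")
        design = sm.add_constant(
            np.column_stack([x, cohort["age"].to_numpy(dtype=float)])
        )
        fit = sm.OLS(y, design).fit()
        rows[col.removeprefix("prop_")] = {
            "beta": fit.params[1],
            "se": fit.bse[1],
            "p": fit.pvalues[1],
            "p_bonferroni": min(1.0, m * fit.pvalues[1]),
        }
    return pd.DataFrame(rows).T


def variance_explained(
    cohort: pd.DataFrame,
    predictor_sets: dict[str, list[str]],
    response: str = "matsuda",
) -> pd.Series:
    """OLS R^2 for each named predictor subset plus the full model."""
    y = cohort[response].to_numpy(dtype=float)
    out = {}
    all_cols: list[str] = []
    for name, cols in predictor_sets.items():
        if not cols:
            raise ModelError(f"empty predictor set {name!r}")
        missing = [c for c in cols if c not in cohort.columns]
        if missing:
            raise ModelError(f"predictors not in cohort: {missing}")
        X = sm.add_constant(cohort[cols].to_numpy(dtype=float))
        out[name] = float(sm.OLS(y, X).fit().rsquared)
        all_cols.extend(c for c in cols if c not in all_cols)
    X = sm.add_constant(cohort[all_cols].to_numpy(dtype=float))
    out["full"] = float(sm.OLS(y, X).fit().rsquared)
    return pd.Series(out, name="r2")


def default_predictor_sets(cohort: pd.DataFrame, obesity_col: str = "bodyfat_pct") -> dict:
    props = _prop_columns(cohort)
    return {
        "obesity": [obesity_col],
        "mt": ["mt_expression"],
        "celltypes": props,
        "mt_plus_celltypes": ["mt_expression"] + props,
    }


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

def _soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _cd_path(
    C: np.ndarray,
    b: np.ndarray,
    lambdas: np.ndarray,
    alpha_mix: float,
    tol: float = 1e-10,
    max_sweeps: int = 2000,
) -> np.ndarray:
    """Cyclic coordinate descent along a descending lambda path.

    ``C`` (..., p, p) and ``b`` (..., p) are the Gram matrix X'X/n and
    moment vector X'y/n of standardized, centred data; leading dimensions
    are solved in parallel (used to fit all CV folds at once).  Returns
    betas of shape (..., L, p).
    """
    C = np.asarray(C, dtype=float)
    b = np.asarray(b, dtype=float)
    batch = b.shape[:-1]
    p = b.shape[-1]
    L = len(lambdas)
    betas = np.empty(batch + (L, p))
    beta = np.zeros(batch + (p,))
    diag = np.einsum("...jj->...j", C)
    for li, lam in enumerate(lambdas):
        l1 = lam * alpha_mix
        l2 = lam * (1.0 - alpha_mix)
        for _ in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                grad = b[..., j] - np.einsum("...k,...k->...", C[..., j, :], beta) \
                    + diag[..., j] * beta[..., j]
                new = _soft_threshold(grad, l1) / (diag[..., j] + l2)
                delta = max(delta, float(np.max(np.abs(new - beta[..., j]), initial=0.0)))
                beta[..., j] = new
            if delta < tol:
                break
        betas[..., li, :] = beta
    return betas


def make_lambda_grid(Xs: np.ndarray, yc: np.ndarray, alpha_mix: float,
                     n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from lambda_max (all betas zero) down ``decades``."""
    n = len(yc)
    lmax = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha_mix, 1e-3))
    lmax = max(lmax, 1e-12)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambda)


@dataclass
class ElasticNetModel:
    """A fitted elastic net with its standardization, portable as JSON."""

    predictors: list[str]
    betas: np.ndarray  # original scale
    intercept: float
    lambda_: float
    alpha_mix: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in table.columns]
        if missing:
            raise ModelError(f"missing predictor columns: {missing}")
        X = table[self.predictors].to_numpy(dtype=float)
        return self.intercept + X @ self.betas

    def to_json(self, path=None) -> str:
        payload = {
            "predictors": self.predictors,
            "betas": self.betas.tolist(),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "alpha_mix": self.alpha_mix,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ElasticNetModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            predictors=payload["predictors"],
            betas=np.asarray(payload["betas"]),
            intercept=payload["intercept"],
            lambda_=payload["lambda"],
            alpha_mix=payload["alpha_mix"],
            x_mean=np.asarray(payload["x_mean"]),
            x_sd=np.asarray(payload["x_sd"]),
        )


def elastic_net_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha_mix: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    predictor_names: list[str] | None = None,
) -> ElasticNetModel:
    """Fit the elastic net with k-fold CV selection of lambda.

    Predictors are standardized (and y centred) before penalization; the
    intercept is unpenalized; coefficients are returned on the original
    scale.  The CV curve is stored on the model (``cv_table``).
    """
    if isinstance(X, pd.DataFrame):
        predictor_names = predictor_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    if np.std(y) == 0:
        raise ModelError("constant response")
    if lambda_grid is not None and len(lambda_grid) == 0:
        raise ModelError("empty lambda grid")
    if not 2 <= n_folds <= n:
        raise ModelError(f"need n >= n_folds >= 2, got n={n}, n_folds={n_folds}")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Xs = (X - x_mean) / x_sd
    y_mean = y.mean()
    yc = y - y_mean
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(Xs, yc, alpha_mix)
    lambdas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    fold_of = rng.permuted(np.arange(n) % n_folds)
    # Per-fold standardized Grams, stacked so the path solves vectorize.
    C = np.empty((n_folds, p, p))
    bv = np.empty((n_folds, p))
    fold_stats = []
    for k in range(n_folds):
        tr = fold_of != k
        Xtr, ytr = X[tr], y[tr]
        m, s = Xtr.mean(axis=0), Xtr.std(axis=0)
        s = np.where(s > 0, s, 1.0)
        Z = (Xtr - m) / s
        zc = ytr - ytr.mean()
        ntr = len(ytr)
        C[k] = Z.T @ Z / ntr
        bv[k] = Z.T @ zc / ntr
        fold_stats.append((m, s, ytr.mean()))
    betas_folds = _cd_path(C, bv, lambdas, alpha_mix)  # (folds, L, p)
    mse = np.zeros((n_folds, len(lambdas)))
    for k in range(n_folds):
        va = fold_of == k
        m, s, ym = fold_stats[k]
        Zva = (X[va] - m) / s
        pred = ym + Zva @ betas_folds[k].T  # (n_va, L)
        mse[k] = np.mean((y[va][:, None] - pred) ** 2, axis=0)
    mean_mse = mse.mean(axis=0)
    best = int(np.argmin(mean_mse))
    lam = float(lambdas[best])

    Cf = Xs.T @ Xs / n
    bf = Xs.T @ yc / n
    beta_std = _cd_path(Cf, bf, lambdas[: best + 1], alpha_mix)[-1]
    beta_orig = beta_std / x_sd
    intercept = y_mean - float(beta_orig @ x_mean)
    cv_table = pd.DataFrame({"lambda": lambdas, "mean_cv_mse": mean_mse})
    return ElasticNetModel(
        predictors=predictor_names,
        betas=beta_orig,
        intercept=intercept,
        lambda_=lam,
        alpha_mix=alpha_mix,
        x_mean=x_mean,
        x_sd=x_sd,
        cv_table=cv_table,
    )


def kkt_residual(model: ElasticNetModel, X, y) -> float:
    """Max violation of the elastic-net stationarity conditions.

    On the standardized scale the subgradient of the objective must vanish:
    for active coordinates |g_j + l2*b_j + l1*sign(b_j)| = 0, for inactive
    ones |g_j| <= l1, where g is the smooth-part gradient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs = (X - model.x_mean) / model.x_sd
    yc = y - y.mean()
    beta_std = model.betas * model.x_sd
    n = len(y)
    grad = -Xs.T @ (yc - Xs @ beta_std) / n
    l1 = model.lambda_ * model.alpha_mix
    l2 = model.lambda_ * (1.0 - model.alpha_mix)
    active = beta_std != 0
    viol = np.zeros_like(beta_std)
    viol[active] = np.abs(
        grad[active] + l2 * beta_std[active] + l1 * np.sign(beta_std[active])
    )
    viol[~active] = np.maximum(np.abs(grad[~active]) - l1, 0.0)
    return float(np.max(viol, initial=0.0))


# ---------------------------------------------------------------------------
# Prediction and validation
# ---------------------------------------------------------------------------

PREDICTOR_PRESETS = {
    "bmi": ["bmi", "mt_expression", "age"],
    "bodyfat": ["bodyfat_pct", "mt_expression", "age"],
}


def preset_predictors(cohort: pd.DataFrame, preset: str = "bmi") -> list[str]:
    """Predictor columns for a preset: obesity trait, MT, age, 7 proportions."""
    if preset not in PREDICTOR_PRESETS:
        raise ModelError(f"unknown preset {preset!r}")
    return PREDICTOR_PRESETS[preset] + _prop_columns(cohort)


def cross_validate_100fold(
    cohort: pd.DataFrame,
    predictors: list[str] | None = None,
    response: str = "matsuda",
    n_groups: int = 100,
    alpha_mix: float = 0.5,
    inner_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Out-of-fold prediction with lambda re-selected in every training set.

    Individuals are split into ``n_groups`` disjoint random groups; each
    group is predicted from an elastic net trained (including its inner CV
    for lambda) on the other groups.  Returns the out-of-fold predictions
    and their Pearson correlation with the observed response.
    """
    predictors = predictors or preset_predictors(cohort)
    X = cohort[predictors].to_numpy(dtype=float)
    y = cohort[response].to_numpy(dtype=float)
    n = len(y)
    if n < n_groups:
        warnings.warn(
            f"n={n} < {n_groups} groups; falling back to leave-one-out ({n} folds)",
            stacklevel=2,
        )
        n_groups = n
    rng = np.random.default_rng(seed)
    group_of = rng.permuted(np.arange(n) % n_groups)
    p_dim = X.shape[1]

    # A shared lambda path lets every training set's inner CV be solved in
    # one stacked coordinate-descent pass; each outer fold still selects its
    # own lambda from its own inner-CV curve.
    x_all_sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    lmax = np.max(np.abs(((X - X.mean(0)) / x_all_sd).T @ (y - y.mean()))) / (
        n * max(alpha_mix, 1e-3)
    )
    lambdas = np.logspace(np.log10(lmax * 1.5), np.log10(lmax * 1.5) - 4.0, 100)

    def _gram(idx: np.ndarray):
        Xt, yt = X[idx], y[idx]
        m, s = Xt.mean(axis=0), Xt.std(axis=0)
        s = np.where(s > 0, s, 1.0)
        Z = (Xt - m) / s
        zc = yt - yt.mean()
        nt = len(yt)
        return Z.T @ Z / nt, Z.T @ zc / nt, m, s, yt.mean()

    C_in = np.empty((n_groups, inner_folds, p_dim, p_dim))
    b_in = np.empty((n_groups, inner_folds, p_dim))
    stats_in: list[list] = []
    inner_splits: list[np.ndarray] = []
    train_idx_of = []
    for g in range(n_groups):
        tr = np.flatnonzero(group_of != g)
        train_idx_of.append(tr)
        inner_of = np.random.default_rng(seed * 100003 + g).permuted(
            np.arange(len(tr)) % inner_folds
        )
        inner_splits.append(inner_of)
        row = []
        for k in range(inner_folds):
            C_in[g, k], b_in[g, k], m, s, ym = _gram(tr[inner_of != k])
            row.append((m, s, ym))
        stats_in.append(row)
    betas_in = _cd_path(C_in, b_in, lambdas, alpha_mix, tol=1e-7)
    mse = np.zeros((n_groups, len(lambdas)))
    for g in range(n_groups):
        tr = train_idx_of[g]
        for k in range(inner_folds):
            va = tr[inner_splits[g] == k]
            m, s, ym = stats_in[g][k]
            pred = ym + ((X[va] - m) / s) @ betas_in[g, k].T
            mse[g] += np.mean((y[va][:, None] - pred) ** 2, axis=0)
    best = np.argmin(mse, axis=1)

    C_out = np.empty((n_groups, p_dim, p_dim))
    b_out = np.empty((n_groups, p_dim))
    stats_out = []
    for g in range(n_groups):
        C_out[g], b_out[g], m, s, ym = _gram(train_idx_of[g])
        stats_out.append((m, s, ym))
    betas_out = _cd_path(C_out, b_out, lambdas, alpha_mix, tol=1e-9)
    oof = np.full(n, np.nan)
    for g in range(n_groups):
        te = group_of == g
        m, s, ym = stats_out[g]
        oof[te] = ym + ((X[te] - m) / s) @ betas_out[g, best[g]]
    r, p = stats.pearsonr(oof, y)
    return {
        "predictions": oof,
        "observed": y,
        "pearson_r": float(r),
        "p": float(p),
        "n_groups": int(n_groups),
        "group_of": group_of,
    }


def predict_matsuda(model: ElasticNetModel, table: pd.DataFrame) -> np.ndarray:
    """Deterministic linear prediction on a new cohort table."""
    return model.predict(table)


def evaluate_unrelated_subset(
    predictions: np.ndarray, truth: np.ndarray, pair_ids, seed: int = 0
) -> dict:
    """Pearson correlation on a random one-individual-per-pair subsample.

    Used for twin cohorts: picking one twin per pair removes the relatedness
    between evaluation rows.
    """
    pred = np.asarray(predictions, dtype=float)
    tru = np.asarray(truth, dtype=float)
    pairs = pd.Series(pair_ids)
    rng = np.random.default_rng(seed)
    idx = [
        int(rng.choice(members.index.to_numpy()))
        for _, members in pairs.groupby(pairs, sort=True)
    ]
    idx = np.sort(idx)
    r, p = stats.pearsonr(pred[idx], tru[idx])
    return {"pearson_r": float(r), "p": float(p), "n": len(idx), "indices": idx}
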