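"""Mitochondrial (MT) expression quantification and technical correction.

MT gene expression is the sum of TPMs over the MT-encoded genes (37 in the
standard human MT annotation).  Because MT reads make up a large share of a
library, RNA metrics computed over *all* reads (intergenic %, exonic %, ...)
are contaminated by the MT read fraction; correcting MT expression for such
metrics would strip real signal.  :func:`rna_metrics_excluding_mt` therefore
recomputes the category fractions over nuclear reads only and returns both
versions, and :func:`residualize` performs the covariate correction proper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Default technical covariates corrected for when adjusting MT expression:
#: standard RNA-seq library metrics plus genotype PCs appended separately.
DEFAULT_TECHNICAL_FACTORS = [f"tech_{j + 1:02d}" for j in range(11)]
DEFAULT_GENOTYPE_PCS = ["pc1", "pc2", "pc3"]


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionSet:
    """Gene x sample counts with gene lengths and MT flags; TPM derived.

    ``gene_meta`` is indexed by gene id with at least ``length`` (bp) and
    ``is_MT`` columns; ``counts`` shares the gene index, columns are samples.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame
    _tpm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_meta.index):
            raise ExpressionError("counts and gene_meta must share the gene index")
        for col in ("length", "is_MT"):
            if col not in self.gene_meta.columns:
                raise ExpressionError(f"gene_meta missing column {col!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ExpressionError("counts must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tpm(self) -> pd.DataFrame:
        if self._tpm is None:
            self._tpm = compute_tpm(self.counts, self.gene_meta["length"])
        return self._tpm

    def mt_expression(self) -> pd.Series:
        return mt_expression(self.tpm, self.gene_meta["is_MT"])

    def write(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def read(cls, counts_path, genes_path) -> "ExpressionSet":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        genes = pd.read_csv(genes_path, sep="\t", index_col=0)
        return cls(counts=counts, gene_meta=genes.loc[counts.index])


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from read counts and gene lengths.

    tpm[g, s] = (counts[g, s] / length_kb[g]) / sum_g(counts/length_kb) * 1e6
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ExpressionError("every gene needs a positive length")
    rate = counts.div(lengths / 1000.0, axis=0)
    depth = rate.sum(axis=0)
    zero = depth[depth == 0]
    if len(zero):
        raise ExpressionError(f"zero-depth samples: {list(zero.index)}")
    return rate.div(depth, axis=1) * 1e6


def mt_expression(tpm: pd.DataFrame, is_mt: pd.Series) -> pd.Series:
    """Per-sample MT expression: the sum of TPMs of the MT-encoded genes."""
    flags = is_mt.reindex(tpm.index).fillna(False).astype(bool)
    if not flags.any():
        raise ExpressionError("no genes flagged as MT-encoded")
    out = tpm.loc[flags].sum(axis=0)
    out.name = "mt_expression"
    return out


READ_CATEGORIES = ["exonic", "intronic", "intergenic"]


def rna_metrics_excluding_mt(read_counts: pd.DataFrame) -> pd.DataFrame:
    """Read-category fractions with and without MT-read contamination.

    Expects per-sample columns ``reads_total``, ``reads_mt`` and
    ``reads_<category>`` for exonic/intronic/intergenic nuclear reads.
    "Biased" fractions divide by all aligned reads (so they co-vary with the
    MT read fraction); "unbiased" fractions remove MT reads from the
    denominator and reflect only nuclear-genome behaviour.
    """
    rc = read_counts
    needed = ["reads_total", "reads_mt"] + [f"reads_{c}" for c in READ_CATEGORIES]
    missing = [c for c in needed if c not in rc.columns]
    if missing:
        raise ExpressionError(f"read-count table missing columns: {missing}")
    if (rc["reads_mt"] > rc["reads_total"]).any():
        raise ExpressionError("mt reads exceed total aligned reads")
    nuclear = rc["reads_total"] - rc["reads_mt"]
    if (nuclear <= 0).any():
        bad = rc.index[nuclear <= 0].tolist()
        raise ExpressionError(f"samples with no nuclear reads: {bad}")
    out = pd.DataFrame(index=rc.index)
    out["mt_read_pct"] = 100.0 * rc["reads_mt"] / rc["reads_total"]
    for cat in READ_CATEGORIES:
        out[f"{cat}_pct_biased"] = 100.0 * rc[f"reads_{cat}"] / rc["reads_total"]
        out[f"{cat}_pct"] = 100.0 * rc[f"reads_{cat}"] / nuclear
    return out


def inverse_normal_transform(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps rank r (average rank on ties) to Phi^{-1}((r - c) / (n - 2c + 1)).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ExpressionError("need a 1-d array with at least 2 values")
    if np.all(x == x[0]):
        raise ExpressionError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(x, method="average")
    n = len(x)
    return stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))


def residualize(y, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of y on the covariates (intercept added).

    Raises on rank deficiency, naming the collinear columns.
    """
    yv = np.asarray(y, dtype=float)
    C = covariates.to_numpy(dtype=float)
    if len(yv) != len(C):
        raise ExpressionError("y and covariates must have equal length")
    X = np.column_stack([np.ones(len(yv)), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns via the QR diagonal.
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = diag < 1e-10 * diag.max()
        names = ["<intercept>"] + list(covariates.columns)
        collinear = [names[i] for i in np.flatnonzero(bad)]
        raise ExpressionError(f"collinear covariates: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    return yv - X @ beta


def adjust_mt_expression(
    mt: pd.Series,
    technical: pd.DataFrame,
    factors: list[str] | None = None,
    pcs: list[str] | None = None,
    transform: bool = True,
) -> pd.Series:
    """Correct MT expression for technical factors and genotype PCs.

    Optionally inverse-normal transforms the corrected values (the scale on
    which downstream association models operate).
    """
    factors = DEFAULT_TECHNICAL_FACTORS if factors is None else factors
    pcs = DEFAULT_GENOTYPE_PCS if pcs is None else pcs
    cols = [c for c in factors + pcs if c in technical.columns]
    missing = [c for c in factors + pcs if c not in technical.columns]
    if missing:
        warnings.warn(f"technical covariates not found, skipped: {missing}", stacklevel=2)
    resid = residualize(mt.to_numpy(), technical[cols])
    if transform:
        resid = inverse_normal_transform(resid)
    return pd.Series(resid, index=mt.index, name="mt_expression_adjusted")


def group_difference_test(values, group_labels) -> dict:
    """Welch two-sample t-test between exactly two groups."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ExpressionError(f"need exactly 2 groups, got {len(levels)}")
    a, b = v[g == levels[0]], v[g == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ExpressionError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "group_means": {str(levels[0]): float(a.mean()), str(levels[1]): float(b.mean())},
        "group_n": {str(levels[0]): int(len(a)), str(levels[1]): int(len(b))},
    }
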