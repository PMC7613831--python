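"""Differential expression on bulk RNA-seq counts and cross-model concordance.

The engine is a deliberately transparent negative-binomial Wald test:
median-of-ratios size factors, within-group method-of-moments dispersion,
log2 fold change of normalized group means with a delta-method standard error
from the NB variance mu + alpha*mu^2, and Benjamini-Hochberg adjustment.
It forgoes dispersion shrinkage and outlier refitting: the downstream
contracts (type-I error control, planted-effect recovery, threshold logic)
do not depend on them.

Differentially expressed genes (DEGs) are called at absolute fold change
>= 1.3 (inclusive) and adjusted p < 0.05 (strict). "Concordant" DEGs are
genes differential in the same direction in both rat models for the same
contrast; a disease-altered gene is "corrected" by treatment when the
treatment contrast shows opposite-direction differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
DEFAULT_FC = 1.3
DEFAULT_ALPHA = 0.05

GROUPS = ("healthy", "SHAM", "DMT")


@dataclass
class CountMatrix:
    """Gene-level counts (genes x samples) with per-sample group/model labels."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    metadata: pd.DataFrame  # index = sample ids; columns include 'group', 'model'

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not set(self.counts.columns) <= set(self.metadata.index):
            missing = set(self.counts.columns) - set(self.metadata.index)
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be nonnegative integers")
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def groups(self) -> pd.Series:
        return self.metadata["group"]


@dataclass
class DEGSet:
    """Genes passing the DEG thresholds for one contrast, with direction."""

    contrast: str
    directions: dict[str, str]  # gene id -> 'up' | 'down'
    fc: float = DEFAULT_FC
    alpha: float = DEFAULT_ALPHA

    @property
    def genes(self) -> set[str]:
        return set(self.directions)

    def __len__(self) -> int:
        return len(self.directions)


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over genes i (with positive geometric mean across samples)
    of k_ij / geomean_i. Genes containing any zero are excluded from the
    reference, as their geometric mean is zero.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(arr)
    finite = np.isfinite(log).all(axis=1)
    if not finite.any():
        raise ValueError("no gene has positive counts in all samples")
    log_geomean = log[finite].mean(axis=1)
    factors = np.exp(np.median(log[finite] - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def estimate_dispersion(
    counts: CountMatrix, size_factors: pd.Series, floor: float = DISPERSION_FLOOR
) -> pd.Series:
    """Per-gene NB dispersion by the within-group method of moments.

    On normalized counts q = k/s, each group contributes
    alpha_g = (var_g - mean_g) / mean_g^2; groups are pooled by a
    degrees-of-freedom-weighted average and floored at a small positive value.
    """
    groups = counts.groups()
    sizes = groups.value_counts()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {bad}")
    norm = counts.counts.to_numpy(dtype=float) / size_factors.loc[counts.sample_ids].to_numpy()
    alphas = np.zeros(norm.shape[0])
    total_df = 0
    for g in sizes.index:
        cols = (groups == g).to_numpy()
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        df = cols.sum() - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        alphas += df * a
        total_df += df
    alphas = np.maximum(alphas / total_df, floor)
    return pd.Series(alphas, index=counts.gene_ids, name="dispersion")


def wald_test(
    counts: CountMatrix,
    contrast: tuple[str, str],
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test for ``contrast = (numerator, denominator)``.

    Returns a DEResult frame (gene, baseMean, log2FC, SE, stat, p, padj).
    log2FC is log2 of the ratio of normalized group means; the Wald z uses a
    delta-method SE built from the NB variance mu + alpha*mu^2 propagated
    through the per-sample size factors. All-zero genes are reported with
    log2FC=0, p=1 and flagged in the 'allzero' column.
    """
    num, den = contrast
    groups = counts.groups()
    for g in (num, den):
        if (groups == g).sum() < 2:
            raise ValueError(f"contrast group {g!r} absent or has <2 samples")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, size_factors)

    sf = size_factors.loc[counts.sample_ids].to_numpy()
    norm = counts.counts.to_numpy(dtype=float) / sf
    alpha = dispersions.loc[counts.gene_ids].to_numpy()

    def group_stats(label: str) -> tuple[np.ndarray, np.ndarray]:
        cols = (groups == label).to_numpy()
        mu = norm[:, cols].mean(axis=1)
        # Var(mean of k_j/s_j) with k_j ~ NB(s_j*mu, alpha):
        # Var(k_j/s_j) = mu/s_j + alpha*mu^2, averaged over n^2.
        n = cols.sum()
        var = (mu[:, None] / sf[None, cols] + alpha[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
        return mu, var

    mu_num, var_num = group_stats(num)
    mu_den, var_den = group_stats(den)

    allzero = (mu_num == 0) & (mu_den == 0)
    onezero = ((mu_num == 0) | (mu_den == 0)) & ~allzero
    # Half-minimum pseudo-mean keeps single-side zeros finite without
    # perturbing genes observed in both groups.
    eps = 0.5 / sf.mean() / max(1, (groups == num).sum())
    safe_num = np.where(mu_num == 0, eps, mu_num)
    safe_den = np.where(mu_den == 0, eps, mu_den)

    log2fc = np.where(allzero, 0.0, np.log2(safe_num / safe_den))
    ln2 = np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_num / safe_num**2 + var_den / safe_den**2) / ln2
    se = np.where(allzero | (se == 0), np.nan, se)
    stat = np.where(np.isnan(se), 0.0, log2fc / np.where(np.isnan(se), 1.0, se))
    # The SE rests on plug-in moment estimates whose residual df is
    # n_samples - n_groups (the dispersion pooling df); a Student-t reference
    # with that df keeps the small-sample type-I error at its nominal level,
    # converging to the usual normal Wald p as replication grows.
    df_resid = max(1, len(counts.sample_ids) - groups.nunique())
    p = np.where(np.isnan(se) & ~onezero, 1.0, 2.0 * stats.t.sf(np.abs(stat), df_resid))
    p = np.where(allzero, 1.0, np.clip(p, 0.0, 1.0))

    res = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FC": log2fc,
            "SE": se,
            "stat": stat,
            "p": p,
            "padj": adjust_bh(p),
            "allzero": allzero,
        },
        index=pd.Index(counts.gene_ids, name="gene"),
    )
    res.attrs["contrast"] = f"{num}_vs_{den}"
    return res


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_degs(
    de: pd.DataFrame, fc: float = DEFAULT_FC, alpha: float = DEFAULT_ALPHA
) -> DEGSet:
    """Threshold a DEResult into a DEGSet.

    Inclusion requires |log2FC| >= log2(fc) (boundary inclusive) and
    padj < alpha (strict); direction is the sign of log2FC.
    """
    lfc_cut = np.log2(fc)
    hits = de[(de["log2FC"].abs() >= lfc_cut) & (de["padj"] < alpha)]
    directions = {
        str(g): ("up" if l > 0 else "down") for g, l in hits["log2FC"].items()
    }
    return DEGSet(contrast=de.attrs.get("contrast", ""), directions=directions, fc=fc, alpha=alpha)


def concordant_degs(a: DEGSet, b: DEGSet) -> DEGSet:
    """Genes differential in both sets with equal direction."""
    shared = {
        g: d for g, d in a.directions.items() if b.directions.get(g) == d
    }
    return DEGSet(contrast=f"concordant({a.contrast},{b.contrast})", directions=shared,
                  fc=a.fc, alpha=a.alpha)


def _round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching how the study prints percentages."""
    factor = 10**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def corrected_fraction(
    disease_degs: DEGSet, treatment_degs: DEGSet, *, any_direction: bool = False
) -> tuple[int, float]:
    """Count and percentage of disease-altered genes corrected by treatment.

    A disease DEG (SHAM vs healthy) counts as corrected when it appears in
    the treatment contrast (DMT vs SHAM) with the opposite direction; set
    ``any_direction=True`` to count any treatment DE regardless of direction.
    """
    if len(disease_degs) == 0:
        raise ValueError("disease DEG set is empty; corrected percentage undefined")
    opposite = {"up": "down", "down": "up"}
    n = 0
    for g, d in disease_degs.directions.items():
        td = treatment_degs.directions.get(g)
        if td is None:
            continue
        if any_direction or td == opposite[d]:
            n += 1
    pct = _round_half_away(100.0 * n / len(disease_degs), 1)
    return n, pct


def rlog_like_transform(
    counts: CountMatrix | pd.DataFrame, size_factors: pd.Series
) -> pd.DataFrame:
    """Variance-stabilizing log transform log2(k/s + 1) of normalized counts."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(mat / size_factors.loc[mat.columns] + 1.0)


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA by SVD of the column-centered samples x features matrix.

    Returns (scores, loadings, variance fractions). The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        warnings.warn("constant matrix: all principal components have zero variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=matrix.index, columns=cols)
    loadings = pd.DataFrame(Vt[:k].T, index=matrix.columns, columns=cols)
    return scores, loadings, frac[:k]
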