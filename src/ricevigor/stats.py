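"""Trait-level statistics: correlation, regression, ANOVA, PCA, ranking.

The published tables report genotype means (n = 7 genotypes), so the
correlation/regression layer operates on genotype-mean vectors by default;
replicate-level vectors work identically.  One-way fixed-effects ANOVA is
available both from raw replicate vectors and from mean ± SE summaries
(SD = SE·√n), matching how the printed tables can be re-analysed without
the unpublished replicate data.  Significance coding follows the tables'
footnote: ** for p < 0.001, * for p < 0.05, NS otherwise.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateStatisticError, ValidationError
from .io import TraitTable

#: Significance thresholds from the trait-table footnotes.
P_STAR = 0.05
P_DOUBLE_STAR = 0.001


@dataclass(frozen=True)
class StatResult:
    """Pearson correlation and simple-regression parameters."""

    r: float
    r_squared: float
    slope: float
    intercept: float
    n: int


class SignifCode(str, enum.Enum):
    NS = "NS"
    STAR = "*"
    DOUBLE_STAR = "**"


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    code: SignifCode
    df_between: int
    df_within: int


@dataclass(frozen=True)
class PcaResult:
    variance_fraction: np.ndarray  # per-component, sums to 1
    loadings: np.ndarray  # traits × components, orthonormal columns
    scores: np.ndarray  # rows × components
    trait_names: tuple
    row_labels: tuple


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValidationError(f"need ≥ 3 complete pairs, have {len(x)}")
    return x, y


def pearson_r(x, y) -> StatResult:
    """Product-moment correlation with pairwise-complete NA handling."""
    x, y = _pairwise_complete(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("correlation undefined: zero variance")
    r = float(sps.pearsonr(x, y).statistic)
    fit = sps.linregress(x, y)
    return StatResult(
        r=r, r_squared=r * r, slope=float(fit.slope),
        intercept=float(fit.intercept), n=len(x),
    )


def linear_regression(x, y) -> StatResult:
    """Least-squares simple regression of y on x (same NA handling)."""
    return pearson_r(x, y)


def significance_code(p_value: float) -> SignifCode:
    if p_value < P_DOUBLE_STAR:
        return SignifCode.DOUBLE_STAR
    if p_value < P_STAR:
        return SignifCode.STAR
    return SignifCode.NS


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from raw replicate vectors."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need ≥ 2 groups with ≥ 2 replicates each")
    means = [g.mean() for g in groups]
    ses = [g.std(ddof=1) / np.sqrt(len(g)) for g in groups]
    return anova_from_summary(means, ses, [len(g) for g in groups])


def anova_from_summary(means, ses, n) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group mean ± SE and n.

    Within-group sums of squares are recovered via SD = SE·√n, so the
    result is identical to ANOVA on any raw data with these summaries.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = len(means)
    ns = np.full(k, n, dtype=float) if np.isscalar(n) else np.asarray(n, dtype=float)
    if k < 2 or np.any(ns < 2):
        raise ValidationError("need ≥ 2 groups with ≥ 2 replicates each")
    total_n = ns.sum()
    grand = (ns * means).sum() / total_n
    ss_between = float((ns * (means - grand) ** 2).sum())
    sds = ses * np.sqrt(ns)
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = int(total_n - k)
    if ss_within == 0:
        if ss_between == 0:
            raise DegenerateStatisticError(
                "F undefined: zero variance both between and within groups"
            )
        return AnovaResult(
            f_stat=float("inf"), p_value=0.0, code=SignifCode.DOUBLE_STAR,
            df_between=df_between, df_within=df_within,
        )
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_stat=float(f), p_value=p, code=significance_code(p),
        df_between=df_between, df_within=df_within,
    )


class PcaScaling(str, enum.Enum):
    COVARIANCE = "covariance"
    CORRELATION = "correlation"


def pca(table: TraitTable, scaling=PcaScaling.COVARIANCE) -> PcaResult:
    """Principal components of a genotype × trait matrix.

    Eigendecomposition of the covariance (default, on unscaled means) or
    correlation matrix of the traits.  Components are ordered by decreasing
    variance; each loading column is signed so its largest-magnitude entry
    is positive.  Trait columns that are entirely NA are dropped with a
    warning; any remaining NA is an error.
    """
    scaling = PcaScaling(scaling)
    frame = table.data
    all_na = [c for c in frame.columns if frame[c].isna().all()]
    if all_na:
        warnings.warn(
            f"dropping all-NA trait column(s): {', '.join(map(str, all_na))}",
            stacklevel=2,
        )
        frame = frame.drop(columns=all_na)
    if frame.isna().any().any():
        raise ValidationError("PCA requires a complete numeric matrix")
    if len(frame) < 2:
        raise ValidationError("PCA needs at least 2 rows")
    x = frame.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    if scaling is PcaScaling.CORRELATION:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateStatisticError(
                "correlation-scaled PCA undefined for constant trait columns"
            )
        xc = xc / sd
    cov = (xc.T @ xc) / (len(x) - 1)
    if not np.any(cov):
        raise DegenerateStatisticError("PCA undefined: matrix has no variance")
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    return PcaResult(
        variance_fraction=eigval / eigval.sum(),
        loadings=eigvec,
        scores=xc @ eigvec,
        trait_names=tuple(frame.columns),
        row_labels=tuple(frame.index),
    )


def rank_genotypes(table: TraitTable, trait: str, descending: bool = True) -> list:
    """Genotypes ordered by one trait; ties broken by label order (stable)."""
    col = table.column(trait).dropna()
    pairs = sorted(
        col.items(),
        key=lambda kv: (-kv[1] if descending else kv[1], str(kv[0])),
    )
    return [label for label, _ in pairs]
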