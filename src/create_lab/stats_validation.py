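"""Statistical validation pipeline.

Components: listwise +/-2 SD outlier filtering, a permutation-based
Spearman correlation matrix with empirical p-values (plain proportion of
permuted |rho| >= observed |rho| over 2000 label permutations by default),
exact/approximate Mann-Whitney U group comparisons, and a single-predictor
OLS fit with the full diagnostic report (R^2, F, AIC/BIC, Durbin-Watson,
omnibus and Jarque-Bera normality checks, residual skew/kurtosis, design
condition number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "OutlierReport",
    "CorrelationResult",
    "GroupComparison",
    "RegressionReport",
    "filter_outliers",
    "spearman_rho",
    "permutation_correlation_matrix",
    "mann_whitney",
    "durbin_watson",
    "ols_fit",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Outlier filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierReport:
    excluded: dict[object, list[str]]  # row id -> offending variables
    bounds: dict[str, tuple[float, float]]
    n_before: int
    n_after: int


def filter_outliers(table: pd.DataFrame, k: float = 2.0) -> tuple[pd.DataFrame, OutlierReport]:
    """Listwise-exclude rows with any value strictly outside mean +/- k*SD.

    Bounds use the sample SD (ddof=1) of each numeric column, computed on
    the incoming table.  Zero-variance columns collapse to inclusive
    bounds at the mean, so equal values are retained.  Missing cells never
    trigger exclusion.
    """
    if k <= 0:
        raise ValidationError("k must be > 0")
    if len(table) < 3:
        raise ValidationError("need at least 3 rows to estimate outlier bounds")
    numeric = table.select_dtypes(include=[np.number])
    bounds: dict[str, tuple[float, float]] = {}
    offending: dict[object, list[str]] = {}
    for col in numeric.columns:
        series = numeric[col]
        mu = series.mean()
        sd = series.std(ddof=1)
        if not np.isfinite(sd):
            sd = 0.0
        lo, hi = mu - k * sd, mu + k * sd
        bounds[col] = (lo, hi)
        out = series[(series < lo) | (series > hi)]
        for idx in out.index:
            offending.setdefault(idx, []).append(col)
    keep = table.index[~table.index.isin(offending)]
    filtered = table.loc[keep]
    report = OutlierReport(
        excluded={idx: offending[idx] for idx in table.index if idx in offending},
        bounds=bounds,
        n_before=len(table),
        n_after=len(filtered),
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Spearman correlation + permutation inference
# ---------------------------------------------------------------------------

def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of mid-ranks; NaN if either rank vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-D samples")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance; correlation undefined", stacklevel=2)
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@dataclass(frozen=True)
class CorrelationResult:
    rho: pd.DataFrame
    p_empirical: pd.DataFrame
    mask: pd.DataFrame  # True where p < alpha
    n_perm: int
    alpha: float
    seed: int
    n_pairs: pd.DataFrame = field(default=None, repr=False)  # complete cases per pair

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, rho, p, significant), upper triangle."""
        cols = list(self.rho.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p_empirical.loc[a, b],
                        "significant": bool(self.mask.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def _permutation_p(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed rho and empirical two-sided p for one complete-case pair."""
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance; correlation undefined", stacklevel=3)
        return float("nan"), float("nan")
    zx = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    zy = (ry - ry.mean()) / np.sqrt(np.sum((ry - ry.mean()) ** 2))
    rho_obs = float(zx @ zy)
    perm = rng.permuted(np.tile(zy, (n_perm, 1)), axis=1)
    rho_perm = perm @ zx
    p = float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - _EPS))
    return rho_obs, p


def permutation_correlation_matrix(
    table: pd.DataFrame,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    smoothing: bool = False,
) -> CorrelationResult:
    """Pairwise Spearman matrix with label-permutation empirical p-values.

    For each variable pair, one variable is randomly permuted ``n_perm``
    times and p is the proportion of permuted correlations whose magnitude
    meets or exceeds the observed magnitude.  Missing cells are handled
    pairwise-complete; pairs with fewer than 3 complete cases (or constant
    ranks) are reported as NaN.  ``smoothing`` switches to the
    (count+1)/(n_perm+1) estimator.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0,1)")
    numeric = table.select_dtypes(include=[np.number])
    cols = list(numeric.columns)
    if len(set(cols)) != len(cols):
        raise ValidationError("column names must be unique")
    k = len(cols)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    npairs = np.full((k, k), len(numeric))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            pair = numeric[[cols[i], cols[j]]].dropna()
            npairs[i, j] = npairs[j, i] = len(pair)
            if len(pair) < 3:
                r, p = float("nan"), float("nan")
            else:
                r, p = _permutation_p(
                    pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy(), n_perm, rng
                )
                if smoothing and np.isfinite(p):
                    p = (p * n_perm + 1) / (n_perm + 1)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pmat, index=cols, columns=cols)
    np.fill_diagonal(p_df.values, 0.0)
    mask = (p_df < alpha) & np.isfinite(rho_df)
    np.fill_diagonal(mask.values, False)
    return CorrelationResult(
        rho=rho_df,
        p_empirical=p_df,
        mask=mask,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        n_pairs=pd.DataFrame(npairs, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    n1: int
    n2: int
    u_statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"

    def as_dict(self) -> dict[str, object]:
        return {
            "variable": self.variable,
            "n1": self.n1,
            "n2": self.n2,
            "u_statistic": self.u_statistic,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
        }


def _u_count_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of arrangements per U value (no ties), by the classic recursion."""
    # DP over (m, n): c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u)
    max_u = n1 * n2
    table = np.zeros((n1 + 1, n2 + 1, max_u + 1))
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for m in range(1, n1 + 1):
        for n in range(1, n2 + 1):
            for u in range(max_u + 1):
                val = table[m, n - 1, u]
                if u - n >= 0:
                    val += table[m - 1, n, u - n]
                table[m, n, u] = val
    return table[n1, n2, : n1 * n2 + 1]


def mann_whitney(a: Sequence[float], b: Sequence[float], variable: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact p by full null enumeration (distribution of U over all rank
    assignments) when there are no ties and ``n1*n2 <= 400``; otherwise a
    normal approximation with tie and continuity corrections.  The
    two-sided exact p is P(|U - n1*n2/2| >= |u_obs - n1*n2/2|).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups need at least one observation")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _rank(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    has_ties = len(np.unique(combined)) < combined.size

    if not has_ties and n1 * n2 <= 400:
        counts = _u_count_distribution(n1, n2)
        total = counts.sum()
        dev = abs(u1 - mu)
        u_values = np.arange(counts.size)
        p = float(counts[np.abs(u_values - mu) >= dev - _EPS].sum() / total)
        method = "exact"
    else:
        _, tie_counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        method = "normal-approximation"
    return GroupComparison(
        variable=variable, n1=n1, n2=n2, u_statistic=float(u1), p_two_sided=p, method=method
    )


# ---------------------------------------------------------------------------
# OLS regression report
# ---------------------------------------------------------------------------

def durbin_watson(residuals: Sequence[float]) -> float:
    """Sum of squared successive residual differences over the residual SS."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValidationError("need at least 2 residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ValidationError("zero residual sum of squares")
    return float(np.sum(np.diff(e) ** 2) / denom)


@dataclass(frozen=True)
class RegressionReport:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_t: float
    slope_t: float
    intercept_p: float
    slope_p: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    prob_f: float
    aic: float
    bic: float
    durbin_watson: float
    omnibus: float
    prob_omnibus: float
    jarque_bera: float
    prob_jarque_bera: float
    skewness: float
    kurtosis: float
    condition_number: float
    n_obs: int
    residuals: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict[str, object]:
        d = {
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_statistic": self.f_statistic,
            "prob_f": self.prob_f,
            "aic": self.aic,
            "bic": self.bic,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_t": self.intercept_t,
            "intercept_p": self.intercept_p,
            "intercept_ci": list(self.intercept_ci),
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_t": self.slope_t,
            "slope_p": self.slope_p,
            "slope_ci": list(self.slope_ci),
            "durbin_watson": self.durbin_watson,
            "omnibus": self.omnibus,
            "prob_omnibus": self.prob_omnibus,
            "jarque_bera": self.jarque_bera,
            "prob_jarque_bera": self.prob_jarque_bera,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "condition_number": self.condition_number,
        }
        return d


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionReport:
    """Least-squares fit of y on x with intercept plus the diagnostic suite.

    The omnibus normality statistic is the D'Agostino-Pearson K^2 on the
    residuals (NaN when n < 8, where the test is undefined); the condition
    number comes from the singular values of the raw design matrix
    including the intercept column.
    """
    import statsmodels.api as sm
    from statsmodels.stats.stattools import jarque_bera as _jb

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise ValidationError("need at least 4 complete pairs")
    if np.ptp(x) == 0:
        raise ValidationError("constant predictor: design matrix is rank deficient")
    exog = sm.add_constant(x)
    res = sm.OLS(y, exog).fit()
    resid = np.asarray(res.resid)
    if resid.size >= 8:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            omni, omni_p = stats.normaltest(resid)
    else:
        omni, omni_p = float("nan"), float("nan")
    jb, jb_p, skew, kurt = _jb(resid)
    ci = res.conf_int(alpha=0.05)
    return RegressionReport(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        intercept_t=float(res.tvalues[0]),
        slope_t=float(res.tvalues[1]),
        intercept_p=float(res.pvalues[0]),
        slope_p=float(res.pvalues[1]),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        prob_f=float(res.f_pvalue),
        aic=float(res.aic),
        bic=float(res.bic),
        durbin_watson=durbin_watson(resid),
        omnibus=float(omni),
        prob_omnibus=float(omni_p),
        jarque_bera=float(jb),
        prob_jarque_bera=float(jb_p),
        skewness=float(skew),
        kurtosis=float(kurt),
        condition_number=float(np.linalg.cond(exog)),
        n_obs=int(res.nobs),
        residuals=resid,
    )


def plot_correlation_heatmap(result: CorrelationResult, path) -> None:
    """Optional triangle heatmap: rho below the diagonal, p above,
    annotated for significant cells only.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = list(result.rho.columns)
    k = len(cols)
    display = np.full((k, k), np.nan)
    annot = np.full((k, k), "", dtype=object)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if not result.mask.iloc[i, j]:
                continue
            if i > j:  # lower triangle: rho
                display[i, j] = result.rho.iloc[i, j]
                annot[i, j] = f"{result.rho.iloc[i, j]:.2f}"
            else:  # upper triangle: p
                display[i, j] = result.rho.iloc[i, j]
                annot[i, j] = f"{result.p_empirical.iloc[i, j]:.3f}"
    fig, ax = plt.subplots(figsize=(max(6, k * 0.6), max(5, k * 0.5)))
    im = ax.imshow(display, vmin=-1, vmax=1, cmap="coolwarm")
    for i in range(k):
        for j in range(k):
            if annot[i, j]:
                ax.text(j, i, annot[i, j], ha="center", va="center", fontsize=7)
    ax.set_xticks(range(k), cols, rotation=90, fontsize=7)
    ax.set_yticks(range(k), cols, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
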