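"""Statistical inference layer.

Mixed two-way ANOVA (between = feedback condition, within = phase/block)
with Mauchly's sphericity test and Greenhouse–Geisser correction, Holm
post hocs, pooled-variance t-test, Lasso with 5-fold cross-validation and
the one-standard-error rule followed by a final OLS refit on the selected
raw-scale regressors, and fixed-model multiple-regression power analysis
based on the noncentral F distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import Lasso, LinearRegression, lasso_path
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: EEG feature columns of the cohort table, in design order
EEG_FEATURES = (
    "frn_early",
    "frn_late",
    "alpha_erd_early",
    "alpha_erd_late",
    "beta_erd_early",
    "beta_erd_late",
)


# ---------------------------------------------------------------------------
# ANOVA and sphericity
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    epsilon_gg: float | None = None
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_corrected: bool = False


@dataclass
class MauchlyGG:
    W: float
    chi2: float
    df: int
    p: float
    epsilon_gg: float


def mauchly_gg(within_data: np.ndarray, groups: Sequence | None = None) -> MauchlyGG:
    """Mauchly's sphericity test and Greenhouse–Geisser epsilon.

    ``within_data`` is participants × levels. If ``groups`` is given the
    level covariance is pooled within groups (the mixed-design variant);
    otherwise rows are centered on the grand level means. With two levels
    there is a single difference variance, so W = 1 and epsilon = 1.
    """
    Y = np.asarray(within_data, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("within_data must be participants x levels with >= 2 levels")
    n, k = Y.shape
    d = k - 1
    if k == 2:
        return MauchlyGG(W=1.0, chi2=0.0, df=0, p=1.0, epsilon_gg=1.0)

    if groups is not None:
        g = np.asarray(groups)
        centered = Y.copy()
        n_groups = 0
        for lvl in np.unique(g):
            m = g == lvl
            centered[m] -= Y[m].mean(axis=0)
            n_groups += 1
        n_eff = n - n_groups
    else:
        centered = Y - Y.mean(axis=0)
        n_eff = n - 1
    S = centered.T @ centered / n_eff  # k x k pooled level covariance

    # orthonormal contrast (Helmert) representation
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, :d].T  # d x k, rows orthonormal
    D = C @ S @ C.T
    eig = np.linalg.eigvalsh(D)
    eig = np.clip(eig, 0.0, None)

    tr = eig.sum()
    if tr <= 0:
        raise ValueError("degenerate (zero) within-subject covariance")
    det = np.prod(eig)
    W = float(det / (tr / d) ** d) if det > 0 else 0.0

    eps = float(tr**2 / (d * (eig**2).sum()))
    eps = min(1.0, max(eps, 1.0 / d))

    df_chi = d * (d + 1) // 2 - 1
    c = (2 * d**2 + d + 2) / (6.0 * d)
    if W > 0:
        chi2 = float(-(n_eff - c) * np.log(W))
        p = float(sps.chi2.sf(chi2, df_chi))
    else:
        chi2, p = np.inf, 0.0
    return MauchlyGG(W=W, chi2=chi2, df=df_chi, p=p, epsilon_gg=eps)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    sphericity_alpha: float = 0.05,
) -> dict[str, AnovaResult]:
    """Two-way mixed ANOVA with GG correction when sphericity is violated.

    Participants missing any within level are dropped listwise (logged).
    The Greenhouse–Geisser correction is applied to the within and
    interaction effects when the within factor has more than two levels
    and Mauchly's test rejects at ``sphericity_alpha``.
    """
    df = data[[subject, within, between, dv]].dropna()
    k = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == k].index
    dropped = counts.size - complete.size
    if dropped:
        logger.info("mixed_anova: dropped %d participants missing within levels", dropped)
    df = df[df[subject].isin(complete)]

    if df[dv].nunique() == 1:
        # degenerate data: no variance anywhere -> every F is zero
        k_lv = df[within].nunique()
        n_s = df[subject].nunique()
        g_n = df[between].nunique()
        zero = lambda eff, d1, d2: AnovaResult(  # noqa: E731
            effect=eff, F=0.0, df1=d1, df2=d2, p=1.0,
            epsilon_gg=None if eff == "between" else 1.0,
        )
        return {
            "between": zero("between", g_n - 1, n_s - g_n),
            "within": zero("within", k_lv - 1, (n_s - g_n) * (k_lv - 1)),
            "interaction": zero("interaction", (g_n - 1) * (k_lv - 1), (n_s - g_n) * (k_lv - 1)),
        }

    aov = pg.mixed_anova(df, dv=dv, within=within, between=between, subject=subject, correction=False)
    aov = aov.set_index("Source")

    wide = df.pivot_table(index=subject, columns=within, values=dv)
    grp = df.groupby(subject)[between].first().loc[wide.index]
    sph = mauchly_gg(wide.to_numpy(), groups=grp.to_numpy()) if k > 2 else mauchly_gg(
        np.zeros((max(3, wide.shape[0]), 2))
    )
    correct = k > 2 and sph.p < sphericity_alpha

    def build(source: str, effect: str, corrected: bool) -> AnovaResult:
        row = aov.loc[source]
        F = float(row["F"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        eps = sph.epsilon_gg if effect != "between" else None
        if corrected:
            df1, df2 = eps * df1, eps * df2
            p = float(sps.f.sf(F, df1, df2))
        return AnovaResult(
            effect=effect,
            F=F,
            df1=df1,
            df2=df2,
            p=p,
            epsilon_gg=eps,
            mauchly_w=sph.W if effect != "between" else None,
            mauchly_p=sph.p if effect != "between" else None,
            gg_corrected=corrected,
        )

    sources = list(aov.index)
    between_src = sources[0]
    within_src = sources[1]
    return {
        "between": build(between_src, "between", False),
        "within": build(within_src, "within", correct),
        "interaction": build("Interaction", "interaction", correct),
    }


def posthoc_holm(contrasts: Sequence[tuple[np.ndarray, np.ndarray, bool]]) -> list[dict]:
    """Pairwise t-tests with Bonferroni–Holm step-down correction.

    Each contrast is ``(x, y, paired)``. Returns one dict per contrast with
    t, df, raw and Holm-adjusted p.
    """
    if len(contrasts) == 0:
        raise ValueError("need at least one contrast")
    rows = []
    for x, y, paired in contrasts:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if paired:
            res = sps.ttest_rel(x, y)
            df = x.size - 1
        else:
            res = sps.ttest_ind(x, y, equal_var=True)
            df = x.size + y.size - 2
        rows.append({"t": float(res.statistic), "df": df, "p_raw": float(res.pvalue)})
    adj = multipletests([r["p_raw"] for r in rows], method="holm")[1]
    for r, a in zip(rows, adj):
        r["p_holm"] = float(a)
    return rows


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, float), method="holm")[1]


def independent_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test: returns (t, df, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t undefined")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), int(x.size + y.size - 2), float(res.pvalue)


# ---------------------------------------------------------------------------
# Lasso → OLS chain
# ---------------------------------------------------------------------------

@dataclass
class LassoResult:
    lambda_grid: np.ndarray  # descending
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected: list[str]
    coef_1se: np.ndarray  # on the standardized scale
    feature_names: list[str]
    fold_seed: int


def _validate_design(X: np.ndarray, y: np.ndarray) -> None:
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the design or outcome")


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coordinate-descent solution of (1/2n)·||y − Xb||² + lam·||b||₁.

    Expects a standardized design and centered outcome (no intercept fit).
    """
    X, y = np.asarray(X, float), np.asarray(y, float)
    _validate_design(X, y)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant column in the design after standardization")
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0:
        return LinearRegression(fit_intercept=False).fit(X, y).coef_
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=200_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero: max|Xᵀy|/n."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / X.shape[0])


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd_safe


def cv_1se(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    n_lambda: int = 100,
) -> LassoResult:
    """Lasso penalty selection by k-fold cross-validation and the 1SE rule.

    Predictors are z-standardized (training-fold statistics inside CV, full
    sample for the final fit); the outcome is centered. ``lambda_1se`` is
    the largest penalty whose CV error is within one standard error of the
    minimum; the selected set is the support of the full-sample fit there.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _validate_design(X, y)
    n, p = X.shape
    if n < k:
        raise ValueError("fewer observations than folds")
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]

    Xs_full, _, _ = _standardize_train(X)
    yc_full = y - y.mean()
    if lambda_grid is None:
        lmax = np.max(np.abs(Xs_full.T @ yc_full)) / n
        lambda_grid = np.logspace(np.log10(lmax), np.log10(lmax * 1e-3), n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    fold_seed = seed
    for attempt in range(10):
        kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
        splits = list(kf.split(X))
        if all(np.std(y[tr]) > 0 for tr, _ in splits):
            break
        logger.info("cv_1se: degenerate fold with seed %d, refolding", fold_seed)
        fold_seed += 1
    else:
        raise ValueError("could not build non-degenerate folds")

    fold_mse = np.empty((k, lambda_grid.size))
    for fi, (tr, va) in enumerate(splits):
        Xtr, mu, sd = _standardize_train(X[tr])
        ybar = y[tr].mean()
        Xva = (X[va] - mu) / sd
        _, coefs, _ = lasso_path(Xtr, y[tr] - ybar, alphas=lambda_grid, max_iter=200_000, tol=1e-10)
        pred = Xva @ coefs + ybar  # (n_va, n_lambda)
        fold_mse[fi] = ((y[va][:, None] - pred) ** 2).mean(axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)

    i_min = int(np.argmin(cv_mean))
    thresh = cv_mean[i_min] + cv_se[i_min]
    ok = np.where(cv_mean <= thresh)[0]
    i_1se = int(ok.min())  # grid is descending, so the first index is the largest lambda
    lam_min, lam_1se = float(lambda_grid[i_min]), float(lambda_grid[i_1se])

    coef = lasso_fit(Xs_full, yc_full, lam_1se)
    selected = [names[j] for j in np.flatnonzero(np.abs(coef) > 1e-10)]
    return LassoResult(
        lambda_grid=lambda_grid,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        selected=selected,
        coef_1se=coef,
        feature_names=names,
        fold_seed=fold_seed,
    )


@dataclass
class OLSResult:
    params: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r2: float
    r2_adj: float
    nobs: int


def ols_final(
    X: np.ndarray | pd.DataFrame | None,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> OLSResult:
    """OLS refit of the selected regressors on their original scale.

    ``X`` may be None/empty (null selection), yielding an intercept-only
    model with adjusted R² of 0.
    """
    y = np.asarray(y, float)
    if X is None or (hasattr(X, "shape") and np.size(X) == 0):
        names = ["const"]
        design = np.ones((y.size, 1))
    else:
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != y.size:
            X = X.T
        names = ["const"] + (
            list(feature_names) if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]
        )
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.cond(design) > 1e10:
            raise ValueError("collinear selection: design condition number exceeds 1e10")
    fit = sm.OLS(y, design).fit()
    r2_adj = 0.0 if design.shape[1] == 1 else float(fit.rsquared_adj)
    return OLSResult(
        params=dict(zip(names, map(float, fit.params))),
        se=dict(zip(names, map(float, fit.bse))),
        t=dict(zip(names, map(float, fit.tvalues))),
        p=dict(zip(names, map(float, fit.pvalues))),
        r2=0.0 if design.shape[1] == 1 else float(fit.rsquared),
        r2_adj=r2_adj,
        nobs=int(fit.nobs),
    )


def build_design(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Regression design from a cohort feature table.

    Columns: condition code (reward = 1, punishment = 0), the six EEG
    features, and the six condition × feature interaction products —
    13 regressors in total. Rows with any missing value are dropped
    listwise (logged).
    """
    cols = ["condition_code", *EEG_FEATURES]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    design = table[cols].copy()
    for f in EEG_FEATURES:
        design[f"cond_x_{f}"] = design["condition_code"] * design[f]
    keep = design.notna().all(axis=1)
    if (~keep).any():
        logger.info("build_design: dropped %d incomplete rows", int((~keep).sum()))
    return design[keep], keep.to_numpy()


def selection_inference(
    table: pd.DataFrame,
    outcome: str = "retention_pct",
    seed: int = 0,
    k: int = 5,
) -> tuple[LassoResult, OLSResult]:
    """Full inference chain: Lasso-1SE selection then raw-scale OLS refit."""
    design, keep = build_design(table)
    y = table.loc[keep, outcome].to_numpy(dtype=float)
    complete = np.isfinite(y)
    design, y = design[complete], y[complete]
    lres = cv_1se(design, y, k=min(k, len(y)), seed=seed)
    Xsel = design[lres.selected] if lres.selected else None
    ores = ols_final(Xsel, y, feature_names=lres.selected)
    return lres, ores


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

def f2_from_r2(r2: float) -> float:
    """Cohen's f² from a squared multiple correlation: r²/(1−r²)."""
    if not 0 <= r2 < 1:
        raise ValueError("R^2 must be in [0, 1)")
    return r2 / (1.0 - r2)


def power_regression(n: int, n_predictors: int, f2: float, alpha: float = 0.05) -> float:
    """Power of the overall F test of a fixed-model multiple regression.

    Noncentrality is f²·N with numerator df = number of predictors and
    denominator df = N − p − 1.
    """
    df1 = n_predictors
    df2 = n - n_predictors - 1
    if df2 < 1:
        return 0.0
    fcrit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, f2 * n))


def power_regression_n(
    n_predictors: int,
    f2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    max_n: int = 100_000,
) -> int:
    """Smallest total N achieving the target power for the overall F test."""
    if f2 <= 0:
        raise ValueError("effect size f2 must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    for n in range(n_predictors + 2, max_n + 1):
        if power_regression(n, n_predictors, f2, alpha) >= power:
            return n
    raise ValueError(f"target power not attainable with N <= {max_n}")
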