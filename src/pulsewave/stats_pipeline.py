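"""Cohort-level statistics for repeated pulse-waveform measurements.

The data are nested: psychological scales are measured once per participant
while waveform features repeat across recordings, so ordinary OLS standard
errors would be anti-conservative.  Two complementary strategies are
provided: participant-level median aggregation followed by OLS, and
cluster-robust (CR1) standard errors at the observation level.  Multiplicity
is controlled by Bonferroni correction; predictive modelling uses a random
forest under participant-exclusive k-fold cross-validation; agreement
between paired measurements uses Bland-Altman limits of agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger("pulsewave")

PSYCH_OUTCOMES = (
    "swls", "svs", "panas_p", "panas_n", "phq9", "gad7", "valence", "arousal",
)
DEFAULT_COVARIATES = ("sbp",)
CORRELATION_THRESHOLD = 0.5
FEATURES_PER_DOMAIN = 2
IQR_MULTIPLIER = 1.5


@dataclass
class RegressionResult:
    feature: str
    outcome: str
    slope: float
    intercept: float
    se: float
    t: float
    p: float
    method: str
    n: int
    n_clusters: int | None = None
    significant_at_bonferroni: bool | None = None


@dataclass
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    p: float
    n: int


@dataclass
class CVResult:
    mae: float
    pearson_r: float
    p: float
    fold_mae: list[float]
    fold_r: list[float]
    importances: pd.Series
    predictions: pd.DataFrame


def iqr_outlier_filter(values, k: float = IQR_MULTIPLIER) -> np.ndarray:
    """Keep values inside [Q1 - k*IQR, Q3 + k*IQR] (linear-interp quartiles)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("IQR filtering needs at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return x[(x >= lo) & (x <= hi)]


def iqr_mask(values, k: float = IQR_MULTIPLIER) -> np.ndarray:
    """Boolean keep-mask version of :func:`iqr_outlier_filter` (NaN-safe)."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 4:
        return ok
    q1, q3 = np.percentile(x[ok], [25, 75])
    iqr = q3 - q1
    return ok & (x >= q1 - k * iqr) & (x <= q3 + k * iqr)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return alpha / m


def correlation_select(
    features: pd.DataFrame,
    domains: dict[str, str],
    outcomes: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    per_domain: int = FEATURES_PER_DOMAIN,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[str]:
    """Collinearity-pruned, outcome-ranked feature selection.

    Within each domain, while any feature pair exceeds |r| > threshold, the
    member of the worst-offending pair with the larger mean absolute
    correlation to the remaining features is dropped; the ``per_domain``
    survivors with the largest mean |r| against the outcome block are then
    retained.  Covariate columns pass through unselected.
    """
    selected: list[str] = []
    for domain in ("time", "curvature", "frequency"):
        cols = [
            c for c in features.columns
            if domains.get(c) == domain and features[c].std(skipna=True) > 0
        ]
        if not cols:
            continue
        cols = list(cols)
        corr = features[cols].corr().abs().fillna(0.0)
        while len(cols) > 1:
            sub = corr.loc[cols, cols].copy()
            np.fill_diagonal(sub.values, 0.0)
            worst = sub.values.max()
            if worst <= threshold:
                break
            i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
            fi, fj = sub.index[i], sub.columns[j]
            # drop the member more entangled with everything else
            drop = fi if sub.loc[fi].mean() >= sub.loc[fj].mean() else fj
            cols.remove(drop)
        relevance = {}
        for c in cols:
            rs = [
                abs(features[c].corr(outcomes[o]))
                for o in outcomes.columns
                if outcomes[o].std(skipna=True) > 0
            ]
            relevance[c] = np.nanmean(rs) if rs else 0.0
        ranked = sorted(cols, key=lambda c: (-relevance[c], cols.index(c)))
        if len(ranked) < per_domain:
            logger.warning(
                "domain %r has only %d survivors (< %d requested)",
                domain, len(ranked), per_domain,
            )
        selected.extend(ranked[:per_domain])
    selected.extend(c for c in covariates if c in features.columns)
    return selected


def univariate_regression(
    cohort: pd.DataFrame,
    feature: str,
    outcome: str,
    mode: str = "aggregated_ols",
    bonferroni_p: float | None = None,
    cluster_col: str = "participant_id",
) -> RegressionResult:
    """Simple regression of a psychological outcome on one waveform feature.

    ``aggregated_ols`` takes the per-participant median of the feature (the
    outcome is constant within participant) and fits OLS across
    participants.  ``cluster_robust`` fits OLS on all observations with CR1
    cluster-robust covariance and refers t to a Student distribution with
    (clusters - 2) degrees of freedom.
    """
    df = cohort[[cluster_col, feature, outcome]].dropna()
    if df[feature].std() == 0:
        raise ValueError(f"feature {feature!r} has zero variance")
    n_clusters = df[cluster_col].nunique()
    if n_clusters < 3:
        raise ValueError("need at least 3 participants")

    if mode == "aggregated_ols":
        agg = df.groupby(cluster_col).median(numeric_only=True)
        X = sm.add_constant(agg[feature])
        fit = sm.OLS(agg[outcome], X).fit()
        slope, se = fit.params[feature], fit.bse[feature]
        tval, p = fit.tvalues[feature], fit.pvalues[feature]
        n = len(agg)
    elif mode == "cluster_robust":
        X = sm.add_constant(df[feature])
        fit = sm.OLS(df[outcome], X).fit(
            cov_type="cluster", cov_kwds={"groups": df[cluster_col]}, use_t=False
        )
        slope, se = fit.params[feature], fit.bse[feature]
        tval = slope / se
        p = 2 * spstats.t.sf(abs(tval), df=n_clusters - 2)
        n = len(df)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return RegressionResult(
        feature=feature,
        outcome=outcome,
        slope=float(slope),
        intercept=float(fit.params["const"]),
        se=float(se),
        t=float(tval),
        p=float(p),
        method=mode,
        n=n,
        n_clusters=n_clusters,
        significant_at_bonferroni=(p < bonferroni_p) if bonferroni_p else None,
    )


def regression_grid(
    cohort: pd.DataFrame,
    features: list[str],
    outcomes: tuple[str, ...] = PSYCH_OUTCOMES,
    mode: str = "aggregated_ols",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (feature, outcome) univariate fits with Bonferroni flags."""
    thr = bonferroni_threshold(alpha, len(features))
    rows = []
    for f in features:
        for o in outcomes:
            if o not in cohort.columns:
                continue
            try:
                r = univariate_regression(cohort, f, o, mode=mode, bonferroni_p=thr)
            except ValueError:
                continue
            rows.append(r.__dict__)
    return pd.DataFrame(rows)


def grouped_folds(
    participants: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded participant-exclusive fold assignment.

    Unique participants are shuffled and split into ``n_folds`` nearly equal
    groups; every participant's observations land in exactly one test fold.
    """
    unique = np.unique(participants)
    if n_folds > len(unique):
        raise ValueError("more folds than participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    return [np.sort(chunk) for chunk in np.array_split(order, n_folds)]


def rf_grouped_cv(
    cohort: pd.DataFrame,
    features: list[str],
    outcome: str,
    n_folds: int = 5,
    seed: int = 0,
    cluster_col: str = "participant_id",
    n_estimators: int = 100,
) -> CVResult:
    """Random-forest regression under participant-exclusive k-fold CV.

    Hyperparameters: ``n_estimators`` trees, squared-error splitting, trees
    grown to full depth, bootstrap sampling — the standard library defaults.
    Out-of-fold predictions are pooled for MAE and Pearson r; mean-decrease-
    in-impurity importances are averaged over folds.
    """
    df = cohort[[cluster_col, outcome, *features]].dropna()
    folds = grouped_folds(df[cluster_col].to_numpy(), n_folds, seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=n_folds)

    preds = []
    fold_mae, fold_r = [], []
    importances = np.zeros(len(features))
    for k, test_participants in enumerate(folds):
        test_mask = df[cluster_col].isin(test_participants)
        train, test = df[~test_mask], df[test_mask]
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            criterion="squared_error",
            max_depth=None,
            bootstrap=True,
            random_state=int(fold_seeds[k]),
        )
        rf.fit(train[features], train[outcome])
        yhat = rf.predict(test[features])
        preds.append(
            pd.DataFrame(
                {
                    cluster_col: test[cluster_col],
                    "observed": test[outcome],
                    "predicted": yhat,
                    "fold": k,
                }
            )
        )
        fold_mae.append(float(np.mean(np.abs(yhat - test[outcome]))))
        if np.std(test[outcome]) > 0 and np.std(yhat) > 0:
            fold_r.append(float(np.corrcoef(yhat, test[outcome])[0, 1]))
        else:
            fold_r.append(np.nan)
        importances += rf.feature_importances_

    pooled = pd.concat(preds, ignore_index=True)
    mae = float(np.mean(np.abs(pooled["predicted"] - pooled["observed"])))
    if pooled["observed"].std() > 0 and pooled["predicted"].std() > 0:
        r, p = spstats.pearsonr(pooled["predicted"], pooled["observed"])
    else:
        r, p = np.nan, np.nan
    return CVResult(
        mae=mae,
        pearson_r=float(r),
        p=float(p),
        fold_mae=fold_mae,
        fold_r=fold_r,
        importances=pd.Series(importances / n_folds, index=features),
        predictions=pooled,
    )


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement: bias and 95% limits of agreement.

    Differences d = x - y; bias = mean(d); LoA = bias +/- 1.96 * SD(d)
    (sample SD, ddof=1); Pearson r on the paired values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("bland_altman needs paired sequences of length >= 3")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.std(x) > 0 and np.std(y) > 0:
        r, p = spstats.pearsonr(x, y)
    else:
        r, p = np.nan, np.nan
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=float(r),
        p=float(p),
        n=len(x),
    )


def plot_bland_altman(result_xy: tuple, ax=None):
    """Difference-vs-mean agreement plot with bias and LoA lines."""
    import matplotlib.pyplot as plt

    x, y = (np.asarray(v, dtype=float) for v in result_xy)
    res = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2, x - y, s=12, alpha=0.6)
    for val, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(val, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    return ax
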