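"""Feature reduction and selection under rigorous cross-validation.

The modelling recipe is deliberately combinatorial rather than regularized:
the wide concatenated representation is first reduced with the Boruta
all-relevant scheme (real features must beat permuted "shadow" copies), then
every combination of a few descriptors is scored by repeated, stratified,
nested k-fold cross-validation, and competing models are compared with
Dietterich's 5×2cv paired t-test and one-way ANOVA.

The continuous ΔΔG‡ target is stratified by quantile binning so every fold
spans the selectivity range.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

MAX_COMBINATIONS = 1_000_000
COLLINEARITY_CONDITION = 1e8


@dataclass
class CVConfig:
    """Cross-validation layout for subset scoring."""

    outer_folds: int = 5
    inner_folds: int = 4
    repeats: int = 10
    strat_bins: int = 4
    subset_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1 or self.subset_size < 1:
            raise ValueError("repeats and subset_size must be >= 1")


@dataclass
class ModelCVStats:
    """Cross-validated scores for one feature combination."""

    features: tuple[str, ...]
    split_rmse: np.ndarray
    split_mae: np.ndarray
    split_r2: np.ndarray
    adj_r2_full: float | None

    @property
    def mean_rmse(self) -> float:
        return float(self.split_rmse.mean())

    @property
    def sd_rmse(self) -> float:
        return float(self.split_rmse.std(ddof=1)) if len(self.split_rmse) > 1 else 0.0

    @property
    def mean_r2(self) -> float:
        return float(self.split_r2.mean())

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "mean_test_rmse": self.mean_rmse,
            "sd_test_rmse": self.sd_rmse,
            "mean_test_mae": float(self.split_mae.mean()),
            "mean_test_r2": self.mean_r2,
            "adj_r2_full": self.adj_r2_full,
        }


@dataclass
class Standardizer:
    """Column-wise (x - mean)/sd with population sd; zero-variance columns dropped."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[self.columns].to_numpy(dtype=float)
        return pd.DataFrame((x - self.means) / self.sds, index=df.index, columns=self.columns)


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize each column to mean 0, sd 1 (population sd).

    Zero-variance columns are dropped and recorded on the returned
    :class:`Standardizer` so the same map applies to unseen rows.
    """
    if len(df) < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = df.mean(axis=0).to_numpy()
    sds = df.std(axis=0, ddof=0).to_numpy()
    keep = sds > 0
    dropped = [c for c, k in zip(df.columns, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-variance columns: %s", len(dropped), dropped[:5])
    std = Standardizer(
        columns=[c for c, k in zip(df.columns, keep) if k],
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )
    return std.transform(df), std


def stratified_bins(y, n_bins: int) -> np.ndarray:
    """Quantile-bin a continuous target into ``n_bins`` labels.

    Bin sizes differ by at most one.  With heavy ties the quantile edges
    degenerate and binning falls back to stable rank order (warned).
    """
    y = np.asarray(y, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(y) < n_bins:
        raise ValueError("need at least n_bins observations")
    if len(np.unique(y)) < n_bins:
        warnings.warn("quantile bins degenerate under ties; using rank-based binning")
    order = np.argsort(y, kind="stable")
    labels = np.empty(len(y), dtype=int)
    labels[order] = np.arange(len(y)) * n_bins // len(y)
    return labels


def make_folds(
    y, n_folds: int, repeats: int, strat_bins: int, seed: int, row_ids=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified k-fold splits, reproducible given the seed.

    When ``row_ids`` is given, folds are computed on rows sorted by id so the
    assignment is invariant to input row order.
    """
    y = np.asarray(y, dtype=float)
    if row_ids is not None:
        perm = np.argsort(np.asarray(row_ids, dtype=str), kind="stable")
    else:
        perm = np.arange(len(y))
    bins = stratified_bins(y[perm], strat_bins)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed * 7919 + r)
        for tr, te in skf.split(np.zeros(len(y)), bins):
            splits.append((perm[tr], perm[te]))
    return splits


# ---------------------------------------------------------------------------
# OLS scoring core (shared by subset_search / cv_5x2 / ensembles)
# ---------------------------------------------------------------------------


def _ols_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray) -> np.ndarray:
    """Least-squares fit with intercept on train-standardized features."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    A = np.column_stack([np.ones(len(Xtr)), (Xtr - mu) / sd])
    beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    B = np.column_stack([np.ones(len(Xte)), (Xte - mu) / sd])
    return B @ beta


def _score_splits(X: np.ndarray, y: np.ndarray, splits) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rmse, mae, r2 = [], [], []
    for tr, te in splits:
        pred = _ols_predict(X[tr], y[tr], X[te])
        err = y[te] - pred
        rmse.append(np.sqrt(np.mean(err**2)))
        mae.append(np.mean(np.abs(err)))
        ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
        r2.append(1.0 - np.sum(err**2) / ss_tot if ss_tot > 0 else np.nan)
    return np.array(rmse), np.array(mae), np.array(r2)


def _full_fit_adj_r2(X: np.ndarray, y: np.ndarray) -> float | None:
    n, p = X.shape
    if n - p - 1 <= 0:
        return None
    pred = _ols_predict(X, y, X)
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return None
    r2 = 1.0 - ss_res / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def subset_search(
    X: pd.DataFrame,
    y,
    cv: CVConfig | None = None,
    subset_size: int | None = None,
) -> list[ModelCVStats]:
    """Exhaustively score every ``subset_size``-feature combination by CV.

    Each combination is evaluated with repeated stratified outer folds (the
    inner loop has nothing left to select once the combination is fixed, so
    the nested scheme collapses to the outer CV).  Ranking is by mean test
    RMSE ascending, ties broken by fewer features then lexicographic feature
    names.  Combinations whose standardized design is numerically collinear
    (condition number > 1e8) are skipped and logged.
    """
    cv = cv or CVConfig()
    k = subset_size if subset_size is not None else cv.subset_size
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    n_comb = _n_combinations(len(cols), k)
    if n_comb > MAX_COMBINATIONS:
        raise ValueError(
            f"{n_comb} combinations of {k} from {len(cols)} features exceeds the "
            f"{MAX_COMBINATIONS} guard; reduce the feature set first (e.g. Boruta)"
        )
    if len(y) < cv.outer_folds:
        raise ValueError("too few rows for the requested outer folds")
    splits = make_folds(y, cv.outer_folds, cv.repeats, cv.strat_bins, cv.seed)
    Xv = X.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(cols)}
    results: list[ModelCVStats] = []
    for combo in itertools.combinations(sorted(cols), k):
        sub = Xv[:, [col_idx[c] for c in combo]]
        mu, sd = sub.mean(axis=0), sub.std(axis=0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        cond = np.linalg.cond(np.column_stack([np.ones(len(sub)), (sub - mu) / sd_safe]))
        if cond > COLLINEARITY_CONDITION or np.any(sd == 0):
            logger.info("skipping collinear combination %s (cond=%.2g)", combo, cond)
            continue
        rmse, mae, r2 = _score_splits(sub, y, splits)
        results.append(ModelCVStats(combo, rmse, mae, r2, _full_fit_adj_r2(sub, y)))
    results.sort(key=lambda s: (s.mean_rmse, len(s.features), s.features))
    return results


def _n_combinations(n: int, k: int) -> int:
    from math import comb

    return comb(n, k) if k <= n else 0


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------


@dataclass
class BorutaResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    hits: dict[str, int]
    iterations: int


def boruta(
    X: pd.DataFrame,
    y,
    estimator_cfg: dict | None = None,
    alpha: float = 0.05,
    max_iter: int = 25,
    seed: int = 0,
    importance: str = "impurity",
    importance_repeats: int = 3,
) -> BorutaResult:
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends a permuted copy of every column, fits a random
    forest, and measures feature importances (mean impurity decrease by
    default, the classic Boruta choice; out-of-sample permutation importance
    via ``importance="permutation"``); a real feature scores a "hit" when
    its importance beats the best shadow.  One-sided binomial tests over the
    accumulated hit counts — Bonferroni-adjusted across the input features,
    as in the canonical algorithm — promote features to confirmed (more hits
    than chance) or rejected (fewer); whatever is undecided at ``max_iter``
    stays tentative.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("Boruta needs at least 10 rows")
    if importance not in ("impurity", "permutation"):
        raise ValueError(f"unknown importance kind {importance!r}")
    cfg = {"n_estimators": 150, "max_depth": None, "max_features": 1 / 3, "n_jobs": 1}
    cfg.update(estimator_cfg or {})
    rng = np.random.default_rng(seed)
    all_cols = list(X.columns)
    hits = {c: 0 for c in all_cols}
    undecided = set(all_cols)
    confirmed: list[str] = []
    rejected: list[str] = []
    it = 0
    while undecided and it < max_iter:
        it += 1
        # rejected features leave the model (and the shadow pool), as in the
        # canonical algorithm: the max-shadow bar adapts to what is left
        cols = [c for c in all_cols if c not in rejected]
        Xv = X[cols].to_numpy(dtype=float)
        shadows = Xv.copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = rng.permutation(shadows[:, j])
        full = np.hstack([Xv, shadows])
        est = RandomForestRegressor(random_state=int(rng.integers(2**31 - 1)), **cfg)
        est.fit(full, y)
        if importance == "impurity":
            imp = est.feature_importances_
        else:
            imp = permutation_importance(
                est,
                full,
                y,
                n_repeats=importance_repeats,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            ).importances_mean
        shadow_max = imp[len(cols):].max()
        for j, c in enumerate(cols):
            if c in undecided and imp[j] > shadow_max:
                hits[c] += 1
        alpha_adj = alpha / len(all_cols)  # Bonferroni over tested features
        for c in list(undecided):
            test_hi = stats.binomtest(hits[c], it, 0.5, alternative="greater")
            test_lo = stats.binomtest(hits[c], it, 0.5, alternative="less")
            if test_hi.pvalue < alpha_adj:
                confirmed.append(c)
                undecided.remove(c)
            elif test_lo.pvalue < alpha_adj:
                rejected.append(c)
                undecided.remove(c)
    return BorutaResult(
        confirmed=sorted(confirmed),
        rejected=sorted(rejected),
        tentative=sorted(undecided),
        hits=hits,
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass
class FiveByTwoResult:
    per_set_rmse: dict[str, np.ndarray]  # name -> 10 half-fit RMSEs
    t_stats: pd.DataFrame
    p_values: pd.DataFrame
    notes: list[str]


def cv_5x2(
    X: pd.DataFrame,
    y,
    feature_sets: dict[str, list[str]],
    seed: int = 0,
    strat_bins: int = 4,
) -> FiveByTwoResult:
    """Dietterich's 5×2cv comparison of feature sets.

    Five repeats of stratified two-fold splits give ten half-fit test RMSEs
    per set; the paired t statistic t = d₁⁽¹⁾ / sqrt((1/5)·Σ sᵢ²) with 5
    degrees of freedom compares each pair.  Identical performance across all
    splits is reported as p = 1 by convention.
    """
    if len(feature_sets) < 2:
        raise ValueError("need at least two feature sets to compare")
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("5x2cv needs at least 10 rows")
    names = list(feature_sets)
    rmse: dict[str, np.ndarray] = {n: np.empty((5, 2)) for n in names}
    bins = stratified_bins(y, strat_bins)
    Xv = {n: X[list(fs)].to_numpy(dtype=float) for n, fs in feature_sets.items()}
    for rep in range(5):
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed * 7919 + rep)
        for half, (tr, te) in enumerate(skf.split(np.zeros(len(y)), bins)):
            for n in names:
                pred = _ols_predict(Xv[n][tr], y[tr], Xv[n][te])
                rmse[n][rep, half] = np.sqrt(np.mean((y[te] - pred) ** 2))
    t_mat = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    p_mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    notes: list[str] = []
    for a, b in itertools.combinations(names, 2):
        d = rmse[a] - rmse[b]  # (5, 2)
        dbar = d.mean(axis=1)
        s2 = ((d - dbar[:, None]) ** 2).sum(axis=1)
        denom = np.sqrt(s2.mean())
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
            notes.append(f"{a} vs {b}: identical performance on every split; p=1 by convention")
        elif denom == 0.0:
            t, p = np.nan, np.nan
            notes.append(f"{a} vs {b}: zero variance of differences, t undefined")
        else:
            t = float(d[0, 0] / denom)
            p = float(2.0 * stats.t.sf(abs(t), df=5))
        t_mat.loc[a, b] = t_mat.loc[b, a] = t
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
    return FiveByTwoResult(
        per_set_rmse={n: rmse[n].ravel() for n in names}, t_stats=t_mat, p_values=p_mat, notes=notes
    )


def anova_models(groups: dict[str, list[float]] | list[list[float]]) -> tuple[float, float]:
    """One-way ANOVA over per-model test-error groups -> (F, p).

    Zero within-group variance is guarded: equal group means report
    (F=0, p=1); different means with no within-group spread report a
    significant (inf, 0).
    """
    arrays = [np.asarray(g, dtype=float) for g in (groups.values() if isinstance(groups, dict) else groups)]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = np.array([a.mean() for a in arrays])
    if within == 0.0:
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
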