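"""Multivariate linear models, RMSE-weighted ensembles, LORO and screening.

A handful of small linear models over selected descriptors, rather than one,
carries both a prediction and an uncertainty: the ensemble mean is weighted
by each member's cross-validated test RMSE (inverse-RMSE, so better models
weigh more) and the spread is the unweighted standard deviation of the
member predictions.  Leave-one-reaction-out (LORO) retrains the whole
selection-plus-ensemble pipeline with an entire transformation held out, the
probe of transferability across reactions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_select import CVConfig, ModelCVStats, boruta, subset_search
from .structio import FeatureMatrix, parse_column_provenance

logger = logging.getLogger(__name__)


def metrics(y_true, y_pred, p_features: int = 0) -> dict[str, float | None]:
    """MAE, RMSE, R² and adjusted R² = 1 - (1-R²)(n-1)/(n-p-1).

    Adjusted R² is ``None`` when n - p - 1 <= 0.  A constant ``y_true`` has
    no variance to explain and raises.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: y_true has zero variance")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    n = y_true.size
    adj = None
    if n - p_features - 1 > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_features - 1)
    return {"mae": mae, "rmse": rmse, "r2": r2, "adj_r2": adj}


@dataclass
class MLRModel:
    """OLS fit on standardized features; coefficients in standardized units."""

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    fit_metrics: dict[str, float | None] = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        Z = (X[list(self.feature_names)].to_numpy(dtype=float) - self.means) / self.sds
        return self.intercept + Z @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "fit_metrics": self.fit_metrics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            feature_names=tuple(d["features"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            fit_metrics=d.get("fit_metrics", {}),
        )


def _dependent_columns(Z: np.ndarray, names) -> list[str]:
    """Columns that are (numerically) linear combinations of the others."""
    bad = []
    for j in range(Z.shape[1]):
        others = np.delete(Z, j, axis=1)
        A = np.column_stack([np.ones(len(Z)), others])
        resid = Z[:, j] - A @ np.linalg.lstsq(A, Z[:, j], rcond=None)[0]
        if np.sum(resid**2) < 1e-10 * max(1.0, np.sum(Z[:, j] ** 2)):
            bad.append(names[j])
    return bad


def fit_ols(X: pd.DataFrame, y, feature_names=None) -> MLRModel:
    """Least-squares fit of ΔΔG‡ on standardized descriptor columns."""
    names = tuple(feature_names) if feature_names is not None else tuple(X.columns)
    y = np.asarray(y, dtype=float)
    sub = X[list(names)].to_numpy(dtype=float)
    n, p = sub.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 rows (n={n}, p={p})")
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    if np.any(sd == 0):
        const = [c for c, s in zip(names, sd) if s == 0]
        raise ValueError(f"zero-variance feature columns: {const}")
    Z = (sub - mu) / sd
    A = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError(f"rank-deficient design; dependent columns: {_dependent_columns(Z, names)}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    model = MLRModel(
        feature_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        means=mu,
        sds=sd,
    )
    model.fit_metrics = metrics(y, model.predict(X), p_features=p)
    return model


@dataclass
class PredictionWithUncertainty:
    mean: float  # kcal/mol
    spread: float  # sd across members, kcal/mol
    per_member: np.ndarray


@dataclass
class EnsembleModel:
    """Top-k linear models with inverse-RMSE weights."""

    members: list[MLRModel]
    weights: np.ndarray
    member_cv_rmse: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != len(self.weights):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "members": [m.to_dict() for m in self.members],
            "weights": self.weights.tolist(),
            "member_cv_rmse": np.asarray(self.member_cv_rmse, dtype=float).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            members=[MLRModel.from_dict(m) for m in d["members"]],
            weights=np.asarray(d["weights"], dtype=float),
            member_cv_rmse=np.asarray(d["member_cv_rmse"], dtype=float),
        )


def ensemble_weights(cv_rmses, scheme: str = "inverse_rmse") -> np.ndarray:
    """Normalized member weights from cross-validated test RMSEs.

    A zero-RMSE member takes all the weight (warned); otherwise weights are
    proportional to 1/RMSE so better members weigh more.
    """
    rmse = np.asarray(cv_rmses, dtype=float)
    if scheme != "inverse_rmse":
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    if np.any(rmse == 0):
        warnings.warn("zero-RMSE ensemble member; it receives all the weight")
        w = (rmse == 0).astype(float)
    else:
        w = 1.0 / rmse
    return w / w.sum()


def build_ensemble(
    ranked_stats: list[ModelCVStats],
    X: pd.DataFrame,
    y,
    k: int = 5,
    weighting: str = "inverse_rmse",
) -> EnsembleModel:
    """Refit the top-k CV-ranked feature combinations and weight them."""
    if len(ranked_stats) < k:
        raise ValueError(f"need >= {k} candidate models, got {len(ranked_stats)}")
    top = ranked_stats[:k]
    members = [fit_ols(X, y, s.features) for s in top]
    rmses = np.array([s.mean_rmse for s in top])
    return EnsembleModel(members=members, weights=ensemble_weights(rmses, weighting), member_cv_rmse=rmses)


def predict_ensemble(model: EnsembleModel, X: pd.DataFrame) -> list[PredictionWithUncertainty]:
    """Weighted-mean prediction with member-spread uncertainty per row."""
    per = np.stack([m.predict(X) for m in model.members], axis=0)  # (k, n)
    mean = model.weights @ per
    spread = per.std(axis=0, ddof=0) if len(model.members) > 1 else np.zeros(per.shape[1])
    return [
        PredictionWithUncertainty(float(mean[i]), float(spread[i]), per[:, i])
        for i in range(per.shape[1])
    ]


def select_and_ensemble(
    X: pd.DataFrame,
    y,
    cv: CVConfig | None = None,
    k: int = 5,
    boruta_first: bool = False,
    boruta_kwargs: dict | None = None,
) -> tuple[EnsembleModel, list[ModelCVStats]]:
    """The selection pipeline: (Boruta →) exhaustive subset CV → top-k ensemble."""
    cv = cv or CVConfig()
    Xs = X
    if boruta_first:
        kw = dict(seed=cv.seed)
        kw.update(boruta_kwargs or {})
        res = boruta(X, y, **kw)
        kept = res.confirmed + res.tentative  # tentative kept: all-relevant, not minimal
        if len(kept) < cv.subset_size:
            # Boruta over-pruned for this n; pad with the strongest univariate
            # correlates to a bounded, deterministic search set
            logger.warning("Boruta kept < subset_size features; padding by |correlation|")
            yv = np.asarray(y, dtype=float)
            r = X.corrwith(pd.Series(yv, index=X.index)).abs().sort_values(ascending=False)
            for c in r.index:
                if c not in kept:
                    kept.append(c)
                if len(kept) >= 3 * cv.subset_size:
                    break
        Xs = X[kept]
    ranked = subset_search(Xs, y, cv)
    if not ranked:
        raise ValueError("no valid feature combinations survived the search")
    k_eff = min(k, len(ranked))
    return build_ensemble(ranked, X, y, k=k_eff), ranked


def loro(
    X: pd.DataFrame,
    y,
    reaction_labels,
    cv: CVConfig | None = None,
    k: int = 5,
    boruta_first: bool = False,
) -> dict:
    """Leave-one-reaction-out transfer analysis.

    For each distinct reaction label the full pipeline (feature selection +
    ensemble) is retrained on the remaining reactions and evaluated on the
    held-out one; selection happens inside the loop, so nothing leaks.
    R² is undefined (None) for single-row hold-outs.
    """
    cv = cv or CVConfig()
    labels = np.asarray(reaction_labels)
    y = np.asarray(y, dtype=float)
    unique = sorted(set(labels.tolist()))
    if len(unique) < 2:
        raise ValueError("LORO needs at least two distinct reaction labels")
    per_reaction: dict[str, dict] = {}
    for lab in unique:
        held = labels == lab
        model, _ = select_and_ensemble(
            X[~held], y[~held], cv=cv, k=k, boruta_first=boruta_first
        )
        preds = predict_ensemble(model, X[held])
        yh = y[held]
        ph = np.array([p.mean for p in preds])
        mae = float(np.mean(np.abs(yh - ph)))
        r2 = None
        if len(yh) >= 2 and np.var(yh) > 0:
            r2 = metrics(yh, ph)["r2"]
        per_reaction[str(lab)] = {"n": int(held.sum()), "mae": mae, "r2": r2}
    maes = np.array([v["mae"] for v in per_reaction.values()])
    return {
        "per_reaction": per_reaction,
        "mae_mean": float(maes.mean()),
        "mae_sd": float(maes.std(ddof=1)) if len(maes) > 1 else 0.0,
    }


def virtual_screen(
    model: EnsembleModel, candidates: FeatureMatrix | pd.DataFrame, reference_ddg: float
) -> pd.DataFrame:
    """Rank candidate ligand/substrate rows by predicted ΔΔG‡.

    A row is flagged ``predicted_improvement`` when its prediction minus one
    spread still clears the reference ΔΔG‡ — an uncertainty-aware margin.
    """
    df = candidates.data if isinstance(candidates, FeatureMatrix) else candidates
    preds = predict_ensemble(model, df)
    out = pd.DataFrame(
        {
            "predicted_ddg": [p.mean for p in preds],
            "spread": [p.spread for p in preds],
        },
        index=df.index,
    )
    out["predicted_improvement"] = out["predicted_ddg"] - out["spread"] > reference_ddg
    return out.sort_values("predicted_ddg", ascending=False, kind="stable")


def feature_provenance_frequency(model: EnsembleModel) -> dict:
    """How often each feature — and each mechanism stage — appears in members."""
    if not model.members:
        raise ValueError("empty ensemble")
    feature_counts: dict[str, int] = {}
    stage_counts: dict[str, int] = {}
    untagged = 0
    for member in model.members:
        for feat in member.feature_names:
            feature_counts[feat] = feature_counts.get(feat, 0) + 1
            stage = parse_column_provenance(feat)["stage"]
            if stage == "unknown":
                untagged += 1
            stage_counts[stage] = stage_counts.get(stage, 0) + 1
    if untagged:
        warnings.warn(f"{untagged} feature occurrences without provenance tags counted as 'unknown'")
    return {
        "n_members": len(model.members),
        "feature_counts": dict(sorted(feature_counts.items(), key=lambda kv: (-kv[1], kv[0]))),
        "stage_counts": dict(sorted(stage_counts.items(), key=lambda kv: (-kv[1], kv[0]))),
    }
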