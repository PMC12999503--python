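"""Gaussian-process active learning over ligand representations.

A GPR model (Matérn-5/2, shared length scale) warm-started on sparse
literature data proposes small batches of ligands by expected improvement
(EI) with a constant-liar greedy scheme; the campaign stops when the mean EI
of a proposed batch, relative to the incumbent ΔΔG‡, drops below a
threshold — diminishing return on further experiments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

logger = logging.getLogger(__name__)

JITTER = 1e-10


@dataclass
class GPState:
    """A fitted GP with its training data and standardization stats."""

    gpr: GaussianProcessRegressor
    X: np.ndarray
    y: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray

    def _z(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, sd = self.gpr.predict(self._z(np.asarray(X, dtype=float)), return_std=True)
        return mu, sd


def fit_gpr(X, y, kernel_cfg: dict | None = None, seed: int = 0) -> GPState:
    """Fit an exact GP with Matérn-5/2 kernel and seeded multi-start ML-II.

    Features are standardized internally (population sd; constant columns
    left unscaled).  The white-noise term is floored at the jitter level.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ValueError("GP fit needs at least 2 observations")
    cfg = {"nu": 2.5, "n_restarts": 3, "noise": 1e-5}
    cfg.update(kernel_cfg or {})
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=1.0, length_scale_bounds=(1e-2, 1e3), nu=cfg["nu"]
    ) + WhiteKernel(cfg["noise"], (JITTER, 1e1))
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=cfg["n_restarts"],
        random_state=seed,
        alpha=JITTER,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gpr.fit(Z, y)
    return GPState(gpr=gpr, X=X, y=y, x_mean=mu, x_sd=sd)


def expected_improvement(gp: GPState, candidates, incumbent: float) -> np.ndarray:
    """EI under the maximization convention (higher ΔΔG‡ is better).

    EI = (μ - f*)·Φ(z) + σ·φ(z) with z = (μ - f*)/σ; at σ = 0 it collapses
    to max(μ - f*, 0).
    """
    mu, sd = gp.predict(np.asarray(candidates, dtype=float))
    improve = mu - incumbent
    ei = np.where(improve > 0, improve, 0.0)
    pos = sd > 0
    z = np.zeros_like(mu)
    z[pos] = improve[pos] / sd[pos]
    ei_pos = improve * norm.cdf(z) + sd * norm.pdf(z)
    return np.where(pos, ei_pos, ei)


def _refit_frozen(gp: GPState, X: np.ndarray, y: np.ndarray) -> GPState:
    """Refit on augmented data with hyperparameters frozen."""
    frozen = GaussianProcessRegressor(
        kernel=gp.gpr.kernel_, optimizer=None, normalize_y=True, alpha=JITTER
    )
    frozen.fit(gp._z(X), y)
    return GPState(gpr=frozen, X=X, y=y, x_mean=gp.x_mean, x_sd=gp.x_sd)


def select_batch(gp: GPState, candidates: pd.DataFrame, q: int, incumbent: float) -> list[str]:
    """Greedy constant-liar batch: pick argmax EI, hallucinate its posterior
    mean as an observation, refit with frozen hyperparameters, repeat.

    Deterministic given the fitted GP; ties break toward the earlier
    candidate id.  Returns ids in selection order (no duplicates).
    """
    if q < 1:
        raise ValueError("batch size must be >= 1")
    if len(candidates) == 0:
        raise ValueError("empty candidate pool")
    q = min(q, len(candidates))
    remaining = candidates.copy()
    state = gp
    chosen: list[str] = []
    inc = incumbent
    for _ in range(q):
        ei = expected_improvement(state, remaining.to_numpy(dtype=float), inc)
        pick = int(np.argmax(ei))  # argmax keeps the first of equal EIs
        cid = str(remaining.index[pick])
        chosen.append(cid)
        x_new = remaining.to_numpy(dtype=float)[pick]
        mu_new, _ = state.predict(x_new[None, :])
        X_aug = np.vstack([state.X, x_new])
        y_aug = np.append(state.y, mu_new[0])
        inc = max(inc, float(mu_new[0]))  # the liar believes its own mean
        state = _refit_frozen(state, X_aug, y_aug)
        remaining = remaining.drop(remaining.index[pick])
    return chosen


@dataclass
class CampaignRound:
    round: int
    batch: list[str]
    measured: dict[str, float]
    incumbent_id: str
    incumbent: float
    mean_rel_ei: float | None


@dataclass
class CampaignState:
    rounds: list[CampaignRound] = field(default_factory=list)
    stopped: bool = False
    stop_reason: str = ""

    @property
    def incumbent(self) -> float:
        return self.rounds[-1].incumbent

    @property
    def evaluated_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.rounds:
            out.extend(r.measured)
        return out

    def to_dict(self) -> dict:
        return {
            "stopped": self.stopped,
            "stop_reason": self.stop_reason,
            "rounds": [
                {
                    "round": r.round,
                    "batch": r.batch,
                    "measured": r.measured,
                    "incumbent_id": r.incumbent_id,
                    "incumbent": r.incumbent,
                    "mean_rel_ei": r.mean_rel_ei,
                }
                for r in self.rounds
            ],
        }


def run_campaign(
    pool_features: pd.DataFrame,
    oracle,
    warm_start: dict[str, float],
    batch_size: int = 5,
    stop_rel_ei: float = 0.05,
    max_rounds: int = 10,
    seed: int = 0,
    kernel_cfg: dict | None = None,
) -> CampaignState:
    """EI-driven screening campaign over a discrete ligand pool.

    Round 0 fits the GP on the warm-start measurements.  Each later round
    proposes a constant-liar batch, queries the oracle (a synthetic truth or
    measured lab results), refits, and records the incumbent and the mean EI
    of the batch relative to |incumbent|; the campaign stops when that ratio
    drops below ``stop_rel_ei`` or at ``max_rounds``.  The incumbent
    trajectory is non-decreasing by construction.
    """
    if not warm_start:
        raise ValueError("warm start must contain at least two measurements")
    state = CampaignState()
    measured = dict(warm_start)
    inc_id = max(measured, key=lambda k: measured[k])
    state.rounds.append(
        CampaignRound(0, [], dict(warm_start), inc_id, measured[inc_id], None)
    )
    remaining = pool_features.drop(
        index=[i for i in measured if i in pool_features.index]
    )
    feats = {str(i): pool_features.loc[i].to_numpy(dtype=float) for i in pool_features.index}
    warm_X = np.array([feats[i] for i in measured if i in feats])
    warm_y = np.array([measured[i] for i in measured if i in feats])
    if len(warm_X) < 2:
        raise ValueError("warm start needs >= 2 pool members with features")
    gp = fit_gpr(warm_X, warm_y, kernel_cfg, seed)
    for rnd in range(1, max_rounds + 1):
        if len(remaining) == 0:
            state.stopped, state.stop_reason = True, "pool exhausted"
            break
        incumbent = state.incumbent
        batch = select_batch(gp, remaining, batch_size, incumbent)
        ei = expected_improvement(gp, remaining.loc[batch].to_numpy(dtype=float), incumbent)
        mean_rel_ei = float(ei.mean() / max(abs(incumbent), 1e-12))
        new_measured: dict[str, float] = {}
        for cid in batch:
            try:
                new_measured[cid] = float(oracle(cid))
            except Exception as exc:  # noqa: BLE001 - lab failures must not kill the campaign
                warnings.warn(f"oracle failed for {cid}: {exc}; excluded from this round")
        measured.update(new_measured)
        inc_id = max(measured, key=lambda k: measured[k])
        state.rounds.append(
            CampaignRound(rnd, batch, new_measured, inc_id, measured[inc_id], mean_rel_ei)
        )
        remaining = remaining.drop(index=batch)
        X_all = np.array([feats[i] for i in measured if i in feats])
        y_all = np.array([measured[i] for i in measured if i in feats])
        gp = fit_gpr(X_all, y_all, kernel_cfg, seed + rnd)
        if mean_rel_ei < stop_rel_ei:
            state.stopped, state.stop_reason = True, (
                f"mean relative EI {mean_rel_ei:.3g} < {stop_rel_ei:g}"
            )
            break
    return state
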