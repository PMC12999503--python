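"""SISSO-style nonlinear descriptor construction and sparse selection.

Candidate descriptors are built by composing base features with a small
operator set (depth-limited to keep the space enumerable), screened by sure
independence screening (|Pearson correlation| with the target), and the
survivors fed to the same exhaustive subset-CV machinery used for linear
models.  This is a faithful SIS + ℓ0 core, not a port of the published
multi-tier SISSO code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_select import CVConfig, ModelCVStats, subset_search

logger = logging.getLogger(__name__)

UNARY_OPS = {
    "square": lambda x: x**2,
    "sqrt_abs": lambda x: np.sqrt(np.abs(x)),
    "log_abs": lambda x: np.log(np.abs(x)),
    "abs": np.abs,
    "inverse": lambda x: 1.0 / x,
}
BINARY_OPS = {
    "+": np.add,
    "-": np.subtract,
    "*": np.multiply,
    "/": np.divide,
}
COMMUTATIVE = {"+", "*"}
DEFAULT_OPERATORS = ("+", "-", "*", "/", "square", "sqrt_abs", "log_abs", "abs", "inverse")

_UNARY_FMT = {
    "square": "({})^2",
    "sqrt_abs": "sqrt|{}|",
    "log_abs": "log|{}|",
    "abs": "|{}|",
    "inverse": "1/({})",
}


@dataclass(frozen=True)
class ExpressionTree:
    """A composed descriptor: a base feature or an operator over children."""

    op: str  # 'feature', a unary name, or a binary symbol
    children: tuple["ExpressionTree", ...] = ()
    feature: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        if self.op == "feature":
            if not self.feature:
                raise ValueError("feature node needs a feature name")
        elif self.op in UNARY_OPS:
            if len(self.children) != 1:
                raise ValueError(f"{self.op} takes one child")
        elif self.op in BINARY_OPS:
            if len(self.children) != 2:
                raise ValueError(f"{self.op} takes two children")
        else:
            raise ValueError(f"unknown operator {self.op!r}")

    @property
    def depth(self) -> int:
        if self.op == "feature":
            return 0
        return 1 + max(c.depth for c in self.children)

    @property
    def formula(self) -> str:
        if self.op == "feature":
            return self.feature
        if self.op in UNARY_OPS:
            return _UNARY_FMT[self.op].format(self.children[0].formula)
        a, b = (c.formula for c in self.children)
        return f"({a} {self.op} {b})"

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        if self.op == "feature":
            return X[self.feature].to_numpy(dtype=float)
        if self.op in UNARY_OPS:
            with np.errstate(all="ignore"):
                return UNARY_OPS[self.op](self.children[0].evaluate(X))
        with np.errstate(all="ignore"):
            return BINARY_OPS[self.op](self.children[0].evaluate(X), self.children[1].evaluate(X))


def _canonical(op: str, a: ExpressionTree, b: ExpressionTree) -> tuple[ExpressionTree, ExpressionTree]:
    if op in COMMUTATIVE and b.formula < a.formula:
        return b, a
    return a, b


def _combined_unit(op: str, a: ExpressionTree, b: ExpressionTree) -> str | None:
    """Unit tag of the combination; None marks a dimensional violation."""
    if op in ("+", "-"):
        if a.unit != b.unit:
            return None
        return a.unit
    if not a.unit and not b.unit:
        return ""
    return f"({a.unit}){op}({b.unit})"


def expand_features(
    X: pd.DataFrame,
    operator_set=DEFAULT_OPERATORS,
    max_depth: int = 1,
    unit_tags: dict[str, str] | None = None,
    column_cap: int = 20000,
) -> tuple[pd.DataFrame, list[ExpressionTree]]:
    """Enumerate unique operator compositions of the base features.

    Depth is capped at 2 to keep the space enumerable.  Candidates producing
    non-finite values on the data, duplicates up to commutativity, and
    divisions of a subtree by itself are dropped; +/- across different unit
    tags is disallowed when tags are provided.  Column order is
    deterministic (by depth, then formula).
    """
    if max_depth > 2:
        raise ValueError("max_depth is capped at 2 to keep the expansion enumerable")
    unary = [o for o in operator_set if o in UNARY_OPS]
    binary = [o for o in operator_set if o in BINARY_OPS]
    unknown = [o for o in operator_set if o not in UNARY_OPS and o not in BINARY_OPS]
    if unknown:
        raise ValueError(f"unknown operators: {unknown}")
    tags = unit_tags or {}
    base = [
        ExpressionTree("feature", feature=c, unit=tags.get(c, "")) for c in X.columns
    ]
    seen: dict[str, ExpressionTree] = {t.formula: t for t in base}
    values: dict[str, np.ndarray] = {t.formula: t.evaluate(X) for t in base}
    levels: list[list[ExpressionTree]] = [base]
    for _depth in range(max_depth):
        pool = [t for lvl in levels for t in lvl]
        new: list[ExpressionTree] = []
        for op in sorted(unary):
            for t in pool:
                cand = ExpressionTree(op, (t,), unit=f"{op}({t.unit})" if t.unit else "")
                _consider(cand, X, seen, values, new)
        pool_sorted = sorted(pool, key=lambda t: t.formula)
        for op in sorted(binary):
            for i, a in enumerate(pool_sorted):
                for b in pool_sorted[i:]:
                    if a.formula == b.formula and op in ("-", "/"):
                        continue  # x-x constant, x/x division by identical subtree
                    unit = _combined_unit(op, a, b)
                    if unit is None:
                        continue
                    ca, cb = _canonical(op, a, b)
                    cand = ExpressionTree(op, (ca, cb), unit=unit)
                    _consider(cand, X, seen, values, new)
        if len(seen) > column_cap:
            raise ValueError(
                f"expansion produced {len(seen)} candidates (> cap {column_cap}); "
                "pre-screen the base features first"
            )
        levels.append(new)
    trees = [t for lvl in levels for t in lvl]
    out = pd.DataFrame({t.formula: values[t.formula] for t in trees}, index=X.index)
    return out, trees


def _consider(cand, X, seen, values, new) -> None:
    if cand.formula in seen:
        return
    v = cand.evaluate(X)
    if not np.all(np.isfinite(v)):
        logger.debug("dropping %s: non-finite values on the data", cand.formula)
        return
    seen[cand.formula] = cand
    values[cand.formula] = v
    new.append(cand)


def sis_screen(expanded: pd.DataFrame, y, n_keep: int = 50) -> list[str]:
    """Sure independence screening: top columns by |Pearson r| with y.

    Zero-variance candidates score 0; ties break by column name.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    denom_y = np.sqrt((yc**2).sum())
    scores: list[tuple[float, str]] = []
    for c in expanded.columns:
        x = expanded[c].to_numpy(dtype=float)
        xc = x - x.mean()
        denom = np.sqrt((xc**2).sum()) * denom_y
        r = 0.0 if denom == 0 else float(abs((xc * yc).sum()) / denom)
        scores.append((r, c))
    scores.sort(key=lambda rc: (-rc[0], rc[1]))
    return [c for _, c in scores[:n_keep]]


def so_select(
    screened: pd.DataFrame,
    y,
    max_terms: int = 4,
    cv: CVConfig | None = None,
) -> list[ModelCVStats]:
    """Sparsifying operator: exhaustive ℓ0 over the screened descriptors.

    Every subset of size 1..max_terms is scored with the same repeated
    stratified CV machinery as linear subset search; the ranked result feeds
    ensemble construction unchanged.
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    cv = cv or CVConfig()
    results: list[ModelCVStats] = []
    for size in range(1, max_terms + 1):
        if size > len(screened.columns):
            break
        results.extend(subset_search(screened, y, cv, subset_size=size))
    results.sort(key=lambda s: (s.mean_rmse, len(s.features), s.features))
    return results


@dataclass
class SissoResult:
    ranked: list[ModelCVStats]
    trees: dict[str, ExpressionTree] = field(default_factory=dict)

    def formulas(self, top: int = 5) -> list[str]:
        return [" + ".join(s.features) for s in self.ranked[:top]]


def sisso_search(
    X: pd.DataFrame,
    y,
    operator_set=DEFAULT_OPERATORS,
    max_depth: int = 1,
    n_sis: int = 50,
    max_terms: int = 4,
    cv: CVConfig | None = None,
    unit_tags: dict[str, str] | None = None,
) -> SissoResult:
    """Full expand → screen → select pipeline.

    With an empty operator set this reduces exactly to exhaustive subset
    search over the base features.
    """
    expanded, trees = expand_features(X, operator_set, max_depth, unit_tags)
    kept = sis_screen(expanded, y, n_sis)
    ranked = so_select(expanded[kept], y, max_terms, cv)
    return SissoResult(ranked=ranked, trees={t.formula: t for t in trees})
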