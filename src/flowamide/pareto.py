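"""Pareto-front analysis and scalarisation of the two reaction objectives.

Bridges the two optimisation stages: nondominated sorting of (product,
impurity) observations, selection of the preferred trade-off by the
diminishing-returns rule, reverse-engineering of linear scalarisation
weights by LP, and the weighted objective f(x) itself (lower is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .simulator import Observation

__all__ = [
    "Weights",
    "ParetoAnalysis",
    "PAPER_WEIGHTS",
    "nondominated",
    "pareto_analysis",
    "diminishing_returns",
    "infer_weights",
    "scalarize",
    "ScalarisationError",
]


class ScalarisationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Weights:
    """Linear scalarisation coefficients: f = w_amide*product + w_enamine*impurity.

    w_amide is negative (product is maximised), w_enamine positive
    (impurity is minimised); both objectives must stay active.
    """

    w_amide: float
    w_enamine: float
    margin: float = float("nan")  # LP margin achieved, if inferred

    def __post_init__(self) -> None:
        if self.w_amide > -0.05:
            raise ValueError(f"w_amide must be <= -0.05, got {self.w_amide}")
        if self.w_enamine < 0.05:
            raise ValueError(f"w_enamine must be >= 0.05, got {self.w_enamine}")

    def to_dict(self) -> dict:
        return {"w_amide": self.w_amide, "w_enamine": self.w_enamine,
                "margin": self.margin}


#: The published scalarisation, f(x) = -0.2667*amide(x) + 0.773*enamine(x).
PAPER_WEIGHTS = Weights(-0.2667, 0.773)


def _as_objectives(observations) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(observations, tuple) and len(observations) == 2 \
            and np.ndim(observations[0]) >= 1:
        return (np.asarray(observations[0], dtype=float),
                np.asarray(observations[1], dtype=float))
    prod = np.array([o.product_norm for o in observations], dtype=float)
    imp = np.array([o.impurity_norm for o in observations], dtype=float)
    return prod, imp


def nondominated(observations) -> np.ndarray:
    """Indices of observations not dominated by any other.

    Orientation: maximise product, minimise impurity; a dominates b when
    product_a >= product_b and impurity_a <= impurity_b with at least one
    strict. Returned indices are ordered by increasing product (ties by
    increasing impurity, then original index, deterministically).
    """
    prod, imp = _as_objectives(observations)
    n = len(prod)
    if n == 0:
        raise ValueError("need at least one observation")
    dominated = np.zeros(n, dtype=bool)
    ge_p = prod[:, None] >= prod[None, :]
    le_i = imp[:, None] <= imp[None, :]
    strict = (prod[:, None] > prod[None, :]) | (imp[:, None] < imp[None, :])
    dom = ge_p & le_i & strict  # dom[k, j]: k dominates j
    dominated = dom.any(axis=0)
    idx = np.flatnonzero(~dominated)
    order = np.lexsort((idx, imp[idx], prod[idx]))
    return idx[order]


@dataclass(frozen=True)
class ParetoAnalysis:
    """Ordered Pareto front with its percentage-change table."""

    front_indices: np.ndarray    # into the original observation list
    product: np.ndarray          # front, increasing product order
    impurity: np.ndarray
    dp_pct: np.ndarray           # % change of product for step k -> k+1
    di_pct: np.ndarray           # % change of impurity for step k -> k+1
    preferred: int               # position in the ordered front

    def table(self) -> list[dict]:
        rows = []
        for k in range(len(self.product)):
            rows.append({
                "rank": k + 1,
                "product_norm": float(self.product[k]),
                "impurity_norm": float(self.impurity[k]),
                "dp_pct": float(self.dp_pct[k - 1]) if k else float("nan"),
                "di_pct": float(self.di_pct[k - 1]) if k else float("nan"),
                "preferred": k == self.preferred,
            })
        return rows


def diminishing_returns(product: np.ndarray, impurity: np.ndarray) -> int:
    """Preferred-point index on a front ordered by increasing product.

    Walk from the lowest-product end, accepting step k -> k+1 while the
    percentage gain in product is at least the percentage increase in
    impurity (both relative to point k; ties accept); stop at the first
    rejection. Steps from a zero-impurity point fall back to absolute
    changes, with a warning.
    """
    product = np.asarray(product, dtype=float)
    impurity = np.asarray(impurity, dtype=float)
    if np.any(np.diff(product) < 0):
        raise ValueError("front must be ordered by increasing product")
    if np.any(product <= 0):
        raise ValueError("all product values on the front must be positive")
    k = 0
    while k + 1 < len(product):
        dp = product[k + 1] - product[k]
        di = impurity[k + 1] - impurity[k]
        if impurity[k] <= 0.0:
            warnings.warn("zero impurity on the front: comparing absolute "
                          "changes for this step")
            accept = dp >= di
        else:
            accept = dp / product[k] >= di / impurity[k]
        if not accept:
            break
        k += 1
    return k


def pareto_analysis(observations, preferred: int | None = None) -> ParetoAnalysis:
    """Full stage-1 front analysis: front, percentage table, preferred point."""
    prod, imp = _as_objectives(observations)
    idx = nondominated((prod, imp))
    p, i = prod[idx], imp[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = 100.0 * np.diff(p) / p[:-1]
        di = 100.0 * np.diff(i) / np.where(i[:-1] > 0, i[:-1], np.nan)
    if preferred is None:
        preferred = diminishing_returns(p, i)
    return ParetoAnalysis(front_indices=idx, product=p, impurity=i,
                          dp_pct=dp, di_pct=di, preferred=int(preferred))


def infer_weights(product: np.ndarray, impurity: np.ndarray, preferred: int,
                  eps_floor: float = 1e-6) -> Weights:
    """Reverse-engineer scalarisation weights by linear programming.

    Maximises the margin eps subject to f(preferred) + eps <= f(j) for every
    other front point j, with both weights active (|w_amide| >= 0.05,
    w_enamine >= 0.05) and the l1 normalisation |w_amide| + w_enamine = 1.
    Raises ScalarisationError when no strict linear scalariser exists (the
    preferred point lies on a non-convex stretch of the front).
    """
    product = np.asarray(product, dtype=float)
    impurity = np.asarray(impurity, dtype=float)
    n = len(product)
    if n < 2:
        raise ValueError("need at least two front points to infer weights")
    if not (0 <= preferred < n):
        raise ValueError(f"preferred index {preferred} outside the front")
    dp = np.delete(product - product[preferred], preferred)
    di = np.delete(impurity - impurity[preferred], preferred)
    # variables (w_e, eps), w_a = w_e - 1:
    #   (w_e - 1) dp_j + w_e di_j >= eps   for all j != preferred
    a_ub = np.column_stack([-(dp + di), np.ones(n - 1)])
    b_ub = -dp
    res = linprog(c=[0.0, -1.0], A_ub=a_ub, b_ub=b_ub,
                  bounds=[(0.05, 0.95), (None, None)], method="highs")
    if not res.success:
        raise ScalarisationError(f"weight-inference LP failed: {res.message}")
    w_e, eps = res.x
    if eps <= eps_floor:
        raise ScalarisationError(
            "no strict linear scalariser prefers this point (margin "
            f"{eps:.2e} <= {eps_floor:.0e}); it lies on a non-convex "
            "stretch of the Pareto front"
        )
    return Weights(w_amide=float(w_e - 1.0), w_enamine=float(w_e),
                   margin=float(eps))


def scalarize(obs, weights: Weights = PAPER_WEIGHTS) -> float:
    """Weighted objective f = w_amide*product + w_enamine*impurity (minimise)."""
    if isinstance(obs, Observation):
        p, i = obs.product_norm, obs.impurity_norm
    else:
        p, i = obs
    return weights.w_amide * p + weights.w_enamine * i
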