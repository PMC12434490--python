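"""Optimisation domain for the flow amidation study.

Four continuous reactor variables (ester concentration, amine equivalents,
residence time, temperature) plus a categorical solvent. All model-side
computation happens on the unit cube; physical units are used for reporting
and for driving the reaction simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ContinuousVar",
    "DesignSpace",
    "Conditions",
    "default_space",
    "lhc_size_rule",
    "lhc_design",
    "stratified_lhc",
    "to_unit_cube",
    "from_unit_cube",
]


@dataclass(frozen=True)
class ContinuousVar:
    name: str
    lower: float
    upper: float
    unit: str

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"variable {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )


@dataclass(frozen=True)
class DesignSpace:
    """Box-bounded continuous variables plus one categorical variable."""

    continuous_vars: tuple[ContinuousVar, ...]
    categorical_name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("categorical level list must be non-empty")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("categorical levels must be unique")

    @property
    def n_continuous(self) -> int:
        return len(self.continuous_vars)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.continuous_vars)

    @property
    def lowers(self) -> np.ndarray:
        return np.array([v.lower for v in self.continuous_vars])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([v.upper for v in self.continuous_vars])


@dataclass(frozen=True)
class Conditions:
    """One reactor setting. ``solvent`` may be None for continuous-only designs."""

    concentration: float  # mM of ester 1
    equivalents: float    # amine 2 : ester 1 molar ratio
    residence_time: float  # min
    temperature: float    # degrees C
    solvent: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.concentration, self.equivalents, self.residence_time, self.temperature]
        )

    def with_solvent(self, solvent: str) -> "Conditions":
        return replace(self, solvent=solvent)


_FIELDS = ("concentration", "equivalents", "residence_time", "temperature")


def default_space() -> DesignSpace:
    """The study's design space: 200-350 mM, 1-4 equiv, 1-10 min, 25-60 degC,
    solvents MeCN / 2-MeTHF / anisole / dioxane."""
    return DesignSpace(
        continuous_vars=(
            ContinuousVar("concentration", 200.0, 350.0, "mM"),
            ContinuousVar("equivalents", 1.0, 4.0, ""),
            ContinuousVar("residence_time", 1.0, 10.0, "min"),
            ContinuousVar("temperature", 25.0, 60.0, "degC"),
        ),
        categorical_name="solvent",
        levels=("MeCN", "2-MeTHF", "anisole", "dioxane"),
    )


def lhc_size_rule(n_continuous: int) -> int:
    """Initial-design size 2n + 1 for n continuous variables."""
    if n_continuous < 1:
        raise ValueError(f"n_continuous must be >= 1, got {n_continuous}")
    return 2 * n_continuous + 1


def check_in_bounds(cond: Conditions, space: DesignSpace) -> None:
    x = cond.as_array()
    lo, hi = space.lowers, space.uppers
    for name, xi, l, u in zip(_FIELDS, x, lo, hi):
        if not (l <= xi <= u):
            raise ValueError(f"{name}={xi} outside bounds [{l}, {u}]")
    if cond.solvent is not None and cond.solvent not in space.levels:
        raise ValueError(f"unknown solvent level {cond.solvent!r}")


def _conditions_from_matrix(x: np.ndarray, space: DesignSpace) -> list[Conditions]:
    lo, hi = space.lowers, space.uppers
    phys = lo + x * (hi - lo)
    return [Conditions(*row) for row in phys]


def lhc_design(space: DesignSpace, n_points: int, seed: int) -> list[Conditions]:
    """Seeded random Latin hypercube over the continuous variables.

    One point per equal-width bin per dimension, sampled uniformly within
    its bin; the solvent is left unset.
    """
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    sampler = qmc.LatinHypercube(d=space.n_continuous, seed=seed)
    return _conditions_from_matrix(sampler.random(n_points), space)


def stratified_lhc(space: DesignSpace, n_points: int, seed: int) -> list[Conditions]:
    """LHC for the continuous part with solvents assigned evenly across levels.

    Levels are assigned to the LHC rows by a seeded block permutation, so each
    level receives exactly ``n_points / n_levels`` settings.
    """
    n_levels = len(space.levels)
    rem = n_points % n_levels
    if rem != 0:
        raise ValueError(
            f"n_points={n_points} not divisible by {n_levels} levels "
            f"(remainder {rem})"
        )
    conds = lhc_design(space, n_points, seed)
    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(n_levels), n_points // n_levels)
    rng.shuffle(assignment)
    return [c.with_solvent(space.levels[k]) for c, k in zip(conds, assignment)]


def to_unit_cube(cond: Conditions, space: DesignSpace) -> np.ndarray:
    """Affine map of the continuous part onto [0, 1]^n."""
    check_in_bounds(cond, space)
    lo, hi = space.lowers, space.uppers
    return (cond.as_array() - lo) / (hi - lo)


def from_unit_cube(
    x: np.ndarray, space: DesignSpace, solvent: str | None = None
) -> Conditions:
    x = np.asarray(x, dtype=float)
    if x.shape != (space.n_continuous,):
        raise ValueError(f"expected vector of length {space.n_continuous}")
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError(f"unit-cube coordinates outside [0, 1]: {x}")
    x = np.clip(x, 0.0, 1.0)
    lo, hi = space.lowers, space.uppers
    phys = lo + x * (hi - lo)
    cond = Conditions(*phys, solvent=solvent)
    if solvent is not None and solvent not in space.levels:
        raise ValueError(f"unknown solvent level {solvent!r}")
    return cond
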