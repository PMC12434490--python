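"""Stage-1 optimiser: multiobjective BO by Thompson sampling (TSEMO-style).

Maximise the amide product and minimise the enamine impurity over the four
continuous reactor variables with the solvent held fixed. Each iteration
fits one GP per objective, draws an approximate posterior sample from each
via a spectral (random Fourier feature) expansion, solves the two-objective
problem on the sampled surfaces with a compact NSGA-II, and proposes the
inner Pareto point with the largest hypervolume improvement over the
observed front.

Objectives are handled internally in minimisation orientation:
(-product, +impurity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .design_space import Conditions, DesignSpace, from_unit_cube, lhc_design
from .gp import GPConfig, GPFit, fit_gp
from .simulator import Observation, SimulatorParams, observe

__all__ = [
    "Experiment",
    "Campaign",
    "TsemoConfig",
    "thompson_sample",
    "hypervolume",
    "observed_front_min",
    "tsemo_step",
    "run_stage1",
    "nsga2",
]

# wall-clock charged per experiment: residence time plus fixed overhead for
# equilibration, sampling and the uHPLC method
EXPERIMENT_OVERHEAD_MIN = 10.0

logger = logging.getLogger("flowamide")


@dataclass(frozen=True)
class Experiment:
    conditions: Conditions
    observation: Observation
    clock_h: float
    objective_f: float | None = None

    def with_objective(self, f: float) -> "Experiment":
        return replace(self, objective_f=f)


@dataclass
class Campaign:
    """Append-only record of an optimisation run."""

    stage: str
    seed: int
    experiments: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.experiments)

    @property
    def clock_h(self) -> float:
        return self.experiments[-1].clock_h if self.experiments else 0.0

    def append(self, cond: Conditions, obs: Observation,
               objective_f: float | None = None) -> None:
        dt = (cond.residence_time + EXPERIMENT_OVERHEAD_MIN) / 60.0
        self.experiments.append(
            Experiment(cond, obs, self.clock_h + dt, objective_f))
        logger.info(
            "%s #%d: %.1f mM, %.2f equiv, %.2f min, %.1f C, %s -> "
            "product %.4f impurity %.4f%s", self.stage, len(self.experiments),
            cond.concentration, cond.equivalents, cond.residence_time,
            cond.temperature, cond.solvent, obs.product_norm,
            obs.impurity_norm,
            "" if objective_f is None else f" f {objective_f:.4f}")

    def conditions(self) -> list:
        return [e.conditions for e in self.experiments]

    def products(self) -> np.ndarray:
        return np.array([e.observation.product_norm for e in self.experiments])

    def impurities(self) -> np.ndarray:
        return np.array([e.observation.impurity_norm for e in self.experiments])

    def observations(self) -> list:
        return [e.observation for e in self.experiments]


@dataclass(frozen=True)
class TsemoConfig:
    n_features: int = 500          # spectral features per posterior draw
    population: int = 100          # inner NSGA-II population
    generations: int = 100         # inner NSGA-II generations
    ref_margin: float = 0.1        # nadir margin for the reference point
    gp: GPConfig = field(default_factory=lambda: GPConfig(n_restarts=3))


# ---------------------------------------------------------------------------
# Thompson sampling via spectral features
# ---------------------------------------------------------------------------

class ThompsonSample:
    """One deterministic draw from a GP posterior (spectral approximation).

    The Matérn-5/2 part is sampled through its spectral density (multivariate
    Student-t frequencies, 5 degrees of freedom); latent squared-exponential
    dimensions, when present, add Gaussian frequencies. Conditioning the
    Bayesian linear model on the training data yields a function drawn
    approximately from the posterior; the same seed reproduces the same draw.
    """

    def __init__(self, fit: GPFit, n_features: int = 500, seed: int = 0):
        if fit._chol is None and not fit.degenerate:
            raise ValueError("Thompson sampling requires a fitted GP")
        self.fit = fit
        rng = np.random.default_rng(seed)
        d = fit.X.shape[1]
        n_lat = 2 if fit.latent_coords is not None else 0
        m = n_features
        if fit.degenerate or fit.signal_var <= 0:
            self._const = fit.y_mean
            self._w = None
            return
        self._const = None
        # Matérn-5/2 spectral frequencies: scaled multivariate t with nu=5
        g = rng.standard_normal((m, d)) / fit.lengthscales
        u = rng.chisquare(5.0, size=m) / 5.0
        w_cont = g / np.sqrt(u)[:, None]
        if n_lat:
            w_lat = rng.standard_normal((m, n_lat))
            self._w = np.hstack([w_cont, w_lat])
        else:
            self._w = w_cont
        self._b = rng.uniform(0.0, 2.0 * np.pi, size=m)
        self._scale = np.sqrt(2.0 * fit.signal_var / m)
        phi = self._features(fit.X, fit.level_idx)
        nv = max(fit.noise_var, 1e-10)
        a = phi.T @ phi + nv * np.eye(m)
        a_chol = np.linalg.cholesky(a)
        mean_theta = np.linalg.solve(a_chol.T, np.linalg.solve(a_chol, phi.T @ fit.y))
        # theta ~ N(mean, nv * A^-1): sample via A^-1/2
        xi = rng.standard_normal(m)
        dev = np.sqrt(nv) * np.linalg.solve(a_chol.T, xi)
        self._theta = mean_theta + dev

    def _features(self, X: np.ndarray, lv) -> np.ndarray:
        z = X
        if self.fit.latent_coords is not None:
            z = np.hstack([X, self.fit.latent_coords[lv]])
        return self._scale * np.cos(z @ self._w.T + self._b)

    def __call__(self, X: np.ndarray, lv=None) -> np.ndarray:
        X = np.atleast_2d(X)
        if self._const is not None:
            return np.full(len(X), self._const)
        vals = self._features(X, lv) @ self._theta
        return self.fit.y_mean + self.fit.y_scale * vals


def thompson_sample(fit: GPFit, n_features: int = 500, seed: int = 0) -> ThompsonSample:
    return ThompsonSample(fit, n_features=n_features, seed=seed)


# ---------------------------------------------------------------------------
# Hypervolume (2D, minimisation)
# ---------------------------------------------------------------------------

def hypervolume(points: np.ndarray, reference: np.ndarray) -> float:
    """Dominated 2D hypervolume of a point set w.r.t. a reference (min-min).

    The reference must be strictly dominated by at least the contributing
    points; a reference lying inside the front region is rejected.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if pts.shape[1] != 2 or ref.shape != (2,):
        raise ValueError("hypervolume is implemented for two objectives")
    # nondominated sweep (min-min): sort by (x, y), keep strictly falling y
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    front = []
    y_min = np.inf
    for x, y in pts[order]:
        if y < y_min:
            front.append((x, y))
            y_min = y
    front = np.array(front)
    if np.any(np.all(front >= ref, axis=1)):
        raise ValueError("reference point lies inside the front region")
    front = front[np.all(front < ref, axis=1)]
    if len(front) == 0:
        return 0.0
    hv, y_prev = 0.0, ref[1]
    for x, y in front:
        if y < y_prev:
            hv += (ref[0] - x) * (y_prev - y)
            y_prev = y
    return float(hv)


def observed_front_min(campaign: Campaign) -> np.ndarray:
    """Observed objectives in minimisation orientation (-product, impurity)."""
    return np.column_stack([-campaign.products(), campaign.impurities()])


# ---------------------------------------------------------------------------
# Compact NSGA-II (box-bounded, 2 objectives)
# ---------------------------------------------------------------------------

def _fast_nondominated_rank(F: np.ndarray) -> np.ndarray:
    n = len(F)
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dom = dom.sum(axis=0)
    ranks = np.full(n, -1)
    current = np.flatnonzero(n_dom == 0)
    r = 0
    remaining = n_dom.copy()
    while len(current):
        ranks[current] = r
        remaining = remaining - dom[current].sum(axis=0)
        remaining[current] = -1
        current = np.flatnonzero(remaining == 0)
        r += 1
    return ranks


def _crowding(F: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    n = len(F)
    crowd = np.zeros(n)
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        if len(idx) <= 2:
            crowd[idx] = np.inf
            continue
        for obj in range(F.shape[1]):
            order = idx[np.argsort(F[idx, obj], kind="stable")]
            span = F[order[-1], obj] - F[order[0], obj]
            crowd[order[0]] = crowd[order[-1]] = np.inf
            if span > 0:
                crowd[order[1:-1]] += (F[order[2:], obj] - F[order[:-2], obj]) / span
    return crowd


def _sbx(parents_a, parents_b, rng, eta=15.0):
    u = rng.random(parents_a.shape)
    beta = np.where(u <= 0.5,
                    (2.0 * u) ** (1.0 / (eta + 1.0)),
                    (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
    swap = rng.random(parents_a.shape) < 0.5
    beta = np.where(swap, beta, 1.0)
    c1 = 0.5 * ((1 + beta) * parents_a + (1 - beta) * parents_b)
    return np.clip(c1, 0.0, 1.0)


def _poly_mutation(X, rng, eta=20.0, p=None):
    p = p if p is not None else 1.0 / X.shape[1]
    mask = rng.random(X.shape) < p
    u = rng.random(X.shape)
    delta = np.where(u < 0.5,
                     (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0,
                     1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0)))
    return np.clip(np.where(mask, X + delta, X), 0.0, 1.0)


def nsga2(objective, n_var: int, population: int = 100, generations: int = 100,
          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Minimise a vectorised 2-objective function over the unit box.

    Returns the nondominated subset (decision vectors, objective values) of
    the final population.
    """
    rng = np.random.default_rng(seed)
    X = rng.random((population, n_var))
    F = np.atleast_2d(objective(X))
    for _ in range(generations):
        ranks = _fast_nondominated_rank(F)
        crowd = _crowding(F, ranks)
        # binary tournament on (rank, -crowding)
        cand = rng.integers(population, size=(2, 2 * population))
        better = np.where(
            (ranks[cand[0]] < ranks[cand[1]]) |
            ((ranks[cand[0]] == ranks[cand[1]]) & (crowd[cand[0]] >= crowd[cand[1]])),
            cand[0], cand[1])
        pa, pb = X[better[:population]], X[better[population:]]
        off = _poly_mutation(_sbx(pa, pb, rng), rng)
        F_off = np.atleast_2d(objective(off))
        X_all = np.vstack([X, off])
        F_all = np.vstack([F, F_off])
        ranks_all = _fast_nondominated_rank(F_all)
        crowd_all = _crowding(F_all, ranks_all)
        order = np.lexsort((-crowd_all, ranks_all))
        sel = order[:population]
        X, F = X_all[sel], F_all[sel]
    ranks = _fast_nondominated_rank(F)
    front = ranks == 0
    return X[front], F[front]


# ---------------------------------------------------------------------------
# TSEMO step and stage-1 driver
# ---------------------------------------------------------------------------

def _reference_point(front_min: np.ndarray, margin: float) -> np.ndarray:
    nadir = front_min.max(axis=0)
    span = front_min.max(axis=0) - front_min.min(axis=0)
    return nadir + margin * np.where(span > 0, span, np.abs(nadir) + 1.0)


def tsemo_step(campaign: Campaign, space: DesignSpace, solvent: str,
               config: TsemoConfig | None = None, seed: int = 0) -> Conditions:
    """Propose the next reactor setting by Thompson-sampled hypervolume improvement."""
    config = config or TsemoConfig()
    if len(campaign) == 0:
        raise ValueError("campaign must contain at least one experiment")
    conds = campaign.conditions()
    prod_data = list(zip(conds, campaign.products()))
    imp_data = list(zip(conds, campaign.impurities()))
    ss = np.random.SeedSequence(seed)
    s_fit_p, s_fit_i, s_ts_p, s_ts_i, s_inner, s_fb = ss.generate_state(6) >> 1
    try:
        fit_p = fit_gp(prod_data, space, replace(config.gp, seed=int(s_fit_p)))
        fit_i = fit_gp(imp_data, space, replace(config.gp, seed=int(s_fit_i)))
        ts_p = thompson_sample(fit_p, config.n_features, seed=int(s_ts_p))
        ts_i = thompson_sample(fit_i, config.n_features, seed=int(s_ts_i))

        def inner(X):
            return np.column_stack([-ts_p(X), ts_i(X)])

        X_cand, F_cand = nsga2(inner, space.n_continuous,
                               population=config.population,
                               generations=config.generations,
                               seed=int(s_inner))
    except Exception as exc:  # pragma: no cover - defensive fallback
        warnings.warn(f"inner multiobjective solve failed ({exc}); "
                      "proposing a random in-bounds candidate")
        rng = np.random.default_rng(int(s_fb))
        return from_unit_cube(rng.random(space.n_continuous), space, solvent)
    if len(X_cand) == 1:
        return from_unit_cube(X_cand[0], space, solvent)
    front = observed_front_min(campaign)
    ref = _reference_point(front, config.ref_margin)
    hv0 = hypervolume(front, ref)
    best_k, best_hvi = 0, -np.inf
    for k, f_k in enumerate(F_cand):
        if np.any(f_k >= ref):
            hvi = 0.0
        else:
            hvi = hypervolume(np.vstack([front, f_k]), ref) - hv0
        if hvi > best_hvi:
            best_k, best_hvi = k, hvi
    return from_unit_cube(X_cand[best_k], space, solvent)


def run_stage1(params: SimulatorParams, space: DesignSpace,
               solvent: str = "MeCN", n_init: int = 9, n_iter: int = 60,
               seed: int = 0, config: TsemoConfig | None = None) -> Campaign:
    """LHC initialisation followed by sequential TSEMO proposals.

    With the study defaults (9 + 60) this reproduces the 69-experiment
    stage-1 campaign on the simulator.
    """
    config = config or TsemoConfig()
    ss = np.random.SeedSequence(seed)
    s_lhc, s_obs, s_steps = (int(s) >> 1 for s in ss.generate_state(3))
    campaign = Campaign(stage="stage1", seed=seed)
    obs_rng = np.random.default_rng(s_obs)
    for cond in lhc_design(space, n_init, seed=s_lhc):
        cond = cond.with_solvent(solvent)
        campaign.append(cond, observe(cond, params,
                                      seed=int(obs_rng.integers(2**31 - 1)),
                                      t_elapsed_h=campaign.clock_h, space=space))
    step_rng = np.random.default_rng(s_steps)
    for _ in range(n_iter):
        cond = tsemo_step(campaign, space, solvent, config,
                          seed=int(step_rng.integers(2**31 - 1)))
        campaign.append(cond, observe(cond, params,
                                      seed=int(obs_rng.integers(2**31 - 1)),
                                      t_elapsed_h=campaign.clock_h, space=space))
    return campaign
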