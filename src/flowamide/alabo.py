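"""Stage-2 optimiser: scalarised mixed-variable BO with latent solvent embedding.

Minimises the weighted objective f = w_amide*product + w_enamine*impurity
over the four continuous variables plus the categorical solvent. A single
latent-variable GP is fitted to f; expected improvement is maximised per
solvent over the continuous unit cube by multi-start local search, and the
best (solvent, conditions) pair is proposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .design_space import Conditions, DesignSpace, from_unit_cube, stratified_lhc
from .gp import GPConfig, GPFit, fit_gp, predict, predict_encoded
from .pareto import Weights, scalarize
from .simulator import SimulatorParams, observe
from .tsemo import Campaign

__all__ = ["AlaboConfig", "expected_improvement", "alabo_step", "run_stage2"]


@dataclass(frozen=True)
class AlaboConfig:
    n_starts: int = 20             # EI multistart count per solvent
    gp: GPConfig = field(default_factory=lambda: GPConfig(n_restarts=3))


def _ei_from_moments(mean: np.ndarray, var: np.ndarray, best: float) -> np.ndarray:
    """Expected improvement for minimisation; exact at zero variance."""
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    std = np.sqrt(np.maximum(var, 0.0))
    imp = best - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std > 0, imp / np.where(std > 0, std, 1.0), 0.0)
    ei = np.where(std > 0, imp * norm.cdf(z) + std * norm.pdf(z),
                  np.maximum(imp, 0.0))
    return np.maximum(ei, 0.0)


def expected_improvement(fit: GPFit, best_f: float, cond: Conditions) -> float:
    """EI (minimisation) of one candidate under the fitted GP on f."""
    mean, var = predict(fit, [cond])
    return float(_ei_from_moments(mean, var, best_f)[0])


def alabo_step(campaign: Campaign, space: DesignSpace, weights: Weights,
               config: AlaboConfig | None = None, seed: int = 0) -> Conditions:
    """Propose the next (solvent, conditions) pair by per-solvent EI maximisation."""
    config = config or AlaboConfig()
    solvents_seen = {e.conditions.solvent for e in campaign.experiments}
    missing = set(space.levels) - solvents_seen
    if missing:
        raise ValueError(f"campaign must cover every solvent; missing {sorted(missing)}")
    f_vals = np.array([scalarize(e.observation, weights)
                       for e in campaign.experiments])
    data = list(zip(campaign.conditions(), f_vals))
    ss = np.random.SeedSequence(seed)
    s_fit, s_starts, s_fb = (int(s) >> 1 for s in ss.generate_state(3))
    fit = fit_gp(data, space, replace(config.gp, seed=s_fit))
    best_f = float(f_vals.min())
    rng = np.random.default_rng(s_starts)
    d = space.n_continuous

    best = None  # (ei, solvent, x)
    for lv_idx, solvent in enumerate(fit.levels or space.levels):
        lv_of = (np.full(1, lv_idx) if fit.levels else None)

        def neg_ei(x):
            mean, var = predict_encoded(fit, x[None, :], lv_of)
            return -float(_ei_from_moments(mean, var, best_f)[0])

        # seeded random starts plus the incumbent's continuous setting
        starts = [rng.random(d) for _ in range(config.n_starts - 1)]
        starts.append(fit.X[int(np.argmin(f_vals))])
        for x0 in starts:
            try:
                res = minimize(neg_ei, x0, method="L-BFGS-B",
                               bounds=[(0.0, 1.0)] * d)
                x, val = np.clip(res.x, 0.0, 1.0), res.fun
            except Exception:  # pragma: no cover - optimiser hiccup
                x, val = x0, neg_ei(x0)
            if best is None or val < best[0]:
                best = (val, solvent, x)

    if best is None or not np.isfinite(best[0]):
        warnings.warn("EI maximisation failed; proposing a random candidate")
        rng_fb = np.random.default_rng(s_fb)
        solvent = space.levels[int(rng_fb.integers(len(space.levels)))]
        return from_unit_cube(rng_fb.random(d), space, solvent)
    return from_unit_cube(best[2], space, best[1])


def run_stage2(params: SimulatorParams, space: DesignSpace, weights: Weights,
               n_init: int = 12, n_iter: int = 27, seed: int = 0,
               config: AlaboConfig | None = None) -> Campaign:
    """Solvent-stratified LHC initialisation followed by sequential EI proposals.

    With the study defaults (12 + 27) this reproduces the 39-experiment
    stage-2 campaign; the scalarised objective is recorded per experiment so
    the raw peak areas can be re-weighted without rerunning anything.
    """
    config = config or AlaboConfig()
    ss = np.random.SeedSequence(seed)
    s_lhc, s_obs, s_steps = (int(s) >> 1 for s in ss.generate_state(3))
    campaign = Campaign(stage="stage2", seed=seed)
    obs_rng = np.random.default_rng(s_obs)

    def run(cond: Conditions) -> None:
        obs = observe(cond, params, seed=int(obs_rng.integers(2**31 - 1)),
                      t_elapsed_h=campaign.clock_h, space=space)
        campaign.append(cond, obs, objective_f=float(scalarize(obs, weights)))

    for cond in stratified_lhc(space, n_init, seed=s_lhc):
        run(cond)
    step_rng = np.random.default_rng(s_steps)
    for _ in range(n_iter):
        run(alabo_step(campaign, space, weights, config,
                       seed=int(step_rng.integers(2**31 - 1))))
    return campaign
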