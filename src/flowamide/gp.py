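"""Gaussian-process surrogates with a learned 2D solvent embedding.

The kernel is a product of a Matérn-5/2 ARD kernel over the continuous
variables (on the unit cube) and a unit-lengthscale squared-exponential
kernel over two latent coordinates learned per solvent; hyperparameters and
latent coordinates jointly maximise the log marginal likelihood under
multi-restart L-BFGS-B. Identifiability is enforced by pinning the first
solvent at the latent origin and the second solvent to the first latent axis,
so any 1D collapse of the embedding has to emerge from the data.

Targets are standardised to zero mean / unit variance before fitting and
predictions are mapped back to the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .design_space import Conditions, DesignSpace, to_unit_cube

__all__ = ["GPConfig", "GPFit", "LoocvReport", "fit_gp", "predict", "loocv"]

_SQRT5 = np.sqrt(5.0)


@dataclass(frozen=True)
class GPConfig:
    n_restarts: int = 10
    seed: int = 0
    lengthscale_bounds: tuple[float, float] = (0.01, 100.0)
    signal_bounds: tuple[float, float] = (1e-4, 100.0)
    noise_bounds: tuple[float, float] = (1e-8, 1.0)
    latent_bound: float = 5.0
    jitter: float = 1e-10
    fixed_noise: float | None = None  # standardised-scale noise variance
    noise_floor: float = 0.0  # known measurement noise std, original scale
    latent_prior_std: float = 1.5  # Gaussian prior on latent coords (MAP)


@dataclass
class GPFit:
    """Fitted surrogate (hyperparameters on the unit-cube / standardised scale)."""

    X: np.ndarray                       # n x d continuous inputs, unit cube
    level_idx: np.ndarray | None        # per-point solvent index, or None
    levels: tuple[str, ...] | None      # solvent names in embedding order
    y: np.ndarray                       # standardised targets
    y_mean: float                       # constant mean on the original scale
    y_scale: float
    signal_var: float
    noise_var: float
    lengthscales: np.ndarray            # one per continuous dimension
    latent_coords: np.ndarray | None    # n_levels x 2
    space: DesignSpace
    lml: float
    restart_initial_lml: tuple          # lml at each restart's starting point
    jitter_used: float
    degenerate: bool = False
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean_const(self) -> float:
        return self.y_mean

    def latent_table(self) -> dict:
        if self.latent_coords is None:
            return {}
        return {lvl: tuple(map(float, z))
                for lvl, z in zip(self.levels, self.latent_coords)}

    def to_dict(self) -> dict:
        return {
            "mean": float(self.y_mean),
            "target_scale": float(self.y_scale),
            "signal_variance": float(self.signal_var),
            "noise_variance": float(self.noise_var),
            "lengthscales": {name: float(l) for name, l in
                             zip(self.space.names, self.lengthscales)},
            "latent_coords": self.latent_table(),
            "log_marginal_likelihood": float(self.lml),
            "jitter": float(self.jitter_used),
        }


@dataclass(frozen=True)
class LoocvReport:
    predictions: np.ndarray   # held-out posterior means, original scale
    targets: np.ndarray
    r2: float


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

def _matern52(X1: np.ndarray, X2: np.ndarray, lengthscales: np.ndarray) -> np.ndarray:
    diff = (X1[:, None, :] - X2[None, :, :]) / lengthscales
    d = np.sqrt(np.maximum(np.sum(diff * diff, axis=-1), 0.0))
    sd = _SQRT5 * d
    return (1.0 + sd + sd * sd / 3.0) * np.exp(-sd)


def _latent_se(Z1: np.ndarray, Z2: np.ndarray) -> np.ndarray:
    diff = Z1[:, None, :] - Z2[None, :, :]
    return np.exp(-0.5 * np.sum(diff * diff, axis=-1))


def kernel_matrix(X1, lv1, X2, lv2, signal_var, lengthscales, latent_coords):
    k = signal_var * _matern52(X1, X2, lengthscales)
    if latent_coords is not None:
        k = k * _latent_se(latent_coords[lv1], latent_coords[lv2])
    return k


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, d: int, n_levels: int):
    sv = np.exp(theta[0])
    nv = np.exp(theta[1])
    ls = np.exp(theta[2:2 + d])
    if n_levels >= 2:
        z = np.zeros((n_levels, 2))
        free = theta[2 + d:]
        z[1, 0] = free[0]
        for k in range(2, n_levels):
            z[k] = free[1 + 2 * (k - 2): 3 + 2 * (k - 2)]
    else:
        z = None
    return sv, nv, ls, z


def _nlml(theta, X, lv, y, d, n_levels, jitter, fixed_noise,
          latent_prior_var=None):
    sv, nv, ls, z = _unpack(theta, d, n_levels)
    if fixed_noise is not None:
        nv = fixed_noise
    n = len(y)
    K = kernel_matrix(X, lv, X, lv, sv, ls, z)
    K[np.diag_indices_from(K)] += nv + jitter * sv
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return 1e12
    alpha = solve_triangular(
        L.T, solve_triangular(L, y, lower=True), lower=False)
    nll = float(0.5 * y @ alpha + np.sum(np.log(np.diag(L)))
                + 0.5 * n * np.log(2.0 * np.pi))
    if n_levels >= 2 and latent_prior_var:
        # MAP: zero-mean Gaussian prior on the free latent coordinates keeps
        # categories together unless the data support separating them
        nll += 0.5 * float(np.sum(theta[2 + d:] ** 2)) / latent_prior_var
    return nll


def _prepare(data, space):
    X, y, solvents = [], [], []
    for cond, target in data:
        X.append(to_unit_cube(cond, space))
        y.append(float(target))
        solvents.append(cond.solvent)
    X = np.array(X)
    y = np.array(y)
    present = [lvl for lvl in space.levels if lvl in set(solvents)]
    return X, y, solvents, present


def fit_gp(data, space: DesignSpace, config: GPConfig | None = None) -> GPFit:
    """Fit the latent-variable GP to (Conditions, scalar target) pairs.

    The solvent embedding is active only when at least two solvents are
    present in the data; otherwise a purely continuous ARD model is fitted.
    """
    config = config or GPConfig()
    if len(data) < 3:
        raise ValueError(f"need at least 3 points to fit a GP, got {len(data)}")
    X, y, solvents, present = _prepare(data, space)
    d = space.n_continuous
    categorical = len(present) >= 2
    if categorical:
        lv = np.array([present.index(s) for s in solvents])
        n_levels = len(present)
    else:
        lv, n_levels = None, 0

    y_mean = float(np.mean(y))
    y_scale = float(np.std(y))
    ls_lo, ls_hi = config.lengthscale_bounds
    if y_scale < 1e-12:
        warnings.warn("degenerate targets (zero variance); returning a "
                      "flat fit with lengthscales at their upper bound")
        n_free_lat = 0 if not categorical else 1 + 2 * (n_levels - 2)
        return GPFit(
            X=X, level_idx=lv,
            levels=tuple(present) if categorical else None,
            y=np.zeros_like(y), y_mean=y_mean, y_scale=1.0,
            signal_var=config.signal_bounds[0], noise_var=config.noise_bounds[0],
            lengthscales=np.full(d, ls_hi),
            latent_coords=np.zeros((n_levels, 2)) if categorical else None,
            space=space, lml=0.0, restart_initial_lml=(),
            jitter_used=config.jitter, degenerate=True,
        )
    ys = (y - y_mean) / y_scale

    n_lat_free = (1 + 2 * (n_levels - 2)) if categorical else 0
    # the fitted noise may not drop below the known measurement noise
    nv_lo = max(config.noise_bounds[0], (config.noise_floor / y_scale) ** 2)
    nv_lo = min(nv_lo, 0.5 * config.noise_bounds[1])
    bounds = ([(np.log(config.signal_bounds[0]), np.log(config.signal_bounds[1])),
               (np.log(nv_lo), np.log(config.noise_bounds[1]))]
              + [(np.log(ls_lo), np.log(ls_hi))] * d
              + [(-config.latent_bound, config.latent_bound)] * n_lat_free)

    rng = np.random.default_rng(config.seed)
    starts = []
    base = np.concatenate([
        [0.0, np.log(1e-2)], np.full(d, np.log(0.5)),
        0.1 * rng.standard_normal(n_lat_free)])
    starts.append(base)
    for _ in range(config.n_restarts - 1):
        starts.append(np.concatenate([
            [rng.uniform(-1, 1), rng.uniform(np.log(1e-4), np.log(0.5))],
            rng.uniform(np.log(0.05), np.log(20.0), size=d),
            rng.uniform(-1.5, 1.5, size=n_lat_free)]))

    args = (X, lv, ys, d, n_levels, config.jitter, config.fixed_noise,
            config.latent_prior_std ** 2)
    best, initial_lmls = None, []
    for x0 in starts:
        initial_lmls.append(-_nlml(x0, *args))
        res = minimize(_nlml, x0, args=args, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res

    sv, nv, ls, z = _unpack(best.x, d, n_levels)
    if config.fixed_noise is not None:
        nv = config.fixed_noise
    K = kernel_matrix(X, lv, X, lv, sv, ls, z)
    K[np.diag_indices_from(K)] += nv + config.jitter * sv
    L = np.linalg.cholesky(K)
    alpha = solve_triangular(L.T, solve_triangular(L, ys, lower=True), lower=False)
    return GPFit(
        X=X, level_idx=lv, levels=tuple(present) if categorical else None,
        y=ys, y_mean=y_mean, y_scale=y_scale,
        signal_var=float(sv), noise_var=float(nv), lengthscales=ls,
        latent_coords=z, space=space, lml=float(-best.fun),
        restart_initial_lml=tuple(initial_lmls),
        jitter_used=config.jitter, _chol=L, _alpha=alpha,
    )


def _encode(fit: GPFit, conds) -> tuple[np.ndarray, np.ndarray | None]:
    X = np.array([to_unit_cube(c, fit.space) for c in conds])
    if fit.levels is None:
        return X, None
    lv = []
    for c in conds:
        if c.solvent not in fit.levels:
            raise ValueError(f"unknown solvent level {c.solvent!r}")
        lv.append(fit.levels.index(c.solvent))
    return X, np.array(lv)


def predict(fit: GPFit, conds) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance (original target scale) at the conditions."""
    X_star, lv_star = _encode(fit, conds)
    return predict_encoded(fit, X_star, lv_star)


def predict_encoded(fit: GPFit, X_star: np.ndarray,
                    lv_star: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """As ``predict`` but on pre-encoded unit-cube inputs (hot path for BO)."""
    if fit.degenerate or fit._chol is None:
        mean = np.full(len(X_star), fit.y_mean)
        var = np.full(len(X_star), (fit.signal_var + fit.noise_var))
        return mean, var * fit.y_scale**2
    Ks = kernel_matrix(X_star, lv_star, fit.X, fit.level_idx,
                       fit.signal_var, fit.lengthscales, fit.latent_coords)
    mean_s = Ks @ fit._alpha
    v = solve_triangular(fit._chol, Ks.T, lower=True)
    var_s = fit.signal_var - np.sum(v * v, axis=0)
    var_s = np.maximum(var_s, 0.0)
    mean = fit.y_mean + fit.y_scale * mean_s
    var = var_s * fit.y_scale**2
    return mean, var


def loocv(data, space: DesignSpace, config: GPConfig | None = None,
          fit: GPFit | None = None) -> LoocvReport:
    """Leave-one-out cross-validation via the closed-form rank-one downdate.

    Hyperparameters are those of the full-data fit; held-out predictions use
    the standard LOO identities on the inverse kernel matrix.
    """
    if len(data) < 5:
        raise ValueError(f"need at least 5 points for LOOCV, got {len(data)}")
    y = np.array([t for _, t in data], dtype=float)
    if np.std(y) < 1e-12:
        raise ValueError("LOOCV R^2 undefined: targets have zero variance")
    fit = fit or fit_gp(data, space, config)
    K = kernel_matrix(fit.X, fit.level_idx, fit.X, fit.level_idx,
                      fit.signal_var, fit.lengthscales, fit.latent_coords)
    K[np.diag_indices_from(K)] += fit.noise_var + fit.jitter_used * fit.signal_var
    Kinv = cho_solve(cho_factor(K, lower=True), np.eye(len(y)))
    diag = np.diag(Kinv)
    mu_loo_s = fit.y - (Kinv @ fit.y) / diag
    preds = fit.y_mean + fit.y_scale * mu_loo_s
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return LoocvReport(predictions=preds, targets=y, r2=1.0 - ss_res / ss_tot)
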