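"""Post-campaign model interrogation.

Ranks the continuous variables by ARD kernel lengthscale (smaller = more
influential), reports the learned 2D solvent embedding and its pairwise
distances, traces partial-dependence curves per solvent, and bundles the
whole analysis — Pareto table, weights, best conditions, productivity — into
a plain-text report directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design_space import DesignSpace, from_unit_cube
from .gp import GPFit, predict_encoded

__all__ = [
    "lengthscale_importance",
    "latent_geometry",
    "partial_dependence",
    "campaign_report",
]


def lengthscale_importance(fit: GPFit) -> pd.DataFrame:
    """Continuous variables ranked by ARD lengthscale, most influential first.

    A fit whose lengthscales all sit at their upper bound carries no
    directional information; the ranking is then flagged non-informative.
    """
    ls = np.asarray(fit.lengthscales, dtype=float)
    df = pd.DataFrame({
        "variable": list(fit.space.names),
        "lengthscale": ls,
        "log10_lengthscale": np.log10(ls),
    }).sort_values("lengthscale", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    upper = ls.max()
    df.attrs["informative"] = not (fit.degenerate or
                                   bool(np.all(ls >= 0.99 * upper)))
    return df


def latent_geometry(fit_product: GPFit, fit_impurity: GPFit) -> dict:
    """Per-solvent latent coordinates and pairwise distances for both models.

    Flags a 1D collapse when the coordinate range along the second latent
    axis is below 1e-3 of the range along the first.
    """
    out = {}
    for name, fit in (("product", fit_product), ("impurity", fit_impurity)):
        if fit.latent_coords is None:
            raise ValueError(f"{name} model has no latent solvent embedding")
        z = np.asarray(fit.latent_coords, dtype=float)
        levels = list(fit.levels)
        dist = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=-1)
        span = z.max(axis=0) - z.min(axis=0)
        collapsed = bool(span[1] < 1e-3 * max(span[0], 1e-30))
        out[name] = {
            "levels": levels,
            "coords": {lvl: [float(z[k, 0]), float(z[k, 1])]
                       for k, lvl in enumerate(levels)},
            "distances": pd.DataFrame(dist, index=levels, columns=levels),
            "max_pairwise_distance": float(dist.max()),
            "collapsed_to_1d": collapsed,
        }
    return out


def campaign_medians(fit: GPFit) -> np.ndarray:
    """Per-dimension medians (unit cube) of the campaign the model was fit to."""
    return np.median(fit.X, axis=0)


def partial_dependence(fit: GPFit, variable: str,
                       solvents: list[str] | None = None,
                       grid_size: int = 50) -> dict:
    """Posterior-mean sweep of one continuous variable, others at their medians.

    Returns the physical grid and one predicted-mean curve per requested
    solvent (all embedded solvents by default; a single unnamed curve for a
    continuous-only model).
    """
    names = list(fit.space.names)
    if variable not in names:
        raise ValueError(f"unknown continuous variable {variable!r}")
    j = names.index(variable)
    med = campaign_medians(fit)
    grid_u = np.linspace(0.0, 1.0, grid_size)
    X = np.tile(med, (grid_size, 1))
    X[:, j] = grid_u
    var = fit.space.continuous_vars[j]
    grid_phys = var.lower + grid_u * (var.upper - var.lower)
    curves = {}
    if fit.levels is None:
        if solvents:
            raise ValueError("model has no solvent embedding")
        mean, _ = predict_encoded(fit, X, None)
        curves[None] = mean
    else:
        for s in (solvents if solvents is not None else list(fit.levels)):
            if s not in fit.levels:
                raise ValueError(f"unknown solvent level {s!r}")
            lv = np.full(grid_size, fit.levels.index(s))
            mean, _ = predict_encoded(fit, X, lv)
            curves[s] = mean
    return {"variable": variable, "grid": grid_phys, "curves": curves}


def _best_by_solvent(campaign) -> pd.DataFrame:
    rows = []
    for e in campaign.experiments:
        c, o = e.conditions, e.observation
        rows.append({"solvent": c.solvent, "concentration_mM": c.concentration,
                     "equivalents": c.equivalents,
                     "residence_time_min": c.residence_time,
                     "temperature_C": c.temperature,
                     "product_norm": o.product_norm,
                     "impurity_norm": o.impurity_norm,
                     "objective_f": e.objective_f})
    df = pd.DataFrame(rows)
    return (df.sort_values(["solvent", "objective_f"], kind="stable")
              .groupby("solvent", sort=True).head(1).reset_index(drop=True))


def campaign_report(stage1, stage2, fit_product: GPFit, fit_impurity: GPFit,
                    analysis, weights, out_dir, sty: dict | None = None) -> dict:
    """Write the full analysis bundle (CSV tables + JSON summary) to ``out_dir``.

    Float formatting and orderings are fixed, so rerunning on the same
    campaigns reproduces the files byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def write_csv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False, float_format="%.10g",
                  lineterminator="\n")

    write_csv(pd.DataFrame(analysis.table()), "pareto_front.csv")
    write_csv(lengthscale_importance(fit_product), "lengthscales_product.csv")
    write_csv(lengthscale_importance(fit_impurity), "lengthscales_impurity.csv")

    geom = latent_geometry(fit_product, fit_impurity)
    latent_rows = []
    for lvl in geom["product"]["levels"]:
        latent_rows.append({
            "solvent": lvl,
            "product_z1": geom["product"]["coords"][lvl][0],
            "product_z2": geom["product"]["coords"][lvl][1],
            "impurity_z1": geom["impurity"]["coords"][lvl][0],
            "impurity_z2": geom["impurity"]["coords"][lvl][1],
        })
    write_csv(pd.DataFrame(latent_rows), "latent_coords.csv")

    pdp_frames = []
    for variable in fit_product.space.names:
        for model_name, fit in (("product", fit_product),
                                ("impurity", fit_impurity)):
            pdp = partial_dependence(fit, variable)
            for solvent, curve in pdp["curves"].items():
                pdp_frames.append(pd.DataFrame({
                    "model": model_name, "variable": variable,
                    "solvent": solvent, "value": pdp["grid"],
                    "predicted_mean": curve}))
    write_csv(pd.concat(pdp_frames, ignore_index=True), "partial_dependence.csv")

    best2 = _best_by_solvent(stage2)
    write_csv(best2, "best_by_solvent.csv")
    best_row = best2.loc[best2["objective_f"].idxmin()]

    summary = {
        "stage1_experiments": len(stage1),
        "stage2_experiments": len(stage2),
        "weights": weights.to_dict(),
        "preferred_front_point": {
            "product_norm": float(analysis.product[analysis.preferred]),
            "impurity_norm": float(analysis.impurity[analysis.preferred]),
        },
        "best_stage2": {k: (float(v) if isinstance(v, (int, float, np.floating))
                            else v) for k, v in best_row.items()},
        "conversion_at_best": float(best_row["product_norm"]
                                    + best_row["impurity_norm"]),
        "selectivity_at_best": float(best_row["product_norm"]
                                     / best_row["impurity_norm"]),
        "latent_collapsed_to_1d": {m: geom[m]["collapsed_to_1d"]
                                   for m in ("product", "impurity")},
        "gp_product": fit_product.to_dict(),
        "gp_impurity": fit_impurity.to_dict(),
    }
    if sty is not None:
        summary["space_time_yield"] = sty
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
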