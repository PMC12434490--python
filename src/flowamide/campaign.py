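"""Campaign persistence, configuration, productivity metrics and orchestration.

Owns the versioned campaign CSV schema, the structured YAML study
configuration, the space-time-yield calculator, and ``run_full_study`` — the
single entry point that chains calibration, the enzyme stability protocol,
both optimisation stages, weight inference and model interpretation into a
reproducible artifact directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alabo import AlaboConfig, run_stage2
from .design_space import Conditions, DesignSpace, check_in_bounds, default_space
from .gp import GPConfig, fit_gp
from .interpret import campaign_report
from .pareto import (ParetoAnalysis, ScalarisationError, Weights,
                     infer_weights, pareto_analysis, scalarize)
from .simulator import calibrate, stability_protocol
from .tsemo import Campaign, TsemoConfig, run_stage1

__all__ = [
    "CSV_COLUMNS",
    "StyInputs",
    "PRODUCT_MOLAR_MASS",
    "compute_sty",
    "write_campaign",
    "read_campaign",
    "default_config",
    "load_config",
    "robust_weights",
    "run_full_study",
]

logger = logging.getLogger("flowamide")

#: molar mass of N-benzyl acetoacetamide (C11H13NO2), g/mol
PRODUCT_MOLAR_MASS = 191.23

CSV_VERSION = "flowamide-campaign-v1"
CSV_COLUMNS = ["run_id", "stage", "clock_h", "concentration_mM", "equivalents",
               "residence_time_min", "temperature_C", "solvent",
               "product_norm", "impurity_norm", "objective_f", "seed"]


# ---------------------------------------------------------------------------
# Space-time yield
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StyInputs:
    """Inputs to the space-time-yield calculation.

    concentration is that of the limiting ester (mol per L), time the
    residence time for flow runs or the reaction time for batch (hours).
    """

    concentration: float   # mol / L
    yield_fraction: float  # dimensionless, <= 1
    time: float            # h
    molar_mass: float = PRODUCT_MOLAR_MASS  # g / mol

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.concentration <= 0 or self.molar_mass <= 0:
            raise ValueError("concentration and molar mass must be positive")
        if not (0.0 <= self.yield_fraction <= 1.0):
            raise ValueError("yield fraction must lie in [0, 1]")


def compute_sty(inputs: StyInputs) -> float:
    """Space-time yield, g of product per litre of reactor per hour."""
    return (inputs.concentration * inputs.yield_fraction * inputs.molar_mass
            / inputs.time)


# ---------------------------------------------------------------------------
# Campaign CSV
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    return "" if x is None else f"{x:.10g}"


def write_campaign(campaign: Campaign, path) -> None:
    """Write a campaign to its versioned CSV representation."""
    path = Path(path)
    lines = [f"# {CSV_VERSION}", ",".join(CSV_COLUMNS)]
    for k, e in enumerate(campaign.experiments):
        c, o = e.conditions, e.observation
        lines.append(",".join([
            str(k), campaign.stage, _fmt(e.clock_h), _fmt(c.concentration),
            _fmt(c.equivalents), _fmt(c.residence_time), _fmt(c.temperature),
            c.solvent or "", _fmt(o.product_norm), _fmt(o.impurity_norm),
            _fmt(e.objective_f), str(campaign.seed)]))
    path.write_text("\n".join(lines) + "\n")


def read_campaign(path, space: DesignSpace | None = None) -> Campaign:
    """Read a campaign CSV; malformed rows are reported with line numbers."""
    from .simulator import Observation
    from .tsemo import Experiment

    space = space or default_space()
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or not text[0].strip():
        warnings.warn(f"{path}: empty campaign file")
        return Campaign(stage="unknown", seed=0)
    if text[0].lstrip("# ").strip() != CSV_VERSION:
        raise ValueError(f"{path}:1: unknown campaign header version "
                         f"{text[0]!r} (expected '# {CSV_VERSION}')")
    if len(text) < 2 or text[1].split(",") != CSV_COLUMNS:
        raise ValueError(f"{path}:2: unexpected column header")
    experiments, stage, seed = [], "unknown", 0
    for ln, line in enumerate(text[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(CSV_COLUMNS):
            raise ValueError(f"{path}:{ln}: expected {len(CSV_COLUMNS)} "
                             f"fields, got {len(parts)}")
        try:
            stage = parts[1]
            clock = float(parts[2])
            cond = Conditions(float(parts[3]), float(parts[4]),
                              float(parts[5]), float(parts[6]),
                              parts[7] or None)
            check_in_bounds(cond, space)
            obs = Observation(float(parts[8]), float(parts[9]))
            f_val = float(parts[10]) if parts[10] else None
            seed = int(parts[11])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from None
        if not all(np.isfinite(v) for v in
                   (clock, cond.concentration, cond.equivalents,
                    cond.residence_time, cond.temperature,
                    obs.product_norm, obs.impurity_norm)):
            raise ValueError(f"{path}:{ln}: non-finite numeric field")
        experiments.append(Experiment(cond, obs, clock, f_val))
    campaign = Campaign(stage=stage, seed=seed)
    campaign.experiments = experiments
    return campaign


def _stability_campaign(records, seed: int, forcing: Conditions) -> Campaign:
    """Repackage stability-protocol records in the campaign container."""
    from .tsemo import Experiment

    camp = Campaign(stage="stability", seed=seed)
    for clock_h, solvent, obs in records:
        camp.experiments.append(
            Experiment(forcing.with_solvent(solvent), obs, clock_h, None))
    return camp


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """The study configuration: design space, budgets and solver settings."""
    space = default_space()
    return {
        "design_space": {
            "continuous": [
                {"name": v.name, "lower": v.lower, "upper": v.upper,
                 "unit": v.unit} for v in space.continuous_vars],
            "categorical": {"name": space.categorical_name,
                            "levels": list(space.levels)},
        },
        "simulator": {
            "noise_sigma": 0.01,
            "impurity_slope": None,   # None: derived from the anchors
            "calibration_restarts": 5,
        },
        "stability": {"hours_per_solvent": 3.0, "total_hours": 24.0,
                      "samples_per_hour": 2},
        "stage1": {"solvent": "MeCN", "n_init": 9, "n_iter": 60,
                   "n_features": 500, "population": 100, "generations": 100,
                   "ref_margin": 0.1},
        "stage2": {"n_init": 12, "n_iter": 27, "n_starts": 20},
        "gp": {"n_restarts": 3, "lengthscale_bounds": [0.01, 100.0],
               "latent_prior_std": 1.5},
        "pareto": {"eps_floor": 1e-6, "use_paper_weights": False},
    }


def load_config(path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def space_from_config(cfg: dict) -> DesignSpace:
    from .design_space import ContinuousVar

    ds = cfg["design_space"]
    return DesignSpace(
        continuous_vars=tuple(ContinuousVar(v["name"], v["lower"], v["upper"],
                                            v.get("unit", ""))
                              for v in ds["continuous"]),
        categorical_name=ds["categorical"]["name"],
        levels=tuple(ds["categorical"]["levels"]),
    )


def _gp_config(cfg: dict, seed: int = 0) -> GPConfig:
    g = cfg["gp"]
    noise_floor = 0.5 * cfg["simulator"]["noise_sigma"]
    return GPConfig(n_restarts=g["n_restarts"], seed=seed,
                    lengthscale_bounds=tuple(g["lengthscale_bounds"]),
                    latent_prior_std=g["latent_prior_std"],
                    noise_floor=noise_floor)


# ---------------------------------------------------------------------------
# Weight inference with a convexity fallback (orchestrator only)
# ---------------------------------------------------------------------------

def robust_weights(analysis: ParetoAnalysis, eps_floor: float = 1e-6
                   ) -> tuple[Weights, int]:
    """Infer scalarisation weights, stepping off non-convex front stretches.

    Under observation noise the diminishing-returns point can fall on a
    non-convex stretch where no strict linear scalariser exists; the
    orchestrator then walks outward to the nearest front point (by product
    distance) that admits one, with a warning.
    """
    order = np.argsort(np.abs(analysis.product - analysis.product[analysis.preferred]),
                       kind="stable")
    last_exc = None
    for k in order:
        try:
            w = infer_weights(analysis.product, analysis.impurity, int(k),
                              eps_floor=eps_floor)
            if int(k) != analysis.preferred:
                warnings.warn(
                    "preferred point lies on a non-convex front stretch; "
                    f"weights anchored at front rank {int(k) + 1} instead")
            return w, int(k)
        except ScalarisationError as exc:
            last_exc = exc
    raise ScalarisationError(
        f"no front point admits a strict linear scalariser: {last_exc}")


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def _stage_seeds(seed: int) -> dict:
    # single global seed fanned out by fixed offsets (kept below 2^31)
    base = int(seed) % (2**31 - 1000)
    return {"calibrate": base, "stability": base + 1, "stage1": base + 2,
            "stage2": base + 3, "gp": base + 4}


def run_full_study(config: dict | None = None, seed: int = 0,
                   out_dir="flowamide_run") -> dict:
    """Execute the complete in-silico study and write all artifacts.

    Chain: simulator calibration -> 24 h enzyme stability protocol ->
    stage-1 multiobjective campaign (9 + 60 experiments, MeCN) -> Pareto
    analysis and LP weight inference -> stage-2 mixed-variable campaign
    (12 + 27 experiments) -> GP interpretation report. Fully reproducible
    from (config, seed).
    """
    cfg = config or default_config()
    seeds = _stage_seeds(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    space = space_from_config(cfg)
    stage = "calibrate"
    try:
        logger.info("calibrating simulator to the printed anchors")
        params = calibrate(seed=seeds["calibrate"],
                           n_restarts=cfg["simulator"]["calibration_restarts"],
                           impurity_slope=cfg["simulator"]["impurity_slope"],
                           noise_sigma=cfg["simulator"]["noise_sigma"],
                           space=space)
        with open(out / "simulator_params.json", "w") as fh:
            json.dump(params.to_dict(), fh, indent=2, sort_keys=True)

        stage = "stability"
        st = cfg["stability"]
        forcing = Conditions(*space.uppers)
        records = stability_protocol(
            params, forcing, hours_per_solvent=st["hours_per_solvent"],
            total_hours=st["total_hours"],
            samples_per_hour=st["samples_per_hour"],
            seed=seeds["stability"], space=space)
        write_campaign(_stability_campaign(records, seeds["stability"],
                                           forcing), out / "stability.csv")

        stage = "stage1"
        s1 = cfg["stage1"]
        tcfg = TsemoConfig(n_features=s1["n_features"],
                           population=s1["population"],
                           generations=s1["generations"],
                           ref_margin=s1["ref_margin"],
                           gp=_gp_config(cfg))
        stage1 = run_stage1(params, space, solvent=s1["solvent"],
                            n_init=s1["n_init"], n_iter=s1["n_iter"],
                            seed=seeds["stage1"], config=tcfg)
        write_campaign(stage1, out / "stage1.csv")

        stage = "pareto"
        analysis = pareto_analysis(stage1.observations())
        if cfg["pareto"]["use_paper_weights"]:
            from .pareto import PAPER_WEIGHTS
            weights, anchor = PAPER_WEIGHTS, analysis.preferred
        else:
            weights, anchor = robust_weights(analysis,
                                             cfg["pareto"]["eps_floor"])
        with open(out / "weights.json", "w") as fh:
            json.dump({**weights.to_dict(), "front_anchor_rank": anchor + 1},
                      fh, indent=2, sort_keys=True)

        stage = "stage2"
        s2 = cfg["stage2"]
        acfg = AlaboConfig(n_starts=s2["n_starts"], gp=_gp_config(cfg))
        stage2 = run_stage2(params, space, weights, n_init=s2["n_init"],
                            n_iter=s2["n_iter"], seed=seeds["stage2"],
                            config=acfg)
        write_campaign(stage2, out / "stage2.csv")

        stage = "interpret"
        gp_cfg = _gp_config(cfg, seed=seeds["gp"])
        conds = stage2.conditions()
        fit_p = fit_gp(list(zip(conds, stage2.products())), space, gp_cfg)
        fit_i = fit_gp(list(zip(conds, stage2.impurities())), space, gp_cfg)
        best = min(stage2.experiments, key=lambda e: e.objective_f)
        sty_val = compute_sty(StyInputs(
            concentration=best.conditions.concentration / 1000.0,
            yield_fraction=best.observation.product_norm,
            time=best.conditions.residence_time / 60.0))
        summary = campaign_report(
            stage1, stage2, fit_p, fit_i, analysis, weights, out,
            sty={"g_per_L_per_h": float(sty_val),
                 "at": {"concentration_mM": best.conditions.concentration,
                        "residence_time_min": best.conditions.residence_time,
                        "solvent": best.conditions.solvent,
                        "yield_fraction": best.observation.product_norm}})
    except Exception as exc:
        raise RuntimeError(f"full study failed during stage "
                           f"'{stage}': {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "stage_seeds": seeds,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "total_optimisation_experiments": len(stage1) + len(stage2),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()
                            and p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    summary["manifest"] = manifest
    return summary
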