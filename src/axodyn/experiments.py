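"""Config-driven experiment presets: figure-level computations at desk scale.

Each preset names the parameter variations of one figure-level experiment
(sodium-site position families, conductance multipliers, activation-slope
variants, correlation times, axial resistivity, soma sizes, myelination,
bifurcation and impedance analyses).  ``run_experiment`` executes
calibration -> simulation -> analysis per condition with counter-based
seeding and JSON/CSV outputs; paper-scale trial counts are a flag away but
the defaults are desk-scale (hundreds of trials).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from .calibration import WorkingPoint, find_operating_point
from .gain import GainPipelineConfig, run_gain_pipeline, desk_config
from .impedance import transfer_impedance_ou, transfer_impedance_sine, passive_cell
from .model import (MorphologySpec, PassiveSpec, SodiumSpec, build_cell,
                    calibrate_thresholds)
from .steady_state import bifurcation_scan
from .stimulus import OUSpec

__all__ = ["ExperimentConfig", "CutoffSurface", "PRESETS", "run_experiment",
           "cutoff_surface"]

# myelination variant of the distal axon (membrane conductance / 50,
# capacitance / 37.5, starting 60 um from the soma)
_MYELIN = (((60.0, 600.0, 50.0, 1.0 / 37.5),),)


def _conditions(preset: str):
    """(kind, list of condition dicts) for each preset."""
    base = {"x_na": 40.0, "gbar_mult": 1.0, "k_a": 6.0, "tau": 5.0,
            "r_a": 150.0, "soma": 50.0, "reset_voltage": None,
            "region_overrides": ()}

    def conds(**axes):
        keys = list(axes)
        out = []

        def rec(i, acc):
            if i == len(keys):
                out.append({**base, **acc})
                return
            for v in axes[keys[i]]:
                rec(i + 1, {**acc, keys[i]: v})
        rec(0, {})
        return out

    table = {
        "fig1": ("bifurcation", [dict(base)]),
        "fig2": ("gain_family", conds(x_na=[0.0, 20.0, 40.0, 80.0])),
        "fig3": ("impedance", conds(x_na=[20.0, 40.0, 80.0, 200.0])),
        "fig3d": ("gain_family", conds(x_na=[20.0, 40.0, 80.0], r_a=[750.0])),
        "fig4": ("gain_family", conds(gbar_mult=[1.0, 5.0, 10.0],
                                      reset_voltage=[-90.0])),
        "fig5": ("surface", conds(x_na=[0.0, 20.0, 80.0],
                                  gbar_mult=[1.0, 4.5, 20.0])),
        "fig6": ("gain_family", conds(x_na=[20.0, 40.0, 80.0],
                                      tau=[5.0, 50.0])),
        "fig7": ("gain_family", conds(k_a=[6.0, 0.1])),
        "fig8": ("gain_family", conds(x_na=[20.0, 40.0, 80.0], k_a=[0.1],
                                      tau=[5.0, 50.0])),
        "fig9": ("surface", conds(k_a=[0.1, 1.0, 6.0],
                                  gbar_mult=[1.0, 4.5, 20.0], tau=[50.0])),
        "fig10": ("gain_family", conds(soma=[10.0, 50.0, 200.0])),
        "fig11": ("impedance", conds(soma=[10.0, 50.0, 200.0])),
        "s3": ("gain_family", conds(k_a=[6.0, 1.0, 0.1], tau=[2.0, 50.0])),
        "s4": ("gain_family",
               conds(region_overrides=[(), _MYELIN[0]])),
    }
    if preset not in table:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(table)}")
    return table[preset]


PRESETS = ("fig1", "fig2", "fig3", "fig3d", "fig4", "fig5", "fig6", "fig7",
           "fig8", "fig9", "fig10", "fig11", "s3", "s4")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment run: preset, scale, seeding and output location."""

    preset: str
    n_trials: int = 300
    dt: float = 0.05                    # ms (25 us at paper scale)
    spatial_step: float = 4.0           # um
    soma_spatial_step: float | None = 10.0
    seed: int = 0
    out_dir: str = "axodyn_out"
    paper_scale: bool = False
    target_rate: float = 5.0
    target_cv: float = 0.85
    pilot_time: float = 200000.0        # ms per calibration evaluation
    compute_significance: bool = False
    n_shift_surrogates: int = 200

    def __post_init__(self):
        _conditions(self.preset)   # validate
        if self.n_trials < 1 or self.dt <= 0 or self.spatial_step <= 0:
            raise ValueError("scale parameters must be positive")

    def gain_config(self) -> GainPipelineConfig:
        if self.paper_scale:
            return GainPipelineConfig(n_trials=20000, dt=0.025,
                                      spatial_step=1.0)
        return desk_config(n_trials=self.n_trials, dt=self.dt,
                           spatial_step=self.spatial_step,
                           soma_spatial_step=self.soma_spatial_step,
                           n_shift_surrogates=self.n_shift_surrogates)


@dataclass(frozen=True)
class CutoffSurface:
    """Cutoff frequencies over a 2-D parameter grid (no interpolation)."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    cutoffs: np.ndarray         # Hz; NaN where undefined or failed
    mode: str                   # operating-point mode

    def __post_init__(self):
        if self.cutoffs.shape != (len(self.axis1_values),
                                  len(self.axis2_values)):
            raise ValueError("cutoff grid does not match the axes")


def _build_condition_cell(cond: dict, config: ExperimentConfig):
    dx = 1.0 if config.paper_scale else config.spatial_step
    dxs = None if config.paper_scale else config.soma_spatial_step
    if cond["soma"] > 2000.0 and (dxs is None or dxs < 1000.0):
        dxs = 1000.0    # huge-soma variant runs on a coarse somatic grid
    morph = MorphologySpec(soma_diameter=cond["soma"],
                           soma_length=cond["soma"],
                           na_position=cond["x_na"], spatial_step=dx,
                           soma_spatial_step=dxs)
    passive = PassiveSpec(axial_resistivity=cond["r_a"],
                          region_overrides=tuple(cond["region_overrides"]))
    sodium = SodiumSpec(peak_conductance=5.23e-9 * cond["gbar_mult"],
                        slope=cond["k_a"])
    return build_cell(morph, passive, sodium)


def _condition_tag(cond: dict) -> str:
    parts = []
    for k in ("x_na", "gbar_mult", "k_a", "tau", "r_a", "soma"):
        parts.append(f"{k}{cond[k]:g}")
    if cond["reset_voltage"] is not None:
        parts.append(f"reset{cond['reset_voltage']:g}")
    if cond["region_overrides"]:
        parts.append("myelin")
    return "_".join(parts)


def _calibrated_gain(cond: dict, config: ExperimentConfig, wp: WorkingPoint,
                     seed: int, compute_ci: bool = True):
    cell = _build_condition_cell(cond, config)
    policy = calibrate_thresholds(cell, config.target_rate, dt=config.dt,
                                  reset_voltage=cond["reset_voltage"])
    cache = os.path.join(config.out_dir, "calibration_cache")
    op = find_operating_point(cell, policy, wp, tau=cond["tau"], seed=seed,
                              dt=config.dt, pilot_time=config.pilot_time,
                              cache_dir=cache)
    result = run_gain_pipeline(cell, policy, op.mu, op.sigma, cond["tau"],
                               config.gain_config(), seed=seed + 1,
                               compute_significance=config.compute_significance,
                               compute_ci=compute_ci)
    return cell, policy, op, result


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one preset; returns (and writes) a summary bundle.

    Outputs under config.out_dir: per-condition gain CSV/JSON (gain
    presets), branch CSV + scan JSON (bifurcation), impedance CSV
    (impedance presets).  All seeds derive from config.seed and the
    condition index, so reruns reproduce the numbers.
    """
    from .io import write_gain_csv

    kind, conds = _conditions(config.preset)
    os.makedirs(config.out_dir, exist_ok=True)
    wp = WorkingPoint(target_rate=config.target_rate,
                      target_cv=config.target_cv)
    summary = {"preset": config.preset, "kind": kind, "seed": config.seed,
               "conditions": []}

    for j, cond in enumerate(conds):
        tag = _condition_tag(cond)
        entry = {"condition": tag, **{k: cond[k] for k in
                                      ("x_na", "gbar_mult", "k_a", "tau",
                                       "r_a", "soma")}}
        seed_j = config.seed + 1000 * (j + 1)
        if kind == "bifurcation":
            cell = _build_condition_cell({**cond, "x_na": 40.0}, config)
            fine = build_cell(replace(cell.morphology, spatial_step=0.25),
                              cell.passive, cell.sodium)
            scan = bifurcation_scan(fine, x_na_grid=[10, 20, 27, 40, 60],
                                    v_soma_grid=np.arange(-60, -49.9, 0.5))
            entry["critical_distance_um"] = scan.critical_distance
            entry["jump_voltages_mv"] = {str(k): v for k, v
                                         in scan.jump_voltages.items()}
            import pandas as pd
            pd.DataFrame(scan.branches, columns=[
                "x_na_um", "v_soma_mv", "v_axon_mv", "stable"]).to_csv(
                os.path.join(config.out_dir, f"{config.preset}_branches.csv"),
                index=False)
        elif kind == "impedance":
            cell = _build_condition_cell(cond, config)
            ou = OUSpec(0.0, 0.02, cond["tau"], config.dt, seed=seed_j)
            curve = transfer_impedance_ou(passive_cell(cell), ou,
                                          duration=50000.0)
            entry["impedance_mohm_at"] = {
                f"{f:g}Hz": float(np.interp(f, curve.frequencies,
                                            curve.magnitude))
                for f in (1.0, 10.0, 100.0, 500.0)}
            import pandas as pd
            pd.DataFrame({"frequency_hz": curve.frequencies,
                          "impedance_mohm": curve.magnitude}).to_csv(
                os.path.join(config.out_dir, f"{config.preset}_{tag}.csv"),
                index=False)
        else:   # gain_family / surface share the calibrated-gain path
            _, _, op, result = _calibrated_gain(cond, config, wp, seed_j)
            entry.update(mu=op.mu, sigma=op.sigma, rate=op.rate, cv=op.cv,
                         calibrated=op.converged,
                         cutoff_hz=result.curve.cutoff,
                         low_f_gain=result._safe_lf(),
                         hf_slope=result._safe_slope())
            write_gain_csv(os.path.join(config.out_dir,
                                        f"{config.preset}_{tag}.csv"),
                           result, extra_meta={"condition": tag})
        summary["conditions"].append(entry)

    with open(os.path.join(config.out_dir,
                           f"{config.preset}_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


def cutoff_surface(config: ExperimentConfig, axis1: tuple, axis2: tuple,
                   mode: str = "rate_and_cv",
                   fixed_std: float | None = None) -> CutoffSurface:
    """Cutoff-frequency grid over two model/stimulus axes.

    axis1/axis2: (name, values) with names from {x_na, gbar_mult, k_a, tau}.
    Per-point calibration failures are flagged (NaN), not fatal; stored data
    are the raw grid (any surface rendering is left to the caller).
    """
    (n1, v1), (n2, v2) = axis1, axis2
    wp = WorkingPoint(target_rate=config.target_rate,
                      target_cv=config.target_cv, mode=mode,
                      fixed_std=fixed_std)
    base_kind, base_conds = _conditions(config.preset)
    base = dict(base_conds[0])
    cut = np.full((len(v1), len(v2)), np.nan)
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            cond = {**base, n1: float(a), n2: float(b)}
            try:
                _, _, op, result = _calibrated_gain(
                    cond, config, wp, config.seed + 10000 * i + 100 * j,
                    compute_ci=False)
                if result.curve.cutoff is not None:
                    cut[i, j] = result.curve.cutoff
            except (RuntimeError, ValueError):
                pass
    return CutoffSurface(axis1_name=n1, axis1_values=np.asarray(v1, float),
                         axis2_name=n2, axis2_values=np.asarray(v2, float),
                         cutoffs=cut, mode=mode)
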