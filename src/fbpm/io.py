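"""Configuration and report I/O.

Run configuration is a YAML (or JSON — YAML is a superset) file with up to
four sections, each mapping directly onto a dataclass:

    particle:  ParticleSpec fields   (radius_um, density_p, density_m,
               viscosity_mPas, temperature_K)
    scenario:  KineticScenario fields (mode, k_on_max, c_half, n_mol, k_off,
               k_ns, k_off_ns, p_multi, k_off_multi, binding_reach_um)
    sim:       SimConfig fields       (frame_rate, block_s, n_blocks,
               n_particles, confine_um, tau_confine_s, sigma_loc_um,
               substeps, fov_um, seed)
    analysis:  AnalysisConfig fields  (cutoff, lo_fraction, min_dwell,
               window, fit_lags, frame_rate, qc, censoring_mode,
               min_complete)

Missing sections/fields fall back to the documented defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .physics import ParticleSpec
from .response import AnalysisConfig
from .simulate import KineticScenario, SimConfig

__all__ = ["RunConfig", "load_config", "save_report"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    particle: ParticleSpec
    scenario: KineticScenario
    sim: SimConfig
    analysis: AnalysisConfig


def _build(cls, section: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown keys in '{name}' section: {sorted(unknown)}")
    if cls is SimConfig and "fov_um" in section:
        section = {**section, "fov_um": tuple(section["fov_um"])}
    return cls(**section)


def load_config(path) -> RunConfig:
    """Load a structured-text run configuration (YAML/JSON)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"particle", "scenario", "sim", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    particle = _build(ParticleSpec, raw.get("particle", {"radius_um": 1.4}), "particle")
    return RunConfig(
        particle=particle,
        scenario=_build(KineticScenario, raw.get("scenario", {}), "scenario"),
        sim=_build(SimConfig, raw.get("sim", {}), "sim"),
        analysis=_build(AnalysisConfig, raw.get("analysis", {}), "analysis"),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_report(report: dict, path) -> None:
    """Write a structured analysis report as JSON (numpy-safe)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))
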