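"""Configuration-driven runs, manifests and report rendering.

An experiment configuration is a YAML document::

    schema_version: 1
    experiment: sweep            # simulate | sweep | widen_neck |
                                 # passive_active | buffer_halving
    geometry: {preset: reference, overrides: {neck_radius: 0.15}}
    parameters: {rho_r: 2.0}     # ModelParameters overrides
    simulation: {t_end: 0.025}   # SimulationConfig overrides
    influx: {mode: fixed, j_peak: 8.6e-18}
    sweep: {resolution: 0.05, rho_max: 5.0}
    output_dir: results/run1

Unknown keys anywhere are schema violations; every violation is listed
before any compute starts.  Every physical quantity in the parameter
block is interpreted in the unit documented on the corresponding
dataclass field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import experiments as xp
from .fvm import build_dual_mesh, simulate
from .geometry import SpineParams, build_synthetic_spine, measure_morphology, reference_spine
from .kinetics import calibrate_pm_leak
from .parameters import InfluxSpec, ModelParameters, SimulationConfig

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "experiment", "geometry", "parameters",
             "simulation", "influx", "sweep", "widen", "output_dir",
             "criterion"}
_EXPERIMENTS = ("simulate", "sweep", "widen_neck", "passive_active",
                "buffer_halving")


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""


@dataclass
class RunManifest:
    """Provenance record of one configuration-driven run."""

    config_hash: str
    experiment: str
    parameters: dict
    geometry: dict
    software_version: str
    started: str
    wall_seconds: float
    outputs: List[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)

    @classmethod
    def from_json(cls, s: str) -> "RunManifest":
        return cls(**json.loads(s))


def _validate(doc: dict) -> List[str]:
    errors = []
    if not isinstance(doc, dict):
        return ["configuration must be a mapping"]
    unknown = set(doc) - _TOP_KEYS
    errors += [f"unknown key {k!r}" for k in sorted(unknown)]
    if doc.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        errors.append(f"unsupported schema_version {doc['schema_version']!r}")
    exp = doc.get("experiment")
    if exp not in _EXPERIMENTS:
        errors.append(f"experiment must be one of {_EXPERIMENTS}, got {exp!r}")
    geo = doc.get("geometry", {})
    if not isinstance(geo, dict):
        errors.append("geometry must be a mapping")
    else:
        bad = set(geo) - {"preset", "overrides"}
        errors += [f"unknown geometry key {k!r}" for k in sorted(bad)]
        over = geo.get("overrides", {}) or {}
        valid = {f.name for f in dataclasses.fields(SpineParams)}
        errors += [f"unknown geometry override {k!r}"
                   for k in sorted(set(over) - valid)]
    for block, cls in (("parameters", ModelParameters),
                       ("simulation", SimulationConfig)):
        over = doc.get(block, {}) or {}
        if not isinstance(over, dict):
            errors.append(f"{block} must be a mapping")
            continue
        valid = {f.name for f in dataclasses.fields(cls)}
        errors += [f"unknown {block} key {k!r}"
                   for k in sorted(set(over) - valid)]
    infl = doc.get("influx", {}) or {}
    if isinstance(infl, dict):
        valid = {f.name for f in dataclasses.fields(InfluxSpec)}
        errors += [f"unknown influx key {k!r}"
                   for k in sorted(set(infl) - valid)]
    else:
        errors.append("influx must be a mapping")
    return errors


def load_config(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    errors = _validate(doc)
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return doc


def _build_inputs(doc: dict):
    geo = doc.get("geometry", {}) or {}
    preset = geo.get("preset", "reference")
    base = reference_spine() if preset == "reference" else SpineParams()
    gparams = base.replace(**(geo.get("overrides") or {}))
    params = ModelParameters(**(doc.get("parameters") or {}))
    config = SimulationConfig(**(doc.get("simulation") or {}))
    infl = doc.get("influx")
    influx = InfluxSpec(**infl) if infl else InfluxSpec(
        j_peak=params.jc_rls, tau=params.tau_rls)
    crit = xp.CouplingCriterion(**(doc.get("criterion") or {}))
    return gparams, params, config, influx, crit


def run_from_config(path, output_dir: Optional[str] = None) -> RunManifest:
    """Validate, execute and archive the experiment named in the config."""
    doc = load_config(path)
    t0 = time.time()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(output_dir or doc.get("output_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    gparams, params, config, influx, crit = _build_inputs(doc)
    cfg_hash = hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]

    outputs: List[str] = []
    summary: dict = {"leak_calibration_nm_s": {
        "printed": params.v_lp * 1e3,
        "zero_net_flux": calibrate_pm_leak(params) * 1e3,
    }}
    exp = doc["experiment"]

    if exp == "simulate":
        mesh = build_synthetic_spine(gparams)
        trace = simulate(mesh, params, config, influx)
        p = out / "trace.csv"
        trace.to_csv(p)
        outputs.append(str(p))
        summary["peaks_uM"] = trace.peaks
        summary["ion_budget"] = trace.ion_budget
        summary["conservation"] = trace.meta["conservation"]
        summary["coupled"] = xp.detect_coupling(trace, crit)
    elif exp == "sweep":
        mesh = build_synthetic_spine(gparams)
        sw = doc.get("sweep", {}) or {}
        sweep = xp.critical_ryr_sweep(
            mesh, params, config, crit,
            resolution=sw.get("resolution", 0.01),
            rho_max=sw.get("rho_max", 5.0))
        p = out / "sweep.csv"
        sweep.to_dataframe().to_csv(p, index=False)
        outputs.append(str(p))
        summary["critical_density_per_um2"] = sweep.critical_density
        summary["jump_ratio"] = sweep.jump_ratio
    elif exp == "widen_neck":
        w = doc.get("widen", {}) or {}
        table = xp.neck_widening_experiment(
            gparams, params, config, crit,
            pcts=tuple(w.get("pcts", (10, 20, 40))),
            resolution=w.get("resolution", 0.05))
        p = out / "neck_widening.csv"
        table.to_csv(p, index=False)
        outputs.append(str(p))
        summary["critical_densities"] = dict(
            zip(table["pct"], table["critical_density"]))
    elif exp == "passive_active":
        table = xp.passive_active_comparison(
            gparams, params, config,
            rho_r_active=params.rho_r if params.rho_r > 0 else 1.0,
            influx=influx, criterion=crit)
        p = out / "passive_active.csv"
        table.to_csv(p, index=False)
        outputs.append(str(p))
        summary["table"] = table.drop(columns=[]).to_dict("records")
    elif exp == "buffer_halving":
        mesh = build_synthetic_spine(gparams)
        sw = doc.get("sweep", {}) or {}
        res = xp.buffer_halving_experiment(
            mesh, params, config, crit,
            resolution=sw.get("resolution", 0.05))
        summary["buffer_halving"] = res

    morph = measure_morphology(build_synthetic_spine(gparams))
    mp = out / "morphology.json"
    mp.write_text(json.dumps(morph.to_dict(), indent=2))
    outputs.append(str(mp))

    manifest = RunManifest(
        config_hash=cfg_hash,
        experiment=exp,
        parameters=params.to_dict(with_units=False),
        geometry=dataclasses.asdict(gparams),
        software_version=_version,
        started=started,
        wall_seconds=round(time.time() - t0, 3),
        outputs=outputs,
        summary=_jsonable(summary),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    manifest.outputs.append(str(out / "manifest.json"))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def render_report(manifest: RunManifest) -> str:
    """Human-readable summary of a run manifest."""
    if not manifest.outputs:
        raise ValueError("manifest lists no outputs; nothing to report")
    lines = [
        f"spinesim {manifest.software_version} -- {manifest.experiment} run",
        f"config hash {manifest.config_hash}, started {manifest.started}, "
        f"{manifest.wall_seconds:.1f} s",
        "",
    ]
    s = manifest.summary
    leak = s.get("leak_calibration_nm_s")
    if leak:
        lines.append(
            f"PM leak coefficient: nominal {leak['printed']:.2f} nm/s; "
            f"zero-net-flux balance would need {leak['zero_net_flux']:.2f} nm/s"
        )
    if "peaks_uM" in s:
        lines.append("zone peaks [µM]: " + ", ".join(
            f"{z} {v:.3g}" for z, v in s["peaks_uM"].items()))
    if "coupled" in s:
        lines.append(f"spine-to-dendrite coupling: "
                     f"{'YES' if s['coupled'] else 'no'}")
    if "critical_density_per_um2" in s:
        cd = s["critical_density_per_um2"]
        lines.append(
            "critical RyR density: "
            + (f"{cd:.2f} /µm²" if cd is not None else "none in range")
        )
        lines.append(f"dendritic peak jump ratio: {s['jump_ratio']:.1f}")
    if "critical_densities" in s:
        lines.append("critical densities by neck widening:")
        for pct, cd in s["critical_densities"].items():
            lines.append(f"  +{pct}%: "
                         + (f"{cd:.2f} /µm²" if cd is not None else "none"))
    if "table" in s:
        lines.append("passive/active peak table:")
        for row in s["table"]:
            lines.append(
                f"  {row['zone']}: passive {row['passive_uM']:.2f} µM, "
                f"active {row['active_uM']:.2f} µM "
                f"({row['pct_increase']:.0f}% increase)"
            )
    if "buffer_halving" in s:
        bh = s["buffer_halving"]
        lines.append(
            f"critical density, nominal buffer: {bh['critical_full_buffer']}, "
            f"halved buffer: {bh['critical_half_buffer']}"
        )
    if "conservation" in s:
        c = s["conservation"]
        lines.append(
            f"total calcium {c['total_initial_uM_um3']:.4g} -> "
            f"{c['total_final_uM_um3']:.4g} µM µm³"
        )
    if "ion_budget" in s:
        lines.append("ion budget: " + ", ".join(
            f"{k} {v:,.0f}" for k, v in s["ion_budget"].items()))
    lines.append("")
    lines.append("outputs:")
    lines += [f"  {p}" for p in manifest.outputs]
    return "\n".join(lines)
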