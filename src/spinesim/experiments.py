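"""Experiment drivers: coupling detection, critical-density sweeps,
passive/active comparisons, neck widening, buffer halving, calibration.

The central quantity is the *critical RyR density*: the smallest
ER-membrane ryanodine-receptor surface density at which synaptic calcium
release in the spine head triggers enough calcium-induced calcium
release for the dendritic measuring zone to exceed 1 µM for at least
1 ms (the spine-to-dendrite coupling criterion).  The transition is
all-or-nothing: the dendritic peak jumps by a large factor across one
0.01 µm⁻² density increment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .fvm import DualMesh, TraceResult, build_dual_mesh, simulate
from .geometry import SpineParams, build_synthetic_spine, widen_neck
from .mesh import TetMesh
from .parameters import InfluxSpec, ModelParameters, SimulationConfig
from .units import MOL_PER_UM3_PER_UM


@dataclass
class CouplingCriterion:
    """Spine-to-dendrite coupling: dendritic [Ca²⁺] above ``threshold``
    (µM) over a contiguous window of at least ``duration`` (s)."""

    threshold: float = 1.0          # µM
    duration: float = 1e-3          # s
    reference_influx: float = 8.6e-18   # mol s⁻¹ µm⁻²
    dendrite_width: float = 1.0     # µm, used for the flux conversion

    def __post_init__(self):
        if self.threshold <= 0 or self.duration <= 0:
            raise ValueError("threshold and duration must be > 0")

    @property
    def fraction_percent(self) -> float:
        """Criterion expressed as % of the reference synaptic influx."""
        rate = threshold_to_volumetric_rate(self.threshold, self.duration)
        return 100.0 * rate * self.dendrite_width / self.reference_influx


def threshold_to_volumetric_rate(threshold_uM: float, duration_s: float) -> float:
    """Concentration-over-time criterion as a volumetric rate.

    1 µM sustained for 1 ms corresponds to 1e-18 mol s⁻¹ µm⁻³.
    """
    if threshold_uM <= 0 or duration_s <= 0:
        raise ValueError("threshold and duration must be > 0")
    return threshold_uM * MOL_PER_UM3_PER_UM / duration_s


def detect_coupling(trace: TraceResult, criterion: CouplingCriterion,
                    zone: str = "dendrite") -> bool:
    """True iff the zone mean exceeds the threshold over a contiguous
    window of at least the criterion duration."""
    t = trace.times
    if len(t) < 3:
        raise ValueError("trace too short to evaluate the criterion")
    dt_max = float(np.max(np.diff(t)))
    if dt_max > criterion.duration / 4:
        raise ValueError(
            f"trace sampling ({dt_max:g} s) too coarse for a "
            f"{criterion.duration:g} s criterion window"
        )
    above = trace.zone_mean[zone] > criterion.threshold
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if t[i - 1] - t[start] >= criterion.duration:
                return True
            start = None
    if start is not None and t[len(above) - 1] - t[start] >= criterion.duration:
        return True
    return False


@dataclass
class SweepResult:
    """Outcome of a RyR-density sweep on one geometry."""

    densities: np.ndarray           # µm⁻², strictly increasing
    dendrite_peak: np.ndarray       # µM
    head_peak: np.ndarray           # µM
    coupled: np.ndarray             # bool
    critical_density: Optional[float]
    traces: Dict[float, TraceResult] = field(default_factory=dict)
    resolution: float = float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rho_r_per_um2": self.densities,
            "dendrite_peak_uM": self.dendrite_peak,
            "head_peak_uM": self.head_peak,
            "coupled": self.coupled,
        })

    def full_horizon_mask(self) -> np.ndarray:
        """Entries whose trace ran to t_end (peaks are honest maxima)."""
        return np.array([
            self.traces[float(r)].meta.get("stopped_early_at") is None
            if float(r) in self.traces else True
            for r in self.densities
        ])

    @property
    def jump_ratio(self) -> float:
        """Largest dendritic-peak ratio between evaluated densities one
        resolution step apart (both run to the full horizon)."""
        d, pk = self.densities, self.dendrite_peak
        if len(pk) < 2:
            return float("nan")
        ok = self.full_horizon_mask()
        gap = np.diff(d)
        pair = ok[1:] & ok[:-1]
        if np.isfinite(self.resolution):
            pair &= gap <= 1.5 * self.resolution
        if not pair.any():
            return float("nan")
        with np.errstate(divide="ignore"):
            r = pk[1:] / np.maximum(pk[:-1], 1e-30)
        return float(np.max(r[pair]))


def _run_density(mesh, params, config, influx, criterion, rho, dual,
                 early_exit=True, keep_trace=False):
    cfg = config
    if early_exit:
        cfg = config.replace(stop_when_coupled=True,
                             coupling_threshold=criterion.threshold,
                             coupling_duration=criterion.duration)
    trace = simulate(mesh, params.replace(rho_r=float(rho)), cfg, influx,
                     dual=dual)
    coupled = detect_coupling(trace, criterion)
    return trace, coupled


def critical_ryr_sweep(mesh: TetMesh, params: ModelParameters,
                       config: SimulationConfig,
                       criterion: CouplingCriterion,
                       grid: Optional[Sequence[float]] = None,
                       rho_max: float = 5.0,
                       resolution: float = 0.01,
                       mode: str = "bisect",
                       dual: Optional[DualMesh] = None,
                       full_final: bool = True,
                       influx: Optional[InfluxSpec] = None,
                       bracket: Optional[Sequence[float]] = None) -> SweepResult:
    """Find the critical RyR density on ``mesh``.

    ``mode='grid'`` simulates every density in ``grid`` (the exhaustive
    protocol); ``mode='bisect'`` brackets the coupled/uncoupled
    transition between 0 and ``rho_max`` and refines it to
    ``resolution`` -- the fast path, requiring ~log2(range/resolution)
    simulations.  All model parameters other than the RyR density are
    held fixed; every run restarts from the full rest state.
    """
    if dual is None:
        dual = build_dual_mesh(mesh)
    if influx is None:
        influx = InfluxSpec(j_peak=params.jc_rls, tau=params.tau_rls)
    results: Dict[float, dict] = {}

    def evaluate(rho, early_exit=True):
        key = round(float(rho), 10)
        if key in results:
            return results[key]
        trace, coupled = _run_density(mesh, params, config, influx,
                                      criterion, rho, dual, early_exit)
        results[key] = {"trace": trace, "coupled": coupled}
        return results[key]

    if mode == "grid":
        if grid is None:
            raise ValueError("grid mode requires an explicit density grid")
        g = np.asarray(sorted(grid), float)
        if np.any(g < 0) or np.any(g > rho_max):
            raise ValueError(f"densities must lie in [0, {rho_max}]")
        for rho in g:
            evaluate(rho, early_exit=False)
    else:
        # optional warm bracket (e.g. around a previously found critical
        # density); invalid endpoints fall back to the full range
        lo, hi = 0.0, float(rho_max)
        if bracket is not None:
            blo = max(0.0, round(float(bracket[0]) / resolution) * resolution)
            bhi = min(float(rho_max),
                      round(float(bracket[1]) / resolution) * resolution)
            if not evaluate(blo)["coupled"]:
                lo = blo
            if evaluate(bhi)["coupled"]:
                hi = bhi
        r_lo = evaluate(lo)
        r_hi = evaluate(hi)
        if r_lo["coupled"]:
            # already coupled without RyR: degenerate, report as critical 0
            pass
        elif not r_hi["coupled"]:
            lo = hi  # no coupling anywhere in range
        else:
            while hi - lo > resolution * (1 + 1e-9):
                mid = round((lo + hi) / 2 / resolution) * resolution
                if mid <= lo or mid >= hi:
                    break
                if evaluate(mid)["coupled"]:
                    hi = mid
                else:
                    lo = mid
            if full_final:
                # re-run early-stopped bracket ends to the full horizon so
                # their peaks are honest maxima
                for rho in (lo, hi):
                    key = round(float(rho), 10)
                    if results[key]["trace"].meta.get("stopped_early_at"):
                        tr, cp = _run_density(mesh, params, config, influx,
                                              criterion, rho, dual,
                                              early_exit=False)
                        results[key] = {"trace": tr, "coupled": cp}

    densities = np.array(sorted(results))
    dend = np.array([results[r]["trace"].peak("dendrite") for r in densities])
    head = np.array([results[r]["trace"].peak("head") for r in densities])
    coupled = np.array([results[r]["coupled"] for r in densities])
    crit = float(densities[coupled][0]) if coupled.any() else None
    return SweepResult(
        densities=densities, dendrite_peak=dend, head_peak=head,
        coupled=coupled, critical_density=crit,
        traces={float(r): results[r]["trace"] for r in densities},
        resolution=float(resolution),
    )


def ryr_count(density: float, area: float) -> int:
    """Number of receptors on a membrane patch: density × area, rounded
    to the nearest integer."""
    if density < 0 or area < 0:
        raise ValueError("density and area must be >= 0")
    return int(round(density * area))


def passive_active_comparison(params_geom: SpineParams,
                              params: ModelParameters,
                              config: SimulationConfig,
                              rho_r_active: float,
                              influx: Optional[InfluxSpec] = None,
                              criterion: Optional[CouplingCriterion] = None,
                              ) -> pd.DataFrame:
    """Peak [Ca²⁺] per zone for no-SA, passive-SA and active-SA runs.

    Percentage increases compare active against passive:
    ``100·(active − passive)/passive``.
    """
    if rho_r_active <= 0:
        raise ValueError("rho_r_active must be > 0")
    if influx is None:
        influx = InfluxSpec(j_peak=params.jc_rls, tau=params.tau_rls)
    runs = {}
    mesh_nosa = build_synthetic_spine(params_geom.replace(include_sa=False))
    runs["no_sa"] = simulate(mesh_nosa, params.replace(rho_r=0.0), config,
                             influx)
    mesh = build_synthetic_spine(params_geom)
    dual = build_dual_mesh(mesh)
    runs["passive"] = simulate(mesh, params.replace(rho_r=0.0), config,
                               influx, dual=dual)
    runs["active"] = simulate(mesh, params.replace(rho_r=rho_r_active),
                              config, influx, dual=dual)
    rows = []
    for zone in ("head", "neck", "dendrite"):
        p = {k: t.peak(zone) for k, t in runs.items()}
        rows.append({
            "zone": zone, "no_sa_uM": p["no_sa"], "passive_uM": p["passive"],
            "active_uM": p["active"],
            "pct_increase": percent_increase(p["passive"], p["active"]),
        })
    df = pd.DataFrame(rows)
    if criterion is not None:
        df.attrs["coupled"] = {k: detect_coupling(t, criterion)
                               for k, t in runs.items()}
    df.attrs["traces"] = runs
    return df


def percent_increase(passive: float, active: float) -> float:
    """Table-style percentage increase of active over passive peaks."""
    if passive == 0:
        return np.inf if active > 0 else 0.0
    return 100.0 * (active - passive) / passive


def neck_widening_experiment(base_params: SpineParams,
                             params: ModelParameters,
                             config: SimulationConfig,
                             criterion: CouplingCriterion,
                             pcts: Sequence[float] = (10.0, 20.0, 40.0),
                             resolution: float = 0.05,
                             rho_max: float = 5.0,
                             influx: Optional[InfluxSpec] = None,
                             ) -> pd.DataFrame:
    """Critical densities after widening the neck, SA morphology fixed.

    For each widening percentage the geometry is rebuilt, the spine is
    re-simulated at the base critical density (checking whether coupling
    survives), and the critical density is re-determined.  Wider necks
    dilute the perimembrane calcium around the SA, so the critical
    density is expected to be nondecreasing in the widening.
    """
    rows = []
    base_sweep = critical_ryr_sweep(
        build_synthetic_spine(base_params), params, config, criterion,
        resolution=resolution, rho_max=rho_max, full_final=False,
        influx=influx)
    if base_sweep.critical_density is None:
        raise RuntimeError("base spine does not couple anywhere in range")
    rho_base = base_sweep.critical_density
    rows.append({"pct": 0.0, "coupled_at_base_density": True,
                 "critical_density": rho_base,
                 "head_peak_uM": base_sweep.head_peak[-1]})
    # widening cannot lower the critical density much, so bracket the
    # re-sweeps around the base value (invalid brackets auto-expand)
    warm = (max(0.0, rho_base - 2 * resolution), rho_base + 10 * resolution)
    for pct in pcts:
        geom = widen_neck(base_params, pct)
        mesh = build_synthetic_spine(geom)
        dual = build_dual_mesh(mesh)
        trace, coupled = _run_density(mesh, params, config,
                                      influx or InfluxSpec(
                                          j_peak=params.jc_rls,
                                          tau=params.tau_rls),
                                      criterion, rho_base, dual)
        sweep = critical_ryr_sweep(mesh, params, config, criterion,
                                   resolution=resolution, rho_max=rho_max,
                                   dual=dual, full_final=False,
                                   bracket=warm, influx=influx)
        rows.append({
            "pct": pct,
            "coupled_at_base_density": coupled,
            "critical_density": sweep.critical_density,
            "head_peak_uM": float(np.max(sweep.head_peak)),
        })
    return pd.DataFrame(rows)


def buffer_halving_experiment(mesh: TetMesh, params: ModelParameters,
                              config: SimulationConfig,
                              criterion: CouplingCriterion,
                              resolution: float = 0.05,
                              rho_max: float = 5.0) -> Dict[str, float]:
    """Critical densities at the nominal and at half the buffer capacity.

    Less mobile buffer leaves more free calcium at the ER membrane, so
    the critical density with ``b_tot/2`` should not exceed the nominal
    one.
    """
    dual = build_dual_mesh(mesh)
    full = critical_ryr_sweep(mesh, params, config, criterion,
                              resolution=resolution, rho_max=rho_max,
                              dual=dual, full_final=False)
    warm = None
    if full.critical_density is not None:
        # halving the buffer can only help coupling
        warm = (0.0, full.critical_density)
    half = critical_ryr_sweep(mesh, params.replace(b_tot=params.b_tot / 2),
                              config, criterion, resolution=resolution,
                              rho_max=rho_max, dual=dual, full_final=False,
                              bracket=warm)
    return {
        "critical_full_buffer": full.critical_density,
        "critical_half_buffer": half.critical_density,
    }


def influx_invariance_experiment(mesh: TetMesh, params: ModelParameters,
                                 config: SimulationConfig,
                                 criterion: CouplingCriterion,
                                 j_grid: Sequence[float],
                                 resolution: float = 0.05,
                                 rho_max: float = 5.0) -> pd.DataFrame:
    """Critical density as a function of the synaptic influx amplitude.

    Within the physiological range (about 8.6e-18 to 2.2e-17
    mol s⁻¹ µm⁻²) buffering absorbs the extra entry and the critical
    density barely moves.
    """
    lo, hi = 8.6e-18, 22.0e-18
    for j in j_grid:
        if not (lo * (1 - 1e-9) <= j <= hi * (1 + 1e-9)):
            raise ValueError(f"influx {j:g} outside the tested range "
                             f"[{lo:g}, {hi:g}]")
    dual = build_dual_mesh(mesh)
    rows = []
    for j in j_grid:
        influx = InfluxSpec(j_peak=float(j), tau=params.tau_rls)
        sweep = critical_ryr_sweep(mesh, params, config, criterion,
                                   resolution=resolution, rho_max=rho_max,
                                   dual=dual, full_final=False,
                                   influx=influx)
        rows.append({"j_peak": float(j),
                     "critical_density": sweep.critical_density})
    df = pd.DataFrame(rows)
    crit = df["critical_density"].dropna()
    df.attrs["spread"] = float(crit.max() - crit.min()) if len(crit) else np.nan
    return df


def calibrate_influx(mesh: TetMesh, params: ModelParameters,
                     config: SimulationConfig,
                     target_head_peak_range: Sequence[float],
                     max_doublings: int = 12,
                     dual: Optional[DualMesh] = None) -> float:
    """Peak influx density whose head-zone peak lands in the target range.

    Monotone bracketing search on ``j_peak`` (the head peak increases
    with the influx amplitude); raises if the target cannot be bracketed
    with nonnegative influx.
    """
    lo_t, hi_t = target_head_peak_range
    if not (0 <= lo_t < hi_t):
        raise ValueError("target range must satisfy 0 <= low < high")
    if dual is None:
        dual = build_dual_mesh(mesh)

    def head_peak(j):
        influx = InfluxSpec(j_peak=float(j), tau=params.tau_rls)
        return simulate(mesh, params, config, influx, dual=dual).peak("head")

    resting = params.c_c0
    if hi_t <= resting:
        raise ValueError(
            "target peak below the resting level is unreachable with "
            "nonnegative influx"
        )
    j = params.jc_rls
    pk = head_peak(j)
    if lo_t <= pk <= hi_t:
        return float(j)
    # bracket by doubling/halving
    j_lo, j_hi = j, j
    for _ in range(max_doublings):
        if pk < lo_t:
            j_hi = j_hi * 2
            pk = head_peak(j_hi)
            j_lo = j_hi / 2 if pk >= lo_t else j_lo
            if lo_t <= pk <= hi_t:
                return float(j_hi)
            if pk > hi_t:
                break
        else:
            j_lo = j_lo / 2
            pk = head_peak(j_lo)
            if lo_t <= pk <= hi_t:
                return float(j_lo)
            if pk < lo_t:
                break
    else:
        raise RuntimeError("could not bracket the target head peak")
    # bisect the bracket
    for _ in range(30):
        mid = np.sqrt(j_lo * j_hi)
        pk = head_peak(mid)
        if lo_t <= pk <= hi_t:
            return float(mid)
        if pk < lo_t:
            j_lo = mid
        else:
            j_hi = mid
    raise RuntimeError("influx calibration did not converge")
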