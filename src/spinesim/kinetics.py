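"""Pointwise biochemistry: buffering, membrane fluxes, RyR gating.

Concentrations enter in µM; flux densities are returned in
mol s⁻¹ µm⁻² (the units physiological single-channel currents are
printed in).  All functions are vectorized over their concentration
arguments.

Sign conventions
----------------
Flux densities are magnitudes of the individual mechanisms; the solver
composes them as

* ER membrane, positive = ER -> cytosol:  ``j_ERM = j_R + j_le``
* plasma membrane, positive = outside -> cytosol:
  ``j_PM = -j_P - j_N + j_lp``

RyR gating (4-state)
--------------------
States ``c1`` (closed), ``o1``/``o2`` (open), ``c2`` (adapted/closed)
with the algebraic constraint ``o1 = 1 - c1 - o2 - c2``::

    dc1/dt = ka- * o1 - ka+ * c^4 * c1
    do2/dt = kb+ * c^3 * o1 - kb- * o2
    dc2/dt = kc+ * o1 - kc- * c2

The open probability is ``p_o = o1 + o2``.  The quartic activation makes
channel opening effectively switch-like above a few hundred nM, which is
what produces the all-or-nothing spine-to-dendrite coupling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import InfluxSpec, ModelParameters
from .units import AVOGADRO, MOL_PER_UM3_PER_UM


@dataclass
class RyRGatingState:
    """Occupancies of the explicit RyR states (arrays or scalars)."""

    c1: np.ndarray
    o2: np.ndarray
    c2: np.ndarray

    @property
    def o1(self):
        return 1.0 - self.c1 - self.o2 - self.c2

    @property
    def open_probability(self):
        return self.o1 + self.o2

    def validate(self) -> None:
        arrs = [np.asarray(x, float) for x in (self.c1, self.o2, self.c2)]
        for a in arrs:
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValueError("gating occupancies must lie in [0, 1]")
        if np.any(arrs[0] + arrs[1] + arrs[2] > 1 + 1e-9):
            raise ValueError("c1 + o2 + c2 must not exceed 1")


def buffer_reaction_rate(c_c, b, params: ModelParameters):
    """Net buffer release rate [µM/s]: ``kb-·(b_tot−b) − kb+·b·c_c``.

    Enters the cytosolic-calcium and free-buffer equations with the same
    sign (both species are produced when the complex dissociates).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b > params.b_tot * (1 + 1e-12)):
        raise ValueError("free buffer exceeds b_tot")
    return params.kb_minus * (params.b_tot - b) - params.kb_plus * b * np.asarray(c_c, float)


def equilibrium_free_buffer(params: ModelParameters) -> float:
    """Free-buffer concentration [µM] in equilibrium with resting calcium."""
    return params.b_tot * params.kb_minus / (
        params.kb_minus + params.kb_plus * params.c_c0
    )


def pmca_flux_density(c_c, params: ModelParameters):
    """PMCA extrusion [mol s⁻¹ µm⁻²], second-order Hill in cytosolic Ca²⁺."""
    c = np.asarray(c_c, dtype=float)
    return params.rho_p * params.I_p * c**2 / (params.K_p**2 + c**2)


def ncx_flux_density(c_c, params: ModelParameters):
    """NCX extrusion [mol s⁻¹ µm⁻²], first-order Hill in cytosolic Ca²⁺."""
    c = np.asarray(c_c, dtype=float)
    return params.rho_N * params.I_N * c / (params.K_N + c)


def leak_flux_densities(c_c, c_e, params: ModelParameters):
    """ER-membrane and plasma-membrane leaks [mol s⁻¹ µm⁻²].

    ``j_le = v_le (c_e − c_c)`` and ``j_lp = v_lp (c_o − c_c)``; the leak
    coefficient (µm/s) multiplies a volumetric concentration, hence the
    µM -> mol/µm³ conversion.
    """
    c_c = np.asarray(c_c, dtype=float)
    erm = params.v_le * (np.asarray(c_e, float) - c_c) * MOL_PER_UM3_PER_UM
    pm = params.v_lp * (params.c_o - c_c) * MOL_PER_UM3_PER_UM
    return erm, pm


def calibrate_pm_leak(params: ModelParameters) -> float:
    """Leak coefficient [µm/s] that balances PMCA+NCX at rest.

    Diagnostic only: simulations default to the nominal ``v_lp``; reports
    print both values.  (The nominal coefficient over-compensates the two
    pumps roughly twofold -- consistent with an additional, unmodeled
    resting influx pathway.)
    """
    extrusion = pmca_flux_density(params.c_c0, params) + ncx_flux_density(
        params.c_c0, params
    )
    gradient = (params.c_o - params.c_c0) * MOL_PER_UM3_PER_UM  # mol/µm³
    return float(extrusion / gradient)


def ryr_single_channel_current(c_c, c_e, params: ModelParameters):
    """Single-RyR current [mol/s], linear in the ER-cytosol gradient."""
    return params.IR_ref * (np.asarray(c_e, float) - np.asarray(c_c, float)) / params.ce_ref


def ryr_gating_rhs(state: RyRGatingState, c_c, params: ModelParameters):
    """Time derivatives (dc1, do2, dc2) of the explicit gating states [1/s]."""
    c = np.asarray(c_c, dtype=float)
    o1 = state.o1
    dc1 = params.ka_minus * o1 - params.ka_plus * c**4 * state.c1
    do2 = params.kb_plus_ryr * c**3 * o1 - params.kb_minus_ryr * state.o2
    dc2 = params.kc_plus * o1 - params.kc_minus * state.c2
    return dc1, do2, dc2


def ryr_steady_state(c_c, params: ModelParameters) -> RyRGatingState:
    """Stationary gating state at fixed cytosolic calcium ``c_c`` [µM].

    Setting the three derivatives to zero gives every occupancy as a
    multiple of ``o1``; the conservation constraint then fixes
    ``o1 = 1 / (1 + ka-/(ka+ c⁴) + kb+ c³/kb- + kc+/kc-)`` in closed form.
    """
    c = np.asarray(c_c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("steady state requires c_c > 0")
    r_c1 = params.ka_minus / (params.ka_plus * c**4)
    r_o2 = params.kb_plus_ryr * c**3 / params.kb_minus_ryr
    r_c2 = params.kc_plus / params.kc_minus
    o1 = 1.0 / (1.0 + r_c1 + r_o2 + r_c2)
    return RyRGatingState(c1=r_c1 * o1, o2=r_o2 * o1, c2=r_c2 * o1 + 0.0 * c)


def ryr_flux_density(state: RyRGatingState, c_c, c_e, rho_r, params: ModelParameters):
    """RyR flux density [mol s⁻¹ µm⁻²]: density × open probability × current."""
    state.validate()
    return rho_r * state.open_probability * ryr_single_channel_current(c_c, c_e, params)


def synaptic_influx_density(t, spec: InfluxSpec, psd_area: float):
    """Synaptic influx [mol s⁻¹ µm⁻²] at time ``t`` s: a triangular pulse.

    ``j(t) = j_peak (1 − t/τ)`` for ``t ≤ τ``, zero afterwards.  In
    ``psd_adjusted`` mode the peak scales as 1/psd_area so the total ion
    count is PSD-size independent.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    j0 = spec.effective_peak(psd_area)
    return np.where(t <= spec.tau, j0 * (1.0 - t / spec.tau), 0.0)


def total_influx_ions(spec: InfluxSpec, psd_area: float) -> float:
    """Ions delivered by the whole pulse: ½ j_peak τ A × Avogadro."""
    j0 = spec.effective_peak(psd_area)
    return 0.5 * j0 * spec.tau * psd_area * AVOGADRO
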