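"""Single-compartment (well-mixed) reduction of the calcium model.

Collapses the spatial model to ODEs for one cytosolic and one ER-lumen
compartment exchanging through the same membrane kinetics and total
areas/volumes.  In the limit of very fast diffusion the spatial solution
converges to this system, which makes it an independent oracle for the
PDE solver; it is also convenient for quick parameter exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import kinetics
from .parameters import InfluxSpec, ModelParameters
from .units import AVOGADRO

FLUX = 1.0e21  # mol s⁻¹ µm⁻² -> µM µm s⁻¹


@dataclass
class CompartmentGeometry:
    """Volumes (µm³) and membrane areas (µm²) of the reduced model."""

    V_cyt: float
    V_er: float
    A_pm: float
    A_erm: float
    A_psd: float

    @classmethod
    def from_mesh(cls, mesh) -> "CompartmentGeometry":
        from .mesh import CYTOSOL, ER_LUMEN, ERM, PM, PSD

        return cls(
            V_cyt=mesh.subdomain_volume(CYTOSOL),
            V_er=mesh.subdomain_volume(ER_LUMEN),
            A_pm=mesh.surface_area(PM),
            A_erm=mesh.surface_area(ERM),
            A_psd=mesh.surface_area(PSD),
        )


def simulate_wellmixed(geom: CompartmentGeometry, params: ModelParameters,
                       t_end: float, influx: Optional[InfluxSpec] = None,
                       membranes_enabled: bool = True,
                       rtol: float = 1e-8, atol: float = 1e-10,
                       max_step: Optional[float] = None):
    """Integrate the reduced ODE system; returns the solve_ivp result.

    State: [c_c, b, c_e, c1, o2, c2] (µM and occupancies).
    """
    p = params
    b0 = kinetics.equilibrium_free_buffer(p)
    g0 = kinetics.ryr_steady_state(p.c_c0, p)
    y0 = [p.c_c0, b0, p.c_e0, float(g0.c1), float(g0.o2), float(g0.c2)]
    has_er = geom.V_er > 0

    def rhs(t, y):
        cc, b, ce, c1, o2, c2 = y
        R = p.kb_minus * (p.b_tot - b) - p.kb_plus * b * cc
        dcc = R
        db = R
        dce = 0.0
        if membranes_enabled:
            pump = (kinetics.pmca_flux_density(cc, p)
                    + kinetics.ncx_flux_density(cc, p)) * FLUX
            jpm = p.v_lp * (p.c_o - cc) - pump
            dcc += geom.A_pm * jpm / geom.V_cyt
            if influx is not None:
                jsyn = float(kinetics.synaptic_influx_density(
                    t, influx, geom.A_psd)) * FLUX
                dcc += geom.A_psd * jsyn / geom.V_cyt
            if has_er:
                p_open = 1.0 - c1 - c2
                g = p.rho_r * (p.IR_ref * FLUX) / p.ce_ref * p_open + p.v_le
                jerm = g * (ce - cc)
                dcc += geom.A_erm * jerm / geom.V_cyt
                dce -= geom.A_erm * jerm / geom.V_er
        o1 = 1.0 - c1 - o2 - c2
        dc1 = p.ka_minus * o1 - p.ka_plus * cc**4 * c1
        do2 = p.kb_plus_ryr * cc**3 * o1 - p.kb_minus_ryr * o2
        dc2 = p.kc_plus * o1 - p.kc_minus * c2
        return [dcc, db, dce, dc1, do2, dc2]

    kw = {}
    if max_step is not None:
        kw["max_step"] = max_step
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=rtol, atol=atol,
                    dense_output=True, **kw)
    if not sol.success:
        raise RuntimeError(f"well-mixed integration failed: {sol.message}")
    return sol


def total_ions(sol_y, geom: CompartmentGeometry, params: ModelParameters):
    """Total calcium ions (free + bound + luminal) along a trajectory."""
    cc, b, ce = sol_y[0], sol_y[1], sol_y[2]
    tot = geom.V_cyt * (cc + params.b_tot - b) + geom.V_er * ce
    return tot * 1e-21 * AVOGADRO
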