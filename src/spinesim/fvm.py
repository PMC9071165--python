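"""Vertex-centered finite-volume discretization and implicit time stepping.

Unknowns live on mesh vertices: cytosolic calcium ``c_c`` and free buffer
``b`` on cytosol vertices, ER-lumen calcium ``c_e`` on ER vertices, and
the three explicit RyR gating states on ER-membrane vertices.  Control
volumes are the barycentric dual (one quarter of each incident tet); the
diffusive exchange between adjacent control volumes is assembled from the
P1 finite-element stiffness, to which the vertex-centered box scheme is
algebraically equivalent for the Laplacian.  Membrane fluxes enter as
boundary integrals lumped to vertices (one third of each incident
boundary triangle).

Time integration is backward Euler; the nonlinear system per step is
solved by a Newton iteration whose linear problems go to BiCGSTAB with an
incomplete-LU splitting preconditioner (with a sparse-LU fallback if the
Krylov solver stagnates).  The step size is halved on nonconvergence down
to ``tau_min = tau_sim / 2**15`` and doubled back after successes.

Internal units: µm, s, µM (1 µM = 1e-21 mol/µm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import kinetics
from .kinetics import RyRGatingState
from .mesh import (
    CYTOSOL, DENDRITE, ER_LUMEN, ERM, HEAD, NECK, PM, PSD, TetMesh,
    tet_signed_volumes, triangle_areas,
)
from .parameters import InfluxSpec, ModelParameters, SimulationConfig
from .units import AVOGADRO

FLUX = 1.0e21  # mol s⁻¹ µm⁻²  ->  µM µm s⁻¹


class SimulationError(RuntimeError):
    pass


class StepFailure(Exception):
    """Recoverable: retry with a smaller time step."""


# ----------------------------------------------------------------------
# dual mesh

def _p1_stiffness(verts: np.ndarray, tets: np.ndarray, nloc: int,
                  gmap: np.ndarray) -> sp.csr_matrix:
    """P1 stiffness matrix (unit diffusivity) on local vertex numbering."""
    p = verts[tets]
    e = p[:, 1:] - p[:, :1]              # (m,3,3) edge matrix
    vol = np.abs(np.linalg.det(e)) / 6.0
    einv = np.linalg.inv(e)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(einv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    kloc = np.einsum("tid,tjd,t->tij", g, g, vol)
    loc = gmap[tets]
    rows = np.repeat(loc, 4, axis=1).ravel()
    cols = np.tile(loc, (1, 4)).ravel()
    K = sp.coo_matrix((kloc.ravel(), (rows, cols)), shape=(nloc, nloc))
    return K.tocsr()


@dataclass
class DualMesh:
    """Barycentric dual of a labeled TetMesh, ready for assembly."""

    mesh: TetMesh
    cyt_verts: np.ndarray          # global vertex ids of the cytosol subdomain
    er_verts: np.ndarray
    Vc: np.ndarray                 # control volumes [µm³]
    Ve: np.ndarray
    Kc: sp.csr_matrix              # unit-diffusivity stiffness, cytosol
    Ke: sp.csr_matrix
    A_pm: np.ndarray               # lumped boundary areas per cytosol vertex
    A_psd: np.ndarray
    erm_c: np.ndarray              # ERM vertices as cytosol-local indices
    erm_e: np.ndarray              # the same vertices, ER-local
    A_erm: np.ndarray              # lumped ERM area per ERM vertex [µm²]
    zone_w: Dict[str, np.ndarray]  # quadrature weights for zone means
    flux_rows: np.ndarray          # stiffness entries crossing the neck base
    flux_cols: np.ndarray
    flux_vals: np.ndarray
    neck_base_area: float

    @property
    def n_c(self) -> int:
        return len(self.cyt_verts)

    @property
    def n_e(self) -> int:
        return len(self.er_verts)

    @property
    def n_m(self) -> int:
        return len(self.erm_c)

    def interior_face_transmissibilities(self) -> sp.csr_matrix:
        """Symmetric two-point transmissibilities between adjacent control
        volumes (negated off-diagonal stiffness); for inspection/tests."""
        K = self.Kc.copy()
        K.setdiag(0.0)
        K.eliminate_zeros()
        return -K


def build_dual_mesh(mesh: TetMesh) -> DualMesh:
    """Construct control volumes, stiffness and boundary lumping."""
    vols = mesh.tet_volumes()
    if np.any(vols <= 0):
        bad = int(np.flatnonzero(vols <= 0)[0])
        raise ValueError(f"degenerate or inverted tet {bad} (volume {vols[bad]:g})")
    if mesh.boundary_tris is None:
        mesh.label_surfaces()

    def subdomain(code):
        tets = mesh.tets_of(code)
        gids = np.unique(tets)
        gmap = np.full(mesh.n_vertices, -1, dtype=np.int64)
        gmap[gids] = np.arange(len(gids))
        v = tet_signed_volumes(mesh.vertices, tets)
        V = np.zeros(len(gids))
        np.add.at(V, gmap[tets].ravel(), np.repeat(v / 4.0, 4))
        K = _p1_stiffness(mesh.vertices, tets, len(gids), gmap)
        return gids, gmap, V, K

    cyt_verts, cmap, Vc, Kc = subdomain(CYTOSOL)
    if mesh.has_er:
        er_verts, emap, Ve, Ke = subdomain(ER_LUMEN)
    else:
        er_verts = np.empty(0, dtype=np.int64)
        emap = np.full(mesh.n_vertices, -1, dtype=np.int64)
        Ve = np.empty(0)
        Ke = sp.csr_matrix((0, 0))

    def lump(label):
        tris = mesh.surface_tris(label)
        A = np.zeros(len(cyt_verts))
        if len(tris):
            a = triangle_areas(mesh.vertices, tris)
            np.add.at(A, cmap[tris].ravel(), np.repeat(a / 3.0, 3))
        return A

    A_pm = lump(PM)
    A_psd = lump(PSD)
    A_erm_c = lump(ERM)
    erm_c = np.flatnonzero(A_erm_c > 0)
    A_erm = A_erm_c[erm_c]
    erm_e = emap[cyt_verts[erm_c]] if mesh.has_er else np.empty(0, dtype=np.int64)
    if mesh.has_er and np.any(erm_e < 0):
        raise ValueError("ERM vertices missing from the ER subdomain")

    zone_w = {}
    for name, code in (("head", HEAD), ("neck", NECK), ("dendrite", DENDRITE)):
        tets = mesh.tets[(mesh.volume_subset == CYTOSOL) & (mesh.zone == code)]
        w = np.zeros(len(cyt_verts))
        if len(tets):
            v = tet_signed_volumes(mesh.vertices, tets)
            np.add.at(w, cmap[tets].ravel(), np.repeat(v / 4.0, 4))
        zone_w[name] = w

    # stiffness couplings crossing the neck base plane (z = 0)
    z = mesh.vertices[cyt_verts][:, 2]
    above = z > 1e-9
    K = Kc.tocoo()
    cross = above[K.row] & ~above[K.col]
    r_neck = mesh.meta.get("neck_radius")
    if r_neck is not None:
        radial = np.hypot(*mesh.vertices[cyt_verts][:, :2].T)
        cross &= (radial[K.row] <= 2 * r_neck) & (radial[K.col] <= 2 * r_neck)
        base_area = np.pi * r_neck**2
    else:
        base_area = 1.0

    return DualMesh(
        mesh=mesh, cyt_verts=cyt_verts, er_verts=er_verts, Vc=Vc, Ve=Ve,
        Kc=Kc, Ke=Ke, A_pm=A_pm, A_psd=A_psd,
        erm_c=erm_c, erm_e=erm_e, A_erm=A_erm, zone_w=zone_w,
        flux_rows=K.row[cross], flux_cols=K.col[cross],
        flux_vals=K.data[cross], neck_base_area=base_area,
    )


# ----------------------------------------------------------------------
# field state

@dataclass
class FieldState:
    """Nodal concentrations (µM) and RyR gating occupancies at time t."""

    c_c: np.ndarray
    b: np.ndarray
    c_e: np.ndarray
    c1: np.ndarray
    o2: np.ndarray
    c2: np.ndarray
    t: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.c_c, self.b, self.c_e,
                               self.c1, self.o2, self.c2])

    @classmethod
    def from_vector(cls, u: np.ndarray, dual: DualMesh, t: float) -> "FieldState":
        nc, ne, nm = dual.n_c, dual.n_e, dual.n_m
        o = 0
        cc = u[o:o + nc]; o += nc
        b = u[o:o + nc]; o += nc
        ce = u[o:o + ne]; o += ne
        c1 = u[o:o + nm]; o += nm
        o2 = u[o:o + nm]; o += nm
        c2 = u[o:o + nm]
        return cls(cc.copy(), b.copy(), ce.copy(), c1.copy(), o2.copy(),
                   c2.copy(), t)

    @property
    def gating(self) -> RyRGatingState:
        return RyRGatingState(c1=self.c1, o2=self.o2, c2=self.c2)

    def total_calcium(self, dual: DualMesh, params: ModelParameters) -> float:
        """Total calcium (free + buffer-bound + luminal) in µM·µm³."""
        bound = params.b_tot - self.b
        tot = float(np.dot(dual.Vc, self.c_c + bound))
        if dual.n_e:
            tot += float(np.dot(dual.Ve, self.c_e))
        return tot


def equilibrium_state(dual: DualMesh, params: ModelParameters) -> FieldState:
    """Rest state: resting concentrations, buffer and gating equilibria."""
    nc, ne, nm = dual.n_c, dual.n_e, dual.n_m
    b0 = kinetics.equilibrium_free_buffer(params)
    g = kinetics.ryr_steady_state(params.c_c0, params)
    return FieldState(
        c_c=np.full(nc, params.c_c0),
        b=np.full(nc, b0),
        c_e=np.full(ne, params.c_e0),
        c1=np.full(nm, float(g.c1)),
        o2=np.full(nm, float(g.o2)),
        c2=np.full(nm, float(g.c2)),
        t=0.0,
    )


# ----------------------------------------------------------------------
# implicit solver

class ImplicitSolver:
    """Backward-Euler/Newton-Krylov integrator on a DualMesh."""

    def __init__(self, dual: DualMesh, params: ModelParameters,
                 config: SimulationConfig, influx: Optional[InfluxSpec] = None,
                 membranes_enabled: bool = True):
        self.dual = dual
        self.params = params
        self.config = config
        self.influx = influx
        self.membranes_enabled = membranes_enabled
        p = params
        self.psd_area_total = float(dual.A_psd.sum())
        # per-unit-open-probability RyR conductance [µm/s]
        self.g_ryr_coeff = p.rho_r * (p.IR_ref * FLUX) / p.ce_ref
        self._const_cache: Dict[float, sp.csr_matrix] = {}
        # Jacobian / preconditioner caches: the Jacobian changes slowly
        # between accepted steps, so both are reused (inexact Newton)
        # and refreshed on age or whenever the Krylov solver slows down
        self._A = None
        self._As = None
        self._diag = None
        self._A_dt = None
        self._ilu = None
        self._ilu_age = 0
        self.ilu_refresh_age = 60
        self.linear_fallbacks = 0
        nc, ne, nm = dual.n_c, dual.n_e, dual.n_m
        self.n = 2 * nc + ne + 3 * nm
        self._off = {
            "cc": 0, "b": nc, "ce": 2 * nc,
            "c1": 2 * nc + ne, "o2": 2 * nc + ne + nm,
            "c2": 2 * nc + ne + 2 * nm,
        }

    # -- residual -----------------------------------------------------
    def residual(self, u: np.ndarray, uprev: np.ndarray, dt: float,
                 t_new: float) -> np.ndarray:
        d, p = self.dual, self.params
        nc, ne, nm = d.n_c, d.n_e, d.n_m
        o = self._off
        cc = u[o["cc"]:o["cc"] + nc]
        b = u[o["b"]:o["b"] + nc]
        ce = u[o["ce"]:o["ce"] + ne]
        c1 = u[o["c1"]:o["c1"] + nm]
        o2 = u[o["o2"]:o["o2"] + nm]
        c2 = u[o["c2"]:o["c2"] + nm]
        if np.any(~np.isfinite(u)):
            raise StepFailure("non-finite state")

        F = np.empty_like(u)
        R = p.kb_minus * (p.b_tot - b) - p.kb_plus * b * cc

        Fcc = d.Vc * (cc - uprev[o["cc"]:o["cc"] + nc]) / dt \
            + p.D_c * (d.Kc @ cc) - d.Vc * R
        Fb = d.Vc * (b - uprev[o["b"]:o["b"] + nc]) / dt \
            + p.D_b * (d.Kc @ b) - d.Vc * R

        # synaptic influx is a boundary condition in its own right; it
        # applies even when the membrane exchange machinery is disabled
        if self.influx is not None:
            Fcc -= d.A_psd * self._j_syn_int(t_new)
        if self.membranes_enabled:
            Fcc -= d.A_pm * self._j_pm_int(cc)
        if ne:
            Fce = d.Ve * (ce - uprev[o["ce"]:o["ce"] + ne]) / dt \
                + p.D_c * (d.Ke @ ce)
            if self.membranes_enabled:
                jerm = self._j_erm_int(cc[d.erm_c], ce[d.erm_e], c1, c2)
                np.subtract.at(Fcc, d.erm_c, d.A_erm * jerm)
                np.add.at(Fce, d.erm_e, d.A_erm * jerm)
            F[o["ce"]:o["ce"] + ne] = Fce
        if nm:
            # clamp to a physical ceiling: Newton trial states can briefly
            # overshoot, and c^4 overflows long before double precision
            c_at = np.minimum(cc[d.erm_c], 1e4)
            o1 = 1.0 - c1 - o2 - c2
            F[o["c1"]:o["c1"] + nm] = (c1 - uprev[o["c1"]:o["c1"] + nm]) / dt \
                - (p.ka_minus * o1 - p.ka_plus * c_at**4 * c1)
            F[o["o2"]:o["o2"] + nm] = (o2 - uprev[o["o2"]:o["o2"] + nm]) / dt \
                - (p.kb_plus_ryr * c_at**3 * o1 - p.kb_minus_ryr * o2)
            F[o["c2"]:o["c2"] + nm] = (c2 - uprev[o["c2"]:o["c2"] + nm]) / dt \
                - (p.kc_plus * o1 - p.kc_minus * c2)
        F[o["cc"]:o["cc"] + nc] = Fcc
        F[o["b"]:o["b"] + nc] = Fb
        return F

    def _j_pm_int(self, cc: np.ndarray) -> np.ndarray:
        """Plasma-membrane flux density, internal units, positive inward."""
        p = self.params
        pump = (kinetics.pmca_flux_density(cc, p)
                + kinetics.ncx_flux_density(cc, p)) * FLUX
        leak = p.v_lp * (p.c_o - cc)
        return leak - pump

    def _j_syn_int(self, t: float) -> float:
        j = kinetics.synaptic_influx_density(t, self.influx, self.psd_area_total)
        return float(j) * FLUX

    def _j_erm_int(self, cc_m, ce_m, c1, c2) -> np.ndarray:
        """ER-membrane flux density (positive ER -> cytosol), internal."""
        p = self.params
        p_open = 1.0 - c1 - c2  # o1 + o2
        g = self.g_ryr_coeff * p_open + p.v_le
        return g * (ce_m - cc_m)

    # -- Jacobian -----------------------------------------------------
    def _const_part(self, dt: float) -> sp.csr_matrix:
        A = self._const_cache.get(dt)
        if A is not None:
            return A
        d, p = self.dual, self.params
        ne, nm = d.n_e, d.n_m
        o = self._off
        blocks = []
        Mc = sp.diags(d.Vc / dt)
        blocks.append(_place(Mc + p.D_c * d.Kc, o["cc"], o["cc"], self.n))
        blocks.append(_place(Mc + p.D_b * d.Kc, o["b"], o["b"], self.n))
        if ne:
            Me = sp.diags(d.Ve / dt)
            blocks.append(_place(Me + p.D_c * d.Ke, o["ce"], o["ce"], self.n))
        if nm:
            I = sp.identity(nm) / dt
            for k in ("c1", "o2", "c2"):
                blocks.append(_place(I, o[k], o[k], self.n))
        A = sum(blocks).tocsr()
        self._const_cache[dt] = A
        if len(self._const_cache) > 8:
            self._const_cache.pop(next(iter(self._const_cache)))
        return A

    def jacobian(self, u: np.ndarray, dt: float) -> sp.csr_matrix:
        d, p = self.dual, self.params
        nc, ne, nm = d.n_c, d.n_e, d.n_m
        o = self._off
        cc = u[o["cc"]:o["cc"] + nc]
        b = u[o["b"]:o["b"] + nc]
        ce = u[o["ce"]:o["ce"] + ne]
        c1 = u[o["c1"]:o["c1"] + nm]
        o2 = u[o["o2"]:o["o2"] + nm]
        c2 = u[o["c2"]:o["c2"] + nm]

        rows: List[np.ndarray] = []
        cols: List[np.ndarray] = []
        data: List[np.ndarray] = []

        def add(r, c, v):
            rows.append(np.asarray(r)); cols.append(np.asarray(c))
            data.append(np.asarray(v, float))

        idx_c = np.arange(nc)
        add(o["cc"] + idx_c, o["cc"] + idx_c, d.Vc * p.kb_plus * b)
        add(o["cc"] + idx_c, o["b"] + idx_c, d.Vc * (p.kb_minus + p.kb_plus * cc))
        add(o["b"] + idx_c, o["b"] + idx_c, d.Vc * (p.kb_minus + p.kb_plus * cc))
        add(o["b"] + idx_c, o["cc"] + idx_c, d.Vc * p.kb_plus * b)

        if self.membranes_enabled:
            dpump = (p.rho_p * p.I_p * 2 * p.K_p**2 * cc
                     / (p.K_p**2 + cc**2) ** 2
                     + p.rho_N * p.I_N * p.K_N / (p.K_N + cc) ** 2) * FLUX
            add(o["cc"] + idx_c, o["cc"] + idx_c, d.A_pm * (p.v_lp + dpump))

        if nm and self.membranes_enabled:
            cm, em, im = d.erm_c, d.erm_e, np.arange(nm)
            p_open = 1.0 - c1 - c2
            g = self.g_ryr_coeff * p_open + p.v_le
            grad = ce[em] - cc[cm]
            Ag = d.A_erm * g
            Agr = d.A_erm * self.g_ryr_coeff * grad
            add(o["cc"] + cm, o["cc"] + cm, +Ag)
            add(o["cc"] + cm, o["ce"] + em, -Ag)
            add(o["cc"] + cm, o["c1"] + im, +Agr)
            add(o["cc"] + cm, o["c2"] + im, +Agr)
            add(o["ce"] + em, o["cc"] + cm, -Ag)
            add(o["ce"] + em, o["ce"] + em, +Ag)
            add(o["ce"] + em, o["c1"] + im, -Agr)
            add(o["ce"] + em, o["c2"] + im, -Agr)

        if nm:
            cm, im = d.erm_c, np.arange(nm)
            c_at = np.minimum(cc[cm], 1e4)
            o1 = 1.0 - c1 - o2 - c2
            c3 = c_at**3
            c4 = c3 * c_at
            add(o["c1"] + im, o["c1"] + im, p.ka_minus + p.ka_plus * c4)
            add(o["c1"] + im, o["o2"] + im, np.full(nm, p.ka_minus))
            add(o["c1"] + im, o["c2"] + im, np.full(nm, p.ka_minus))
            add(o["c1"] + im, o["cc"] + cm, p.ka_plus * 4 * c3 * c1)
            add(o["o2"] + im, o["c1"] + im, p.kb_plus_ryr * c3)
            add(o["o2"] + im, o["o2"] + im, p.kb_plus_ryr * c3 + p.kb_minus_ryr)
            add(o["o2"] + im, o["c2"] + im, p.kb_plus_ryr * c3)
            add(o["o2"] + im, o["cc"] + cm, -p.kb_plus_ryr * 3 * c_at**2 * o1)
            add(o["c2"] + im, o["c1"] + im, np.full(nm, p.kc_plus))
            add(o["c2"] + im, o["o2"] + im, np.full(nm, p.kc_plus))
            add(o["c2"] + im, o["c2"] + im, np.full(nm, p.kc_plus + p.kc_minus))

        var = sp.coo_matrix(
            (np.concatenate(data),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsr()
        return self._const_part(dt) + var

    # -- linear solve -------------------------------------------------
    def _refresh_jacobian(self, u: np.ndarray, dt: float) -> None:
        A = self.jacobian(u, dt)
        # row equilibration: volume-type and probability-type equations
        # differ by many orders of magnitude
        diag = np.abs(A.diagonal())
        diag[diag == 0] = 1.0
        self._A = A
        self._diag = diag
        self._As = (sp.diags(1.0 / diag) @ A).tocsc()
        self._A_dt = dt

    def _refresh_ilu(self) -> None:
        # exact LU of the lagged, row-equilibrated Jacobian: a robust
        # splitting preconditioner whose quality degrades only slowly as
        # the state drifts, so BiCGSTAB needs very few iterations
        try:
            self._ilu = spla.splu(self._As)
            self._ilu_age = 0
        except RuntimeError:
            self._ilu = None

    def _linear_solve(self, rhs: np.ndarray) -> np.ndarray:
        cfg = self.config
        rs = rhs / self._diag
        if self._ilu is None:
            self._refresh_ilu()
        n_iter = [0]

        def count(_):
            n_iter[0] += 1

        # the inner tolerance is modest: the Newton outer iteration
        # controls the final accuracy (inexact-Newton), and a target
        # below the matvec noise floor would never be reached
        if self._ilu is not None:
            M = spla.LinearOperator(self._As.shape, self._ilu.solve)
            x, info = spla.bicgstab(self._As, rs, M=M, rtol=1e-8,
                                    atol=cfg.linear_tol,
                                    maxiter=min(cfg.linear_max_iter, 500),
                                    callback=count)
            self._ilu_age += 1
            if n_iter[0] > 25:
                self._ilu = None  # stale preconditioner: rebuild next time
            if info == 0 and np.all(np.isfinite(x)):
                return x
            self._refresh_ilu()
            if self._ilu is not None:
                M = spla.LinearOperator(self._As.shape, self._ilu.solve)
                x, info = spla.bicgstab(self._As, rs, M=M, rtol=1e-8,
                                        atol=cfg.linear_tol,
                                        maxiter=min(cfg.linear_max_iter, 500))
                if info == 0 and np.all(np.isfinite(x)):
                    return x
        self.linear_fallbacks += 1
        try:
            return spla.splu(self._As).solve(rs)
        except RuntimeError as exc:  # singular matrix
            raise StepFailure(f"linear solver failure: {exc}") from exc

    # -- single implicit step ------------------------------------------
    def step(self, uprev: np.ndarray, dt: float, t_prev: float) -> np.ndarray:
        cfg = self.config
        t_new = t_prev + dt
        u = uprev.copy()
        F = self.residual(u, uprev, dt, t_new)
        norm = np.linalg.norm(F)
        # the achievable residual is limited by cancellation in the
        # storage/diffusion terms; anchor the tolerance to their scale
        scale = np.linalg.norm(self._const_part(dt) @ uprev)
        tol = max(cfg.newton_tol, cfg.newton_rtol * norm,
                  cfg.newton_scale_floor * scale)
        converged = norm <= tol
        norm0 = norm
        grow_streak = 0
        prev_grew = False
        for it in range(cfg.newton_max_iter):
            if converged:
                break
            # modified Newton: the early iterations and any iteration
            # following residual growth get a fresh Jacobian (stale ones
            # overshoot on stiff states); quiet iterations reuse it.
            # The ILU factors live longer still, until they go stale.
            if it <= 1 or it == 3 or prev_grew:
                self._refresh_jacobian(u, dt)
            if self._ilu_age >= self.ilu_refresh_age:
                self._ilu = None
            du = self._linear_solve(-F)
            u = u + du
            F = self.residual(u, uprev, dt, t_new)
            norm_prev = norm
            norm = np.linalg.norm(F)
            if not np.isfinite(norm):
                raise StepFailure("Newton diverged (non-finite residual)")
            # fail fast instead of burning the full iteration budget --
            # but only on *sustained* growth: a single overshoot on the
            # first correction of a stiff state is normal
            prev_grew = norm > 2.0 * norm_prev
            grow_streak = grow_streak + 1 if prev_grew else 0
            if grow_streak >= 3:
                raise StepFailure("Newton diverging")
            if it >= 6 and norm > 0.25 * norm0:
                raise StepFailure("Newton stagnating")
            converged = norm <= tol
        if not converged:
            raise StepFailure(f"Newton did not converge (residual {norm:g})")
        # positivity: reject clearly negative concentrations, forgive dust
        conc_end = self._off["c1"] if self.dual.n_m else len(u)
        conc = u[:conc_end]
        if conc.min() < -1e-6:
            raise StepFailure(f"negative concentration {conc.min():g}")
        np.clip(conc, 0.0, None, out=conc)
        if self.dual.n_m:
            gat = u[self._off["c1"]:]
            if gat.min() < -1e-6 or gat.max() > 1 + 1e-6:
                raise StepFailure("gating state left [0, 1]")
            np.clip(gat, 0.0, 1.0, out=gat)
        return u


def _place(block: sp.spmatrix, r0: int, c0: int, n: int) -> sp.coo_matrix:
    b = block.tocoo()
    return sp.coo_matrix((b.data, (b.row + r0, b.col + c0)), shape=(n, n))


# module-level wrappers matching the operation-style API ----------------

def assemble_residual(state: FieldState, prev: FieldState, dt: float,
                      dual: DualMesh, params: ModelParameters,
                      influx: Optional[InfluxSpec] = None,
                      membranes_enabled: bool = True) -> np.ndarray:
    """Backward-Euler residual of ``state`` against ``prev`` over ``dt``."""
    solver = ImplicitSolver(dual, params, SimulationConfig(), influx,
                            membranes_enabled)
    return solver.residual(state.to_vector(), prev.to_vector(), dt, state.t)


def step(state: FieldState, dt: float, dual: DualMesh,
         params: ModelParameters, config: SimulationConfig,
         influx: Optional[InfluxSpec] = None,
         membranes_enabled: bool = True) -> FieldState:
    """One implicit step; raises :class:`StepFailure` for retry-smaller-dt."""
    solver = ImplicitSolver(dual, params, config, influx, membranes_enabled)
    u = solver.step(state.to_vector(), dt, state.t)
    return FieldState.from_vector(u, dual, state.t + dt)


# ----------------------------------------------------------------------
# trace container

@dataclass
class TraceResult:
    """Zone-averaged time series and bookkeeping from one simulation."""

    times: np.ndarray                   # s
    zone_mean: Dict[str, np.ndarray]    # µM per zone
    ce_mean: np.ndarray                 # µM
    neck_base_flux: np.ndarray          # mol s⁻¹ µm⁻²
    ion_budget: Dict[str, float]        # cumulative ions
    meta: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)

    @property
    def peaks(self) -> Dict[str, float]:
        return {z: float(np.max(v)) for z, v in self.zone_mean.items()}

    def peak(self, zone: str) -> float:
        return float(np.max(self.zone_mean[zone]))

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for z, v in self.zone_mean.items():
            cols[f"{z}_uM"] = v
        cols["er_uM"] = self.ce_mean
        cols["neck_base_flux_mol_s_um2"] = self.neck_base_flux
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ----------------------------------------------------------------------
# time loop

def simulate(mesh: TetMesh, params: ModelParameters, config: SimulationConfig,
             influx: Optional[InfluxSpec] = None,
             membranes_enabled: bool = True,
             dual: Optional[DualMesh] = None,
             initial: Optional[FieldState] = None) -> TraceResult:
    """Run the calcium model from the rest state on a labeled mesh.

    Adaptive backward-Euler loop: a failed step is retried with dt/2
    (aborting below ``tau_min``); successes double dt back toward
    ``tau_sim``.  Zone means, the diffusive flux through the neck base,
    and the cumulative ion budget are recorded every ``output_stride``
    accepted steps.
    """
    if dual is None:
        dual = build_dual_mesh(mesh)
    solver = ImplicitSolver(dual, params, config, influx, membranes_enabled)
    state = initial if initial is not None else equilibrium_state(dual, params)
    u = state.to_vector()
    t = state.t

    wsum = {z: w.sum() for z, w in dual.zone_w.items()}
    Ve_tot = dual.Ve.sum() if dual.n_e else 1.0

    times: List[float] = []
    series: Dict[str, List[float]] = {z: [] for z in dual.zone_w}
    ce_series: List[float] = []
    neck_flux: List[float] = []
    snapshots = []

    def record(u, t):
        nc = dual.n_c
        cc = u[:nc]
        times.append(t)
        for z, w in dual.zone_w.items():
            series[z].append(float(np.dot(w, cc) / wsum[z]) if wsum[z] else 0.0)
        if dual.n_e:
            ce = u[2 * nc:2 * nc + dual.n_e]
            ce_series.append(float(np.dot(dual.Ve, ce) / Ve_tot))
        else:
            ce_series.append(0.0)
        # diffusive inflow into the dendritic side, µM µm³/s
        dc = cc[dual.flux_cols] - cc[dual.flux_rows]
        q = params.D_c * float(np.dot(dual.flux_vals, dc))
        neck_flux.append(q / FLUX / dual.neck_base_area)

    budget = {"influx": 0.0, "pm_extrusion": 0.0, "pm_leak": 0.0,
              "er_release": 0.0}
    total0 = FieldState.from_vector(u, dual, t).total_calcium(dual, params)

    record(u, t)
    dt = config.tau_sim
    n_accepted = n_rejected = 0
    n_success_streak = 0
    stride_count = 0
    coupled_since: Optional[float] = None
    t_stop = None

    while t < config.t_end - 1e-15:
        dt = min(dt, config.t_end - t)
        try:
            u_new = solver.step(u, dt, t)
        except StepFailure:
            n_rejected += 1
            n_success_streak = 0
            solver._ilu = None
            dt = dt / 2
            if dt < config.tau_min:
                raise SimulationError(
                    f"time step underflow below tau_min = {config.tau_min:g} s"
                    f" at t = {t:g} s"
                )
            continue
        nc = dual.n_c
        cc = u_new[:nc]
        if influx is not None:
            budget["influx"] += solver._j_syn_int(t + dt) \
                * float(dual.A_psd.sum()) * dt
        if membranes_enabled:
            pump = (kinetics.pmca_flux_density(cc, params)
                    + kinetics.ncx_flux_density(cc, params)) * FLUX
            budget["pm_extrusion"] += float(np.dot(dual.A_pm, pump)) * dt
            budget["pm_leak"] += float(
                np.dot(dual.A_pm, params.v_lp * (params.c_o - cc))) * dt
            if dual.n_m:
                off = solver._off
                c1 = u_new[off["c1"]:off["c1"] + dual.n_m]
                c2 = u_new[off["c2"]:off["c2"] + dual.n_m]
                ce = u_new[2 * nc:2 * nc + dual.n_e]
                jerm = solver._j_erm_int(cc[dual.erm_c], ce[dual.erm_e], c1, c2)
                budget["er_release"] += float(np.dot(dual.A_erm, jerm)) * dt

        t += dt
        u = u_new
        n_accepted += 1
        stride_count += 1
        if stride_count >= config.output_stride:
            record(u, t)
            stride_count = 0
        if config.snapshot_stride and n_accepted % config.snapshot_stride == 0:
            snapshots.append((t, FieldState.from_vector(u, dual, t)))
        # re-grow dt only after a few consecutive successes; doubling
        # straight back after each accepted step thrashes at stiff phases
        n_success_streak += 1
        if dt < config.tau_sim and n_success_streak >= 4:
            dt = min(dt * 2, config.tau_sim)
            n_success_streak = 0

        if config.stop_when_coupled and wsum.get("dendrite", 0) > 0:
            dend = float(np.dot(dual.zone_w["dendrite"], u[:nc])
                         / wsum["dendrite"])
            if dend > config.coupling_threshold:
                if coupled_since is None:
                    coupled_since = t
                elif t - coupled_since >= 1.5 * config.coupling_duration:
                    t_stop = t
                    break
            else:
                coupled_since = None

    if stride_count:
        record(u, t)

    final = FieldState.from_vector(u, dual, t)
    total1 = final.total_calcium(dual, params)
    for k in budget:
        budget[k] *= 1e-21 * AVOGADRO  # µM µm³ -> ions
    budget["net_gain"] = (total1 - total0) * 1e-21 * AVOGADRO

    meta = {
        "config": config.to_dict(),
        "params_hash": params.content_hash(),
        "rho_r": params.rho_r,
        "n_accepted": n_accepted,
        "n_rejected": n_rejected,
        "linear_fallbacks": solver.linear_fallbacks,
        "stopped_early_at": t_stop,
        "conservation": {
            "total_initial_uM_um3": total0,
            "total_final_uM_um3": total1,
        },
    }
    return TraceResult(
        times=np.asarray(times),
        zone_mean={z: np.asarray(v) for z, v in series.items()},
        ce_mean=np.asarray(ce_series),
        neck_base_flux=np.asarray(neck_flux),
        ion_budget=budget,
        meta=meta,
        snapshots=snapshots,
    )


def convergence_study(mesh: TetMesh, params: ModelParameters,
                      config: SimulationConfig, n_halvings: int,
                      influx: Optional[InfluxSpec] = None,
                      membranes_enabled: bool = True) -> pd.DataFrame:
    """Temporal self-convergence: successive dt-halving differences.

    Runs the model with tau_sim, tau_sim/2, ... and reports the maximum
    zone-mean difference between consecutive levels at the shared output
    times, plus the observed convergence order between those differences
    (backward Euler should show order about one).
    """
    if n_halvings < 2:
        raise ValueError("n_halvings must be >= 2")
    dual = build_dual_mesh(mesh)
    runs = []
    for k in range(n_halvings + 1):
        cfg = config.replace(tau_sim=config.tau_sim / 2**k,
                             output_stride=config.output_stride * 2**k)
        runs.append(simulate(mesh, params, cfg, influx, membranes_enabled,
                             dual=dual))
    rows = []
    prev_diff = None
    for k in range(n_halvings):
        a, b = runs[k], runs[k + 1]
        # adaptive rejections can shift the recorded times, so compare on
        # the coarse run's grid with the fine run interpolated onto it
        diff = 0.0
        for z in a.zone_mean:
            fine = np.interp(a.times, b.times, b.zone_mean[z])
            diff = max(diff, float(np.max(np.abs(a.zone_mean[z] - fine))))
        order = np.log2(prev_diff / diff) if (prev_diff and diff > 0) else np.nan
        rows.append({"tau_sim": config.tau_sim / 2**k, "max_diff_uM": diff,
                     "observed_order": order})
        prev_diff = diff
    return pd.DataFrame(rows)
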