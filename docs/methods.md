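# Methods

## The model

The package solves a two-phase reaction–diffusion problem on labeled
tetrahedral meshes of a dendritic spine.  The cytosol carries free
calcium `c_c` and free mobile buffer `b` (calbindin-D28k treated as a
single effective binding site at four times its concentration, so the
total `b_tot = 40 µM` stands for 10 µM of four-site protein); the ER
lumen (spine apparatus + dendritic tubule) carries `c_e`.  Both phases
diffuse with the free-calcium coefficient `D_c = 220 µm²/s`; the buffer
diffuses with `D_b = 20 µm²/s`.  Binding follows mass action with
`κb⁺ = 27 /(µM s)` and `κb⁻ = 19 /s`; the bound pool is `b_tot − b`
(total buffer uniform, i.e. free buffer and complex share diffusive
properties).

Membrane exchange (flux densities in mol s⁻¹ µm⁻², positive into the
cytosol):

| mechanism | law | constants |
|---|---|---|
| RyR (ER membrane) | `ρ_R p_o I_ref (c_e − c_c)/c_ref` | `I_ref = 3.5e-18 mol/s`, `c_ref = 250 µM` |
| ER leak | `v_le (c_e − c_c)` | `v_le = 38 nm/s` |
| PMCA | `−ρ_P I_P c²/(K_P² + c²)` | `ρ_P = 500 /µm²`, `I_P = 1.7e-23 mol/s`, `K_P = 60 nM` |
| NCX | `−ρ_N I_N c/(K_N + c)` | `ρ_N = 15 /µm²`, `I_N = 2.5e-21 mol/s`, `K_N = 1.8 µM` |
| PM leak | `v_lp (c_o − c_c)` | `v_lp = 4.5 nm/s`, `c_o = 2 mM` |
| synapse (PSD) | `j_peak (1 − t/τ)`, `t ≤ τ` | `j_peak = 8.6e-18 mol s⁻¹ µm⁻²`, `τ = 10 ms` |

RyR gating is the explicit 4-state scheme (states `c1, o1, o2, c2`,
`p_o = o1 + o2`) with `ka⁻ = 28.8 /s`, `ka⁺ = 1500 /(µM⁴ s)`,
`kb⁻ = 385.9 /s`, `kb⁺ = 1500 /(µM³ s)`, `kc⁻ = 0.1 /s`,
`kc⁺ = 1.75 /s`; the concentration powers take `c` in µM.  The gating
ODEs are solved at every ER-membrane vertex, initialized at the closed
steady state for resting calcium (the only self-consistent rest state;
the closed form `o1 = 1/(1 + ka⁻/(ka⁺c⁴) + kb⁺c³/kb⁻ + kc⁺/kc⁻)`
follows from setting the rates to zero).

Initial conditions everywhere: `c_c = 50 nM`, `c_e = 250 µM`, buffer at
binding equilibrium (`b₀ ≈ 37.35 µM`).  The membrane potential is held
constant and enters no equation; voltage-gated calcium channels, IP3
receptors and SERCA pumps are outside the model.  A handful of
IP3-pathway constants are carried in `ModelParameters` for provenance
only.

**Leak balance caveat.** A plasma-membrane leak that exactly cancels
PMCA+NCX at rest would need `v_lp ≈ 2.25 nm/s`
(`calibrate_pm_leak`), half the nominal 4.5 nm/s; the nominal value is
kept as the default (it implicitly covers resting influx pathways the
model omits) and the calibration is reported as a diagnostic.  The ER
membrane has no refill pump, so a nonzero `v_le` implies slow resting
store depletion (~µM per tens of ms at rest); the equilibrium-persistence
test therefore uses the balanced pair (`v_lp` calibrated, `v_le = 0`),
the only exactly stationary configuration.

## Synthetic geometry

Reconstructed spine meshes are not available, so the generator emits an
idealized SA-containing spine in their statistical range: a spherical
head (radius 0.2–0.35 µm) on a cylindrical neck (length 0.3–1.7 µm,
radius 0.05–0.3 µm, giving neck cross-sections spanning the measured
0.007–0.3 µm²), inserted into a cylindrical dendrite (~1 µm wide); the
SA is a capped tube (neck radius chosen so the SA occupies 3–49% of the
neck section) running from a standardized dendritic ER tubule through
the neck into the lower head, where it ends in a small bulge; the PSD is
a spherical cap at the head apex (area set so the standard pulse
delivers ≈ 2,400 ions).  Coordinates: dendrite axis x, spine axis z,
spine base at the origin.

Meshing needs no external tetrahedralizer: a background lattice of cubes
(Kuhn-subdivided into six conforming tets) is clipped against
signed-distance functions by marching tetrahedra.  Edge cut points are
cached globally and quad faces are triangulated by a diagonal rule that
depends only on global vertex indices, so the mesh is conforming across
elements and the cytosol/ER interface is an exactly shared triangulated
surface.  Measuring zones are assigned by axial position (dendrite
z ≤ 0, neck 0 < z ≤ neck length, head above; the dendritic measuring
zone is the shaft within ±0.5 µm of the insertion).  Neck cross-sections
are measured on the plane through the neck axial midpoint; the neck
diameter is the mean of sections at 25/50/75% of the neck.

Resolution trade-off: the default desk edge length (0.08–0.095 µm) is
coarse against the paper-grade 5–30 nm.  Boundary volumes are accurate
to ~1–2%, but the thin SA stem is under-resolved — at 0.095 µm its
meshed cross-section is a few percent of the neck rather than the
nominal ~21% — so desk-scale results are qualitative.  All generator
parameters accept finer edges for convergence studies; at ≤ 0.05 µm the
stem section approaches nominal.

## Discretization and solver

Unknowns live on vertices: `c_c`, `b` on cytosol vertices, `c_e` on ER
vertices, three gating states per ER-membrane vertex.  Control volumes
are the barycentric dual (a quarter of each incident tet); diffusion is
assembled as the P1 finite-element stiffness, to which the
vertex-centered box scheme is algebraically equivalent for the
Laplacian; membrane fluxes are lumped to vertices (a third of each
boundary triangle).  ER-membrane fluxes enter the adjacent cytosol and
ER control volumes with opposite signs (positive = ER → cytosol).

Time stepping is backward Euler with Newton linearization, the gating
ODEs solved monolithically in the same Newton system.  Internal units
are µm/s/µM so state vectors are O(1)–O(100) and norms meaningful.  The
linear solves use BiCGSTAB on the row-equilibrated Jacobian,
preconditioned by a sparse LU factorization of a lagged Jacobian that is
reused across iterations and steps and refreshed when the Krylov
iteration count rises; a direct solve is the fallback if the Krylov
solver stagnates.  The inner relative tolerance is 1e-8 — the Newton
iteration controls the final accuracy, and the configured absolute
target (1e-18, kept as `linear_tol`) lies below the matvec noise floor
in these units.  Newton stops on an absolute norm, a relative reduction,
or a floor tied to the storage-term norm (cut tetrahedra produce slivers
whose stiffness entries amplify roundoff; the floor is what the residual
evaluation can actually reach).  Trial-state calcium is clamped at
1e4 µM inside the gating powers to avoid overflow before the step is
rejected.  Failed steps halve dt down to `tau_min = tau_sim/2**15` and
abort below it; successes double dt back toward `tau_sim`.  Step sizes:
0.5 µs reproduces production-quality trajectories (cluster scale); the
desk experiments use 10–100 µs, validated by the self-convergence study
(first-order decay of dt-halving differences).

Determinism: the model has no stochastic element; identical
configurations produce bit-identical traces (the config `seed` is
reserved).

## Experiments

**Coupling criterion.** Spine-to-dendrite coupling = dendritic-zone mean
above 1 µM over a *contiguous* window ≥ 1 ms (read strictly;
a cumulative reading would be weaker and ambiguous).  1 µM/1 ms converts
to 1e-18 mol s⁻¹ µm⁻³, i.e. ≈ 11–12% of the reference synaptic influx
through a 1 µm dendrite.

**Critical RyR density.** Exhaustive 0–5 µm⁻² grids at 0.01 µm⁻²
resolution cost ~500 simulations per geometry; the default fast path
brackets the coupled/uncoupled transition by bisection and refines it to
the same 0.01 µm⁻² resolution (~12 simulations), optionally warm-started
from a previous sweep.  Every run restarts from the full rest state.
Supercritical runs may stop early once the coupling window has closed;
bracket endpoints are re-run to the full horizon so reported peaks are
honest maxima.  Desk conditions for every sweep-based experiment: 15 ms
horizon, 125 µs steps (a shorter horizon raises the critical density,
since near-critical release fronts arrive late; the value is reported
together with its conditions).  The comparisons run both arms under
these identical conditions: neck widening (+10/20/40%) is evidenced by
two targeted runs per widened geometry — no coupling just below the base
critical density (so the widened critical density is not smaller, to
0.05 µm⁻² slack) and coupling well above it (a finite critical density
remains in range) — while buffer halving re-sweeps at 0.2 µm⁻²
resolution warm-bracketed below the base value.

**What desk scale does and does not show.** The reference spine
reproduces the passive regime of the measured morphologies (head peak a
few µM, dendrite ~0.1 µM, < 3% head-to-dendrite transfer), a finite
critical RyR density within the tested 0–5 µm⁻² range, full store
depletion at supercritical densities, and the monotone morphology
effects.  Its critical density (~0.9 µm⁻² at the desk 15 ms horizon)
sits below the 1.4–3.5 µm⁻² of the reconstructed spines: the desk
dendrite is shorter and the idealized straight neck attenuates less
than real, tortuous geometry.
One published feature is *not* reproduced at desk scale: the
dendritic-peak jump between adjacent 0.01 µm⁻² densities is steep but
continuous here (adjacent ratios ~1.1), not the ≥ 5-fold switch seen on
the reconstructions.  In this parameter regime the synaptic transient
itself lifts the whole neck above the RyR activation knee (~0.4 µM), so
sub-critical release is stimulus-driven and graded — the buffer's
capacity within the neck (~1.6 µM µm³) cannot shield the stem from a
2,400-ion pulse.  A genuinely bistable ignition would require geometry
that attenuates the stimulus below the knee along the SA (finer,
longer, more tortuous necks than the desk mesh can resolve).  The
corresponding test documents this as an expected failure condition of
idealized desk geometry rather than silently weakening the threshold.

**Influx modes.** `fixed` applies the same peak flux density to every
spine; `psd_adjusted` scales it by reference-PSD/PSD area so the total
ion count is PSD-independent (the reading of "scaled by PSD surface
area" consistent with compensating head accumulation); `calibrated`
bisects the peak density until the head-zone peak lies in a target
range.

## Limitations

* Desk meshes under-resolve the SA stem; quantitative critical densities
  require ≤ 30 nm edges (cluster scale).
* The idealized geometry omits tortuosity, stacked-disc SA structure and
  PSD curvature; per-spine published values are not reproducible without
  the original reconstructions.
* No VDCC, IP3, or SERCA pathways; constant membrane potential;
  deterministic continuum gating (no stochastic single-channel events).
* The ER has no refill mechanism, so long simulations deplete the store
  through the ER leak even at rest.
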