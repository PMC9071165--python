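"""Physical model parameters and run configuration.

``ModelParameters`` houses every constant of the calcium model with
explicit units.  Concentrations are stored in µM, lengths in µm, times in
s, single-channel currents in mol/s, flux densities in mol s⁻¹ µm⁻², and
membrane leak coefficients in µm/s.

The defaults are the physiological set used for human cortical spines:
resting cytosolic calcium 50 nM against 250 µM in the ER lumen and 2 mM
outside, calbindin-D28k as a single-site mobile buffer at quadrupled
concentration (40 µM total), PMCA and NCX extrusion on the plasma
membrane, a 4-state ryanodine-receptor model on the ER membrane, and a
linearly decaying 10 ms synaptic calcium pulse at the PSD.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml


@dataclass
class ModelParameters:
    """Constants of the calcium model (units in field comments).

    The handful of IP3-pathway constants (``p``, ``D_p``, ``kappa_p``,
    ``p_r``) are carried for provenance only; no implemented equation
    reads them.
    """

    # initial / equilibrium concentrations [µM]
    c_c0: float = 0.05       # resting cytosolic Ca²⁺ (50 nM)
    c_e0: float = 250.0      # resting ER-lumen Ca²⁺
    c_o: float = 2000.0      # extracellular Ca²⁺ (2 mM), held constant

    # mobile buffer (calbindin-D28k, one effective site, 4x concentration)
    b_tot: float = 40.0      # total buffer [µM]
    kb_minus: float = 19.0   # unbinding rate [1/s]
    kb_plus: float = 27.0    # binding rate [1/(µM s)]

    # diffusion [µm²/s]
    D_c: float = 220.0       # free Ca²⁺ (cytosol and ER lumen)
    D_b: float = 20.0        # buffer

    # PMCA pumps
    I_p: float = 1.7e-23     # single-pump current [mol/s]
    K_p: float = 0.06        # half-activation [µM] (60 nM)
    rho_p: float = 500.0     # surface density [1/µm²]

    # NCX exchangers
    I_N: float = 2.5e-21     # single-exchanger current [mol/s]
    K_N: float = 1.8         # half-activation [µM]
    rho_N: float = 15.0      # surface density [1/µm²]

    # leak coefficients [µm/s]  (38 nm/s and 4.5 nm/s)
    v_le: float = 38.0e-3    # ER membrane
    v_lp: float = 4.5e-3     # plasma membrane

    # RyR channel (4-state gating; concentration powers in µM)
    ka_minus: float = 28.8     # [1/s]
    ka_plus: float = 1500.0    # [1/(µM⁴ s)]
    kb_minus_ryr: float = 385.9  # [1/s]
    kb_plus_ryr: float = 1500.0  # [1/(µM³ s)]
    kc_minus: float = 0.1      # [1/s]
    kc_plus: float = 1.75      # [1/s]
    rho_r: float = 0.0         # RyR surface density [1/µm²], sweep range 0-5
    ce_ref: float = 250.0      # reference ER Ca²⁺ for channel current [µM]
    IR_ref: float = 3.5e-18    # reference single-channel current [mol/s]

    # synaptic calcium release
    jc_rls: float = 8.6e-18  # peak influx density [mol s⁻¹ µm⁻²]
    tau_rls: float = 0.010   # pulse duration [s]

    # held constant, used by no implemented equation
    V_m: float = -70.0       # membrane potential [mV]

    # IP3-pathway leftovers (provenance only, never read)
    p: float = 0.040         # [µM]
    D_p: float = 280.0       # [µm²/s]
    kappa_p: float = 0.11    # [1/s]
    p_r: float = 0.040       # [µM]

    def __post_init__(self) -> None:
        for name in ("c_c0", "c_e0", "c_o", "b_tot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"concentration {name} must be > 0")
        for f in dataclasses.fields(self):
            if f.name in ("V_m",):
                continue
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)

    # -- serialization -------------------------------------------------
    _UNITS = {
        "c_c0": "uM", "c_e0": "uM", "c_o": "uM", "b_tot": "uM",
        "kb_minus": "1/s", "kb_plus": "1/(uM s)",
        "D_c": "um^2/s", "D_b": "um^2/s",
        "I_p": "mol/s", "K_p": "uM", "rho_p": "1/um^2",
        "I_N": "mol/s", "K_N": "uM", "rho_N": "1/um^2",
        "v_le": "um/s", "v_lp": "um/s",
        "ka_minus": "1/s", "ka_plus": "1/(uM^4 s)",
        "kb_minus_ryr": "1/s", "kb_plus_ryr": "1/(uM^3 s)",
        "kc_minus": "1/s", "kc_plus": "1/s",
        "rho_r": "1/um^2", "ce_ref": "uM", "IR_ref": "mol/s",
        "jc_rls": "mol/(s um^2)", "tau_rls": "s",
        "V_m": "mV", "p": "uM", "D_p": "um^2/s",
        "kappa_p": "1/s", "p_r": "uM",
    }

    def to_dict(self, with_units: bool = True) -> dict:
        d = dataclasses.asdict(self)
        if with_units:
            return {k: {"value": v, "unit": self._UNITS[k]} for k, v in d.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        plain = {k: (v["value"] if isinstance(v, dict) else v) for k, v in d.items()}
        return cls(**plain)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelParameters":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_yaml(cls, s: str) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(s))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(with_units=False), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class InfluxSpec:
    """Synaptic calcium influx at the PSD.

    ``mode``:

    * ``fixed`` -- the same peak flux density ``j_peak`` for every spine;
    * ``psd_adjusted`` -- ``j_peak`` rescaled by ``reference_psd_area /
      psd_area`` so the total number of released ions matches the
      reference spine regardless of PSD size;
    * ``calibrated`` -- ``j_peak`` found by bracketing so the head-zone
      peak lands in a prescribed range (see
      :func:`spinesim.experiments.calibrate_influx`).
    """

    mode: str = "fixed"                   # fixed | psd_adjusted | calibrated
    j_peak: float = 8.6e-18               # mol s⁻¹ µm⁻²
    tau: float = 0.010                    # s
    reference_psd_area: Optional[float] = None  # µm² (psd_adjusted)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "psd_adjusted", "calibrated"):
            raise ValueError(f"unknown influx mode {self.mode!r}")
        if self.j_peak < 0:
            raise ValueError("j_peak must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.mode == "psd_adjusted" and (
            self.reference_psd_area is None or self.reference_psd_area <= 0
        ):
            raise ValueError("psd_adjusted mode needs a positive reference_psd_area")

    def effective_peak(self, psd_area: float) -> float:
        """Peak flux density [mol s⁻¹ µm⁻²] for a PSD of ``psd_area`` µm²."""
        if self.mode == "psd_adjusted":
            if psd_area <= 0:
                raise ValueError("psd_area must be > 0 in psd_adjusted mode")
            return self.j_peak * self.reference_psd_area / psd_area
        return self.j_peak


@dataclass
class SimulationConfig:
    """Time-stepping and solver controls.

    ``tau_sim`` is the prescribed (maximum) time-step; on Newton or Krylov
    failure the step is halved down to ``tau_min = tau_sim / 2**15`` and
    doubled back after successes.  The desk-scale default is 10 µs; the
    high-fidelity preset used for production-quality trajectories is
    0.5 µs (cluster-scale on fine meshes).
    """

    t_end: float = 0.040          # s
    tau_sim: float = 10e-6        # s
    newton_tol: float = 1e-12     # absolute residual norm (µM-based units)
    newton_rtol: float = 1e-10    # relative residual reduction
    newton_scale_floor: float = 1e-10  # floor relative to the storage-term norm
    newton_max_iter: int = 20
    linear_tol: float = 1e-18     # Krylov absolute residual target
    linear_max_iter: int = 10000
    output_stride: int = 1        # record traces every N accepted steps
    snapshot_stride: int = 0      # 0 = no field snapshots
    seed: int = 0                 # reserved; the model is deterministic
    stop_when_coupled: bool = False  # early exit once the coupling window closes
    coupling_threshold: float = 1.0  # µM, used only with stop_when_coupled
    coupling_duration: float = 1e-3  # s

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.tau_sim <= 0:
            raise ValueError("t_end and tau_sim must be > 0")
        for name in ("newton_tol", "newton_rtol", "linear_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def tau_min(self) -> float:
        """Smallest admissible step: tau_sim / 2¹⁵ exactly."""
        return self.tau_sim / 2**15

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def high_fidelity(cls, **kw) -> "SimulationConfig":
        """Production-quality preset: 0.5 µs steps (cluster-scale)."""
        kw.setdefault("tau_sim", 0.5e-6)
        return cls(**kw)
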