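"""Pulse sequences and time-stepped signal evolution.

The signal loop advances the magnetization of every site (a diffusing spin
for the Monte Carlo backend, a grid element for the deterministic one) in
steps of length dt.  Step s covers the interval (s*dt, (s+1)*dt]; an RF
pulse with ``step_index = s`` is applied at time s*dt, before that step's
evolution, so a refocusing pulse at step TE/(2*dt) splits the echo time
exactly in half.  Within a step the order is: RF (if scheduled), diffusion
update, field sampling, precession/relaxation, signal recording.

Precession applies the Larmor phase increment gamma * dBz * dt as a complex
rotation of the transverse magnetization; transverse decay multiplies by
exp(-dt/T2) and the longitudinal component relaxes toward equilibrium
(+1) with time constant T1 where those times are given (absent times mean
no decay on the simulated timescale).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detdiff, fieldmap, montecarlo
from .geometry import GAMMA_PROTON, GriddedVoxel, PhysicalConstants, VoxelSpec
from .naming import MethodSelector, parse_method_name

__all__ = [
    "RFPulse",
    "SequenceTiming",
    "TissueProperties",
    "SignalTimecourse",
    "SimulationConfig",
    "rotation_matrix",
    "apply_rf",
    "apply_rf_complex",
    "evolve_step",
    "sum_signal",
    "build_sequence",
    "run_simulation",
]


@dataclass(frozen=True)
class RFPulse:
    """An instantaneous RF rotation.

    The rotation axis is given in polar coordinates: ``axis_polar`` from the
    +z axis and ``axis_azimuth`` from +x, so a pulse about x is
    (pi/2, 0) and about y is (pi/2, pi/2).  ``alpha`` is the flip angle and
    the rotation follows the right-hand rule about the axis.
    """

    axis_polar: float
    axis_azimuth: float
    alpha: float
    step_index: int

    def __post_init__(self) -> None:
        if self.step_index < 0:
            raise ValueError("step_index must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        st, ct = np.sin(self.axis_polar), np.cos(self.axis_polar)
        return np.array([st * np.cos(self.axis_azimuth),
                         st * np.sin(self.axis_azimuth), ct])


def rotation_matrix(pulse: RFPulse) -> np.ndarray:
    """Right-handed Rodrigues rotation by ``alpha`` about the pulse axis."""
    k = pulse.axis
    kx = np.array([[0.0, -k[2], k[1]],
                   [k[2], 0.0, -k[0]],
                   [-k[1], k[0], 0.0]])
    c, s = np.cos(pulse.alpha), np.sin(pulse.alpha)
    return np.eye(3) * c + s * kx + (1.0 - c) * np.outer(k, k)


def apply_rf(m: np.ndarray, pulse: RFPulse) -> np.ndarray:
    """Rotate magnetization 3-vectors (shape ``(..., 3)``) by the pulse."""
    m = np.asarray(m, dtype=float)
    return m @ rotation_matrix(pulse).T


def apply_rf_complex(mxy: np.ndarray, mz: np.ndarray, pulse: RFPulse):
    """Pulse applied to the (complex transverse, longitudinal) split."""
    r = rotation_matrix(pulse)
    mx, my = mxy.real, mxy.imag
    nx = r[0, 0] * mx + r[0, 1] * my + r[0, 2] * mz
    ny = r[1, 0] * mx + r[1, 1] * my + r[1, 2] * mz
    nz = r[2, 0] * mx + r[2, 1] * my + r[2, 2] * mz
    return nx + 1j * ny, nz


def evolve_step(mxy: np.ndarray, mz: np.ndarray, dbz: np.ndarray, dt: float,
                *, r2: np.ndarray | float = 0.0, r1: np.ndarray | float = 0.0,
                gamma: float = GAMMA_PROTON):
    """One step of precession and relaxation.

    ``r2`` and ``r1`` are per-site relaxation rates (1/T2, 1/T1; zero means
    no decay).  Longitudinal magnetization recovers toward equilibrium +1.
    """
    phase = gamma * dt * dbz
    mxy = mxy * np.exp(1j * phase - dt * r2) if np.any(r2) else mxy * np.exp(1j * phase)
    if np.any(r1):
        mz = 1.0 + (mz - 1.0) * np.exp(-dt * r1)
    return mxy, mz


def sum_signal(mxy: np.ndarray, labels: np.ndarray):
    """Total / intravascular / extravascular complex sums.

    The partition is exact: total = iv + ev.
    """
    mxy = np.asarray(mxy).ravel()
    labels = np.asarray(labels).ravel()
    iv = complex(mxy[labels > 0].sum())
    ev = complex(mxy[labels == 0].sum())
    return iv + ev, iv, ev


@dataclass(frozen=True)
class SequenceTiming:
    """Time stepping and the RF pulse train of one acquisition."""

    dt: float
    n_steps: int
    pulses: tuple[RFPulse, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        for p in self.pulses:
            if p.step_index >= self.n_steps:
                raise ValueError(
                    f"pulse at step {p.step_index} lies beyond the "
                    f"{self.n_steps}-step sequence")

    @property
    def te(self) -> float:
        return self.n_steps * self.dt

    def pulses_at(self, step: int) -> list[RFPulse]:
        return [p for p in self.pulses if p.step_index == step]


def _steps_for(interval: float, dt: float, what: str) -> int:
    n = int(round(interval / dt))
    rem = abs(n * dt - interval)
    if n < 1 or rem > 1e-9 * max(abs(interval), dt):
        raise ValueError(
            f"{what} ({interval} s) is not divisible by dt ({dt} s); "
            f"remainder {interval - n * dt:.3e} s")
    return n


def build_sequence(kind: str, te: float, dt: float,
                   tau_shift: float = 0.0) -> SequenceTiming:
    """GE / SE / ASE pulse trains.

    All start with a 90° excitation about +x at step 0.  SE adds a 180°
    refocusing pulse about +y at TE/2; ASE displaces the refocusing pulse
    by ``tau_shift`` (signed); GE has the excitation only.
    """
    kind = kind.upper()
    n = _steps_for(te, dt, "TE")
    excite = RFPulse(np.pi / 2, 0.0, np.pi / 2, 0)
    if kind == "GE":
        pulses = (excite,)
    elif kind in ("SE", "ASE"):
        if n % 2:
            raise ValueError("TE must be an even number of steps so the "
                             "refocusing pulse can sit at TE/2")
        shift = 0
        if kind == "ASE" and tau_shift != 0.0:
            shift = int(round(tau_shift / dt))
            if abs(shift * dt - tau_shift) > 1e-9 * max(abs(tau_shift), dt):
                raise ValueError(
                    f"tau_shift ({tau_shift} s) is not divisible by dt")
        refocus_step = n // 2 + shift
        if not 0 < refocus_step < n:
            raise ValueError("the refocusing pulse must fall inside the sequence")
        pulses = (excite, RFPulse(np.pi / 2, np.pi / 2, np.pi, refocus_step))
    else:
        raise ValueError(f"unknown sequence kind {kind!r} (use GE, SE or ASE)")
    return SequenceTiming(dt=dt, n_steps=n, pulses=pulses, name=kind)


@dataclass(frozen=True)
class TissueProperties:
    """Per-compartment relaxation times, keyed by compartment label
    (0 = extravascular).  Missing labels mean no decay."""

    t2: dict | None = None
    t1: dict | None = None

    def __post_init__(self) -> None:
        for d in (self.t2, self.t1):
            if d:
                for k, v in d.items():
                    if not v > 0:
                        raise ValueError(f"relaxation time for label {k} must be positive")

    def _rate_table(self, d: dict | None, n_labels: int) -> np.ndarray:
        table = np.zeros(n_labels + 1)
        if d:
            for k, v in d.items():
                if not 0 <= int(k) <= n_labels:
                    raise ValueError(f"tissue label {k} outside the label range")
                table[int(k)] = 1.0 / v
        return table

    def r2_table(self, n_labels: int) -> np.ndarray:
        return self._rate_table(self.t2, n_labels)

    def r1_table(self, n_labels: int) -> np.ndarray:
        return self._rate_table(self.t1, n_labels)


@dataclass
class SignalTimecourse:
    """Complex total / intravascular / extravascular signal per time step,
    sampled at t = 0, dt, ..., TE (unnormalized site-count units)."""

    time: np.ndarray
    total: np.ndarray
    iv: np.ndarray
    ev: np.ndarray
    metadata: dict = field(default_factory=dict)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.total)

    def at_te(self) -> complex:
        return complex(self.total[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "re_total": self.total.real, "im_total": self.total.imag,
            "re_iv": self.iv.real, "im_iv": self.iv.imag,
            "re_ev": self.ev.real, "im_ev": self.ev.imag,
        })


@dataclass
class SimulationConfig:
    """Everything one simulation run needs.

    ``method`` is a method-name string (see :mod:`boldsim.naming`);
    ``perturbers`` feeds analytic/continuous paths, ``gridded`` the
    discretized ones (if the method is gridded and only perturbers are
    given, the voxel is discretized on the fly).
    """

    method: str
    spec: VoxelSpec
    sequence: SequenceTiming
    diffusion: montecarlo.DiffusionConfig
    perturbers: list | None = None
    gridded: GriddedVoxel | None = None
    tissue: TissueProperties | None = None
    n_spins: int = 10_000
    placement: str = "uniform"
    kernel_kind: str = "gaussian"
    n_hw: int | None = None
    pad_elements: int | None = None
    seed: int = 0
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    @property
    def selector(self) -> MethodSelector:
        return parse_method_name(self.method)


def _config_digest(cfg: SimulationConfig) -> str:
    h = hashlib.sha1()
    h.update(repr((cfg.method, cfg.spec, cfg.sequence, cfg.diffusion,
                   cfg.tissue, cfg.n_spins, cfg.placement, cfg.kernel_kind,
                   cfg.n_hw, cfg.pad_elements, cfg.seed)).encode())
    return h.hexdigest()[:12]


def _resolve_geometry(cfg: SimulationConfig, sel: MethodSelector):
    """Return (continuous perturbers or None, GriddedVoxel or None)."""
    from .geometry import discretize_voxel

    if sel.perturber == "VAN":
        if cfg.gridded is None:
            raise ValueError("VAN methods need a GriddedVoxel mask")
        return None, cfg.gridded
    if sel.space == "CTN":
        if cfg.perturbers is None:
            raise ValueError("continuous methods need a perturber list")
        return cfg.perturbers, None
    gv = cfg.gridded
    if gv is None:
        if cfg.perturbers is None:
            raise ValueError("gridded methods need perturbers or a GriddedVoxel")
        if not cfg.spec.is_gridded:
            raise ValueError("gridded methods need a gridded VoxelSpec (set n)")
        gv = discretize_voxel(cfg.perturbers, cfg.spec)
    return cfg.perturbers, gv


def _field_source(cfg: SimulationConfig, sel: MethodSelector, perturbers, gv):
    if sel.field == "ANA":
        if sel.space == "CTN":
            return montecarlo.AnalyticFieldSource(perturbers, cfg.spec.b0,
                                                  cfg.spec.b0_dir)
        if perturbers is None:
            raise ValueError(
                "analytic (ANA) field computation needs the perturber list; "
                "a mask-only voxel requires the FFT field method")
        return fieldmap.analytic_field_grid(perturbers, gv.spec)
    return fieldmap.field_for_gridded_voxel(gv, pad_elements=cfg.pad_elements)


def run_simulation(cfg: SimulationConfig) -> SignalTimecourse:
    """Run the full time-stepped simulation selected by ``cfg.method``.

    Deterministic given ``cfg.seed``; the seed, method name and a config
    digest are recorded in the output metadata.
    """
    sel = cfg.selector
    if sel.ndim != cfg.spec.ndim:
        raise ValueError(
            f"method {sel} is {sel.ndim}D but the voxel spec is {cfg.spec.ndim}D")
    perturbers, gv = _resolve_geometry(cfg, sel)
    source = _field_source(cfg, sel, perturbers, gv)
    if sel.diffusion == "MC":
        tc = _run_mc(cfg, sel, perturbers, gv, source)
    else:
        tc = _run_dd(cfg, sel, gv, source)
    tc.metadata.update(method=str(sel), seed=cfg.seed,
                       config_digest=_config_digest(cfg),
                       dt=cfg.sequence.dt, te=cfg.sequence.te,
                       sequence=cfg.sequence.name)
    return tc


def _run_mc(cfg, sel, perturbers, gv, source) -> SignalTimecourse:
    seq = cfg.sequence
    rng = np.random.default_rng(cfg.seed)
    geometry = gv if sel.space == "GRD" else perturbers
    n = cfg.n_spins
    if cfg.placement == "grid":
        n = int(np.prod(gv.spec.shape))
    ens = montecarlo.init_spins(n, cfg.spec, geometry, rng, cfg.placement)
    n_labels = (gv.n_labels if gv is not None
                else (len(perturbers) if perturbers else 0))
    tissue = cfg.tissue or TissueProperties()
    r2_tab = tissue.r2_table(n_labels)
    r1_tab = tissue.r1_table(n_labels)
    use_r2, use_r1 = np.any(r2_tab), np.any(r1_tab)
    gamma = cfg.constants.gamma

    n_rec = seq.n_steps + 1
    total = np.zeros(n_rec, dtype=complex)
    iv = np.zeros(n_rec, dtype=complex)
    ev = np.zeros(n_rec, dtype=complex)

    # Trapezoidal phase accrual: each step dephases with the mean of the
    # field at the step's start and end positions (second-order accurate in
    # dt; the start value is the cached previous endpoint, so the cost per
    # step is a single field evaluation).
    dbz_prev = montecarlo.sample_field(ens, source)
    for s in range(seq.n_steps):
        for p in seq.pulses_at(s):
            ens.mxy, ens.mz = apply_rf_complex(ens.mxy, ens.mz, p)
        if s == 0:
            total[0], iv[0], ev[0] = sum_signal(ens.mxy, ens.compartment)
        montecarlo.mc_step(ens, cfg.diffusion, geometry, rng)
        dbz = montecarlo.sample_field(ens, source)
        phase = gamma * seq.dt * 0.5 * (dbz_prev + dbz)
        dbz_prev = dbz
        ens.phase += phase
        factor = np.exp(1j * phase)
        if use_r2:
            factor = factor * np.exp(-seq.dt * r2_tab[ens.compartment])
        ens.mxy = ens.mxy * factor
        if use_r1:
            ens.mz = 1.0 + (ens.mz - 1.0) * np.exp(-seq.dt * r1_tab[ens.compartment])
        total[s + 1], iv[s + 1], ev[s + 1] = sum_signal(ens.mxy, ens.compartment)

    time = np.arange(n_rec) * seq.dt
    meta = {"n_spins": ens.n_spins,
            "crossings_attempted": ens.n_crossings_attempted,
            "crossings_blocked": ens.n_crossings_blocked,
            "retry_exhausted": ens.n_retry_exhausted}
    return SignalTimecourse(time, total, iv, ev, meta)


def _run_dd(cfg, sel, gv: GriddedVoxel, source) -> SignalTimecourse:
    seq = cfg.sequence
    perm = gv.perm_table()[1:]
    if perm.size and (np.any((perm > 0.0) & (perm < 1.0))
                      or (np.any(perm == 0.0) and np.any(perm == 1.0))):
        raise ValueError(
            "deterministic diffusion supports only uniformly fully permeable "
            "(1) or fully impermeable (0) perturbers; intermediate or mixed "
            "permeation probabilities require the Monte Carlo backend")
    impermeable = bool(perm.size) and bool(np.all(perm == 0.0))

    sigma = cfg.diffusion.step_sigma
    make = detdiff.gaussian_kernel if cfg.kernel_kind == "gaussian" \
        else detdiff.bessel_kernel
    kernel = make(sigma, gv.dx, cfg.n_hw)

    tissue = cfg.tissue or TissueProperties()
    r2_tab = tissue.r2_table(gv.n_labels)
    r1_tab = tissue.r1_table(gv.n_labels)
    r2 = r2_tab[gv.label]
    r1 = r1_tab[gv.label]
    if gv.t2_map is not None:
        with np.errstate(divide="ignore"):
            r2 = np.where(gv.t2_map > 0, 1.0 / np.where(gv.t2_map > 0, gv.t2_map, 1.0), r2)
    if gv.t1_map is not None:
        r1 = np.where(gv.t1_map > 0, 1.0 / np.where(gv.t1_map > 0, gv.t1_map, 1.0), r1)
    use_r1 = np.any(r1)
    gamma = cfg.constants.gamma
    step_factor = np.exp(1j * gamma * seq.dt * source.values - seq.dt * r2)

    m = detdiff.MagnetizationGrid(np.zeros(gv.spec.shape, dtype=complex),
                                  np.ones(gv.spec.shape), gv.spec)
    n_rec = seq.n_steps + 1
    total = np.zeros(n_rec, dtype=complex)
    ivs = np.zeros(n_rec, dtype=complex)
    evs = np.zeros(n_rec, dtype=complex)

    for s in range(seq.n_steps):
        for p in seq.pulses_at(s):
            m.mxy, m.mz = apply_rf_complex(m.mxy, m.mz, p)
        if s == 0:
            total[0], ivs[0], evs[0] = sum_signal(m.mxy, gv.label)
        # Eq-of-motion ordering: relax/precess, then diffuse.
        m.mxy = m.mxy * step_factor
        if use_r1:
            m.mz = 1.0 + (m.mz - 1.0) * np.exp(-seq.dt * r1)
        if cfg.diffusion.d > 0:
            detdiff.dd_step(m, kernel, gv, impermeable=impermeable)
        total[s + 1], ivs[s + 1], evs[s + 1] = sum_signal(m.mxy, gv.label)

    time = np.arange(n_rec) * seq.dt
    meta = {"n_sites": int(np.prod(gv.spec.shape)),
            "kernel_kind": kernel.kind, "kernel_n_hw": kernel.n_hw,
            "impermeable": impermeable}
    return SignalTimecourse(time, total, ivs, evs, meta)
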