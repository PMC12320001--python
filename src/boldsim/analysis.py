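"""Relaxation-rate summaries and Boxerman-style radius sweeps.

The susceptibility-attributable relaxation-rate increase at a single echo
time is

    dR2 = -(1/TE) * ln(|S_perturbed(TE)| / |S_reference(TE)|),

where the reference is the identical simulation with every susceptibility
difference set to zero (same seed, same geometry, same diffusion), so the
ratio isolates the field-perturbation effect from T2 decay and sampling
noise common to both runs.  Applied to a gradient-echo signal this yields
dR2* and to a spin-echo signal dR2; their difference dR2' = dR2* - dR2 is
the refocusable component.

A radius sweep repeats this over perturber radii at fixed blood volume
fraction.  The classic result: the spin-echo curve peaks at capillary-scale
radii (diffusion averaging is strongest when spins traverse the field
structure during TE) while the gradient-echo curve rises to a static-
dephasing plateau at large radii.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .montecarlo import DiffusionConfig
from .naming import parse_method_name
from .sequence import (SignalTimecourse, SimulationConfig, TissueProperties,
                       build_sequence, run_simulation)

__all__ = [
    "RateSummary",
    "compute_dr2",
    "rates_for_config",
    "radius_sweep",
    "aggregate_sweep",
]


@dataclass(frozen=True)
class RateSummary:
    """Relaxation-rate increases for one voxel realization (s^-1)."""

    radius: float
    cbv: float
    te: float
    dr2_ge: float
    dr2_se: float
    dr2_prime: float
    dr2_ge_iv: float = np.nan
    dr2_se_iv: float = np.nan
    dr2_ge_ev: float = np.nan
    dr2_se_ev: float = np.nan


def compute_dr2(s_perturbed: complex, s_reference: complex, te: float) -> float:
    """Single-TE susceptibility-attributable rate increase (s^-1)."""
    sp, sr = abs(s_perturbed), abs(s_reference)
    if sr <= 0 or sp <= 0:
        raise ValueError(
            f"signal magnitudes must be positive (got {sp:g} and {sr:g}); "
            "the log-ratio rate is undefined")
    if not te > 0:
        raise ValueError("te must be positive")
    return -np.log(sp / sr) / te


def _zero_dchi(perturbers):
    out = []
    for p in perturbers:
        q = dataclasses.replace(p)
        q.dchi = 0.0
        out.append(q)
    return out


def _reference_config(cfg: SimulationConfig) -> SimulationConfig:
    """The dchi=0 twin of a run: same seed, geometry and diffusion."""
    ref = dataclasses.replace(cfg)
    if cfg.perturbers is not None:
        ref.perturbers = _zero_dchi(cfg.perturbers)
    if cfg.gridded is not None:
        gv = cfg.gridded
        ref.gridded = geometry.GriddedVoxel(
            spec=gv.spec, label=gv.label, dchi_map=np.zeros_like(gv.dchi_map),
            t2_map=gv.t2_map, t1_map=gv.t1_map, perm_by_label=gv.perm_by_label)
    return ref


def rates_for_config(cfg: SimulationConfig, *, radius: float = np.nan,
                     cbv: float = np.nan,
                     return_timecourses: bool = False):
    """GE and SE rates for one configured voxel.

    Runs GE and SE acquisitions with the configured susceptibilities and
    their zero-susceptibility references (same seed), and reduces the four
    time courses to a :class:`RateSummary` at the sequence TE.
    """
    te, dt = cfg.sequence.te, cfg.sequence.dt
    if (cfg.gridded is None and cfg.perturbers is not None
            and cfg.selector.space == "GRD"):
        # discretize once; the GE/SE runs and their references share it
        cfg = dataclasses.replace(
            cfg, gridded=geometry.discretize_voxel(cfg.perturbers, cfg.spec))
    out = {}
    for kind in ("GE", "SE"):
        run = dataclasses.replace(cfg, sequence=build_sequence(kind, te, dt))
        ref = _reference_config(run)
        out[kind] = (run_simulation(run), run_simulation(ref))

    def rate(kind, attr):
        tc, rc = out[kind]
        return compute_dr2(getattr(tc, attr)[-1], getattr(rc, attr)[-1], te)

    def rate_safe(kind, attr):
        tc, rc = out[kind]
        if abs(getattr(rc, attr)[-1]) == 0:
            return np.nan
        return rate(kind, attr)

    summary = RateSummary(
        radius=radius, cbv=cbv, te=te,
        dr2_ge=rate("GE", "total"), dr2_se=rate("SE", "total"),
        dr2_prime=rate("GE", "total") - rate("SE", "total"),
        dr2_ge_iv=rate_safe("GE", "iv"), dr2_se_iv=rate_safe("SE", "iv"),
        dr2_ge_ev=rate_safe("GE", "ev"), dr2_se_ev=rate_safe("SE", "ev"),
    )
    if return_timecourses:
        return summary, out
    return summary


def _sweep_voxel(perturber: str, radius: float, cbv: float, dchi: float,
                 perm: float, n_perturbers_target: int, seed: int, b0: float,
                 b0_dir):
    """A fresh random voxel for one sweep cell, sized so the expected
    perturber count stays near ``n_perturbers_target`` at every radius."""
    if perturber == "cylinder2d":
        w = radius * np.sqrt(n_perturbers_target * np.pi / cbv)
        spec = geometry.VoxelSpec(2, w, b0=b0, b0_dir=b0_dir)
        perts = geometry.make_random_cylinders_2d(spec, radius, cbv, dchi,
                                                  perm, rng_seed=seed)
        method = "2D-CTN-CYL-ANA-MC"
    elif perturber == "cylinder3d":
        w = radius * np.sqrt(n_perturbers_target * np.pi / cbv)
        spec = geometry.VoxelSpec(3, w, b0=b0, b0_dir=b0_dir)
        perts = geometry.make_random_cylinders_3d(spec, radius, cbv, dchi,
                                                  perm, rng_seed=seed)
        method = "3D-CTN-CYL-ANA-MC"
    elif perturber == "sphere3d":
        w = radius * (n_perturbers_target * 4.0 * np.pi / (3.0 * cbv)) ** (1.0 / 3.0)
        spec = geometry.VoxelSpec(3, w, b0=b0, b0_dir=b0_dir)
        perts = geometry.make_random_spheres_3d(spec, radius, cbv, dchi,
                                                perm, rng_seed=seed)
        method = "3D-CTN-SPH-ANA-MC"
    else:
        raise ValueError(f"unknown perturber class {perturber!r}")
    return spec, perts, method


def radius_sweep(radii, *, cbv: float = 0.02, dchi: float | None = None,
                 d: float = 1e-3, dt: float = 2e-4, te: float = 0.07,
                 b0: float = 3.0, b0_dir=(0.0, 0.0, 1.0),
                 perturber: str = "cylinder2d", perm: float = 0.0,
                 n_spins: int = 4000, n_repeats: int = 3, seed: int = 0,
                 n_perturbers_target: int = 50,
                 tissue: TissueProperties | None = None) -> pd.DataFrame:
    """Monte Carlo GE/SE rate sweep over perturber radii at fixed CBV.

    Each (radius, repeat) cell draws a fresh random voxel whose width keeps
    the expected perturber count constant, so every radius is simulated
    under comparable statistics.  Returns one row per cell.
    """
    if dchi is None:
        dchi = geometry.ppm_cgs_to_si(0.3)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, radius in enumerate(radii):
        for rep in range(n_repeats):
            child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            spec, perts, method = _sweep_voxel(
                perturber, radius, cbv, dchi, perm, n_perturbers_target,
                child, b0, b0_dir)
            cbv_est = geometry.compute_cbv(perts, spec, rng_seed=child + 1)
            cfg = SimulationConfig(
                method=method, spec=spec,
                sequence=build_sequence("SE", te, dt),
                diffusion=DiffusionConfig(d, dt), perturbers=perts,
                tissue=tissue, n_spins=n_spins, seed=child)
            s = rates_for_config(cfg, radius=radius, cbv=cbv_est.value)
            row = dataclasses.asdict(s)
            row.update(repeat=rep, n_perturbers=len(perts),
                       voxel_width=spec.width, seed=child)
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of the rates per radius."""
    cols = [c for c in df.columns if c.startswith("dr2")]
    g = df.groupby("radius")[cols]
    agg = g.agg(["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
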