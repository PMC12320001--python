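"""Self-contained synthetic voxels for tests, demos and validation.

Every fixture is fully determined by its name, a seed and an override map:

* ``gm_cylinders_2d`` -- a cortical grey-matter-like 2D voxel: randomly
  oriented 1 µm blood vessels at 2% blood volume, deoxygenated-blood
  susceptibility 0.3 ppm (cgs), ADC 0.001 mm²/s, spin-echo TE 70 ms.
* ``wm_axons_2d`` -- a white-matter-bundle voxel: densely packed parallel
  axons (jittered hexagonal lattice, diameters 0.4-3.5 µm, myelin
  susceptibility -0.15 ppm cgs, B0 perpendicular to the fibers) threaded by
  1% CBV randomly oriented vessels.
* ``single_cylinder_3d`` / ``single_sphere_3d`` -- one centered analytic
  perturber, the oracle geometry for field-computation checks.
* ``toy_mask_3d`` -- a small labelled 3D grid exercising the custom-mask
  (VAN) pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import (Cylinder2D, Cylinder3D, GriddedVoxel, Sphere3D,
                       VoxelSpec, ppm_cgs_to_si)
from .montecarlo import DiffusionConfig
from .sequence import SimulationConfig, build_sequence

__all__ = ["FixtureSpec", "FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("gm_cylinders_2d", "wm_axons_2d", "single_sphere_3d",
                 "single_cylinder_3d", "toy_mask_3d")


@dataclass(frozen=True)
class FixtureSpec:
    """A named, seeded, overridable fixture request."""

    name: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in FIXTURE_NAMES:
            raise ValueError(
                f"unknown fixture {self.name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(name, seed: int = 0, **overrides) -> SimulationConfig:
    """Build a ready-to-run :class:`SimulationConfig` for a named fixture.

    ``name`` may also be a :class:`FixtureSpec`.  Overrides replace the
    documented defaults (e.g. ``width=...``, ``n=...``, ``method=...``,
    ``n_spins=...``); the returned config carries the generated geometry.
    """
    if isinstance(name, FixtureSpec):
        fs = name
    else:
        fs = FixtureSpec(str(name), seed, dict(overrides))
    builder = {
        "gm_cylinders_2d": _gm_cylinders_2d,
        "wm_axons_2d": _wm_axons_2d,
        "single_sphere_3d": _single_sphere_3d,
        "single_cylinder_3d": _single_cylinder_3d,
        "toy_mask_3d": _toy_mask_3d,
    }[fs.name]
    return builder(fs.seed, dict(fs.overrides))


def _pop(ov, key, default):
    return ov.pop(key, default)


def _finish(ov, **kwargs) -> SimulationConfig:
    cfg = SimulationConfig(**kwargs)
    for k, v in ov.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown override {k!r}")
        setattr(cfg, k, v)
    return cfg


def _gm_cylinders_2d(seed: int, ov: dict) -> SimulationConfig:
    width = _pop(ov, "width", 0.1)
    radius = _pop(ov, "radius", 1e-3)
    cbv = _pop(ov, "cbv", 0.02)
    dchi = _pop(ov, "dchi", ppm_cgs_to_si(0.3))
    perm = _pop(ov, "perm", 0.0)
    d = _pop(ov, "d", 1e-3)
    # default step: sqrt(2*D*dt) ~ R/2, resolving the smallest vessel
    dt = _pop(ov, "dt", 1e-4)
    te = _pop(ov, "te", 0.07)
    b0 = _pop(ov, "b0", 3.0)
    kind = _pop(ov, "sequence_kind", "SE")
    method = str(_pop(ov, "method", "2D-CTN-CYL-ANA-MC")).upper()
    n = _pop(ov, "n", None)
    gridded = "GRD" in method
    if gridded and n is None:
        # honour the >= 6 elements-per-diameter sampling rule with margin
        n = int(np.ceil(width / (radius / 4.0)))
    # small voxels hold few vessels, so the reachable CBV granularity is
    # coarse; the tolerance can be relaxed accordingly
    tol = _pop(ov, "cbv_tol", 0.1)
    spec = VoxelSpec(2, width, "gridded" if gridded else "continuous",
                     n=n, b0=b0)
    perts = geometry.make_random_cylinders_2d(spec, radius, cbv, dchi, perm,
                                              rng_seed=seed, tol=tol)
    return _finish(ov, method=method, spec=spec,
                   sequence=build_sequence(kind, te, dt),
                   diffusion=DiffusionConfig(d, dt), perturbers=perts,
                   seed=seed)


def _hex_axon_packing(width, diam_lo, diam_hi, target_fraction, rng,
                      jitter_frac, theta, phi0, dchi, avoid=()):
    """Jittered hexagonal circle packing with hard (non-overlapping) axons.

    Lattice pitch is set so the expected circle area per hexagonal cell
    matches the target packing fraction; each site gets a uniform random
    diameter and a Gaussian positional jitter, and circles overlapping an
    already-accepted circle (or the ``avoid`` list) are dropped.
    """
    r_lo, r_hi = diam_lo / 2.0, diam_hi / 2.0
    mean_r2 = (r_lo**2 + r_lo * r_hi + r_hi**2) / 3.0  # E[r^2], r ~ U(r_lo, r_hi)
    pitch = np.sqrt(np.pi * mean_r2 / (target_fraction * np.sqrt(3.0) / 2.0))
    rows = int(np.ceil(width / (pitch * np.sqrt(3.0) / 2.0))) + 2
    cols = int(np.ceil(width / pitch)) + 2
    axons = []
    for j in range(rows):
        y = (j - 1) * pitch * np.sqrt(3.0) / 2.0
        for i in range(cols):
            x = (i - 1) * pitch + (pitch / 2.0 if j % 2 else 0.0)
            # large-diameter draws cannot always fit between neighbours;
            # retry with fresh diameter and shrinking jitter before giving
            # up on the site, to stay near the target packing fraction
            jf = jitter_frac
            for _ in range(20):
                r = rng.uniform(r_lo, r_hi)
                c = np.array([x, y]) + rng.normal(0.0, jf * pitch, 2)
                cand = Cylinder2D(r, c, theta, phi0, dchi, perm=0.0)
                if not geometry._overlaps(cand, axons) and \
                        not geometry._overlaps(cand, avoid):
                    axons.append(cand)
                    break
                jf *= 0.7
    return axons


def _wm_axons_2d(seed: int, ov: dict) -> SimulationConfig:
    width = _pop(ov, "width", 0.02)
    axon_fraction = _pop(ov, "axon_fraction", 0.5)
    diam_lo = _pop(ov, "diam_lo", 0.4e-3)
    diam_hi = _pop(ov, "diam_hi", 3.5e-3)
    dchi_axon = _pop(ov, "dchi_axon", ppm_cgs_to_si(-0.15))
    vessel_cbv = _pop(ov, "vessel_cbv", 0.01)
    vessel_radius = _pop(ov, "vessel_radius", 1e-3)
    dchi_vessel = _pop(ov, "dchi_vessel", ppm_cgs_to_si(0.3))
    d = _pop(ov, "d", 1e-3)
    dt = _pop(ov, "dt", 2e-4)
    te = _pop(ov, "te", 0.07)
    b0 = _pop(ov, "b0", 3.0)
    jitter = _pop(ov, "jitter_frac", 0.12)
    kind = _pop(ov, "sequence_kind", "SE")
    spec = VoxelSpec(2, width, b0=b0)
    rng = np.random.default_rng(seed)
    # a single 1 um vessel is already ~0.8% of this small voxel, so the
    # reachable CBV granularity is coarse
    vessels = geometry.make_random_cylinders_2d(
        spec, vessel_radius, vessel_cbv, dchi_vessel, perm=0.0,
        rng_seed=int(rng.integers(2**31)), tol=0.8)
    # B0 perpendicular to the fiber axis, pointing "up" in the plane.
    axons = _hex_axon_packing(width, diam_lo, diam_hi, axon_fraction, rng,
                              jitter, np.pi / 2.0, np.pi / 2.0, dchi_axon,
                              avoid=vessels)
    return _finish(ov, method="2D-CTN-CYL-ANA-MC", spec=spec,
                   sequence=build_sequence(kind, te, dt),
                   diffusion=DiffusionConfig(d, dt),
                   perturbers=vessels + axons, seed=seed)


def _single_sphere_3d(seed: int, ov: dict) -> SimulationConfig:
    width = _pop(ov, "width", 0.1)
    radius = _pop(ov, "radius", width / 8.0)
    dchi = _pop(ov, "dchi", 1e-6)
    n = _pop(ov, "n", 64)
    b0 = _pop(ov, "b0", 3.0)
    d = _pop(ov, "d", 1e-3)
    dt = _pop(ov, "dt", 2e-4)
    te = _pop(ov, "te", 0.02)
    spec = VoxelSpec(3, width, "gridded", n=n, b0=b0)
    sphere = Sphere3D(radius, np.full(3, width / 2.0), dchi, perm=0.0)
    return _finish(ov, method="3D-GRD-SPH-FFT-MC", spec=spec,
                   sequence=build_sequence("GE", te, dt),
                   diffusion=DiffusionConfig(d, dt), perturbers=[sphere],
                   seed=seed)


def _single_cylinder_3d(seed: int, ov: dict) -> SimulationConfig:
    width = _pop(ov, "width", 0.1)
    radius = _pop(ov, "radius", width / 8.0)
    dchi = _pop(ov, "dchi", 1e-6)
    n = _pop(ov, "n", 64)
    b0 = _pop(ov, "b0", 3.0)
    d = _pop(ov, "d", 1e-3)
    dt = _pop(ov, "dt", 2e-4)
    te = _pop(ov, "te", 0.02)
    axis_dir = np.asarray(_pop(ov, "axis_dir", (0.0, 1.0, 0.0)), dtype=float)
    spec = VoxelSpec(3, width, "gridded", n=n, b0=b0)
    cyl = Cylinder3D(radius, np.full(3, width / 2.0), axis_dir, dchi, perm=0.0)
    return _finish(ov, method="3D-GRD-CYL-ANA-MC", spec=spec,
                   sequence=build_sequence("GE", te, dt),
                   diffusion=DiffusionConfig(d, dt), perturbers=[cyl],
                   seed=seed)


def _toy_mask_3d(seed: int, ov: dict) -> SimulationConfig:
    """A hand-sized custom mask: one sphere and one cylinder, labelled 1 and
    2, built by discretizing analytic shapes so the mask path can be checked
    against the analytic one (synthetic stand-in for a measured network)."""
    width = _pop(ov, "width", 0.05)
    n = _pop(ov, "n", 32)
    b0 = _pop(ov, "b0", 3.0)
    d = _pop(ov, "d", 1e-3)
    dt = _pop(ov, "dt", 2e-4)
    te = _pop(ov, "te", 0.02)
    dchi = _pop(ov, "dchi", ppm_cgs_to_si(0.3))
    spec = VoxelSpec(3, width, "gridded", n=n, b0=b0)
    sphere = Sphere3D(width / 6.0, np.array([0.3, 0.3, 0.35]) * width, dchi)
    cyl = Cylinder3D(width / 8.0, np.array([0.7, 0.65, 0.5]) * width,
                     np.array([0.2, 0.3, 1.0]), dchi)
    gv = geometry.discretize_voxel([sphere, cyl], spec, warn=False)
    return _finish(ov, method="3D-GRD-VAN-FFT-MC", spec=spec,
                   sequence=build_sequence("GE", te, dt),
                   diffusion=DiffusionConfig(d, dt), gridded=gv, seed=seed)
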