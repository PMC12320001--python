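"""Monte Carlo random-walk diffusion with periodic voxel boundaries and
probabilistic perturber-wall permeation.

Spin positions are always continuous, even when the geometry is gridded, so
sub-element diffusion steps accumulate correctly.  Each step draws per-axis
displacements from N(0, 2*D*dt); positions wrap modulo the voxel width.  A
step whose endpoint lies in a different compartment than its start counts
as a wall crossing: it succeeds with the wall's permeation probability
(one Bernoulli draw per attempted crossing), otherwise new steps are drawn
until one stays in the starting compartment (bounded retries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fieldmap import FieldGrid, analytic_field
from .geometry import GriddedVoxel, VoxelSpec, label_points, perm_table

__all__ = [
    "DiffusionConfig",
    "SpinEnsemble",
    "AnalyticFieldSource",
    "init_spins",
    "mc_step",
    "sample_field",
]


@dataclass(frozen=True)
class DiffusionConfig:
    """Diffusion coefficient D (mm^2/s) and time step dt (s)."""

    d: float
    dt: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("D must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def step_sigma(self) -> float:
        """Per-axis displacement standard deviation sqrt(2*D*dt) in mm."""
        return float(np.sqrt(2.0 * self.d * self.dt))


@dataclass
class SpinEnsemble:
    """Positions, accumulated phase, compartment labels and magnetization of
    the diffusing spins.

    ``displacement`` accumulates the raw (unwrapped) accepted steps, which
    makes mean-squared-displacement checks independent of the periodic wrap.
    Crossing statistics are kept for run diagnostics.
    """

    spec: VoxelSpec
    positions: np.ndarray
    compartment: np.ndarray
    phase: np.ndarray
    mxy: np.ndarray
    mz: np.ndarray
    displacement: np.ndarray
    n_crossings_attempted: int = 0
    n_crossings_blocked: int = 0
    n_retry_exhausted: int = 0

    @property
    def n_spins(self) -> int:
        return self.positions.shape[0]


class AnalyticFieldSource:
    """Continuous field source: exact analytic superposition at any point."""

    def __init__(self, perturbers, b0: float, b0_dir=(0.0, 0.0, 1.0)):
        self.perturbers = list(perturbers)
        self.b0 = b0
        self.b0_dir = b0_dir
        self._zero = all(p.dchi == 0.0 for p in self.perturbers)

    def at(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        if self._zero:
            return np.zeros(points.shape[0])
        return analytic_field(points, self.perturbers, self.b0, self.b0_dir)


def _labels(geometry, points: np.ndarray) -> np.ndarray:
    if geometry is None:
        return np.zeros(np.atleast_2d(points).shape[0], dtype=np.int32)
    if isinstance(geometry, GriddedVoxel):
        return geometry.label_at(points)
    return label_points(points, geometry)


def _perm_table(geometry) -> np.ndarray:
    if geometry is None:
        return np.ones(1)
    if isinstance(geometry, GriddedVoxel):
        return geometry.perm_table()
    return perm_table(geometry)


def init_spins(n: int, spec: VoxelSpec, geometry=None, rng=None,
               placement: str = "uniform", *, max_tries: int = 1000) -> SpinEnsemble:
    """Place ``n`` spins in the voxel with zero phase and magnetization
    (0, 0, 1).

    ``placement`` selects uniform positions over the whole voxel, the
    extravascular space only (``ev_only``), the perturber interiors only
    (``iv_only``; fails on an empty-perturber voxel), or the grid-element
    centers of a gridded geometry (``grid``, for cross-checks against the
    deterministic backend).
    """
    if n < 1:
        raise ValueError("need at least one spin")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if placement == "grid":
        if not isinstance(geometry, GriddedVoxel):
            raise ValueError("placement='grid' requires a GriddedVoxel")
        c1 = geometry.spec.element_centers_1d()
        grids = np.meshgrid(*([c1] * geometry.spec.ndim), indexing="ij")
        positions = np.column_stack([g.ravel() for g in grids])
        if n != positions.shape[0]:
            raise ValueError(
                f"placement='grid' places one spin per element "
                f"({positions.shape[0]}), but n={n} was requested")
    elif placement == "uniform":
        positions = rng.random((n, spec.ndim)) * spec.width
    elif placement in ("ev_only", "iv_only"):
        want_iv = placement == "iv_only"
        chunks, have = [], 0
        for _ in range(max_tries):
            cand = rng.random((n, spec.ndim)) * spec.width
            lab = _labels(geometry, cand)
            keep = (lab > 0) if want_iv else (lab == 0)
            chunks.append(cand[keep])
            have += int(keep.sum())
            if have >= n:
                break
        else:
            raise RuntimeError(
                f"could not place {n} spins with placement={placement!r}; "
                "the requested region appears to be (nearly) empty")
        positions = np.concatenate(chunks)[:n]
    else:
        raise ValueError(f"unknown placement {placement!r}")
    compartment = _labels(geometry, positions)
    return SpinEnsemble(
        spec=spec,
        positions=positions,
        compartment=compartment,
        phase=np.zeros(positions.shape[0]),
        mxy=np.zeros(positions.shape[0], dtype=complex),
        mz=np.ones(positions.shape[0]),
        displacement=np.zeros_like(positions),
    )


def _transition_perm(from_lab: np.ndarray, to_lab: np.ndarray,
                     table: np.ndarray) -> np.ndarray:
    """Permeation probability of a compartment change: the wall of the
    compartment being left and of the one being entered each gate the step
    (extra-perturber space, label 0, has no wall)."""
    p = np.ones(from_lab.shape[0])
    leaving = from_lab > 0
    p[leaving] *= table[from_lab[leaving]]
    entering = to_lab > 0
    p[entering] *= table[to_lab[entering]]
    return p


def mc_step(ens: SpinEnsemble, cfg: DiffusionConfig, geometry, rng,
            retry_cap: int = 100) -> SpinEnsemble:
    """Advance every spin by one diffusion step (in place).

    Blocked crossings resample the step until it no longer crosses; after
    ``retry_cap`` failures the spin stays put for this step (counted in
    ``n_retry_exhausted``).
    """
    if cfg.d == 0.0:
        return ens
    w = ens.spec.width
    sigma = cfg.step_sigma
    n = ens.n_spins
    step = rng.normal(0.0, sigma, size=(n, ens.spec.ndim))
    cand = np.mod(ens.positions + step, w)
    new_lab = _labels(geometry, cand)
    crossed = new_lab != ens.compartment
    blocked = np.zeros(n, dtype=bool)
    if np.any(crossed):
        table = _perm_table(geometry)
        idx = np.nonzero(crossed)[0]
        p = _transition_perm(ens.compartment[idx], new_lab[idx], table)
        ok = rng.random(idx.size) < p
        blocked[idx[~ok]] = True
        ens.n_crossings_attempted += int(idx.size)
        ens.n_crossings_blocked += int((~ok).sum())
    accept = ~blocked
    ens.positions[accept] = cand[accept]
    ens.compartment[accept] = new_lab[accept]
    ens.displacement[accept] += step[accept]

    active = np.nonzero(blocked)[0]
    for _ in range(retry_cap):
        if active.size == 0:
            break
        s2 = rng.normal(0.0, sigma, size=(active.size, ens.spec.ndim))
        cand = np.mod(ens.positions[active] + s2, w)
        lab = _labels(geometry, cand)
        good = lab == ens.compartment[active]
        gi = active[good]
        ens.positions[gi] = cand[good]
        ens.displacement[gi] += s2[good]
        active = active[~good]
    ens.n_retry_exhausted += int(active.size)
    return ens


def sample_field(ens_or_points, source) -> np.ndarray:
    """Per-spin ΔBz from a field source.

    Continuous sources (:class:`AnalyticFieldSource`) evaluate the closed
    forms at the exact positions; gridded sources (:class:`FieldGrid`)
    return the value of the element containing each position.
    """
    points = ens_or_points.positions if isinstance(ens_or_points, SpinEnsemble) \
        else np.atleast_2d(ens_or_points)
    if isinstance(source, (FieldGrid, AnalyticFieldSource)):
        return source.at(points)
    raise TypeError(
        "field source must be a FieldGrid or an AnalyticFieldSource")
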