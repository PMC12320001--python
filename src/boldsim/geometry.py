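"""Voxel geometry: the simulation domain and the susceptibility perturbers.

Units throughout the package: lengths in millimetres, times in seconds,
magnetic fields in tesla, angles in radians.  Susceptibility differences
(``dchi``) are dimensionless SI volume susceptibilities; literature values
quoted in ppm (cgs) convert via ``chi_SI = 4*pi*chi_cgs`` (see
:func:`ppm_cgs_to_si`).

A voxel is the simulation domain: a square (2D) or cube (3D) of side
``width`` spanning ``[0, width)`` on each axis, with periodic boundary
conditions for diffusing spins.  Perturbers are the magnetized objects
inside it -- blood vessels modelled as infinite cylinders, microspheres, or
arbitrary labelled masks -- each carrying a susceptibility difference and a
wall permeation probability.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels

__all__ = [
    "GAMMA_PROTON",
    "PhysicalConstants",
    "ppm_cgs_to_si",
    "VoxelSpec",
    "Cylinder3D",
    "Cylinder2D",
    "Sphere3D",
    "GriddedVoxel",
    "CBVEstimate",
    "compute_cbv",
    "label_points",
    "perm_table",
    "make_random_cylinders_3d",
    "make_random_cylinders_2d",
    "make_random_spheres_3d",
    "discretize_voxel",
    "check_sampling",
    "load_perturber_mask",
    "save_gridded_voxel",
    "random_unit_vectors",
    "sample_polar_angles",
]

#: Proton gyromagnetic ratio in rad/s/T.
GAMMA_PROTON = 2.6752218744e8


def ppm_cgs_to_si(chi_ppm_cgs: float) -> float:
    """Convert a volume susceptibility from ppm (cgs) to dimensionless SI.

    Deoxygenated blood is commonly quoted as 0.3 ppm (cgs) relative to
    tissue, which is ``4*pi*0.3e-6 ~ 3.77e-6`` in SI units.
    """
    return 4.0 * np.pi * chi_ppm_cgs * 1e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants entering the Larmor phase accrual."""

    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be a nonzero vector")
    return v / n


@dataclass(frozen=True)
class VoxelSpec:
    """The simulation domain.

    Parameters
    ----------
    ndim:
        2 (planar voxel, cylinders perpendicular to the plane) or 3.
    width:
        Voxel side length W in mm; the domain is ``[0, W)`` per axis.
    representation:
        ``"continuous"`` or ``"gridded"``.  Gridded voxels discretize each
        axis into ``n`` elements with centers at ``(i + 1/2) * W / n``.
    n:
        Grid elements per side (gridded only).
    b0:
        Main field strength in tesla.
    b0_dir:
        Unit direction of B0 (3-vector; used by 3D geometries -- 2D
        cylinders carry their own per-cylinder effective field direction).
    """

    ndim: int
    width: float
    representation: str = "continuous"
    n: int | None = None
    b0: float = 3.0
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if self.representation not in ("continuous", "gridded"):
            raise ValueError("representation must be 'continuous' or 'gridded'")
        if self.representation == "gridded":
            if self.n is None or self.n < 2:
                raise ValueError("gridded voxels need n >= 2 grid elements per side")
        u = _as_unit(self.b0_dir, "b0_dir")
        object.__setattr__(self, "b0_dir", tuple(float(x) for x in u))

    @property
    def is_gridded(self) -> bool:
        return self.representation == "gridded"

    @property
    def dx(self) -> float:
        """Grid spacing W/N (gridded voxels only)."""
        if not self.is_gridded:
            raise ValueError("dx is only defined for gridded voxels")
        return self.width / self.n

    @property
    def b0_direction(self) -> np.ndarray:
        return np.asarray(self.b0_dir, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        if not self.is_gridded:
            raise ValueError("shape is only defined for gridded voxels")
        return (self.n,) * self.ndim

    def element_centers_1d(self) -> np.ndarray:
        """Element-center coordinates along one axis: (i + 1/2) * dx."""
        return (np.arange(self.n) + 0.5) * self.dx


class _Perturber:
    """Mixin with equality on fields (numpy-aware) for reproducibility tests."""

    def __eq__(self, other):  # pragma: no cover - trivial
        if type(self) is not type(other):
            return NotImplemented
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


def _check_perm(perm: float) -> None:
    if not 0.0 <= perm <= 1.0:
        raise ValueError("perm must be in [0, 1]")


@dataclass(eq=False)
class Cylinder3D(_Perturber):
    """Infinite cylinder in 3D: radius, a point on the axis, the unit axis
    direction, susceptibility difference and wall permeation probability.

    The cylinder is unbounded along its axis; containment and field use the
    perpendicular distance to the axis only.
    """

    radius: float
    axis_point: np.ndarray
    axis_dir: np.ndarray
    dchi: float
    perm: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        _check_perm(self.perm)
        self.axis_point = np.asarray(self.axis_point, dtype=float).reshape(3)
        self.axis_dir = _as_unit(np.asarray(self.axis_dir, dtype=float).reshape(3), "axis_dir")

    def perp_vectors(self, points: np.ndarray) -> np.ndarray:
        """Component of (points - axis_point) perpendicular to the axis."""
        d = np.atleast_2d(points) - self.axis_point
        along = d @ self.axis_dir
        return d - along[:, None] * self.axis_dir

    def contains(self, points: np.ndarray) -> np.ndarray:
        dp = self.perp_vectors(points)
        return np.einsum("ij,ij->i", dp, dp) <= self.radius**2


@dataclass(eq=False)
class Cylinder2D(_Perturber):
    """Infinite cylinder perpendicular to a 2D voxel plane.

    To emulate randomly oriented 3D cylinders with in-plane cross-sections,
    each 2D cylinder carries its own effective field orientation: ``theta``
    is the angle between B0 and the cylinder axis, ``phi0`` the in-plane
    azimuth of the B0 projection.
    """

    radius: float
    center: np.ndarray
    theta: float
    phi0: float
    dchi: float
    perm: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.theta <= np.pi:
            raise ValueError("theta must be in [0, pi]")
        _check_perm(self.perm)
        self.center = np.asarray(self.center, dtype=float).reshape(2)

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,ij->i", d, d) <= self.radius**2


@dataclass(eq=False)
class Sphere3D(_Perturber):
    """Spherical perturber (red blood cells, ferritin, phantom microspheres).

    Spheres have no orientation; the dipolar field pattern is set by B0.
    """

    radius: float
    center: np.ndarray
    dchi: float
    perm: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        _check_perm(self.perm)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,ij->i", d, d) <= self.radius**2


# ---------------------------------------------------------------------------
# Point labelling and volume-fraction estimation
# ---------------------------------------------------------------------------


_LABEL_CHUNK = 16_384


def _contains_matrix(pts: np.ndarray, perturbers, cls) -> np.ndarray:
    """(n, k) containment mask for a homogeneous perturber list."""
    if cls is Cylinder3D:
        u = np.array([p.axis_dir for p in perturbers])
        a = np.array([p.axis_point for p in perturbers])
        p_u = pts @ u.T - np.einsum("kj,kj->k", a, u)
        d2 = (np.einsum("ij,ij->i", pts, pts)[:, None]
              - 2.0 * (pts @ a.T) + np.einsum("kj,kj->k", a, a))
        r2 = d2 - p_u**2
    else:
        c = np.array([p.center for p in perturbers])
        r2 = (np.einsum("ij,ij->i", pts, pts)[:, None]
              - 2.0 * (pts @ c.T) + np.einsum("kj,kj->k", c, c))
    return r2 <= np.array([p.radius**2 for p in perturbers])


def label_points(points: np.ndarray, perturbers) -> np.ndarray:
    """Compartment label per point: 0 outside all perturbers, else the
    1-based index of the first perturber containing the point."""
    points = np.atleast_2d(points)
    perturbers = list(perturbers)
    labels = np.zeros(points.shape[0], dtype=np.int32)
    if not perturbers:
        return labels
    classes = {type(p) for p in perturbers}
    if len(classes) == 1:
        cls = classes.pop()
        if _kernels.HAVE_NUMBA:
            pts = np.ascontiguousarray(points, dtype=float)
            r2c = np.array([p.radius**2 for p in perturbers])
            if cls is Cylinder3D:
                a = np.array([p.axis_point for p in perturbers])
                u = np.array([p.axis_dir for p in perturbers])
                _kernels.label_cylinders_3d(pts, a, u, r2c, labels)
            elif cls is Sphere3D:
                c = np.array([p.center for p in perturbers])
                _kernels.label_spheres(pts, c, r2c, labels)
            else:
                cx = np.array([p.center[0] for p in perturbers])
                cy = np.array([p.center[1] for p in perturbers])
                _kernels.label_circles(pts, cx, cy, r2c, labels)
            return labels
        for lo in range(0, points.shape[0], _LABEL_CHUNK):
            pts = points[lo:lo + _LABEL_CHUNK]
            m = _contains_matrix(pts, perturbers, cls)
            any_in = m.any(axis=1)
            labels[lo:lo + _LABEL_CHUNK] = np.where(
                any_in, m.argmax(axis=1) + 1, 0)
        return labels
    for k, p in enumerate(perturbers, start=1):
        m = (labels == 0) & p.contains(points)
        labels[m] = k
    return labels


def perm_table(perturbers) -> np.ndarray:
    """Permeation probability per label (index 0 = extra-perturber, unused)."""
    return np.array([1.0] + [p.perm for p in perturbers], dtype=float)


@dataclass(frozen=True)
class CBVEstimate:
    """Monte Carlo estimate of the perturber union volume/area fraction."""

    value: float
    stderr: float
    n_samples: int

    def __float__(self) -> float:  # pragma: no cover - trivial
        return self.value


def compute_cbv(perturbers, spec: VoxelSpec, n_samples: int = 100_000,
                rng_seed: int = 0) -> CBVEstimate:
    """Monte Carlo estimate of the fraction of the voxel occupied by the
    union of the perturbers, with its binomial standard error.

    Overlapping perturbers count once (union semantics).
    """
    if n_samples < 1e4:
        raise ValueError("n_samples must be at least 1e4 for a stable estimate")
    perturbers = list(perturbers)
    if not perturbers:
        return CBVEstimate(0.0, 0.0, n_samples)
    rng = np.random.default_rng(rng_seed)
    pts = rng.random((n_samples, spec.ndim)) * spec.width
    inside = np.zeros(n_samples, dtype=bool)
    for p in perturbers:
        inside |= p.contains(pts)
    frac = float(inside.mean())
    se = float(np.sqrt(max(frac * (1.0 - frac), 0.0) / n_samples))
    return CBVEstimate(frac, se, n_samples)


# ---------------------------------------------------------------------------
# Random generation at a target CBV
# ---------------------------------------------------------------------------


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniformly distributed unit 3-vectors (isotropic orientations)."""
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # Degenerate zero draws are essentially impossible; guard anyway.
    norms[norms == 0] = 1.0
    return v / norms


def sample_polar_angles(rng: np.random.Generator, n: int) -> np.ndarray:
    """Polar angles theta with cos(theta) uniform on [-1, 1].

    This is the distribution of the angle between a fixed B0 and a
    uniformly random 3D axis, used for the effective field direction of 2D
    cylinders.
    """
    return np.arccos(rng.uniform(-1.0, 1.0, size=n))


def _overlaps(p, others) -> bool:
    """Pairwise center/axis-distance overlap test (hard perturbers)."""
    for q in others:
        if isinstance(p, Cylinder3D):
            cross = np.cross(p.axis_dir, q.axis_dir)
            d12 = q.axis_point - p.axis_point
            nc = np.linalg.norm(cross)
            if nc < 1e-12:  # parallel axes: perpendicular offset
                dist = np.linalg.norm(d12 - (d12 @ p.axis_dir) * p.axis_dir)
            else:
                dist = abs(d12 @ (cross / nc))
            if dist < p.radius + q.radius:
                return True
        else:
            if np.linalg.norm(p.center - q.center) < p.radius + q.radius:
                return True
    return False


def _generate_until_cbv(spec, make_one, target_cbv, rng, *, tol, max_perturbers,
                        n_probe, overlap):
    if target_cbv == 0:
        return []
    if not 0.0 < target_cbv < 1.0:
        raise ValueError("target_cbv must lie in (0, 1)")
    probe = rng.random((n_probe, spec.ndim)) * spec.width
    covered = np.zeros(n_probe, dtype=bool)
    out: list = []
    frac = 0.0
    while frac < target_cbv:
        if len(out) >= max_perturbers:
            raise RuntimeError(
                f"target CBV {target_cbv} not reached within the cap of "
                f"{max_perturbers} perturbers (estimated CBV {frac:.4g})")
        p = make_one(rng)
        if overlap == "forbid":
            tries = 0
            while _overlaps(p, out):
                tries += 1
                if tries > 1000:
                    raise RuntimeError(
                        "could not place a non-overlapping perturber after "
                        "1000 attempts; lower target_cbv or allow overlap")
                p = make_one(rng)
        covered |= p.contains(probe)
        out.append(p)
        frac = float(covered.mean())
    if frac > target_cbv * (1.0 + tol):
        raise ValueError(
            f"a single perturber overshoots the target CBV beyond the "
            f"{tol:.0%} tolerance (got {frac:.4g} for target {target_cbv}); "
            "the radius is too large for this voxel")
    return out


def make_random_cylinders_3d(spec: VoxelSpec, radius: float, target_cbv: float,
                             dchi: float, perm: float = 0.0, rng_seed: int = 0,
                             *, tol: float = 0.1, max_perturbers: int = 100_000,
                             n_probe: int = 100_000,
                             overlap: str = "allow") -> list[Cylinder3D]:
    """Randomly oriented infinite cylinders filling a 3D voxel to a target
    blood volume fraction.

    Cylinders are added one at a time -- isotropic random axis, axis point
    uniform in the enclosing ball of radius ``W*sqrt(3)/2`` -- until the
    Monte-Carlo-estimated union fraction first reaches ``target_cbv``.
    Deterministic given ``rng_seed``.
    """
    if spec.ndim != 3:
        raise ValueError("make_random_cylinders_3d needs a 3D voxel spec")
    rng = np.random.default_rng(rng_seed)
    center = np.full(3, spec.width / 2.0)
    r_ball = spec.width * np.sqrt(3.0) / 2.0

    def make_one(rng):
        axis = random_unit_vectors(rng, 1)[0]
        direction = random_unit_vectors(rng, 1)[0]
        rad = r_ball * rng.random() ** (1.0 / 3.0)
        point = center + rad * direction
        return Cylinder3D(radius, point, axis, dchi, perm)

    return _generate_until_cbv(spec, make_one, target_cbv, rng, tol=tol,
                               max_perturbers=max_perturbers, n_probe=n_probe,
                               overlap=overlap)


def make_random_cylinders_2d(spec: VoxelSpec, radius: float, target_cbv: float,
                             dchi: float, perm: float = 0.0, rng_seed: int = 0,
                             *, tol: float = 0.1, max_perturbers: int = 100_000,
                             n_probe: int = 100_000,
                             overlap: str = "allow") -> list[Cylinder2D]:
    """Random 2D cylinders: centers uniform in the square, effective field
    orientation isotropic (cos(theta) uniform on [-1, 1], phi0 uniform)."""
    if spec.ndim != 2:
        raise ValueError("make_random_cylinders_2d needs a 2D voxel spec")
    rng = np.random.default_rng(rng_seed)

    def make_one(rng):
        c = rng.random(2) * spec.width
        theta = float(sample_polar_angles(rng, 1)[0])
        phi0 = float(rng.uniform(0.0, 2.0 * np.pi))
        return Cylinder2D(radius, c, theta, phi0, dchi, perm)

    return _generate_until_cbv(spec, make_one, target_cbv, rng, tol=tol,
                               max_perturbers=max_perturbers, n_probe=n_probe,
                               overlap=overlap)


def make_random_spheres_3d(spec: VoxelSpec, radius: float, target_cbv: float,
                           dchi: float, perm: float = 0.0, rng_seed: int = 0,
                           *, tol: float = 0.1, max_perturbers: int = 100_000,
                           n_probe: int = 100_000,
                           overlap: str = "allow") -> list[Sphere3D]:
    """Random spheres at a target volume fraction; centers uniform in the
    voxel cube expanded by one radius per side so coverage stays uniform up
    to the faces.  Spheres carry no orientation."""
    if spec.ndim != 3:
        raise ValueError("make_random_spheres_3d needs a 3D voxel spec")
    rng = np.random.default_rng(rng_seed)

    def make_one(rng):
        c = rng.uniform(-radius, spec.width + radius, size=3)
        return Sphere3D(radius, c, dchi, perm)

    return _generate_until_cbv(spec, make_one, target_cbv, rng, tol=tol,
                               max_perturbers=max_perturbers, n_probe=n_probe,
                               overlap=overlap)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


@dataclass
class GriddedVoxel:
    """A discretized voxel: per-element compartment label and susceptibility,
    with optional per-element relaxation times and a per-label permeation
    table for Monte Carlo diffusion on gridded geometries.

    Label 0 is extra-perturber space; labels k > 0 identify perturbers (or
    compartments of a custom mask).
    """

    spec: VoxelSpec
    label: np.ndarray
    dchi_map: np.ndarray
    t2_map: np.ndarray | None = None
    t1_map: np.ndarray | None = None
    perm_by_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.spec.is_gridded:
            raise ValueError("GriddedVoxel requires a gridded VoxelSpec")
        shape = self.spec.shape
        self.label = np.asarray(self.label)
        self.dchi_map = np.asarray(self.dchi_map, dtype=float)
        for name in ("label", "dchi_map", "t2_map", "t1_map"):
            g = getattr(self, name)
            if g is not None and g.shape != shape:
                raise ValueError(
                    f"{name} has shape {g.shape}, expected {shape}")

    @property
    def dx(self) -> float:
        return self.spec.dx

    @property
    def n_labels(self) -> int:
        return int(self.label.max())

    def indices_at(self, points: np.ndarray) -> tuple:
        idx = np.floor(np.atleast_2d(points) / self.dx).astype(np.intp)
        np.clip(idx, 0, self.spec.n - 1, out=idx)
        return tuple(idx.T)

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Compartment label of the grid element containing each point."""
        return self.label[self.indices_at(points)]

    def perm_table(self) -> np.ndarray:
        if self.perm_by_label is not None:
            return np.asarray(self.perm_by_label, dtype=float)
        # Unspecified permeability on a mask: fully permeable.
        return np.ones(self.n_labels + 1, dtype=float)

    def save(self, path) -> None:
        save_gridded_voxel(self, path)


def discretize_voxel(perturbers, spec: VoxelSpec, *, chunk: int = 4_000_000,
                     warn: bool = True) -> GriddedVoxel:
    """Sample every grid-element center against the perturbers.

    Element centers sit at ``(i + 1/2) * W / N`` per axis.  The label map
    stores the first containing perturber (1-based); ``dchi_map`` holds that
    perturber's susceptibility difference.
    """
    if not spec.is_gridded:
        raise ValueError("discretize_voxel requires a gridded VoxelSpec")
    if warn:
        check_sampling(spec, perturbers)
    perturbers = list(perturbers)
    n = spec.n
    shape = spec.shape
    c1 = spec.element_centers_1d()
    if spec.ndim == 2:
        xx, yy = np.meshgrid(c1, c1, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        labels = label_points(pts, perturbers).reshape(shape)
    else:
        labels = np.empty(shape, dtype=np.int32)
        yy, zz = np.meshgrid(c1, c1, indexing="ij")
        plane = np.column_stack([yy.ravel(), zz.ravel()])
        rows_per_chunk = max(1, chunk // (n * n))
        for i0 in range(0, n, rows_per_chunk):
            i1 = min(n, i0 + rows_per_chunk)
            block = []
            for i in range(i0, i1):
                pts = np.column_stack([np.full(plane.shape[0], c1[i]), plane])
                block.append(label_points(pts, perturbers))
            labels[i0:i1] = np.asarray(block).reshape(i1 - i0, n, n)
    dchi_by_label = np.array([0.0] + [p.dchi for p in perturbers])
    dchi_map = dchi_by_label[labels]
    return GriddedVoxel(spec=spec, label=labels, dchi_map=dchi_map,
                        perm_by_label=perm_table(perturbers))


def check_sampling(spec: VoxelSpec, perturbers) -> list[str]:
    """Grid-sampling rule: every perturber should span at least 6 grid
    elements across its diameter.  Returns (and emits) warnings for
    violations; continuous voxels always pass."""
    if not spec.is_gridded:
        return []
    out = []
    dx = spec.dx
    for k, p in enumerate(perturbers, start=1):
        n_across = 2.0 * p.radius / dx
        if n_across < 6.0:
            msg = (f"perturber {k} ({type(p).__name__}, R={p.radius:g} mm) spans "
                   f"only {n_across:.2f} grid elements across its diameter; "
                   "at least 6 are recommended for faithful discretization")
            out.append(msg)
            warnings.warn(msg, stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# HDF5 container for gridded voxels / custom masks
# ---------------------------------------------------------------------------


def save_gridded_voxel(gv: GriddedVoxel, path, *, dbz: np.ndarray | None = None) -> None:
    """Write a gridded voxel to an HDF5 container.

    Layout: datasets ``label``, ``dchi`` (and optional ``t2``, ``t1``,
    ``perm_by_label``, ``dbz``); attributes ``width``, ``n``, ``ndim``,
    ``b0``, ``b0_dir``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["width"] = gv.spec.width
        f.attrs["n"] = gv.spec.n
        f.attrs["ndim"] = gv.spec.ndim
        f.attrs["b0"] = gv.spec.b0
        f.attrs["b0_dir"] = np.asarray(gv.spec.b0_dir)
        f.create_dataset("label", data=gv.label)
        f.create_dataset("dchi", data=gv.dchi_map)
        if gv.t2_map is not None:
            f.create_dataset("t2", data=gv.t2_map)
        if gv.t1_map is not None:
            f.create_dataset("t1", data=gv.t1_map)
        if gv.perm_by_label is not None:
            f.create_dataset("perm_by_label", data=gv.perm_by_label)
        if dbz is not None:
            f.create_dataset("dbz", data=dbz)


def load_perturber_mask(path) -> GriddedVoxel:
    """Load a gridded voxel / custom perturber mask from HDF5.

    The container must hold a ``label`` grid plus either a full ``dchi``
    grid or a per-label ``dchi_by_label`` table covering every label present.
    Shape mismatches or missing label properties fail loudly.
    """
    with h5py.File(path, "r") as f:
        label = f["label"][()]
        attrs = dict(f.attrs)
        spec = VoxelSpec(ndim=int(attrs["ndim"]), width=float(attrs["width"]),
                         representation="gridded", n=int(attrs["n"]),
                         b0=float(attrs.get("b0", 3.0)),
                         b0_dir=tuple(attrs.get("b0_dir", (0.0, 0.0, 1.0))))
        if label.shape != spec.shape:
            raise ValueError(
                f"label grid shape {label.shape} does not match the declared "
                f"spec shape {spec.shape}")
        max_label = int(label.max())
        if "dchi" in f:
            dchi_map = f["dchi"][()]
            if dchi_map.shape != label.shape:
                raise ValueError(
                    f"dchi grid shape {dchi_map.shape} does not match the "
                    f"label grid shape {label.shape}")
        elif "dchi_by_label" in f:
            table = np.asarray(f["dchi_by_label"][()], dtype=float)
            if table.size < max_label + 1 or np.isnan(table[: max_label + 1]).any():
                raise ValueError(
                    f"dchi_by_label table does not define a susceptibility "
                    f"for every label up to {max_label}")
            dchi_map = table[label]
        else:
            raise ValueError("mask container has neither 'dchi' nor 'dchi_by_label'")
        def _grid(name):
            if name not in f:
                return None
            g = f[name][()]
            if g.shape != label.shape:
                raise ValueError(
                    f"{name} grid shape {g.shape} does not match the label "
                    f"grid shape {label.shape}")
            return g
        t2_map = _grid("t2")
        t1_map = _grid("t1")
        perm = f["perm_by_label"][()] if "perm_by_label" in f else None
        if perm is not None and perm.size < max_label + 1:
            raise ValueError("perm_by_label table shorter than the label range")
    return GriddedVoxel(spec=spec, label=label, dchi_map=dchi_map,
                        t2_map=t2_map, t1_map=t1_map, perm_by_label=perm)
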