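"""Magnetic field offsets from susceptibility perturbers.

Two routes to the local field offset ΔBz (tesla):

* analytic -- the closed-form dipolar fields of an infinite cylinder and a
  sphere, superposed over all perturbers; exact, works in continuous or
  gridded space;
* Fourier -- convolution of the discretized susceptibility distribution
  with the spatial-domain z-dipole kernel, evaluated with FFTs on a
  zero-padded (or deliberately periodic) grid; approximate but independent
  of any closed form, so it accepts arbitrary masks.

The cylinder field inside the vessel is ``B0*dchi/6*(3cos^2(theta)-1)``
and outside ``B0*dchi/2*(R/r)^2*cos(2*phi)*sin^2(theta)``; the sphere field
vanishes inside and is ``B0*dchi/3*(R/r)^3*(3cos^2(theta)-1)`` outside.
Both vanish at the magic angle (3cos^2 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from . import _kernels
from .geometry import Cylinder2D, Cylinder3D, GriddedVoxel, Sphere3D, VoxelSpec

__all__ = [
    "FieldGrid",
    "cylinder_field_3d",
    "cylinder_field_2d",
    "sphere_field",
    "analytic_field",
    "analytic_field_grid",
    "dipole_kernel_3d",
    "fft_field",
    "field_for_gridded_voxel",
]


@dataclass
class FieldGrid:
    """ΔBz per grid element (tesla) on a gridded voxel."""

    values: np.ndarray
    spec: VoxelSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match the voxel "
                f"shape {self.spec.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field grid contains non-finite values")

    def at(self, points: np.ndarray) -> np.ndarray:
        """Value of the grid element containing each point."""
        dx = self.spec.dx
        idx = np.floor(np.atleast_2d(points) / dx).astype(np.intp)
        np.clip(idx, 0, self.spec.n - 1, out=idx)
        return self.values[tuple(idx.T)]


def cylinder_field_3d(points: np.ndarray, cyl: Cylinder3D, b0: float,
                      b0_dir) -> np.ndarray:
    """ΔBz of one infinite 3D cylinder at arbitrary points (tesla).

    theta is the angle between B0 and the cylinder axis; phi the angle
    between the perpendicular offset vector and the projection of B0 onto
    the plane orthogonal to the axis.  Inside uses the uniform
    ``(3cos^2-1)/6`` term; outside the ``cos(2phi)`` dipole cross-section.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    b = np.asarray(b0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    u = cyl.axis_dir
    cos_t = float(b @ u)
    b_perp = b - cos_t * u
    sin2_t = float(b_perp @ b_perp)  # |b|=1 so sin^2(theta) = |b_perp|^2

    dp = cyl.perp_vectors(points)
    r2 = np.einsum("ij,ij->i", dp, dp)
    out = np.empty(points.shape[0], dtype=float)
    inside = r2 < cyl.radius**2
    out[inside] = b0 * cyl.dchi / 6.0 * (3.0 * cos_t**2 - 1.0)

    ext = ~inside
    if np.any(ext):
        if sin2_t < 1e-30:
            out[ext] = 0.0
        else:
            r2e = r2[ext]
            cos_phi = (dp[ext] @ b_perp) / np.sqrt(r2e * sin2_t)
            cos_2phi = 2.0 * cos_phi**2 - 1.0
            out[ext] = (b0 * cyl.dchi / 2.0 * (cyl.radius**2 / r2e)
                        * cos_2phi * sin2_t)
    return out


def cylinder_field_2d(points: np.ndarray, cyl: Cylinder2D, b0: float) -> np.ndarray:
    """ΔBz of one 2D cylinder: same closed form, with the per-cylinder
    effective orientation (theta, phi0) supplying the B0 geometry."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dx = points[:, 0] - cyl.center[0]
    dy = points[:, 1] - cyl.center[1]
    r2 = dx * dx + dy * dy
    cos_t = np.cos(cyl.theta)
    inside = r2 < cyl.radius**2
    # cos(2(phi - phi0)) expanded so the hot path is trig-free:
    # cos2phi = (dx^2 - dy^2)/r^2, sin2phi = 2 dx dy / r^2.
    c0, s0 = np.cos(2.0 * cyl.phi0), np.sin(2.0 * cyl.phi0)
    amp = b0 * cyl.dchi / 2.0 * np.sin(cyl.theta) ** 2 * cyl.radius**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = amp * ((dx * dx - dy * dy) * c0 + 2.0 * dx * dy * s0) / (r2 * r2)
    out[inside] = b0 * cyl.dchi / 6.0 * (3.0 * cos_t**2 - 1.0)
    return out


def sphere_field(points: np.ndarray, sph: Sphere3D, b0: float, b0_dir) -> np.ndarray:
    """ΔBz of one sphere: zero inside, external dipole outside (tesla)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    b = np.asarray(b0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    d = points - sph.center
    r2 = np.einsum("ij,ij->i", d, d)
    out = np.zeros(points.shape[0], dtype=float)
    ext = r2 >= sph.radius**2
    if np.any(ext):
        r2e = r2[ext]
        cos_t2 = (d[ext] @ b) ** 2 / r2e
        out[ext] = (b0 * sph.dchi / 3.0 * (sph.radius**2 / r2e) ** 1.5
                    * (3.0 * cos_t2 - 1.0))
    return out


def _batch_cyl2d(pts: np.ndarray, cyls: list, b0: float,
                 out: np.ndarray) -> None:
    cx = np.array([c.center[0] for c in cyls])
    cy = np.array([c.center[1] for c in cyls])
    r2c = np.array([c.radius**2 for c in cyls])
    sin2t = np.sin([c.theta for c in cyls]) ** 2
    dchi = np.array([c.dchi for c in cyls])
    c0 = np.cos(2.0 * np.array([c.phi0 for c in cyls]))
    s0 = np.sin(2.0 * np.array([c.phi0 for c in cyls]))
    amp = b0 * dchi / 2.0 * sin2t * r2c
    inside_val = b0 * dchi / 6.0 * (3.0 * np.cos([c.theta for c in cyls]) ** 2 - 1.0)
    if _kernels.HAVE_NUMBA:
        _kernels.cyl2d_field(pts, cx, cy, r2c, amp, c0, s0, inside_val, out)
        return
    dx = pts[:, 0, None] - cx
    dy = pts[:, 1, None] - cy
    r2 = dx * dx + dy * dy
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = amp * ((dx * dx - dy * dy) * c0 + 2.0 * dx * dy * s0) / (r2 * r2)
    inside = r2 < r2c
    if inside.any():
        vals = np.where(inside, inside_val, vals)
    out += vals.sum(axis=1)


def _batch_cyl3d(pts: np.ndarray, cyls: list, b0: float, b,
                 out: np.ndarray) -> None:
    u = np.array([c.axis_dir for c in cyls])              # (k, 3)
    a = np.array([c.axis_point for c in cyls])
    r2c = np.array([c.radius**2 for c in cyls])
    dchi = np.array([c.dchi for c in cyls])
    cos_t = u @ b
    b_perp = b[None, :] - cos_t[:, None] * u              # (k, 3)
    sin2t = np.einsum("kj,kj->k", b_perp, b_perp)
    inside_val = b0 * dchi / 6.0 * (3.0 * cos_t**2 - 1.0)
    if _kernels.HAVE_NUMBA:
        _kernels.cyl3d_field(pts, a, u, b_perp, r2c, b0 * dchi / 2.0,
                             sin2t, inside_val, out)
        return
    # d = p - a; r2 = |d|^2 - (d.u)^2; q = d.b_perp (b_perp is axis-normal)
    p_u = pts @ u.T - np.einsum("kj,kj->k", a, u)         # (n, k)
    p2 = np.einsum("ij,ij->i", pts, pts)
    d2 = p2[:, None] - 2.0 * (pts @ a.T) + np.einsum("kj,kj->k", a, a)
    r2 = d2 - p_u**2
    q = pts @ b_perp.T - np.einsum("kj,kj->k", a, b_perp)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (b0 * dchi / 2.0 * r2c
                * (2.0 * q**2 / (r2 * r2) - sin2t / r2))
    inside = r2 < r2c
    if inside.any():
        vals = np.where(inside, inside_val, vals)
    out += vals.sum(axis=1)


def _batch_sph3d(pts: np.ndarray, sphs: list, b0: float, b,
                 out: np.ndarray) -> None:
    c = np.array([s.center for s in sphs])
    r3 = np.array([s.radius**3 for s in sphs])
    r2c = np.array([s.radius**2 for s in sphs])
    dchi = np.array([s.dchi for s in sphs])
    if _kernels.HAVE_NUMBA:
        _kernels.sph3d_field(pts, c, b, r2c, r3, b0 * dchi / 3.0, out)
        return
    p2 = np.einsum("ij,ij->i", pts, pts)
    r2 = p2[:, None] - 2.0 * (pts @ c.T) + np.einsum("kj,kj->k", c, c)
    q = (pts @ b)[:, None] - (c @ b)                      # d . b
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (b0 * dchi / 3.0 * r3
                * (3.0 * q**2 - r2) / r2**2.5)
    vals[r2 < r2c] = 0.0
    out += vals.sum(axis=1)


_BATCH_CHUNK = 16_384


def analytic_field(points: np.ndarray, perturbers, b0: float,
                   b0_dir=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Superposed analytic ΔBz of a perturber list.

    Linearity holds exactly: each perturber contributes its own inside or
    outside term independently of the others.  Perturbers are grouped by
    class and evaluated in vectorized batches.
    """
    perturbers = list(perturbers)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    total = np.zeros(points.shape[0], dtype=float)
    b = np.asarray(b0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    groups: dict[type, list] = {}
    for p in perturbers:
        if not isinstance(p, (Cylinder2D, Cylinder3D, Sphere3D)):
            raise TypeError(f"unsupported perturber type {type(p).__name__}")
        groups.setdefault(type(p), []).append(p)
    for cls, group in groups.items():
        for lo in range(0, points.shape[0], _BATCH_CHUNK):
            pts = np.ascontiguousarray(points[lo:lo + _BATCH_CHUNK])
            seg = total[lo:lo + _BATCH_CHUNK]
            if cls is Cylinder2D:
                _batch_cyl2d(pts, group, b0, seg)
            elif cls is Cylinder3D:
                _batch_cyl3d(pts, group, b0, b, seg)
            else:
                _batch_sph3d(pts, group, b0, b, seg)
    return total


def analytic_field_grid(perturbers, spec: VoxelSpec, *, chunk: int = 2_000_000) -> FieldGrid:
    """Analytic ΔBz evaluated at every grid-element center."""
    if not spec.is_gridded:
        raise ValueError("analytic_field_grid requires a gridded VoxelSpec")
    perturbers = list(perturbers)
    if all(p.dchi == 0.0 for p in perturbers):
        return FieldGrid(np.zeros(spec.shape), spec)
    c1 = spec.element_centers_1d()
    n = spec.n
    if spec.ndim == 2:
        xx, yy = np.meshgrid(c1, c1, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        vals = analytic_field(pts, perturbers, spec.b0, spec.b0_dir)
        return FieldGrid(vals.reshape(spec.shape), spec)
    vals = np.empty(spec.shape, dtype=float)
    yy, zz = np.meshgrid(c1, c1, indexing="ij")
    plane = np.column_stack([yy.ravel(), zz.ravel()])
    for i in range(n):
        pts = np.column_stack([np.full(plane.shape[0], c1[i]), plane])
        vals[i] = analytic_field(pts, perturbers, spec.b0, spec.b0_dir).reshape(n, n)
    return FieldGrid(vals, spec)


# ---------------------------------------------------------------------------
# Fourier route
# ---------------------------------------------------------------------------


def dipole_kernel_3d(shape, spacing: float, b0_dir=(0.0, 0.0, 1.0),
                     *, centered: bool = True) -> np.ndarray:
    """Spatial-domain z-dipole kernel ``(1/4pi)(3 z^2 - r^2)/r^5`` sampled at
    element-center offsets, with the singular r=0 element set to zero.

    ``z`` is the offset component along ``b0_dir``.  With ``centered`` the
    kernel origin sits at index ``m // 2`` per axis; otherwise the origin is
    at index 0 with negative offsets wrapped (FFT layout).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("dipole_kernel_3d builds 3D kernels only")
    b = np.asarray(b0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    axes = []
    for m in shape:
        if centered:
            off = (np.arange(m) - m // 2) * spacing
        else:
            off = np.arange(m)
            off[off > m // 2] -= m
            off = off * spacing
        axes.append(off)
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    zb = x * b[0] + y * b[1] + z * b[2]
    r2 = x * x + y * y + z * z
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (3.0 * zb**2 - r2) / (4.0 * np.pi * r2**2.5)
    g[r2 == 0] = 0.0
    return g


def fft_field(chi: np.ndarray, spacing: float, b0: float,
              b0_dir=(0.0, 0.0, 1.0), pad_elements=None,
              fold_images: int = 3) -> np.ndarray:
    """ΔBz from the susceptibility grid by Fourier dipole convolution.

    The kernel is evaluated in the spatial domain on a support as wide as
    the voxel (M = N per axis) and convolved with χ on a grid of
    ``N + pad_elements`` per axis.  ``pad_elements=None`` (default) applies
    the full ``N + M - 1`` zero padding that removes wrap-around;
    ``pad_elements=0`` keeps the transform periodic, which surrounds the
    voxel with copies of itself (a deliberate "infinite similar tissue"
    boundary condition).  A per-axis tuple mixes the two, e.g. periodic
    continuation along an infinite cylinder's axis (pad 0) with full
    padding transversally (pad None).  The result is cropped back to the
    voxel.
    """
    chi = np.asarray(chi, dtype=float)
    if chi.ndim != 3:
        raise ValueError(
            "fft_field operates on 3D susceptibility grids; 2D voxels use "
            "per-cylinder analytic fields")
    shape = chi.shape
    full = [n + m - 1 for n, m in zip(shape, shape)]  # M = N per axis
    if pad_elements is None or np.isscalar(pad_elements):
        pads = (pad_elements,) * 3
    else:
        pads = tuple(pad_elements)
        if len(pads) != 3:
            raise ValueError("pad_elements must be a scalar or a 3-tuple")
    padded = []
    for n, f, p in zip(shape, full, pads):
        if p is None:
            padded.append(f)
        elif p < 0:
            raise ValueError("pad_elements must be >= 0")
        else:
            padded.append(n + int(p))
    # Beyond the no-wrap length the circular convolution equals the linear
    # one, so a fast FFT length is free; below it the exact length matters.
    work = [sfft.next_fast_len(p) if p >= f else p
            for p, f in zip(padded, full)]

    chi_pad = np.zeros(work, dtype=float)
    chi_pad[tuple(slice(0, n) for n in shape)] = chi

    folded = tuple(p == 0 for p in pads)
    kernel = _wrapped_kernel(tuple(work), tuple(shape), spacing,
                             tuple(np.asarray(b0_dir, float)), folded,
                             fold_images)
    dbz = sfft.irfftn(sfft.rfftn(chi_pad) * sfft.rfftn(kernel), s=work)
    dbz = dbz[tuple(slice(0, n) for n in shape)] * b0 * spacing**3
    return np.ascontiguousarray(dbz)


def _wrapped_kernel(work: tuple, support: tuple, spacing: float,
                    b0_dir: tuple, folded: tuple, fold_images: int) -> np.ndarray:
    """Dipole kernel in FFT (origin-at-0) layout on the working grid.

    Zero-padded axes keep a centered, symmetric M-element support (odd
    element count, so the cube-symmetric dipole sum cancels exactly and no
    spurious uniform offset leaks into the convolution).  Periodic (pad=0)
    axes instead fold the kernel over ``fold_images`` periodic images per
    side -- the proper circular dipole kernel, whose plain one-period
    truncation converges only as 1/L² for extended sources such as infinite
    cylinders.
    """
    from itertools import product

    b = np.asarray(b0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    base = []
    for p in work:
        off = np.arange(p)
        off[off > p // 2] -= p
        base.append(off.astype(float) * spacing)
    image_ranges = [range(-fold_images, fold_images + 1) if f else (0,)
                    for f in folded]
    g = np.zeros(work)
    for shifts in product(*image_ranges):
        ax = [base[i] + shifts[i] * work[i] * spacing for i in range(3)]
        x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)
        zb = x * b[0] + y * b[1] + z * b[2]
        r2 = x * x + y * y + z * z
        with np.errstate(divide="ignore", invalid="ignore"):
            gk = (3.0 * zb**2 - r2) / (4.0 * np.pi * r2**2.5)
        gk[r2 == 0] = 0.0
        g += gk
    for ax_i, (p, m, f) in enumerate(zip(work, support, folded)):
        if f:
            continue
        off = np.arange(p)
        off[off > p // 2] -= p
        half = (m - 1) // 2 if m % 2 == 0 else m // 2
        keep = np.abs(off) <= half
        sl = [None] * 3
        sl[ax_i] = slice(None)
        g = g * keep[tuple(sl)]
    return g


def field_for_gridded_voxel(gv: GriddedVoxel, pad_elements: int | None = None) -> FieldGrid:
    """Convenience: Fourier field of a gridded voxel's susceptibility map."""
    vals = fft_field(gv.dchi_map, gv.dx, gv.spec.b0, gv.spec.b0_dir,
                     pad_elements=pad_elements)
    return FieldGrid(vals, gv.spec)
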