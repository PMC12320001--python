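"""Deterministic diffusion for 2D gridded voxels.

Diffusion of an ensemble of spins over one time step is a Gaussian blur of
width sigma = sqrt(2*D*dt), so the magnetization grid can be evolved by
convolving it with a discrete kernel instead of walking individual spins.
Two kernels are offered: samples of the continuous Gaussian, and the
discrete ("Bessel") kernel exp(-t) * I_n(t) with t = (sigma/dx)^2, which is
the lattice-exact solution of the discrete diffusion equation.  Both are
applied separably (one 1D pass per axis) under periodic boundary
conditions -- the voxel is padded with itself, matching the periodic wrap
of the Monte Carlo walker.

Perturber walls are either fully permeable (plain convolution) or fully
impermeable: an optional correction returns any kernel weight that would
carry magnetization across the intravascular/extravascular boundary back
to its source element, so each tissue class conserves its own total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import special, stats

from .geometry import GriddedVoxel, VoxelSpec

__all__ = [
    "DiffusionKernel",
    "MagnetizationGrid",
    "gaussian_kernel",
    "bessel_kernel",
    "default_n_hw",
    "effective_elements",
    "dd_step",
]


@dataclass
class DiffusionKernel:
    """Separable 1D diffusion kernel of length 2*n_hw + 1, unit sum."""

    weights: np.ndarray
    sigma: float
    dx: float
    kind: str
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size % 2 != 1:
            raise ValueError("kernel weights must be a 1D array of odd length")
        if np.any(self.weights < 0):
            raise ValueError("kernel weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")

    @property
    def n_hw(self) -> int:
        return (self.weights.size - 1) // 2


def default_n_hw(sigma: float, dx: float, min_hw: int = 5) -> int:
    """Half-width covering ~4 sigma of the kernel, at least 5 (so the
    kernel spans >= 11 elements whenever the width warrants it)."""
    if sigma <= 0:
        return min_hw
    return max(min_hw, int(np.ceil(4.0 * sigma / dx)))


def _tail_warning(tail: float, kind: str, sigma: float, dx: float, n_hw: int) -> None:
    if tail > 1e-3:
        warnings.warn(
            f"{kind} diffusion kernel truncates {tail:.2e} of its mass at "
            f"n_hw={n_hw} (sigma/dx={sigma / dx:.3g}); enlarge n_hw or the "
            "grid resolution to keep diffusion faithful",
            stacklevel=3)


def gaussian_kernel(sigma: float, dx: float, n_hw: int | None = None) -> DiffusionKernel:
    """Sampled Gaussian kernel: w_k ∝ exp(-(k*dx)^2 / (2 sigma^2)) for
    k in [-n_hw, n_hw], renormalized to unit sum.

    ``sigma=0`` degenerates to the identity (delta) kernel.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not dx > 0:
        raise ValueError("dx must be positive")
    if n_hw is None:
        n_hw = default_n_hw(sigma, dx)
    k = np.arange(-n_hw, n_hw + 1)
    if sigma == 0.0:
        w = (k == 0).astype(float)
        return DiffusionKernel(w, sigma, dx, "gaussian")
    w = np.exp(-((k * dx) ** 2) / (2.0 * sigma**2))
    # mass of the continuous Gaussian beyond the sampled span
    tail = float(2.0 * stats.norm.sf((n_hw + 0.5) * dx / sigma))
    _tail_warning(tail, "gaussian", sigma, dx, n_hw)
    return DiffusionKernel(w / w.sum(), sigma, dx, "gaussian")


def bessel_kernel(sigma: float, dx: float, n_hw: int | None = None) -> DiffusionKernel:
    """Discrete diffusion kernel D_n = exp(-t) * I_n(t), t = (sigma/dx)^2,
    for orders n in [-n_hw, n_hw], renormalized to unit sum.

    The untruncated kernel sums to exactly 1 (sum_n exp(-t) I_n(t) = 1);
    the pre-normalization deficiency is the truncation error.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not dx > 0:
        raise ValueError("dx must be positive")
    if n_hw is None:
        n_hw = default_n_hw(sigma, dx)
    t = (sigma / dx) ** 2
    orders = np.arange(-n_hw, n_hw + 1)
    w = special.ive(orders, t) if t > 0 else (orders == 0).astype(float)
    tail = float(1.0 - w.sum())
    _tail_warning(max(tail, 0.0), "bessel", sigma, dx, n_hw)
    return DiffusionKernel(w / w.sum(), sigma, dx, "bessel")


def effective_elements(kernel: DiffusionKernel, rel_threshold: float = 0.01) -> int:
    """Number of kernel elements above ``rel_threshold`` of the peak --
    a quick gauge of under-resolution (a near-delta kernel has <= 3)."""
    return int(np.sum(kernel.weights > rel_threshold * kernel.weights.max()))


@dataclass
class MagnetizationGrid:
    """Complex transverse plus real longitudinal magnetization per element."""

    mxy: np.ndarray
    mz: np.ndarray
    spec: VoxelSpec

    def __post_init__(self) -> None:
        self.mxy = np.asarray(self.mxy, dtype=complex)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.mxy.shape != self.spec.shape or self.mz.shape != self.spec.shape:
            raise ValueError("magnetization grids must match the voxel shape")


def _kernel_fft(kernel: DiffusionKernel, shape: tuple) -> np.ndarray:
    key = ("kfft", shape)
    if key not in kernel._cache:
        n_hw = kernel.n_hw
        if 2 * n_hw + 1 > min(shape):
            raise ValueError(
                f"kernel span {2 * n_hw + 1} exceeds the grid size {min(shape)}")
        k2 = np.outer(kernel.weights, kernel.weights)
        idx = [np.arange(-n_hw, n_hw + 1) % s for s in shape]
        wrapped = np.zeros(shape)
        wrapped[np.ix_(*idx)] = k2
        kernel._cache[key] = sfft.fft2(wrapped)
    return kernel._cache[key]


def _conv(x: np.ndarray, kfft: np.ndarray) -> np.ndarray:
    return sfft.ifft2(sfft.fft2(x.astype(complex)) * kfft)


def dd_step(m: MagnetizationGrid, kernel: DiffusionKernel,
            gv: GriddedVoxel | None = None,
            impermeable: bool = False) -> MagnetizationGrid:
    """One deterministic diffusion update of the magnetization grid
    (relaxation and precession for the step are applied beforehand by the
    sequence driver).

    Permeable walls: a plain periodic (self-padded) separable convolution,
    which conserves the grid totals exactly because the kernel sums to one.
    Impermeable walls: per tissue class c (intravascular = any label > 0,
    extravascular = label 0) the new value at an element p in c is
    ``conv(M * mask_c)(p) + M(p) * conv(mask_not_c)(p)`` -- the kernel
    weight that would cross the tissue boundary stays at its source, so
    each class conserves its own total.
    """
    shape = m.mxy.shape
    kfft = _kernel_fft(kernel, shape)
    # a spatially uniform mz is a fixed point of the unit-sum kernel
    mz_uniform = np.ptp(m.mz) == 0.0
    if not impermeable:
        m.mxy = _conv(m.mxy, kfft)
        if not mz_uniform:
            m.mz = _conv(m.mz, kfft).real
        return m
    if gv is None:
        raise ValueError("the impermeable correction needs the GriddedVoxel labels")
    table = gv.perm_table()[1:]
    if table.size and np.any((table > 0.0) & (table < 1.0)):
        raise ValueError(
            "deterministic diffusion supports only fully permeable (1) or "
            "fully impermeable (0) perturbers; intermediate permeation "
            "probabilities require the Monte Carlo backend")
    key = ("masks", shape)
    if key not in kernel._cache or kernel._cache[key][0] is not gv:
        iv = (gv.label > 0).astype(float)
        ev = 1.0 - iv
        kernel._cache[key] = (gv, iv, ev,
                              _conv(iv, kfft).real, _conv(ev, kfft).real)
    _, iv, ev, conv_iv, conv_ev = kernel._cache[key]
    mxy = m.mxy
    m.mxy = (ev * (_conv(mxy * ev, kfft) + mxy * conv_iv)
             + iv * (_conv(mxy * iv, kfft) + mxy * conv_ev))
    if not mz_uniform:
        mzc = m.mz
        m.mz = (ev * (_conv(mzc * ev, kfft).real + mzc * conv_iv)
                + iv * (_conv(mzc * iv, kfft).real + mzc * conv_ev))
    return m
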