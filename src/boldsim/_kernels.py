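"""Optional numba-accelerated inner loops.

The superposed dipole-field and containment-label evaluations are the hot
paths of Monte Carlo runs (n_spins x n_perturbers per time step).  The
numpy implementations in :mod:`boldsim.fieldmap` and
:mod:`boldsim.geometry` are the reference; these fused loops compute the
same quantities with identical per-term arithmetic and are used when numba
imports cleanly.  ``HAVE_NUMBA`` reports which path is active.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def cyl2d_field(pts, cx, cy, r2c, amp, c0, s0, inside_val, out):
    n, k = pts.shape[0], cx.shape[0]
    for i in range(n):
        x, y = pts[i, 0], pts[i, 1]
        tot = 0.0
        for j in range(k):
            dx = x - cx[j]
            dy = y - cy[j]
            r2 = dx * dx + dy * dy
            if r2 < r2c[j]:
                tot += inside_val[j]
            else:
                tot += (amp[j] * ((dx * dx - dy * dy) * c0[j]
                                  + 2.0 * dx * dy * s0[j]) / (r2 * r2))
        out[i] += tot


@njit(cache=False)
def cyl3d_field(pts, a, u, b_perp, r2c, half_bdchi, sin2t, inside_val, out):
    n, k = pts.shape[0], a.shape[0]
    for i in range(n):
        x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
        tot = 0.0
        for j in range(k):
            dx = x - a[j, 0]
            dy = y - a[j, 1]
            dz = z - a[j, 2]
            along = dx * u[j, 0] + dy * u[j, 1] + dz * u[j, 2]
            r2 = dx * dx + dy * dy + dz * dz - along * along
            if r2 < r2c[j]:
                tot += inside_val[j]
            else:
                q = dx * b_perp[j, 0] + dy * b_perp[j, 1] + dz * b_perp[j, 2]
                tot += (half_bdchi[j] * r2c[j]
                        * (2.0 * q * q / (r2 * r2) - sin2t[j] / r2))
        out[i] += tot


@njit(cache=False)
def sph3d_field(pts, c, b, r2c, r3, third_bdchi, out):
    n, k = pts.shape[0], c.shape[0]
    for i in range(n):
        x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
        tot = 0.0
        for j in range(k):
            dx = x - c[j, 0]
            dy = y - c[j, 1]
            dz = z - c[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= r2c[j]:
                q = dx * b[0] + dy * b[1] + dz * b[2]
                tot += (third_bdchi[j] * r3[j] * (3.0 * q * q - r2)
                        / (r2 * r2 * np.sqrt(r2)))
        out[i] += tot


@njit(cache=False)
def label_circles(pts, cx, cy, r2c, out):
    n, k = pts.shape[0], cx.shape[0]
    for i in range(n):
        x, y = pts[i, 0], pts[i, 1]
        lab = 0
        for j in range(k):
            dx = x - cx[j]
            dy = y - cy[j]
            if dx * dx + dy * dy <= r2c[j]:
                lab = j + 1
                break
        out[i] = lab


@njit(cache=False)
def label_spheres(pts, c, r2c, out):
    n, k = pts.shape[0], c.shape[0]
    for i in range(n):
        x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
        lab = 0
        for j in range(k):
            dx = x - c[j, 0]
            dy = y - c[j, 1]
            dz = z - c[j, 2]
            if dx * dx + dy * dy + dz * dz <= r2c[j]:
                lab = j + 1
                break
        out[i] = lab


@njit(cache=False)
def label_cylinders_3d(pts, a, u, r2c, out):
    n, k = pts.shape[0], a.shape[0]
    for i in range(n):
        x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
        lab = 0
        for j in range(k):
            dx = x - a[j, 0]
            dy = y - a[j, 1]
            dz = z - a[j, 2]
            along = dx * u[j, 0] + dy * u[j, 1] + dz * u[j, 2]
            if dx * dx + dy * dy + dz * dz - along * along <= r2c[j]:
                lab = j + 1
                break
        out[i] = lab
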