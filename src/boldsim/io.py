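"""File formats and run configuration.

Columnar text (CSV) for perturber lists, signal time courses and sweep
tables; HDF5 for gridded voxels and field maps (see
:func:`boldsim.geometry.save_gridded_voxel`); YAML for run configs.  Every
signal file embeds the metadata needed to reproduce it (method name, seed,
config digest) as ``# key: value`` header lines.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .geometry import (Cylinder2D, Cylinder3D, Sphere3D, VoxelSpec,
                       ppm_cgs_to_si)
from .montecarlo import DiffusionConfig
from .naming import parse_method_name
from .sequence import (SignalTimecourse, SimulationConfig, TissueProperties,
                       build_sequence)

__all__ = [
    "perturbers_to_csv",
    "perturbers_from_csv",
    "write_signal_csv",
    "read_signal_csv",
    "load_config",
    "config_hash",
    "build_simulation_config",
]

_COLUMNS = {
    "cylinder3d": ["kind", "radius", "px", "py", "pz", "ax", "ay", "az",
                   "dchi", "perm"],
    "cylinder2d": ["kind", "radius", "cx", "cy", "theta", "phi0", "dchi",
                   "perm"],
    "sphere3d": ["kind", "radius", "cx", "cy", "cz", "dchi", "perm"],
}


def _kind(p) -> str:
    return type(p).__name__.lower()


def perturbers_to_csv(perturbers, path) -> None:
    """Write a homogeneous perturber list as columnar text."""
    perturbers = list(perturbers)
    if not perturbers:
        raise ValueError("refusing to write an empty perturber list")
    kinds = {_kind(p) for p in perturbers}
    if len(kinds) > 1:
        raise ValueError(f"mixed perturber classes in one file: {sorted(kinds)}")
    kind = kinds.pop()
    rows = []
    for p in perturbers:
        if kind == "cylinder3d":
            rows.append([kind, p.radius, *p.axis_point, *p.axis_dir, p.dchi, p.perm])
        elif kind == "cylinder2d":
            rows.append([kind, p.radius, *p.center, p.theta, p.phi0, p.dchi, p.perm])
        else:
            rows.append([kind, p.radius, *p.center, p.dchi, p.perm])
    df = pd.DataFrame(rows, columns=_COLUMNS[kind])
    for col in df.columns[1:]:
        df[col] = df[col].astype(float)
    # shortest round-trip repr so reading back is bit-exact
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def perturbers_from_csv(path) -> list:
    """Read a perturber list written by :func:`perturbers_to_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "kind" not in df.columns or df.empty:
        raise ValueError(f"{path} is not a perturber table")
    kind = df["kind"].iloc[0]
    if not (df["kind"] == kind).all():
        raise ValueError("mixed perturber classes in one file")
    expected = _COLUMNS.get(kind)
    if expected is None or list(df.columns) != expected:
        raise ValueError(
            f"unexpected columns for {kind}: {list(df.columns)} (expected "
            f"{expected})")
    out = []
    for r in df.itertuples(index=False):
        if kind == "cylinder3d":
            out.append(Cylinder3D(r.radius, (r.px, r.py, r.pz),
                                  (r.ax, r.ay, r.az), r.dchi, r.perm))
        elif kind == "cylinder2d":
            out.append(Cylinder2D(r.radius, (r.cx, r.cy), r.theta, r.phi0,
                                  r.dchi, r.perm))
        else:
            out.append(Sphere3D(r.radius, (r.cx, r.cy, r.cz), r.dchi, r.perm))
    return out


def write_signal_csv(tc: SignalTimecourse, path) -> None:
    """Signal time course as CSV with a ``# key: value`` metadata header."""
    with open(path, "w") as f:
        for k in sorted(tc.metadata):
            f.write(f"# {k}: {tc.metadata[k]}\n")
        tc.to_dataframe().to_csv(f, index=False)


def read_signal_csv(path) -> SignalTimecourse:
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    return SignalTimecourse(
        time=df["time_s"].to_numpy(),
        total=df["re_total"].to_numpy() + 1j * df["im_total"].to_numpy(),
        iv=df["re_iv"].to_numpy() + 1j * df["im_iv"].to_numpy(),
        ev=df["re_ev"].to_numpy() + 1j * df["im_ev"].to_numpy(),
        metadata=meta)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML run config into a plain dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable digest of a config dict (order-independent)."""
    return hashlib.sha1(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def build_simulation_config(cfg: dict, *, seed: int | None = None) -> SimulationConfig:
    """Turn a config dict (from YAML) into a :class:`SimulationConfig`.

    Perturbers come either from a generator block
    (``perturbers: {kind, radius, cbv, dchi | dchi_ppm_cgs, perm}``), from a
    CSV file (``perturbers: {file: ...}``) or, for gridded/VAN methods, from
    an HDF5 mask (``mask: path``).
    """
    method = str(cfg["method"]).upper()
    sel = parse_method_name(method)
    v = cfg["voxel"]
    spec = VoxelSpec(
        ndim=int(v.get("ndim", sel.ndim)), width=float(v["width"]),
        representation="gridded" if sel.space == "GRD" else "continuous",
        n=int(v["n"]) if "n" in v and v["n"] is not None else None,
        b0=float(v.get("b0", 3.0)),
        b0_dir=tuple(v.get("b0_dir", (0.0, 0.0, 1.0))))
    dcfg = cfg["diffusion"]
    diffusion = DiffusionConfig(float(dcfg["d"]), float(dcfg["dt"]))
    s = cfg["sequence"]
    sequence = build_sequence(s.get("kind", "SE"), float(s["te"]),
                              diffusion.dt, float(s.get("tau_shift", 0.0)))
    run_seed = int(cfg.get("seed", 0)) if seed is None else int(seed)

    perturbers, gridded = None, None
    if "mask" in cfg:
        gridded = geometry.load_perturber_mask(cfg["mask"])
    elif "perturbers" in cfg:
        p = cfg["perturbers"]
        if "file" in p:
            perturbers = perturbers_from_csv(p["file"])
        else:
            dchi = (float(p["dchi"]) if "dchi" in p
                    else ppm_cgs_to_si(float(p["dchi_ppm_cgs"])))
            args = dict(spec=spec, radius=float(p["radius"]),
                        target_cbv=float(p["cbv"]), dchi=dchi,
                        perm=float(p.get("perm", 0.0)), rng_seed=run_seed)
            kind = p.get("kind", "CYL" if sel.perturber == "CYL" else "SPH")
            if sel.perturber == "SPH":
                perturbers = geometry.make_random_spheres_3d(**args)
            elif sel.ndim == 2:
                perturbers = geometry.make_random_cylinders_2d(**args)
            else:
                perturbers = geometry.make_random_cylinders_3d(**args)
    else:
        raise ValueError("config needs a 'perturbers' or 'mask' section")

    tissue = None
    if "tissue" in cfg and cfg["tissue"]:
        t = cfg["tissue"]
        as_map = lambda d: {int(k): float(v) for k, v in d.items()} if d else None
        tissue = TissueProperties(t2=as_map(t.get("t2")), t1=as_map(t.get("t1")))

    return SimulationConfig(
        method=method, spec=spec, sequence=sequence, diffusion=diffusion,
        perturbers=perturbers, gridded=gridded, tissue=tissue,
        n_spins=int(cfg.get("nspins", 10_000)),
        kernel_kind=cfg.get("kernel", "gaussian"),
        n_hw=cfg.get("n_hw"), pad_elements=cfg.get("pad_elements"),
        seed=run_seed)
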