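"""Simulation method names.

A method is a combination of five choices, written as a hyphenated token
string such as ``3D-CTN-CYL-ANA-MC``: dimensionality (2D/3D), spatial
representation (CTN continuous / GRD gridded), perturber class (CYL
cylinders / SPH spheres / VAN custom mask), field computation (ANA
analytic / FFT Fourier convolution) and diffusion backend (MC Monte Carlo
/ DD deterministic).  Not every combination is physical; the compatibility
rules below reject the rest with a message naming the violated rule.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MethodSelector", "MethodCompatibilityError", "parse_method_name"]

_TOKENS = {
    "ndim": {"2D": 2, "3D": 3},
    "space": {"CTN", "GRD"},
    "perturber": {"CYL", "SPH", "VAN"},
    "field": {"ANA", "FFT"},
    "diffusion": {"MC", "DD"},
}


class MethodCompatibilityError(ValueError):
    """An invalid combination of simulation options."""


@dataclass(frozen=True)
class MethodSelector:
    """A validated simulation method combination."""

    ndim: int
    space: str
    perturber: str
    field: str
    diffusion: str

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise MethodCompatibilityError("dimensionality must be 2D or 3D")
        for name in ("space", "perturber", "field", "diffusion"):
            if getattr(self, name) not in _TOKENS[name]:
                raise MethodCompatibilityError(
                    f"unknown {name} token {getattr(self, name)!r}")
        self.validate()

    def validate(self) -> None:
        if self.field == "FFT" and self.space != "GRD":
            raise MethodCompatibilityError(
                f"{self}: the Fourier field method requires a gridded (GRD) "
                "voxel, since the convolution is evaluated on the grid")
        if self.perturber == "VAN" and self.field != "FFT":
            raise MethodCompatibilityError(
                f"{self}: custom perturber masks (VAN) carry no closed-form "
                "field and require the Fourier (FFT) field method")
        if self.perturber == "VAN" and self.ndim != 3:
            raise MethodCompatibilityError(
                f"{self}: custom perturber masks (VAN) are 3D only")
        if self.diffusion == "DD" and (self.ndim != 2 or self.space != "GRD"):
            raise MethodCompatibilityError(
                f"{self}: deterministic diffusion (DD) is implemented for 2D "
                "gridded (GRD) voxels only")
        if self.perturber == "SPH" and self.ndim != 3:
            raise MethodCompatibilityError(
                f"{self}: spherical perturbers (SPH) are 3D only")
        if self.field == "FFT" and self.ndim != 3:
            raise MethodCompatibilityError(
                f"{self}: the Fourier field method uses the 3D dipole kernel; "
                "2D cylinders carry per-cylinder effective field directions, "
                "which a single convolution cannot represent")

    def __str__(self) -> str:
        return "-".join([f"{self.ndim}D", self.space, self.perturber,
                         self.field, self.diffusion])


def parse_method_name(s: str) -> MethodSelector:
    """Parse and validate a hyphenated method name.

    >>> parse_method_name("3D-CTN-CYL-ANA-MC")
    MethodSelector(ndim=3, space='CTN', perturber='CYL', field='ANA', diffusion='MC')
    """
    parts = str(s).strip().upper().split("-")
    if len(parts) != 5:
        raise MethodCompatibilityError(
            f"method name {s!r} must have 5 hyphen-separated tokens "
            "(e.g. 3D-CTN-CYL-ANA-MC)")
    ndim_tok, space, perturber, fieldm, diffusion = parts
    if ndim_tok not in _TOKENS["ndim"]:
        raise MethodCompatibilityError(
            f"unknown dimensionality token {ndim_tok!r} in {s!r}")
    return MethodSelector(_TOKENS["ndim"][ndim_tok], space, perturber,
                          fieldm, diffusion)
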