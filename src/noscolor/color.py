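"""CIE colorimetry: reflectance spectrum → XYZ → chromaticity / CIELAB / sRGB.

Tristimulus values are discrete sums of ``R(λ)·S(λ)·c̄(λ)·Δλ`` over the
spectral grid, where ``S`` is the illuminant power distribution and ``c̄``
one of the 2° standard-observer colour-matching functions.  The
normalisation is fixed so a perfect reflector (``R ≡ 1``) has ``Y = 100``;
the same illuminant's white point is used for the CIELAB transform unless
one is supplied explicitly.

The bundled observer is an analytic multi-lobe Gaussian fit to the CIE 1931
2° colour-matching functions (see ``scripts/make_reference_tables.py``);
the bundled daylight illuminant approximates D65 by a 6504 K Planckian
radiator.  Both tables resample linearly onto whatever grid the spectrum
uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedChromaticityError
from .tmm import Spectrum

__all__ = [
    "CMFTable", "Tristimulus", "LabPoint", "SRGBColor",
    "cie1931_observer", "illuminant", "spectrum_to_tristimulus",
    "tristimulus_to_xy", "xyz_to_lab", "delta_e", "xyz_to_srgb",
    "srgb_to_xyz",
]


@dataclass(frozen=True)
class CMFTable:
    """Colour-matching functions x̄, ȳ, z̄ on a wavelength grid (nm)."""

    wavelengths_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        for name in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != w.shape:
                raise InputError("CMF columns must match the wavelength grid")
            if np.any(v < 0):
                raise InputError("colour-matching functions are non-negative")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "wavelengths_nm", w)

    def resampled(self, wavelengths_nm: np.ndarray) -> "CMFTable":
        lam = np.asarray(wavelengths_nm, dtype=float)
        cols = [np.interp(lam, self.wavelengths_nm, getattr(self, c),
                          left=0.0, right=0.0)
                for c in ("xbar", "ybar", "zbar")]
        return CMFTable(lam, *cols)


@dataclass(frozen=True)
class Tristimulus:
    """CIE XYZ with chromaticity; perfect-reflector normalisation Y = 100."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        for v in (self.X, self.Y, self.Z):
            if not np.isfinite(v) or v < 0:
                raise InputError("tristimulus values must be finite and >= 0")

    @property
    def xy(self) -> tuple[float, float]:
        return tristimulus_to_xy(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class LabPoint:
    """CIELAB coordinates (L* in [0, 100]; a*, b* opponent axes)."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])

    def clamped(self) -> "LabPoint":
        """a*, b* clamped to [−128, 127] (the image-extraction convention)."""
        return LabPoint(self.L, float(np.clip(self.a, -128, 127)),
                        float(np.clip(self.b, -128, 127)))


@dataclass(frozen=True)
class SRGBColor:
    """Gamma-encoded sRGB triple in [0, 1]; ``clipped`` flags gamut clipping."""

    r: float
    g: float
    b: float
    clipped: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b])


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("noscolor.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def cie1931_observer() -> CMFTable:
    """Bundled CIE 1931 2° observer (analytic-fit table, 360-830 nm, 1 nm)."""
    df = _read_bundled("cmf_cie1931_2deg_synthetic.csv")
    return CMFTable(df["wavelength_nm"].to_numpy(), df["xbar"].to_numpy(),
                    df["ybar"].to_numpy(), df["zbar"].to_numpy())


def illuminant(name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Spectral power distribution of a named illuminant on a grid.

    ``"E"`` is the equal-energy illuminant; ``"D65"`` the bundled 6504 K
    Planckian daylight approximation (resampled linearly).
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    key = name.upper()
    if key == "E":
        return np.ones_like(lam)
    if key == "D65":
        df = _read_bundled("illuminant_d65_synthetic.csv")
        return np.interp(lam, df["wavelength_nm"].to_numpy(),
                         df["value"].to_numpy())
    raise InputError(f"unknown illuminant {name!r} (use 'E' or 'D65')")


def spectrum_to_tristimulus(spectrum: Spectrum,
                            illuminant_spd: np.ndarray,
                            cmf: CMFTable) -> Tristimulus:
    """Integrate a reflectance spectrum to XYZ (perfect reflector → Y = 100).

    All three inputs must share the spectrum's wavelength grid; resample the
    CMF table with :meth:`CMFTable.resampled` first if needed.
    """
    lam = spectrum.wavelengths_nm
    spd = np.asarray(illuminant_spd, dtype=float)
    if spd.shape != lam.shape or cmf.wavelengths_nm.shape != lam.shape:
        raise InputError("spectrum, illuminant and CMFs must share one grid")
    if not np.allclose(cmf.wavelengths_nm, lam):
        raise InputError("CMF table is on a different wavelength grid")
    dlam = np.gradient(lam) if lam.size > 1 else np.ones(1)
    norm = float(np.sum(spd * cmf.ybar * dlam))
    if norm <= 0:
        raise InputError("illuminant × ȳ integrates to zero")
    k = 100.0 / norm
    r = spectrum.values
    X = k * float(np.sum(r * spd * cmf.xbar * dlam))
    Y = k * float(np.sum(r * spd * cmf.ybar * dlam))
    Z = k * float(np.sum(r * spd * cmf.zbar * dlam))
    return Tristimulus(X, Y, Z)


def white_point(illuminant_spd: np.ndarray, cmf: CMFTable,
                wavelengths_nm: np.ndarray) -> Tristimulus:
    """Tristimulus of the perfect reflector under the given illuminant."""
    ones = Spectrum(wavelengths_nm, np.ones_like(np.asarray(wavelengths_nm,
                                                            dtype=float)))
    return spectrum_to_tristimulus(ones, illuminant_spd, cmf)


def tristimulus_to_xy(t: Tristimulus) -> tuple[float, float]:
    """Chromaticity ``x = X/(X+Y+Z)``, ``y = Y/(X+Y+Z)``."""
    total = t.X + t.Y + t.Z
    if total <= 0:
        raise UndefinedChromaticityError(
            "chromaticity undefined for zero tristimulus")
    return t.X / total, t.Y / total


def _lab_f(t: np.ndarray) -> np.ndarray:
    d = 6.0 / 29.0
    return np.where(t > d ** 3, np.cbrt(t), t / (3 * d * d) + 4.0 / 29.0)


def xyz_to_lab(t: Tristimulus, white: Tristimulus) -> LabPoint:
    """CIE 1976 L*a*b* transform relative to the given white point."""
    wp = white.as_array()
    if np.any(wp <= 0):
        raise InputError("white point must have strictly positive components")
    fx, fy, fz = _lab_f(t.as_array() / wp)
    return LabPoint(float(116.0 * fy - 16.0), float(500.0 * (fx - fy)),
                    float(200.0 * (fy - fz)))


def delta_e(p: LabPoint, q: LabPoint) -> float:
    """CIE76 colour difference ΔE*ab: Euclidean distance in (L*, a*, b*)."""
    return float(np.linalg.norm(p.as_array() - q.as_array()))


# sRGB (IEC 61966-2-1) linear-RGB ↔ XYZ matrices for the D65 white, with
# XYZ on the Y=100 scale handled by the 1/100 factor below.
_XYZ_TO_RGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])
_RGB_TO_XYZ = np.linalg.inv(_XYZ_TO_RGB)


def _gamma_encode(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.0031308, 12.92 * c,
                    1.055 * np.power(np.clip(c, 0, None), 1 / 2.4) - 0.055)


def _gamma_decode(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92,
                    np.power((c + 0.055) / 1.055, 2.4))


def xyz_to_srgb(t: Tristimulus, white: Tristimulus | None = None) -> SRGBColor:
    """Encode XYZ (Y=100 scale) as gamma-encoded sRGB in [0, 1].

    If *white* is given, the XYZ triple is first von-Kries-scaled so that
    this white maps to the sRGB reference white; out-of-gamut channels are
    clipped and flagged.
    """
    xyz = t.as_array() / 100.0
    if white is not None:
        ref = srgb_to_xyz(SRGBColor(1.0, 1.0, 1.0)).as_array() / 100.0
        xyz = xyz / (white.as_array() / 100.0) * ref
    lin = _XYZ_TO_RGB @ xyz
    clipped = bool(np.any(lin < -1e-9) or np.any(_gamma_encode(
        np.clip(lin, 0, None)) > 1 + 1e-9))
    rgb = np.clip(_gamma_encode(np.clip(lin, 0.0, None)), 0.0, 1.0)
    return SRGBColor(float(rgb[0]), float(rgb[1]), float(rgb[2]), clipped)


def srgb_to_xyz(c: SRGBColor) -> Tristimulus:
    """Decode gamma-encoded sRGB to XYZ on the Y=100 scale."""
    lin = _gamma_decode(np.array([c.r, c.g, c.b], dtype=float))
    xyz = 100.0 * (_RGB_TO_XYZ @ lin)
    return Tristimulus(*np.clip(xyz, 0.0, None))
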