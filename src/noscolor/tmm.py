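"""Coherent multilayer reflectance via the transfer-matrix method (TMM).

The stack is ``ambient | layer_1 | ... | layer_m | substrate`` with the
substrate treated as optically semi-infinite: no back-surface reflection is
added, which matches an opaque carrier such as a silicon wafer in the
visible.  The characteristic-matrix formulation (Abelès/Macleod) is used
with the complex-index convention ``ñ = n − i·k`` of
:mod:`noscolor.dispersion`.

For each layer the phase thickness is ``δ = 2π ñ d cosθ / λ`` and the layer
matrix is::

    M = [[cos δ,        i sin δ / η],
         [i η sin δ,    cos δ     ]]

with the tilted admittance ``η = ñ cosθ`` (s-polarisation) or ``ñ / cosθ``
(p-polarisation).  The amplitude reflection coefficient follows from the
product matrix and the ambient/substrate admittances; reflectance is
``R = |r|²``.  Unpolarised light is the mean of the s and p intensity
reflectances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersion import DispersionTable, constant_index
from .errors import InputError

__all__ = ["Layer", "LayerStack", "Spectrum", "default_grid", "tmm_reflectance"]

#: default spectral grid: 360-830 nm at 1 nm resolution
DEFAULT_GRID_NM = (360.0, 830.0, 1.0)


def default_grid() -> np.ndarray:
    lo, hi, step = DEFAULT_GRID_NM
    return np.arange(lo, hi + 0.5 * step, step)


@dataclass(frozen=True)
class Layer:
    """One finite film: a dispersion table plus a physical thickness in nm."""

    dispersion: DispersionTable
    thickness_nm: float

    def __post_init__(self) -> None:
        t = float(self.thickness_nm)
        if not np.isfinite(t) or t < 0:
            raise InputError(f"layer thickness must be finite and >= 0, got {t}")


@dataclass(frozen=True)
class LayerStack:
    """Ordered optical multilayer: ambient → layers → semi-infinite substrate."""

    substrate: DispersionTable
    layers: tuple[Layer, ...] = ()
    ambient: DispersionTable = field(default_factory=lambda: constant_index(1.0, material_id="air"))

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))


@dataclass(frozen=True)
class Spectrum:
    """Reflectance sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise InputError("empty wavelength grid")
        if v.shape != w.shape:
            raise InputError("wavelengths and values must have equal length")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise InputError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, self.values * factor)


def _cos_theta(n: np.ndarray, n0_sin0: np.ndarray) -> np.ndarray:
    # Snell: ñ_j sinθ_j = ñ_0 sinθ_0 ; principal sqrt keeps Re(cosθ) >= 0
    s = n0_sin0 / n
    return np.sqrt(1.0 - s * s + 0j)


def _amplitude_r(stack: LayerStack, lam: np.ndarray, angle_rad: float,
                 pol: str) -> np.ndarray:
    n0 = stack.ambient.complex_index(lam)
    if np.any(np.abs(n0.imag) > 0):
        raise InputError("ambient medium must be lossless")
    n0_sin0 = n0 * np.sin(angle_rad)

    def admittance(n: np.ndarray) -> np.ndarray:
        ct = _cos_theta(n, n0_sin0)
        return n * ct if pol == "s" else n / ct

    eta0 = admittance(n0)
    eta_sub = admittance(stack.substrate.complex_index(lam))

    m11 = np.ones_like(lam, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    for layer in stack.layers:
        n = layer.dispersion.complex_index(lam)
        ct = _cos_theta(n, n0_sin0)
        delta = 2.0 * np.pi * n * layer.thickness_nm * ct / lam
        eta = n * ct if pol == "s" else n / ct
        c, s = np.cos(delta), np.sin(delta)
        a11, a12, a21, a22 = c, 1j * s / eta, 1j * eta * s, c
        m11, m12, m21, m22 = (m11 * a11 + m12 * a21, m11 * a12 + m12 * a22,
                              m21 * a11 + m22 * a21, m21 * a12 + m22 * a22)

    b = m11 + m12 * eta_sub
    c = m21 + m22 * eta_sub
    return (eta0 * b - c) / (eta0 * b + c)


def tmm_reflectance(stack: LayerStack,
                    wavelengths_nm: np.ndarray | None = None,
                    angle_deg: float = 0.0,
                    polarization: str = "unpolarized") -> Spectrum:
    """Coherent reflectance of *stack* on a wavelength grid.

    Parameters
    ----------
    stack
        Ambient / finite layers / semi-infinite substrate.
    wavelengths_nm
        Strictly increasing grid in nm; default 360-830 nm at 1 nm.
    angle_deg
        Angle of incidence from the surface normal, ``0 <= angle < 90``.
    polarization
        ``"s"``, ``"p"`` or ``"unpolarized"`` (mean of s and p intensities).

    Returns
    -------
    Spectrum
        Reflectance per wavelength, each value in ``[0, 1]`` for passive
        stacks.
    """
    lam = default_grid() if wavelengths_nm is None else np.asarray(
        wavelengths_nm, dtype=float)
    if lam.size == 0:
        raise InputError("empty wavelength grid")
    if not 0.0 <= angle_deg < 90.0:
        raise InputError(f"angle must be in [0, 90) degrees, got {angle_deg}")
    if polarization not in ("s", "p", "unpolarized"):
        raise InputError(f"unknown polarization {polarization!r}")

    angle = np.deg2rad(angle_deg)
    if polarization == "unpolarized":
        rs = np.abs(_amplitude_r(stack, lam, angle, "s")) ** 2
        rp = np.abs(_amplitude_r(stack, lam, angle, "p")) ** 2
        refl = 0.5 * (rs + rp)
    else:
        refl = np.abs(_amplitude_r(stack, lam, angle, polarization)) ** 2
    return Spectrum(lam, refl)
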