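"""Forward model of the nanocavity-on-silicon (NOS) slide's structural color.

A tissue section of (assumed non-dispersive) refractive index ``n`` and
thickness ``d`` sits on a Si₃N₄ nanocavity on a semi-infinite Si wafer.
The air/tissue/Si₃N₄/Si stack is evaluated with the transfer-matrix method
on the 360-830 nm grid and pushed through the CIE colour chain
(XYZ → chromaticity → CIELAB → sRGB).

The default cavity thickness (111 nm) renders the green-family slide used
for the sensitivity scans; the six bundled cavity presets span the slide
colour palette.  The just-noticeable-difference scan reports the smallest
fractional perturbation of tissue index or thickness whose colour shift
reaches a CIE76 ΔE*ab threshold (default 2.3, a classical JND).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import color as _color
from .dispersion import DispersionTable, bk7_glass, constant_index, silicon, silicon_nitride
from .errors import InputError, ThresholdNotReachedError
from .tmm import Layer, LayerStack, Spectrum, default_grid, tmm_reflectance

__all__ = [
    "SlideConfig", "SlideColor", "JndScanResult", "CAVITY_PRESETS_NM",
    "simulate_slide_color", "simulate_glass_color", "sweep_tissue_index",
    "sweep_cavity_thickness", "jnd_fraction_scan",
]

#: Si₃N₄ cavity thicknesses of the six slide colour variants (nm)
CAVITY_PRESETS_NM = (268.0, 243.0, 197.0, 158.0, 111.0, 85.0)

#: default "green slide" cavity (nm); configurable in SlideConfig
GREEN_CAVITY_NM = 111.0

#: classical just-noticeable CIE76 colour difference
DEFAULT_JND_THRESHOLD = 2.3


class SlideConfig:
    """Slide geometry plus the colorimetric conversion settings.

    Parameters
    ----------
    cavity_thickness_nm
        Si₃N₄ film thickness; default the green-slide preset (111 nm).
    illuminant
        ``"D65"`` (bundled daylight approximation, default) or ``"E"``.
    angle_deg, polarization
        Incidence geometry passed to the transfer-matrix solver.
    jnd_threshold
        ΔE*ab threshold used by :func:`jnd_fraction_scan`.
    wavelengths_nm
        Spectral grid; default 360-830 nm at 1 nm.
    """

    def __init__(self,
                 cavity_thickness_nm: float = GREEN_CAVITY_NM,
                 illuminant: str = "D65",
                 angle_deg: float = 0.0,
                 polarization: str = "unpolarized",
                 jnd_threshold: float = DEFAULT_JND_THRESHOLD,
                 wavelengths_nm: np.ndarray | None = None,
                 cavity_material: DispersionTable | None = None,
                 substrate: DispersionTable | None = None,
                 ambient: DispersionTable | None = None) -> None:
        if cavity_thickness_nm < 0:
            raise InputError("cavity thickness must be >= 0")
        self.cavity_thickness_nm = float(cavity_thickness_nm)
        self.illuminant_name = illuminant
        self.angle_deg = float(angle_deg)
        self.polarization = polarization
        self.jnd_threshold = float(jnd_threshold)
        self.wavelengths_nm = (default_grid() if wavelengths_nm is None
                               else np.asarray(wavelengths_nm, dtype=float))
        self.cavity_material = cavity_material or silicon_nitride()
        self.substrate = substrate or silicon()
        self.ambient = ambient or constant_index(1.0, material_id="air")
        # resample the colour tables once; every simulate call reuses them
        self.cmf = _color.cie1931_observer().resampled(self.wavelengths_nm)
        self.illuminant_spd = _color.illuminant(illuminant, self.wavelengths_nm)
        self.white = _color.white_point(self.illuminant_spd, self.cmf,
                                        self.wavelengths_nm)

    def with_cavity(self, cavity_thickness_nm: float) -> "SlideConfig":
        return SlideConfig(cavity_thickness_nm, self.illuminant_name,
                           self.angle_deg, self.polarization,
                           self.jnd_threshold, self.wavelengths_nm,
                           self.cavity_material, self.substrate, self.ambient)


@dataclass(frozen=True)
class SlideColor:
    """Full colour record of one simulated slide/tissue combination."""

    spectrum: Spectrum
    xyz: _color.Tristimulus
    xy: tuple[float, float]
    lab: _color.LabPoint
    srgb: _color.SRGBColor

    def to_record(self) -> dict:
        return {"X": self.xyz.X, "Y": self.xyz.Y, "Z": self.xyz.Z,
                "x": self.xy[0], "y": self.xy[1],
                "L": self.lab.L, "a": self.lab.a, "b": self.lab.b,
                "srgb": [self.srgb.r, self.srgb.g, self.srgb.b],
                "clipped": self.srgb.clipped}


def _colorize(config: SlideConfig, spectrum: Spectrum) -> SlideColor:
    xyz = _color.spectrum_to_tristimulus(spectrum, config.illuminant_spd,
                                         config.cmf)
    xy = _color.tristimulus_to_xy(xyz) if xyz.X + xyz.Y + xyz.Z > 0 else (
        1.0 / 3.0, 1.0 / 3.0)
    lab = _color.xyz_to_lab(xyz, config.white)
    srgb = _color.xyz_to_srgb(xyz, white=config.white)
    return SlideColor(spectrum, xyz, xy, lab, srgb)


def simulate_slide_color(config: SlideConfig,
                         tissue_n: float,
                         tissue_thickness_nm: float,
                         cavity_thickness_nm: float | None = None) -> SlideColor:
    """Colour of a tissue layer on the NOS slide.

    ``tissue_thickness_nm = 0`` reproduces the bare slide.  The tissue is
    modelled as a non-dispersive lossless film of index *tissue_n*.
    """
    if tissue_thickness_nm < 0:
        raise InputError("tissue thickness must be >= 0")
    cavity = (config.cavity_thickness_nm if cavity_thickness_nm is None
              else float(cavity_thickness_nm))
    layers = []
    if tissue_thickness_nm > 0:
        layers.append(Layer(constant_index(tissue_n, material_id="tissue"),
                            tissue_thickness_nm))
    if cavity > 0:
        layers.append(Layer(config.cavity_material, cavity))
    stack = LayerStack(substrate=config.substrate, layers=tuple(layers),
                       ambient=config.ambient)
    spectrum = tmm_reflectance(stack, config.wavelengths_nm,
                               config.angle_deg, config.polarization)
    return _colorize(config, spectrum)


def simulate_glass_color(config: SlideConfig,
                         tissue_n: float,
                         tissue_thickness_nm: float) -> SlideColor:
    """Weak-contrast plain-glass rendering (synthetic-only control model).

    Brightfield transmission through a tissue film on a glass slide is
    proxied by ``T(λ) = 1 − R(λ)`` of the air/tissue/glass stack; with no
    nanocavity the interface reflections are small, so the colour barely
    responds to the tissue's index — the control against which the NOS
    slide's colour contrast is compared.
    """
    if tissue_thickness_nm < 0:
        raise InputError("tissue thickness must be >= 0")
    layers = []
    if tissue_thickness_nm > 0:
        layers.append(Layer(constant_index(tissue_n, material_id="tissue"),
                            tissue_thickness_nm))
    stack = LayerStack(substrate=bk7_glass(), layers=tuple(layers),
                       ambient=config.ambient)
    refl = tmm_reflectance(stack, config.wavelengths_nm, config.angle_deg,
                           config.polarization)
    transmitted = Spectrum(refl.wavelengths_nm, 1.0 - refl.values)
    return _colorize(config, transmitted)


def sweep_tissue_index(config: SlideConfig, tissue_n_values: np.ndarray,
                       tissue_thickness_nm: float) -> list[SlideColor]:
    """Colour trajectory over a range of tissue refractive indices."""
    return [simulate_slide_color(config, float(n), tissue_thickness_nm)
            for n in np.asarray(tissue_n_values, dtype=float)]


def sweep_cavity_thickness(config: SlideConfig, cavities_nm=CAVITY_PRESETS_NM,
                           tissue_n: float = 1.0,
                           tissue_thickness_nm: float = 0.0) -> list[SlideColor]:
    """Colours of the slide palette across cavity thicknesses."""
    return [simulate_slide_color(config, tissue_n, tissue_thickness_nm,
                                 cavity_thickness_nm=float(c))
            for c in cavities_nm]


@dataclass(frozen=True)
class JndScanResult:
    """Outcome of a just-noticeable-difference perturbation scan.

    ``delta_plus``/``delta_minus`` are the smallest fractional increases /
    decreases of the scanned parameter reaching the ΔE threshold (``None``
    if unreachable within the scan limit); ``delta_min`` is their minimum.
    All fractions are dimensionless; multiply by 100 for percent.
    """

    parameter: str
    threshold: float
    delta_plus: float | None
    delta_minus: float | None

    @property
    def delta_min(self) -> float:
        found = [d for d in (self.delta_plus, self.delta_minus)
                 if d is not None]
        return min(found)

    @property
    def percent(self) -> float:
        return 100.0 * self.delta_min


def _perturbed_lab(config: SlideConfig, tissue_n: float, thickness_nm: float,
                   parameter: str, fraction: float) -> _color.LabPoint:
    if parameter == "tissue_n":
        return simulate_slide_color(config, tissue_n * (1.0 + fraction),
                                    thickness_nm).lab
    if parameter == "tissue_thickness":
        return simulate_slide_color(config, tissue_n,
                                    thickness_nm * (1.0 + fraction)).lab
    raise InputError(f"unknown scan parameter {parameter!r}")


def jnd_fraction_scan(config: SlideConfig,
                      tissue_n: float,
                      tissue_thickness_nm: float,
                      parameter: str = "tissue_n",
                      threshold: float | None = None,
                      max_fraction: float = 0.5,
                      rtol: float = 1e-3) -> JndScanResult:
    """Smallest fractional parameter change producing a noticeable colour shift.

    For each direction (+/−) the bracket is grown geometrically from 1e-4
    until ΔE*ab against the unperturbed baseline reaches *threshold*, then
    bisected to relative tolerance *rtol*.  Directions that never reach the
    threshold within ``|δ| <= max_fraction`` report ``None``; if both fail,
    :class:`~noscolor.errors.ThresholdNotReachedError` is raised.
    """
    thr = config.jnd_threshold if threshold is None else float(threshold)
    if thr < 0:
        raise InputError("JND threshold must be >= 0")
    if thr == 0:
        return JndScanResult(parameter, thr, 0.0, 0.0)
    baseline = simulate_slide_color(config, tissue_n, tissue_thickness_nm).lab

    def excess(fraction: float) -> float:
        lab = _perturbed_lab(config, tissue_n, tissue_thickness_nm,
                             parameter, fraction)
        return _color.delta_e(baseline, lab) - thr

    def scan(sign: float) -> float | None:
        hi = 1e-4
        while excess(sign * hi) < 0:
            hi *= 1.6
            if hi > max_fraction:
                return None
        lo = 0.0
        while hi - lo > rtol * hi:
            mid = 0.5 * (lo + hi)
            if excess(sign * mid) >= 0:
                hi = mid
            else:
                lo = mid
        return hi

    plus, minus = scan(+1.0), scan(-1.0)
    if plus is None and minus is None:
        raise ThresholdNotReachedError(
            f"ΔE threshold {thr} unreachable within ±{max_fraction:.0%} "
            f"perturbation of {parameter}")
    return JndScanResult(parameter, thr, plus, minus)
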