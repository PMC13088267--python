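"""Material dispersion tables.

A :class:`DispersionTable` holds tabulated optical constants ``(wavelength
[nm], n, k)`` and interpolates them linearly onto an arbitrary wavelength
grid as a complex refractive index.

Sign convention
---------------
The complex index is returned as ``ñ(λ) = n(λ) − i·k(λ)`` under the
``exp(+iωt)`` time convention, so a positive extinction coefficient ``k``
attenuates a forward-propagating wave.  The transfer-matrix code in
:mod:`noscolor.tmm` assumes exactly this convention.

Bundled tables (``noscolor/data``) are synthetic stand-ins generated from
closed-form dispersion models (see ``scripts/make_reference_tables.py``);
they reproduce the qualitative visible-range optics of crystalline Si and
Si₃N₄ but are not measured datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError, WavelengthRangeError

__all__ = [
    "DispersionTable",
    "constant_index",
    "load_dispersion_csv",
    "silicon",
    "silicon_nitride",
    "bk7_glass",
]


@dataclass(frozen=True)
class DispersionTable:
    """Tabulated optical constants of one material.

    Parameters
    ----------
    material_id
        Free-form label ("si", "tissue", ...).
    wavelengths_nm
        Strictly increasing sample wavelengths in nanometres.
    n
        Real refractive index at each sample, ``> 0``.
    k
        Extinction coefficient at each sample, ``>= 0``.
    """

    material_id: str
    wavelengths_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = (np.zeros_like(n) if self.k is None
             else np.asarray(self.k, dtype=float))
        if w.ndim != 1 or w.size < 2:
            raise InputError("dispersion table needs >= 2 samples")
        if n.shape != w.shape or k.shape != w.shape:
            raise InputError("wavelengths, n and k must have equal length")
        if not np.all(np.diff(w) > 0):
            raise InputError("wavelengths must be strictly increasing")
        if np.any(n <= 0):
            raise InputError("refractive index must be positive")
        if np.any(k < 0):
            raise InputError("extinction coefficient must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def complex_index(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Interpolate ``ñ(λ) = n − i·k`` at the requested wavelengths.

        Linear interpolation between tabulated samples; no extrapolation —
        a wavelength outside the table span raises
        :class:`~noscolor.errors.WavelengthRangeError`.
        """
        lam = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        lo, hi = self.span
        if lam.size == 0:
            raise InputError("empty wavelength grid")
        if lam.min() < lo or lam.max() > hi:
            raise WavelengthRangeError(
                f"{self.material_id}: requested {lam.min():g}-{lam.max():g} nm "
                f"outside tabulated span {lo:g}-{hi:g} nm")
        n = np.interp(lam, self.wavelengths_nm, self.n)
        k = np.interp(lam, self.wavelengths_nm, self.k)
        return n - 1j * k


def constant_index(n: float, k: float = 0.0,
                   material_id: str | None = None,
                   span_nm: tuple[float, float] = (200.0, 2000.0),
                   ) -> DispersionTable:
    """Non-dispersive material with constant ``n`` and ``k`` over *span_nm*."""
    mid = material_id or f"const(n={n:g},k={k:g})"
    w = np.array(span_nm, dtype=float)
    return DispersionTable(mid, w, np.full(2, float(n)), np.full(2, float(k)))


def load_dispersion_csv(path, material_id: str | None = None) -> DispersionTable:
    """Read a ``wavelength_nm,n,k`` CSV (header required) into a table."""
    df = pd.read_csv(path)
    missing = {"wavelength_nm", "n"} - set(df.columns)
    if missing:
        raise InputError(f"dispersion CSV lacks columns: {sorted(missing)}")
    k = df["k"].to_numpy() if "k" in df.columns else None
    mid = material_id or str(path)
    return DispersionTable(mid, df["wavelength_nm"].to_numpy(),
                           df["n"].to_numpy(), k)


def _bundled(name: str, material_id: str) -> DispersionTable:
    with resources.files("noscolor.data").joinpath(name).open("r") as fh:
        return load_dispersion_csv(fh, material_id=material_id)


def silicon() -> DispersionTable:
    """Bundled synthetic crystalline-Si optical constants (visible range)."""
    return _bundled("si_nk_synthetic.csv", "si")


def silicon_nitride() -> DispersionTable:
    """Bundled synthetic Si₃N₄ Sellmeier index (lossless in the visible)."""
    return _bundled("si3n4_nk_synthetic.csv", "si3n4")


def bk7_glass() -> DispersionTable:
    """Plain crown-glass slide, modelled non-dispersive (n = 1.523)."""
    return constant_index(1.523, material_id="glass")
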