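"""Regenerate the bundled reference tables under src/noscolor/data/.

All four CSVs are synthetic stand-ins computed from closed-form models, not
copies of measured tabulations:

* ``cmf_cie1931_2deg_synthetic.csv`` — CIE 1931 2-degree standard-observer
  colour-matching functions from the multi-lobe piecewise-Gaussian analytic
  fit of Wyman, Sloan & Shirley (2013), sampled 360-830 nm at 1 nm and
  rescaled so all three functions share the same sum on that grid (the
  equal-energy stimulus then maps exactly to chromaticity (1/3, 1/3)).
* ``illuminant_d65_synthetic.csv`` — daylight illuminant approximated by a
  Planckian radiator at 6504 K, normalised to 100 at 560 nm.
* ``si_nk_synthetic.csv`` — crystalline-silicon n, k: smooth monotone
  interpolation of handbook-scale visible-range values (high index ~4-7,
  strong absorption toward the near-UV, nearly transparent in the red).
* ``si3n4_nk_synthetic.csv`` — silicon-nitride index from a Sellmeier
  dispersion relation (lossless in the visible).

Run from the repository root:  python scripts/make_reference_tables.py
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "noscolor" / "data"

GRID = np.arange(360.0, 831.0, 1.0)


def _lobe(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def make_cmf() -> pd.DataFrame:
    lam = GRID
    xbar = (1.056 * _lobe(lam, 599.8, 37.9, 31.0)
            + 0.362 * _lobe(lam, 442.0, 16.0, 26.7)
            - 0.065 * _lobe(lam, 501.1, 20.4, 26.2))
    ybar = (0.821 * _lobe(lam, 568.8, 46.9, 40.5)
            + 0.286 * _lobe(lam, 530.9, 16.3, 31.1))
    zbar = (1.217 * _lobe(lam, 437.0, 11.8, 36.0)
            + 0.681 * _lobe(lam, 459.0, 26.0, 13.8))
    # the fit leaves tiny negative tails on xbar; the observer is non-negative
    xbar = np.clip(xbar, 0.0, None)
    # equal-integral normalisation: equal-energy white at exactly (1/3, 1/3)
    xbar *= ybar.sum() / xbar.sum()
    zbar *= ybar.sum() / zbar.sum()
    return pd.DataFrame({"wavelength_nm": lam, "xbar": xbar, "ybar": ybar,
                         "zbar": zbar})


def make_d65() -> pd.DataFrame:
    lam_m = GRID * 1e-9
    c2 = 1.4388e-2  # m K, second radiation constant
    T = 6504.0
    spd = lam_m ** -5 / np.expm1(c2 / (lam_m * T))
    spd = 100.0 * spd / spd[np.argmin(np.abs(GRID - 560.0))]
    return pd.DataFrame({"wavelength_nm": GRID, "value": spd})


# visible-range crystalline Si optical constants, handbook scale (synthetic)
_SI_ANCHORS = np.array([
    [340.0, 5.10, 2.95], [350.0, 5.44, 2.99], [360.0, 6.00, 2.92],
    [370.0, 6.87, 2.14], [380.0, 6.55, 0.92], [390.0, 5.98, 0.46],
    [400.0, 5.57, 0.39], [420.0, 5.01, 0.24], [440.0, 4.75, 0.16],
    [460.0, 4.55, 0.12], [480.0, 4.42, 0.090], [500.0, 4.30, 0.073],
    [520.0, 4.20, 0.060], [540.0, 4.12, 0.048], [560.0, 4.05, 0.040],
    [580.0, 3.99, 0.032], [600.0, 3.94, 0.025], [620.0, 3.90, 0.022],
    [640.0, 3.87, 0.018], [660.0, 3.84, 0.015], [680.0, 3.81, 0.013],
    [700.0, 3.78, 0.011], [720.0, 3.76, 0.009], [740.0, 3.73, 0.008],
    [760.0, 3.72, 0.007], [780.0, 3.70, 0.006], [800.0, 3.69, 0.005],
    [830.0, 3.67, 0.004], [850.0, 3.66, 0.004],
])


def make_si() -> pd.DataFrame:
    return pd.DataFrame({"wavelength_nm": _SI_ANCHORS[:, 0],
                         "n": _SI_ANCHORS[:, 1], "k": _SI_ANCHORS[:, 2]})


def make_si3n4() -> pd.DataFrame:
    lam = np.arange(340.0, 851.0, 5.0)
    lu = lam / 1000.0  # um
    n2 = (1.0 + 3.0249 * lu ** 2 / (lu ** 2 - 0.1353406 ** 2)
          + 40314.0 * lu ** 2 / (lu ** 2 - 1239.842 ** 2))
    return pd.DataFrame({"wavelength_nm": lam, "n": np.sqrt(n2),
                         "k": np.zeros_like(lam)})


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    make_cmf().to_csv(DATA / "cmf_cie1931_2deg_synthetic.csv", index=False,
                      float_format="%.8g")
    make_d65().to_csv(DATA / "illuminant_d65_synthetic.csv", index=False,
                      float_format="%.8g")
    make_si().to_csv(DATA / "si_nk_synthetic.csv", index=False,
                     float_format="%.6g")
    make_si3n4().to_csv(DATA / "si3n4_nk_synthetic.csv", index=False,
                        float_format="%.8g")
    for p in sorted(DATA.glob("*.csv")):
        print(p.name, p.stat().st_size, "bytes")


if __name__ == "__main__":
    main()
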