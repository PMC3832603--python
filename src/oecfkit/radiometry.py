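"""Spectral bookkeeping and the forward exposure model.

Converts energy radiance to photon flux, bins spectra, applies neutral
density filters, and evaluates the standard camera equation

    n = pi * A_d * t_int / (4 * f#^2 * (1 + m)^2) * sum L(l) S(l) T(l) dl

relating the photoelectron-generating exposure to scene radiance, lens
transmittance, sensor sensitivity and the selected exposure settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import Avogadro, c as speed_of_light, h as planck

from .errors import DataError

__all__ = [
    "Spectrum",
    "ExposureSettings",
    "energy_to_photon_flux",
    "bin_spectrum",
    "exposure_integral",
    "apply_nd_filter",
    "read_spectrum",
    "write_spectrum",
]

#: Valid spectrum kinds and their units.
KINDS = {
    "radiance_energy": "W m-2 sr-1 nm-1",
    "radiance_photon": "umol m-2 s-1 nm-1 sr-1",
    "sensitivity": "dimensionless",
    "transmittance": "dimensionless",
}


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral quantity on a strictly increasing nm grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "radiance_energy"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in KINDS:
            raise TypeError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or wl.size == 0 or wl.shape != vals.shape:
            raise DataError("wavelengths and values must be equal-length 1-D")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise DataError("spectrum contains non-finite entries")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise DataError("wavelengths must be strictly increasing")
        if self.kind == "transmittance" and (
            np.any(vals < 0) or np.any(vals > 1)
        ):
            raise DataError("transmittance values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


@dataclass(frozen=True)
class ExposureSettings:
    """Lens/shutter configuration entering the camera equation."""

    f_number: float
    t_int_s: float
    magnification: float = 0.0
    detector_area_m2: float = 1.0e-10
    iso: int = 200  # informational only

    def __post_init__(self) -> None:
        if self.f_number <= 0:
            raise ValueError("f_number must be > 0")
        if self.t_int_s <= 0:
            raise ValueError("t_int_s must be > 0")
        if self.magnification < 0:
            raise ValueError("magnification must be >= 0")
        if self.detector_area_m2 <= 0:
            raise ValueError("detector_area_m2 must be > 0")


def energy_to_photon_flux(spec: Spectrum) -> Spectrum:
    """Convert an energy-radiance spectrum to photon flux in umol.

    Each per-nm value v(l) becomes v(l) * l / (h c N_A) * 1e6 with the
    wavelength l in metres, i.e. watts -> micromoles of photons per second.
    """
    if spec.kind != "radiance_energy":
        raise TypeError(
            f"expected kind 'radiance_energy', got {spec.kind!r}"
        )
    wl_m = spec.wavelengths_nm * 1e-9
    factor = wl_m / (planck * speed_of_light * Avogadro) * 1e6
    return Spectrum(spec.wavelengths_nm, spec.values * factor, "radiance_photon")


def bin_spectrum(spec: Spectrum, bin_width_nm: float) -> Spectrum:
    """Average a spectrum into contiguous bins of width ``bin_width_nm``.

    Output wavelengths are bin centres; each output value is the arithmetic
    mean of the input samples falling in that bin (per-nm units preserved).
    Empty bins are dropped.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    wl = spec.wavelengths_nm
    if wl.size > 1:
        spacing = float(np.min(np.diff(wl)))
        if bin_width_nm <= spacing:
            raise ValueError(
                f"bin width {bin_width_nm} nm must exceed sample spacing "
                f"{spacing} nm"
            )
    edges = np.arange(wl[0], wl[-1] + bin_width_nm, bin_width_nm)
    if edges[-1] <= wl[-1]:
        edges = np.append(edges, edges[-1] + bin_width_nm)
    idx = np.digitize(wl, edges) - 1
    n_bins = edges.size - 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=spec.values, minlength=n_bins)
    keep = counts > 0
    centres = (edges[:-1] + bin_width_nm / 2.0)[keep]
    means = sums[keep] / counts[keep]
    return Spectrum(centres, means, spec.kind)


def _overlap_grid(
    radiance: Spectrum, sens: Spectrum, trans: Spectrum
) -> np.ndarray:
    """Radiance grid restricted to the spectra overlap and S(l) support."""
    nz = np.nonzero(sens.values)[0]
    if nz.size == 0:
        raise DataError("sensitivity is zero everywhere")
    lo = max(
        radiance.wavelengths_nm[0],
        sens.wavelengths_nm[nz[0]],
        trans.wavelengths_nm[0],
    )
    hi = min(
        radiance.wavelengths_nm[-1],
        sens.wavelengths_nm[nz[-1]],
        trans.wavelengths_nm[-1],
    )
    grid = radiance.wavelengths_nm
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        raise DataError("spectra share no usable wavelength overlap")
    return grid


def exposure_integral(
    radiance: Spectrum,
    sens: Spectrum,
    trans: Spectrum,
    settings: ExposureSettings,
) -> float:
    """Photoelectron-generating exposure (photon amount, umol).

    Spectra are linearly interpolated onto the radiance grid restricted to
    their common overlap and the non-zero support of the sensitivity, then
    integrated with the trapezoidal rule and scaled by the camera-equation
    prefactor. Scales linearly in integration time and as 1/f#^2.
    """
    if radiance.kind != "radiance_photon":
        raise TypeError("radiance must be of kind 'radiance_photon'")
    if sens.kind != "sensitivity":
        raise TypeError("sens must be of kind 'sensitivity'")
    if trans.kind != "transmittance":
        raise TypeError("trans must be of kind 'transmittance'")
    grid = _overlap_grid(radiance, sens, trans)
    L = np.interp(grid, radiance.wavelengths_nm, radiance.values)
    S = np.interp(grid, sens.wavelengths_nm, sens.values)
    T = np.interp(grid, trans.wavelengths_nm, trans.values)
    integral = float(np.trapezoid(L * S * T, grid))
    pref = (
        math.pi
        * settings.detector_area_m2
        * settings.t_int_s
        / (4.0 * settings.f_number**2 * (1.0 + settings.magnification) ** 2)
    )
    return pref * integral


def apply_nd_filter(spec: Spectrum, optical_density: float) -> Spectrum:
    """Attenuate a spectrum by a neutral density filter of the given OD.

    Values scale by 10**(-OD); stacked filters add their ODs.
    """
    if optical_density < 0:
        raise ValueError("optical density must be >= 0")
    return replace(spec, values=spec.values * 10.0 ** (-optical_density))


def read_spectrum(path: str | Path, kind: str = "radiance_energy") -> Spectrum:
    """Read a two-column (wavelength nm, value) delimited text file.

    Whitespace or comma delimited; an optional single header line is
    skipped automatically.
    """
    df = pd.read_csv(
        path, sep=None, engine="python", comment="#", header=None,
        skip_blank_lines=True,
    )
    # Drop a header row if the first row is not numeric.
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    arr = df.iloc[:, :2].apply(pd.to_numeric).to_numpy(dtype=float)
    if arr.shape[0] == 0:
        raise DataError(f"no spectral samples in {path}")
    return Spectrum(arr[:, 0], arr[:, 1], kind)


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV with a header."""
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths_nm, "value": spec.values}
    ).to_csv(path, index=False)
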