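"""Synthetic fixture generation: exposure ladders, OECF datasets, images.

Ladders reproduce the three measurement protocols (neutral density
filters, f-stop series, diffuse reflectance targets). Synthetic OECF
datasets and patch images apply a known biexponential gain to true
exposures, add Gaussian read noise in intensity levels, and quantise to
the configured bit depth — every downstream stage is testable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biexp import BiexpParams, eval_biexp
from .errors import DataError
from .linearizer import RawImage
from .oecf_core import OECFDataset

__all__ = [
    "ExposureLadder",
    "SyntheticTruth",
    "make_ladder",
    "default_ladder",
    "simulate_oecf",
    "simulate_image",
]

#: Nominal single-filter ODs plus the stacked combinations used alongside.
ND_OD_SINGLE = (0.1, 0.2, 0.5, 1.0)
ND_OD_COMBINED = (0.3, 0.7, 1.2, 1.5)
#: Near-UV diffuse-target reflectances (percent).
REFLECTANCES_PCT = (86.0, 60.0, 51.0, 15.0, 2.0)


@dataclass(frozen=True)
class ExposureLadder:
    """Labelled true-exposure steps from one attenuation protocol."""

    labels: tuple[str, ...]
    exposures: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        expo = np.asarray(self.exposures, dtype=float)
        object.__setattr__(self, "exposures", expo)
        if len(self.labels) != expo.size:
            raise DataError("labels and exposures differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise DataError("ladder labels must be unique")
        if np.any(expo <= 0):
            raise DataError("ladder exposures must be > 0")

    def __len__(self) -> int:
        return int(self.exposures.size)


@dataclass
class SyntheticTruth:
    """Ground-truth gain model plus noise/quantisation settings."""

    true_params: BiexpParams
    noise_sd: float = 1.0
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")


def make_ladder(base_exposure: float, mode: str, **params) -> ExposureLadder:
    """Build an exposure ladder from a base exposure and a protocol.

    mode="nd": ``ods`` (default: the four single filters plus their
    stacked combinations and OD 0); exposures base * 10**(-OD).
    mode="fstop": ``f_numbers`` and ``f_ref``; exposures base*(f_ref/f)**2.
    mode="reflectance": ``reflectances_pct``; exposures base * R / 100.
    """
    if base_exposure <= 0:
        raise ValueError("base_exposure must be > 0")
    if mode == "nd":
        ods = params.get(
            "ods", (0.0,) + ND_OD_SINGLE + ND_OD_COMBINED
        )
        if len(ods) == 0:
            raise ValueError("empty OD list")
        ods = tuple(sorted(ods))
        return ExposureLadder(
            labels=tuple(f"OD{od:g}" for od in ods),
            exposures=base_exposure * 10.0 ** (-np.asarray(ods, dtype=float)),
            provenance="nd_filters",
        )
    if mode == "fstop":
        f_numbers = params.get("f_numbers")
        if not f_numbers:
            raise ValueError("fstop mode needs f_numbers")
        f_ref = params.get("f_ref", min(f_numbers))
        f_arr = np.asarray(sorted(f_numbers), dtype=float)
        return ExposureLadder(
            labels=tuple(f"f{f:g}" for f in f_arr),
            exposures=base_exposure * (f_ref / f_arr) ** 2,
            provenance="f_stops",
        )
    if mode == "reflectance":
        refl = params.get("reflectances_pct", REFLECTANCES_PCT)
        if len(refl) == 0:
            raise ValueError("empty reflectance list")
        r_arr = np.asarray(refl, dtype=float)
        return ExposureLadder(
            labels=tuple(f"R{r:g}%" for r in r_arr),
            exposures=base_exposure * r_arr / 100.0,
            provenance="reflectance_targets",
        )
    raise ValueError(f"unknown ladder mode {mode!r}")


def default_ladder(truth: SyntheticTruth, n_levels: int = 12) -> ExposureLadder:
    """Log-spaced ladder spanning the truth curve's dynamic range.

    Levels run from E_max/300 to 1.1*E_max (E_max solved from the truth
    parameters at g_max), covering both exponential scales of the gain.
    """
    from .biexp import invert_biexp

    p = truth.true_params
    e_max = p.e_max if p.e_max is not None else invert_biexp(p, p.g_max)
    expo = np.geomspace(e_max / 300.0, 1.1 * e_max, n_levels)
    return ExposureLadder(
        labels=tuple(f"L{i}" for i in range(n_levels)),
        exposures=expo,
        provenance="nd_filters",
    )


def simulate_oecf(
    truth: SyntheticTruth,
    ladder: ExposureLadder | None = None,
    replicates: int = 8,
    channel: str = "synthetic",
) -> OECFDataset:
    """Measure a synthetic OECF: gain + Gaussian noise + quantisation.

    Each ladder step is measured ``replicates`` times; with the default
    12-level ladder and 8 replicates the dataset has 96 points. Responses
    are round(clip(f(E) + N(0, noise_sd), 0, 2**bit_depth - 1)).
    """
    if ladder is None:
        ladder = default_ladder(truth)
    rng = np.random.default_rng(truth.seed)
    full = 2**truth.bit_depth - 1
    expo = np.repeat(ladder.exposures, replicates)
    clean = eval_biexp(truth.true_params, expo)
    noisy = clean + rng.normal(0.0, truth.noise_sd, size=expo.size) \
        if truth.noise_sd > 0 else clean
    resp = np.round(np.clip(noisy, 0, full))
    return OECFDataset(
        channel=channel,
        exposure=expo,
        response=resp,
        bit_depth=truth.bit_depth,
        g_max=truth.true_params.g_max,
    )


def simulate_image(
    truth: SyntheticTruth,
    exposure_map: np.ndarray,
    dark_level: float = 0.0,
    channel: str = "synthetic",
) -> tuple[RawImage, RawImage]:
    """Render a raw image (and matching dark frame) from an exposure map.

    Per pixel: round(clip(f(E) + dark_level + noise, 0, full scale)); the
    dark frame is round(clip(dark_level + noise, ...)) with an independent
    stream from the same master seed.
    """
    emap = np.asarray(exposure_map, dtype=float)
    if np.any(emap < 0):
        raise DataError("exposure map must be >= 0")
    rng = np.random.default_rng(truth.seed)
    full = 2**truth.bit_depth - 1
    signal = eval_biexp(truth.true_params, emap) + dark_level
    if truth.noise_sd > 0:
        signal = signal + rng.normal(0.0, truth.noise_sd, size=emap.shape)
    img = RawImage(
        pixels=np.round(np.clip(signal, 0, full)).astype(np.int64),
        bit_depth=truth.bit_depth,
        channel=channel,
    )
    dark = np.full(emap.shape, float(dark_level))
    if truth.noise_sd > 0:
        dark = dark + rng.normal(0.0, truth.noise_sd, size=emap.shape)
    dark_img = RawImage(
        pixels=np.round(np.clip(dark, 0, full)).astype(np.int64),
        bit_depth=truth.bit_depth,
        channel=channel,
    )
    return img, dark_img
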