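"""OECF data model and normalisation protocol.

An OECF (opto-electronic conversion function) dataset holds measured
(exposure, response) pairs for one colour channel together with its
normalisation anchors: ``g_max`` (the maximum response included in the
characterisation, below full saturation), ``e_max`` (the exposure producing
``g_max``) and ``p_min`` (the smallest linearisable response).

Normalisation divides the response axis by 2**bit_depth - 1 and the
exposure axis by ``e_max``, mapping both onto [0, ~1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, EstimationError, StateError

__all__ = [
    "OECFDataset",
    "normalise_dataset",
    "denormalise_dataset",
    "estimate_e_max",
    "filter_p_min",
    "average_replicates",
    "read_oecf_csv",
    "write_oecf_csv",
]

MIN_POINTS_FIT = 6       # biexponential fit
MIN_POINTS_BEZIER = 4    # cubic Bezier is underdetermined below this


@dataclass
class OECFDataset:
    """Measured (exposure, response) pairs for one colour channel."""

    channel: str
    exposure: np.ndarray
    response: np.ndarray
    bit_depth: int = 8
    g_max: float = 250.0
    p_min: float | None = None
    e_max: float | None = None
    normalised: bool = False

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.exposure.shape != self.response.shape or self.exposure.ndim != 1:
            raise DataError("exposure and response must be equal-length 1-D")
        if self.exposure.size == 0:
            raise DataError("empty OECF dataset")
        if np.any(~np.isfinite(self.exposure)) or np.any(~np.isfinite(self.response)):
            raise DataError("OECF dataset contains non-finite entries")
        if np.any(self.exposure < 0):
            raise DataError("exposures must be >= 0")
        hi = 1.05 if self.normalised else 2**self.bit_depth - 1
        if np.any(self.response < 0) or np.any(self.response > hi):
            raise DataError(
                f"responses outside [0, {hi}] for "
                f"{'normalised' if self.normalised else f'{self.bit_depth}-bit'} data"
            )
        # Saturation-region points legitimately sit past E_max, so the
        # normalised exposure axis may overshoot 1; cap only gross errors.
        if self.normalised and np.any(self.exposure > 2.0):
            raise DataError("normalised exposures must lie within [0, ~1]")

    def __len__(self) -> int:
        return int(self.exposure.size)

    @property
    def response_scale(self) -> float:
        """Full-scale response divisor (2**bit_depth - 1)."""
        return float(2**self.bit_depth - 1)

    def sorted_by_exposure(self) -> "OECFDataset":
        order = np.argsort(self.exposure, kind="stable")
        return replace(self, exposure=self.exposure[order], response=self.response[order])


def normalise_dataset(oecf: OECFDataset) -> OECFDataset:
    """Map responses to [0,1] via 2**bit_depth-1 and exposures via e_max.

    ``g_max`` and ``p_min`` are rescaled onto the same normalised axes;
    ``e_max`` is retained (in original units) so the transform round-trips.
    """
    if oecf.normalised:
        return oecf
    if oecf.e_max is None:
        raise StateError(
            "e_max is not set; call estimate_e_max() first"
        )
    scale = oecf.response_scale
    return replace(
        oecf,
        exposure=oecf.exposure / oecf.e_max,
        response=oecf.response / scale,
        g_max=oecf.g_max / scale,
        p_min=None if oecf.p_min is None else oecf.p_min / scale,
        normalised=True,
    )


def denormalise_dataset(oecf: OECFDataset) -> OECFDataset:
    """Exact inverse of :func:`normalise_dataset`."""
    if not oecf.normalised:
        return oecf
    if oecf.e_max is None:
        raise StateError("normalised dataset lost its e_max anchor")
    scale = oecf.response_scale
    return replace(
        oecf,
        exposure=oecf.exposure * oecf.e_max,
        response=oecf.response * scale,
        g_max=oecf.g_max * scale,
        p_min=None if oecf.p_min is None else oecf.p_min * scale,
        normalised=False,
    )


def estimate_e_max(oecf: OECFDataset, method: str = "biexp_fit") -> float:
    """Exposure producing response ``g_max``.

    ``biexp_fit`` fits the biexponential model on the dataset's own scale
    and solves f(E) = g_max; ``interpolation`` inverts the piecewise-linear
    OECF through the measured points, requiring data that bracket g_max.
    """
    if method == "biexp_fit":
        from . import biexp  # local import: biexp depends on this module

        params = biexp.fit_biexp(oecf)
        if params.a <= oecf.g_max:
            raise EstimationError(
                f"fitted asymptote a={params.a:.3g} does not exceed "
                f"g_max={oecf.g_max:.3g}; E_max undefined"
            )
        return biexp.invert_biexp(params, oecf.g_max)
    if method == "interpolation":
        ds = average_replicates(oecf).sorted_by_exposure()
        resp, expo = ds.response, ds.exposure
        if resp.max() < oecf.g_max or resp.min() > oecf.g_max:
            raise EstimationError(
                "data do not bracket g_max; interpolation impossible"
            )
        order = np.argsort(resp, kind="stable")
        return float(np.interp(oecf.g_max, resp[order], expo[order]))
    raise ValueError(f"unknown method {method!r}")


def filter_p_min(oecf: OECFDataset, p_min: float) -> OECFDataset:
    """Drop points whose response is strictly below ``p_min``.

    Responses equal to p_min are retained. Errors if fewer than four
    points survive (a cubic Bezier would be underdetermined).
    """
    keep = oecf.response >= p_min
    n_kept = int(keep.sum())
    if n_kept < MIN_POINTS_BEZIER:
        raise DataError(
            f"p_min={p_min} leaves {n_kept} < {MIN_POINTS_BEZIER} points"
        )
    return replace(
        oecf,
        exposure=oecf.exposure[keep],
        response=oecf.response[keep],
        p_min=p_min,
    )


def average_replicates(oecf: OECFDataset) -> OECFDataset:
    """Average responses sharing the same exposure value.

    Mirrors taking the ROI mean over replicate frames of one signal level.
    """
    uniq, inv = np.unique(oecf.exposure, return_inverse=True)
    sums = np.bincount(inv, weights=oecf.response)
    counts = np.bincount(inv)
    return replace(oecf, exposure=uniq, response=sums / counts)


def read_oecf_csv(path: str | Path, channel: str | None = None, **kwargs) -> OECFDataset:
    """Read an OECF table (CSV with header channel,exposure,response).

    Extra keyword arguments (bit_depth, g_max, ...) pass to
    :class:`OECFDataset`. When the file holds several channels, ``channel``
    selects one; otherwise it must be unique.
    """
    df = pd.read_csv(path)
    required = {"channel", "exposure", "response"}
    if not required.issubset(df.columns):
        raise DataError(f"OECF table must have columns {sorted(required)}")
    if channel is not None:
        df = df[df["channel"] == channel]
        if df.empty:
            raise DataError(f"channel {channel!r} not present in {path}")
    else:
        channels = df["channel"].unique()
        if len(channels) != 1:
            raise DataError(
                f"{path} holds channels {list(channels)}; pass channel="
            )
        channel = str(channels[0])
    return OECFDataset(
        channel=str(channel),
        exposure=df["exposure"].to_numpy(dtype=float),
        response=df["response"].to_numpy(dtype=float),
        **kwargs,
    )


def write_oecf_csv(oecf: OECFDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "channel": oecf.channel,
            "exposure": oecf.exposure,
            "response": oecf.response,
        }
    ).to_csv(path, index=False)
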