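"""Packaged per-channel calibration fixtures.

Four channels ship with the package: the red/green/blue channels of a
visible-light DSLR and the UV-sensitive red channel of a modified DSLR.
Each fixture carries the published biexponential coefficients and cubic
Bezier control points with their 95% CI half-widths, plus the channel's
normalisation anchors (g_max, p_min, E_max).

Note the published values are stored verbatim and are known to be
internally inconsistent in two respects (exposure units of the rate
coefficients versus the printed E_max, and the red channel's control-point
x ordering); see the fixture docstrings of the consuming operations.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .bezier import BezierCurve
from .biexp import BiexpParams

__all__ = [
    "CHANNELS",
    "load_fixture",
    "fixture_biexp",
    "fixture_bezier",
]

CHANNELS = (
    "canon40d_red",
    "canon40d_green",
    "canon40d_blue",
    "nikond70s_uv",
)


def load_fixture(name: str) -> dict:
    """Raw fixture dict for one channel (see :data:`CHANNELS`)."""
    if name not in CHANNELS:
        raise KeyError(f"unknown fixture {name!r}; choose from {CHANNELS}")
    ref = resources.files("oecfkit.data").joinpath(f"{name}.json")
    return json.loads(ref.read_text())


def fixture_biexp(name: str) -> BiexpParams:
    """Biexponential coefficients for one channel, a = b + d enforced.

    ``e_max`` is left unset: the printed anchor exposure is not consistent
    with the printed rate coefficients, so callers derive it from the
    coefficients (f(E_max) = g_max) or use the fixture's ``e_max_umol``
    explicitly.
    """
    raw = load_fixture(name)
    bx = raw["biexp"]
    return BiexpParams(
        b=bx["b"],
        c=bx["c"],
        d=bx["d"],
        g=bx["g"],
        ci_halfwidths=dict(bx["ci_halfwidths"]),
        g_max=raw["g_max"],
        scale="original",
    )


def fixture_bezier(name: str) -> BezierCurve:
    """Cubic Bezier control points for one channel (normalised axes)."""
    raw = load_fixture(name)
    bz = raw["bezier"]
    return BezierCurve(
        control_x=np.asarray(bz["x"], dtype=float),
        control_y=np.asarray(bz["y"], dtype=float),
        ci_x=np.asarray(bz["ci_x"], dtype=float),
        ci_y=np.asarray(bz["ci_y"], dtype=float),
        p_min=float(bz["y"][0]),
    )
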