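"""Cubic Bezier fitting of normalised OECF curves and LUT inversion.

A curve is defined by four control points P0..P3 on normalised axes
(x = exposure, y = response) and evaluated through the cubic Bernstein
basis for t in [0, 1]:

    B(t) = sum_i C(3,i) (1-t)^(3-i) t^i P_i

P0 and P3 are pinned to the extreme data points; P1 and P2 are solved by
linear least squares on the Bernstein design under chord-length parameter
assignment, optionally refined by alternating foot-point projection and
refitting (parameter correction). Inversion swaps the axes into a look-up
table sampled at uniformly spaced t values (256 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BelowRangeError, DataError, LUTError
from .oecf_core import MIN_POINTS_BEZIER, OECFDataset

__all__ = [
    "BezierCurve",
    "LUT",
    "eval_bezier",
    "fit_bezier",
    "fit_bezier_segments",
    "build_lut",
    "lut_lookup",
    "save_bezier_curve",
    "load_bezier_curve",
    "save_lut",
    "load_lut",
]

_MONOTONE_SAMPLES = 1024


@dataclass
class BezierCurve:
    """Cubic Bezier on normalised OECF axes, with optional 95% CIs."""

    control_x: np.ndarray
    control_y: np.ndarray
    ci_x: np.ndarray | None = None
    ci_y: np.ndarray | None = None
    p_min: float | None = None
    sse: float | None = None
    x_monotone: bool = True

    def __post_init__(self) -> None:
        self.control_x = np.asarray(self.control_x, dtype=float)
        self.control_y = np.asarray(self.control_y, dtype=float)
        if self.control_x.shape != (4,) or self.control_y.shape != (4,):
            raise DataError("a cubic Bezier needs exactly four control points")
        if not (
            np.all(np.isfinite(self.control_x))
            and np.all(np.isfinite(self.control_y))
        ):
            raise DataError("control points must be finite")
        for name in ("ci_x", "ci_y"):
            ci = getattr(self, name)
            if ci is not None:
                ci = np.asarray(ci, dtype=float)
                if ci.shape != (4,) or np.any(ci < 0):
                    raise DataError(f"{name} must be four non-negative values")
                setattr(self, name, ci)
        ts = np.linspace(0.0, 1.0, _MONOTONE_SAMPLES)
        self.x_monotone = bool(np.all(np.diff(_bernstein(ts) @ self.control_x) > 0))

    def as_dict(self) -> dict:
        out = {
            "control_points": [
                {"x": float(x), "y": float(y)}
                for x, y in zip(self.control_x, self.control_y)
            ],
            "p_min": self.p_min,
            "sse": self.sse,
            "x_monotone": self.x_monotone,
        }
        if self.ci_x is not None and self.ci_y is not None:
            out["ci_halfwidths"] = [
                {"x": float(cx), "y": float(cy)}
                for cx, cy in zip(self.ci_x, self.ci_y)
            ]
        return out


@dataclass
class LUT:
    """Ordered (response, exposure) pairs inverting a Bezier OECF curve."""

    response: np.ndarray
    exposure: np.ndarray

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if self.response.shape != self.exposure.shape or self.response.ndim != 1:
            raise DataError("LUT columns must be equal-length 1-D")
        if not np.all(np.diff(self.response) > 0):
            raise LUTError("LUT responses must be strictly increasing")

    def __len__(self) -> int:
        return int(self.response.size)


def _bernstein(t: np.ndarray) -> np.ndarray:
    """Cubic Bernstein design matrix, shape (len(t), 4)."""
    t = np.asarray(t, dtype=float)
    u = 1.0 - t
    return np.stack([u**3, 3 * u**2 * t, 3 * u * t**2, t**3], axis=-1)


def eval_bezier(curve: BezierCurve, t):
    """Evaluate the curve at parameter t (scalar or array) -> (x, y).

    Endpoint interpolation is exact: B(0) = P0, B(1) = P3.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("t must lie in [0, 1]")
    basis = _bernstein(t_arr)
    x = basis @ curve.control_x
    y = basis @ curve.control_y
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(x), float(y)
    return x, y


def _chord_length_params(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = np.hypot(np.diff(x), np.diff(y))
    total = d.sum()
    if total == 0:
        return np.linspace(0.0, 1.0, x.size)
    return np.concatenate([[0.0], np.cumsum(d)]) / total


def _solve_inner(
    t: np.ndarray, x: np.ndarray, y: np.ndarray,
    p0: np.ndarray, p3: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares P1, P2 with P0/P3 pinned; shared design for x and y."""
    basis = _bernstein(t)
    design = basis[:, 1:3]
    rhs = np.stack([x, y], axis=1) - np.outer(basis[:, 0], p0) - np.outer(basis[:, 3], p3)
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return sol[0], sol[1]


def _bernstein_deriv(t: np.ndarray) -> np.ndarray:
    """Derivative of the cubic Bernstein basis, shape (len(t), 4)."""
    t = np.asarray(t, dtype=float)
    u = 1.0 - t
    return np.stack(
        [-3 * u**2, 3 * u**2 - 6 * u * t, 6 * u * t - 3 * t**2, 3 * t**2],
        axis=-1,
    )


def _correct_parameters(
    t: np.ndarray, x: np.ndarray, y: np.ndarray,
    p0: np.ndarray, p3: np.ndarray,
    p1: np.ndarray, p2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gauss-Newton parameter correction of (interior t, P1, P2) jointly.

    The first/last parameters stay pinned at 0/1 (their data points anchor
    P0/P3). Returns the refined (t, P1, P2).
    """
    from scipy.optimize import least_squares

    n = x.size
    n_in = n - 2

    def unpack(v):
        t_full = np.concatenate([[0.0], v[:n_in], [1.0]])
        return t_full, v[n_in : n_in + 2], v[n_in + 2 : n_in + 4]

    def residuals(v):
        t_full, q1, q2 = unpack(v)
        cx = np.array([p0[0], q1[0], q2[0], p3[0]])
        cy = np.array([p0[1], q1[1], q2[1], p3[1]])
        basis = _bernstein(t_full)
        return np.concatenate([basis @ cx - x, basis @ cy - y])

    def jac(v):
        t_full, q1, q2 = unpack(v)
        cx = np.array([p0[0], q1[0], q2[0], p3[0]])
        cy = np.array([p0[1], q1[1], q2[1], p3[1]])
        basis = _bernstein(t_full)
        dbasis = _bernstein_deriv(t_full)
        J = np.zeros((2 * n, n_in + 4))
        rows = np.arange(1, n - 1)
        J[rows, rows - 1] = dbasis[1:-1] @ cx
        J[n + rows, rows - 1] = dbasis[1:-1] @ cy
        J[:n, n_in] = basis[:, 1]      # d res_x / d P1.x
        J[:n, n_in + 2] = basis[:, 2]  # d res_x / d P2.x
        J[n:, n_in + 1] = basis[:, 1]  # d res_y / d P1.y
        J[n:, n_in + 3] = basis[:, 2]  # d res_y / d P2.y
        return J

    v0 = np.concatenate([np.clip(t[1:-1], 0.0, 1.0), p1, p2])
    lb = np.concatenate([np.zeros(n_in), np.full(4, -np.inf)])
    ub = np.concatenate([np.ones(n_in), np.full(4, np.inf)])
    res = least_squares(
        residuals, v0, jac=jac, bounds=(lb, ub), method="trf",
        ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=100,
    )
    return unpack(res.x)


def fit_bezier(
    oecf_norm: OECFDataset, parameter_correction: bool = True
) -> BezierCurve:
    """Fit a cubic Bezier to a normalised, p_min-filtered OECF dataset.

    P0/P3 are pinned to the extreme data points; P1/P2 come from linear
    least squares under chord-length parameterisation. With
    ``parameter_correction`` (default) the parameter assignment and P1/P2
    are jointly refined by a Gauss-Newton correction pass. A non-monotone
    fitted x(t) is flagged with a warning, not repaired.
    """
    if not oecf_norm.normalised:
        raise DataError("fit_bezier requires a normalised dataset")
    ds = oecf_norm.sorted_by_exposure()
    if len(ds) < MIN_POINTS_BEZIER:
        raise DataError(
            f"need >= {MIN_POINTS_BEZIER} points, got {len(ds)}"
        )
    x, y = ds.exposure, ds.response
    p0 = np.array([x[0], y[0]])
    p3 = np.array([x[-1], y[-1]])
    t = _chord_length_params(x, y)
    p1, p2 = _solve_inner(t, x, y, p0, p3)

    if parameter_correction and len(ds) > 2:
        t, p1, p2 = _correct_parameters(t, x, y, p0, p3, p1, p2)

    curve = BezierCurve(
        control_x=np.array([p0[0], p1[0], p2[0], p3[0]]),
        control_y=np.array([p0[1], p1[1], p2[1], p3[1]]),
        p_min=float(y[0]) if ds.p_min is None else float(ds.p_min),
    )
    basis = _bernstein(t)
    curve.sse = float(
        np.sum((basis @ curve.control_x - x) ** 2)
        + np.sum((basis @ curve.control_y - y) ** 2)
    )
    if not curve.x_monotone:
        warnings.warn(
            f"fitted Bezier x(t) is not strictly increasing "
            f"(channel {ds.channel!r}); LUT inversion may be undefined",
            stacklevel=2,
        )
    return curve


def fit_bezier_segments(
    oecf_norm: OECFDataset, n_segments: int, parameter_correction: bool = True
) -> list[BezierCurve]:
    """Piecewise fit: contiguous exposure partitions with shared anchors.

    Segments share their breakpoint data points (C0 continuity only).
    Note the resulting LUT samples cluster per segment rather than covering
    the curve uniformly.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    ds = oecf_norm.sorted_by_exposure()
    n = len(ds)
    if n_segments * (MIN_POINTS_BEZIER - 1) + 1 > n:
        raise DataError(
            f"{n} points cannot support {n_segments} segments of >= "
            f"{MIN_POINTS_BEZIER} points with shared breakpoints"
        )
    # Breakpoints: near-equal contiguous chunks, boundary point shared.
    bounds = np.unique(
        np.round(np.linspace(0, n - 1, n_segments + 1)).astype(int)
    )
    curves = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = replace(
            ds,
            exposure=ds.exposure[lo : hi + 1],
            response=ds.response[lo : hi + 1],
        )
        if len(seg) < MIN_POINTS_BEZIER:
            raise DataError(
                f"segment [{lo}, {hi}] has {len(seg)} < "
                f"{MIN_POINTS_BEZIER} points"
            )
        curves.append(fit_bezier(seg, parameter_correction=parameter_correction))
    return curves


def build_lut(curve: BezierCurve, n_entries: int = 256) -> LUT:
    """Invert the curve by swapping axes at uniformly spaced t values.

    Evaluates the curve at ``n_entries`` uniform parameters and stores the
    (response, exposure) pairs. Requires y(t) strictly increasing (and
    warns upstream if x(t) is not).
    """
    if n_entries < 2:
        raise ValueError("n_entries must be >= 2")
    ts = np.linspace(0.0, 1.0, n_entries)
    x, y = eval_bezier(curve, ts)
    if not np.all(np.diff(y) > 0):
        raise LUTError("y(t) is not strictly increasing; inversion undefined")
    if not curve.x_monotone:
        raise LUTError("x(t) is not strictly increasing; inversion undefined")
    return LUT(response=y, exposure=x)


def lut_lookup(lut: LUT, p_norm) -> float | np.ndarray:
    """Piecewise-linear inverse lookup: normalised response -> exposure.

    Responses below the table (under the p_min anchor) raise
    :class:`BelowRangeError`; responses above the table saturate to the top
    exposure with a warning.
    """
    p_arr = np.asarray(p_norm, dtype=float)
    if np.any(p_arr < lut.response[0] - 1e-12):
        raise BelowRangeError(
            f"response below the linearisable range "
            f"(min {lut.response[0]:.6g})"
        )
    if np.any(p_arr > lut.response[-1] + 1e-12):
        warnings.warn("response above LUT range; saturating", stacklevel=2)
    out = np.interp(p_arr, lut.response, lut.exposure)
    return float(out) if np.isscalar(p_norm) or p_arr.ndim == 0 else out


def save_bezier_curve(curve: BezierCurve, path: str | Path) -> None:
    Path(path).write_text(json.dumps(curve.as_dict(), indent=2))


def load_bezier_curve(path: str | Path) -> BezierCurve:
    raw = json.loads(Path(path).read_text())
    pts = raw["control_points"]
    ci = raw.get("ci_halfwidths")
    curve = BezierCurve(
        control_x=[p["x"] for p in pts],
        control_y=[p["y"] for p in pts],
        ci_x=None if ci is None else [p["x"] for p in ci],
        ci_y=None if ci is None else [p["y"] for p in ci],
        p_min=raw.get("p_min"),
        sse=raw.get("sse"),
    )
    return curve


def save_lut(lut: LUT, path: str | Path) -> None:
    pd.DataFrame({"response": lut.response, "exposure": lut.exposure}).to_csv(
        path, index=False
    )


def load_lut(path: str | Path) -> LUT:
    df = pd.read_csv(path)
    return LUT(
        response=df["response"].to_numpy(float),
        exposure=df["exposure"].to_numpy(float),
    )
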