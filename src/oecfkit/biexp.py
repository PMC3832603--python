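"""Biexponential OECF model: constrained fit, evaluation, inversion.

The camera gain is modelled as

    f(E) = a - b*exp(-c*E) - d*exp(-g*E),    a := b + d

so that f(0) = 0 exactly and f saturates at the notional limit ``a`` as the
exposure E grows. ``b`` and ``d`` are in pixel-response units, ``c`` and
``g`` in inverse-exposure units. The anchor exposure ``E_max`` is *defined*
from the fit as the solution of f(E_max) = g_max.

Fitting uses a bounded trust-region least-squares solver with multi-start
initialisation over log-spaced rate pairs; inversion is bracketed
root-finding (geometric bracket growth + Brent).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import DataError, FitConvergenceError, NoSolutionError
from .oecf_core import MIN_POINTS_FIT, OECFDataset

__all__ = [
    "BiexpParams",
    "eval_biexp",
    "fit_biexp",
    "invert_biexp",
    "linearise_response",
    "save_biexp_params",
    "load_biexp_params",
]

_COEFFS = ("b", "c", "d", "g")


@dataclass
class BiexpParams:
    """Coefficients of the constrained biexponential gain curve."""

    b: float
    c: float
    d: float
    g: float
    ci_halfwidths: dict[str, float] | None = None
    g_max: float = 250.0
    e_max: float | None = None
    scale: str = "original"  # "original" | "normalised"

    def __post_init__(self) -> None:
        for name in _COEFFS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DataError(f"coefficient {name} must be finite and > 0")
        if self.ci_halfwidths is not None:
            bad = [k for k, v in self.ci_halfwidths.items() if v < 0]
            if bad:
                raise DataError(f"negative CI half-widths for {bad}")

    @property
    def a(self) -> float:
        """Asymptotic response limit; a = b + d enforces f(0) = 0."""
        return self.b + self.d

    def as_dict(self) -> dict:
        out = {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "g": self.g,
            "g_max": self.g_max,
            "e_max": self.e_max,
            "scale": self.scale,
        }
        if self.ci_halfwidths is not None:
            out["ci_halfwidths"] = dict(self.ci_halfwidths)
        return out


def eval_biexp(params: BiexpParams, E):
    """Forward gain curve f(E); scalar in -> scalar out, array in -> array."""
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < 0):
        raise ValueError("exposure must be >= 0")
    val = (
        params.a
        - params.b * np.exp(-params.c * E_arr)
        - params.d * np.exp(-params.g * E_arr)
    )
    return float(val) if np.isscalar(E) or E_arr.ndim == 0 else val


def _model(theta: np.ndarray, E: np.ndarray) -> np.ndarray:
    b, c, d, g = theta
    return (b + d) - b * np.exp(-c * E) - d * np.exp(-g * E)


def _jac(theta: np.ndarray, E: np.ndarray) -> np.ndarray:
    b, c, d, g = theta
    ec = np.exp(-c * E)
    eg = np.exp(-g * E)
    return np.column_stack(
        [1.0 - ec, b * E * ec, 1.0 - eg, d * E * eg]
    )


def fit_biexp(oecf: OECFDataset) -> BiexpParams:
    """Constrained least-squares fit of the biexponential gain curve.

    Works on either the original or the normalised scale. Returns fitted
    coefficients with 95% CI half-widths (1.96 * SE from the Jacobian-based
    covariance) and ``e_max`` solved from f(E_max) = g_max when the
    asymptote allows it. Raises :class:`FitConvergenceError` if no start
    converges.
    """
    ds = oecf.sorted_by_exposure()
    if len(ds) < MIN_POINTS_FIT:
        raise DataError(
            f"need >= {MIN_POINTS_FIT} points to fit, got {len(ds)}"
        )
    E = ds.exposure
    y = ds.response
    if np.count_nonzero(E > 0) < MIN_POINTS_FIT - 1:
        raise DataError("exposures must be strictly positive (one zero allowed)")

    e_span = float(E[E > 0].max())
    base_rate = 1.0 / e_span
    y_max = float(y.max())
    amp0 = max(y_max / 2.0, 1e-6)
    resp_cap = 2.0**ds.bit_depth if not ds.normalised else 2.0

    # Multi-start: log-spaced rate pairs over two decades, fast rate first.
    rates = base_rate * np.array([1.0, 3.0, 10.0, 30.0, 100.0])
    starts = [
        np.array([amp0, rc, amp0, rg])
        for i, rc in enumerate(rates)
        for rg in rates[:i]
    ]
    starts.append(np.array([amp0, 3.0 * base_rate, amp0, 3.0 * base_rate * 1.01]))

    lb = np.array([1e-12, 1e-12, 1e-12, 1e-12])
    ub = np.array([resp_cap, np.inf, resp_cap, np.inf])
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda th: _model(th, E) - y,
                x0,
                jac=lambda th: _jac(th, E),
                bounds=(lb, ub),
                method="trf",
                ftol=1e-10,
                xtol=1e-10,
                gtol=1e-10,
                max_nfev=2000,
            )
        except Exception:  # pragma: no cover - solver-internal failure
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitConvergenceError(
            f"biexponential fit failed from {len(starts)} starts "
            f"(n={len(ds)}, channel={ds.channel!r})"
        )

    b, c, d, g = best.x
    # Exchangeable exponentials: report the solution with c >= g.
    if c < g:
        b, c, d, g = d, g, b, c
        swapped = True
    else:
        swapped = False

    ci = _ci_halfwidths(best, n=len(ds), swapped=swapped)
    g_max = ds.g_max
    params = BiexpParams(
        b=b, c=c, d=d, g=g,
        ci_halfwidths=ci,
        g_max=g_max,
        scale="normalised" if ds.normalised else "original",
    )
    if params.a > g_max:
        params.e_max = invert_biexp(params, g_max)
    return params


def _ci_halfwidths(res, n: int, swapped: bool) -> dict[str, float]:
    """95% half-widths from the trust-region fit's Jacobian covariance."""
    dof = max(n - 4, 1)
    sigma2 = 2.0 * res.cost / dof
    try:
        cov = sigma2 * np.linalg.pinv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(4, np.nan)
    if swapped:
        se = se[[2, 3, 0, 1]]
    return dict(zip(_COEFFS, (1.96 * se).tolist()))


def invert_biexp(params: BiexpParams, p: float) -> float:
    """Unique exposure E >= 0 with f(E) = p, by bracketed root-finding.

    The upper bracket grows geometrically until f(E_hi) > p; Brent's method
    then solves to |f(E) - p| <= 1e-9 * a.
    """
    if p < 0:
        raise ValueError("response must be >= 0")
    if p >= params.a:
        raise NoSolutionError(
            f"response {p:.6g} is at/above the asymptote a={params.a:.6g}"
        )
    if p == 0:
        return 0.0
    e_hi = 1.0 / min(params.c, params.g)
    for _ in range(600):
        if eval_biexp(params, e_hi) > p:
            break
        e_hi *= 2.0
    else:  # pragma: no cover - a > p guarantees an eventual bracket
        raise FitConvergenceError("failed to bracket the inversion root")
    root = brentq(
        lambda E: eval_biexp(params, E) - p,
        0.0,
        e_hi,
        xtol=1e-12 / max(params.c, params.g) if params.scale == "original" else 1e-12,
        rtol=8.881784197001252e-16,
        maxiter=200,
    )
    return float(root)


def linearise_response(
    params: BiexpParams, p_raw: float, bit_depth: int = 8
) -> tuple[float, bool]:
    """Recover the exposure for a raw pixel level.

    Normalises ``p_raw`` onto the fitted scale and inverts the gain curve;
    the returned exposure is on the fitted exposure axis (multiply a
    normalised-scale result by the channel's E_max for photon amounts).
    Levels at or above ``g_max`` (on the raw scale) saturate: the returned
    exposure is ``E_max`` and the flag is True.
    """
    full_scale = 2**bit_depth - 1
    if p_raw < 0 or p_raw > full_scale:
        raise ValueError(f"pixel level {p_raw} outside [0, {full_scale}]")
    if params.scale == "normalised":
        g_max_raw = params.g_max * full_scale
        p_fit = p_raw / full_scale
    else:
        g_max_raw = params.g_max
        p_fit = float(p_raw)
    if params.e_max is None:
        raise DataError("params carry no e_max; fit did not reach g_max")
    e_max_fit = params.e_max  # on the fitted scale
    if p_raw >= g_max_raw:
        exposure = e_max_fit
        saturated = True
    else:
        exposure = invert_biexp(params, p_fit)
        saturated = False
    return float(exposure), saturated


def save_biexp_params(params: BiexpParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.as_dict(), indent=2))


def load_biexp_params(path: str | Path) -> BiexpParams:
    raw = json.loads(Path(path).read_text())
    return BiexpParams(
        b=raw["b"],
        c=raw["c"],
        d=raw["d"],
        g=raw["g"],
        ci_halfwidths=raw.get("ci_halfwidths"),
        g_max=raw.get("g_max", 250.0),
        e_max=raw.get("e_max"),
        scale=raw.get("scale", "original"),
    )
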