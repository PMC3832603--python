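"""Uncertainty propagation for the two linearisation methods.

Fitted-coefficient 95% confidence intervals are converted to Gaussian
standard deviations (half-width / 1.96) and propagated by Monte-Carlo
simulation: coefficients are drawn independently, each draw's curve is
inverted at a ladder of response levels, and the per-level mean and
standard deviation of the recovered exposure are recorded. Bezier
control-point confidence intervals come from bootstrap resampling of the
measured OECF points (fixed-size subsets drawn without replacement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bezier as _bz
from .biexp import BiexpParams
from .bezier import LUT, BezierCurve, _bernstein
from .errors import DataError, StateError
from .oecf_core import OECFDataset

__all__ = [
    "ParamSamples",
    "MCBounds",
    "sample_coefficients",
    "mc_linear_bounds",
    "bootstrap_bezier",
    "sd_curve",
]

_BIEXP_LABELS = ("b", "c", "d", "g")
_BEZIER_LABELS = ("x0", "x1", "x2", "x3", "y0", "y1", "y2", "y3")


@dataclass
class ParamSamples:
    """Monte-Carlo coefficient draws for one fitted parameter set."""

    draws: np.ndarray                 # (n_draws, k)
    labels: tuple[str, ...]
    seed: int
    source: BiexpParams | BezierCurve
    n_redraws: int = 0

    @property
    def n_draws(self) -> int:
        return int(self.draws.shape[0])

    @property
    def kind(self) -> str:
        return "biexp" if isinstance(self.source, BiexpParams) else "bezier"


@dataclass
class MCBounds:
    """Per-response-level mean/SD of Monte-Carlo recovered exposures."""

    response_levels: np.ndarray
    mean_exposure: np.ndarray
    sd_exposure: np.ndarray
    n_draws: int
    seed: int
    method: str
    n_dropped: int = 0
    sd_response: np.ndarray | None = None  # Bezier only: response-axis SD

    def __post_init__(self) -> None:
        if not (
            self.response_levels.shape
            == self.mean_exposure.shape
            == self.sd_exposure.shape
        ):
            raise DataError("MCBounds columns must share one shape")
        if np.any(self.sd_exposure < 0):
            raise DataError("standard deviations must be >= 0")
        if np.any(np.diff(self.response_levels) <= 0):
            raise DataError("response levels must be increasing")


def sample_coefficients(
    params: BiexpParams | BezierCurve,
    n_draws: int = 1000,
    seed: int = 0,
) -> ParamSamples:
    """Draw coefficients independently from Normal(fit, half-width/1.96).

    Biexponential draws must stay positive; violating entries are redrawn
    (count reported on the result). The asymptote a is never sampled: it is
    recomputed per draw as b + d, so f(0) = 0 holds for every draw.
    """
    rng = np.random.default_rng(seed)
    if isinstance(params, BiexpParams):
        if params.ci_halfwidths is None:
            raise StateError("params carry no CI half-widths")
        try:
            means = np.array([getattr(params, k) for k in _BIEXP_LABELS])
            sds = np.array(
                [params.ci_halfwidths[k] for k in _BIEXP_LABELS]
            ) / 1.96
        except KeyError as exc:
            raise StateError(f"missing CI half-width for {exc}") from exc
        draws = rng.normal(means, sds, size=(n_draws, 4))
        n_redraws = 0
        for _ in range(1000):
            bad = draws <= 0
            if not bad.any():
                break
            n_redraws += int(bad.sum())
            draws[bad] = rng.normal(
                np.broadcast_to(means, draws.shape)[bad],
                np.broadcast_to(sds, draws.shape)[bad],
            )
        else:
            raise DataError("positivity redraw did not terminate")
        return ParamSamples(draws, _BIEXP_LABELS, seed, params, n_redraws)

    if isinstance(params, BezierCurve):
        if params.ci_x is None or params.ci_y is None:
            raise StateError("curve carries no CI half-widths")
        means = np.concatenate([params.control_x, params.control_y])
        sds = np.concatenate([params.ci_x, params.ci_y]) / 1.96
        draws = rng.normal(means, sds, size=(n_draws, 8))
        return ParamSamples(draws, _BEZIER_LABELS, seed, params)

    raise TypeError(f"cannot sample from {type(params).__name__}")


def _bisect_invert(
    b: np.ndarray, c: np.ndarray, d: np.ndarray, g: np.ndarray,
    levels: np.ndarray, iters: int = 90,
) -> np.ndarray:
    """Vectorised bracketed bisection of f(E) = level for every draw.

    ``b..g`` have shape (m,), ``levels`` shape (L,); returns (L, m).
    Same bracket-growth contract as ``invert_biexp`` (geometric growth
    until f(hi) exceeds the level), then fixed-count bisection.
    """
    a = b + d

    def f(E):
        return a - b * np.exp(-c * E) - d * np.exp(-g * E)

    hi = np.broadcast_to(1.0 / np.minimum(c, g), (levels.size, b.size)).copy()
    target = np.broadcast_to(levels[:, None], hi.shape)
    for _ in range(600):
        need = f(hi) <= target
        if not need.any():
            break
        hi[need] *= 2.0
    else:  # pragma: no cover
        raise DataError("bisection failed to bracket some draws")
    lo = np.zeros_like(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = f(mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def _std_exact0(arr: np.ndarray, axis: int) -> np.ndarray:
    """Population SD, exactly 0 where every entry along ``axis`` is equal."""
    sd = arr.std(axis=axis, ddof=0)
    return np.where(np.ptp(arr, axis=axis) == 0, 0.0, sd)


def mc_linear_bounds(
    samples: ParamSamples, levels: int = 256, method: str | None = None
) -> MCBounds:
    """Invert every coefficient draw at a ladder of response levels.

    Biexponential: levels span [0, g_max] on the fitted scale; draws whose
    asymptote b + d does not exceed g_max are not invertible over the full
    ladder and are dropped (warned above 5%, error at 100%). Bezier: levels
    span [P0.y, P3.y]; each draw's curve is tabulated into a LUT and looked
    up, with draws whose y(t) is non-monotone dropped; the response-axis
    spread across draws is recorded as ``sd_response``.
    """
    if method is None:
        method = samples.kind
    if method == "biexp":
        src = samples.source
        level_vals = np.linspace(0.0, src.g_max, levels)
        b, c, d, g = samples.draws.T
        ok = (b + d) > src.g_max * (1.0 + 1e-12)
        n_dropped = int((~ok).sum())
        _check_dropped(n_dropped, samples.n_draws)
        E = _bisect_invert(b[ok], c[ok], d[ok], g[ok], level_vals)
        return MCBounds(
            response_levels=level_vals,
            mean_exposure=E.mean(axis=1),
            sd_exposure=_std_exact0(E, axis=1),
            n_draws=int(ok.sum()),
            seed=samples.seed,
            method="biexp",
            n_dropped=n_dropped,
        )

    if method == "bezier_lut":
        src = samples.source
        level_vals = np.linspace(src.control_y[0], src.control_y[3], levels)
        ts = np.linspace(0.0, 1.0, levels)
        basis = _bernstein(ts)                      # (levels, 4)
        xs = samples.draws[:, :4] @ basis.T         # (n, levels)
        ys = samples.draws[:, 4:] @ basis.T
        ok = np.all(np.diff(ys, axis=1) > 0, axis=1)
        n_dropped = int((~ok).sum())
        _check_dropped(n_dropped, samples.n_draws)
        xs, ys = xs[ok], ys[ok]
        E = np.empty((int(ok.sum()), levels))
        for i in range(E.shape[0]):  # np.interp per draw (grids differ)
            E[i] = np.interp(level_vals, ys[i], xs[i])
        sd_resp = _std_exact0(ys, axis=0)
        mean_y = ys.mean(axis=0)
        order = np.argsort(mean_y)
        sd_response = np.interp(level_vals, mean_y[order], sd_resp[order])
        return MCBounds(
            response_levels=level_vals,
            mean_exposure=E.mean(axis=0),
            sd_exposure=_std_exact0(E, axis=0),
            n_draws=E.shape[0],
            seed=samples.seed,
            method="bezier_lut",
            n_dropped=n_dropped,
            sd_response=sd_response,
        )

    raise ValueError(f"unknown method {method!r}")


def _check_dropped(n_dropped: int, n_total: int) -> None:
    if n_dropped == n_total:
        raise DataError("every Monte-Carlo draw was non-invertible")
    if n_dropped > 0.05 * n_total:
        warnings.warn(
            f"{n_dropped}/{n_total} Monte-Carlo draws non-invertible",
            stacklevel=3,
        )


def bootstrap_bezier(
    oecf: OECFDataset,
    n_boot: int = 1000,
    subset_size: int = 32,
    seed: int = 0,
    parameter_correction: bool = True,
) -> BezierCurve:
    """Bootstrap control-point CIs from fixed-size subsets of the data.

    Each replicate draws ``subset_size`` points without replacement, always
    including the two extreme points so all replicates share the P0/P3
    normalisation anchors, and refits the curve. The full-data fit is
    returned with per-coordinate 95% half-widths (1.96 * SD across
    replicates) attached.
    """
    if not oecf.normalised:
        raise DataError("bootstrap_bezier requires a normalised dataset")
    ds = oecf.sorted_by_exposure()
    n = len(ds)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds dataset size {n}")
    if subset_size < 4:
        raise ValueError("subset_size must be >= 4")
    rng = np.random.default_rng(seed)
    interior = np.arange(1, n - 1)
    cx = np.empty((n_boot, 4))
    cy = np.empty((n_boot, 4))
    for i in range(n_boot):
        if subset_size == n:
            idx = np.arange(n)
        else:
            picked = rng.choice(interior, size=subset_size - 2, replace=False)
            idx = np.sort(np.concatenate([[0], picked, [n - 1]]))
        sub = replace(
            ds, exposure=ds.exposure[idx], response=ds.response[idx]
        )
        fit = _bz.fit_bezier(sub, parameter_correction=parameter_correction)
        cx[i], cy[i] = fit.control_x, fit.control_y
    full = _bz.fit_bezier(ds, parameter_correction=parameter_correction)
    full.ci_x = 1.96 * cx.std(axis=0, ddof=1)
    full.ci_y = 1.96 * cy.std(axis=0, ddof=1)
    return full


def sd_curve(bounds: MCBounds) -> pd.DataFrame:
    """SD-versus-level table: one row per response level.

    Columns: ``p_over_gmax`` (level / top level), ``sd_exposure``, and for
    the Bezier method also ``sd_response``.
    """
    top = bounds.response_levels[-1]
    data = {
        "p_over_gmax": bounds.response_levels / top if top != 0 else bounds.response_levels,
        "mean_exposure": bounds.mean_exposure,
        "sd_exposure": bounds.sd_exposure,
    }
    if bounds.sd_response is not None:
        data["sd_response"] = bounds.sd_response
    return pd.DataFrame(data)
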