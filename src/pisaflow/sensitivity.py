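"""Aliasing-velocity sensitivity analysis of the PISA estimate.

For a steady convergence-zone model at known flow rate Q, the PISA
chain is run at each aliasing velocity Va on a grid and the relative
RFlow error (RFlow_est - Q) / Q is recorded.  On the exact circular-
aperture model the curve is the closed form

    rel_error(Va) = -2 pi a^2 Va / Q,

a monotone linear under-estimation growing with Va and with orifice
radius a — the high-Va trend.  With chamber confinement switched on the
far field is elevated, the curve turns positive at low Va, and an
optimal aliasing velocity Va* (the zero crossing) appears, decreasing
with orifice size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import OrificeSpec, make_orifice
from .pisa_estimator import (AliasingTooHigh, BeamSpec, ContourOutsideDomain,
                             ray_crossing, regurgitant_flow)
from .synthetic_flow import SinkFlowSpec, ray_speed_profile

__all__ = [
    "SensitivityCurve", "OptimalVa", "error_curve", "optimal_aliasing",
    "admissible_band", "sweep_shapes_sizes", "default_va_grid",
    "extended_circle_catalog",
]


def default_va_grid(lo: float = 5.0, hi: float = 60.0,
                    step: float = 1.0) -> np.ndarray:
    """Aliasing-velocity grid (cm/s) spanning the clinically quoted
    range; the literature recommends anywhere from 15 to 60 cm/s."""
    return np.arange(lo, hi + step / 2, step)


@dataclass
class SensitivityCurve:
    """Relative RFlow error vs aliasing velocity for one configuration.

    ``rel_error`` is NaN and ``no_crossing`` True where the aliasing
    contour could not be located on the scan ray."""

    spec: SinkFlowSpec
    beam: BeamSpec
    va: np.ndarray
    rel_error: np.ndarray
    no_crossing: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        if len(self.va) > 1 and np.any(np.diff(self.va) <= 0):
            raise ValueError("va grid must be strictly increasing")


@dataclass(frozen=True)
class OptimalVa:
    """Optimal aliasing velocity: the zero crossing of the error curve,
    or (flagged) the grid point minimizing |error| when the curve never
    changes sign."""

    va: float
    boundary: bool


def error_curve(spec: SinkFlowSpec, beam: BeamSpec | None = None,
                va_grid: np.ndarray | None = None,
                n_panels: int = 512, ray_step: float = 2e-3) -> SensitivityCurve:
    """PISA RFlow error over the aliasing-velocity grid.

    The on-ray speed profile of the configured model is sampled once at
    ``ray_step`` resolution; each Va is located on it with the same
    contiguous-crossing rule the gridded estimator uses.
    """
    beam = beam or BeamSpec()
    va_grid = default_va_grid() if va_grid is None else np.asarray(va_grid, float)
    profile = ray_speed_profile(spec, n_panels=n_panels)
    s_hi = 1.5 * math.sqrt(spec.Q / (2.0 * math.pi * float(va_grid[0])))
    if spec.chamber_halfwidth:
        s_hi *= 1.5
    s = np.arange(ray_step, s_hi, ray_step)
    v = profile(s)
    rel = np.full(len(va_grid), np.nan)
    rad = np.full(len(va_grid), np.nan)
    miss = np.zeros(len(va_grid), dtype=bool)
    for i, va in enumerate(va_grid):
        try:
            r = ray_crossing(s, v, float(va))
        except (AliasingTooHigh, ContourOutsideDomain):
            miss[i] = True
            continue
        rad[i] = r
        rel[i] = (regurgitant_flow(r, float(va)) - spec.Q) / spec.Q
    return SensitivityCurve(spec, beam, va_grid, rel, miss, rad)


def optimal_aliasing(curve: SensitivityCurve) -> OptimalVa:
    """Zero crossing of rel_error(Va), linearly interpolated between the
    bracketing grid points; when the error never changes sign, the grid
    Va minimizing |rel_error|, flagged as a boundary optimum."""
    ok = ~curve.no_crossing & np.isfinite(curve.rel_error)
    va = curve.va[ok]
    err = curve.rel_error[ok]
    if len(va) < 3:
        raise ValueError("curve needs at least 3 valid points")
    sign_change = np.nonzero(np.diff(np.sign(err)) != 0)[0]
    sign_change = [i for i in sign_change if err[i] != 0 or err[i + 1] != 0]
    if len(sign_change) == 0:
        return OptimalVa(float(va[np.argmin(np.abs(err))]), boundary=True)
    i = int(sign_change[0])
    f = err[i] / (err[i] - err[i + 1])
    return OptimalVa(float(va[i] + f * (va[i + 1] - va[i])), boundary=False)


def admissible_band(curve: SensitivityCurve, tol: float = 0.2
                    ) -> tuple[float, float]:
    """Maximal contiguous Va interval containing Va* on which
    |rel_error| <= tol; edges refined by linear interpolation."""
    if not tol > 0:
        raise ValueError("tol must be positive")
    ok = ~curve.no_crossing & np.isfinite(curve.rel_error)
    va = curve.va[ok]
    err = curve.rel_error[ok]
    opt = optimal_aliasing(curve)
    inside = np.abs(err) <= tol
    if not inside.any():
        raise ValueError(f"|rel_error| exceeds tol={tol} everywhere on the grid")
    k = int(np.argmin(np.abs(va - opt.va)))
    if not inside[k]:
        k = int(np.nonzero(inside)[0][np.argmin(np.abs(va[inside] - opt.va))])
    lo = k
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = k
    while hi < len(va) - 1 and inside[hi + 1]:
        hi += 1

    def refine(i_in: int, i_out: int) -> float:
        e_in, e_out = err[i_in], err[i_out]
        target = tol if e_out > 0 else -tol
        f = (target - e_in) / (e_out - e_in)
        return float(va[i_in] + f * (va[i_out] - va[i_in]))

    va_lo = refine(lo, lo - 1) if lo > 0 else float(va[0])
    va_hi = refine(hi, hi + 1) if hi < len(va) - 1 else float(va[-1])
    return va_lo, va_hi


def extended_circle_catalog() -> list[OrificeSpec]:
    """The three catalog circles plus the two extra diameters (16 and
    20 mm) added to expose the size trend."""
    return [make_orifice("circle", d, label=f"circle-{d:g}mm")
            for d in (4.7, 8.7, 12.2, 16.0, 20.0)]


def sweep_shapes_sizes(catalog: list[OrificeSpec], Q: float,
                       beam: BeamSpec | None = None,
                       va_grid: np.ndarray | None = None,
                       model: str = "sink_sheet",
                       chamber_halfwidth: float | None = None,
                       image_order: int | None = None,
                       tol: float = 0.2,
                       n_panels: int = 512) -> pd.DataFrame:
    """Long-form sensitivity table over a catalog of orifices.

    One row per (orifice, Va) with the relative error, plus the
    per-orifice optimal aliasing velocity and +-tol admissible band
    repeated on every row of that orifice.
    """
    if len(catalog) == 0:
        raise ValueError("empty orifice catalog")
    va_grid = default_va_grid() if va_grid is None else np.asarray(va_grid, float)
    rows = []
    for orf in catalog:
        spec = SinkFlowSpec(orf, Q, model=model,
                            chamber_halfwidth=chamber_halfwidth,
                            image_order=image_order)
        curve = error_curve(spec, beam, va_grid, n_panels=n_panels)
        opt = optimal_aliasing(curve)
        try:
            band = admissible_band(curve, tol)
        except ValueError:
            band = (float("nan"), float("nan"))
        for va, err, miss in zip(curve.va, curve.rel_error, curve.no_crossing):
            rows.append({
                "label": orf.label or orf.shape, "shape": orf.shape,
                "h_mm": orf.h, "w_mm": orf.w, "area_mm2": orf.area_mm2,
                "model": model, "Q_ml_s": Q, "va_cm_s": float(va),
                "rel_error": float(err), "no_crossing": bool(miss),
                "va_opt_cm_s": opt.va, "va_opt_boundary": opt.boundary,
                "band_lo_cm_s": band[0], "band_hi_cm_s": band[1],
            })
    return pd.DataFrame(rows)
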