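"""The clinical flow-convergence (PISA) estimation chain.

On color Doppler only the velocity component along the ultrasound beam
is seen.  The method assumes the converging flow upstream of the
regurgitant orifice is an ideal half-space sink, so the isovelocity
contour at the aliasing velocity Va is a hemisphere of radius r and

    RFlow = 2 pi r^2 * Va          (regurgitant flow, ml/s)
    EROa  = RFlow / Vmax           (effective orifice area, cm^2)
    RVol  = EROa * VTI             (regurgitant volume per beat, ml)

with Vmax the peak jet speed and VTI the velocity-time integral of the
peak-speed trace over systole.  This module implements each link of the
chain plus the aliasing-radius extraction along the scan ray, with the
conventions: scan ray from the orifice centroid into the convergence
zone (-x), projected velocity positive toward the probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .synthetic_flow import FieldSeries, VelocityField

__all__ = [
    "BeamSpec", "PisaMeasurement", "ProjectedField",
    "AliasingTooHigh", "ContourOutsideDomain",
    "beam_project", "pisa_radius", "pisa_radius_profile", "ray_crossing",
    "regurgitant_flow", "vmax_and_vti", "vmax_trace", "eroa", "rvol",
    "estimate_full", "VMAX_SEARCH_CM",
]

#: search depth for the peak jet speed: within 20 mm of the orifice
VMAX_SEARCH_CM = 2.0


class AliasingTooHigh(ValueError):
    """The chosen aliasing velocity exceeds the on-ray maximum."""


class ContourOutsideDomain(ValueError):
    """The isovelocity contour lies beyond the sampled domain."""


@dataclass(frozen=True)
class BeamSpec:
    """Ultrasound scan-ray geometry.

    ``direction`` is the unit vector of the line of sight, running from
    the orifice centroid into the convergence zone; the aligned default
    is -x.  ``tilt_deg`` is the derived angle to the -x axis; the PISA
    scan requires it below 90 degrees (enforced where the ray is
    marched), while pure projection accepts any orientation.
    ``origin`` (cm) defaults to the orifice centroid and absorbs any
    orifice-localization error.
    """

    direction: tuple[float, ...] = (-1.0, 0.0)
    origin: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ValueError("beam direction must be a nonzero vector")
        object.__setattr__(self, "direction", tuple(d / n))

    @classmethod
    def tilted(cls, tilt_deg: float, ndim: int = 2,
               origin: tuple[float, ...] | None = None) -> "BeamSpec":
        """Beam tilted in the x-y plane by ``tilt_deg`` from -x."""
        th = math.radians(tilt_deg)
        d = [-math.cos(th), math.sin(th)] + [0.0] * (ndim - 2)
        return cls(direction=tuple(d), origin=origin)

    @property
    def tilt_deg(self) -> float:
        return math.degrees(math.acos(max(-1.0, min(1.0, -self.direction[0]))))

    def origin_for(self, ndim: int) -> np.ndarray:
        if self.origin is not None:
            return np.asarray(self.origin, dtype=float)
        return np.zeros(ndim)

    def direction_for(self, ndim: int) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        if len(d) < ndim:
            d = np.concatenate([d, np.zeros(ndim - len(d))])
        return d[:ndim]


@dataclass(frozen=True)
class PisaMeasurement:
    """The full clinical estimate bundle (clinical units)."""

    Va: float        # aliasing velocity, cm/s
    r: float         # PISA radius, cm
    RFlow: float     # regurgitant flow, ml/s
    Vmax: float      # peak jet speed, cm/s
    VTI: float       # velocity-time integral, cm
    EROa: float      # effective regurgitant orifice area, cm^2
    RVol: float      # regurgitant volume, ml
    peak_time_ms: float = float("nan")
    vmax_trace: tuple = dc_field(default=(), repr=False)


@dataclass
class ProjectedField:
    """Beam-projected scalar velocity (cm/s) on the parent grid."""

    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    beam: BeamSpec


def beam_project(field: VelocityField, beam: BeamSpec) -> ProjectedField:
    """Pointwise velocity component along the line of sight, positive
    toward the probe (i.e. opposite the scan-ray direction): the
    converging flow, which runs against the ray, projects positive."""
    d = beam.direction_for(field.ndim)
    proj = -sum(di * ci for di, ci in zip(d, field.components))
    return ProjectedField(field.axes, proj, beam)


def ray_crossing(s: np.ndarray, v: np.ndarray, Va: float) -> float:
    """Distance of the farthest contiguous super-threshold sample along
    a ray, refined by linear interpolation at the bracketing pair.

    ``s`` are increasing distances from the orifice centroid, ``v`` the
    projected velocities there.  Walking outward from the high-speed
    core next to the orifice (the on-ray velocity maximum), the contour
    sits where v first drops below Va; contiguity makes isolated
    super-threshold noise islands farther out irrelevant.
    """
    if not Va > 0:
        raise ValueError("aliasing velocity must be positive")
    v = np.asarray(v, dtype=float)
    j0 = int(np.argmax(v))
    if v[j0] < Va:
        raise AliasingTooHigh(
            f"Va={Va} exceeds the on-ray maximum projected velocity {v[j0]:.3g}")
    below = j0 + np.nonzero(v[j0:] < Va)[0]
    if len(below) == 0:
        raise ContourOutsideDomain(
            f"projected velocity stays above Va={Va} to the domain edge")
    j = int(below[0])
    f = (v[j - 1] - Va) / (v[j - 1] - v[j])
    return float(s[j - 1] + f * (s[j] - s[j - 1]))


def pisa_radius(projected: ProjectedField, beam: BeamSpec, Va: float,
                step: float | None = None) -> float:
    """PISA radius r (cm): distance from the orifice centroid along the
    scan ray to the aliasing isovelocity crossing, sub-cell-refined.

    The ray is sampled at ``step`` (default: the finest grid spacing)
    by linear interpolation of the projected field; the ray must stay
    inside the grid until the crossing.
    """
    if beam.tilt_deg >= 90.0:
        raise ValueError("PISA scan ray must point into the convergence zone "
                         "(beam tilt below 90 degrees)")
    ndim = len(projected.axes)
    d = beam.direction_for(ndim)
    o = beam.origin_for(ndim)
    if step is None:
        step = min(float(np.min(np.diff(ax))) for ax in projected.axes
                   if len(ax) > 1)
    # maximal in-grid extent of the ray
    s_max = np.inf
    for k, ax in enumerate(projected.axes):
        if d[k] > 0:
            s_max = min(s_max, (ax[-1] - o[k]) / d[k])
        elif d[k] < 0:
            s_max = min(s_max, (ax[0] - o[k]) / d[k])
    if not np.isfinite(s_max) or s_max <= 0:
        raise ValueError("scan ray leaves the grid immediately")
    s = np.arange(step, s_max + 1e-12, step)
    pts = o[None, :] + s[:, None] * d[None, :]
    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator(projected.axes, projected.values,
                                     bounds_error=False, fill_value=np.nan)
    v = interp(pts)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("scan ray has no valid samples inside the grid")
    first = int(np.argmax(ok))
    last = len(ok) - int(np.argmax(ok[::-1]))
    return ray_crossing(s[first:last], v[first:last], Va)


def pisa_radius_profile(profile, Va: float, s_max: float,
                        s_min: float = 1e-3, step: float = 2e-3) -> float:
    """PISA radius from an analytic on-ray speed profile ``u(s)``."""
    s = np.arange(s_min, s_max, step)
    return ray_crossing(s, profile(s), Va)


def regurgitant_flow(r: float, Va: float) -> float:
    """RFlow (ml/s) through the hemispherical shell: 2 pi r^2 Va."""
    if r < 0 or Va < 0:
        raise ValueError("r and Va must be non-negative")
    return 2.0 * math.pi * r**2 * Va


def vmax_trace(series: FieldSeries, beam: BeamSpec | None = None) -> np.ndarray:
    """Peak projected speed per phase, searched within 20 mm of the
    orifice on the jet side (x >= 0) when the grid reaches it, else
    within 20 mm of the orifice centroid."""
    beam = beam or BeamSpec(direction=(-1.0, 0.0))
    ref = series.grid
    x = ref.x
    jet_side = x >= -1e-12
    if jet_side.any():
        sel = jet_side & (x <= VMAX_SEARCH_CM)
    else:
        sel = np.abs(x) <= VMAX_SEARCH_CM
    if not sel.any():
        sel = np.abs(x) == np.min(np.abs(x))
    out = np.empty(len(series))
    for k, f in enumerate(series.fields):
        proj = beam_project(f, beam).values
        out[k] = float(np.max(np.abs(proj[sel])))
    return out


def _default_window(t: np.ndarray, trace: np.ndarray) -> tuple[float, float]:
    """Contiguous interval around the peak where the trace stays at or
    above 10% of its maximum."""
    peak = int(np.argmax(trace))
    thr = 0.1 * trace[peak]
    lo = peak
    while lo > 0 and trace[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(t) - 1 and trace[hi + 1] >= thr:
        hi += 1
    return float(t[lo]), float(t[hi])


def vmax_and_vti(series_or_trace, window: tuple[float, float] | None = None,
                 beam: BeamSpec | None = None):
    """Peak speed Vmax (cm/s), VTI (cm) and the per-phase Vmax trace.

    Accepts a :class:`FieldSeries` or a precomputed ``(t_ms, values)``
    trace.  VTI is the trapezoidal integral of the Vmax trace over the
    window; a single-phase (steady) series integrates as a constant.
    """
    if isinstance(series_or_trace, FieldSeries):
        t = series_or_trace.t
        trace = vmax_trace(series_or_trace, beam)
        if window is None:
            window = series_or_trace.systole
    else:
        t, trace = series_or_trace
        t = np.asarray(t, dtype=float)
        trace = np.asarray(trace, dtype=float)
    if window is None:
        window = _default_window(t, trace)
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty systole window")
    if len(t) == 1:
        vmax = float(trace[0])
        return vmax, vmax * (t1 - t0) * 1e-3, trace
    sel = (t >= t0) & (t <= t1)
    if not sel.any():
        raise ValueError("no phases inside the systole window")
    idx = np.nonzero(sel)[0]
    lo, hi = max(idx[0] - 1, 0), min(idx[-1] + 1, len(t) - 1)
    tt, vv = t[lo:hi + 1], trace[lo:hi + 1]
    vmax = float(np.max(trace[sel]))
    vti = float(np.trapezoid(vv, tt)) * 1e-3  # ms -> s, cm/s*s = cm
    return vmax, vti, trace


def eroa(RFlow: float, Vmax: float) -> float:
    """Effective regurgitant orifice area (cm^2): RFlow / Vmax."""
    if Vmax <= 0:
        raise ValueError("Vmax must be positive")
    return RFlow / Vmax


def rvol(EROa: float, VTI: float) -> float:
    """Regurgitant volume per beat (ml): EROa * VTI."""
    if EROa < 0 or VTI < 0:
        raise ValueError("EROa and VTI must be non-negative")
    return EROa * VTI


def estimate_full(series: FieldSeries, Va: float,
                  beam: BeamSpec | None = None,
                  window: tuple[float, float] | None = None,
                  phase_mode: str = "peak") -> PisaMeasurement:
    """Run the whole clinical chain on a field series.

    The PISA radius and RFlow are read at the phase of peak Vmax
    (mirroring the frozen peak-systolic color-Doppler frame); with
    ``phase_mode='mean'`` the radius is instead averaged over the
    systole window.  Vmax and VTI come from the systole window (the
    series' own systole interval, or the contiguous >= 10%-of-peak
    interval for measured series).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    beam = beam or BeamSpec(direction=(-1.0,) + (0.0,) * (series.grid.ndim - 1))
    t = series.t
    trace = vmax_trace(series, beam)
    if window is None:
        window = series.systole
    if window is None:
        if len(t) == 1 or np.all(trace == 0):
            window = (float(t[0]), float(t[0]) + 1.0) if len(t) == 1 else \
                     (float(t[0]), float(t[-1]))
        else:
            window = _default_window(t, trace)
    vmax, vti, _ = vmax_and_vti((t, trace), window)
    if vmax == 0.0:
        return PisaMeasurement(Va=Va, r=0.0, RFlow=0.0, Vmax=0.0, VTI=0.0,
                               EROa=0.0, RVol=0.0, peak_time_ms=float(t[0]),
                               vmax_trace=tuple(trace))
    sel = (t >= window[0]) & (t <= window[1]) if len(t) > 1 else np.ones(1, bool)
    cand = np.nonzero(sel)[0]
    peak = int(cand[np.argmax(trace[cand])])

    def radius_at(k: int) -> float:
        proj = beam_project(series.fields[k], beam)
        return pisa_radius(proj, beam, Va)

    if phase_mode == "peak":
        r = radius_at(peak)
    elif phase_mode == "mean":
        r = float(np.mean([radius_at(int(k)) for k in cand]))
    else:
        raise ValueError("phase_mode must be 'peak' or 'mean'")
    rf = regurgitant_flow(r, Va)
    er = eroa(rf, vmax)
    return PisaMeasurement(Va=Va, r=r, RFlow=rf, Vmax=vmax, VTI=vti,
                           EROa=er, RVol=rvol(er, vti),
                           peak_time_ms=float(t[peak]),
                           vmax_trace=tuple(trace))
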