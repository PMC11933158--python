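"""Synthetic velocity-field generators.

Two families of fields are produced, both with known ground truth so the
clinical flow-convergence (PISA) chain and the PIV-style reference
integrator can be tested against exact values:

* **Convergence-zone models** — steady, irrotational flow drawn toward a
  regurgitant orifice in a plane wall: the idealized half-space point
  sink, the exact circular-aperture axial profile, a uniform-strength
  sink-sheet panel model for arbitrary orifice polygons, and an
  image-sink confinement correction for a finite atrial chamber.
  The convergence region occupies x <= 0; the jet occupies x >= 0.

* **Pulsatile jet exit fields** — a prescribed systolic waveform with a
  starting-vortex local maximum, a global maximum and an exponential
  decay, carried by a saddle-backed exit profile, plus PIV-like
  resampling (coarser grid, frame ensembles, additive Gaussian noise).

Units: lengths in cm, velocities in cm/s, flow rates in ml/s, times in
ms.  Orifice geometry (mm) is converted at the boundary via
:class:`~pisaflow.geometry.OrificeSpec` accessors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import shapely
from scipy.integrate import quad
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Polygon

from .geometry import OrificeSpec

__all__ = [
    "VelocityField", "FieldSeries", "SinkFlowSpec", "JetSpec", "Waveform",
    "FrameEnsemble",
    "point_sink_field", "aperture_axial_profile", "sink_sheet_field",
    "confined_sink_field", "ray_speed_profile", "pulse_waveform",
    "jet_exit_series", "piv_sample", "hemisphere_flux",
    "sink_sheet_panels", "default_phases", "CYCLE_MS",
]

#: cardiac cycle length at the pump rate of 80 bpm (ms)
CYCLE_MS = 750.0
#: phase positions per cardiac cycle
N_PHASES = 42


def default_phases(n: int = N_PHASES, cycle_ms: float = CYCLE_MS) -> np.ndarray:
    """Phase times (ms) of the cardiac-phase-resolved acquisition."""
    return np.arange(n) * cycle_ms / n


# ---------------------------------------------------------------------------
# field containers
# ---------------------------------------------------------------------------

@dataclass
class VelocityField:
    """Velocity components on a structured grid.

    ``x`` is the beam/streamwise axis, ``y`` in-plane transverse, ``z``
    the optional out-of-plane (laser-sheet traversal) axis, all in cm
    and strictly increasing.  Components ``u``, ``v`` (and ``w`` for 3D)
    are in cm/s with shape ``(nx, ny[, nz])``.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    z: np.ndarray | None = None
    w: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        for ax in self.axes:
            if ax.ndim != 1 or (len(ax) > 1 and np.any(np.diff(ax) <= 0)):
                raise ValueError("grid axes must be 1-D and strictly increasing")
        shape = self.shape
        for name in ("u", "v", "w"):
            comp = getattr(self, name)
            if comp is None:
                continue
            comp = np.asarray(comp, dtype=float)
            if comp.shape != shape:
                raise ValueError(f"component {name} shape {comp.shape} != grid {shape}")
            if not np.all(np.isfinite(comp)):
                raise ValueError(f"component {name} contains non-finite values")
            setattr(self, name, comp)
        if (self.z is None) != (self.w is None):
            raise ValueError("3-D fields need both a z axis and a w component")

    @property
    def axes(self) -> tuple[np.ndarray, ...]:
        return (self.x, self.y) if self.z is None else (self.x, self.y, self.z)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.axes)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def components(self) -> tuple[np.ndarray, ...]:
        return (self.u, self.v) if self.w is None else (self.u, self.v, self.w)

    def interpolator(self, component: np.ndarray) -> RegularGridInterpolator:
        return RegularGridInterpolator(self.axes, component,
                                       bounds_error=False, fill_value=np.nan)

    def min_spacing(self) -> float:
        return min(float(np.min(np.diff(a))) for a in self.axes if len(a) > 1)


@dataclass
class FieldSeries:
    """Time-resolved fields over one cardiac cycle, sharing one grid."""

    t: np.ndarray
    fields: list[VelocityField]
    programmed_rvol: float | None = None
    systole: tuple[float, float] | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if len(self.t) != len(self.fields):
            raise ValueError("one field per phase time required")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("phase times must be strictly increasing")
        ref = self.fields[0]
        for f in self.fields[1:]:
            if f.shape != ref.shape or any(
                    not np.array_equal(a, b) for a, b in zip(f.axes, ref.axes)):
                raise ValueError("all fields in a series must share one grid")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def grid(self) -> VelocityField:
        return self.fields[0]


# ---------------------------------------------------------------------------
# steady convergence-zone models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinkFlowSpec:
    """Configuration of a steady convergence-zone flow at rate ``Q``
    (ml/s) through ``orifice``, using one of the potential-flow models.

    ``chamber_halfwidth`` (cm) and ``image_order`` switch on the
    image-sink confinement correction for a chamber bounded by walls at
    y = +-chamber_halfwidth.
    """

    orifice: OrificeSpec
    Q: float
    model: str = "point_sink"  # point_sink | aperture_exact | sink_sheet
    chamber_halfwidth: float | None = None
    image_order: int | None = None

    def __post_init__(self) -> None:
        if not self.Q > 0:
            raise ValueError("flow rate Q must be positive")
        if self.model not in ("point_sink", "aperture_exact", "sink_sheet"):
            raise ValueError(f"unknown flow model {self.model!r}")
        if self.chamber_halfwidth is not None:
            half = max(self.orifice.h, self.orifice.w or 0.0) / 2.0 / 10.0
            if self.chamber_halfwidth <= half:
                raise ValueError("chamber halfwidth must exceed the orifice half-size")


def _grid_points(x, y, z=None):
    axes = (x, y) if z is None else (x, y, z)
    mesh = np.meshgrid(*axes, indexing="ij")
    return mesh


def point_sink_field(Q: float, x: np.ndarray, y: np.ndarray,
                     z: np.ndarray | None = None) -> VelocityField:
    """Idealized half-space sink on a wall at the origin.

    Speed at distance R is Q / (2 pi R^2), directed toward the origin,
    so the flux through every concentric hemisphere equals Q.  The grid
    must keep clear of the singularity (two grid cells minimum).
    """
    mesh = _grid_points(x, y, z)
    R2 = sum(m**2 for m in mesh)
    R = np.sqrt(R2)
    spacings = [float(np.min(np.diff(a))) for a in ((x, y) if z is None else (x, y, z))
                if len(a) > 1]
    if float(R.min()) < 2.0 * max(spacings):
        raise ValueError("grid contains points within 2 cells of the sink singularity")
    speed = Q / (2.0 * math.pi * R2)
    comps = [-speed * m / R for m in mesh]
    meta = {"generator": "point_sink", "Q": Q}
    if z is None:
        return VelocityField(x, y, comps[0], comps[1], meta=meta)
    return VelocityField(x, y, comps[0], comps[1], z=z, w=comps[2], meta=meta)


def aperture_axial_profile(Q: float, a: float, x) -> np.ndarray | float:
    """Axial velocity (cm/s) of potential flow through a circular
    aperture of radius ``a`` (cm) in a plane wall, at axial distance
    ``x`` (cm) upstream: u = Q / (2 pi (x^2 + a^2)).

    The far field recovers the point sink; at the aperture the velocity
    saturates at Q / (2 pi a^2) instead of diverging.
    """
    if not a > 0:
        raise ValueError("aperture radius a must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("axial distance x must be >= 0")
    out = Q / (2.0 * math.pi * (x**2 + a**2))
    return float(out) if out.ndim == 0 else out


def sink_sheet_panels(orifice: OrificeSpec, Q: float,
                      n_panels: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-strength panel decomposition of the orifice: centroids
    (n, 2) in cm (in-plane coordinates) and per-panel sink strengths
    (ml/s) summing to Q.

    The polygon (star-shaped about its area centroid) is triangulated
    into radial rings so panel centroids tile the whole opening; a pure
    boundary fan would lump all centroids onto one ring and distort the
    near field.  Returns at least ``n_panels`` triangles.
    """
    if n_panels < 3:
        raise ValueError("need at least 3 panels")
    n_rings = max(2, int(round(math.sqrt(n_panels / 8.0))) + 1)
    m = max(16, int(math.ceil(n_panels / (2 * n_rings - 1))))
    boundary = orifice.polygon_cm(m)
    rings = [f * boundary for f in np.linspace(0.0, 1.0, n_rings + 1)[1:]]
    tris = []
    inner = np.zeros_like(boundary)
    for outer in rings:
        nxt_o = np.roll(outer, -1, axis=0)
        nxt_i = np.roll(inner, -1, axis=0)
        tris.append(np.stack([inner, outer, nxt_o], axis=1))
        if inner.any():
            tris.append(np.stack([inner, nxt_o, nxt_i], axis=1))
        inner = outer
    tri = np.concatenate(tris)                      # (n, 3, 2)
    d1 = tri[:, 1] - tri[:, 0]
    d2 = tri[:, 2] - tri[:, 0]
    areas = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    keep = areas > 1e-15
    cents = tri[keep].mean(axis=1)
    areas = areas[keep]
    strengths = Q * areas / areas.sum()
    return cents, strengths


def _sink_sheet_velocity(points: np.ndarray, cents: np.ndarray,
                         strengths: np.ndarray) -> np.ndarray:
    """Velocity (cm/s) at (m, 3) points from half-space point sinks at
    (0, cy, cz) with the given strengths; chunked to bound memory."""
    out = np.zeros_like(points)
    sinks = np.column_stack([np.zeros(len(cents)), cents])  # (n, 3)
    chunk = max(1, int(2e6) // max(len(sinks), 1))
    for i in range(0, len(points), chunk):
        p = points[i:i + chunk]
        d = p[:, None, :] - sinks[None, :, :]          # (m, n, 3)
        r2 = np.einsum("mnk,mnk->mn", d, d)
        r3 = r2 * np.sqrt(r2)
        coef = strengths[None, :] / (2.0 * math.pi * r3)
        out[i:i + chunk] = -np.einsum("mn,mnk->mk", coef, d)
    return out


def sink_sheet_field(orifice: OrificeSpec, Q: float, x: np.ndarray,
                     y: np.ndarray, z: np.ndarray | None = None,
                     n_panels: int = 512) -> VelocityField:
    """Convergence-zone field of a uniform-strength sink sheet spanning
    the orifice polygon; reduces to the point sink in the far field.

    The grid must lie on or upstream of the wall (x <= 0) and keep a
    quadrature standoff of half a panel pitch from every panel point.
    """
    if np.any(np.asarray(x) > 1e-12):
        raise ValueError("sink-sheet grid must lie upstream of the wall (x <= 0)")
    cents, strengths = sink_sheet_panels(orifice, Q, n_panels)
    panel_pitch = math.sqrt(orifice.area_cm2 / len(strengths))
    mesh = _grid_points(x, y, z)
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    sinks = np.column_stack([np.zeros(len(cents)), cents])
    # standoff check on the nearest panel only (cheap lower bound per point)
    d2min = np.min(
        ((pts[:, None, :] - sinks[None, :, :])**2).sum(-1), axis=1) if len(pts) * len(sinks) < 2e6 else None
    if d2min is None:
        # large grids: conservative bound via wall distance
        d2min = pts[:, 0]**2
    if float(np.min(d2min)) < (0.5 * panel_pitch)**2:
        raise ValueError("grid point violates the panel quadrature standoff")
    vel = _sink_sheet_velocity(pts, cents, strengths)
    shape = tuple(len(a) for a in ((x, y) if z is None else (x, y, z)))
    comps = [vel[:, k].reshape(shape) for k in range(3)]
    meta = {"generator": "sink_sheet", "Q": Q, "n_panels": len(strengths),
            "orifice": orifice.label or orifice.shape}
    if z is None:
        return VelocityField(x, y, comps[0], comps[1], meta=meta)
    return VelocityField(x, y, comps[0], comps[1], z=z, w=comps[2], meta=meta)


def _image_sink_u_on_axis(Q: float, s: np.ndarray, halfwidth: float,
                          order: int) -> np.ndarray:
    """Streamwise velocity added on the scan ray (distance s upstream)
    by image sinks mirrored across chamber walls at y = +-halfwidth."""
    u = np.zeros_like(s, dtype=float)
    for k in range(1, order + 1):
        d2 = s**2 + (2.0 * k * halfwidth)**2
        u += 2.0 * Q * s / (2.0 * math.pi * d2**1.5)
    return u


def confined_sink_field(spec: SinkFlowSpec, x: np.ndarray, y: np.ndarray,
                        z: np.ndarray | None = None,
                        n_panels: int = 512) -> VelocityField:
    """Base convergence field of ``spec.model`` plus image sinks across
    the chamber walls at y = +-chamber_halfwidth, truncated at
    ``image_order`` reflections.  Confinement raises far-field speeds,
    which is what drives PISA over-estimation at low aliasing velocity.
    """
    order = spec.image_order or 0
    if order < 0:
        raise ValueError("image_order must be >= 0")
    if spec.model == "sink_sheet":
        base = sink_sheet_field(spec.orifice, spec.Q, x, y, z, n_panels)
    else:
        base = point_sink_field(spec.Q, x, y, z)
    if order == 0 or spec.chamber_halfwidth is None:
        return base
    L = spec.chamber_halfwidth
    mesh = _grid_points(x, y, z)
    comps = [c.copy() for c in base.components]
    for k in range(1, order + 1):
        for sy in (+1.0, -1.0):
            cy = sy * 2.0 * k * L
            dx = mesh[0]
            dy = mesh[1] - cy
            parts = [dx, dy] + ([mesh[2]] if len(mesh) == 3 else [])
            r2 = sum(p**2 for p in parts)
            r3 = r2 * np.sqrt(r2)
            for c, p in zip(comps, parts):
                c -= spec.Q * p / (2.0 * math.pi * r3)
    meta = dict(base.meta, confined=True, chamber_halfwidth=L, image_order=order)
    if z is None:
        return VelocityField(x, y, comps[0], comps[1], meta=meta)
    return VelocityField(x, y, comps[0], comps[1], z=z, w=comps[2], meta=meta)


def ray_speed_profile(spec: SinkFlowSpec, n_panels: int = 512):
    """Streamwise speed u(s) on the PISA scan ray, s cm upstream of the
    orifice centroid along -x, as a vectorized callable.

    This is the same physics as the gridded generators evaluated exactly
    on the ray; the sensitivity sweeps use it to avoid building full 3-D
    grids for every aliasing velocity.
    """
    Q = spec.Q
    if spec.model == "point_sink":
        def base(s):
            return Q / (2.0 * math.pi * np.asarray(s, dtype=float)**2)
    elif spec.model == "aperture_exact":
        a = spec.orifice.equivalent_radius_cm
        def base(s):
            return aperture_axial_profile(Q, a, np.asarray(s, dtype=float))
    else:
        cents, strengths = sink_sheet_panels(spec.orifice, Q, n_panels)
        r2p = (cents**2).sum(axis=1)
        def base(s):
            s = np.asarray(s, dtype=float)
            d2 = s[..., None]**2 + r2p[None, :]
            return np.sum(strengths[None, :] * s[..., None]
                          / (2.0 * math.pi * d2**1.5), axis=-1)
    order = spec.image_order or 0
    if order and spec.chamber_halfwidth:
        L, Qc = spec.chamber_halfwidth, Q
        def profile(s):
            s = np.asarray(s, dtype=float)
            return base(s) + _image_sink_u_on_axis(Qc, s, L, order)
        return profile
    return lambda s: base(np.asarray(s, dtype=float))


def hemisphere_flux(field_velocity, radius: float, n_theta: int = 96,
                    n_phi: int = 192) -> float:
    """Inward volume flux (ml/s) through the upstream hemisphere of the
    given radius centred on the orifice, by Gauss-Legendre quadrature in
    the polar angle and the trapezoid rule in azimuth.

    ``field_velocity`` maps (m, 3) points (x <= 0 half-space) to (m, 3)
    velocities.  The conservation oracle: every steady convergence model
    returns its configured flow rate here.
    """
    # polar angle from the -x axis: theta in [0, pi/2]
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    cos_t = 0.5 * (nodes + 1.0)          # cos(theta) in (0, 1)
    wt = 0.5 * weights
    phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
    ct, ph = np.meshgrid(cos_t, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    # outward unit normal of the hemisphere (pointing away from origin)
    nrm = np.stack([-ct, st * np.cos(ph), st * np.sin(ph)], axis=-1)
    pts = radius * nrm.reshape(-1, 3)
    vel = np.asarray(field_velocity(pts)).reshape(-1, 3)
    vn = np.einsum("mk,mk->m", vel, nrm.reshape(-1, 3))
    dphi = 2.0 * math.pi / n_phi
    integrand = -vn.reshape(n_theta, n_phi)  # inward positive
    return float(radius**2 * dphi * np.sum(wt[:, None] * integrand))


# ---------------------------------------------------------------------------
# pulsatile jet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Waveform:
    """Systolic jet-speed waveform U(t).

    A first local maximum ``U_local`` at ``t_local_peak`` marks the
    starting-vortex passage, followed by a shallow dip, the global
    maximum ``U_global`` at ``t_global_peak`` and an exponential decay
    with time constant ``decay_tau``; zero outside the systole window.
    All segment joins are C1 (zero-slope cosine blends; the decay onset
    is smoothed over ``smooth_ms``) so trapezoidal phase sampling of the
    flow rate converges cleanly.
    """

    t_local_peak: float = 210.0
    t_global_peak: float = 245.0
    U_local: float = 80.0
    U_global: float = 100.0
    decay_tau: float = 50.0
    systole: tuple[float, float] = (180.0, 480.0)
    dip_frac: float = 0.9      # dip depth as a fraction of U_local
    smooth_ms: float = 10.0    # decay-onset smoothing scale

    def __post_init__(self) -> None:
        t0, t1 = self.systole
        if not (t0 < self.t_local_peak < self.t_global_peak < t1):
            raise ValueError("require t0 < t_local_peak < t_global_peak < t1")
        if not (self.U_global >= self.U_local > 0):
            raise ValueError("require U_global >= U_local > 0")
        if not self.decay_tau > 0:
            raise ValueError("decay_tau must be positive")

    def __call__(self, t) -> np.ndarray | float:
        return pulse_waveform(self, t)

    def integral(self, ta: float | None = None, tb: float | None = None) -> float:
        """Exact time integral of U(t) in cm/s * s over [ta, tb] (defaults
        to the full systole); adaptive quadrature per smooth segment."""
        t0, t1 = self.systole
        ta = t0 if ta is None else max(ta, t0)
        tb = t1 if tb is None else min(tb, t1)
        if tb <= ta:
            return 0.0
        knots = [ta, self.t_local_peak,
                 0.5 * (self.t_local_peak + self.t_global_peak),
                 self.t_global_peak, tb]
        knots = sorted({float(np.clip(k, ta, tb)) for k in knots})
        total = 0.0
        for a, b in zip(knots[:-1], knots[1:]):
            val, _ = quad(lambda t: pulse_waveform(self, t), a, b, limit=200)
            total += val
        return total * 1e-3  # ms -> s

    def scaled(self, factor: float) -> "Waveform":
        return replace(self, U_local=self.U_local * factor,
                       U_global=self.U_global * factor)


def pulse_waveform(w: Waveform, t) -> np.ndarray | float:
    """Evaluate the waveform (cm/s) at time(s) ``t`` in ms."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    t0, t1 = w.systole
    tl, tg = w.t_local_peak, w.t_global_peak
    tm = 0.5 * (tl + tg)
    U_dip = w.dip_frac * w.U_local
    out = np.zeros_like(t)

    m = (t >= t0) & (t <= tl)
    out[m] = w.U_local * 0.5 * (1.0 - np.cos(math.pi * (t[m] - t0) / (tl - t0)))
    m = (t > tl) & (t <= tm)
    out[m] = U_dip + (w.U_local - U_dip) * 0.5 * (
        1.0 + np.cos(math.pi * (t[m] - tl) / (tm - tl)))
    m = (t > tm) & (t <= tg)
    out[m] = U_dip + (w.U_global - U_dip) * 0.5 * (
        1.0 - np.cos(math.pi * (t[m] - tm) / (tg - tm)))
    m = (t > tg) & (t <= t1)
    dt = t[m] - tg
    phase = (np.sqrt(dt**2 + w.smooth_ms**2) - w.smooth_ms) / w.decay_tau
    out[m] = w.U_global * np.exp(-phase)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class JetSpec:
    """Pulsatile jet configuration: orifice, waveform, saddle amplitude
    ``beta`` (profile maximum sits near the rim, u_center/u_max =
    1/(1+beta) for the untapered profile), PIV noise level and ensemble
    size.  ``taper_mm`` is the shear-layer width over which the exit
    profile blends to zero at the orifice rim (0 = sharp edge)."""

    orifice: OrificeSpec
    waveform: Waveform = Waveform()
    beta: float = 0.3
    noise_sd: float = 0.0
    n_frames: int = 1
    seed: int = 0
    taper_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _exit_profile(jet: JetSpec, yy: np.ndarray, zz: np.ndarray) -> np.ndarray:
    """Normalized exit profile g on in-plane points (cm): g = c (1 +
    beta rho^2) * taper(rho) inside the orifice, 0 outside, with rho the
    normalized boundary-distance coordinate (0 at the deepest interior
    point, 1 at the rim) and c fixed so the area mean of g is 1."""
    poly = Polygon(jet.orifice.polygon_cm(720))
    d_max = jet.orifice.h / 2.0 / 10.0  # deepest-point rim distance, all shapes
    delta_hat = min(0.9, (jet.taper_mm / 10.0) / d_max) if jet.taper_mm > 0 else 0.0

    def raw(points):
        pts = shapely.points(points)
        inside = shapely.contains(poly, pts)
        rho = np.ones(len(points))
        d = shapely.distance(pts[inside], poly.exterior)
        rho[inside] = np.clip(1.0 - d / d_max, 0.0, 1.0)
        g = np.zeros(len(points))
        gi = 1.0 + jet.beta * rho[inside]**2
        if delta_hat > 0:
            gi = gi * _smoothstep((1.0 - rho[inside]) / delta_hat)
        g[inside] = gi
        return g

    # normalization by fine quadrature over the bounding box
    minx, miny, maxx, maxy = poly.bounds
    nfine = 320
    fy = np.linspace(minx, maxx, nfine)
    fz = np.linspace(miny, maxy, nfine)
    FY, FZ = np.meshgrid(fy, fz, indexing="ij")
    fine = np.column_stack([FY.ravel(), FZ.ravel()])
    dA = (fy[1] - fy[0]) * (fz[1] - fz[0])
    integral = raw(fine).sum() * dA
    c = jet.orifice.area_cm2 / integral

    pts = np.column_stack([yy.ravel(), zz.ravel()])
    return c * raw(pts).reshape(yy.shape)


def jet_exit_series(jet: JetSpec, x: np.ndarray, y: np.ndarray,
                    z: np.ndarray | None = None,
                    phases: np.ndarray | None = None) -> FieldSeries:
    """Pulsatile jet series: streamwise u(y, z, t) = U(t) g(y, z) on the
    jet side, replicated along the x stations of the grid (frozen near
    the exit), v = w = 0.

    For 2-D (x, y) grids the profile is the z = 0 mid-plane slice.  The
    grid must cover the orifice cross-section.  ``programmed_rvol`` is
    the exact systolic time-area integral A * int U dt (ml).
    """
    phases = default_phases() if phases is None else np.asarray(phases, dtype=float)
    poly = Polygon(jet.orifice.polygon_cm(256))
    minx, miny, maxx, maxy = poly.bounds
    if y[0] > minx or y[-1] < maxx or (z is not None and (z[0] > miny or z[-1] < maxy)):
        raise ValueError("grid does not cover the orifice cross-section")
    if z is None:
        yy, zz = np.meshgrid(y, np.array([0.0]), indexing="ij")
        g = _exit_profile(jet, yy, zz)[:, 0]          # (ny,)
        g_full = np.broadcast_to(g[None, :], (len(x), len(y)))
    else:
        yy, zz = np.meshgrid(y, z, indexing="ij")
        g = _exit_profile(jet, yy, zz)                # (ny, nz)
        g_full = np.broadcast_to(g[None, :, :], (len(x), len(y), len(z)))
    U = pulse_waveform(jet.waveform, phases)
    fields = []
    for Ut in U:
        u = Ut * np.array(g_full)
        zero = np.zeros_like(u)
        if z is None:
            fields.append(VelocityField(x, y, u, zero,
                                        meta={"generator": "jet_exit"}))
        else:
            fields.append(VelocityField(x, y, u, zero, z=z, w=zero.copy(),
                                        meta={"generator": "jet_exit"}))
    rvol = jet.orifice.area_cm2 * jet.waveform.integral()
    return FieldSeries(phases, fields, programmed_rvol=rvol,
                       systole=jet.waveform.systole,
                       meta={"jet": jet.orifice.label or jet.orifice.shape,
                             "beta": jet.beta})


# ---------------------------------------------------------------------------
# PIV-like sampling
# ---------------------------------------------------------------------------

#: PIV vector pitch of the reference acquisition (cm): one vector each 0.5323 mm
PIV_SPACING_CM = 0.05323


@dataclass
class FrameEnsemble:
    """Per-phase frame ensembles on the PIV grid.

    ``frames`` has shape (n_phases, n_frames, n_components, *grid_shape);
    ``axes`` are the PIV grid axes (cm); ``t`` the phase times (ms)."""

    t: np.ndarray
    axes: tuple[np.ndarray, ...]
    frames: np.ndarray
    programmed_rvol: float | None = None
    systole: tuple[float, float] | None = None
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    def mean_series(self) -> FieldSeries:
        """Ensemble-mean fields per phase, as a FieldSeries."""
        mean = self.frames.mean(axis=1)
        fields = []
        for k in range(len(self.t)):
            comps = mean[k]
            if len(self.axes) == 2:
                fields.append(VelocityField(self.axes[0], self.axes[1],
                                            comps[0], comps[1]))
            else:
                fields.append(VelocityField(self.axes[0], self.axes[1],
                                            comps[0], comps[1],
                                            z=self.axes[2], w=comps[2]))
        return FieldSeries(self.t, fields, programmed_rvol=self.programmed_rvol,
                           systole=self.systole)


def piv_sample(series: FieldSeries, spacing: float = PIV_SPACING_CM,
               noise_sd: float = 0.0, n_frames: int = 100,
               seed: int = 0) -> FrameEnsemble:
    """Resample a series to a PIV grid of the given vector pitch (cm)
    and build per-phase frame ensembles with i.i.d. zero-mean Gaussian
    noise of ``noise_sd`` (cm/s) added per frame, per vector, per
    component.  Bit-reproducible for a fixed seed.
    """
    ref = series.grid
    native = ref.min_spacing()
    if spacing < native - 1e-12:
        raise ValueError("PIV spacing must not be finer than the native grid")
    new_axes = []
    for ax in ref.axes:
        if len(ax) == 1:
            new_axes.append(ax.copy())
            continue
        n = max(2, int(math.floor((ax[-1] - ax[0]) / spacing)) + 1)
        # symmetric placement keeps y = 0 on the grid for symmetric ranges
        start = ax[0] + 0.5 * ((ax[-1] - ax[0]) - (n - 1) * spacing)
        new_axes.append(start + spacing * np.arange(n))
    mesh = np.meshgrid(*new_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    shape = tuple(len(a) for a in new_axes)

    truth = np.empty((len(series), len(ref.components), *shape))
    for k, f in enumerate(series.fields):
        for c, comp in enumerate(f.components):
            interp = RegularGridInterpolator(f.axes, comp, bounds_error=False,
                                             fill_value=None)
            truth[k, c] = interp(pts).reshape(shape)

    rng = np.random.default_rng(seed)
    frames = np.repeat(truth[:, None], n_frames, axis=1)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return FrameEnsemble(series.t.copy(), tuple(new_axes), frames,
                         programmed_rvol=series.programmed_rvol,
                         systole=series.systole, seed=seed)
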