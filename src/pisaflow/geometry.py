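"""Parametric regurgitant-orifice geometry.

Orifice phantoms come in three planar shapes — circle, slit (pointed
oval) and drop — characterised by a height ``h`` (the diameter for a
circle) and, for the non-circular shapes, a width ``w`` measured along
the long axis.  Dimensions follow the phantom-catalog convention and are
stored in millimetres; everything downstream of this module works in the
clinical units (cm, cm/s, ml/s), so unit conversions are confined to the
accessors defined here.

The slit is modelled as a symmetric two-arc lens (two circular segments
sharing the chord ``w``, each with sagitta ``h/2``), the drop as a disk
of diameter ``h`` joined to its tangent wedge whose apex sits at axial
distance ``w`` from the blunt end.  Both have closed-form areas used to
validate the polygonized boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "OrificeSpec",
    "make_orifice",
    "polygonize",
    "shoelace_area",
    "polygon_centroid",
    "load_catalog",
    "MM_PER_CM",
]

MM_PER_CM = 10.0

_SHAPES = ("circle", "slit", "drop")


def shoelace_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed or open polygon, in the polygon's
    length units squared.  Positive for counter-clockwise orientation."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (shoelace-weighted)."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass(frozen=True)
class OrificeSpec:
    """Parametric orifice: shape, height ``h`` (mm), width ``w`` (mm,
    ``None`` for a circle), with the model area derived on construction."""

    shape: str
    h: float
    w: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown orifice shape {self.shape!r}")
        if not self.h > 0:
            raise ValueError("orifice height h must be positive")
        if self.shape == "circle":
            if self.w is not None:
                raise ValueError("circle takes no width w")
        else:
            if self.w is None:
                raise ValueError(f"{self.shape} requires a width w")
            if not self.w > self.h:
                raise ValueError(f"{self.shape} requires w > h")

    # -- areas ---------------------------------------------------------

    @property
    def area_mm2(self) -> float:
        """Model area (mm^2), closed form per shape."""
        if self.shape == "circle":
            return math.pi * self.h**2 / 4.0
        if self.shape == "slit":
            return _lens_area(self.h, self.w)
        return _drop_area(self.h, self.w)

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / MM_PER_CM**2

    @property
    def equivalent_radius_cm(self) -> float:
        """Radius of the circle with the same area (cm)."""
        return math.sqrt(self.area_cm2 / math.pi)

    # -- boundary ------------------------------------------------------

    def polygon_mm(self, n: int = 512) -> np.ndarray:
        return polygonize(self, n)

    def polygon_cm(self, n: int = 512) -> np.ndarray:
        return polygonize(self, n) / MM_PER_CM

    def scaled_to_area(self, area_mm2: float) -> "OrificeSpec":
        """Uniformly rescale h (and w) so the model area equals
        ``area_mm2``; used for equal-area shape comparisons."""
        s = math.sqrt(area_mm2 / self.area_mm2)
        w = None if self.w is None else self.w * s
        return OrificeSpec(self.shape, self.h * s, w,
                           label=f"{self.label or self.shape}-scaled")


def _lens_area(h: float, w: float) -> float:
    # Two circular segments with chord w and sagitta h/2 each.
    R = (w**2 / 4.0 + h**2 / 4.0) / h
    theta = 2.0 * math.asin(w / (2.0 * R))
    return R**2 * (theta - math.sin(theta))


def _drop_area(h: float, w: float) -> float:
    # Disk of radius h/2 plus the kite bounded by the two tangents from
    # the apex, minus nothing: sector of angle 2(pi - phi) + kite.
    R = h / 2.0
    d = w - R  # apex distance from the disk centre
    phi = math.acos(R / d)
    return R**2 * (math.pi - phi) + R * math.sqrt(d**2 - R**2)


def make_orifice(shape: str, h: float, w: float | None = None,
                 label: str = "") -> OrificeSpec:
    """Build an :class:`OrificeSpec` from shape and dimensions in mm."""
    return OrificeSpec(shape=shape, h=h, w=w, label=label)


def polygonize(orifice: OrificeSpec, n: int = 512) -> np.ndarray:
    """Closed counter-clockwise boundary polygon, (n, 2) array in mm,
    centred on the area centroid.  The last vertex is *not* repeated.

    ``n`` is the total vertex budget; at least 16 is required so the
    shoelace area is meaningful.
    """
    if n < 16:
        raise ValueError("polygonize requires n >= 16 vertices")
    h, w = orifice.h, orifice.w
    if orifice.shape == "circle":
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        R = h / 2.0
        poly = np.column_stack([R * np.cos(t), R * np.sin(t)])
    elif orifice.shape == "slit":
        R = (w**2 / 4.0 + h**2 / 4.0) / h
        alpha = math.atan2(R - h / 2.0, w / 2.0)  # tip angle seen from arc centre
        m = n // 2
        # upper arc: right tip -> left tip, centre below the chord
        t_up = np.linspace(alpha, math.pi - alpha, m)
        up = np.column_stack([R * np.cos(t_up), (h / 2.0 - R) + R * np.sin(t_up)])
        # lower arc: mirror, left tip -> right tip
        t_lo = np.linspace(math.pi - alpha, alpha, n - m)
        lo = np.column_stack([R * np.cos(t_lo), (R - h / 2.0) - R * np.sin(t_lo)])
        # drop duplicated tips where the arcs meet
        poly = np.vstack([up[:-1], lo[:-1]])
    else:  # drop
        R = h / 2.0
        d = w - R
        phi = math.acos(R / d)
        t = np.linspace(phi, 2.0 * math.pi - phi, n - 1)
        arc = np.column_stack([R * np.cos(t), R * np.sin(t)])
        poly = np.vstack([arc, [[d, 0.0]]])
    poly = poly - polygon_centroid(poly)
    if shoelace_area(poly) < 0:  # defensive: enforce CCW
        poly = poly[::-1]
    return poly


def load_catalog() -> list[OrificeSpec]:
    """The nine phantom orifices (three shapes x three sizes) with the
    catalog's printed, scanner-measured areas attached as labels.

    Returns specs built from the printed h/w; the printed areas live in
    :func:`load_catalog_table` for validation and reporting.
    """
    return [make_orifice(r["shape"], r["h_mm"], r.get("w_mm"), label=r["label"])
            for r in load_catalog_table()]


def load_catalog_table() -> list[dict]:
    """Raw catalog rows: label, shape, h_mm, w_mm (None for circles) and
    the scanner-measured area printed in the catalog (mm^2)."""
    with resources.files("pisaflow.data").joinpath("orifice_catalog.json").open() as f:
        return json.load(f)["orifices"]
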