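"""Reading and writing velocity fields and series.

Two dialects:

* delimited text — ``# key=value`` header lines (grid shape, units,
  provenance) followed by columns ``x y [z] u v [w]``, one row per grid
  node in C order; units cm and cm/s;
* binary — a NumPy ``.npz`` container holding the axes, components and
  a JSON metadata string; round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic_flow import FieldSeries, VelocityField

__all__ = ["write_field_text", "read_field_text", "write_field_npz",
           "read_field_npz", "write_series_npz", "read_series_npz"]


def write_field_text(field: VelocityField, path) -> None:
    path = Path(path)
    axes = field.axes
    names = "x y z"[: 2 * len(axes) - 1]
    comps = field.components
    cnames = "u v w"[: 2 * len(comps) - 1]
    mesh = np.meshgrid(*axes, indexing="ij")
    cols = [m.ravel() for m in mesh] + [c.ravel() for c in comps]
    header = [f"# columns={names} {cnames}",
              f"# shape={','.join(str(len(a)) for a in axes)}",
              "# length_unit=cm", "# velocity_unit=cm/s"]
    for k, v in field.meta.items():
        header.append(f"# meta.{k}={v}")
    with path.open("w") as f:
        f.write("\n".join(header) + "\n")
        np.savetxt(f, np.column_stack(cols), fmt="%.9e")


def read_field_text(path) -> VelocityField:
    path = Path(path)
    meta: dict = {}
    shape = None
    with path.open() as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key == "shape":
                shape = tuple(int(s) for s in val.split(","))
            elif key.startswith("meta."):
                meta[key[5:]] = val
    if shape is None:
        raise ValueError(f"{path}: missing '# shape=' header")
    data = np.loadtxt(path)
    ndim = len(shape)
    axes = []
    for k in range(ndim):
        grid = data[:, k].reshape(shape)
        axes.append(np.unique(grid))
    comps = [data[:, ndim + k].reshape(shape) for k in range(ndim)]
    if ndim == 2:
        return VelocityField(axes[0], axes[1], comps[0], comps[1], meta=meta)
    return VelocityField(axes[0], axes[1], comps[0], comps[1],
                         z=axes[2], w=comps[2], meta=meta)


def write_field_npz(field: VelocityField, path) -> None:
    arrays = {"x": field.x, "y": field.y, "u": field.u, "v": field.v,
              "meta": np.array(json.dumps(field.meta, default=str))}
    if field.z is not None:
        arrays["z"] = field.z
        arrays["w"] = field.w
    np.savez(path, **arrays)


def read_field_npz(path) -> VelocityField:
    with np.load(path, allow_pickle=False) as d:
        meta = json.loads(str(d["meta"])) if "meta" in d else {}
        return VelocityField(d["x"], d["y"], d["u"], d["v"],
                             z=d["z"] if "z" in d else None,
                             w=d["w"] if "w" in d else None, meta=meta)


def write_series_npz(series: FieldSeries, path) -> None:
    ref = series.grid
    comps = np.stack([np.stack(f.components) for f in series.fields])
    arrays = {"t": series.t, "x": ref.x, "y": ref.y, "components": comps,
              "meta": np.array(json.dumps(series.meta, default=str))}
    if ref.z is not None:
        arrays["z"] = ref.z
    if series.programmed_rvol is not None:
        arrays["programmed_rvol"] = np.array(series.programmed_rvol)
    if series.systole is not None:
        arrays["systole"] = np.asarray(series.systole)
    np.savez(path, **arrays)


def read_series_npz(path) -> FieldSeries:
    with np.load(path, allow_pickle=False) as d:
        t = d["t"]
        z = d["z"] if "z" in d else None
        comps = d["components"]
        fields = []
        for k in range(len(t)):
            if z is None:
                fields.append(VelocityField(d["x"], d["y"],
                                            comps[k, 0], comps[k, 1]))
            else:
                fields.append(VelocityField(d["x"], d["y"], comps[k, 0],
                                            comps[k, 1], z=z, w=comps[k, 2]))
        rvol = float(d["programmed_rvol"]) if "programmed_rvol" in d else None
        systole = tuple(d["systole"]) if "systole" in d else None
        meta = json.loads(str(d["meta"])) if "meta" in d else {}
        return FieldSeries(t, fields, programmed_rvol=rvol,
                           systole=systole, meta=meta)
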