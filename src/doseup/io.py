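"""Self-describing grid containers (JSON) and CSV export.

A grid file is a JSON object with keys ``format``, ``unit``, ``spacing_mm``,
``origin_mm`` and ``values``; array measurements additionally carry the
boolean ``mask`` and the ``layout`` geometry, so the round-trip is lossless.
JSON float serialization preserves doubles exactly (shortest round-trip
representation).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .detector import ArrayMeasurement, DetectorLayout
from .grids import DoseGrid

__all__ = ["read_grid", "write_grid", "write_csv", "FormatError"]

_FORMAT = "doseup-grid"


class FormatError(ValueError):
    """Malformed grid container."""


def write_grid(obj: DoseGrid | ArrayMeasurement, path) -> None:
    """Write a dose grid or array measurement to a JSON container."""
    if isinstance(obj, ArrayMeasurement):
        grid, layout = obj.grid, obj.layout
        extra = {
            "mask": layout.chamber_mask.astype(int).tolist(),
            "layout": {
                "n_rows": layout.n_rows,
                "n_cols": layout.n_cols,
                "grid_pitch_mm": layout.grid_pitch_mm,
                "chamber_size_mm": layout.chamber_size_mm,
                "name": layout.name,
            },
        }
    elif isinstance(obj, DoseGrid):
        grid, extra = obj, {}
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    doc = {
        "format": _FORMAT,
        "version": 1,
        "unit": grid.unit,
        "spacing_mm": grid.spacing_mm,
        "origin_mm": list(grid.origin_mm),
        "values": grid.values.tolist(),
        **extra,
    }
    Path(path).write_text(json.dumps(doc))


def _require(doc: dict, key: str):
    if key not in doc:
        raise FormatError(f"grid container missing required key {key!r}")
    return doc[key]


def read_grid(path) -> DoseGrid | ArrayMeasurement:
    """Read a grid container; returns an ArrayMeasurement when a mask is present."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"not a valid grid container: {e}") from e
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise FormatError(f"grid container missing required key 'format'={_FORMAT!r}")
    grid = DoseGrid(
        np.asarray(_require(doc, "values"), dtype=float),
        spacing_mm=_require(doc, "spacing_mm"),
        origin_mm=tuple(_require(doc, "origin_mm")),
        unit=doc.get("unit", "Gy"),
    )
    if "mask" not in doc:
        return grid
    lay = _require(doc, "layout")
    layout = DetectorLayout(
        n_rows=_require(lay, "n_rows"),
        n_cols=_require(lay, "n_cols"),
        grid_pitch_mm=_require(lay, "grid_pitch_mm"),
        chamber_mask=np.asarray(doc["mask"], dtype=bool),
        chamber_size_mm=lay.get("chamber_size_mm", 0.0),
        name=lay.get("name", ""),
    )
    return ArrayMeasurement(grid=grid, layout=layout)


def write_csv(grid: DoseGrid | ArrayMeasurement, path) -> None:
    """Plain CSV export of the value matrix (row-major, no metadata)."""
    values = grid.grid.values if isinstance(grid, ArrayMeasurement) else grid.values
    np.savetxt(path, values, delimiter=",", fmt="%.10g")
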