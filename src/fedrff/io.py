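"""Readers and writers for locations, surfaces, policies, and reports.

Everything is plain text: location datasets are CSV with header ``x`` (1D)
or ``x,y`` (2D; ``lat,lon`` headers are accepted and mapped to planar
``(x, y) = (lon, lat)``).  A surface is a CSV matrix plus a JSON sidecar
carrying the grid and provenance metadata; policies and attack reports are
JSON.  Latitude/longitude are treated as planar coordinates — bandwidths
and privacy scores for geographic data are in degrees, and no geodesic
correction is applied.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import List

import numpy as np

from . import __version__
from .adversary import AttackReport
from .grid import GridSpec, Surface
from .protocol import BandwidthPolicy

__all__ = [
    "load_dataset",
    "write_dataset",
    "save_surface",
    "load_surface",
    "save_policy",
    "load_policy",
    "save_attack_reports",
]


class DatasetFormatError(ValueError):
    """Malformed dataset file; the message names the offending line."""


def load_dataset(path) -> np.ndarray:
    """Read locations from CSV; returns an ``(N, dim)`` array.

    Header must be ``x``, ``x,y``, or ``lat,lon`` (the latter is mapped to
    planar ``(lon, lat)``).  Non-numeric or wrong-width rows raise
    :class:`DatasetFormatError` naming the line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [c.strip().lower() for c in next(reader)]
        except StopIteration:
            raise DatasetFormatError(f"{path}: empty file")
        if header == ["x"]:
            dim, latlon = 1, False
        elif header == ["x", "y"]:
            dim, latlon = 2, False
        elif header == ["lat", "lon"]:
            dim, latlon = 2, True
        else:
            raise DatasetFormatError(
                f"{path}: line 1: header must be 'x', 'x,y' or 'lat,lon', got {header}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != dim:
                raise DatasetFormatError(
                    f"{path}: line {lineno}: expected {dim} fields, got {len(row)}"
                )
            try:
                vals = [float(c) for c in row]
            except ValueError:
                raise DatasetFormatError(f"{path}: line {lineno}: non-numeric field in {row}")
            if not all(np.isfinite(vals)):
                raise DatasetFormatError(f"{path}: line {lineno}: non-finite value in {row}")
            if latlon:
                vals = [vals[1], vals[0]]  # (lat, lon) -> (x, y) = (lon, lat)
            rows.append(vals)
    if not rows:
        raise DatasetFormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def write_dataset(points, path) -> None:
    """Write locations as CSV with header ``x`` or ``x,y``."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    header = ["x"] if points.shape[1] == 1 else ["x", "y"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in points:
            writer.writerow([repr(float(v)) for v in row])


def _provenance(meta: dict) -> dict:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return {"package_version": __version__, "config_hash": hashlib.sha256(blob).hexdigest()[:16]}


def save_surface(surface: Surface, prefix) -> None:
    """Write ``<prefix>.csv`` (value matrix) and ``<prefix>.json`` (grid + meta)."""
    prefix = Path(prefix)
    vals = np.atleast_2d(surface.values)
    np.savetxt(prefix.with_suffix(".csv"), vals, delimiter=",")
    sidecar = {
        "grid": surface.grid.to_dict(),
        "meta": surface.meta,
        "provenance": _provenance({**surface.grid.to_dict(), **surface.meta}),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_surface(prefix) -> Surface:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    grid = GridSpec.from_dict(sidecar["grid"])
    vals = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    if grid.dim == 1:
        vals = vals.ravel()
    return Surface(vals, grid, meta=sidecar.get("meta", {}))


def save_policy(policy: BandwidthPolicy, path) -> None:
    Path(path).write_text(json.dumps(policy.to_dict(), indent=2))


def load_policy(path) -> BandwidthPolicy:
    return BandwidthPolicy.from_dict(json.loads(Path(path).read_text()))


def save_attack_reports(reports: List[AttackReport], prefix) -> None:
    """Per-user JSON details plus a system-level CSV table (user, K, Z)."""
    prefix = Path(prefix)
    detail = [r.to_dict() for r in reports]
    prefix.with_suffix(".json").write_text(json.dumps(detail, indent=2))
    with open(prefix.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["user", "K", "Z"])
        for i, r in enumerate(reports):
            writer.writerow([i, r.K, repr(r.z)])
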