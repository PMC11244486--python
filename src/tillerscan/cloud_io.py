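"""Point-cloud and result file input/output.

The package works on single-plant terrestrial-laser-scan clouds expressed in
meters with the vertical axis Z. Supported cloud formats are PCD (ASCII and
uncompressed binary, the export format of the scanner workflow), PLY (via
trimesh, ASCII and binary little-endian) and plain whitespace-separated XYZ
text. Fields beyond x, y, z (color, intensity, ...) are discarded on read.

Extraction results are serialized to JSON (one object per plant) or CSV (one
row per plant). The JSON keys are part of the public contract and documented
in the README:

``crown_radius_m, stem_perimeter_m, plant_height_m, surface_area_m2,
volume_m3, pla_pct, tiller_count, params_used``
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import trimesh

from .errors import CloudIOError, EmptyCloudError, MalformedFileError

__all__ = [
    "PointCloud",
    "PhenotypeResult",
    "read_point_cloud",
    "write_point_cloud",
    "write_results",
    "read_results",
    "RESULT_FIELDS",
]


@dataclass(frozen=True)
class PointCloud:
    """An N x 3 array of (x, y, z) coordinates in meters.

    Invariants enforced at construction: at least one point, every
    coordinate finite. Point order is preserved from the source file but no
    downstream computation relies on it.
    """

    points: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise EmptyCloudError(
                f"point array must have shape (N, 3), got {pts.shape}"
            )
        if pts.shape[0] < 1:
            raise EmptyCloudError("a point cloud must contain at least one point")
        if not np.isfinite(pts).all():
            raise MalformedFileError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def translated(self, offset) -> "PointCloud":
        return PointCloud(self.points + np.asarray(offset, dtype=np.float64))

    def scaled(self, factor: float) -> "PointCloud":
        return PointCloud(self.points * float(factor), source_path=self.source_path)

    def z_extent(self) -> tuple[float, float]:
        z = self.points[:, 2]
        return float(z.min()), float(z.max())


RESULT_FIELDS = (
    "crown_radius_m",
    "stem_perimeter_m",
    "plant_height_m",
    "surface_area_m2",
    "volume_m3",
    "pla_pct",
    "tiller_count",
)


@dataclass
class PhenotypeResult:
    """The seven extracted traits of one plant plus every tunable used.

    Traits that were not requested are ``None``. ``params_used`` is complete
    enough to re-run the extraction deterministically.
    """

    crown_radius: float | None = None       # m
    stem_perimeter: float | None = None     # m
    plant_height: float | None = None       # m
    surface_area: float | None = None       # m^2
    volume: float | None = None             # m^3
    pla: float | None = None                # percent of the bounding rectangle
    tiller_count: int | None = None
    params_used: dict[str, Any] = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self) -> None:
        for name in ("crown_radius", "stem_perimeter", "plant_height",
                     "surface_area", "volume", "pla"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.tiller_count is not None and self.tiller_count < 0:
            raise ValueError("tiller_count must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "crown_radius_m": self.crown_radius,
            "stem_perimeter_m": self.stem_perimeter,
            "plant_height_m": self.plant_height,
            "surface_area_m2": self.surface_area,
            "volume_m3": self.volume,
            "pla_pct": self.pla,
            "tiller_count": self.tiller_count,
            "params_used": self.params_used,
        }
        if self.source is not None:
            d["source"] = self.source
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PhenotypeResult":
        return cls(
            crown_radius=d.get("crown_radius_m"),
            stem_perimeter=d.get("stem_perimeter_m"),
            plant_height=d.get("plant_height_m"),
            surface_area=d.get("surface_area_m2"),
            volume=d.get("volume_m3"),
            pla=d.get("pla_pct"),
            tiller_count=d.get("tiller_count"),
            params_used=dict(d.get("params_used", {})),
            source=d.get("source"),
        )


# ---------------------------------------------------------------------------
# PCD
# ---------------------------------------------------------------------------

_PCD_TYPE_MAP = {("F", 4): "<f4", ("F", 8): "<f8",
                 ("I", 1): "<i1", ("I", 2): "<i2", ("I", 4): "<i4", ("I", 8): "<i8",
                 ("U", 1): "<u1", ("U", 2): "<u2", ("U", 4): "<u4", ("U", 8): "<u8"}


def _read_pcd(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header: dict[str, list[str]] = {}
        while True:
            raw = fh.readline()
            if not raw:
                raise MalformedFileError(f"{path}: truncated PCD header")
            line = raw.decode("ascii", errors="replace").strip()
            if not line or line.startswith("#"):
                continue
            key, *vals = line.split()
            header[key.upper()] = vals
            if key.upper() == "DATA":
                break
        body = fh.read()

    for req in ("FIELDS", "DATA", "POINTS"):
        if req not in header:
            raise MalformedFileError(f"{path}: PCD header missing {req}")
    fields = header["FIELDS"]
    for ax in ("x", "y", "z"):
        if ax not in fields:
            raise MalformedFileError(f"{path}: PCD FIELDS lack '{ax}' (got {fields})")
    n_points = int(header["POINTS"][0])
    if n_points < 1:
        raise MalformedFileError(f"{path}: PCD declares zero points")
    sizes = [int(s) for s in header.get("SIZE", ["4"] * len(fields))]
    types = header.get("TYPE", ["F"] * len(fields))
    counts = [int(c) for c in header.get("COUNT", ["1"] * len(fields))]
    mode = header["DATA"][0].lower()

    if mode == "ascii":
        text = body.decode("ascii", errors="replace")
        # column index of each scalar, honouring COUNT
        col = 0
        cols = {}
        for f_name, c in zip(fields, counts):
            cols[f_name] = col
            col += c
        try:
            arr = np.loadtxt(text.splitlines(), dtype=np.float64, ndmin=2)
        except ValueError as exc:
            raise MalformedFileError(f"{path}: malformed ASCII PCD data: {exc}") from exc
        if arr.shape[0] != n_points:
            raise MalformedFileError(
                f"{path}: PCD declares {n_points} points but body has {arr.shape[0]}"
            )
        if arr.shape[1] < col:
            raise MalformedFileError(f"{path}: PCD rows have too few columns")
        return np.column_stack([arr[:, cols["x"]], arr[:, cols["y"]], arr[:, cols["z"]]])

    if mode == "binary":
        dtype_fields = []
        for f_name, s, t, c in zip(fields, sizes, types, counts):
            key = (t.upper(), s)
            if key not in _PCD_TYPE_MAP:
                raise MalformedFileError(f"{path}: unsupported PCD TYPE/SIZE {t}/{s}")
            base = _PCD_TYPE_MAP[key]
            dtype_fields.append((f_name, base, (c,)) if c > 1 else (f_name, base))
        dt = np.dtype(dtype_fields)
        expected = dt.itemsize * n_points
        if len(body) < expected:
            raise MalformedFileError(
                f"{path}: binary PCD body holds {len(body)} bytes, "
                f"expected {expected}"
            )
        rec = np.frombuffer(body[:expected], dtype=dt, count=n_points)
        return np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(np.float64)

    raise MalformedFileError(
        f"{path}: unsupported PCD DATA mode '{mode}' (ascii/binary only)"
    )


def _write_pcd(points: np.ndarray, path: Path, binary: bool) -> None:
    n = points.shape[0]
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        "FIELDS x y z\n"
        "SIZE 4 4 4\n"
        "TYPE F F F\n"
        "COUNT 1 1 1\n"
        f"WIDTH {n}\n"
        "HEIGHT 1\n"
        "VIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {n}\n"
        f"DATA {'binary' if binary else 'ascii'}\n"
    )
    pts32 = points.astype("<f4")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(pts32.tobytes())
        else:
            np.savetxt(fh, pts32.astype(np.float64), fmt="%.17g")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> np.ndarray:
    rows: list[tuple[float, float, float]] = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 3:
                raise MalformedFileError(
                    f"{path}: line {lineno}: expected at least 3 columns, "
                    f"got {len(tokens)}"
                )
            try:
                rows.append((float(tokens[0]), float(tokens[1]), float(tokens[2])))
            except ValueError as exc:
                raise MalformedFileError(
                    f"{path}: line {lineno}: non-numeric token ({exc})"
                ) from exc
    if not rows:
        raise MalformedFileError(f"{path}: XYZ file contains no points")
    return np.asarray(rows, dtype=np.float64)


def _write_xyz(points: np.ndarray, path: Path) -> None:
    np.savetxt(path, points.astype("<f4").astype(np.float64), fmt="%.17g")


# ---------------------------------------------------------------------------
# PLY (delegated to trimesh)
# ---------------------------------------------------------------------------

def _read_ply(path: Path) -> np.ndarray:
    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:
        raise MalformedFileError(f"{path}: unreadable PLY: {exc}") from exc
    verts = np.asarray(getattr(obj, "vertices", np.empty((0, 3))), dtype=np.float64)
    if verts.shape[0] == 0:
        raise MalformedFileError(f"{path}: PLY file contains no vertices")
    return verts


def _write_ply(points: np.ndarray, path: Path, binary: bool) -> None:
    pc = trimesh.points.PointCloud(points.astype(np.float32).astype(np.float64))
    pc.export(str(path), encoding="binary_little_endian" if binary else "ascii")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_EXTENSIONS = {".pcd": "pcd", ".ply": "ply", ".xyz": "xyz", ".txt": "xyz"}


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    guess = _EXTENSIONS.get(path.suffix.lower())
    if guess is None:
        raise CloudIOError(
            f"{path}: cannot infer cloud format from extension "
            f"'{path.suffix}'; pass format explicitly"
        )
    return guess


def read_point_cloud(path, format: str = "auto", unit_scale: float = 1.0) -> PointCloud:
    """Read a cloud from PCD, PLY or XYZ.

    ``unit_scale`` multiplies all coordinates at read time (e.g. 0.001 for a
    scan exported in millimeters); everything downstream assumes meters.
    """
    p = Path(path)
    if not p.is_file():
        raise CloudIOError(f"no such point-cloud file: {p}")
    fmt = _detect_format(p, format)
    if fmt == "pcd":
        pts = _read_pcd(p)
    elif fmt == "ply":
        pts = _read_ply(p)
    elif fmt == "xyz":
        pts = _read_xyz(p)
    else:
        raise CloudIOError(f"unknown cloud format '{fmt}' (pcd/ply/xyz)")
    if unit_scale != 1.0:
        pts = pts * float(unit_scale)
    return PointCloud(pts, source_path=str(p))


def write_point_cloud(cloud: PointCloud, path, format: str = "auto",
                      binary: bool = False) -> None:
    """Write a cloud; round-trips through :func:`read_point_cloud` preserve
    N and coordinates to 32-bit float precision."""
    p = Path(path)
    if not p.parent.is_dir():
        raise CloudIOError(f"parent directory does not exist: {p.parent}")
    fmt = _detect_format(p, format)
    if fmt == "pcd":
        _write_pcd(cloud.points, p, binary)
    elif fmt == "ply":
        _write_ply(cloud.points, p, binary)
    elif fmt == "xyz":
        _write_xyz(cloud.points, p)
    else:
        raise CloudIOError(f"unknown cloud format '{fmt}' (pcd/ply/xyz)")


def write_results(results, path, format: str = "auto") -> None:
    """Write one or more :class:`PhenotypeResult` records to JSON or CSV.

    JSON holds a list of objects with the documented keys. CSV holds one row
    per plant; writing to an existing CSV appends rows (the header is written
    once).
    """
    if isinstance(results, PhenotypeResult):
        results = [results]
    p = Path(path)
    if not p.parent.is_dir():
        raise CloudIOError(f"parent directory does not exist: {p.parent}")
    fmt = format
    if fmt == "auto":
        fmt = {".json": "json", ".csv": "csv"}.get(p.suffix.lower(), "json")
    if fmt == "json":
        payload = [r.to_dict() for r in results]
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(payload if len(payload) != 1 else payload[0], fh,
                      indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        cols = ("source",) + RESULT_FIELDS + ("params_used",)
        exists = p.is_file() and os.path.getsize(p) > 0
        with open(p, "a", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            if not exists:
                writer.writerow(cols)
            for r in results:
                d = r.to_dict()
                d.setdefault("source", "")
                writer.writerow(
                    [d["source"]] + [d[k] for k in RESULT_FIELDS]
                    + [json.dumps(d["params_used"], sort_keys=True)]
                )
    else:
        raise CloudIOError(f"unknown result format '{fmt}' (json/csv)")


def read_results(path) -> list[PhenotypeResult]:
    """Read back a JSON results file written by :func:`write_results`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [PhenotypeResult.from_dict(d) for d in payload]
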