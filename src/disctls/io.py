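"""Point-cloud, mesh and sample-table I/O with explicit unit handling.

All geometry is carried in the unit the file declares (``m``, ``cm`` or
``mm``); volumes are converted to cm³ only at the reporting boundary, via
:func:`volume_to_cm3`, so no cumulative scaling error accrues inside the
pipeline.

Point clouds are read from PLY (ASCII or binary little-endian, element
``vertex`` with at least x/y/z properties) or whitespace-separated XYZ text.
Extra per-vertex properties (normals, intensity, color) are preserved when
present but never required.  Rows with non-finite coordinates are rejected,
counted and warned about — they never abort a read.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PointCloud",
    "DiscSample",
    "read_point_cloud",
    "write_point_cloud",
    "read_samples_table",
    "write_samples_table",
    "length_factor",
    "volume_to_cm3",
]

#: length-unit → centimetre conversion factors
_UNIT_TO_CM = {"m": 100.0, "cm": 1.0, "mm": 0.1}


def length_factor(from_unit: str, to_unit: str) -> float:
    """Multiplicative factor converting lengths between two supported units."""
    try:
        return _UNIT_TO_CM[from_unit] / _UNIT_TO_CM[to_unit]
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unsupported unit: {exc.args[0]!r} (use m, cm or mm)") from None


def volume_to_cm3(volume: float, unit: str) -> float:
    """Convert a volume expressed in ``unit``³ to cm³ (cube of the length factor)."""
    f = length_factor(unit, "cm")
    return volume * f**3


class EmptyCloudError(ValueError):
    """Raised when a read yields zero valid points."""


@dataclass
class PointCloud:
    """Raw 3D points of one scanned disc.

    Z is "up" (the gravity axis); a disc resting on the ground touches the
    minimum-Z plane.
    """

    points: np.ndarray                      # (n, 3) float64, finite
    unit: str = "m"
    id: str = ""
    extra: Dict[str, np.ndarray] = field(default_factory=dict)  # per-vertex props
    rejected_rows: int = 0                  # non-finite records dropped at read

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(np.atleast_2d(self.points), dtype=np.float64)
        if self.points.size == 0:
            raise EmptyCloudError("point cloud must contain at least one point")
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.unit not in _UNIT_TO_CM:
            raise ValueError(f"unsupported unit {self.unit!r} (use m, cm or mm)")

    def __len__(self) -> int:
        return self.points.shape[0]

    def converted(self, to_unit: str) -> "PointCloud":
        """Return a copy with coordinates rescaled into ``to_unit``."""
        f = length_factor(self.unit, to_unit)
        return PointCloud(self.points * f, unit=to_unit, id=self.id,
                          extra=dict(self.extra), rejected_rows=self.rejected_rows)

    @property
    def normals(self) -> Optional[np.ndarray]:
        if all(k in self.extra for k in ("nx", "ny", "nz")):
            return np.column_stack([self.extra["nx"], self.extra["ny"], self.extra["nz"]])
        return None


@dataclass
class DiscSample:
    """One disc's TLS volume estimate paired with reference replicate volumes.

    The reference volume is the arithmetic mean of up to three water-
    displacement replicate measurements; all volumes are in cm³.
    """

    id: str
    species: str
    estimated_volume: float
    reference_replicates: Sequence[float]
    reference_volume: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        reps = [float(r) for r in self.reference_replicates if np.isfinite(r)]
        if not 1 <= len(reps) <= 3:
            raise ValueError("need 1–3 finite reference replicates")
        self.reference_replicates = reps
        if self.reference_volume is None:
            self.reference_volume = float(np.mean(reps))
        if self.estimated_volume <= 0 or any(r <= 0 for r in reps) or self.reference_volume <= 0:
            raise ValueError("all volumes must be strictly positive")
        if abs(self.reference_volume - np.mean(reps)) > 0.5 + 1e-9 * abs(self.reference_volume):
            raise ValueError("reference_volume must equal the replicate mean (to rounding)")


# ---------------------------------------------------------------------------
# PLY / XYZ point clouds
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _parse_ply_header(fh) -> tuple:
    magic = fh.readline().strip()
    if magic != b"ply":
        raise ValueError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: List[tuple] = []  # (name, count, [(prop_name, dtype_code)])
    while True:
        line = fh.readline()
        if not line:
            raise ValueError("unterminated PLY header")
        tokens = line.decode("ascii", "replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if tokens[1] == "list":
                elements[-1][2].append((tokens[-1], "list", tokens[2], tokens[3]))
            else:
                elements[-1][2].append((tokens[-1], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def _read_ply_vertices(path: Path) -> Dict[str, np.ndarray]:
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        out: Dict[str, np.ndarray] = {}
        for name, count, props in elements:
            if any(p[1] == "list" for p in props):
                if name == "vertex":
                    raise ValueError("list properties on vertex element are unsupported")
                break  # faces etc. — not needed for a point cloud
            dtype = np.dtype([(p[0], ("<" + p[1]) if fmt != "ascii" else p[1]) for p in props])
            if fmt == "ascii":
                rows = [fh.readline().split() for _ in range(count)]
                arr = np.array([tuple(r) for r in rows], dtype=dtype)
            else:
                arr = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
            if name == "vertex":
                for p in props:
                    out[p[0]] = np.asarray(arr[p[0]], dtype=np.float64)
                return out
    raise ValueError("PLY file has no 'vertex' element")


def read_point_cloud(path: Union[str, Path], unit: str = "m",
                     sample_id: Optional[str] = None) -> PointCloud:
    """Read a point cloud from a PLY or XYZ file.

    Parameters
    ----------
    path : path to a ``.ply`` (ASCII or binary little-endian) or whitespace
        XYZ text file (≥3 columns; extra columns ignored).
    unit : declared length unit of the coordinates (``m``, ``cm``, ``mm``).
    sample_id : free-text label; defaults to the file stem.

    Non-finite rows are dropped with a warning and counted in
    ``PointCloud.rejected_rows``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(3)
    extra: Dict[str, np.ndarray] = {}
    if magic == b"ply":
        cols = _read_ply_vertices(path)
        for axis in "xyz":
            if axis not in cols:
                raise ValueError(f"PLY vertex element lacks property {axis!r}")
        pts = np.column_stack([cols.pop("x"), cols.pop("y"), cols.pop("z")])
        extra = cols
    else:
        rows, nrej = [], 0
        with open(path, "rt") as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                try:
                    xyz = [float(parts[0]), float(parts[1]), float(parts[2])]
                except (ValueError, IndexError):
                    nrej += 1
                    continue
                rows.append(xyz)
        pts = np.asarray(rows, dtype=np.float64).reshape(-1, 3)
        finite = np.isfinite(pts).all(axis=1) if pts.size else np.zeros(0, bool)
        nrej += int((~finite).sum())
        pts = pts[finite]
        if pts.shape[0] == 0:
            raise EmptyCloudError(f"no valid points in {path}")
        if nrej:
            warnings.warn(f"{path}: rejected {nrej} malformed/non-finite rows")
        return PointCloud(pts, unit=unit, id=sample_id or path.stem, rejected_rows=nrej)

    finite = np.isfinite(pts).all(axis=1)
    nrej = int((~finite).sum())
    if nrej:
        warnings.warn(f"{path}: rejected {nrej} non-finite vertices")
        pts = pts[finite]
        extra = {k: v[finite] for k, v in extra.items()}
    if pts.shape[0] == 0:
        raise EmptyCloudError(f"no valid points in {path}")
    return PointCloud(pts, unit=unit, id=sample_id or path.stem,
                      extra=extra, rejected_rows=nrej)


def write_point_cloud(cloud: PointCloud, path: Union[str, Path],
                      fmt: str = "ply_binary") -> None:
    """Write a point cloud as ``ply_ascii``, ``ply_binary`` or ``xyz``.

    Per-vertex extras (``nx``/``ny``/``nz`` normals, intensity, …) are written
    as additional PLY properties; XYZ output carries coordinates only.
    """
    path = Path(path)
    pts = cloud.points
    if fmt == "xyz":
        np.savetxt(path, pts, fmt="%.17g")
        return
    if fmt not in ("ply_ascii", "ply_binary"):
        raise ValueError(f"unknown format {fmt!r}")
    names = ["x", "y", "z"] + list(cloud.extra)
    cols = [pts[:, 0], pts[:, 1], pts[:, 2]] + [np.asarray(cloud.extra[k], float) for k in cloud.extra]
    header = ["ply",
              "format ascii 1.0" if fmt == "ply_ascii" else "format binary_little_endian 1.0",
              f"comment unit {cloud.unit}",
              f"element vertex {len(cloud)}"]
    header += [f"property double {n}" for n in names]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        data = np.rec.fromarrays(cols, dtype=[(n, "<f8") for n in names])
        if fmt == "ply_binary":
            fh.write(data.tobytes())
        else:
            buf = _io.StringIO()
            np.savetxt(buf, np.column_stack(cols), fmt="%.17g")
            fh.write(buf.getvalue().encode("ascii"))


# ---------------------------------------------------------------------------
# Paired-volume sample tables
# ---------------------------------------------------------------------------

def read_samples_table(path: Union[str, Path]) -> List[DiscSample]:
    """Read a CSV of paired disc volumes into :class:`DiscSample` records.

    Required columns: ``id, species, estimated_volume, rep1`` (``rep2``,
    ``rep3`` optional).  Rows with non-positive volumes are rejected with a
    warning; they never abort the read.
    """
    df = pd.read_csv(path)
    required = {"id", "species", "estimated_volume", "rep1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"samples table missing required columns: {sorted(missing)}")
    rep_cols = [c for c in ("rep1", "rep2", "rep3") if c in df.columns]
    samples: List[DiscSample] = []
    nrej = 0
    for _, row in df.iterrows():
        reps = [row[c] for c in rep_cols if pd.notna(row[c])]
        try:
            samples.append(DiscSample(str(row["id"]), str(row["species"]),
                                      float(row["estimated_volume"]), reps))
        except (ValueError, TypeError):
            nrej += 1
    if nrej:
        warnings.warn(f"{path}: rejected {nrej} invalid sample rows")
    return samples


def write_samples_table(samples: Sequence[DiscSample], path: Union[str, Path]) -> None:
    rows = []
    for s in samples:
        reps = list(s.reference_replicates) + [np.nan] * (3 - len(s.reference_replicates))
        rows.append({"id": s.id, "species": s.species,
                     "estimated_volume": s.estimated_volume,
                     "rep1": reps[0], "rep2": reps[1], "rep3": reps[2]})
    pd.DataFrame(rows).to_csv(path, index=False)
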