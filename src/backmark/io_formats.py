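"""Container types and file I/O for organized depth frames, point clouds,
landmark sets and multi-rater annotation stores.

Coordinate convention (camera frame of a front-facing ToF sensor):
``x`` frontal axis (left to right), ``y`` longitudinal axis (bottom to
top), ``z`` sagittal axis (distance from the camera).  All coordinates
are stored in meters; millimeter conversions happen only in reporting.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical landmark names: left/right axilla, left/right shoulder,
#: left/right waist indentation, cervicothoracic junction, thoracic
#: kyphosis apex, lumbar lordosis apex, sacral base.
LANDMARK_NAMES = ("AL", "AR", "SL", "SR", "WL", "WR", "C7T1", "TK", "LL", "S1")

DEFAULT_GRID_SHAPE = (144, 176)


class FrameParseError(ValueError):
    """Malformed organized-frame file."""


class FrameShapeError(ValueError):
    """Frame matrices disagree with the declared grid shape."""


class CloudFormatError(ValueError):
    """Unrecognized or malformed point-cloud file."""


class AnnotationIntegrityError(ValueError):
    """Duplicate (cloud_id, rater_id) record or malformed annotation file."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class OrganizedFrame:
    """One ToF acquisition: per-pixel (x, y, z) on an H x W sensor grid.

    Invalid pixels (dropouts, out-of-range returns) are marked in
    ``valid``; their coordinate entries are NaN.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise FrameShapeError(
                f"frame matrices have inconsistent shapes: "
                f"{self.x.shape}, {self.y.shape}, {self.z.shape}")
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.z)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {self.x.shape, self.y.shape, self.z.shape, self.valid.shape}
        if len(shapes) != 1:
            raise FrameShapeError(f"frame matrices have inconsistent shapes: {shapes}")
        if np.any(self.z[self.valid] < 0):
            raise ValueError("valid pixels must have non-negative depth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_cloud(self, source_id: str | None = None) -> "PointCloud":
        """Flatten the frame into an unordered cloud of its valid pixels."""
        pts = np.column_stack(
            [self.x[self.valid], self.y[self.valid], self.z[self.valid]]
        )
        return PointCloud(pts, source_id=source_id)


@dataclass
class PointCloud:
    """Unordered set of 3-D points in meters, camera coordinates."""

    points: np.ndarray
    source_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.points[mask], source_id=self.source_id)


@dataclass(frozen=True)
class LandmarkFailure:
    """Recorded reason why a landmark could not be located."""

    reason: str


class LandmarkSet:
    """Named 3-D positions for the 10 back-surface landmarks.

    Each entry is either a length-3 position (meters) or a
    :class:`LandmarkFailure`.  Keys are exactly :data:`LANDMARK_NAMES`;
    unset landmarks default to a ``"not_computed"`` failure so that a
    set is always total.
    """

    def __init__(self, entries: Mapping[str, object] | None = None) -> None:
        self._entries: dict[str, object] = {
            name: LandmarkFailure("not_computed") for name in LANDMARK_NAMES
        }
        if entries:
            for name, value in entries.items():
                self[name] = value

    def __setitem__(self, name: str, value) -> None:
        if name not in LANDMARK_NAMES:
            raise KeyError(f"unknown landmark {name!r}")
        if isinstance(value, LandmarkFailure):
            self._entries[name] = value
        else:
            pt = np.asarray(value, dtype=float).reshape(3)
            if not np.all(np.isfinite(pt)):
                raise ValueError(f"landmark {name} has non-finite coordinates")
            self._entries[name] = pt

    def __getitem__(self, name: str):
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(LANDMARK_NAMES)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        for name in LANDMARK_NAMES:
            a, b = self[name], other[name]
            if isinstance(a, LandmarkFailure) != isinstance(b, LandmarkFailure):
                return False
            if isinstance(a, LandmarkFailure):
                if a.reason != b.reason:
                    return False
            elif not np.array_equal(a, b):
                return False
        return True

    def is_present(self, name: str) -> bool:
        return not isinstance(self._entries[name], LandmarkFailure)

    def present(self) -> dict[str, np.ndarray]:
        return {n: v for n, v in self._entries.items() if not isinstance(v, LandmarkFailure)}

    def failures(self) -> dict[str, str]:
        return {
            n: v.reason for n, v in self._entries.items() if isinstance(v, LandmarkFailure)
        }

    def position(self, name: str) -> np.ndarray:
        value = self._entries[name]
        if isinstance(value, LandmarkFailure):
            raise KeyError(f"landmark {name} failed: {value.reason}")
        return value

    def to_jsonable(self) -> dict:
        out: dict[str, object] = {}
        for name in LANDMARK_NAMES:
            value = self._entries[name]
            if isinstance(value, LandmarkFailure):
                out[name] = {"failed": value.reason}
            else:
                out[name] = [float(c) for c in value]
        return out

    @classmethod
    def from_jsonable(cls, data: Mapping[str, object]) -> "LandmarkSet":
        ls = cls()
        for name, value in data.items():
            if isinstance(value, Mapping):
                ls[name] = LandmarkFailure(str(value["failed"]))
            else:
                ls[name] = value
        return ls

    def __repr__(self) -> str:
        n = len(self.present())
        return f"LandmarkSet({n}/{len(LANDMARK_NAMES)} present)"


@dataclass
class AnnotationStore:
    """Landmark indications per (cloud, rater).

    Raters are typically the experts ``E1``–``E3`` and the automatic
    method ``M``.  At most one :class:`LandmarkSet` per (cloud, rater).
    """

    _records: dict[tuple[str, str], LandmarkSet] = field(default_factory=dict)

    def add(self, cloud_id: str, rater_id: str, landmarks: LandmarkSet,
            replace: bool = False) -> None:
        key = (str(cloud_id), str(rater_id))
        if key in self._records and not replace:
            raise AnnotationIntegrityError(f"duplicate record for {key}")
        self._records[key] = landmarks

    def get(self, cloud_id: str, rater_id: str) -> LandmarkSet | None:
        return self._records.get((cloud_id, rater_id))

    @property
    def cloud_ids(self) -> list[str]:
        return sorted({c for c, _ in self._records})

    @property
    def rater_ids(self) -> list[str]:
        return sorted({r for _, r in self._records})

    def __len__(self) -> int:
        return len(self._records)

    def items(self):
        return self._records.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationStore):
            return NotImplemented
        return self._records == other._records


# ---------------------------------------------------------------------------
# Organized frames: matrix-text and HDF5 dialects
# ---------------------------------------------------------------------------

_FRAME_MAGIC = "BACKMARK-FRAME 1"


def write_frame(frame: OrganizedFrame, path: str | Path,
                dialect: str = "matrix-text") -> None:
    """Write an organized frame; ``dialect`` is ``matrix-text`` or ``hdf5``.

    Invalid pixels are stored as NaN and recovered as such; the text
    dialect uses ``repr``-exact floats so round-trips are bit-exact.
    """
    path = Path(path)
    if dialect == "matrix-text":
        h, w = frame.shape
        with path.open("w") as fh:
            fh.write(f"{_FRAME_MAGIC}\n")
            fh.write(f"shape {h} {w}\n")
            ts = "none" if frame.timestamp is None else repr(float(frame.timestamp))
            fh.write(f"timestamp {ts}\n")
            for name, mat in (("X", frame.x), ("Y", frame.y), ("Z", frame.z)):
                fh.write(f"{name}\n")
                masked = np.where(frame.valid, mat, np.nan)
                for row in masked:
                    fh.write(" ".join(repr(float(v)) for v in row))
                    fh.write("\n")
    elif dialect == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = _FRAME_MAGIC
            fh.attrs["shape"] = frame.shape
            if frame.timestamp is not None:
                fh.attrs["timestamp"] = float(frame.timestamp)
            for name, mat in (("x", frame.x), ("y", frame.y), ("z", frame.z)):
                fh.create_dataset(name, data=np.where(frame.valid, mat, np.nan),
                                  chunks=True)
            fh.create_dataset("valid", data=frame.valid, chunks=True)
    else:
        raise ValueError(f"unknown frame dialect {dialect!r}")


def read_frame(path: str | Path, dialect: str | None = None) -> OrganizedFrame:
    """Read an organized frame written by :func:`write_frame`.

    The dialect is inferred from the extension (``.h5``/``.hdf5`` vs
    text) when not given.  Pixels with any non-finite coordinate are
    marked invalid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "matrix-text"
    if dialect == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            ts = float(fh.attrs["timestamp"]) if "timestamp" in fh.attrs else None
            return OrganizedFrame(
                x=fh["x"][()], y=fh["y"][()], z=fh["z"][()],
                valid=fh["valid"][()], timestamp=ts,
            )
    if dialect != "matrix-text":
        raise ValueError(f"unknown frame dialect {dialect!r}")

    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _FRAME_MAGIC:
        raise FrameParseError(f"{path}: line 1: missing {_FRAME_MAGIC!r} header")
    try:
        _, h_s, w_s = lines[1].split()
        h, w = int(h_s), int(w_s)
    except (IndexError, ValueError) as exc:
        raise FrameParseError(f"{path}: line 2: malformed shape declaration") from exc
    ts_field = lines[2].split()
    if len(ts_field) != 2 or ts_field[0] != "timestamp":
        raise FrameParseError(f"{path}: line 3: malformed timestamp line")
    timestamp = None if ts_field[1] == "none" else float(ts_field[1])

    mats: dict[str, np.ndarray] = {}
    idx = 3
    for name in ("X", "Y", "Z"):
        if idx >= len(lines) or lines[idx].strip() != name:
            raise FrameParseError(f"{path}: line {idx + 1}: expected block {name!r}")
        idx += 1
        block = lines[idx : idx + h]
        if len(block) < h:
            raise FrameShapeError(f"{path}: block {name} has {len(block)} rows, expected {h}")
        try:
            mat = np.array([[float(v) for v in row.split()] for row in block])
        except ValueError as exc:
            raise FrameParseError(f"{path}: block {name}: unparseable value") from exc
        if mat.shape != (h, w):
            raise FrameShapeError(
                f"{path}: block {name} parsed to {mat.shape}, declared ({h}, {w})"
            )
        mats[name] = mat
        idx += h
    return OrganizedFrame(x=mats["X"], y=mats["Y"], z=mats["Z"],
                          valid=None, timestamp=timestamp)


# ---------------------------------------------------------------------------
# Point clouds: PLY / XYZ / CSV
# ---------------------------------------------------------------------------


def write_cloud(cloud: PointCloud, path: str | Path, fmt: str | None = None,
                binary: bool = False) -> None:
    """Write a point cloud as PLY (ascii or binary little-endian), XYZ or CSV."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    pts = cloud.points
    if fmt == "ply":
        header = [
            "ply",
            "format binary_little_endian 1.0" if binary else "format ascii 1.0",
            f"element vertex {len(pts)}",
            "property double x",
            "property double y",
            "property double z",
            "end_header",
        ]
        if binary:
            with path.open("wb") as fh:
                fh.write(("\n".join(header) + "\n").encode("ascii"))
                fh.write(pts.astype("<f8").tobytes())
        else:
            with path.open("w") as fh:
                fh.write("\n".join(header) + "\n")
                for p in pts:
                    fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
    elif fmt == "xyz":
        with path.open("w") as fh:
            for p in pts:
                fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "z"])
            for p in pts:
                writer.writerow([repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
    else:
        raise CloudFormatError(f"unknown point-cloud format {fmt!r}")


def _read_ply(path: Path) -> np.ndarray:
    with path.open("rb") as fh:
        raw = fh.read()
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise CloudFormatError(f"{path}: not a PLY file")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end + len(b"end_header\n"):]
    fmt = None
    n_vertex = 0
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header[1:]:
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            props.append((tok[1], tok[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise CloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
    names = [name for _, name in props]
    for axis in "xyz":
        if axis not in names:
            raise CloudFormatError(f"{path}: PLY vertex element lacks property {axis!r}")
    if fmt == "ascii":
        rows = body.decode("ascii").split()
        vals = np.array([float(v) for v in rows], dtype=float)
        if vals.size < n_vertex * len(props):
            raise CloudFormatError(f"{path}: truncated PLY body")
        table = vals[: n_vertex * len(props)].reshape(n_vertex, len(props))
    else:
        np_types = {"float": "<f4", "float32": "<f4", "double": "<f8",
                    "float64": "<f8", "uchar": "u1", "uint8": "u1",
                    "int": "<i4", "int32": "<i4"}
        try:
            dtype = np.dtype([(name, np_types[t]) for t, name in props])
        except KeyError as exc:
            raise CloudFormatError(f"{path}: unsupported PLY property type") from exc
        if len(body) < n_vertex * dtype.itemsize:
            raise CloudFormatError(f"{path}: truncated PLY body")
        rec = np.frombuffer(body, dtype=dtype, count=n_vertex)
        table = np.column_stack([rec[name].astype(float) for _, name in props])
    cols = [names.index(a) for a in "xyz"]
    return table[:, cols]


def read_cloud(path: str | Path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud; format from extension unless given (ply/xyz/csv)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        pts = _read_ply(path)
    elif fmt == "xyz":
        text = path.read_text().split()
        if not text:
            logger.warning("empty point-cloud file %s", path)
            pts = np.empty((0, 3))
        else:
            vals = np.array([float(v) for v in text])
            if vals.size % 3:
                raise CloudFormatError(f"{path}: XYZ token count not divisible by 3")
            pts = vals.reshape(-1, 3)
    elif fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                logger.warning("empty point-cloud file %s", path)
                return PointCloud(np.empty((0, 3)), source_id=path.stem)
            cols = {name.strip().lower(): i for i, name in enumerate(header)}
            if not {"x", "y", "z"} <= set(cols):
                raise CloudFormatError(f"{path}: CSV header must contain x,y,z")
            rows = [[float(r[cols["x"]]), float(r[cols["y"]]), float(r[cols["z"]])]
                    for r in reader if r]
            pts = np.array(rows) if rows else np.empty((0, 3))
    else:
        raise CloudFormatError(f"unknown point-cloud format {fmt!r}")
    if len(pts) == 0:
        logger.warning("point-cloud file %s contains no points", path)
    return PointCloud(pts, source_id=path.stem)


# ---------------------------------------------------------------------------
# Annotation stores: JSON and long-form CSV
# ---------------------------------------------------------------------------


def write_annotations(store: AnnotationStore, path: str | Path,
                      fmt: str | None = None) -> None:
    """Serialize an annotation store as nested JSON or long-form CSV."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        nested: dict[str, dict[str, dict]] = {}
        for (cloud_id, rater_id), ls in sorted(store.items()):
            nested.setdefault(cloud_id, {})[rater_id] = ls.to_jsonable()
        path.write_text(json.dumps(nested, indent=1, sort_keys=True))
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cloud_id", "rater_id", "landmark", "x", "y", "z",
                             "failed_reason"])
            for (cloud_id, rater_id), ls in sorted(store.items()):
                for name in LANDMARK_NAMES:
                    val = ls[name]
                    if isinstance(val, LandmarkFailure):
                        writer.writerow([cloud_id, rater_id, name, "", "", "",
                                         val.reason])
                    else:
                        writer.writerow([cloud_id, rater_id, name, repr(float(val[0])),
                                         repr(float(val[1])), repr(float(val[2])), ""])
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


def read_annotations(path: str | Path, fmt: str | None = None) -> AnnotationStore:
    """Read an annotation store written by :func:`write_annotations`."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    store = AnnotationStore()
    if fmt == "json":
        nested = json.loads(path.read_text())
        for cloud_id, raters in nested.items():
            for rater_id, entries in raters.items():
                store.add(cloud_id, rater_id, LandmarkSet.from_jsonable(entries))
    elif fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            partial: dict[tuple[str, str], LandmarkSet] = {}
            for row in reader:
                key = (row["cloud_id"], row["rater_id"])
                ls = partial.setdefault(key, LandmarkSet())
                if row["failed_reason"]:
                    ls[row["landmark"]] = LandmarkFailure(row["failed_reason"])
                else:
                    ls[row["landmark"]] = [float(row["x"]), float(row["y"]),
                                           float(row["z"])]
            for (cloud_id, rater_id), ls in partial.items():
                store.add(cloud_id, rater_id, ls)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return store
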