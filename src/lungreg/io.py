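"""Point-cloud and motion-field file formats.

Supported cloud formats: PLY (ascii and binary little-endian vertex
elements with x/y/z and optional nx/ny/nz), OBJ (``v``/``vn`` lines,
faces ignored) and XYZ tables (whitespace- or comma-delimited, 3 or 6
columns, ``#`` comments).  Motion fields are 6-column delimited tables
``x y z dx dy dz`` with an optional header line.  ASCII output uses nine
significant digits; binary PLY stores doubles, so a write/read roundtrip
is bit-exact.  All coordinates are millimetres.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import PointCloud
from .synthetic import MotionField

__all__ = [
    "read_cloud",
    "write_cloud",
    "read_motion_field",
    "write_motion_field",
]

_PLY_TYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "char": ("<i1", 1), "int8": ("<i1", 1),
    "uchar": ("<u1", 1), "uint8": ("<u1", 1),
    "short": ("<i2", 2), "int16": ("<i2", 2),
    "ushort": ("<u2", 2), "uint16": ("<u2", 2),
    "int": ("<i4", 4), "int32": ("<i4", 4),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
}


class CloudFormatError(ValueError):
    """Malformed point-cloud or motion-field file."""


def _fail(path, lineno, msg):
    raise CloudFormatError(f"{path}:{lineno}: {msg}")


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if magic.strip() != b"ply":
            _fail(path, 1, "not a PLY file (missing 'ply' magic)")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                _fail(path, lineno, "unexpected end of header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                if tokens[1] not in ("ascii", "binary_little_endian"):
                    _fail(path, lineno, f"unsupported PLY format {tokens[1]!r}")
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    _fail(path, lineno, "property before any element")
                if tokens[1] == "list":
                    elements[-1][2].append(("list:" + tokens[2] + ":" + tokens[3],
                                            tokens[4]))
                else:
                    elements[-1][2].append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt is None:
            _fail(path, lineno, "missing 'format' line")
        if not elements or elements[0][0] != "vertex":
            _fail(path, lineno, "first PLY element must be 'vertex'")
        _, n_vertex, props = elements[0]
        if n_vertex < 1:
            _fail(path, lineno, "zero vertices")
        names = [p[1] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                _fail(path, lineno, f"vertex element lacks property {axis!r}")
        has_normals = all(a in names for a in ("nx", "ny", "nz"))
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                line = fh.readline()
                lineno += 1
                vals = line.split()
                if len(vals) != len(props):
                    _fail(path, lineno,
                          f"expected {len(props)} values, got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    _fail(path, lineno, "non-numeric vertex value")
            arr = np.asarray(rows)
            cols = {name: arr[:, j] for j, (_, name) in enumerate(props)}
        else:
            dtypes = []
            for typ, name in props:
                if typ.startswith("list:"):
                    _fail(path, lineno, "list property in vertex element")
                if typ not in _PLY_TYPES:
                    _fail(path, lineno, f"unsupported property type {typ!r}")
                dtypes.append((name, _PLY_TYPES[typ][0]))
            dt = np.dtype(dtypes)
            buf = fh.read(dt.itemsize * n_vertex)
            if len(buf) < dt.itemsize * n_vertex:
                _fail(path, lineno, "truncated binary vertex data")
            rec = np.frombuffer(buf, dtype=dt, count=n_vertex)
            cols = {name: rec[name].astype(float) for _, name in props}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if has_normals:
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
        lens = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = np.divide(normals, lens, out=np.zeros_like(normals), where=lens > 0)
        if (lens == 0).any():
            normals = None  # degenerate normals dropped
    return PointCloud(points, normals)


def _write_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    names = ["x", "y", "z"] + (["nx", "ny", "nz"] if cloud.normals is not None else [])
    data = cloud.points if cloud.normals is None else np.column_stack(
        [cloud.points, cloud.normals])
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {cloud.n}"]
    header += [f"property double {name}" for name in names]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(data, dtype="<f8").tobytes())
        else:
            np.savetxt(fh, data, fmt="%.9g")


def _read_obj(path: Path) -> PointCloud:
    verts, norms = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if tokens[0] == "v":
                if len(tokens) < 4:
                    _fail(path, lineno, "vertex line needs 3 coordinates")
                try:
                    verts.append([float(v) for v in tokens[1:4]])
                except ValueError:
                    _fail(path, lineno, "non-numeric vertex coordinate")
            elif tokens[0] == "vn":
                if len(tokens) < 4:
                    _fail(path, lineno, "normal line needs 3 components")
                try:
                    norms.append([float(v) for v in tokens[1:4]])
                except ValueError:
                    _fail(path, lineno, "non-numeric normal component")
            # faces and all other records are ignored
    if not verts:
        raise CloudFormatError(f"{path}: no vertices found")
    points = np.asarray(verts)
    normals = None
    if len(norms) == len(verts):
        normals = np.asarray(norms)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(points, normals)


def _write_obj(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for p in cloud.points:
            fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        if cloud.normals is not None:
            for m in cloud.normals:
                fh.write(f"vn {m[0]:.9g} {m[1]:.9g} {m[2]:.9g}\n")


def _read_table(path: Path, n_cols: tuple[int, ...]):
    rows = []
    header_skipped = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            vals = line.replace(",", " ").split()
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                if not header_skipped and not rows:
                    header_skipped = True  # single optional header line
                    continue
                _fail(path, lineno, "non-numeric row")
            if len(rows[-1]) not in n_cols:
                _fail(path, lineno,
                      f"expected {' or '.join(map(str, n_cols))} columns, "
                      f"got {len(rows[-1])}")
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                _fail(path, lineno, "inconsistent column count")
    if not rows:
        raise CloudFormatError(f"{path}: no data rows")
    return np.asarray(rows)


def _read_xyz(path: Path) -> PointCloud:
    arr = _read_table(path, (3, 6))
    normals = None
    if arr.shape[1] == 6:
        normals = arr[:, 3:6]
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(arr[:, :3], normals)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    data = cloud.points if cloud.normals is None else np.column_stack(
        [cloud.points, cloud.normals])
    np.savetxt(path, data, fmt="%.9g")


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "obj"):
        return suffix
    if suffix in ("xyz", "txt", "csv", "tsv"):
        return "xyz"
    with open(path, "rb") as fh:
        head = fh.read(64)
    if head.startswith(b"ply"):
        return "ply"
    if head.lstrip()[:2] in (b"v ", b"vn"):
        return "obj"
    return "xyz"


def read_cloud(path: str | Path, fmt: str = "auto") -> PointCloud:
    """Read a point cloud; format from extension/header sniffing by default."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "obj":
        return _read_obj(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown cloud format: {fmt!r}")


def write_cloud(cloud: PointCloud, path: str | Path, fmt: str = "auto") -> None:
    """Write a point cloud (PLY defaults to binary little-endian;
    ``fmt='ply-ascii'`` forces ascii)."""
    path = Path(path)
    if fmt == "auto":
        fmt = _detect_format_for_write(path)
    if fmt == "ply":
        _write_ply(cloud, path, binary=True)
    elif fmt == "ply-ascii":
        _write_ply(cloud, path, binary=False)
    elif fmt == "obj":
        _write_obj(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise ValueError(f"unknown cloud format: {fmt!r}")


def _detect_format_for_write(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "ply":
        return "ply"
    if suffix == "obj":
        return "obj"
    return "xyz"


def read_motion_field(path: str | Path) -> tuple[PointCloud, MotionField]:
    """Read a 6-column ``x y z dx dy dz`` table.

    Returns the anchor points and the displacement field; ids are
    assigned by row order.
    """
    path = Path(path)
    arr = _read_table(path, (6,))
    ids = np.arange(arr.shape[0])
    return (PointCloud(arr[:, :3], ids=ids), MotionField(arr[:, 3:6], ids=ids))


def write_motion_field(path: str | Path, cloud: PointCloud,
                       field: MotionField) -> None:
    """Write anchor points and displacements as a 6-column table."""
    if cloud.n != field.n:
        raise ValueError("cloud and field must have the same number of points")
    data = np.column_stack([cloud.points, field.displacements])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t",
               header="x\ty\tz\tdx\tdy\tdz", comments="# ")
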