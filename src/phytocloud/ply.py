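"""PLY reader/writer for colored point clouds.

Supports the vertex element in ``ascii`` and ``binary_little_endian`` PLY:
``x,y,z`` positions, ``red,green,blue`` 8-bit colors, an integer ``leaf``
property for leaf labels, and arbitrary extra scalar properties which
round-trip through the cloud's named attributes.  The cloud's coordinate
frame tag is persisted in a header comment so calibrated clouds survive a
write/read cycle.

Only vertex data is interpreted; face or edge elements are skipped on read
and never written.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .cloud import RAW, CALIBRATED, ColoredPointCloud
from .errors import ColorlessCloudError, PlyParseError

_PLY_TO_NUMPY = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_FRAME_COMMENT = "phytocloud frame="


def _parse_header(stream: io.BufferedReader):
    magic = stream.readline().strip()
    if magic != b"ply":
        raise PlyParseError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    frame = RAW
    while True:
        raw = stream.readline()
        if not raw:
            raise PlyParseError("unexpected end of file inside PLY header")
        line = raw.decode("ascii", errors="replace").strip()
        if not line:
            continue
        tokens = line.split()
        keyword = tokens[0]
        if keyword == "format":
            if len(tokens) < 2 or tokens[1] not in ("ascii", "binary_little_endian"):
                raise PlyParseError(f"unsupported PLY format line: {line!r}")
            fmt = tokens[1]
        elif keyword == "comment":
            rest = line[len("comment"):].strip()
            if rest.startswith(_FRAME_COMMENT):
                tag = rest[len(_FRAME_COMMENT):]
                if tag in (RAW, CALIBRATED):
                    frame = tag
        elif keyword == "element":
            if len(tokens) != 3:
                raise PlyParseError(f"malformed element line: {line!r}")
            elements.append((tokens[1], int(tokens[2]), []))
        elif keyword == "property":
            if not elements:
                raise PlyParseError("property declared before any element")
            if tokens[1] == "list":
                elements[-1][2].append(("__list__", " ".join(tokens[2:])))
            else:
                if len(tokens) != 3:
                    raise PlyParseError(f"malformed property line: {line!r}")
                ply_type, name = tokens[1], tokens[2]
                if ply_type not in _PLY_TO_NUMPY:
                    raise PlyParseError(
                        f"unknown property type {ply_type!r} in element "
                        f"{elements[-1][0]!r}"
                    )
                elements[-1][2].append((name, ply_type))
        elif keyword == "end_header":
            break
        elif keyword == "obj_info":
            continue
        else:
            raise PlyParseError(f"unrecognized header keyword {keyword!r}")
    if fmt is None:
        raise PlyParseError("PLY header missing format line")
    return fmt, elements, frame


def _read_element_ascii(stream, count: int, props) -> np.ndarray:
    dtype = np.dtype([(name, "f8" if _PLY_TO_NUMPY[t][0] == "f" else "i8")
                      for name, t in props])
    out = np.empty(count, dtype=dtype)
    for i in range(count):
        line = stream.readline()
        if not line:
            raise PlyParseError(f"vertex element truncated at row {i}")
        values = line.split()
        if len(values) != len(props):
            raise PlyParseError(
                f"vertex row {i} has {len(values)} values, expected {len(props)}"
            )
        for (name, t), v in zip(props, values):
            out[name][i] = float(v) if _PLY_TO_NUMPY[t][0] == "f" else int(float(v))
    return out


def read_ply(path: str | Path) -> ColoredPointCloud:
    """Read a colored point cloud from a PLY file.

    Raises :class:`ColorlessCloudError` when the vertex element lacks
    red/green/blue (the chlorophyll pipeline requires RGB), and
    :class:`PlyParseError` on malformed input.
    """
    path = Path(path)
    with open(path, "rb") as stream:
        fmt, elements, frame = _parse_header(stream)
        vertex = None
        for name, count, props in elements:
            if any(p[0] == "__list__" for p in props):
                if name == "vertex":
                    raise PlyParseError("list properties on vertex are unsupported")
                # cannot skip list-typed elements in binary without parsing
                if fmt != "ascii":
                    raise PlyParseError(
                        f"cannot skip binary element {name!r} with list properties"
                    )
                for _ in range(count):
                    stream.readline()
                continue
            if fmt == "ascii":
                data = _read_element_ascii(stream, count, props)
            else:
                dtype = np.dtype([(n, "<" + _PLY_TO_NUMPY[t]) for n, t in props])
                buf = stream.read(dtype.itemsize * count)
                if len(buf) != dtype.itemsize * count:
                    raise PlyParseError(f"element {name!r} truncated")
                data = np.frombuffer(buf, dtype=dtype)
            if name == "vertex":
                vertex = (data, [p[0] for p in props])
    if vertex is None:
        raise PlyParseError("PLY file has no vertex element")
    data, names = vertex
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PlyParseError(f"vertex element missing {axis!r} property")
    points = np.column_stack(
        [data["x"], data["y"], data["z"]]
    ).astype(np.float64)
    color_names = ("red", "green", "blue")
    if not all(c in names for c in color_names):
        raise ColorlessCloudError(
            f"{path.name}: vertex element has no red/green/blue properties; "
            "the chlorophyll pipeline requires a colored cloud"
        )
    colors = np.column_stack([data[c] for c in color_names]).astype(np.uint8)
    leaf_labels = data["leaf"].astype(np.int64) if "leaf" in names else None
    skip = {"x", "y", "z", "red", "green", "blue", "leaf", "alpha"}
    attributes = {
        n: np.asarray(data[n], dtype=np.float64) for n in names if n not in skip
    }
    return ColoredPointCloud(
        points=points,
        colors=colors,
        attributes=attributes,
        leaf_labels=leaf_labels,
        frame=frame,
    )


def write_ply(
    cloud: ColoredPointCloud,
    path: str | Path,
    format: str = "ascii",
) -> None:
    """Write a cloud to PLY (``ascii`` or ``binary_little_endian``).

    Attributes are written as extra float vertex properties and leaf labels
    as an ``int`` property named ``leaf``.
    """
    if format not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {format!r}")
    path = Path(path)
    n = len(cloud)
    attr_names = sorted(cloud.attributes)
    header = ["ply", f"format {format} 1.0",
              f"comment {_FRAME_COMMENT}{cloud.frame}",
              f"element vertex {n}"]
    # positions as double: float32 would round ~cm-scale coordinates by >1e-6
    fields: list[tuple[str, str]] = [("x", "f8"), ("y", "f8"), ("z", "f8")]
    for axis in ("x", "y", "z"):
        header.append(f"property double {axis}")
    if cloud.has_colors:
        for c in ("red", "green", "blue"):
            header.append(f"property uchar {c}")
            fields.append((c, "u1"))
    for name in attr_names:
        header.append(f"property float {name}")
        fields.append((name, "f4"))
    if cloud.leaf_labels is not None:
        header.append("property int leaf")
        fields.append(("leaf", "i4"))
    header.append("end_header")

    dtype = np.dtype([(name, "<" + kind) for name, kind in fields])
    table = np.empty(n, dtype=dtype)
    table["x"], table["y"], table["z"] = cloud.points.T
    if cloud.has_colors:
        table["red"], table["green"], table["blue"] = cloud.colors.T
    for name in attr_names:
        table[name] = cloud.attributes[name].astype(np.float32)
    if cloud.leaf_labels is not None:
        table["leaf"] = cloud.leaf_labels.astype(np.int32)

    with open(path, "wb") as stream:
        stream.write(("\n".join(header) + "\n").encode("ascii"))
        if format == "binary_little_endian":
            stream.write(table.tobytes())
        else:
            fmt_parts = []
            for name, kind in fields:
                if kind == "f8":
                    fmt_parts.append("%.17g")
                elif kind == "f4":
                    fmt_parts.append("%.9g")
                else:
                    fmt_parts.append("%d")
            np.savetxt(stream, _as_2d(table, fields), fmt=" ".join(fmt_parts))


def _as_2d(table: np.ndarray, fields) -> np.ndarray:
    return np.column_stack([table[name].astype(np.float64) for name, _ in fields])
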