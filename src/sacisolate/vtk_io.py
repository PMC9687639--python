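"""Minimal legacy-VTK (ASCII) polydata reader/writer.

Supports the subset this package exchanges with FEA post-processing
pipelines: POINTS, triangular POLYGONS, and scalar POINT_DATA fields.
"""

from __future__ import annotations

import numpy as np

from .errors import MeshIOError

__all__ = ["read_polydata", "write_polydata"]


def _tokens(text: str):
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        yield from line.split()


def read_polydata(path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read an ASCII legacy-VTK polydata file.

    Returns (points (n,3) float64, triangles (m,3) int64, point_data scalars).
    """
    try:
        with open(path, "r", encoding="utf-8", errors="replace") as fh:
            text = fh.read()
    except OSError as exc:
        raise MeshIOError(f"cannot read {path}: {exc}") from exc

    lines = text.splitlines()
    if len(lines) < 4 or not lines[0].lstrip().startswith("# vtk DataFile"):
        raise MeshIOError(f"{path}: not a legacy VTK file")
    if "ASCII" not in text.upper().split("BINARY")[0][:400] and "ASCII" not in text[:400].upper():
        raise MeshIOError(f"{path}: only ASCII legacy VTK is supported")

    # Tokenize everything after the 3-line header (title may contain anything).
    body = "\n".join(lines[2:])
    toks = list(_tokens(body))
    points = None
    triangles = None
    point_data: dict[str, np.ndarray] = {}
    i = 0
    try:
        while i < len(toks):
            key = toks[i].upper()
            if key == "DATASET":
                if toks[i + 1].upper() != "POLYDATA":
                    raise MeshIOError(f"{path}: only DATASET POLYDATA supported")
                i += 2
            elif key == "POINTS":
                n = int(toks[i + 1])
                vals = np.array(toks[i + 3 : i + 3 + 3 * n], dtype=float)
                points = vals.reshape(n, 3)
                i += 3 + 3 * n
            elif key == "POLYGONS":
                m = int(toks[i + 1])
                size = int(toks[i + 2])
                raw = toks[i + 3 : i + 3 + size]
                if len(raw) < size:
                    raise MeshIOError(f"{path}: truncated POLYGONS section")
                tris = []
                j = 0
                for _ in range(m):
                    k = int(raw[j])
                    if k != 3:
                        raise MeshIOError(f"{path}: only triangular polygons supported (got {k}-gon)")
                    tris.append([int(raw[j + 1]), int(raw[j + 2]), int(raw[j + 3])])
                    j += k + 1
                triangles = np.asarray(tris, dtype=np.int64)
                i += 3 + size
            elif key == "POINT_DATA":
                n = int(toks[i + 1])
                i += 2
                while i < len(toks) and toks[i].upper() == "SCALARS":
                    name = toks[i + 1]
                    ncomp = 1
                    j = i + 3
                    if j < len(toks) and toks[j].isdigit():
                        ncomp = int(toks[j])
                        j += 1
                    if j + 1 < len(toks) and toks[j].upper() == "LOOKUP_TABLE":
                        j += 2
                    if ncomp != 1:
                        raise MeshIOError(f"{path}: only 1-component scalars supported")
                    point_data[name] = np.array(toks[j : j + n], dtype=float)
                    i = j + n
            else:
                i += 1  # tolerate unknown sections (e.g. CELL_DATA we ignore)
    except (ValueError, IndexError) as exc:
        raise MeshIOError(f"{path}: malformed legacy VTK content ({exc})") from exc

    if points is None or triangles is None or len(points) == 0:
        raise MeshIOError(f"{path}: no polydata geometry parsed")
    return points, triangles, point_data


def write_polydata(path, points, triangles, point_data: dict | None = None,
                   title: str = "sacisolate surface") -> None:
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals, dtype=float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in vals:
                    fh.write(f"{v:.9g}\n")
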