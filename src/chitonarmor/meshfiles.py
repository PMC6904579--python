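"""Mesh file input/output.

Binary STL is the default exchange format (one solid per file, units mm);
ASCII STL, OBJ and PLY are supported for diffing and interchange.  trimesh
provides the codecs; this module adds format policing and the package's
error taxonomy.
"""

from __future__ import annotations

from pathlib import Path

import trimesh

from .errors import GeometryError, ParameterError
from .loft import ScaleMesh, as_trimesh

__all__ = ["write_mesh", "read_mesh", "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = ("stl", "stl_ascii", "obj", "ply")


def write_mesh(mesh, path, file_format: str | None = None) -> Path:
    """Write a mesh; format from ``file_format`` or the path suffix.

    ``stl`` is binary; pass ``stl_ascii`` for a diffable STL.
    """
    path = Path(path)
    fmt = file_format or path.suffix.lstrip(".").lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ParameterError(
            f"unsupported mesh format {fmt!r}; supported: {SUPPORTED_FORMATS}"
        )
    tm = as_trimesh(mesh)
    path.parent.mkdir(parents=True, exist_ok=True)
    export_fmt = {"stl": "stl", "stl_ascii": "stl_ascii", "obj": "obj", "ply": "ply"}[fmt]
    tm.export(path, file_type=export_fmt)
    return path


def read_mesh(path) -> ScaleMesh:
    """Read an STL/OBJ/PLY file into a ScaleMesh (provenance 'external')."""
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"mesh file not found: {path}")
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("stl", "obj", "ply"):
        raise ParameterError(
            f"unsupported mesh format {fmt!r}; supported: stl, obj, ply"
        )
    try:
        tm = trimesh.load(path, file_type=fmt, force="mesh")
    except Exception as exc:
        raise GeometryError(f"malformed mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise GeometryError(f"malformed mesh file {path}: no triangles found")
    return ScaleMesh(tm, provenance="external")
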