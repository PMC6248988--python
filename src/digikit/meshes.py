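"""Minimal head-surface mesh readers (ASCII STL, OFF).

Meshes are parsed and bounding-box validated for downstream consumers;
no rendering.  Binary STL is rejected with a clear message — deliverable
data in this package is text-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = ["Mesh", "load_mesh"]


@dataclass
class Mesh:
    vertices: np.ndarray   # (N, 3) mm
    faces: np.ndarray      # (M, 3) int vertex indices

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def validate(self) -> None:
        if len(self.vertices) < 3:
            raise FormatError("mesh has fewer than 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise FormatError("mesh has non-finite vertices")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise FormatError("face index out of range")
        lo, hi = self.bounding_box
        if np.any(hi - lo <= 0):
            raise FormatError("degenerate (zero-extent) bounding box")


def _load_stl(path: Path) -> Mesh:
    with open(path, "rb") as fh:
        head = fh.read(5)
    if head != b"solid":
        raise FormatError("binary STL not supported; export ASCII STL", path)
    verts: list[list[float]] = []
    vert_index: dict[tuple, int] = {}
    faces: list[list[int]] = []
    current: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if parts[0] == "vertex":
                if len(parts) != 4:
                    raise FormatError("vertex needs 3 coordinates", path, lineno)
                try:
                    xyz = tuple(float(v) for v in parts[1:])
                except ValueError as exc:
                    raise FormatError(str(exc), path, lineno) from exc
                i = vert_index.setdefault(xyz, len(verts))
                if i == len(verts):
                    verts.append(list(xyz))
                current.append(i)
            elif parts[0] == "endfacet":
                if len(current) != 3:
                    raise FormatError(
                        f"facet with {len(current)} vertices", path, lineno
                    )
                faces.append(current)
                current = []
    if not faces:
        raise FormatError("no facets found", path)
    return Mesh(np.array(verts, dtype=float), np.array(faces, dtype=int))


def _load_off(path: Path) -> Mesh:
    with open(path, "r", encoding="utf-8") as fh:
        tokens: list[str] = []
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError("missing OFF header", path)
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # skip edge count
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            idx = [int(v) for v in tokens[pos + 1 : pos + 1 + k]]
            pos += 1 + k
            for j in range(1, k - 1):  # fan-triangulate polygons
                faces.append([idx[0], idx[j], idx[j + 1]])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed OFF data: {exc}", path) from exc
    return Mesh(verts, np.array(faces, dtype=int).reshape(-1, 3))


def load_mesh(path, fmt: str | None = None) -> Mesh:
    """Load and validate a surface mesh (.stl ASCII or .off)."""
    path = Path(path)
    if not path.exists():
        raise FormatError("mesh file not found", path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "stl":
        mesh = _load_stl(path)
    elif fmt == "off":
        mesh = _load_off(path)
    else:
        raise FormatError(f"unsupported mesh format {fmt!r}", path)
    mesh.validate()
    return mesh
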