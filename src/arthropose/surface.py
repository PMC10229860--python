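"""Triangle surface mesh type and plain-text mesh IO (OBJ / STL / PLY).

Coordinates are millimetres throughout.  Vertex indices are 0-based; the
optional ``source_node_ids`` array is the single bridge back to 1-based FE
node ids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParseError, ValidationError

__all__ = ["TriMesh", "read_surface", "write_surface"]


@dataclass
class TriMesh:
    """An indexed triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex-index triples, consistently wound per manifold component.
    source_node_ids : (n,) int array, optional
        FE node id of each vertex, when the mesh was extracted from a model.
    """

    vertices: np.ndarray
    faces: np.ndarray
    source_node_ids: Optional[np.ndarray] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (n, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValidationError("faces must be (m, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValidationError("face indices out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValidationError("degenerate (repeated-index) faces")
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("non-finite vertex coordinates")
        if self.source_node_ids is not None:
            self.source_node_ids = np.asarray(self.source_node_ids, dtype=np.int64)
            if self.source_node_ids.shape != (len(self.vertices),):
                raise ValidationError("source_node_ids must be (n,)")

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _cached(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def face_normals(self) -> np.ndarray:
        """Unit face normals (right-hand rule on vertex order)."""

        def compute():
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            lens = np.linalg.norm(n, axis=1)
            lens[lens == 0] = 1.0
            return n / lens[:, None]

        return self._cached("face_normals", compute)

    @property
    def face_areas(self) -> np.ndarray:
        def compute():
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            return 0.5 * np.linalg.norm(n, axis=1)

        return self._cached("face_areas", compute)

    @property
    def face_centroids(self) -> np.ndarray:
        return self._cached(
            "face_centroids", lambda: self.vertices[self.faces].mean(axis=1)
        )

    @property
    def corner_angles(self) -> np.ndarray:
        """(m, 3) interior angle at each face corner, radians."""

        def compute():
            v = self.vertices[self.faces]
            ang = np.empty((len(self.faces), 3))
            for k in range(3):
                a = v[:, (k + 1) % 3] - v[:, k]
                b = v[:, (k + 2) % 3] - v[:, k]
                na = np.linalg.norm(a, axis=1)
                nb = np.linalg.norm(b, axis=1)
                cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300)
                ang[:, k] = np.arccos(np.clip(cosang, -1.0, 1.0))
            return ang

        return self._cached("corner_angles", compute)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted unit vertex pseudonormals."""

        def compute():
            normals = np.zeros_like(self.vertices)
            w = self.corner_angles
            fn = self.face_normals
            for k in range(3):
                np.add.at(normals, self.faces[:, k], fn * w[:, k, None])
            lens = np.linalg.norm(normals, axis=1)
            lens[lens == 0] = 1.0
            return normals / lens[:, None]

        return self._cached("vertex_normals", compute)

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) unique undirected edges, each row sorted ascending."""

        def compute():
            f = self.faces
            e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            e = np.sort(e, axis=1)
            return np.unique(e, axis=0)

        return self._cached("edges", compute)

    @property
    def edge_faces(self):
        """dict mapping sorted edge tuple -> list of incident face indices."""

        def compute():
            d: dict = {}
            for fi, (a, b, c) in enumerate(self.faces):
                for u, v in ((a, b), (b, c), (c, a)):
                    key = (u, v) if u < v else (v, u)
                    d.setdefault(key, []).append(fi)
            return d

        return self._cached("edge_faces", compute)

    @property
    def boundary_vertex_mask(self) -> np.ndarray:
        def compute():
            mask = np.zeros(self.n_vertices, dtype=bool)
            for (u, v), fl in self.edge_faces.items():
                if len(fl) != 2:
                    mask[u] = True
                    mask[v] = True
            return mask

        return self._cached("boundary_vertex_mask", compute)

    @property
    def vertex_faces(self):
        """List of incident face-index arrays per vertex."""

        def compute():
            lists = [[] for _ in range(self.n_vertices)]
            for fi, face in enumerate(self.faces):
                for vi in face:
                    lists[vi].append(fi)
            return [np.asarray(l, dtype=np.int64) for l in lists]

        return self._cached("vertex_faces", compute)

    def is_watertight(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        return all(len(fl) == 2 for fl in self.edge_faces.values())

    def winding_consistent(self) -> bool:
        """True when the two faces of every interior edge traverse it in
        opposite directions."""
        directed: dict = {}
        for fi, (a, b, c) in enumerate(self.faces):
            for u, v in ((a, b), (b, c), (c, a)):
                directed.setdefault((u, v), 0)
                directed[(u, v)] += 1
        for (u, v), cnt in directed.items():
            if cnt > 1:
                return False
            if directed.get((v, u), 0) + cnt > 2:
                return False
        return True

    def signed_volume(self) -> float:
        """Signed enclosed volume (positive for outward winding)."""
        v = self.vertices
        f = self.faces
        return float(
            np.einsum(
                "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
            ).sum()
            / 6.0
        )

    # ------------------------------------------------------------------
    def copy(self) -> "TriMesh":
        ids = None if self.source_node_ids is None else self.source_node_ids.copy()
        return TriMesh(self.vertices.copy(), self.faces.copy(), ids)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                              axis=1)

    def transformed(self, transform) -> "TriMesh":
        """Return a rigidly transformed copy.

        ``transform`` is anything with ``rotation`` (3x3) and
        ``translation`` (3,) attributes.
        """
        R = np.asarray(transform.rotation)
        t = np.asarray(transform.translation)
        ids = None if self.source_node_ids is None else self.source_node_ids.copy()
        return TriMesh(self.vertices @ R.T + t, self.faces.copy(), ids)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        ids = None if self.source_node_ids is None else self.source_node_ids.copy()
        return TriMesh(np.asarray(vertices, float), self.faces.copy(), ids)

    def connected_components(self) -> np.ndarray:
        """Vertex component labels via union-find on edges."""
        parent = np.arange(self.n_vertices)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for u, v in self.edges:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        return np.asarray([find(i) for i in range(self.n_vertices)])


# ----------------------------------------------------------------------
# Plain-text mesh IO
# ----------------------------------------------------------------------

def read_surface(path) -> TriMesh:
    """Read an OBJ, ascii STL, or ascii PLY file into a TriMesh."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError("file not found", path=path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        return _read_obj(path)
    if ext == ".stl":
        return _read_stl(path)
    if ext == ".ply":
        return _read_ply(path)
    raise ParseError(f"unsupported mesh extension {ext!r}", path=path)


def write_surface(mesh: TriMesh, path) -> None:
    """Write a TriMesh as OBJ, ascii STL, or ascii PLY by extension."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        _write_obj(mesh, path)
    elif ext == ".stl":
        _write_stl(mesh, path)
    elif ext == ".ply":
        _write_ply(mesh, path)
    else:
        raise ParseError(f"unsupported mesh extension {ext!r}", path=path)


def _read_obj(path) -> TriMesh:
    verts, faces = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise ParseError("short vertex line", path=path, line=lineno)
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                    faces.append([idx[0], idx[k], idx[k + 1]])
    return TriMesh(np.asarray(verts, float), np.asarray(faces, np.int64))


def _write_obj(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _read_stl(path) -> TriMesh:
    verts, faces = [], []
    index: dict = {}
    tri: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "vertex":
                xyz = tuple(float(x) for x in parts[1:4])
                if xyz not in index:
                    index[xyz] = len(verts)
                    verts.append(xyz)
                tri.append(index[xyz])
                if len(tri) == 3:
                    faces.append(tri)
                    tri = []
            elif parts[0] == "solid" and lineno > 1:
                raise ParseError("binary STL not supported", path=path)
    if not faces:
        raise ParseError("no facets found (binary STL?)", path=path)
    return TriMesh(np.asarray(verts, float), np.asarray(faces, np.int64))


def _write_stl(mesh: TriMesh, path) -> None:
    fn = mesh.face_normals
    with open(path, "w") as fh:
        fh.write("solid arthropose\n")
        for i, f in enumerate(mesh.faces):
            n = fn[i]
            fh.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
            fh.write(" outer loop\n")
            for vi in f:
                v = mesh.vertices[vi]
                fh.write(f"  vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid arthropose\n")


def _read_ply(path) -> TriMesh:
    with open(path) as fh:
        line = fh.readline()
        if line.strip() != "ply":
            raise ParseError("not a PLY file", path=path, line=1)
        n_vert = n_face = 0
        fmt = None
        while True:
            line = fh.readline()
            if not line:
                raise ParseError("unexpected EOF in header", path=path)
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                if parts[1] == "vertex":
                    n_vert = int(parts[2])
                elif parts[1] == "face":
                    n_face = int(parts[2])
            elif parts[0] == "end_header":
                break
        if fmt != "ascii":
            raise ParseError("only ascii PLY supported", path=path)
        verts = np.empty((n_vert, 3))
        for i in range(n_vert):
            verts[i] = [float(x) for x in fh.readline().split()[:3]]
        faces = []
        for _ in range(n_face):
            parts = [int(x) for x in fh.readline().split()]
            idx = parts[1 : 1 + parts[0]]
            for k in range(1, len(idx) - 1):
                faces.append([idx[0], idx[k], idx[k + 1]])
    return TriMesh(verts, np.asarray(faces, np.int64))


def _write_ply(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
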