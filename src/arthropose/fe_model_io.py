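"""LS-DYNA keyword-format model subset IO and boundary-surface extraction.

Supported blocks: *NODE, *ELEMENT_SOLID, *ELEMENT_SHELL, *PART,
*SET_NODE / *SET_NODE_LIST.  Unknown keyword blocks are preserved verbatim
so a read -> write round trip keeps the file semantically intact.

Both fixed-width (8/16-char) and comma-separated data lines are accepted,
detected per line.  Node ids are 1-based as in the format; extracted surface
meshes carry a ``source_node_ids`` array as the single bridge between the
0-based vertex indices and the FE node ids.  Coordinates are millimetres.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .errors import ParseError, ValidationError
from .surface import TriMesh

__all__ = [
    "FEModel",
    "read_keyword_model",
    "write_keyword_model",
    "extract_surface",
]

# outward-oriented faces of a positively oriented 8-node hex (0-based
# positions into the connectivity tuple)
_HEX_FACES = (
    (0, 3, 2, 1),
    (4, 5, 6, 7),
    (0, 1, 5, 4),
    (1, 2, 6, 5),
    (2, 3, 7, 6),
    (3, 0, 4, 7),
)
_TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))

_HEX_EDGES = (
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
)
_TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class FEModel:
    """In-memory FE model subset.

    ``nodes`` maps node id -> (3,) coordinate; ``solids`` / ``shells`` map
    element id -> (part id, node-id tuple); ``parts`` maps part id -> label;
    ``node_sets`` maps set id -> node-id list.  ``other_blocks`` holds
    verbatim unknown keyword blocks for round-tripping.
    """

    nodes: Dict[int, np.ndarray] = field(default_factory=dict)
    solids: Dict[int, Tuple[int, Tuple[int, ...]]] = field(default_factory=dict)
    shells: Dict[int, Tuple[int, Tuple[int, ...]]] = field(default_factory=dict)
    parts: Dict[int, str] = field(default_factory=dict)
    node_sets: Dict[int, List[int]] = field(default_factory=dict)
    other_blocks: List[str] = field(default_factory=list)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for nid, xyz in self.nodes.items():
            if not isinstance(nid, (int, np.integer)) or nid <= 0:
                raise ValidationError(f"node id {nid!r} is not a positive integer")
            if not np.all(np.isfinite(xyz)):
                raise ValidationError(f"node {nid} has non-finite coordinates")
        for table, kind in ((self.solids, "solid"), (self.shells, "shell")):
            for eid, (pid, nids) in table.items():
                if eid <= 0:
                    raise ValidationError(f"{kind} id {eid} is not positive")
                for nid in nids:
                    if nid not in self.nodes:
                        raise ValidationError(
                            f"{kind} element {eid} references missing node {nid}"
                        )
        for sid, nids in self.node_sets.items():
            for nid in nids:
                if nid not in self.nodes:
                    raise ValidationError(
                        f"node set {sid} references missing node {nid}"
                    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FEModel):
            return NotImplemented
        if set(self.nodes) != set(other.nodes):
            return False
        for nid in self.nodes:
            if not np.array_equal(self.nodes[nid], other.nodes[nid]):
                return False
        return (
            self.solids == other.solids
            and self.shells == other.shells
            and self.parts == other.parts
            and self.node_sets == other.node_sets
            and self.other_blocks == other.other_blocks
        )

    # ------------------------------------------------------------------
    def copy(self) -> "FEModel":
        return FEModel(
            nodes={k: np.array(v) for k, v in self.nodes.items()},
            solids=dict(self.solids),
            shells=dict(self.shells),
            parts=dict(self.parts),
            node_sets={k: list(v) for k, v in self.node_sets.items()},
            other_blocks=list(self.other_blocks),
        )

    def node_array(self):
        """(sorted ids array, (n, 3) coords array, id -> row index dict)."""
        ids = np.array(sorted(self.nodes), dtype=np.int64)
        coords = np.array([self.nodes[i] for i in ids], dtype=float)
        index = {int(i): k for k, i in enumerate(ids)}
        return ids, coords, index

    def part_elements(self, part_id: int):
        solids = {e: c for e, (p, c) in self.solids.items() if p == part_id}
        shells = {e: c for e, (p, c) in self.shells.items() if p == part_id}
        return solids, shells

    def part_node_ids(self, part_id: int):
        nids: set = set()
        for p, conn in self.solids.values():
            if p == part_id:
                nids.update(conn)
        for p, conn in self.shells.values():
            if p == part_id:
                nids.update(conn)
        return sorted(nids)

    def coords_of(self, node_ids) -> np.ndarray:
        return np.array([self.nodes[int(i)] for i in node_ids], dtype=float)

    def set_coords(self, node_ids, coords) -> None:
        for nid, xyz in zip(node_ids, np.asarray(coords, float)):
            self.nodes[int(nid)] = np.array(xyz, dtype=float)

    def transform_nodes(self, node_ids, transform) -> None:
        ids = list(node_ids)
        self.set_coords(ids, transform.apply(self.coords_of(ids)))


# ----------------------------------------------------------------------
# Parsing
# ----------------------------------------------------------------------

_KNOWN_PREFIXES = (
    "*NODE",
    "*ELEMENT_SOLID",
    "*ELEMENT_SHELL",
    "*PART",
    "*SET_NODE",
)


def _fields(line: str, widths, lineno: int, path) -> List[str]:
    """Split a keyword data line: comma, whitespace, or fixed-width."""
    if "," in line:
        return [f.strip() for f in line.split(",")]
    toks = line.split()
    if len(toks) >= 2:
        return toks
    out = []
    pos = 0
    for w in widths:
        out.append(line[pos : pos + w].strip())
        pos += w
    return [t for t in out if t]


def _to_int(tok: str, lineno: int, path) -> int:
    try:
        return int(float(tok)) if "." in tok or "e" in tok.lower() else int(tok)
    except ValueError:
        raise ParseError(f"malformed integer field {tok!r}", path=path, line=lineno)


def _to_float(tok: str, lineno: int, path) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"malformed float field {tok!r}", path=path, line=lineno)


def read_keyword_model(path) -> FEModel:
    """Parse an LS-DYNA keyword file into an FEModel.

    Raises ParseError (with line number) for malformed lines, a missing
    file, or elements referencing absent nodes.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError("file not found", path=path)
    model = FEModel()
    current = None
    part_state: list = []
    set_state: list = []
    other: list = []
    saw_node_block = False

    with open(path) as fh:
        lines = fh.readlines()

    def flush_other():
        nonlocal other
        if other:
            model.other_blocks.append("".join(other))
            other = []

    def flush_part(lineno):
        nonlocal part_state
        if part_state:
            if len(part_state) < 2:
                raise ParseError("truncated *PART block", path=path, line=lineno)
            title = part_state[0].rstrip("\n")
            pid = _to_int(_fields(part_state[1], (10,), lineno, path)[0], lineno, path)
            model.parts[pid] = title
            part_state = []

    def flush_set(lineno):
        nonlocal set_state
        if set_state:
            sid = _to_int(_fields(set_state[0], (10,), lineno, path)[0], lineno, path)
            nids: List[int] = []
            for ln in set_state[1:]:
                for tok in _fields(ln, (10,) * 8, lineno, path):
                    nid = _to_int(tok, lineno, path)
                    if nid != 0:
                        nids.append(nid)
            model.node_sets[sid] = nids
            set_state = []

    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if stripped.startswith("$"):
            if current == "other":
                other.append(line)
            continue
        if stripped.startswith("*"):
            flush_part(lineno)
            flush_set(lineno)
            kw = stripped.upper()
            if kw in ("*KEYWORD", "*END"):
                flush_other()
                current = None
                continue
            if kw.startswith("*NODE") and not kw.startswith("*NODE_SET"):
                flush_other()
                current = "node"
                saw_node_block = True
            elif kw.startswith("*ELEMENT_SOLID"):
                flush_other()
                current = "solid"
            elif kw.startswith("*ELEMENT_SHELL"):
                flush_other()
                current = "shell"
            elif kw.startswith("*PART"):
                flush_other()
                current = "part"
            elif kw.startswith("*SET_NODE"):
                flush_other()
                current = "set"
            else:
                flush_other()
                current = "other"
                other.append(line)
            continue
        if not stripped:
            if current == "other":
                other.append(line)
            continue

        if current == "node":
            f = _fields(line, (8, 16, 16, 16), lineno, path)
            if len(f) < 4:
                raise ParseError("short *NODE line", path=path, line=lineno)
            nid = _to_int(f[0], lineno, path)
            model.nodes[nid] = np.array(
                [_to_float(f[1], lineno, path),
                 _to_float(f[2], lineno, path),
                 _to_float(f[3], lineno, path)]
            )
        elif current == "solid":
            f = _fields(line, (8,) * 10, lineno, path)
            if len(f) < 6:
                raise ParseError("short *ELEMENT_SOLID line", path=path, line=lineno)
            vals = [_to_int(t, lineno, path) for t in f]
            eid, pid = vals[0], vals[1]
            conn = tuple(n for n in vals[2:10] if n != 0)
            if len(conn) == 8 and len(set(conn[3:])) == 1:
                conn = conn[:4]  # collapsed-tet convention n4 repeated
            if len(conn) not in (4, 8):
                raise ParseError(
                    f"solid {eid} has {len(conn)} nodes (need 4 or 8)",
                    path=path, line=lineno,
                )
            model.solids[eid] = (pid, conn)
        elif current == "shell":
            f = _fields(line, (8,) * 6, lineno, path)
            if len(f) < 5:
                raise ParseError("short *ELEMENT_SHELL line", path=path, line=lineno)
            vals = [_to_int(t, lineno, path) for t in f]
            eid, pid = vals[0], vals[1]
            conn = tuple(n for n in vals[2:6] if n != 0)
            if len(conn) == 4 and conn[2] == conn[3]:
                conn = conn[:3]  # collapsed-tri convention
            if len(conn) not in (3, 4):
                raise ParseError(
                    f"shell {eid} has {len(conn)} nodes (need 3 or 4)",
                    path=path, line=lineno,
                )
            model.shells[eid] = (pid, conn)
        elif current == "part":
            part_state.append(line)
        elif current == "set":
            set_state.append(line)
        elif current == "other":
            other.append(line)

    flush_part(len(lines))
    flush_set(len(lines))
    flush_other()

    if not saw_node_block:
        raise ParseError("file contains no *NODE block", path=path)
    model.validate()
    return model


# ----------------------------------------------------------------------
# Writing
# ----------------------------------------------------------------------

def write_keyword_model(model: FEModel, path) -> None:
    """Write an FEModel as a keyword file (round-trips through the reader).

    Node coordinates are written with 17 significant digits (exact float
    round trip, satisfying the >= 9 significant digit contract).
    """
    model.validate()
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("*KEYWORD\n")
        for pid in sorted(model.parts):
            fh.write("*PART\n")
            fh.write(f"{model.parts[pid]}\n")
            fh.write(f"{pid:10d}\n")
        fh.write("*NODE\n")
        for nid in sorted(model.nodes):
            x, y, z = model.nodes[nid]
            fh.write(f"{nid:8d}, {x:.17g}, {y:.17g}, {z:.17g}\n")
        if model.solids:
            fh.write("*ELEMENT_SOLID\n")
            for eid in sorted(model.solids):
                pid, conn = model.solids[eid]
                if len(conn) == 4:
                    conn = conn + (conn[3],) * 4
                fh.write(
                    f"{eid:8d}{pid:8d}" + "".join(f"{n:8d}" for n in conn) + "\n"
                )
        if model.shells:
            fh.write("*ELEMENT_SHELL\n")
            for eid in sorted(model.shells):
                pid, conn = model.shells[eid]
                fh.write(
                    f"{eid:8d}{pid:8d}" + "".join(f"{n:8d}" for n in conn) + "\n"
                )
        for sid in sorted(model.node_sets):
            fh.write("*SET_NODE_LIST\n")
            fh.write(f"{sid:10d}\n")
            nids = model.node_sets[sid]
            for k in range(0, len(nids), 8):
                fh.write("".join(f"{n:10d}" for n in nids[k : k + 8]) + "\n")
        for block in model.other_blocks:
            fh.write(block if block.endswith("\n") else block + "\n")
        fh.write("*END\n")


# ----------------------------------------------------------------------
# Surface extraction
# ----------------------------------------------------------------------

def _solid_orientation_sign(coords: np.ndarray, conn_len: int) -> float:
    if conn_len == 8:
        v = np.linalg.det(
            np.stack([coords[1] - coords[0], coords[3] - coords[0],
                      coords[4] - coords[0]])
        )
    else:
        v = np.linalg.det(
            np.stack([coords[1] - coords[0], coords[2] - coords[0],
                      coords[3] - coords[0]])
        )
    return 1.0 if v >= 0 else -1.0


def extract_surface(model: FEModel, part_ids) -> TriMesh:
    """Extract the boundary of the given parts as an outward-wound TriMesh.

    Solid boundary quads (faces belonging to exactly one solid) are split
    into two triangles along the shorter diagonal; shell elements contribute
    directly.  ``source_node_ids`` maps vertices back to FE node ids.
    Non-manifold boundaries produce a warning, not an error.
    """
    if isinstance(part_ids, (int, np.integer)):
        part_ids = [int(part_ids)]
    part_ids = list(part_ids)
    for pid in part_ids:
        if pid not in model.parts and not any(
            p == pid for p, _ in list(model.solids.values()) + list(model.shells.values())
        ):
            raise ValidationError(f"part {pid} not present in model")

    face_count: Dict[frozenset, list] = {}
    for eid, (pid, conn) in model.solids.items():
        if pid not in part_ids:
            continue
        coords = model.coords_of(conn)
        sign = _solid_orientation_sign(coords, len(conn))
        face_table = _HEX_FACES if len(conn) == 8 else _TET_FACES
        for face in face_table:
            nodes = tuple(conn[i] for i in face)
            if sign < 0:
                nodes = nodes[::-1]
            key = frozenset(nodes)
            face_count.setdefault(key, []).append(nodes)

    boundary_faces = [v[0] for v in face_count.values() if len(v) == 1]

    def split_quad(a, b, c, d):
        la = np.linalg.norm(model.nodes[a] - model.nodes[c])
        lb = np.linalg.norm(model.nodes[b] - model.nodes[d])
        # id-based tie-break keeps the split stable under mirroring
        if abs(la - lb) < 1e-9 * max(la, lb, 1e-30):
            take_ac = min(a, c) < min(b, d)
        else:
            take_ac = la < lb
        if take_ac:
            return [(a, b, c), (a, c, d)]
        return [(a, b, d), (b, c, d)]

    tri_nodes: List[Tuple[int, ...]] = []
    for nodes in boundary_faces:
        if len(nodes) == 4:
            tri_nodes += split_quad(*nodes)
        else:
            tri_nodes.append(tuple(nodes))

    for eid, (pid, conn) in model.shells.items():
        if pid not in part_ids:
            continue
        if len(conn) == 4:
            tri_nodes += split_quad(*conn)
        else:
            tri_nodes.append(tuple(conn))

    if not tri_nodes:
        raise ValidationError(f"parts {part_ids} contain no elements")

    used = sorted({n for tri in tri_nodes for n in tri})
    index = {n: k for k, n in enumerate(used)}
    vertices = np.array([model.nodes[n] for n in used], dtype=float)
    faces = np.array([[index[a], index[b], index[c]] for a, b, c in tri_nodes],
                     dtype=np.int64)
    mesh = TriMesh(vertices, faces, source_node_ids=np.array(used, dtype=np.int64))

    edge_counts: Dict[tuple, int] = {}
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edge_counts[key] = edge_counts.get(key, 0) + 1
    if any(c > 2 for c in edge_counts.values()):
        warnings.warn(
            f"extracted surface of parts {part_ids} is non-manifold",
            RuntimeWarning,
        )
    return mesh
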