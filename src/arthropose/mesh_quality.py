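"""FE element quality metrics and threshold-based audit reports.

Metrics follow common preprocessor conventions: corner-based scaled
Jacobian for hexes, warpage as the max angle between the two triangle
normals over both diagonal splits of a quad (evaluated per hex face for
solids, element value = max over faces), and aspect ratio as longest /
shortest element edge.  Default thresholds: warpage > 15.0 deg,
aspect > 5.0, scaled Jacobian < 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .fe_model_io import _HEX_EDGES, _HEX_FACES, _TET_EDGES, FEModel

__all__ = [
    "scaled_jacobian_hex",
    "warpage_quad",
    "aspect_ratio",
    "quality_report",
    "QualityReport",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {"warpage": 15.0, "aspect": 5.0, "jacobian": 0.5}

# the three edge-neighbours of each hex corner, in a right-handed order
_HEX_CORNER_NEIGHBOURS = (
    (1, 3, 4),
    (2, 0, 5),
    (3, 1, 6),
    (0, 2, 7),
    (7, 5, 0),
    (4, 6, 1),
    (5, 7, 2),
    (6, 4, 3),
)


def scaled_jacobian_hex(corners) -> float:
    """Minimum over the 8 corners of det of the normalized edge triad.

    1.0 for a cube; <= 0 for degenerate or inverted corners (coincident
    corners return a value <= 0, no exception).
    """
    x = np.asarray(corners, dtype=float)
    if x.shape != (8, 3):
        raise ValidationError("scaled_jacobian_hex needs 8 ordered corners")
    worst = 1.0
    for k, (i, j, l) in enumerate(_HEX_CORNER_NEIGHBOURS):
        e = np.stack([x[i] - x[k], x[j] - x[k], x[l] - x[k]])
        norms = np.linalg.norm(e, axis=1)
        if np.any(norms < 1e-300):
            return 0.0
        det = float(np.linalg.det(e / norms[:, None]))
        worst = min(worst, det)
    return worst


def warpage_quad(corners) -> float:
    """Out-of-plane angle of a quad, degrees.

    Angle between the normals of the two triangles obtained by splitting
    along each diagonal, maximized over the two splits.  0 for a planar
    quad.  Raises for collinear corners.
    """
    x = np.asarray(corners, dtype=float)
    if x.shape != (4, 3):
        raise ValidationError("warpage_quad needs 4 corners")
    worst = 0.0
    for (t1, t2) in (((0, 1, 2), (0, 2, 3)), ((0, 1, 3), (1, 2, 3))):
        n1 = np.cross(x[t1[1]] - x[t1[0]], x[t1[2]] - x[t1[0]])
        n2 = np.cross(x[t2[1]] - x[t2[0]], x[t2[2]] - x[t2[0]])
        l1, l2 = np.linalg.norm(n1), np.linalg.norm(n2)
        if l1 < 1e-300 or l2 < 1e-300:
            raise DegenerateGeometryError("collinear quad corners")
        cosang = np.clip(n1 @ n2 / (l1 * l2), -1.0, 1.0)
        worst = max(worst, math.degrees(math.acos(cosang)))
    return worst


def _element_edges(n_corners: int):
    if n_corners == 8:
        return _HEX_EDGES
    if n_corners == 4:
        return _TET_EDGES  # also correct lengths-wise for quads? no: quads
    raise ValidationError(f"unsupported element with {n_corners} corners")


def aspect_ratio(corners) -> float:
    """Longest / shortest edge length; +inf for a zero-length edge."""
    x = np.asarray(corners, dtype=float)
    n = len(x)
    if n == 8:
        edges = _HEX_EDGES
    elif n == 4:
        # ambiguous between tet and quad by corner count alone; treated as
        # tet here — quality_report dispatches quads explicitly
        edges = _TET_EDGES
    elif n == 3:
        edges = ((0, 1), (1, 2), (2, 0))
    else:
        raise ValidationError(f"unsupported element with {n} corners")
    return _aspect_from_edges(x, edges)


def _aspect_from_edges(x, edges) -> float:
    lens = np.array([np.linalg.norm(x[a] - x[b]) for a, b in edges])
    lo = lens.min()
    if lo < 1e-300:
        return math.inf
    return float(lens.max() / lo)


_QUAD_EDGES = ((0, 1), (1, 2), (2, 3), (3, 0))
_TRI_EDGES = ((0, 1), (1, 2), (2, 0))


@dataclass
class MetricResult:
    threshold: float
    evaluated: int = 0
    failing: int = 0
    worst_value: float = math.nan
    worst_element: int = -1

    @property
    def fraction(self) -> float:
        return self.failing / self.evaluated if self.evaluated else 0.0

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "evaluated": self.evaluated,
            "failing": self.failing,
            "fraction": self.fraction,
            "worst_value": None if math.isnan(self.worst_value) else self.worst_value,
            "worst_element": self.worst_element,
        }


@dataclass
class QualityReport:
    """Per-metric audit of an FE model."""

    metrics: Dict[str, MetricResult] = field(default_factory=dict)
    total_elements: int = 0

    def as_dict(self) -> dict:
        return {
            "total_elements": self.total_elements,
            "metrics": {k: v.as_dict() for k, v in self.metrics.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def table(self) -> str:
        lines = [
            f"{'metric':<10}{'threshold':>10}{'evaluated':>11}"
            f"{'failing':>9}{'fraction':>10}{'worst':>12}"
        ]
        for name, m in self.metrics.items():
            worst = "-" if math.isnan(m.worst_value) else f"{m.worst_value:.4g}"
            lines.append(
                f"{name:<10}{m.threshold:>10.3g}{m.evaluated:>11d}"
                f"{m.failing:>9d}{m.fraction:>10.4f}{worst:>12}"
            )
        return "\n".join(lines)

    def failing_counts(self):
        return tuple(m.failing for m in self.metrics.values())


def quality_report(model: FEModel, thresholds=None) -> QualityReport:
    """Audit all elements of a model against the quality thresholds.

    warpage: shell quads and every hex face (max over the 6 faces per
    solid); jacobian: hexes; aspect: all elements.  Each metric's fraction
    denominator is the number of elements that metric applies to.
    """
    if not model.solids and not model.shells:
        raise ValidationError("model has no elements")
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    warp = MetricResult(threshold=th["warpage"])
    asp = MetricResult(threshold=th["aspect"])
    jac = MetricResult(threshold=th["jacobian"])

    def update_max(metric, eid, value, fails):
        metric.evaluated += 1
        if fails:
            metric.failing += 1

    for eid, (pid, conn) in model.solids.items():
        x = model.coords_of(conn)
        if len(conn) == 8:
            w = max(warpage_quad(x[list(face)]) for face in _HEX_FACES)
            warp.evaluated += 1
            if w > th["warpage"]:
                warp.failing += 1
            if math.isnan(warp.worst_value) or w > warp.worst_value:
                warp.worst_value, warp.worst_element = w, eid
            j = scaled_jacobian_hex(x)
            jac.evaluated += 1
            if j < th["jacobian"]:
                jac.failing += 1
            if math.isnan(jac.worst_value) or j < jac.worst_value:
                jac.worst_value, jac.worst_element = j, eid
            a = _aspect_from_edges(x, _HEX_EDGES)
        else:
            a = _aspect_from_edges(x, _TET_EDGES)
        asp.evaluated += 1
        if a > th["aspect"]:
            asp.failing += 1
        if math.isnan(asp.worst_value) or a > asp.worst_value:
            asp.worst_value, asp.worst_element = a, eid

    for eid, (pid, conn) in model.shells.items():
        x = model.coords_of(conn)
        if len(conn) == 4:
            w = warpage_quad(x)
            warp.evaluated += 1
            if w > th["warpage"]:
                warp.failing += 1
            if math.isnan(warp.worst_value) or w > warp.worst_value:
                warp.worst_value, warp.worst_element = w, eid
            a = _aspect_from_edges(x, _QUAD_EDGES)
        else:
            a = _aspect_from_edges(x, _TRI_EDGES)
        asp.evaluated += 1
        if a > th["aspect"]:
            asp.failing += 1
        if math.isnan(asp.worst_value) or a > asp.worst_value:
            asp.worst_value, asp.worst_element = a, eid

    report = QualityReport(
        metrics={"warpage": warp, "aspect": asp, "jacobian": jac},
        total_elements=len(model.solids) + len(model.shells),
    )
    return report


def solid_failure_fraction(model: FEModel, thresholds=None) -> float:
    """Fraction of *solid* elements violating any applicable threshold."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if not model.solids:
        return 0.0
    bad = 0
    for eid, (pid, conn) in model.solids.items():
        x = model.coords_of(conn)
        if len(conn) == 8:
            if scaled_jacobian_hex(x) < th["jacobian"]:
                bad += 1
                continue
            if max(warpage_quad(x[list(f)]) for f in _HEX_FACES) > th["warpage"]:
                bad += 1
                continue
            if _aspect_from_edges(x, _HEX_EDGES) > th["aspect"]:
                bad += 1
        else:
            if _aspect_from_edges(x, _TET_EDGES) > th["aspect"]:
                bad += 1
    return bad / len(model.solids)


def min_scaled_jacobian(model: FEModel) -> float:
    """Minimum scaled Jacobian over all hex solids (inversion check)."""
    worst = math.inf
    for eid, (pid, conn) in model.solids.items():
        if len(conn) == 8:
            worst = min(worst, scaled_jacobian_hex(model.coords_of(conn)))
    return worst
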