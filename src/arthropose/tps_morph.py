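"""Thin-plate-spline displacement interpolation from landmark pairs.

3D biharmonic kernel phi(r) = r with an affine term:

    f(x) = A [x; 1] + sum_i w_i phi(|x - s_i|)

Fitting solves the standard bordered linear system with the polynomial
side conditions sum w = 0 and sum w s^T = 0; lambda = 0 gives exact
interpolation at the landmarks.  The interpolated variable is the nodal
position (equivalently displacement: target - source plus identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, ValidationError

__all__ = ["TPSModel", "fit_tps", "apply_tps", "read_landmarks_csv",
           "write_landmarks_csv", "farthest_point_subsample"]

MAX_DENSE_LANDMARKS = 5000


@dataclass
class TPSModel:
    """A fitted thin-plate-spline map."""

    source_landmarks: np.ndarray  # (n, 3)
    affine: np.ndarray  # (3, 4), f_affine(x) = affine @ [x; 1]
    kernel_weights: np.ndarray  # (n, 3)
    regularization: float = 0.0
    kernel: str = "r"

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_tps(self, points)

    def bending_energy(self) -> float:
        """Quadratic-form energy trace(W^T Phi W).

        For the 3D kernel phi(r) = r the energy form is -K (phi is
        conditionally negative definite); the value is >= 0 on the
        side-condition subspace the weights live in.
        """
        K = cdist(self.source_landmarks, self.source_landmarks)
        return float(-np.einsum("ia,ij,ja->", self.kernel_weights, K,
                                self.kernel_weights))


def fit_tps(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> TPSModel:
    """Fit a TPS mapping source landmarks to target landmarks.

    Requires n >= 4 pairwise-distinct, non-coplanar source landmarks.
    ``lam`` >= 0 regularizes (lam = 0: exact interpolation).  Landmark sets
    larger than MAX_DENSE_LANDMARKS are farthest-point subsampled with a
    warning (O(n^3) dense solve).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
        raise ValidationError("source/target must be matching (n, 3) arrays")
    n = len(src)
    if n < 4:
        raise DegenerateGeometryError("TPS needs at least 4 landmarks")
    if lam < 0:
        raise ValidationError("regularization must be >= 0")

    if n > MAX_DENSE_LANDMARKS:
        import warnings

        warnings.warn(
            f"subsampling {n} landmarks to {MAX_DENSE_LANDMARKS} "
            "(dense TPS solve limit)",
            RuntimeWarning,
        )
        keep = farthest_point_subsample(src, MAX_DENSE_LANDMARKS)
        src, tgt = src[keep], tgt[keep]
        n = len(src)

    tree = cKDTree(src)
    dmin, imin = tree.query(src, 2)
    if dmin[:, 1].min() <= 1e-6:
        raise DegenerateGeometryError(
            "duplicate source landmarks (min pairwise distance <= 1e-6 mm); "
            "deduplicate or use lam > 0 after perturbation"
        )
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1e-12):
        raise DegenerateGeometryError(
            "coplanar source landmarks: TPS side conditions are rank deficient"
        )

    K = cdist(src, src)
    if lam > 0:
        # phi(r) = r is conditionally negative definite: the energy form is
        # -K, so the ridge term enters as K - lam*I (== -(Phi + lam*I))
        K = K - lam * np.eye(n)
    P = np.hstack([src, np.ones((n, 1))])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"TPS system singular: {exc}") from exc
    weights = sol[:n]
    affine = sol[n:].T  # (3, 4): rows act on [x, y, z, 1]
    return TPSModel(
        source_landmarks=src.copy(),
        affine=affine,
        kernel_weights=weights,
        regularization=lam,
    )


def apply_tps(model: TPSModel, points: np.ndarray,
              chunk: int = 4096) -> np.ndarray:
    """Evaluate the TPS map at m points; returns (m, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(pts)
    for k in range(0, len(pts), chunk):
        block = pts[k : k + chunk]
        phi = cdist(block, model.source_landmarks)
        out[k : k + chunk] = (
            block @ model.affine[:, :3].T
            + model.affine[:, 3]
            + phi @ model.kernel_weights
        )
    return out[0] if np.ndim(points) == 1 else out


def farthest_point_subsample(points: np.ndarray, n_keep: int,
                             seed: int = 0) -> np.ndarray:
    """Indices of a farthest-point subsample (deterministic given seed)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n_keep >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    chosen = [start]
    d = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(n_keep - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.asarray(chosen, dtype=np.int64)


def read_landmarks_csv(path):
    """Read landmark pairs: columns id, sx, sy, sz, tx, ty, tz."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    src = np.stack([data["sx"], data["sy"], data["sz"]], axis=1)
    tgt = np.stack([data["tx"], data["ty"], data["tz"]], axis=1)
    return np.atleast_2d(src), np.atleast_2d(tgt)


def write_landmarks_csv(path, source, target) -> None:
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    with open(path, "w") as fh:
        fh.write("id,sx,sy,sz,tx,ty,tz\n")
        for i, (s, t) in enumerate(zip(source, target)):
            fh.write(
                f"{i},{s[0]:.9g},{s[1]:.9g},{s[2]:.9g},"
                f"{t[0]:.9g},{t[1]:.9g},{t[2]:.9g}\n"
            )
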