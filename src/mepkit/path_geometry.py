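"""Geometric primitives for discretized paths and structures.

A transition pathway is represented as an ordered set of images (points in a
D-dimensional collective-variable space).  This module provides the
operations the string method and the free-energy analysis are built on:
membrane-symmetry-aware rigid fitting (rotation about z + translation in the
xy-plane only, z passed through), construction of a 3-fold symmetric
reference structure, equal-arc-length reparameterization, weak three-point
smoothing, projection of samples onto the path (progress coordinate +
orthogonal distance), and simple structural monitors (pair distances, group
center-of-mass z).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mepkit.errors import ConfigError, InputError

__all__ = [
    "ImagePath",
    "PathProjection",
    "fit_xy_plane",
    "symmetric_reference",
    "reparameterize",
    "smooth_path",
    "project_onto_path",
    "project_points",
    "monitor_observables",
]


@dataclass
class ImagePath:
    """Ordered set of M images in a D-dimensional CV space.

    Images are stored 0-based internally; reports use 1-based image indices
    (image 1 = initial state, image M = final state).
    """

    images: np.ndarray
    units: str = "reduced"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.atleast_2d(np.asarray(self.images, dtype=float))
        if self.images.ndim != 2 or len(self.images) < 2:
            raise InputError("an ImagePath needs at least 2 images of equal dimension")

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def dimension(self) -> int:
        return self.images.shape[1]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.images, axis=0), axis=1)

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        path = Path(path)
        d = self.dimension
        cols = ["image_index"] + [f"cv_{i}" for i in range(d)]
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            for i, img in enumerate(self.images, start=1):
                fh.write(",".join([str(i)] + [repr(float(v)) for v in img]) + "\n")
        meta = {"units": self.units, **self.metadata}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImagePath":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        units = meta.pop("units", "reduced")
        return cls(images=data[:, 1:], units=units, metadata=meta)


@dataclass
class PathProjection:
    """Projection of a sample onto a path.

    ``progress`` is the interpolable 0-based image coordinate in [0, M-1]
    (segment index plus fractional position of the orthogonal foot point);
    ``orthogonal_sq_distance`` is the squared distance from the sample to
    that foot point (A^2 in physical mode).
    """

    progress: float
    orthogonal_sq_distance: float
    n_images: int

    @property
    def image_coordinate(self) -> float:
        """1-based interpolable image coordinate in [1, M]."""
        return self.progress + 1.0

    @property
    def normalized(self) -> float:
        """Progress normalized to [0, 1] along the image index."""
        return self.progress / (self.n_images - 1)


# ---------------------------------------------------------------------------
# Rigid fitting restricted to the xy-plane


def _rz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def fit_xy_plane(mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None):
    """Least-squares fit restricted to rotation about z and xy translation.

    Finds the angle ``theta`` and xy translation ``t`` minimizing the
    weighted squared deviation of ``Rz(theta) @ (mobile + t)`` from
    ``reference``; z-coordinates pass through unchanged (membrane systems
    are symmetric only in the xy-plane).

    Returns ``(transformed, theta, t)`` where ``transformed`` applies the
    fit to ``mobile``.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InputError("mobile and reference must be matching (N, 3) coordinate sets")
    n = len(mob)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n or np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mob[:, :2]
    cr = w @ ref[:, :2]
    pm = mob[:, :2] - cm
    pr = ref[:, :2] - cr
    if np.sum(w * np.sum(pm * pm, axis=1)) < 1e-24:
        raise InputError("degenerate fit: all points collinear with the z-axis in projection")
    # closed-form 2-D Procrustes angle
    num = np.sum(w * (pm[:, 0] * pr[:, 1] - pm[:, 1] * pr[:, 0]))
    den = np.sum(w * (pm[:, 0] * pr[:, 0] + pm[:, 1] * pr[:, 1]))
    theta = float(np.arctan2(num, den))
    rot = _rz(theta)[:2, :2]
    # transformed = R (p + t); post-rotation offset is cr - R cm
    t_post = cr - rot @ cm
    t = rot.T @ t_post
    out = mob.copy()
    out[:, :2] = (mob[:, :2] + t) @ rot.T
    return out, theta, t


def symmetric_reference(states: Sequence[np.ndarray], permutation: np.ndarray | None = None):
    """Three-fold symmetric reference by averaging 120-degree-rotated states.

    ``states`` are three (N, 3) coordinate sets of the cyclic assembly
    states, given in a common frame so that state k is (approximately) the
    k-th 120-degree z-rotation of state 0 with points relabeled by
    ``permutation`` (the subunit-relabeling map sigma, with sigma^3 = id).
    The output is exactly invariant under a 120-degree rotation about z
    followed by the correspondence permutation.
    """
    if permutation is None:
        raise InputError("point-correspondence permutation map is required")
    sigma = np.asarray(permutation, dtype=int)
    if len(states) != 3:
        raise InputError("exactly three coordinate sets are required")
    sets = [np.asarray(s, dtype=float) for s in states]
    n = len(sets[0])
    for s in sets:
        if s.shape != (n, 3):
            raise InputError("all states must be (N, 3) with equal N")
    if sorted(sigma.tolist()) != list(range(n)):
        raise InputError("permutation must be a permutation of point indices")
    if not np.array_equal(sigma[sigma[sigma]], np.arange(n)):
        raise InputError("permutation must have order dividing 3 (sigma^3 = identity)")
    r120 = _rz(2.0 * np.pi / 3.0)

    def fwd(x):  # T: rotate +120 deg and relabel
        return x[sigma] @ r120.T

    def inv(x):  # T^-1
        inv_sigma = np.argsort(sigma)
        return (x @ r120) [inv_sigma]

    # map each state back into the frame of state 0, average, then symmetrize
    avg = (sets[0] + inv(sets[1]) + inv(inv(sets[2]))) / 3.0
    ref = (avg + fwd(avg) + fwd(fwd(avg))) / 3.0
    return ref


# ---------------------------------------------------------------------------
# Path reparameterization and smoothing


def _equal_arclength_pass(pts: np.ndarray, m: int) -> np.ndarray:
    """One pass: place m points at equal cumulative arc length on the polyline."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], m)
    new = np.empty((m, pts.shape[1]))
    new[0] = pts[0]
    new[-1] = pts[-1]
    idx = np.clip(np.searchsorted(s, targets[1:-1], side="right") - 1, 0, len(seg) - 1)
    frac = (targets[1:-1] - s[idx]) / seg[idx]
    new[1:-1] = pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])
    return new


def reparameterize(path: ImagePath, n_images: int | None = None, max_passes: int = 200) -> ImagePath:
    """Redistribute images so consecutive gaps are equal, endpoints fixed.

    Points are placed at equal cumulative arc length along the current
    polyline; because chords of a curved polyline are shorter than arcs, the
    pass is iterated to a fixed point where the straight-line gaps themselves
    are equal (relative spread below 1e-12), which also makes the operation
    idempotent to round-off.  Zero-length segments (duplicate consecutive
    images) are merged with a warning.
    """
    pts = path.images
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        warnings.warn("duplicate consecutive images merged during reparameterization")
        keep = np.concatenate([[True], seg > 0])
        pts = pts[keep]
        if len(pts) < 2:
            raise InputError("path degenerate: all images coincide")
    m = path.n_images if n_images is None else int(n_images)
    if m < 2:
        raise ConfigError("need at least 2 images")
    scale = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    new = pts
    for _ in range(max_passes):
        prev = new
        new = _equal_arclength_pass(prev, m)
        moved = float(np.max(np.linalg.norm(new - prev, axis=1))) if prev.shape == new.shape else np.inf
        gaps = np.linalg.norm(np.diff(new, axis=0), axis=1)
        if gaps.std() <= 1e-13 * gaps.mean() and moved <= 1e-13 * scale:
            break
    return ImagePath(images=new, units=path.units, metadata=dict(path.metadata))


def smooth_path(path: ImagePath, kappa: float) -> ImagePath:
    """Weak three-point smoothing of interior images.

    Interior image i is replaced by ``(1-kappa) x_i + kappa (x_{i-1} +
    x_{i+1}) / 2``; endpoints are fixed.  ``kappa`` in [0, 1).
    """
    if not (0.0 <= kappa < 1.0):
        raise ConfigError("smoothing kappa must lie in [0, 1)")
    pts = path.images
    new = pts.copy()
    if kappa > 0 and len(pts) > 2:
        new[1:-1] = (1.0 - kappa) * pts[1:-1] + kappa * 0.5 * (pts[:-2] + pts[2:])
    return ImagePath(images=new, units=path.units, metadata=dict(path.metadata))


# ---------------------------------------------------------------------------
# Path collective variables


def project_points(samples: np.ndarray, path: ImagePath):
    """Vectorized nearest-segment projection of many samples onto a path.

    Returns ``(progress, orthogonal_sq_distance)`` arrays.  ``progress`` is
    the 0-based interpolable image coordinate (segment index plus clamped
    fractional foot position); ties between segments break to the lower
    segment index.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[1] != path.dimension:
        raise InputError("sample dimension does not match path dimension")
    p = path.images
    d = np.diff(p, axis=0)  # (M-1, D)
    seg_sq = np.sum(d * d, axis=1)
    seg_sq = np.where(seg_sq == 0, 1.0, seg_sq)
    # t[n, s] = fractional foot of sample n on segment s, clamped to [0, 1]
    diff = x[:, None, :] - p[None, :-1, :]
    t = np.clip(np.einsum("nsd,sd->ns", diff, d) / seg_sq, 0.0, 1.0)
    foot = p[None, :-1, :] + t[..., None] * d[None, :, :]
    dist_sq = np.sum((x[:, None, :] - foot) ** 2, axis=2)
    best = np.argmin(dist_sq, axis=1)  # argmin takes the first (lower) index on ties
    nn = np.arange(len(x))
    progress = best + t[nn, best]
    return progress, dist_sq[nn, best]


def project_onto_path(sample: np.ndarray, path: ImagePath) -> PathProjection:
    """Project a single CV sample onto the path."""
    progress, dsq = project_points(np.atleast_1d(np.asarray(sample, float))[None, :], path)
    return PathProjection(
        progress=float(progress[0]),
        orthogonal_sq_distance=float(dsq[0]),
        n_images=path.n_images,
    )


# ---------------------------------------------------------------------------
# Structural monitors


def monitor_observables(
    frames: np.ndarray,
    pairs: Sequence[tuple[int, int]] = (),
    z_groups: Sequence[Sequence[int]] = (),
    masses: np.ndarray | None = None,
):
    """Per-frame pair distances and group center-of-mass z-coordinates.

    ``frames`` has shape (n_frames, n_points, 3).  ``pairs`` are point-index
    pairs for Euclidean distances; ``z_groups`` are point-index groups whose
    (optionally mass-weighted) center-of-mass z is monitored — z being the
    membrane normal in the physical setting.

    Returns a dict with ``"distances"`` (n_frames, n_pairs) and ``"com_z"``
    (n_frames, n_groups).
    """
    f = np.asarray(frames, dtype=float)
    if f.ndim != 3 or f.shape[2] != 3:
        raise InputError("frames must have shape (n_frames, n_points, 3)")
    n_pts = f.shape[1]
    dists = np.empty((f.shape[0], len(pairs)))
    for k, (i, j) in enumerate(pairs):
        dists[:, k] = np.linalg.norm(f[:, i, :] - f[:, j, :], axis=1)
    com_z = np.empty((f.shape[0], len(z_groups)))
    for k, grp in enumerate(z_groups):
        idx = np.asarray(grp, dtype=int)
        if idx.size == 0:
            raise InputError(f"z_group {k} is empty")
        if np.any(idx >= n_pts):
            raise InputError(f"z_group {k} has out-of-range point indices")
        if masses is None:
            com_z[:, k] = f[:, idx, 2].mean(axis=1)
        else:
            w = np.asarray(masses, dtype=float)[idx]
            com_z[:, k] = (f[:, idx, 2] @ w) / w.sum()
    return {"distances": dists, "com_z": com_z}
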