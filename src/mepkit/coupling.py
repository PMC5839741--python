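"""Reactive-trajectory resampling and mutual-information coupling maps.

The distribution of reactive trajectories (segments that leave the initial
state and reach the final state before returning) equals the equilibrium
distribution restricted to isocommittor surfaces, which for a converged
pathway are orthogonal to it.  Pseudo-reactive trajectories are therefore
resampled from umbrella-sampling data: frames are assigned to slices
orthogonal to the path by their progress coordinate, and per slice frames
are drawn with replacement proportional to their MBAR weights.  Dynamic
coupling between coordinate groups (e.g. transmembrane-helix and
porter-domain sidechain centers of mass) is then quantified by the Kraskov
k-nearest-neighbor estimator of the mutual information

    MI = ∫∫ p(r1, r2) ln [ p(r1, r2) / (p(r1) p(r2)) ] dr1 dr2  (nats),

which is binning-free and practical for 3-D coordinate data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from mepkit.errors import ConfigError, InputError
from mepkit.free_energy import MBARResult, UmbrellaDataset
from mepkit.path_geometry import ImagePath, project_points

__all__ = [
    "SlicePools",
    "ReactiveTrajectorySet",
    "MIMatrix",
    "slice_assign",
    "uniform_slice_pools",
    "resample_reactive",
    "kraskov_mi",
    "mi_matrix",
    "threshold_pairs",
    "permutation_null_mi",
]


@dataclass
class SlicePools:
    """Per-slice pools of pooled-frame indices with normalized weights."""

    indices: list  # list of int arrays, one per slice
    weights: list  # list of float arrays, each summing to 1
    n_slices: int
    window_of_frame: np.ndarray | None = None  # pooled index -> window id

    def __post_init__(self):
        if len(self.indices) != self.n_slices or len(self.weights) != self.n_slices:
            raise InputError("pools must have one entry per slice")
        for s, w in enumerate(self.weights):
            if len(w) and abs(w.sum() - 1.0) > 1e-10:
                raise InputError(f"slice {s} weights do not sum to 1")

    def ess(self) -> np.ndarray:
        """Kish effective sample size per slice."""
        return np.array(
            [1.0 / np.sum(w * w) if len(w) else 0.0 for w in self.weights]
        )


@dataclass
class ReactiveTrajectorySet:
    """Slice-ordered pseudo-reactive trajectories with provenance.

    ``frame_indices[t, s]`` is the pooled-frame index drawn for slice s of
    trajectory t; ``source[t, s]`` is the (window, frame-in-window) pair when
    window provenance is known, else (-1, pooled index).
    """

    frame_indices: np.ndarray  # (n_trajectories, n_slices)
    source: np.ndarray  # (n_trajectories, n_slices, 2)
    seed: int

    def __post_init__(self):
        if self.frame_indices.ndim != 2:
            raise InputError("frame_indices must be (n_trajectories, n_slices)")

    @property
    def n_trajectories(self) -> int:
        return self.frame_indices.shape[0]

    @property
    def n_slices(self) -> int:
        return self.frame_indices.shape[1]

    def pooled(self) -> np.ndarray:
        """All drawn frame indices pooled over trajectories and slices."""
        return self.frame_indices.reshape(-1)


@dataclass
class MIMatrix:
    """Mutual information (nats) between two sets of coordinate groups."""

    values: np.ndarray  # (n_A, n_B)
    labels_A: list
    labels_B: list
    k: int
    n_samples: int
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("group_A,group_B,MI_nats\n")
            for i, la in enumerate(self.labels_A):
                for j, lb in enumerate(self.labels_B):
                    fh.write(f"{la},{lb},{float(self.values[i, j])!r}\n")


# ---------------------------------------------------------------------------
# Slicing and resampling


def slice_assign(
    dataset: UmbrellaDataset,
    mbar: MBARResult,
    path: ImagePath,
    n_slices: int = 29,
    tube_cutoff_sq: float = 2000.0,
) -> SlicePools:
    """Assign umbrella frames to path-orthogonal slices.

    Each retained frame (inside the reactive tube) goes to exactly one slice
    by its progress coordinate; per-slice MBAR weights are renormalized to
    sum 1.  An empty slice raises, signalling insufficient sampling.
    """
    frames = dataset.all_frames()
    if len(frames) != len(mbar.weights):
        raise InputError("MBAR result does not match dataset frame count")
    progress, dsq = project_points(frames, path)
    inside = dsq <= tube_cutoff_sq
    edges = np.linspace(0.0, path.n_images - 1.0, n_slices + 1)
    slot = np.clip(np.searchsorted(edges, progress, side="right") - 1, 0, n_slices - 1)
    counts = dataset.frame_counts()
    window_of_frame = np.repeat(np.arange(len(counts)), counts)
    indices, weights = [], []
    for s in range(n_slices):
        sel = np.flatnonzero((slot == s) & inside)
        if sel.size == 0:
            raise InputError(f"slice {s} is empty: insufficient sampling along the path")
        w = mbar.weights[sel]
        tot = w.sum()
        if tot <= 0:
            raise InputError(f"slice {s} has zero total weight")
        indices.append(sel)
        weights.append(w / tot)
    return SlicePools(
        indices=indices, weights=weights, n_slices=n_slices, window_of_frame=window_of_frame
    )


def uniform_slice_pools(n_frames: int, n_slices: int = 29) -> SlicePools:
    """Uniform-weight slice pools over a frame range (contiguous split).

    Used to route externally generated ensembles (e.g. the planted-coupling
    Gaussian ensemble) through the resampling machinery when no umbrella
    weighting applies.
    """
    chunks = np.array_split(np.arange(n_frames), n_slices)
    for s, c in enumerate(chunks):
        if len(c) == 0:
            raise InputError(f"slice {s} is empty: too many slices for {n_frames} frames")
    return SlicePools(
        indices=[c for c in chunks],
        weights=[np.full(len(c), 1.0 / len(c)) for c in chunks],
        n_slices=n_slices,
    )


def resample_reactive(
    pools: SlicePools, n_trajectories: int = 100, seed: int = 0
) -> ReactiveTrajectorySet:
    """Resample slice-ordered pseudo-reactive trajectories.

    Per slice, ``n_trajectories`` frames are drawn with replacement
    proportionally to the per-slice weights and concatenated slice-by-slice
    into trajectories.  Deterministic under ``seed``; warns when a draw
    exceeds a slice's effective sample size.
    """
    ess = pools.ess()
    low = np.flatnonzero(ess < n_trajectories)
    if low.size:
        worst = int(low[np.argmin(ess[low])])
        warnings.warn(
            f"{low.size} slices have effective sample size below n_trajectories "
            f"(worst: slice {worst}, ESS {ess[worst]:.1f})"
        )
    master = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(pools.n_slices)]
    draws = np.empty((n_trajectories, pools.n_slices), dtype=int)
    for s, rng in enumerate(streams):
        picks = rng.choice(len(pools.indices[s]), size=n_trajectories, p=pools.weights[s])
        draws[:, s] = pools.indices[s][picks]
    source = np.empty((n_trajectories, pools.n_slices, 2), dtype=int)
    if pools.window_of_frame is not None:
        win = pools.window_of_frame[draws]
        source[..., 0] = win
        source[..., 1] = draws  # pooled index; window-local offset recoverable
    else:
        source[..., 0] = -1
        source[..., 1] = draws
    return ReactiveTrajectorySet(frame_indices=draws, source=source, seed=seed)


# ---------------------------------------------------------------------------
# Kraskov mutual information


def kraskov_mi(x: np.ndarray, y: np.ndarray, k: int = 3, jitter_seed: int = 0) -> float:
    """Kraskov k-NN mutual information (variant 1), in nats.

    MI = psi(k) + psi(n) - < psi(n_x + 1) + psi(n_y + 1) > with neighbor
    counts taken strictly inside the joint k-th-neighbor max-norm radius.
    Duplicate points (zero radii) are broken by a deterministic jitter of
    1e-10 times the coordinate scale, keyed to ``jitter_seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise InputError("x and y must have equal sample counts")
    n = x.shape[0]
    if not (1 <= k < n):
        raise ConfigError("need n > k >= 1")
    joint = np.hstack([x, y])
    # duplicate joint points give zero k-NN radii; jitter deterministically
    uniq = np.unique(joint, axis=0)
    if len(uniq) < len(joint):
        warnings.warn("duplicate points detected; applying deterministic jitter")
        rng = np.random.default_rng(np.random.SeedSequence(jitter_seed))
        scale = joint.std(axis=0)
        scale[scale == 0] = 1.0
        joint = joint + 1e-10 * scale * rng.standard_normal(joint.shape)
        x = joint[:, : x.shape[1]]
        y = joint[:, x.shape[1] :]
    tree_joint = cKDTree(joint)
    # distance to the k-th neighbor (excluding self) in the max-norm
    dists, _ = tree_joint.query(joint, k=k + 1, p=np.inf)
    eps = dists[:, -1]
    # strict inequality: shrink the radius to just below eps
    radius = np.nextafter(eps, 0.0)
    tree_x = cKDTree(x)
    tree_y = cKDTree(y)
    nx = tree_x.query_ball_point(x, radius, p=np.inf, return_length=True) - 1
    ny = tree_y.query_ball_point(y, radius, p=np.inf, return_length=True) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(mi)


def mi_matrix(
    trajset: ReactiveTrajectorySet,
    groups_A,
    groups_B,
    coordinate_extractor,
    k: int = 3,
    pool_slices: bool = True,
) -> MIMatrix:
    """Mutual information between every (A, B) group pair.

    ``coordinate_extractor(group, frame_indices)`` must return the group's
    3-D coordinates (e.g. a sidechain center of mass) for the given pooled
    frame indices, shape (len(frame_indices), 3).  By default samples are
    pooled over trajectories and slices; ``pool_slices=False`` averages
    per-slice estimates instead.
    """
    groups_A = list(groups_A)
    groups_B = list(groups_B)
    if not groups_A or not groups_B:
        raise InputError("both group sets must be non-empty")
    idx_pool = trajset.pooled()
    values = np.empty((len(groups_A), len(groups_B)))
    if pool_slices:
        xa = [np.asarray(coordinate_extractor(g, idx_pool)) for g in groups_A]
        xb = [np.asarray(coordinate_extractor(g, idx_pool)) for g in groups_B]
        for arr in xa + xb:
            if arr.ndim != 2 or len(arr) != len(idx_pool):
                raise InputError("coordinate_extractor must return (n_frames, d) arrays")
        for i, a in enumerate(xa):
            for j, b in enumerate(xb):
                values[i, j] = kraskov_mi(a, b, k=k, jitter_seed=trajset.seed)
    else:
        per_slice = np.empty((len(groups_A), len(groups_B), trajset.n_slices))
        for s in range(trajset.n_slices):
            idx = trajset.frame_indices[:, s]
            xa = [np.asarray(coordinate_extractor(g, idx)) for g in groups_A]
            xb = [np.asarray(coordinate_extractor(g, idx)) for g in groups_B]
            for i, a in enumerate(xa):
                for j, b in enumerate(xb):
                    per_slice[i, j, s] = kraskov_mi(a, b, k=k, jitter_seed=trajset.seed)
        values = per_slice.mean(axis=2)
    return MIMatrix(
        values=values,
        labels_A=groups_A,
        labels_B=groups_B,
        k=k,
        n_samples=len(idx_pool),
        metadata={"seed": trajset.seed, "pool_slices": pool_slices},
    )


def threshold_pairs(matrix: MIMatrix, threshold: float):
    """Group pairs with MI strictly above threshold, sorted descending."""
    out = []
    for i, la in enumerate(matrix.labels_A):
        for j, lb in enumerate(matrix.labels_B):
            v = float(matrix.values[i, j])
            if v > threshold:
                out.append((la, lb, v))
    out.sort(key=lambda t: -t[2])
    return out


def permutation_null_mi(
    x: np.ndarray, y: np.ndarray, k: int = 3, n_permutations: int = 20, seed: int = 0
) -> np.ndarray:
    """Null distribution of the MI estimator under frame shuffling.

    Shuffling one variable's frames destroys any dependence, so the returned
    values calibrate a data-driven threshold in place of a guessed one.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = np.asarray(y)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        out[i] = kraskov_mi(x, y[rng.permutation(len(y))], k=k, jitter_seed=seed + i + 1)
    return out
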