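"""Umbrella-window reweighting (MBAR) and path free-energy profiles.

Umbrella windows — one harmonic restraint per path image — are post-processed
with the multistate Bennett acceptance ratio (MBAR): the self-consistent
estimator of the relative free energies of the biased states, which yields
per-frame weights for the restraint-free (unbiased) ensemble.  Free-energy
profiles are then accumulated along the path progress coordinate inside a
reactive tube (samples deviating from the path by more than a squared-distance
cutoff are ignored) and referenced to the profile minimum.  Standard errors
come from block averages over contiguous blocks within each window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from mepkit.errors import ConfigError, ConvergenceError, InputError
from mepkit.path_geometry import ImagePath, project_points
from mepkit.toy_systems import RestraintSpec, Trajectory
from mepkit.units import kt as thermal_energy

__all__ = [
    "UmbrellaDataset",
    "MBARResult",
    "FreeEnergyProfile",
    "solve_mbar",
    "pmf_along_path",
    "block_average_error",
]

DEFAULT_TUBE_CUTOFF_SQ = 2000.0  # squared position units (A^2 in physical mode)


@dataclass
class UmbrellaDataset:
    """Per-window trajectories with their restraints and a shared temperature."""

    windows: list  # list of (Trajectory, RestraintSpec)
    temperature: float = 1.0
    mode: str = "reduced"
    path_ref: str = ""

    def __post_init__(self):
        if not self.windows:
            raise InputError("dataset needs at least one window")
        dim = self.windows[0][0].frames.shape[1]
        for i, (traj, restraint) in enumerate(self.windows):
            if traj.frames.shape[1] != dim:
                raise InputError("all windows must share the CV dimension")
            recomputed = restraint.energy(traj.frames)
            if not np.allclose(recomputed, traj.bias_energy, rtol=0, atol=1e-10):
                raise InputError(
                    f"window {i}: stored bias energies do not match the restraint spec"
                )

    @property
    def kt(self) -> float:
        return thermal_energy(self.temperature, self.mode)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def all_frames(self) -> np.ndarray:
        return np.concatenate([t.frames for t, _ in self.windows], axis=0)

    def frame_counts(self) -> np.ndarray:
        return np.array([len(t) for t, _ in self.windows])


@dataclass
class MBARResult:
    """Relative window free energies and unbiased per-frame weights."""

    f: np.ndarray  # per-window free energies, kT units, f[0] = 0
    weights: np.ndarray  # unbiased per-frame weights over pooled frames, sum 1
    residual: float
    overlap_min: float = 1.0

    def __post_init__(self):
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-10:
            raise InputError("weights must be non-negative and sum to 1")


def _reduced_bias_matrix(dataset: UmbrellaDataset) -> np.ndarray:
    """u[k, n] = beta * bias_k(x_n) over pooled frames (windows share U)."""
    beta = 1.0 / dataset.kt
    frames = dataset.all_frames()
    u = np.empty((dataset.n_windows, len(frames)))
    for k, (_, restraint) in enumerate(dataset.windows):
        u[k] = beta * restraint.energy(frames)
    return u


def solve_mbar(dataset: UmbrellaDataset, tol: float = 1e-8, max_iter: int = 10000) -> MBARResult:
    """Solve the MBAR self-consistency equations for an umbrella dataset.

    The convex MBAR objective is minimized (quasi-Newton) and the solution is
    polished by self-consistent iteration until the free-energy residual
    drops below ``tol``.  Returns per-window free energies in kT (gauge
    f_1 = 0) and normalized per-frame weights of the unbiased state.
    """
    u_kn = _reduced_bias_matrix(dataset)
    n_k = dataset.frame_counts().astype(float)
    k, n = u_kn.shape
    log_nk = np.log(n_k)

    def objective(f):
        d = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
        val = d.sum() / n - float(n_k @ f) / n
        c = np.exp(log_nk[:, None] + f[:, None] - u_kn - d[None, :])
        grad = c.sum(axis=1) / n - n_k / n
        return val, grad

    f = np.zeros(k)
    if k > 1:
        res = minimize(objective, f, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
        f = res.x
    # self-consistent polish to the stated residual in f
    residual = np.inf
    for _ in range(max_iter):
        d = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - d[None, :], axis=1)
        f_new = f_new - f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(f"MBAR did not converge: residual {residual:g} > {tol:g}")

    d = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
    log_w = -d
    log_w -= logsumexp(log_w)
    weights = np.exp(log_w)
    weights /= weights.sum()

    overlap_min = 1.0
    if k > 1:
        # per-frame state responsibilities; adjacent-window overlap mass
        c = np.exp(log_nk[:, None] + f[:, None] - u_kn - d[None, :])  # (K, N)
        w_state = c / n_k[:, None]  # rows sum to 1
        overlap = w_state @ (c.T)  # O[i, j] ~ mass window i shares with j
        off = np.diag(overlap, 1)
        overlap_min = float(off.min()) if len(off) else 1.0
        if overlap_min < 1e-3:
            warnings.warn(
                f"poor window overlap: minimum adjacent overlap mass {overlap_min:.2e}"
            )
    return MBARResult(f=f, weights=weights, residual=residual, overlap_min=overlap_min)


@dataclass
class FreeEnergyProfile:
    """Free energy along the path progress coordinate inside a reactive tube.

    ``bin_progress`` holds 0-based interpolable image coordinates of bin
    centers; reports add 1 to match 1-based image labels.  ``F`` is
    referenced to the profile minimum; empty bins carry NaN and
    ``n_effective`` 0 (flagged, never interpolated).
    """

    bin_progress: np.ndarray
    F: np.ndarray
    se: np.ndarray
    n_effective: np.ndarray
    tube_cutoff_sq: float
    kt: float
    units: str = "kT"
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("bin,image_coordinate,progress_normalized,F,SE,n_effective\n")
            span = max(float(self.bin_progress.max()), 1.0)
            for i, (p, f, s, ne) in enumerate(
                zip(self.bin_progress, self.F, self.se, self.n_effective)
            ):
                fh.write(
                    f"{i},{float(p + 1.0)!r},{float(p / span)!r},{float(f)!r},{float(s)!r},{float(ne)!r}\n"
                )


def pmf_along_path(
    dataset: UmbrellaDataset,
    mbar: MBARResult,
    path: ImagePath,
    n_bins: int | None = None,
    tube_cutoff_sq: float = DEFAULT_TUBE_CUTOFF_SQ,
    n_blocks: int = 5,
) -> FreeEnergyProfile:
    """Free-energy profile along the progress coordinate within the tube.

    Frames are projected onto the path; those with orthogonal squared
    distance above ``tube_cutoff_sq`` are ignored.  By default there is one
    bin per image (binning by nearest image along progress).  Per-bin free
    energies are -kT ln of the accumulated unbiased weight, renormalized over
    retained frames and referenced to the profile minimum.  Standard errors
    are block averages over contiguous within-window blocks.
    """
    m = path.n_images
    if n_bins is None:
        n_bins = m
    frames = dataset.all_frames()
    if len(frames) != len(mbar.weights):
        raise InputError("MBAR result does not match dataset frame count")
    progress, dsq = project_points(frames, path)
    inside = dsq <= tube_cutoff_sq
    if not np.any(inside):
        raise InputError("no frames inside the reactive tube")
    # bin centers uniform over [0, M-1]; default n_bins = M puts one center
    # per image and assigns by nearest image
    edges = np.linspace(0.0, m - 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:]) if n_bins != m else np.arange(m, dtype=float)
    if n_bins == m:
        bins = np.clip(np.rint(progress).astype(int), 0, m - 1)
    else:
        bins = np.clip(np.searchsorted(edges, progress, side="right") - 1, 0, n_bins - 1)

    w = np.where(inside, mbar.weights, 0.0)
    wsum = w.sum()
    w = w / wsum
    bin_w = np.bincount(bins, weights=w, minlength=n_bins)
    bin_w2 = np.bincount(bins, weights=w * w, minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = np.where(bin_w2 > 0, bin_w**2 / bin_w2, 0.0)
        f_bins = np.where(bin_w > 0, -np.log(bin_w), np.nan)
    missing = bin_w == 0
    if missing.mean() > 0.25:
        warnings.warn(f"{int(missing.sum())} of {n_bins} bins have no retained weight")
    f_bins = f_bins - np.nanmin(f_bins)
    ref_bin = int(np.nanargmin(f_bins))

    # block-average errors: block b pools the b-th contiguous slice of every window
    counts = dataset.frame_counts()
    offsets = np.concatenate([[0], np.cumsum(counts)])
    block_f = np.full((n_blocks, n_bins), np.nan)
    for b in range(n_blocks):
        sel = np.zeros(len(frames), dtype=bool)
        for k, c in enumerate(counts):
            lo = offsets[k] + (b * c) // n_blocks
            hi = offsets[k] + ((b + 1) * c) // n_blocks
            sel[lo:hi] = True
        wb = np.where(sel, w, 0.0)
        tot = wb.sum()
        if tot <= 0:
            continue
        bw = np.bincount(bins, weights=wb / tot, minlength=n_bins)
        with np.errstate(divide="ignore"):
            fb = np.where(bw > 0, -np.log(bw), np.nan)
        if np.isfinite(fb[ref_bin]):
            block_f[b] = fb - fb[ref_bin]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(block_f, axis=0, ddof=1) / np.sqrt(n_blocks)
    se = np.where(missing, np.nan, se)

    kbt = dataset.kt
    return FreeEnergyProfile(
        bin_progress=centers,
        F=f_bins,
        se=se,
        n_effective=n_eff,
        tube_cutoff_sq=float(tube_cutoff_sq),
        kt=kbt,
        units="kT",
        metadata={"n_blocks": n_blocks, "n_frames_inside": int(inside.sum())},
    )


def block_average_error(series: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of a (possibly correlated) series from block means.

    The series is split into ``n_blocks`` contiguous blocks; the SE is the
    standard deviation of the block means divided by sqrt(n_blocks).
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ConfigError("need at least 2 blocks")
    if len(x) < 2 * n_blocks:
        raise InputError(f"series of length {len(x)} too short for {n_blocks} blocks")
    means = np.array([b.mean() for b in np.array_split(x, n_blocks)])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))
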