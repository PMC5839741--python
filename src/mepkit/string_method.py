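"""Mean-forces string method for minimum (free-)energy paths.

The string method discretizes a transition pathway into images in
collective-variable space and iterates: sample a restrained (umbrella-like)
window around each image, estimate the mean force from the restraint-force
average, step each image along the mean force, then smooth weakly and
reparameterize to equal arc-length spacing.  Terminal images are held fixed
for an initial number of cycles and afterwards updated with the
path-tangential force component removed so they cannot drift along the
pathway.  Convergence is monitored by the RMSD of the images from the
initial path.

A deterministic zero-temperature variant (exact gradients instead of sampled
mean forces) is provided both as a usable feature and as the natural
reference the sampled method must agree with on analytic potentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mepkit.errors import ConfigError, InputError
from mepkit.path_geometry import ImagePath, reparameterize, smooth_path
from mepkit.toy_systems import (
    RestraintSpec,
    ToySystem,
    Trajectory,
    potential_and_gradient,
    propagate_batch,
)

__all__ = [
    "StringConfig",
    "StringDiagnostics",
    "steered_initial_path",
    "path_from_trajectory",
    "estimate_mean_force",
    "remove_external_components",
    "update_images",
    "run_string",
    "zero_temperature_string",
]


@dataclass
class StringConfig:
    """Parameters of the string iteration.

    ``restraint_k`` is the umbrella force constant per image (0.1 kcal/A^2 in
    the physical setting; reduced units otherwise); ``mean_force_batch`` is
    the number of sampling steps per window per cycle (the per-cycle MD
    batch); ``fixed_terminal_cycles`` holds images 1 and M fixed for the
    first cycles (default 9).  ``step_size`` is capped each cycle so the
    largest image displacement does not exceed ``trust_fraction`` of the mean
    inter-image spacing.
    """

    n_images: int = 30
    restraint_k: float = 0.1
    mean_force_batch: int = 2000
    burn_in: int = 400
    step_size: float = 1.0
    n_cycles: int = 50
    fixed_terminal_cycles: int = 9
    smoothing_kappa: float = 0.1
    convergence_tol: float = 1e-3
    trust_fraction: float = 0.2
    n_blocks: int = 5

    def __post_init__(self):
        if self.n_images < 3:
            raise ConfigError("n_images must be >= 3")
        if self.step_size <= 0:
            raise ConfigError("step_size must be positive")
        if self.fixed_terminal_cycles > self.n_cycles:
            raise ConfigError("fixed_terminal_cycles cannot exceed n_cycles")
        if not (0.0 <= self.smoothing_kappa < 1.0):
            raise ConfigError("smoothing_kappa must lie in [0, 1)")


@dataclass
class StringDiagnostics:
    """Per-cycle convergence record of a string run."""

    rmsd_to_initial: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_force_norms: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    n_cycles_run: int = 0
    converged: bool = False


def _path_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Initial path


def path_from_trajectory(frames: np.ndarray, n_images: int, units: str = "reduced") -> ImagePath:
    """Piecewise-linear resampling of a trajectory into equidistant images.

    Endpoints coincide with the first and last frames.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    return reparameterize(ImagePath(images=frames, units=units), n_images=n_images)


def steered_initial_path(
    system: ToySystem,
    start: np.ndarray,
    target: np.ndarray,
    n_steps: int,
    pull_k: float,
    seed: int = 0,
    n_images: int = 30,
    target_tol: float = 0.05,
) -> ImagePath:
    """Initial pathway from a steered (targeted-dynamics-style) run.

    Dynamics are propagated with a harmonic restraint whose center moves
    linearly from ``start`` to ``target`` over ``n_steps``; the resulting
    trajectory is resampled piecewise-linearly into ``n_images`` equidistant
    images with endpoints at the trajectory's first and last frames.
    """
    start = np.atleast_1d(np.asarray(start, dtype=float))
    target = np.atleast_1d(np.asarray(target, dtype=float))
    if np.allclose(start, target):
        raise InputError("start and target must differ")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dt = system.timestep
    gamma = system.friction
    sigma = np.sqrt(2.0 * system.kt * dt / gamma)
    x = start.copy()
    frames = np.empty((n_steps + 1, len(start)))
    frames[0] = x
    noise = rng.standard_normal((n_steps, len(start)))
    for i in range(n_steps):
        center = start + (target - start) * ((i + 1) / n_steps)
        _, grad = potential_and_gradient(system, x)
        force = -grad - pull_k * (x - center)
        x = x + (dt / gamma) * force + sigma * noise[i]
        frames[i + 1] = x
    gap = float(np.linalg.norm(frames[-1] - target))
    if gap > target_tol:
        warnings.warn(
            f"steered trajectory ended {gap:.3g} from the target (tolerance {target_tol:g})"
        )
    return path_from_trajectory(frames, n_images, units=system.mode)


# ---------------------------------------------------------------------------
# Mean forces


def estimate_mean_force(window: Trajectory, restraint: RestraintSpec, n_blocks: int = 5):
    """Mean force on the CV from a restrained window.

    For a harmonic restraint centered at c the restraint-force average gives
    the (negative) free-energy gradient at the window: F = k_r (<x> - c) per
    restrained dimension.  The standard error comes from block averages of
    the window mean.
    """
    frames = window.frames
    if restraint.restrained_indices is not None:
        frames = frames[:, restraint.restrained_indices]
    n = len(frames)
    if n < 2 * n_blocks:
        raise InputError(f"window of {n} frames is shorter than 2 blocks of {n_blocks}")
    mean_force = restraint.force_constant * (frames.mean(axis=0) - restraint.center)
    blocks = np.array_split(frames, n_blocks, axis=0)
    block_means = np.stack([b.mean(axis=0) for b in blocks])
    se = restraint.force_constant * block_means.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return mean_force, se


def remove_external_components(
    forces: np.ndarray, coords: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Project out rigid-body xy-translation and z-rotation from atom forces.

    ``forces`` and ``coords`` are (N, 3) (or batched (M, N, 3)) per-atom
    arrays.  The components along the two uniform xy-translation generators
    and the infinitesimal z-rotation generator (evaluated about the
    structure's xy centroid) are removed; z-translation is retained because
    fitting is restricted to the xy-plane.  The operation is an orthogonal
    projection, hence idempotent.
    """
    f = np.asarray(forces, dtype=float)
    x = np.asarray(coords, dtype=float)
    if f.shape != x.shape:
        raise InputError("forces and coordinates must have matching shapes")
    if f.ndim == 3:
        return np.stack(
            [remove_external_components(f[i], x[i], reference) for i in range(len(f))]
        )
    if f.ndim != 2 or f.shape[1] != 3:
        raise InputError("expected (N, 3) per-atom arrays")
    n = len(f)
    pose = x if reference is None else reference
    cen = pose[:, :2].mean(axis=0)
    # generator basis: uniform x/y translation, infinitesimal rotation about z
    g = np.zeros((3, n, 3))
    g[0, :, 0] = 1.0
    g[1, :, 1] = 1.0
    g[2, :, 0] = -(pose[:, 1] - cen[1])
    g[2, :, 1] = pose[:, 0] - cen[0]
    basis = g.reshape(3, -1)
    # orthonormalize (rotation generator is already orthogonal to translations
    # about the centroid, but keep it robust)
    q, r = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r).max())
    if not np.all(keep):
        raise InputError("degenerate external-component generator basis")
    flat = f.reshape(-1)
    flat = flat - q @ (q.T @ flat)
    return flat.reshape(n, 3)


# ---------------------------------------------------------------------------
# Image updates


def _tangents(images: np.ndarray) -> np.ndarray:
    """Unit tangents per image (central differences, one-sided at ends)."""
    t = np.empty_like(images)
    t[0] = images[1] - images[0]
    t[-1] = images[-1] - images[-2]
    t[1:-1] = images[2:] - images[:-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def update_images(
    path: ImagePath, mean_forces: np.ndarray, config: StringConfig, cycle: int
) -> ImagePath:
    """One string update: step along mean forces, smooth, reparameterize.

    Interior images move by ``step_size * F``; terminal images are fixed
    while ``cycle <= fixed_terminal_cycles`` and afterwards move by the force
    with its path-tangential component removed.  Displacements are capped at
    ``trust_fraction`` of the mean image spacing.
    """
    forces = np.asarray(mean_forces, dtype=float)
    pts = path.images
    if forces.shape != pts.shape:
        raise InputError("mean_forces must match the image array shape")
    step = config.step_size
    disp = step * forces
    tang = _tangents(pts)
    terminals_free = cycle > config.fixed_terminal_cycles
    if terminals_free:
        for j in (0, -1):
            f = forces[j] - np.dot(forces[j], tang[j]) * tang[j]
            disp[j] = step * f
    else:
        disp[0] = 0.0
        disp[-1] = 0.0
    # per-image trust region: no image moves more than a fraction of the
    # mean spacing, without letting one stiff image stall the others
    mean_gap = path.arc_length() / (path.n_images - 1)
    cap = config.trust_fraction * mean_gap
    norms = np.linalg.norm(disp, axis=1)
    over = norms > cap
    if cap > 0 and np.any(over):
        disp[over] *= (cap / norms[over])[:, None]
    for _ in range(20):
        new = pts + disp
        seg = np.linalg.norm(np.diff(new, axis=0), axis=1)
        if np.all(seg > 0):
            break
        warnings.warn("image collision after step; halving displacement")
        disp *= 0.5
    out = ImagePath(images=new, units=path.units, metadata=dict(path.metadata))
    out = smooth_path(out, config.smoothing_kappa)
    return reparameterize(out)


# ---------------------------------------------------------------------------
# Drivers


def run_string(
    system: ToySystem, initial: ImagePath, config: StringConfig, seed: int = 0
):
    """Iterate the mean-forces string method from an initial path.

    Each cycle propagates one restrained window per image (all windows
    simultaneously, one independent noise substream per window), estimates
    per-image mean forces from the restraint-force averages, and applies
    :func:`update_images`.  Stops early when the RMSD-to-initial series
    plateaus (spread over the last five cycles below ``convergence_tol``).
    Deterministic for a fixed seed.
    """
    if initial.n_images != config.n_images:
        raise ConfigError("initial path image count must equal config.n_images")
    path = reparameterize(initial)
    initial_images = path.images.copy()
    master = np.random.SeedSequence(seed)
    cycle_seeds = master.spawn(config.n_cycles)
    rmsds = []
    force_norms = []
    converged = False
    n_cycles_run = 0
    for cycle in range(1, config.n_cycles + 1):
        window_streams = cycle_seeds[cycle - 1].spawn(config.n_images)
        rngs = [np.random.default_rng(s) for s in window_streams]
        restraints = [
            RestraintSpec(center=img.copy(), force_constant=config.restraint_k)
            for img in path.images
        ]
        all_frames = propagate_batch(
            system,
            path.images,
            restraints,
            config.mean_force_batch + config.burn_in,
            rngs,
        )[config.burn_in :]
        means = all_frames.mean(axis=0)  # (M, D)
        forces = config.restraint_k * (means - path.images)
        path = update_images(path, forces, config, cycle)
        rmsds.append(_path_rmsd(path.images, initial_images))
        force_norms.append(np.linalg.norm(forces, axis=1))
        n_cycles_run = cycle
        if cycle > config.fixed_terminal_cycles and len(rmsds) >= 5:
            recent = rmsds[-5:]
            if max(recent) - min(recent) < config.convergence_tol:
                converged = True
                break
    diag = StringDiagnostics(
        rmsd_to_initial=np.asarray(rmsds),
        mean_force_norms=np.asarray(force_norms),
        n_cycles_run=n_cycles_run,
        converged=converged,
    )
    return path, diag


def zero_temperature_string(
    system: ToySystem,
    initial: ImagePath,
    n_images: int | None = None,
    max_iter: int = 20000,
    tol: float = 1e-7,
    trust_fraction: float = 0.2,
) -> ImagePath:
    """Deterministic string on exact gradients (zero-temperature limit).

    Images follow steepest descent on U with reparameterization after every
    step until the largest per-iteration image displacement falls below
    ``tol``.  On an analytic potential this converges to the minimum-energy
    path, the reference the sampled string is validated against.
    """
    m = initial.n_images if n_images is None else int(n_images)
    path = reparameterize(initial, n_images=m)
    pts = path.images
    for _ in range(max_iter):
        _, grad = potential_and_gradient(system, pts)
        force = -grad
        gap = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))) / (m - 1)
        fmax = float(np.max(np.linalg.norm(force, axis=1)))
        if fmax == 0:
            break
        step = trust_fraction * gap / fmax
        new = pts + step * force
        new = reparameterize(ImagePath(images=new, units=path.units)).images
        moved = float(np.max(np.linalg.norm(new - pts, axis=1)))
        pts = new
        if moved < tol:
            break
    return ImagePath(images=pts, units=path.units, metadata={"mode": "zero_temperature"})
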