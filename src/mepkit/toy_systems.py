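"""Synthetic-data generators standing in for all-atom molecular dynamics.

This module provides the ground-truth systems the rest of the pipeline is
exercised on:

* analytic potentials (Müller–Brown, 1-D double well, isotropic harmonic,
  linear) with exact gradients,
* restrained overdamped Langevin (Euler–Maruyama) sampling, the stand-in for
  restrained MD umbrella windows and mean-force batches,
* λ-coupled alchemical toy models whose free-energy differences are known in
  closed form,
* multi-group Gaussian coordinate ensembles with planted inter-group
  correlations, the stand-in for transmembrane-helix/porter-domain sidechain
  center-of-mass motions.

The integrator is overdamped Langevin because the downstream estimators only
require correct stationary (Boltzmann) sampling, not kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mepkit.errors import ConfigError, InputError, NumericalStabilityError
from mepkit.units import kt

__all__ = [
    "ToySystem",
    "RestraintSpec",
    "Trajectory",
    "CoupledDomainEnsemble",
    "evaluate_potential",
    "sample_restrained",
    "sample_windows",
    "generate_alchemical_samples",
    "generate_coupled_domains",
    "MULLER_BROWN_PARAMS",
]

# Standard four-Gaussian Müller-Brown parameterization; kept in the system's
# parameter map (not at call sites) so variants can be configured.
MULLER_BROWN_PARAMS = {
    "A": (-200.0, -100.0, -170.0, 15.0),
    "a": (-1.0, -1.0, -6.5, 0.7),
    "b": (0.0, 0.0, 11.0, 0.6),
    "c": (-10.0, -10.0, -6.5, 0.7),
    "x0": (1.0, 0.0, -0.5, -1.0),
    "y0": (0.0, 0.5, 1.5, 1.0),
}

_POTENTIAL_DIMENSIONS = {
    "muller_brown": 2,
    "double_well_1d": 1,
    "linear_1d": 1,
}

# Conservative curvature (max Hessian eigenvalue) bounds on the sampled
# domain, used by the integrator stability guard.  The Müller-Brown value was
# obtained from a fine-grid Hessian scan restricted to the U < 200 basin
# region; double-well bound is max|U''| = h(12 x^2 - 4) on |x| <= 2.
_MULLER_BROWN_STIFFNESS = 4200.0


@dataclass
class ToySystem:
    """An analytic potential plus thermodynamic and integrator parameters.

    ``temperature`` is in kelvin in ``"physical"`` mode and directly equals
    kT in ``"reduced"`` mode.  ``friction`` (gamma) and ``timestep`` are in
    reduced time units.
    """

    potential_id: str
    dimension: int = 1
    parameters: dict = field(default_factory=dict)
    temperature: float = 1.0
    friction: float = 1.0
    timestep: float = 1e-3
    mode: str = "reduced"
    metropolis: bool = True

    def __post_init__(self):
        if self.potential_id not in ("muller_brown", "double_well_1d", "harmonic_nd", "linear_1d"):
            raise ConfigError(f"unknown potential_id {self.potential_id!r}")
        expected = _POTENTIAL_DIMENSIONS.get(self.potential_id)
        if expected is not None and self.dimension != expected:
            raise ConfigError(
                f"{self.potential_id} requires dimension {expected}, got {self.dimension}"
            )
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if self.timestep <= 0:
            raise ConfigError("timestep must be positive")
        if self.friction <= 0:
            raise ConfigError("friction must be positive")
        if self.potential_id == "muller_brown" and not self.parameters:
            self.parameters = dict(MULLER_BROWN_PARAMS)

    @property
    def kt(self) -> float:
        return kt(self.temperature, self.mode)

    def stiffness_bound(self) -> float:
        """Upper bound on the potential's curvature on the sampled domain."""
        if self.potential_id == "harmonic_nd":
            return float(self.parameters.get("k", 1.0))
        if self.potential_id == "linear_1d":
            return 0.0
        if self.potential_id == "double_well_1d":
            h = float(self.parameters.get("h", 1.0))
            return 44.0 * h  # max of h*(12x^2-4) on |x| <= 2
        return _MULLER_BROWN_STIFFNESS


@dataclass
class RestraintSpec:
    """Harmonic positional restraint ``(k/2)|x - c|^2`` on a CV subset.

    ``force_constant`` is kcal/mol/A^2 in physical mode, reduced units
    otherwise.  ``restrained_indices=None`` restrains all dimensions.
    """

    center: np.ndarray
    force_constant: float
    restrained_indices: Sequence[int] | None = None

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        if self.force_constant < 0:
            raise ConfigError("force_constant must be non-negative")
        if self.restrained_indices is not None:
            idx = np.asarray(self.restrained_indices, dtype=int)
            if len(idx) != len(self.center):
                raise InputError("center length must equal number of restrained dimensions")
            self.restrained_indices = idx

    def energy(self, frames: np.ndarray) -> np.ndarray:
        """Bias energy per frame; frames shape (n, D) or (D,)."""
        x = np.atleast_2d(frames)
        sub = x if self.restrained_indices is None else x[:, self.restrained_indices]
        d = sub - self.center
        return 0.5 * self.force_constant * np.sum(d * d, axis=1)

    def force(self, frames: np.ndarray) -> np.ndarray:
        """Restraint force -dU_bias/dx, same shape as frames (2-D)."""
        x = np.atleast_2d(frames)
        f = np.zeros_like(x)
        if self.restrained_indices is None:
            f[:] = -self.force_constant * (x - self.center)
        else:
            f[:, self.restrained_indices] = -self.force_constant * (
                x[:, self.restrained_indices] - self.center
            )
        return f


@dataclass
class Trajectory:
    """Time-ordered CV frames with per-frame potential and bias energies."""

    frames: np.ndarray
    potential_energy: np.ndarray
    bias_energy: np.ndarray
    seed: int
    system_ref: str = ""

    def __post_init__(self):
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.potential_energy = np.asarray(self.potential_energy, dtype=float)
        self.bias_energy = np.asarray(self.bias_energy, dtype=float)
        n = len(self.frames)
        if n < 1:
            raise InputError("trajectory must contain at least one frame")
        if len(self.potential_energy) != n or len(self.bias_energy) != n:
            raise InputError("energy arrays must match frame count")
        if not (np.all(np.isfinite(self.potential_energy)) and np.all(np.isfinite(self.bias_energy))):
            raise InputError("energies must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Persist as CSV (frame_index, cv_0..cv_{D-1}, energies) + JSON sidecar."""
        path = Path(path)
        d = self.frames.shape[1]
        cols = ["frame_index"] + [f"cv_{i}" for i in range(d)] + ["potential_energy", "bias_energy"]
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            for i in range(len(self.frames)):
                row = [str(i)] + [repr(float(v)) for v in self.frames[i]] + [
                    repr(float(self.potential_energy[i])),
                    repr(float(self.bias_energy[i])),
                ]
                fh.write(",".join(row) + "\n")
        meta = {"seed": int(self.seed), "system_ref": self.system_ref}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            frames=data[:, 1:-2],
            potential_energy=data[:, -2],
            bias_energy=data[:, -1],
            seed=int(meta.get("seed", 0)),
            system_ref=str(meta.get("system_ref", "")),
        )


# ---------------------------------------------------------------------------
# Potentials


def _mb_terms(params: dict, xy: np.ndarray):
    A = np.asarray(params["A"], dtype=float)
    a = np.asarray(params["a"], dtype=float)
    b = np.asarray(params["b"], dtype=float)
    c = np.asarray(params["c"], dtype=float)
    x0 = np.asarray(params["x0"], dtype=float)
    y0 = np.asarray(params["y0"], dtype=float)
    dx = xy[..., 0:1] - x0
    dy = xy[..., 1:2] - y0
    expo = a * dx**2 + b * dx * dy + c * dy**2
    terms = A * np.exp(expo)
    return terms, a, b, c, dx, dy


def potential_and_gradient(system: ToySystem, points: np.ndarray):
    """Vectorized U and grad U for an array of points, shape (..., D)."""
    x = np.asarray(points, dtype=float)
    if x.shape[-1] != system.dimension:
        raise InputError(
            f"point dimension {x.shape[-1]} does not match system dimension {system.dimension}"
        )
    p = system.parameters
    if system.potential_id == "harmonic_nd":
        k = float(p.get("k", 1.0))
        u = 0.5 * k * np.sum(x * x, axis=-1)
        g = k * x
    elif system.potential_id == "linear_1d":
        g0 = float(p.get("slope", p.get("g", 1.0)))
        u = g0 * x[..., 0]
        g = np.full_like(x, g0)
    elif system.potential_id == "double_well_1d":
        h = float(p.get("h", 1.0))
        a = float(p.get("a", 1.0))  # wells at +-a
        s = (x[..., 0] / a) ** 2 - 1.0
        u = h * s * s
        g = np.empty_like(x)
        g[..., 0] = 4.0 * h * s * x[..., 0] / (a * a)
    elif system.potential_id == "muller_brown":
        terms, a, b, c, dx, dy = _mb_terms(p, x)
        u = np.sum(terms, axis=-1)
        gx = np.sum(terms * (2.0 * a * dx + b * dy), axis=-1)
        gy = np.sum(terms * (b * dx + 2.0 * c * dy), axis=-1)
        g = np.stack([gx, gy], axis=-1)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigError(f"unknown potential_id {system.potential_id!r}")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(g))):
        raise NumericalStabilityError("potential or gradient not finite at evaluated point")
    return u, g


def evaluate_potential(system: ToySystem, point: np.ndarray):
    """Energy U(x) and gradient dU/dx at a single CV point."""
    pt = np.atleast_1d(np.asarray(point, dtype=float))
    u, g = potential_and_gradient(system, pt)
    return float(u), g


# ---------------------------------------------------------------------------
# Restrained Langevin sampling

_GUARD_RADIUS = 1e3


def _check_timestep(system: ToySystem, restraint_k: float) -> None:
    # Plain Euler-Maruyama needs dt well below friction/k_max for an accurate
    # stationary law; the Metropolis-adjusted sampler is exact at any stable
    # timestep, so only drift-map stability constrains it.
    factor = 0.5 if system.metropolis else 0.1
    k_max = system.stiffness_bound() + restraint_k
    if k_max > 0:
        bound = factor * system.friction / k_max
        if system.timestep > bound:
            raise NumericalStabilityError(
                f"timestep {system.timestep:g} exceeds stability bound {bound:g} "
                f"({factor}*friction/k_max with k_max={k_max:g})"
            )


def propagate_batch(
    system: ToySystem,
    x0: np.ndarray,
    restraints: list[RestraintSpec] | None,
    n_steps: int,
    rngs: list[np.random.Generator],
) -> np.ndarray:
    """Euler-Maruyama propagation of a batch of walkers, one per restraint.

    ``x0`` has shape (M, D); walker m feels ``restraints[m]`` (or none).
    Returns all frames, shape (n_steps, M, D).  Used both by the public
    single-window sampler and by the string driver, which propagates all
    umbrella windows simultaneously.  The restraint forces are evaluated in
    one vectorized pass per step using stacked centers and force constants.

    With ``system.metropolis`` (the default) each Euler-Maruyama move is
    accepted or rejected by the Metropolis criterion with the asymmetric
    proposal correction, which makes the stationary distribution exactly
    Boltzmann at any stable timestep; without it the plain discretization
    carries an O(dt) stationary bias.
    """
    x = np.array(x0, dtype=float)
    m, d = x.shape
    dt = system.timestep
    gamma = system.friction
    kbt = system.kt
    sigma = np.sqrt(2.0 * kbt * dt / gamma)
    # one noise stream per walker so adding walkers never perturbs existing ones
    noise = np.empty((n_steps, m, d))
    log_u = np.empty((n_steps, m))
    for j, rng in enumerate(rngs):
        noise[:, j, :] = rng.standard_normal((n_steps, d))
        log_u[:, j] = np.log(rng.uniform(size=n_steps))
    # stack restraints into (M, D) center/mask and (M,) k arrays
    centers = np.zeros((m, d))
    ks = np.zeros(m)
    mask = np.zeros((m, d))
    if restraints is not None:
        for j, r in enumerate(restraints):
            if r is None:
                continue
            ks[j] = r.force_constant
            idx = (
                np.arange(d)
                if r.restrained_indices is None
                else np.asarray(r.restrained_indices)
            )
            centers[j, idx] = r.center
            mask[j, idx] = 1.0
    k_mask = ks[:, None] * mask

    def total_energy_force(xx):
        u, grad = potential_and_gradient(system, xx)
        dev = mask * (xx - centers)
        u_bias = 0.5 * np.einsum("md,md->m", k_mask * dev, dev)
        return u + u_bias, -grad - k_mask * dev

    step_scale = dt / gamma
    out = np.empty((n_steps, m, d))
    u_cur, f_cur = total_energy_force(x)
    for i in range(n_steps):
        drift = x + step_scale * f_cur
        prop = drift + sigma * noise[i]
        u_prop, f_prop = total_energy_force(prop)
        if system.metropolis:
            back = prop + step_scale * f_prop
            log_q_fwd = -np.sum((prop - drift) ** 2, axis=-1) / (2.0 * sigma**2)
            log_q_bwd = -np.sum((x - back) ** 2, axis=-1) / (2.0 * sigma**2)
            log_alpha = -(u_prop - u_cur) / kbt + log_q_bwd - log_q_fwd
            accept = log_u[i] < log_alpha
            x = np.where(accept[:, None], prop, x)
            u_cur = np.where(accept, u_prop, u_cur)
            f_cur = np.where(accept[:, None], f_prop, f_cur)
        else:
            x = prop
            u_cur, f_cur = u_prop, f_prop
        out[i] = x
        if i % 1000 == 0 and np.any(np.abs(x) > _GUARD_RADIUS):
            raise NumericalStabilityError(
                f"trajectory diverged beyond guard radius {_GUARD_RADIUS:g} at step {i}; "
                f"timestep {dt:g} is too large for this system"
            )
    if np.any(np.abs(out[-1]) > _GUARD_RADIUS) or not np.all(np.isfinite(out[-1])):
        raise NumericalStabilityError(
            f"trajectory diverged beyond guard radius {_GUARD_RADIUS:g}; "
            f"timestep {dt:g} is too large for this system"
        )
    return out


def sample_restrained(
    system: ToySystem,
    restraint: RestraintSpec | None,
    n_steps: int,
    burn_in: int = 0,
    seed: int = 0,
    x0: np.ndarray | None = None,
    stride: int = 1,
) -> Trajectory:
    """Sample the Boltzmann distribution of U + U_bias by overdamped Langevin.

    ``n_steps`` frames are recorded after ``burn_in`` integrator steps; with
    ``stride`` > 1 every stride-th integrator step is recorded, reducing the
    autocorrelation of the stored frames.  Per-frame potential and bias
    energies are attached; reproducible for a fixed seed.
    """
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    k_r = restraint.force_constant if restraint is not None else 0.0
    _check_timestep(system, k_r)
    if x0 is None:
        if restraint is not None:
            x0 = np.zeros(system.dimension)
            if restraint.restrained_indices is None:
                x0[:] = restraint.center
            else:
                x0[restraint.restrained_indices] = restraint.center
        else:
            x0 = np.zeros(system.dimension)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = propagate_batch(
        system, x0[None, :], [restraint], n_steps * stride + burn_in, [rng]
    )[burn_in + stride - 1 :: stride, 0, :]
    u, _ = potential_and_gradient(system, frames)
    bias = restraint.energy(frames) if restraint is not None else np.zeros(len(frames))
    return Trajectory(
        frames=frames,
        potential_energy=u,
        bias_energy=bias,
        seed=seed,
        system_ref=system.potential_id,
    )


def sample_windows(
    system: ToySystem,
    restraints: list[RestraintSpec],
    n_steps: int,
    burn_in: int = 0,
    seed: int = 0,
    stride: int = 1,
) -> list[Trajectory]:
    """Sample many restrained windows simultaneously (one walker each).

    Equivalent to calling :func:`sample_restrained` per window but propagated
    as one vectorized batch.  Each window draws from its own substream of the
    master seed, so adding windows never perturbs existing ones.
    """
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    k_max = max(r.force_constant for r in restraints)
    _check_timestep(system, k_max)
    x0 = np.zeros((len(restraints), system.dimension))
    for j, r in enumerate(restraints):
        if r.restrained_indices is None:
            x0[j] = r.center
        else:
            x0[j, r.restrained_indices] = r.center
    master = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(len(restraints))]
    all_frames = propagate_batch(system, x0, restraints, n_steps * stride + burn_in, rngs)
    recorded = all_frames[burn_in + stride - 1 :: stride]
    out = []
    for j, r in enumerate(restraints):
        frames = recorded[:, j, :]
        u, _ = potential_and_gradient(system, frames)
        out.append(
            Trajectory(
                frames=frames,
                potential_energy=u,
                bias_energy=r.energy(frames),
                seed=seed,
                system_ref=system.potential_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Alchemical toy models


def generate_alchemical_samples(schedule, model: str, n_per_state: int, seed: int = 0, temperature: float = 1.0, mode: str = "reduced", **model_params):
    """Draw per-stage energy-difference samples for a λ-coupled toy model.

    ``schedule`` is a strictly monotone λ list in [0, 1] with S states giving
    S-1 stages.  Supported models and their analytic stage free energies:

    * ``"constant"`` (``c``): every ΔU sample equals c; ΔF = c per stage.
    * ``"gaussian"`` (``mu``, ``sigma2``): per-stage forward ΔU ~ N(mu, sigma2)
      so ΔF = mu - β sigma2 / 2; backward draws are Crooks-consistent,
      -ΔU_bwd ~ N(mu - β sigma2, sigma2).
    * ``"harmonic_k_change"`` (``k0``, ``k1``): spring constant interpolated
      linearly in λ; ΔU = (k_{i+1}-k_i) x^2 / 2 with x Boltzmann-distributed
      under the sampling state's spring; total ΔF = (kT/2) ln(k1/k0).

    Returns a :class:`mepkit.alchemy.FEPDataset` with ``analytic_dF`` attached.
    """
    from mepkit.alchemy import FEPDataset  # local import avoids cycle

    lambdas = np.asarray(schedule, dtype=float)
    if len(lambdas) < 2 or np.any(np.diff(lambdas) <= 0):
        raise ConfigError("lambda schedule must be strictly monotone increasing with >= 2 states")
    beta = 1.0 / kt(temperature, mode)
    kbt = 1.0 / beta
    n_stages = len(lambdas) - 1
    master = np.random.SeedSequence(seed)
    # one named substream per λ-stage: adding stages never perturbs existing ones
    stage_rngs = [np.random.default_rng(s) for s in master.spawn(n_stages)]

    fwd, bwd = [], []
    if model == "constant":
        c = float(model_params.get("c", 0.0))
        for _ in range(n_stages):
            fwd.append(np.full(n_per_state, c))
            bwd.append(np.full(n_per_state, -c))
        analytic = c * n_stages
    elif model == "gaussian":
        mu = float(model_params.get("mu", 0.0))
        sigma2 = float(model_params.get("sigma2", 1.0))
        sd = np.sqrt(sigma2)
        for rng in stage_rngs:
            fwd.append(rng.normal(mu, sd, n_per_state))
            bwd.append(-rng.normal(mu - beta * sigma2, sd, n_per_state))
        analytic = (mu - beta * sigma2 / 2.0) * n_stages
    elif model == "harmonic_k_change":
        k0 = float(model_params.get("k0", 1.0))
        k1 = float(model_params.get("k1", 1.0))
        if k0 <= 0 or k1 <= 0:
            raise ConfigError("spring constants must be positive")
        ks = k0 + lambdas * (k1 - k0)
        for i, rng in enumerate(stage_rngs):
            xa = rng.normal(0.0, np.sqrt(kbt / ks[i]), n_per_state)
            xb = rng.normal(0.0, np.sqrt(kbt / ks[i + 1]), n_per_state)
            dk = ks[i + 1] - ks[i]
            fwd.append(0.5 * dk * xa * xa)
            bwd.append(-0.5 * dk * xb * xb)
        analytic = 0.5 * kbt * np.log(k1 / k0)
    else:
        raise ConfigError(f"unknown alchemical model {model!r}")

    return FEPDataset(
        lambdas=lambdas,
        forward_dU=fwd,
        backward_dU=bwd,
        temperature=temperature,
        mode=mode,
        analytic_dF=float(analytic),
    )


# ---------------------------------------------------------------------------
# Coupled-domain Gaussian ensembles


@dataclass
class CoupledDomainEnsemble:
    """Per-group 3-D coordinate time series with planted correlations.

    ``coords_A`` has shape (n_frames, n_groups_A, 3), likewise ``coords_B``.
    Planted (A, B) pairs share per-axis Gaussian correlation ``rho``; all
    other pairs are independent; every marginal has unit variance.  The
    closed-form per-axis mutual information, -ln(1-rho^2)/2 nats, is stored
    as ground truth.
    """

    coords_A: np.ndarray
    coords_B: np.ndarray
    coupled_pairs: list
    rho: float
    seed: int

    @property
    def true_mi_per_axis(self) -> float:
        return -0.5 * np.log(1.0 - self.rho**2) if self.rho != 0 else 0.0

    @property
    def true_mi_3d(self) -> float:
        return 3.0 * self.true_mi_per_axis


def generate_coupled_domains(
    n_groups_A: int,
    n_groups_B: int,
    coupled_pairs: Sequence[tuple[int, int]],
    coupling_rho: float,
    n_frames: int,
    seed: int = 0,
) -> CoupledDomainEnsemble:
    """Gaussian coordinate ensembles with planted inter-group couplings.

    Each group is a 3-D coordinate (emulating a sidechain center of mass).
    For each planted pair, every axis of the A group is correlated with the
    matching axis of the B group at ``coupling_rho``; all other cross- and
    intra-ensemble correlations vanish and marginal variances are 1.
    """
    if not (0 <= coupling_rho < 1):
        raise ConfigError("coupling_rho must lie in [0, 1)")
    pairs = [(int(i), int(j)) for i, j in coupled_pairs]
    for i, j in pairs:
        if not (0 <= i < n_groups_A and 0 <= j < n_groups_B):
            raise InputError(f"coupled pair ({i}, {j}) out of range")
    if len({i for i, _ in pairs}) < len(pairs) or len({j for _, j in pairs}) < len(pairs):
        raise InputError("each group may appear in at most one coupled pair")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a = rng.standard_normal((n_frames, n_groups_A, 3))
    b = rng.standard_normal((n_frames, n_groups_B, 3))
    # x_B = rho * x_A + sqrt(1-rho^2) * eps keeps unit marginal variance
    for i, j in pairs:
        b[:, j, :] = coupling_rho * a[:, i, :] + np.sqrt(1.0 - coupling_rho**2) * b[:, j, :]
    return CoupledDomainEnsemble(
        coords_A=a, coords_B=b, coupled_pairs=pairs, rho=float(coupling_rho), seed=seed
    )
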