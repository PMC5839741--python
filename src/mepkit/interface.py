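"""Configuration, orchestration and structure I/O.

The pipeline is driven by a YAML configuration validated against a flat
schema of defaults (unknown or duplicate keys are rejected).  Every output
carries the configuration hash so resumed runs cannot silently mix
incompatible artifacts.  A minimal fixed-column PDB reader/writer supports
the optional ingestion of real structures into CV vectors; the pipeline
never requires it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from mepkit.errors import ConfigError, InputError

logger = logging.getLogger("mepkit")

__all__ = [
    "RunConfig",
    "DEFAULT_CONFIG",
    "load_config",
    "config_hash",
    "read_structure",
    "write_structure",
    "orchestrate",
]

# Defaults define the full schema; unknown keys anywhere are rejected.
DEFAULT_CONFIG: dict = {
    "mode": "reduced",
    "seed": 0,
    "out_dir": "mepkit_out",
    "string": {
        "potential": "muller_brown",
        "kT": 0.25,
        "friction": 1.0,
        "timestep": 4.0e-5,
        "n_images": 30,
        "restraint_k": 8000.0,
        "mean_force_batch": 2000,
        "burn_in": 400,
        "n_cycles": 150,
        "fixed_terminal_cycles": 9,
        "smoothing_kappa": 0.05,
        "step_size": 2.0e-4,
        "convergence_tol": 1.0e-3,
        "steer_steps": 40000,
        "steer_k": 2000.0,
    },
    "pmf": {
        "n_bins": 30,
        "tube_cutoff_sq": 2000.0,
        "n_blocks": 5,
        "samples_per_window": 2000,
        "window_k": 300.0,
        "window_burn_in": 400,
        "window_stride": 5,
    },
    "fep": {
        "n_states": 26,
        "n_per_state": 1000,
        "model": "harmonic_k_change",
        "k0": 1.0,
        "k1": 4.0,
        "estimator": "exp",
    },
    "mi": {
        "k": 3,
        "n_slices": 29,
        "n_trajectories": 100,
        "n_groups_A": 10,
        "n_groups_B": 10,
        "coupling_rho": 0.9,
        "n_frames": 5800,
        "threshold": 0.5,
    },
}


def _merge_with_defaults(user: dict, defaults: dict, prefix: str = "") -> dict:
    unknown = [f"{prefix}{k}" for k in user if k not in defaults]
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict):
                if not isinstance(uval, dict):
                    raise ConfigError(f"key {prefix}{key} must be a mapping")
                out[key] = _merge_with_defaults(uval, dval, prefix=f"{prefix}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = dict(dval) if isinstance(dval, dict) else dval
    return out


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _no_duplicates(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ConfigError(f"duplicate configuration key: {key!r}")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)


def config_hash(params: dict) -> str:
    """Stable hash of a configuration (invariant to key ordering)."""
    blob = json.dumps(params, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Validated pipeline configuration with provenance stamp."""

    params: dict
    source: str = ""

    @property
    def hash(self) -> str:
        return config_hash(self.params)

    def provenance(self) -> dict:
        from mepkit import __version__

        return {"package_version": __version__, "config_hash": self.hash}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.params, sort_keys=True))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML configuration, filling defaults.

    Unknown keys (at any nesting level) and duplicate keys are rejected;
    omitted keys take package defaults.  ``overrides`` are applied on top of
    the file content before validation.
    """
    user: dict = {}
    source = ""
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise InputError(f"configuration file not found: {p}")
        loaded = yaml.load(p.read_text(), Loader=_StrictLoader)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        user = loaded
        source = str(p)
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict) and isinstance(user.get(key), dict):
                user[key] = {**user[key], **val}
            else:
                user[key] = val
    params = _merge_with_defaults(user, DEFAULT_CONFIG)
    if params["mode"] not in ("reduced", "physical"):
        raise ConfigError("mode must be 'reduced' or 'physical'")
    return RunConfig(params=params, source=source)


# ---------------------------------------------------------------------------
# Structure I/O (optional ingestion path)


def read_structure(pdb_path: str | Path, selection_spec: dict | None = None):
    """Read coordinates from PDB ATOM/HETATM records with a name selection.

    ``selection_spec`` maps either ``{"atom_names": [...]}`` (selected in
    every residue) or ``{"residue_atoms": {resname: [names]}}``.  Returns
    ``(coords, labels)`` where labels are (chain, resseq, resname, atom name)
    tuples in file order.  Residues missing a requested atom are reported.
    """
    path = Path(pdb_path)
    if not path.exists():
        raise InputError(f"PDB file not found: {path}")
    atom_names = None
    residue_atoms = None
    if selection_spec:
        atom_names = selection_spec.get("atom_names")
        residue_atoms = selection_spec.get("residue_atoms")
    coords, labels = [], []
    seen_residues: dict = {}
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        key = (chain, resseq, resname)
        seen_residues.setdefault(key, set()).add(name)
        if atom_names is not None and name not in atom_names:
            continue
        if residue_atoms is not None and name not in residue_atoms.get(resname, ()):
            continue
        coords.append(xyz)
        labels.append((chain, resseq, resname, name))
    if atom_names is not None:
        missing = [
            f"{k[2]}{k[1]}:{n}"
            for k, names in seen_residues.items()
            for n in atom_names
            if n not in names
        ]
        if missing:
            raise InputError(f"selection atoms missing in residues: {', '.join(missing)}")
    if not coords:
        raise InputError("selection matched no atoms")
    return np.array(coords), labels


def write_structure(path: str | Path, coords: np.ndarray, labels) -> None:
    """Write coordinates back out as minimal PDB ATOM records."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for i, ((chain, resseq, resname, name), xyz) in enumerate(
            zip(labels, coords), start=1
        ):
            fh.write(
                f"ATOM  {i:5d} {name:<4s} {resname:>3s} {chain:1s}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Orchestration

_STAGES = ("simulate", "string", "pmf", "fep", "mi")


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    meta = out / f"{stage}.json"
    if not meta.exists():
        return False
    recorded = json.loads(meta.read_text()).get("config_hash")
    if recorded != cfg_hash:
        raise ConfigError(
            f"stage {stage}: existing output was produced with config hash "
            f"{recorded}, current is {cfg_hash}; refusing to resume"
        )
    return True


def orchestrate(config: RunConfig, stages=_STAGES, resume: bool = True) -> dict:
    """Run the toy pipeline stage by stage, resumably.

    Stages: simulate (steered initial path), string (path optimization), pmf
    (umbrella + MBAR profile along the converged path), fep (staged toy
    decoupling), mi (planted-coupling ensemble, resampling, MI matrix).
    Each stage writes CSV artifacts plus a JSON sidecar carrying the config
    hash; a hash mismatch on resume aborts.  Later stages load the artifacts
    of earlier ones, so a missing upstream artifact is reported by name.
    """
    from mepkit import alchemy, coupling, free_energy, path_geometry, string_method, toy_systems

    p = config.params
    out = Path(p["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash
    results: dict = {"config_hash": cfg_hash}
    seed = int(p["seed"])

    def finish(stage, payload):
        payload = {"config_hash": cfg_hash, "stage": stage, **payload}
        (out / f"{stage}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        results[stage] = payload

    sp = p["string"]
    system = toy_systems.ToySystem(
        potential_id=sp["potential"],
        dimension=2 if sp["potential"] == "muller_brown" else 1,
        temperature=sp["kT"],
        friction=sp["friction"],
        timestep=sp["timestep"],
        mode=p["mode"],
    )

    for stage in stages:
        if stage not in _STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        if resume and _stage_done(out, stage, cfg_hash):
            logger.info("stage %s: up to date, skipping", stage)
            results[stage] = json.loads((out / f"{stage}.json").read_text())
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)

        if stage == "simulate":
            start = np.array([-0.558, 1.442]) if system.dimension == 2 else np.array([-1.0])
            target = np.array([0.623, 0.028]) if system.dimension == 2 else np.array([1.0])
            initial = string_method.steered_initial_path(
                system, start, target,
                n_steps=int(sp["steer_steps"]), pull_k=float(sp["steer_k"]),
                seed=seed, n_images=int(sp["n_images"]),
            )
            initial.to_csv(out / "initial_path.csv", sidecar=config.provenance())
            finish(stage, {"n_images": initial.n_images, "arc_length": initial.arc_length()})

        elif stage == "string":
            path_file = out / "initial_path.csv"
            if not path_file.exists():
                raise InputError("missing upstream artifact initial_path.csv (stage simulate)")
            initial = path_geometry.ImagePath.from_csv(path_file)
            cfg = string_method.StringConfig(
                n_images=int(sp["n_images"]),
                restraint_k=float(sp["restraint_k"]),
                mean_force_batch=int(sp["mean_force_batch"]),
                burn_in=int(sp["burn_in"]),
                step_size=float(sp["step_size"]),
                n_cycles=int(sp["n_cycles"]),
                fixed_terminal_cycles=int(sp["fixed_terminal_cycles"]),
                smoothing_kappa=float(sp["smoothing_kappa"]),
                convergence_tol=float(sp["convergence_tol"]),
            )
            converged, diag = string_method.run_string(system, initial, cfg, seed=seed)
            converged.to_csv(out / "converged_path.csv", sidecar=config.provenance())
            finish(stage, {
                "n_cycles_run": diag.n_cycles_run,
                "converged": bool(diag.converged),
                "rmsd_to_initial": diag.rmsd_to_initial.tolist(),
            })

        elif stage == "pmf":
            path_file = out / "converged_path.csv"
            if not path_file.exists():
                raise InputError("missing upstream artifact converged_path.csv (stage string)")
            path = path_geometry.ImagePath.from_csv(path_file)
            pp = p["pmf"]
            restraints = [
                toy_systems.RestraintSpec(center=img.copy(), force_constant=float(pp["window_k"]))
                for img in path.images
            ]
            trajs = toy_systems.sample_windows(
                system, restraints,
                n_steps=int(pp["samples_per_window"]),
                burn_in=int(pp["window_burn_in"]),
                seed=seed + 1,
                stride=int(pp["window_stride"]),
            )
            dataset = free_energy.UmbrellaDataset(
                windows=list(zip(trajs, restraints)),
                temperature=system.temperature, mode=p["mode"],
            )
            mbar = free_energy.solve_mbar(dataset)
            profile = free_energy.pmf_along_path(
                dataset, mbar, path,
                n_bins=int(pp["n_bins"]),
                tube_cutoff_sq=float(pp["tube_cutoff_sq"]),
                n_blocks=int(pp["n_blocks"]),
            )
            profile.to_csv(out / "free_energy_profile.csv")
            finish(stage, {
                "barrier_kT": float(np.nanmax(profile.F)),
                "mbar_residual": mbar.residual,
                "n_frames_inside": profile.metadata["n_frames_inside"],
            })

        elif stage == "fep":
            fp = p["fep"]
            site = alchemy.staged_decoupling(
                fp["model"], n_states=int(fp["n_states"]),
                n_per_state=int(fp["n_per_state"]), seed=seed + 2,
                temperature=system.temperature, mode=p["mode"],
                k0=float(fp["k0"]), k1=float(fp["k1"]),
            )
            solvent = alchemy.staged_decoupling(
                fp["model"], n_states=int(fp["n_states"]),
                n_per_state=int(fp["n_per_state"]), seed=seed + 3,
                temperature=system.temperature, mode=p["mode"],
                k0=float(fp["k0"]), k1=float(fp["k0"]),  # null transformation leg
            )
            est = alchemy.exp_fep if fp["estimator"] == "exp" else alchemy.bar_estimate
            site_est = est(site)
            solv_est = est(solvent)
            bind = alchemy.binding_cycle(site_est, solv_est)
            finish(stage, {
                "dG_site": site_est.dF, "se_site": site_est.se,
                "dG_solvent": solv_est.dF, "se_solvent": solv_est.se,
                "dG_bind": bind.dF, "se_bind": bind.se,
                "analytic_site": site.analytic_dF,
            })

        elif stage == "mi":
            mp = p["mi"]
            n_planted = min(4, int(mp["n_groups_A"]), int(mp["n_groups_B"]))
            planted = [(g, g) for g in range(n_planted)]
            ens = toy_systems.generate_coupled_domains(
                int(mp["n_groups_A"]), int(mp["n_groups_B"]),
                planted, float(mp["coupling_rho"]),
                int(mp["n_frames"]), seed=seed + 4,
            )
            pools = coupling.uniform_slice_pools(int(mp["n_frames"]), int(mp["n_slices"]))
            trajset = coupling.resample_reactive(
                pools, n_trajectories=int(mp["n_trajectories"]), seed=seed + 5
            )
            mat = coupling.mi_matrix(
                trajset,
                groups_A=[("A", g) for g in range(int(mp["n_groups_A"]))],
                groups_B=[("B", g) for g in range(int(mp["n_groups_B"]))],
                coordinate_extractor=lambda tag, idx, e=ens: (
                    e.coords_A[idx, tag[1], :] if tag[0] == "A" else e.coords_B[idx, tag[1], :]
                ),
                k=int(mp["k"]),
            )
            mat.to_csv(out / "mi_matrix.csv")
            hits = coupling.threshold_pairs(mat, float(mp["threshold"]))
            finish(stage, {
                "n_pairs_above_threshold": len(hits),
                "top_pairs": [[str(a), str(b), v] for a, b, v in hits[:10]],
                "true_mi_3d": ens.true_mi_3d,
            })

        logger.info("stage %s: done in %.1f s", stage, time.perf_counter() - t0)
    return results
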