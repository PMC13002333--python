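"""Orchestration, configuration and format adapters.

Ties the stages together: simulate -> profiles -> fit-hmm -> classify ->
report. All randomness flows from one root seed, split per stage and per
participant through a counter-based scheme, so re-running any stage (or the
whole pipeline) with the same configuration reproduces identical outputs; a
manifest with SHA-256 hashes of every written file makes that checkable.

Tables travel as UTF-8 comma-separated CSV with a mandatory header; image
stacks as HDF5 (one dataset per session) with an NPY fallback; model fits as
JSON; configurations as YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glmhmm, stats, stimpower, synth
from .exceptions import ConfigurationError, InsufficientDataError, SchemaError

__all__ = [
    "RunConfig",
    "stage_seed",
    "run_pipeline",
    "simulate_experiment",
    "load_design",
    "load_observer",
    "save_trials",
    "load_trials",
    "save_profiles",
    "load_profiles",
    "save_image_stack",
    "load_image_stack",
    "load_external_dataset",
]

logger = logging.getLogger("modeseek")

STAGES = ("simulate", "profiles", "fit_hmm", "classify", "report")

#: Columns every trial table carries, in canonical order.
TRIAL_COLUMNS = [
    "participant", "session", "trial", "stim_class", "contrast",
    "orientation_deg", "response", "prev_response", "mode_true", "relpower",
]


@dataclass
class RunConfig:
    """End-to-end run configuration."""

    seed: int = 0
    out_dir: str = "modeseek_run"
    n_participants: int = 6
    design: synth.ExperimentDesign = dataclasses.field(default_factory=synth.ExperimentDesign)
    observer: synth.GenerativeObserver = dataclasses.field(default_factory=synth.GenerativeObserver)
    hmm: glmhmm.HMMConfig = dataclasses.field(default_factory=glmhmm.HMMConfig)
    stages: tuple[str, ...] = STAGES
    calibrate: bool = False  # replace design.low_contrast by a d'=1.5 calibration
    save_images: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")


def stage_seed(root_seed: int, stage: str, counter: int = 0) -> int:
    """Deterministic per-stage (and per-participant) seed below 2**31."""
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(root_seed), STAGES.index(stage), int(counter)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} fields {sorted(unknown)}")
    kwargs = {}
    for k, v in mapping.items():
        if k == "transition_matrix_true":
            kwargs[k] = np.asarray(v, dtype=float)
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_design(path: str | Path) -> synth.ExperimentDesign:
    """Read an :class:`ExperimentDesign` from a YAML mapping."""
    with open(path) as fh:
        return _from_mapping(synth.ExperimentDesign, yaml.safe_load(fh) or {})


def load_observer(path: str | Path) -> synth.GenerativeObserver:
    """Read a :class:`GenerativeObserver` from a YAML mapping."""
    with open(path) as fh:
        return _from_mapping(synth.GenerativeObserver, yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Tables and image stacks
# ---------------------------------------------------------------------------

def save_trials(trials: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials[cols].to_csv(path, index=False)


def load_trials(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("session", "trial", "stim_class", "contrast", "response")
               if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table at {path} is missing columns {missing}")
    return table


def save_profiles(profiles: np.ndarray, path: str | Path) -> None:
    """One row per trial, 60 power columns ``power_000`` ... ``power_177``."""
    centers = stimpower.bin_centers()
    frame = pd.DataFrame(
        np.asarray(profiles, dtype=float),
        columns=[f"power_{int(c):03d}" for c in centers],
    )
    frame.to_csv(path, index=False)


def load_profiles(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path)
    cols = [c for c in frame.columns if c.startswith("power_")]
    if len(cols) != stimpower.N_BINS:
        raise SchemaError(
            f"expected {stimpower.N_BINS} power columns, found {len(cols)} in {path}"
        )
    return frame[cols].to_numpy(dtype=float)


def save_image_stack(
    stacks: dict[int, np.ndarray], path: str | Path, pixels_per_degree: float,
    seed: int | None = None,
) -> None:
    """Write per-session image stacks to HDF5 (NPY fallback for .npy paths)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.concatenate([stacks[k] for k in sorted(stacks)]))
        return
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["pixels_per_degree"] = pixels_per_degree
        if seed is not None:
            fh.attrs["seed"] = seed
        for session, arr in stacks.items():
            fh.create_dataset(f"session_{session:03d}", data=arr)


def load_image_stack(path: str | Path) -> dict[int, np.ndarray]:
    path = Path(path)
    if path.suffix == ".npy":
        return {0: np.load(path)}
    import h5py

    out: dict[int, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            out[int(name.split("_")[-1])] = fh[name][...]
    return out


# ---------------------------------------------------------------------------
# External dataset adapter
# ---------------------------------------------------------------------------

#: Canonical column -> accepted aliases in external deposits.
_ALIASES = {
    "participant": ["participant", "subject", "subj", "id", "participant_id"],
    "session": ["session", "block", "run"],
    "trial": ["trial", "trial_index", "t"],
    "stim_class": ["stim_class", "stimulus", "stim_type", "condition"],
    "contrast": ["contrast", "signal_contrast", "stim_contrast"],
    "orientation_deg": ["orientation_deg", "orientation", "angle"],
    "response": ["response", "alarm", "resp", "y"],
}


def load_external_dataset(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Map an externally deposited trial table onto the package schema.

    ``column_map`` overrides the built-in alias table (canonical name ->
    column name in the file). Unmapped extra columns are preserved untouched.
    The on-disk file is never modified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"external dataset not found at {path}")
    raw = pd.read_csv(path)
    rename: dict[str, str] = {}
    missing: list[str] = []
    for canonical, aliases in _ALIASES.items():
        source = None
        if column_map and canonical in column_map:
            source = column_map[canonical]
            if source not in raw.columns:
                missing.append(canonical)
                continue
        else:
            source = next((a for a in aliases if a in raw.columns), None)
        if source is None:
            missing.append(canonical)
        elif source != canonical:
            rename[source] = canonical
    required = {"participant", "session", "trial", "contrast", "response"}
    missing_required = sorted(set(missing) & required)
    if missing_required:
        raise SchemaError(
            f"could not map required columns {missing_required}; "
            f"found columns {sorted(raw.columns)}"
        )
    table = raw.rename(columns=rename)
    table = table.sort_values(["participant", "session", "trial"]).reset_index(drop=True)
    if "prev_response" not in table.columns:
        table = glmhmm.rebuild_prev_response(table)
    return table


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def simulate_experiment(
    config: RunConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate all participants and compute per-trial noise profiles.

    Noise images are rendered per trial, enveloped, and reduced to
    orientation-power profiles that drive the simulated observer's template
    coupling. Returns the concatenated trial table and the aligned
    (n_trials, 60) profile array.
    """
    design = config.design
    if config.calibrate:
        cal = synth.calibrate_contrast(
            config.observer, design, target_dprime=1.5,
            seed=stage_seed(config.seed, "simulate", 10_000),
        )
        design = dataclasses.replace(design, low_contrast=cal)
        logger.info("calibrated low contrast: %.3f", cal)
    tables, profile_blocks = [], []
    for p in range(config.n_participants):
        seed_p = stage_seed(config.seed, "simulate", p)
        seq = synth.generate_trial_sequence(design, seed=seed_p)
        profiles = stimpower.simulate_noise_profiles(
            design, len(seq), stage_seed(config.seed, "profiles", p)
        )
        table = synth.simulate_observer(
            seq, config.observer, seed=seed_p + 1, profiles=profiles,
            bin_centers=stimpower.bin_centers(), participant=p,
        )
        tables.append(table)
        profile_blocks.append(profiles)
    trials = pd.concat(tables, ignore_index=True)
    return trials, np.concatenate(profile_blocks)


def compute_report(trials: pd.DataFrame, mode_column: str = "mode") -> pd.DataFrame:
    """Tidy table of all applicable regression/test statistics.

    Statistics whose preconditions the data cannot meet (e.g. too few trials
    decoded into one mode on a very small run) are skipped with a log message
    rather than failing the whole report.
    """
    results = []
    results += [r.as_dict() for r in stats.alarm_rate_model(trials)]
    if mode_column in trials.columns:
        named = (
            trials.rename(columns={mode_column: "mode"})
            if mode_column != "mode"
            else trials
        )
        try:
            sd = stats.mode_conditional_serial_dependence(named)
            results += [r.as_dict() for r in sd.values()]
        except InsufficientDataError as exc:
            logger.warning("skipping serial-dependence contrast: %s", exc)
        try:
            results.append(stats.fa_rate_by_mode(named).as_dict())
        except InsufficientDataError as exc:
            logger.warning("skipping FA-rate contrast: %s", exc)
    return pd.DataFrame(results)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a reproducibility manifest.

    Stages that are toggled off re-use the previous outputs found in
    ``config.out_dir``; a missing input makes the run fail with a path
    diagnostic before any computation. Returns the manifest dictionary
    (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "completed": [],
        "files": {},
    }
    trials_path = out / "trials.csv"
    profiles_path = out / "profiles.csv"

    def _require(path: Path, stage: str) -> None:
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {path}, which was not produced by a "
                "previous run; enable the producing stage or provide the file"
            )

    try:
        if "simulate" in config.stages:
            trials, profiles = simulate_experiment(config)
            save_trials(trials, trials_path)
            if "profiles" in config.stages:
                save_profiles(profiles, profiles_path)
            manifest["completed"].append("simulate")
            if "profiles" in config.stages:
                manifest["completed"].append("profiles")
        else:
            _require(trials_path, "fit_hmm")
            _require(profiles_path, "classify")
            trials = load_trials(trials_path)
            profiles = load_profiles(profiles_path)

        if "fit_hmm" in config.stages:
            fits = glmhmm.fit_per_participant(trials, config.hmm)
            labels = np.empty(len(trials), dtype=object)
            p_external = np.empty(len(trials))
            fit_records = {}
            for pid, (hmm_fit, one_state) in fits.items():
                sel = (trials["participant"] == pid).to_numpy()
                ml = glmhmm.label_modes(hmm_fit, trial_duration=config.design.trial_duration)
                labels[sel] = ml.labels
                p_external[sel] = ml.p_external
                fit_records[str(pid)] = {
                    "weights": hmm_fit.weights.tolist(),
                    "A": hmm_fit.A.tolist(),
                    "loglik": hmm_fit.loglik,
                    "bic": hmm_fit.bic,
                    "delta_bic": glmhmm.delta_bic(hmm_fit, one_state),
                    "converged": hmm_fit.converged,
                    "occupancy_internal": ml.occupancy_internal,
                    "mean_run_length_trials": ml.mean_run_length_trials,
                }
            trials = trials.assign(mode=labels)
            save_trials(trials, trials_path)
            trials[["participant", "session", "trial"]].assign(
                p_external=p_external, mode=labels
            ).to_csv(out / "mode_posteriors.csv", index=False)
            (out / "fits.json").write_text(json.dumps(fit_records, indent=2))
            manifest["completed"].append("fit_hmm")

        if "classify" in config.stages:
            if "mode" not in trials.columns:
                _require(out / "fits.json", "classify")
            angles = stats.classification_vector_angles(trials, profiles)
            angles.to_csv(out / "classification_vectors.csv", index=False)
            manifest["completed"].append("classify")

        if "report" in config.stages:
            compute_report(trials).to_csv(out / "report.csv", index=False)
            manifest["completed"].append("report")
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
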