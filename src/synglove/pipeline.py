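"""End-to-end experiment pipeline: simulate -> prior -> design -> reconstruct -> recognize.

Mirrors the glove study's flow on synthetic data: generate an a-priori
grasp ensemble and a labeled multi-subject panel; estimate the synergy
prior; choose the m joints to sense; push every panel pose through simulated
goniometers (two-point calibration, noisy windows, window averaging) and
minimum-variance reconstruction; run leave-one-subject-out K-means
recognition on the reconstructions.

Every output file carries a provenance comment with the config hash and
seed, and a JSON manifest lists all artifacts.  The same config and seed
reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io
from .design import select_exhaustive, select_greedy
from .goniometer import CALIBRATION_ANGLES, GoniometerModel, calibrate, response
from .hand_model import build_selection_matrix, extract_measurements
from .prior import estimate_prior
from .recognition import KMeansConfig, accuracy_report, loocv_recognition
from .reconstruction import reconstruct_from_sensors
from .synthetic import (
    DEFAULT_PRIOR_SET_SIZE,
    DEFAULT_SUBJECT_JITTER_SD,
    GraspPanel,
    default_generator,
    make_grasp_generators,
    sample_grasp_panel,
    sample_prior_set,
)

#: Known config keys and their defaults; unknown keys are rejected.
CONFIG_SCHEMA = {
    "seed": 0,
    "out_dir": "synglove_out",
    "simulate": {
        "n_prior": DEFAULT_PRIOR_SET_SIZE,
        "n_subjects": 5,
        "n_labels": 8,
        "n_reps": 3,
        "separation": 10.0,
        "subject_jitter_sd": DEFAULT_SUBJECT_JITTER_SD,
    },
    "design": {"m": 5, "method": "exhaustive"},
    "goniometer": {
        "noise_sd": 0.8,
        "calibration_angles": list(CALIBRATION_ANGLES),
        "window_samples": 1000,
    },
    "recognition": {"max_iter": 100, "update_centroids": True},
}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration entry."""


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    def merge(schema, user, path=""):
        if not isinstance(user, dict):
            raise ConfigError(f"config section {path or '<root>'} must be a mapping")
        unknown = set(user) - set(schema)
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)} in {path or '<root>'}")
        merged = {}
        for key, default in schema.items():
            if isinstance(default, dict):
                merged[key] = merge(default, user.get(key, {}), f"{path}{key}.")
            else:
                merged[key] = user.get(key, default)
        return merged

    return merge(CONFIG_SCHEMA, config or {})


def config_hash(config: dict) -> str:
    text = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _simulated_sensor_suite(rng: np.random.Generator, m: int, noise_sd: float):
    """Random sensor models (plausible sensitivities/offsets) + exact two-point calibrations."""
    models, cals = [], []
    for _ in range(m):
        model = GoniometerModel(
            sensitivity=rng.uniform(1.5, 3.0) * rng.choice([-1.0, 1.0]),
            offset=rng.uniform(-20.0, 20.0),
            noise_sd=noise_sd,
        )
        t1, t2 = CALIBRATION_ANGLES
        cals.append(calibrate(t1, float(response(model, t1)), t2, float(response(model, t2))))
        models.append(model)
    return models, cals


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json).

    Any stage failure propagates with the stage name prefixed.
    """
    cfg = validate_config(config)
    tag = f"synglove config_hash={config_hash(cfg)} seed={cfg['seed']}"
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config": cfg, "config_hash": config_hash(cfg), "artifacts": {}}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    def simulate():
        gen = default_generator(seed)
        X = sample_prior_set(gen, int(cfg["simulate"]["n_prior"]), seed=seed + 1)
        io.write_pose_csv(X, out / "prior_set.csv", header_comment=tag)
        gens = make_grasp_generators(
            seed=seed + 2,
            n_labels=int(cfg["simulate"]["n_labels"]),
            separation=float(cfg["simulate"]["separation"]),
            subject_jitter_sd=float(cfg["simulate"]["subject_jitter_sd"]),
        )
        panel = sample_grasp_panel(
            gens,
            n_subjects=int(cfg["simulate"]["n_subjects"]),
            n_reps=int(cfg["simulate"]["n_reps"]),
            subject_jitter_sd=float(cfg["simulate"]["subject_jitter_sd"]),
            seed=seed + 3,
        )
        io.write_panel_csv(panel, out / "panel.csv", header_comment=tag)
        manifest["artifacts"]["prior_set"] = str(out / "prior_set.csv")
        manifest["artifacts"]["panel"] = str(out / "panel.csv")
        return X, panel

    X, panel = stage("simulate", simulate)

    def prior_stage():
        prior = estimate_prior(X)
        io.write_prior_json(prior, out / "prior.json")
        manifest["artifacts"]["prior"] = str(out / "prior.json")
        return prior

    prior = stage("prior", prior_stage)

    def design_stage():
        m = int(cfg["design"]["m"])
        method = cfg["design"]["method"]
        if method == "exhaustive":
            res = select_exhaustive(prior, m)
        elif method == "greedy":
            res = select_greedy(prior, m)
        else:
            raise ConfigError(f"unknown design method {method!r}")
        io.write_json(
            {"joints": list(res.joints), "cost": res.cost, "method": res.method,
             "evaluated": res.evaluated, "provenance": tag},
            out / "design.json",
        )
        manifest["artifacts"]["design"] = str(out / "design.json")
        return res

    design = stage("design", design_stage)

    def reconstruct_stage():
        sel = build_selection_matrix(design.joints)
        rng = np.random.default_rng(seed + 4)
        models, cals = _simulated_sensor_suite(
            rng, sel.m, float(cfg["goniometer"]["noise_sd"])
        )
        n_win = int(cfg["goniometer"]["window_samples"])
        recon = np.empty_like(panel.poses)
        for i, pose in enumerate(panel.poses):
            true_angles = extract_measurements(pose, sel)
            windows = [
                response(models[j], true_angles[j] + rng.normal(0, models[j].noise_sd, n_win))
                for j in range(sel.m)
            ]
            est = reconstruct_from_sensors(prior, cals, windows, sel)
            recon[i] = est.x_hat
        recon_panel = GraspPanel(
            poses=recon,
            subject_id=panel.subject_id,
            grasp_label=panel.grasp_label,
            repetition=panel.repetition,
        )
        io.write_panel_csv(recon_panel, out / "reconstructed_panel.csv", header_comment=tag)
        manifest["artifacts"]["reconstructed_panel"] = str(out / "reconstructed_panel.csv")
        return recon_panel

    recon_panel = stage("reconstruct", reconstruct_stage)

    def recognize_stage():
        kcfg = KMeansConfig(
            n_clusters=int(cfg["simulate"]["n_labels"]),
            max_iter=int(cfg["recognition"]["max_iter"]),
            update_centroids=bool(cfg["recognition"]["update_centroids"]),
        )
        results = loocv_recognition(recon_panel, kcfg)
        summary = {}
        for subject, cm in results:
            path = out / f"confusion_subject_{subject}.csv"
            io.write_confusion_csv(cm, path, header_comment=tag)
            manifest["artifacts"][f"confusion_subject_{subject}"] = str(path)
            relative, absolute = accuracy_report(cm)
            summary[str(subject)] = {
                "relative_accuracy_pct": list(relative),
                "absolute_accuracy_pct": absolute,
            }
        summary["mean_absolute_accuracy_pct"] = float(
            np.mean([v["absolute_accuracy_pct"] for v in summary.values()])
        )
        io.write_json(summary, out / "accuracy.json")
        manifest["artifacts"]["accuracy"] = str(out / "accuracy.json")
        return summary

    stage("recognize", recognize_stage)

    io.write_json(manifest, out / "manifest.json")
    return manifest
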