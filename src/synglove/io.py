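"""File formats: pose CSV, panel CSV, prior JSON, confusion CSV, joint lists.

Pose files are plain CSV with a header row of the 19 joint codes in
canonical order, one pose per row, angles in degrees, full-precision floats
(repr round-trip).  Panel files add subject_id, grasp_label and repetition
columns.  Lines starting with '#' are treated as comments (pipeline outputs
carry a provenance comment line).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hand_model import JOINT_ORDER
from .prior import SynergyPrior
from .recognition import ConfusionMatrix
from .synthetic import GraspPanel

PANEL_META_COLUMNS = ("subject_id", "grasp_label", "repetition")


def parse_joint_list(text: str) -> tuple[str, ...]:
    """Parse a comma-separated joint-code list like 'TA,MM,RP,LA,LM'."""
    return tuple(tok.strip() for tok in text.split(",") if tok.strip())


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # default str() formatting is the shortest repr that round-trips float64
        df.to_csv(fh, index=False)


def write_pose_csv(poses, path, header_comment: str | None = None) -> None:
    """Write poses (n x 19 or a 19 x n matrix-like of columns) to CSV.

    Accepts either orientation; rows of the file are always poses.
    """
    arr = np.asarray(poses, dtype=float)
    if arr.ndim != 2:
        raise ValueError("poses must be 2-D")
    if arr.shape[1] != len(JOINT_ORDER):
        if arr.shape[0] == len(JOINT_ORDER):
            arr = arr.T
        else:
            raise ValueError(f"poses must have {len(JOINT_ORDER)} columns, got {arr.shape}")
    _write_csv(pd.DataFrame(arr, columns=list(JOINT_ORDER)), path, header_comment)


def read_pose_csv(path) -> np.ndarray:
    """Read a pose CSV into an n x 19 array (canonical column order)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in JOINT_ORDER if c not in df.columns]
    if missing:
        raise ValueError(f"pose CSV missing joint columns: {missing}")
    return df[list(JOINT_ORDER)].to_numpy(dtype=float)


def write_panel_csv(panel: GraspPanel, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(panel.poses, columns=list(JOINT_ORDER))
    df.insert(0, "subject_id", panel.subject_id)
    df.insert(1, "grasp_label", panel.grasp_label)
    df.insert(2, "repetition", panel.repetition)
    _write_csv(df, path, header_comment)


def read_panel_csv(path) -> GraspPanel:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in (*PANEL_META_COLUMNS, *JOINT_ORDER) if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns: {missing}")
    return GraspPanel(
        poses=df[list(JOINT_ORDER)].to_numpy(dtype=float),
        subject_id=df["subject_id"].to_numpy(dtype=int),
        grasp_label=df["grasp_label"].to_numpy(dtype=int),
        repetition=df["repetition"].to_numpy(dtype=int),
    )


def write_prior_json(prior: SynergyPrior, path) -> None:
    Path(path).write_text(prior.to_json(), encoding="utf-8")


def read_prior_json(path) -> SynergyPrior:
    return SynergyPrior.from_json(Path(path).read_text(encoding="utf-8"))


def write_confusion_csv(cm: ConfusionMatrix, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        cm.counts,
        index=[f"true_{g}" for g in cm.labels],
        columns=[f"recognized_{g}" for g in cm.labels],
    )
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=True, index_label="grasp")


def read_confusion_csv(path) -> ConfusionMatrix:
    df = pd.read_csv(path, comment="#", index_col=0)
    counts = df.to_numpy(dtype=int)
    labels = tuple(int(c.split("_")[-1]) for c in df.columns)
    return ConfusionMatrix(counts=counts, labels=labels)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
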