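"""Plain-text readers/writers for the pipeline's tabular interfaces.

Behavior sequences travel as long-format CSV (subject, session,
bin_index, state_label); pose tracks as (frame, keypoint, x_cm, y_cm)
tables with arena/cup geometry in a YAML config; calcium traces as a
cells-x-frames CSV matrix with a YAML sidecar for the frame rate; ephys
sweeps as per-sweep (time_s, Vm_mV) CSVs with a protocol manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .markov import BehaviorSequence
from .pose import Arena, Cup, InteractionVector, PoseTrack

__all__ = [
    "read_behavior_sequences",
    "write_behavior_sequences",
    "read_category_map",
    "read_pose_track",
    "write_pose_track",
    "read_trace_matrix",
    "write_trace_matrix",
    "write_interaction_vector",
    "read_interaction_vector",
    "write_trials",
]


def read_behavior_sequences(
    path: str | Path,
    category_map: dict[str, str] | None = None,
    alphabet: list[str] | None = None,
) -> list[BehaviorSequence]:
    """Load per-(subject, session) label sequences from long-format CSV."""
    df = pd.read_csv(path)
    required = {"subject", "session", "bin_index", "state_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavior CSV missing columns: {sorted(missing)}")
    out = []
    for (subject, session), grp in df.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values("bin_index")
        out.append(
            BehaviorSequence(
                labels=grp["state_label"].tolist(),
                alphabet=alphabet or [],
                category_map=category_map,
                subject=str(subject),
                session=str(session),
            )
        )
    return out


def write_behavior_sequences(seqs: Iterable[BehaviorSequence], path: str | Path) -> None:
    rows = []
    for seq in seqs:
        for i, lab in enumerate(seq.labels):
            rows.append(
                {
                    "subject": seq.subject,
                    "session": seq.session,
                    "bin_index": i,
                    "state_label": lab,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_category_map(path: str | Path) -> dict[str, str]:
    """YAML mapping of behavior label -> social/nonsocial."""
    with open(path) as fh:
        cmap = yaml.safe_load(fh)
    if not isinstance(cmap, dict):
        raise ValueError("category map must be a mapping")
    return {str(k): str(v) for k, v in cmap.items()}


def _geometry_from_config(config: dict) -> tuple[Arena, list[Cup]]:
    arena = Arena(**config["arena"])
    cups = [
        Cup(center=tuple(c["center"]), diameter=c["diameter"], stimulus=c["stimulus"])
        for c in config.get("cups", [])
    ]
    return arena, cups


def read_pose_track(path: str | Path, config_path: str | Path) -> PoseTrack:
    """Pose table (frame, keypoint, x_cm, y_cm) plus a YAML geometry config."""
    df = pd.read_csv(path)
    required = {"frame", "keypoint", "x_cm", "y_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pose CSV missing columns: {sorted(missing)}")
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    arena, cups = _geometry_from_config(config)
    frame_rate = float(config["frame_rate"])
    n = int(df["frame"].max()) + 1
    keypoints: dict[str, np.ndarray] = {}
    for name, grp in df.groupby("keypoint"):
        arr = np.full((n, 2), np.nan)
        idx = grp["frame"].to_numpy(dtype=int)
        arr[idx, 0] = grp["x_cm"].to_numpy()
        arr[idx, 1] = grp["y_cm"].to_numpy()
        keypoints[str(name)] = arr
    return PoseTrack(keypoints=keypoints, frame_rate=frame_rate, arena=arena, cups=cups)


def write_pose_track(track: PoseTrack, path: str | Path, config_path: str | Path | None = None) -> None:
    frames = np.arange(track.n_frames)
    parts = []
    for name, arr in track.keypoints.items():
        parts.append(
            pd.DataFrame(
                {"frame": frames, "keypoint": name, "x_cm": arr[:, 0], "y_cm": arr[:, 1]}
            )
        )
    pd.concat(parts).to_csv(path, index=False)
    if config_path is not None:
        config = {
            "frame_rate": track.frame_rate,
            "arena": {"width": track.arena.width, "height": track.arena.height}
            if track.arena
            else None,
            "cups": [
                {"center": list(c.center), "diameter": c.diameter, "stimulus": c.stimulus}
                for c in track.cups
            ],
        }
        with open(config_path, "w") as fh:
            yaml.safe_dump(config, fh)


def read_trace_matrix(path: str | Path, sidecar_path: str | Path) -> tuple[np.ndarray, float]:
    """Cells-x-frames trace matrix CSV plus YAML sidecar with frame_rate."""
    traces = pd.read_csv(path, header=None).to_numpy(dtype=float)
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    return traces, float(meta["frame_rate"])


def write_trace_matrix(
    traces: np.ndarray, frame_rate: float, path: str | Path, sidecar_path: str | Path
) -> None:
    pd.DataFrame(np.asarray(traces)).to_csv(path, index=False, header=False)
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump({"frame_rate": float(frame_rate)}, fh)


def write_interaction_vector(vec: InteractionVector, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_index": np.arange(len(vec)),
            "stimulus": vec.stimulus,
            "value": vec.values,
        }
    ).to_csv(path, index=False)


def read_interaction_vector(path: str | Path, bin_width: float = 0.040) -> InteractionVector:
    df = pd.read_csv(path).sort_values("bin_index")
    stim = str(df["stimulus"].iloc[0]) if "stimulus" in df else "social"
    return InteractionVector(stimulus=stim, values=df["value"].to_numpy(), bin_width=bin_width)


def write_trials(trials, path: str | Path) -> None:
    pd.DataFrame(
        [{"stimulus": t.stimulus, "onset_s": t.onset, "offset_s": t.offset} for t in trials]
    ).to_csv(path, index=False)
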