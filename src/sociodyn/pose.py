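"""Pose-geometry detection of social/object cup interactions.

Top-down pose tracking yields per-frame keypoint coordinates for a
15-point mouse skeleton.  A frame counts as an interaction with a cup
(housing either a novel juvenile mouse or a novel object) when the nose
lies within 1.3x the cup diameter of the cup and the cup falls inside a
90-degree cone in front of the animal's head.  Framewise detections are
binarized into 40-ms bins and segmented into discrete trials by three
temporal rules: bouts separated by pauses shorter than 1.5 s merge, a
trial must last at least 1 s, and a trial must begin at least 5 s after
the end of the previous accepted interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

__all__ = [
    "Arena",
    "Cup",
    "PoseTrack",
    "InteractionVector",
    "Trial",
    "head_direction",
    "detect_interaction",
    "binarize_bins",
    "extract_trials",
]

#: keypoints the detection rule needs
REQUIRED_KEYPOINTS = ("nose", "head", "neck")

#: full skeleton, for generators and file IO
SKELETON = (
    "nose", "head", "left_ear", "right_ear", "neck",
    "left_forelimb", "right_forelimb", "trunk",
    "left_hindlimb", "right_hindlimb", "tail_base",
    "tail_1", "tail_2", "tail_3", "tail_tip",
)


@dataclass(frozen=True)
class Arena:
    """Rectangular arena, cm, origin at the lower-left corner, y up."""

    width: float
    height: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= 0)
            & (xy[..., 0] <= self.width)
            & (xy[..., 1] >= 0)
            & (xy[..., 1] <= self.height)
        )


@dataclass(frozen=True)
class Cup:
    """An upturned wire-mesh cup holding a stimulus."""

    center: tuple[float, float]
    diameter: float
    stimulus: str  # "social" or "object"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("cup diameter must be positive")
        if self.stimulus not in ("social", "object"):
            raise ValueError(f"unknown stimulus {self.stimulus!r}")


@dataclass
class PoseTrack:
    """Per-frame keypoint coordinates (cm) at a fixed frame rate.

    ``keypoints`` maps keypoint name -> (n_frames, 2) float array; missing
    detections are NaN.
    """

    keypoints: dict[str, np.ndarray]
    frame_rate: float
    arena: Arena | None = None
    cups: list[Cup] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        lengths = {k: len(v) for k, v in self.keypoints.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"keypoint arrays have unequal lengths: {lengths}")
        for k, v in self.keypoints.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"keypoint {k!r} must be (n_frames, 2)")
            self.keypoints[k] = arr

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.keypoints.values())))

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class InteractionVector:
    """Binary interaction time series at a fixed bin width (default 40 ms)."""

    stimulus: str
    values: np.ndarray
    bin_width: float = 0.040
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("interaction values must be binary")
        self.values = vals.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) * self.bin_width


@dataclass(frozen=True)
class Trial:
    """One accepted interaction bout."""

    stimulus: str
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def head_direction(track: PoseTrack) -> np.ndarray:
    """Per-frame unit heading vector.

    The heading is the unit vector from neck to head; frames where the
    neck is missing fall back to head-to-nose.  Frames where neither pair
    is usable (missing or coincident points) are NaN and are treated as
    non-interacting downstream.
    """
    n = track.n_frames
    head = track.keypoints.get("head", np.full((n, 2), np.nan))
    neck = track.keypoints.get("neck", np.full((n, 2), np.nan))
    nose = track.keypoints.get("nose", np.full((n, 2), np.nan))

    vec = head - neck
    fallback = nose - head
    use_fb = ~np.isfinite(vec).all(axis=1) | (np.linalg.norm(vec, axis=1) == 0)
    vec = np.where(use_fb[:, None], fallback, vec)

    norm = np.linalg.norm(vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = vec / norm[:, None]
    unit[~np.isfinite(norm) | (norm == 0)] = np.nan
    return unit


def detect_interaction(
    track: PoseTrack,
    cup: Cup,
    distance_factor: float = 1.3,
    cone_half_angle_deg: float = 45.0,
    distance_reference: str = "center",
) -> np.ndarray:
    """Framewise interaction detection for one cup.

    A frame is positive iff the nose is within ``distance_factor`` times
    the cup diameter of the cup (measured to the cup center by default,
    ``distance_reference="edge"`` subtracts the cup radius) and the angle
    between the head direction and the head-to-cup vector is at most the
    cone half-angle (45 degrees, i.e. a 90-degree full cone).  Frames with
    a missing nose or undefined heading are negative.
    """
    if distance_reference not in ("center", "edge"):
        raise ValueError("distance_reference must be 'center' or 'edge'")
    n = track.n_frames
    nose = track.keypoints.get("nose", np.full((n, 2), np.nan))
    head = track.keypoints.get("head", np.full((n, 2), np.nan))
    center = np.asarray(cup.center, dtype=float)

    dist = np.linalg.norm(nose - center, axis=1)
    if distance_reference == "edge":
        dist = dist - cup.diameter / 2.0
    near = dist <= distance_factor * cup.diameter

    heading = head_direction(track)
    to_cup = center[None, :] - head
    to_cup_norm = np.linalg.norm(to_cup, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", heading, to_cup) / to_cup_norm
    cos_thresh = np.cos(np.deg2rad(cone_half_angle_deg))
    # head exactly at the cup center: direction undefined, treat as facing
    at_center = to_cup_norm == 0
    facing = (cosang >= cos_thresh) | at_center

    out = near & facing
    out[~np.isfinite(dist)] = False
    out[np.isnan(heading).any(axis=1) & ~at_center] = False
    return out


def binarize_bins(
    framewise: np.ndarray,
    frame_rate: float,
    bin_width: float = 0.040,
    stimulus: str = "social",
    rule: str = "any",
) -> InteractionVector:
    """Aggregate framewise detections into fixed-width time bins.

    Frame i occupies the interval [i, i+1)/frame_rate, which may overlap
    one or more bins.  ``rule="any"`` (default) marks a bin positive when
    any part of it overlaps a positive frame; ``rule="majority"``
    requires positive frames to cover more than half of the bin.
    """
    if frame_rate <= 0 or bin_width <= 0:
        raise ValueError("frame_rate and bin_width must be positive")
    if rule not in ("any", "majority"):
        raise ValueError("rule must be 'any' or 'majority'")
    framewise = np.asarray(framewise).astype(bool)
    n_frames = len(framewise)
    duration = n_frames / frame_rate
    n_bins = max(int(ceil(duration / bin_width - 1e-9)), 1)
    # cumulative positive-frame time evaluated at the bin edges: exact
    # overlap bookkeeping without a per-frame loop
    frame_dur = 1.0 / frame_rate
    edges = np.arange(n_bins + 1) * bin_width
    j = np.minimum((edges * frame_rate + 1e-9).astype(int), n_frames)
    cum_pos = np.concatenate(([0.0], np.cumsum(framewise) * frame_dur))
    frac = np.clip(edges - j * frame_dur, 0.0, frame_dur)
    partial = np.where(j < n_frames, framewise[np.minimum(j, n_frames - 1)] * frac, 0.0)
    pos_time = np.diff(cum_pos[j] + partial)
    tot_time = np.diff(np.clip(edges, 0.0, duration))
    if rule == "any":
        values = (pos_time > 1e-12).astype(np.uint8)
    else:
        values = (pos_time > tot_time / 2.0 + 1e-12).astype(np.uint8)
    return InteractionVector(stimulus=stimulus, values=values, bin_width=bin_width)


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) bin index pairs of maximal runs of 1s; stop exclusive."""
    v = np.asarray(values).astype(np.int8)
    d = np.diff(np.concatenate(([0], v, [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def extract_trials(
    vector: InteractionVector,
    min_duration: float = 1.0,
    refractory: float = 5.0,
    merge_gap: float = 1.5,
) -> list[Trial]:
    """Segment an interaction vector into discrete trials.

    Rule order: (c) bouts separated by a pause strictly shorter than
    ``merge_gap`` are merged into one candidate; (a) candidates shorter
    than ``min_duration`` are discarded; (b) a candidate starting less
    than ``refractory`` seconds after the end of the previous *accepted*
    trial is discarded.
    """
    bw = vector.bin_width
    eps = 1e-9
    intervals = [(s * bw, e * bw) for s, e in _runs(vector.values)]

    merged: list[list[float]] = []
    for on, off in intervals:
        if merged and on - merged[-1][1] < merge_gap - eps:
            merged[-1][1] = off
        else:
            merged.append([on, off])

    trials: list[Trial] = []
    last_end: float | None = None
    for on, off in merged:
        if off - on < min_duration - eps:
            continue
        if last_end is not None and on - last_end < refractory - eps:
            continue
        t = Trial(stimulus=vector.stimulus, onset=vector.origin + on, offset=vector.origin + off)
        trials.append(t)
        last_end = on + (off - on)  # end of this accepted interaction
    return trials
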