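"""Single-neuron response classification from calcium imaging.

Each neuron's calcium trace is z-scored over the whole session and
compared with a binary behavior vector (social or object cup
interaction, 40-ms bins) via a threshold-sweep ROC analysis: 100
thresholds spanning the trace's z-range binarize activity, yielding a
(FPR, TPR) point per threshold, and the trapezoidal area under the
resulting curve (auROC) measures how strongly the neuron is modulated
by the behavior.  Significance comes from a circular-shift permutation
null: the behavior vector is rotated by 1000 random offsets (which
preserves its autocorrelation while destroying alignment with the
trace) and a neuron is called excited/inhibited when its auROC falls
above the 97.5th / below the 2.5th percentile of the shuffled values.

:class:`ResponseModel` packages the pipeline statsmodels-style:
construct from a trace and a behavior vector, ``fit()`` returns a
:class:`ResponseResults` with the auROC, the null distribution, the
classification and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .pose import InteractionVector, Trial

__all__ = [
    "ZTrace",
    "RocCurve",
    "zscore",
    "resample_to_bins",
    "roc_auroc",
    "circular_shift_null",
    "classify_response",
    "ResponseModel",
    "ResponseResults",
    "event_triggered_average",
    "cluster_response_profiles",
    "population_summary",
]

N_THRESHOLDS = 100


@dataclass
class ZTrace:
    """Whole-session z-scored activity of one cell."""

    values: np.ndarray
    frame_rate: float
    cell: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("z-trace contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


def zscore(trace: np.ndarray, frame_rate: float, cell: str = "") -> ZTrace:
    """Z-score a raw trace using the whole-session mean and SD."""
    x = np.asarray(trace, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant trace: z-score undefined")
    return ZTrace(values=(x - x.mean()) / sd, frame_rate=frame_rate, cell=cell)


def resample_to_bins(
    z: ZTrace,
    n_bins: int,
    bin_width: float = 0.040,
    method: str = "nearest",
) -> np.ndarray:
    """Resample a frame-based trace onto the behavior time base.

    Calcium frames (e.g. 50 ms at 20 fps) and behavior bins (40 ms) do
    not align; each bin takes the frame nearest its center (default) or a
    linear interpolation between the neighboring frames.
    """
    if method not in ("nearest", "linear"):
        raise ValueError("method must be 'nearest' or 'linear'")
    centers = (np.arange(n_bins) + 0.5) * bin_width
    frame_pos = centers * z.frame_rate - 0.5  # frame i sampled at (i+0.5)/fps
    if method == "nearest":
        idx = np.clip(np.round(frame_pos).astype(int), 0, len(z.values) - 1)
        return z.values[idx]
    return np.interp(frame_pos, np.arange(len(z.values)), z.values)


@dataclass
class RocCurve:
    """Threshold-sweep ROC curve of one cell against one behavior."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def _threshold_grid(z: np.ndarray, n: int = N_THRESHOLDS) -> np.ndarray:
    return np.linspace(z.min(), z.max(), n)


def _check_behavior(behavior: np.ndarray) -> np.ndarray:
    b = np.asarray(behavior).astype(bool)
    if b.all() or not b.any():
        raise ValueError("behavior vector must contain positive and negative bins")
    return b


def _auroc_from_rates(fpr: np.ndarray, tpr: np.ndarray) -> float:
    # append the (0,0) and (1,1) anchors, sort by FPR, trapezoid
    x = np.concatenate(([0.0], fpr, [1.0]))
    y = np.concatenate(([0.0], tpr, [1.0]))
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def roc_auroc(z_bins: np.ndarray, behavior: np.ndarray) -> RocCurve:
    """ROC curve from a 100-step threshold sweep over the z-range.

    For each threshold t (100 linear steps from min(z) to max(z)), the
    activity vector is ``z >= t``; TPR is the active fraction of
    behavior-positive bins and FPR the active fraction of negatives.  The
    auROC is the trapezoidal area after sorting by FPR with (0,0) and
    (1,1) appended.
    """
    z_bins = np.asarray(z_bins, dtype=float)
    b = _check_behavior(behavior)
    if len(z_bins) != len(b):
        raise ValueError("activity and behavior vectors differ in length")
    thr = _threshold_grid(z_bins)
    active = z_bins[None, :] >= thr[:, None]
    tpr = active[:, b].mean(axis=1)
    fpr = active[:, ~b].mean(axis=1)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auroc=_auroc_from_rates(fpr, tpr))


def _auroc_counts(
    pos_counts: np.ndarray, total_counts: np.ndarray, n_pos: int, n_neg: int
) -> np.ndarray:
    """auROC(s) from per-threshold-index histograms of the z values.

    ``pos_counts[..., k]`` counts behavior-positive bins whose z falls in
    threshold slot k (i.e. passes thresholds 0..k); vectorized over
    leading axes.  Equivalent to the explicit sweep in :func:`roc_auroc`.
    """
    neg_counts = total_counts - pos_counts
    # survival counts: number of bins active at threshold k
    tp = np.flip(np.cumsum(np.flip(pos_counts, -1), -1), -1) / n_pos
    fp = np.flip(np.cumsum(np.flip(neg_counts, -1), -1), -1) / n_neg
    # points ordered by descending threshold = ascending FPR
    tp = np.flip(tp, -1)
    fp = np.flip(fp, -1)
    shape = tp.shape[:-1]
    ones = np.ones(shape + (1,))
    zeros = np.zeros(shape + (1,))
    x = np.concatenate([zeros, fp, ones], axis=-1)
    y = np.concatenate([zeros, tp, ones], axis=-1)
    return np.trapezoid(y, x, axis=-1)


def circular_shift_null(
    z_bins: np.ndarray,
    behavior: np.ndarray,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Null auROC distribution from circular shifts of the behavior vector.

    Each of ``n_permutations`` draws rotates the behavior vector by an
    offset sampled uniformly (with replacement) from {1, ..., T-1} — the
    unshifted alignment is excluded by construction — and recomputes the
    threshold-sweep auROC against the unchanged activity vector.
    """
    z_bins = np.asarray(z_bins, dtype=float)
    b = _check_behavior(behavior)
    T = len(b)
    if T < 2:
        raise ValueError("need at least 2 bins to shift")
    if len(z_bins) != T:
        raise ValueError("activity and behavior vectors differ in length")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    thr = _threshold_grid(z_bins)
    # slot k of bin i = highest threshold index that bin i passes
    slot = np.searchsorted(thr, z_bins, side="right") - 1
    slot = np.clip(slot, 0, N_THRESHOLDS - 1)
    total_counts = np.bincount(slot, minlength=N_THRESHOLDS)

    pos = np.flatnonzero(b)
    n_pos, n_neg = len(pos), T - len(pos)
    offsets = rng.integers(1, T, size=n_permutations)
    # behavior shifted by s has positives at (pos + s) mod T
    shifted = (pos[None, :] + offsets[:, None]) % T
    slots = slot[shifted]
    pos_counts = np.zeros((n_permutations, N_THRESHOLDS), dtype=np.int64)
    rows = np.repeat(np.arange(n_permutations), n_pos)
    np.add.at(pos_counts, (rows, slots.ravel()), 1)
    return _auroc_counts(pos_counts, total_counts[None, :], n_pos, n_neg)


def classify_response(auroc: float, null: np.ndarray) -> str:
    """Excited/inhibited/none call from the permutation null.

    Excited iff the observed auROC strictly exceeds the 97.5th percentile
    of the null (linear-interpolation percentile); inhibited iff it falls
    strictly below the 2.5th percentile; otherwise none.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    hi = np.percentile(null, 97.5)
    lo = np.percentile(null, 2.5)
    if auroc > hi:
        return "excited"
    if auroc < lo:
        return "inhibited"
    return "none"


class ResponseModel:
    """Threshold-sweep ROC response model for one cell and one behavior.

    Parameters
    ----------
    trace : array
        Raw calcium trace (one value per frame).  Z-scored internally
        over the whole session.
    behavior : InteractionVector or binary array
        Stimulus interaction vector on 40-ms bins.
    frame_rate : float
        Trace sampling rate, Hz.
    bin_width : float
        Behavior bin width, s (used to resample the trace).
    resample : str
        ``"nearest"`` (default) or ``"linear"`` frame-to-bin mapping.
    """

    def __init__(
        self,
        trace: np.ndarray,
        behavior: InteractionVector | np.ndarray,
        frame_rate: float,
        bin_width: float = 0.040,
        cell: str = "",
        resample: str = "nearest",
    ) -> None:
        if isinstance(behavior, InteractionVector):
            self.stimulus = behavior.stimulus
            self.behavior = behavior.values.astype(bool)
            bin_width = behavior.bin_width
        else:
            self.stimulus = ""
            self.behavior = np.asarray(behavior).astype(bool)
        self.z = zscore(trace, frame_rate, cell=cell)
        self.bin_width = bin_width
        self.cell = cell
        self.z_bins = resample_to_bins(self.z, len(self.behavior), bin_width, method=resample)

    def fit(
        self, n_permutations: int = 1000, seed: int | np.random.Generator | None = None
    ) -> "ResponseResults":
        roc = roc_auroc(self.z_bins, self.behavior)
        null = circular_shift_null(self.z_bins, self.behavior, n_permutations, seed)
        label = classify_response(roc.auroc, null)
        return ResponseResults(self, roc, null, label)


@dataclass
class ResponseResults:
    """auROC, permutation null, and the excited/inhibited/none call."""

    model: ResponseModel
    roc: RocCurve
    null_distribution: np.ndarray
    classification: str

    @property
    def auroc(self) -> float:
        return self.roc.auroc

    @property
    def null_percentiles(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.null_distribution, 2.5)),
            float(np.percentile(self.null_distribution, 97.5)),
        )

    def summary(self) -> str:
        lo, hi = self.null_percentiles
        return "\n".join(
            [
                "Neuron response classification (threshold-sweep ROC)",
                "=" * 52,
                f"cell: {self.model.cell or '<unnamed>'}   stimulus: {self.model.stimulus or '<binary vector>'}",
                f"bins: {len(self.model.behavior)} x {self.model.bin_width * 1000:.0f} ms "
                f"({int(self.model.behavior.sum())} positive)",
                f"auROC = {self.auroc:.4f}",
                f"null ({len(self.null_distribution)} circular shifts): "
                f"[2.5th, 97.5th] = [{lo:.4f}, {hi:.4f}]",
                f"classification: {self.classification}",
            ]
        )

    def plot(self, ax=None):
        """ROC curve with the chance diagonal (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.roc.fpr, self.roc.tpr, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.set_title(f"auROC = {self.auroc:.3f} ({self.classification})")
        return ax


def event_triggered_average(
    z: ZTrace,
    trials: Sequence[Trial],
    window: tuple[float, float] = (-5.0, 5.0),
) -> np.ndarray:
    """Mean z-scored activity around trial onsets.

    Averages the trace over ``window`` seconds relative to each trial
    onset; trials whose window is truncated by the session edges are
    excluded.  Raises if no usable trial remains.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be increasing")
    n_lo = int(round(lo * z.frame_rate))
    n_hi = int(round(hi * z.frame_rate))
    snippets = []
    for tr in trials:
        onset_frame = int(round(tr.onset * z.frame_rate))
        a, b = onset_frame + n_lo, onset_frame + n_hi
        if a < 0 or b > len(z.values):
            continue
        snippets.append(z.values[a:b])
    if not snippets:
        raise ValueError("no trial with a full peri-event window inside the session")
    return np.mean(snippets, axis=0)


def cluster_response_profiles(
    profiles: np.ndarray,
    threshold_frac: float = 0.770,
) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage clustering of concatenated peri-event profiles.

    ``profiles`` has one row per cell (social and object peri-event
    averages concatenated).  Clusters are the flat cut of the Ward tree at
    ``threshold_frac`` times the maximum linkage height.

    Returns ``(labels, linkage_matrix)``; labels are 1-based as returned
    by :func:`scipy.cluster.hierarchy.fcluster`.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need a 2-D profile matrix with at least 2 cells")
    Z = hierarchy.linkage(profiles, method="ward", metric="euclidean")
    cut = threshold_frac * Z[:, 2].max()
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return labels, Z


@dataclass
class PopulationSummary:
    """Per-animal response proportions joined with a behavioral metric."""

    animal: str
    n_cells: int
    prop_excited: dict[str, float] = field(default_factory=dict)
    prop_inhibited: dict[str, float] = field(default_factory=dict)
    social_object_ratio: float | None = None


def population_summary(
    classifications: dict[str, dict[str, Sequence[str]]],
    social_object_ratios: dict[str, float] | None = None,
    stimulus: str = "social",
) -> tuple[list[PopulationSummary], tuple[float, float] | None]:
    """Per-animal excited/inhibited proportions and, when a behavioral
    metric is supplied, the Pearson correlation between the proportion of
    stimulus-excited cells and the social:object zone ratio.

    Parameters
    ----------
    classifications : mapping
        ``animal -> stimulus -> per-cell labels`` (excited/inhibited/none).
    social_object_ratios : mapping, optional
        ``animal -> social:object ratio``.
    stimulus : str
        Stimulus whose excited proportion enters the correlation.

    Returns
    -------
    summaries, correlation
        ``correlation`` is ``(r, p)`` or None when not computable
        (fewer than 3 animals with both values, or zero variance).
    """
    summaries = []
    for animal, per_stim in classifications.items():
        stims = list(per_stim)
        n_cells = len(per_stim[stims[0]])
        s = PopulationSummary(animal=animal, n_cells=n_cells)
        for st, labels in per_stim.items():
            labels = list(labels)
            n = len(labels)
            s.prop_excited[st] = sum(1 for x in labels if x == "excited") / n
            s.prop_inhibited[st] = sum(1 for x in labels if x == "inhibited") / n
        if social_object_ratios is not None:
            s.social_object_ratio = social_object_ratios.get(animal)
        summaries.append(s)

    corr = None
    if social_object_ratios is not None:
        xs, ys = [], []
        for s in summaries:
            if s.social_object_ratio is not None and stimulus in s.prop_excited:
                xs.append(s.prop_excited[stimulus])
                ys.append(s.social_object_ratio)
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            r, p = stats.pearsonr(xs, ys)
            corr = (float(r), float(p))
    return summaries, corr
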