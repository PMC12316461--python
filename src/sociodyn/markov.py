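"""First-order Markov analysis of behavioral state sequences.

A behavioral session is annotated as one categorical state label per 1-s
bin.  The questions asked of such a sequence are (i) whether transitions
between states carry first-order structure at all (G test against a
zeroth-order, i.e. time-independent, null), (ii) whether the transition
structure is stationary across the session (LRX test comparing per-segment
transition probabilities with the whole-sequence estimate), and (iii) how
the transition matrix changes between experimental conditions.

The module follows a model/results split: :class:`MarkovChainModel` is
built from a :class:`BehaviorSequence` and ``fit()`` returns a
:class:`MarkovChainResults` carrying the count matrix ``O``, the
row-stochastic probability matrix ``P``, the expected counts ``E`` under
the zeroth-order null, and the test methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BehaviorSequence",
    "TransitionModel",
    "MarkovTest",
    "MarkovChainModel",
    "MarkovChainResults",
    "encode_two_state",
    "fit_transitions",
    "g_order_test",
    "lrx_stationarity_test",
    "transition_delta",
    "state_transition_summary",
    "resolve_multilabel",
]

SOCIAL = "social"
NONSOCIAL = "nonsocial"

#: Ethogram of the juvenile-intruder assay: 15 behaviors, one code per
#: second, split into social and nonsocial categories.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "face_sniff_reciprocated": SOCIAL,
    "face_sniff": SOCIAL,
    "flank_sniff": SOCIAL,
    "anogenital_sniff_reciprocated": SOCIAL,
    "anogenital_sniff": SOCIAL,
    "close_follow": SOCIAL,
    "approach": SOCIAL,
    "dominant_climb": SOCIAL,
    "attack": SOCIAL,
    "groom": NONSOCIAL,
    "dig": NONSOCIAL,
    "rear": NONSOCIAL,
    "climb": NONSOCIAL,
    "still": NONSOCIAL,
    "ambulate": NONSOCIAL,
}


@dataclass
class BehaviorSequence:
    """Per-bin categorical state labels for one subject/session.

    Parameters
    ----------
    labels : sequence of str
        One state label per time bin (1-s bins).
    alphabet : sequence of str, optional
        Ordered state alphabet.  Defaults to the labels' order of first
        appearance.
    category_map : mapping, optional
        Maps each label to ``"social"`` or ``"nonsocial"``.
    subject, session : str, optional
        Identifiers carried through to outputs.
    """

    labels: list[str]
    alphabet: list[str] = field(default_factory=list)
    category_map: dict[str, str] | None = None
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) < 2:
            raise ValueError("a behavior sequence needs at least 2 bins")
        if not self.alphabet:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.alphabet = list(seen)
        else:
            self.alphabet = list(self.alphabet)
        extra = set(self.labels) - set(self.alphabet)
        if extra:
            raise ValueError(f"labels outside alphabet: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def support(self) -> list[str]:
        """States that actually occur, in alphabet order."""
        occ = set(self.labels)
        return [s for s in self.alphabet if s in occ]


def resolve_multilabel(
    codes_per_bin: Sequence[Sequence[str]],
    priority: Sequence[str] | None = None,
    category_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Collapse bins annotated with several simultaneous codes to one label.

    Manual annotation may assign more than one code to a second.  The
    default policy prefers social over nonsocial codes (ties broken by a
    priority list, falling back to first-listed).
    """
    cmap = dict(category_map) if category_map is not None else DEFAULT_CATEGORY_MAP
    prio = list(priority) if priority is not None else []
    out = []
    for codes in codes_per_bin:
        codes = list(codes)
        if not codes:
            raise ValueError("empty code set in a bin")
        if len(codes) == 1:
            out.append(codes[0])
            continue
        ranked = sorted(
            codes,
            key=lambda c: (
                prio.index(c) if c in prio else len(prio),
                0 if cmap.get(c) == SOCIAL else 1,
            ),
        )
        out.append(ranked[0])
    return out


def encode_two_state(seq: BehaviorSequence) -> BehaviorSequence:
    """Map a sequence onto the two-state social/nonsocial alphabet."""
    cmap = seq.category_map or DEFAULT_CATEGORY_MAP
    mapped = []
    for lab in seq.labels:
        cat = cmap.get(lab)
        if cat not in (SOCIAL, NONSOCIAL):
            raise ValueError(f"label {lab!r} has no social/nonsocial category")
        mapped.append(cat)
    return BehaviorSequence(
        labels=mapped,
        alphabet=[SOCIAL, NONSOCIAL],
        category_map={SOCIAL: SOCIAL, NONSOCIAL: NONSOCIAL},
        subject=seq.subject,
        session=seq.session,
    )


@dataclass
class TransitionModel:
    """Fitted transition structure of one sequence.

    ``O[i, j]`` counts transitions from state ``i`` to ``j`` over
    consecutive bins (self-transitions included — dwelling in a state is a
    transition to itself).  ``P`` row-normalizes ``O`` by the outgoing
    transitions of each state; rows with no outgoing transition are NaN.
    ``E`` holds the expected counts under a zeroth-order (no time
    dependence) null, the product of observed margins:
    ``E[i, j] = n_i. * n_.j / N``.
    """

    states: list[str]
    O: np.ndarray
    P: np.ndarray
    E: np.ndarray
    N: int

    @property
    def k(self) -> int:
        return len(self.states)


def _count_transitions(labels: Sequence[str], states: Sequence[str]) -> np.ndarray:
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    O = np.zeros((k, k), dtype=np.int64)
    idx = np.fromiter((index[lab] for lab in labels), dtype=np.int64, count=len(labels))
    np.add.at(O, (idx[:-1], idx[1:]), 1)
    return O


def _model_from_counts(states: Sequence[str], O: np.ndarray) -> TransitionModel:
    N = int(O.sum())
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = O / row[:, None]
    P[row == 0] = np.nan
    E = np.outer(row, col) / N if N > 0 else np.zeros_like(O, dtype=float)
    return TransitionModel(states=list(states), O=O, P=P, E=E, N=N)


def fit_transitions(
    seq: BehaviorSequence, states: Sequence[str] | None = None
) -> TransitionModel:
    """Count transitions and estimate the transition probability matrix.

    ``states`` defaults to the sequence's occupied states in alphabet
    order; pass an explicit list to force a common state space across
    sessions (e.g. for condition differences).
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 bins to count a transition")
    if states is None:
        states = seq.support
    else:
        missing = set(seq.labels) - set(states)
        if missing:
            raise ValueError(f"sequence contains states outside `states`: {sorted(missing)}")
    O = _count_transitions(seq.labels, states)
    return _model_from_counts(states, O)


@dataclass
class MarkovTest:
    """A chi-squared test of Markov order or stationarity."""

    statistic: float
    df: int
    p_value: float
    kind: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MarkovTest(kind={self.kind!r}, statistic={self.statistic:.4f}, "
            f"df={self.df}, p_value={self.p_value:.4g})"
        )


def g_order_test(model: TransitionModel) -> MarkovTest:
    """Log-likelihood G test of first-order structure against a
    zeroth-order null.

    G = 2 * sum_ij O_ij * ln(O_ij / E_ij), summed over cells with
    O_ij > 0 (the 0*ln(0) convention); cells with E_ij = 0 have O_ij = 0
    and drop out.  Degrees of freedom are (k-1)^2 for k occupied states;
    the p-value is the upper chi-squared tail.
    """
    if model.N < 1:
        raise ValueError("no transitions observed")
    O = model.O.astype(float)
    E = model.E
    mask = O > 0
    G = 2.0 * float(np.sum(O[mask] * np.log(O[mask] / E[mask])))
    occupied = (model.O.sum(axis=1) + model.O.sum(axis=0)) > 0
    k = int(occupied.sum())
    df = max((k - 1) ** 2, 1)
    p = float(stats.chi2.sf(G, df))
    return MarkovTest(statistic=G, df=df, p_value=p, kind="order")


def _segment_slices(T: int, n_segments: int) -> list[slice]:
    # near-equal durations; earlier segments take the extra bins
    base, extra = divmod(T, n_segments)
    sls, start = [], 0
    for s in range(n_segments):
        ln = base + (1 if s < extra else 0)
        sls.append(slice(start, start + ln))
        start += ln
    return sls


def lrx_stationarity_test(seq: BehaviorSequence, n_segments: int = 2) -> MarkovTest:
    """Likelihood-ratio test of transition-matrix stationarity.

    The sequence is divided into ``n_segments`` segments of (near-)equal
    duration.  With f_ijs the transition counts of segment s, p_bar_ijs
    the per-segment transition probabilities and p_ij the whole-sequence
    probabilities (pooled over the segments' transitions, so that
    segments with identical counts give exactly zero),

        LRX = 2 * sum_s sum_ij f_ijs * ln(p_bar_ijs / p_ij).

    Terms with f_ijs = 0 contribute 0.  Degrees of freedom are
    (n_segments - 1) * k * (k - 1) for k occupied states of the full
    sequence.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    states = seq.support
    seg_counts = []
    for sl in _segment_slices(len(seq), n_segments):
        seg_labels = seq.labels[sl]
        if len(seg_labels) < 2:
            raise ValueError("segment with no transitions; sequence too short")
        f = _count_transitions(seg_labels, states).astype(float)
        if f.sum() == 0:
            raise ValueError("segment with no transitions")
        seg_counts.append(f)
    pooled = np.sum(seg_counts, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = pooled / pooled.sum(axis=1, keepdims=True)
    lrx = 0.0
    for f in seg_counts:
        row = f.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_bar = f / row[:, None]
        mask = f > 0
        lrx += 2.0 * float(np.sum(f[mask] * np.log(p_bar[mask] / p[mask])))
    k = len(states)
    df = max((n_segments - 1) * k * (k - 1), 1)
    p = float(stats.chi2.sf(lrx, df))
    return MarkovTest(statistic=lrx, df=df, p_value=p, kind="stationarity")


def transition_delta(model_on: TransitionModel, model_off: TransitionModel) -> np.ndarray:
    """Elementwise ON - OFF difference of transition probabilities.

    Rows unoccupied in either session propagate NaN so they can be
    excluded from group means.
    """
    if model_on.states != model_off.states:
        raise ValueError("state order mismatch between sessions")
    return model_on.P - model_off.P


def state_transition_summary(model: TransitionModel) -> dict[str, tuple[float, float]]:
    """Within- vs across-state transition probabilities of a 2-state model.

    Returns the diagonal of P (probability of staying within the
    social/nonsocial state) and the off-diagonal (switching across).
    """
    if model.k != 2:
        raise ValueError(f"expected a two-state model, got k={model.k}")
    P = model.P
    return {
        "within": (float(P[0, 0]), float(P[1, 1])),
        "across": (float(P[0, 1]), float(P[1, 0])),
    }


class MarkovChainModel:
    """First-order Markov chain model of a behavioral sequence.

    Parameters
    ----------
    sequence : BehaviorSequence
        The annotated session.
    two_state : bool, default False
        Collapse the ethogram onto the social/nonsocial alphabet before
        fitting.
    states : list of str, optional
        Explicit state space (forces a common ordering across sessions).
    """

    def __init__(
        self,
        sequence: BehaviorSequence,
        two_state: bool = False,
        states: Sequence[str] | None = None,
    ) -> None:
        self.sequence = encode_two_state(sequence) if two_state else sequence
        self.two_state = two_state
        self.states = list(states) if states is not None else None

    def fit(self) -> "MarkovChainResults":
        tm = fit_transitions(self.sequence, states=self.states)
        return MarkovChainResults(self, tm)


class MarkovChainResults:
    """Fitted transition structure plus the order/stationarity tests."""

    def __init__(self, model: MarkovChainModel, transitions: TransitionModel) -> None:
        self.model = model
        self.transitions = transitions

    # convenience views
    @property
    def states(self) -> list[str]:
        return self.transitions.states

    @property
    def counts(self) -> np.ndarray:
        return self.transitions.O

    @property
    def transition_matrix(self) -> np.ndarray:
        return self.transitions.P

    @property
    def expected(self) -> np.ndarray:
        return self.transitions.E

    @property
    def n_transitions(self) -> int:
        return self.transitions.N

    def order_test(self) -> MarkovTest:
        return g_order_test(self.transitions)

    def stationarity_test(self, n_segments: int = 2) -> MarkovTest:
        return lrx_stationarity_test(self.model.sequence, n_segments=n_segments)

    def state_summary(self) -> dict[str, tuple[float, float]]:
        return state_transition_summary(self.transitions)

    def summary(self) -> str:
        tm = self.transitions
        g = self.order_test()
        lines = [
            "First-order Markov chain fit",
            "=" * 42,
            f"states ({tm.k}): {', '.join(tm.states)}",
            f"transitions N = {tm.N}",
            "",
            "Transition probability matrix P (rows: from)",
        ]
        header = "            " + "  ".join(f"{s[:10]:>10}" for s in tm.states)
        lines.append(header)
        for i, s in enumerate(tm.states):
            row = "  ".join(
                f"{v:10.4f}" if np.isfinite(v) else f"{'nan':>10}" for v in tm.P[i]
            )
            lines.append(f"{s[:10]:>10}  {row}")
        lines += [
            "",
            f"G (order) = {g.statistic:.4f}, df = {g.df}, p = {g.p_value:.4g}",
        ]
        try:
            lrx = self.stationarity_test()
            lines.append(
                f"LRX (stationarity, 2 segments) = {lrx.statistic:.4f}, "
                f"df = {lrx.df}, p = {lrx.p_value:.4g}"
            )
        except ValueError:
            lines.append("LRX (stationarity): not computable (segment too short)")
        return "\n".join(lines)
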