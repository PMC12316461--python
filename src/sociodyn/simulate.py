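"""Synthetic data with planted ground truth for every pipeline input.

Each generator emulates the statistical structure its downstream
analysis assumes and returns the planted truth alongside the data, so
recovery can be verified exactly:

* behavioral label sequences drawn from a known first-order Markov chain;
* pose-keypoint sessions with planted cup-interaction bouts that satisfy
  the nose-distance/head-cone detection rule by construction;
* calcium trace populations with known excited/inhibited/none cells
  responding to interaction-bout onsets;
* current-clamp recordings synthesized from intrinsic-property
  archetypes (sag, ramp ratio, firing delay, max frequency, capacitance)
  plus an optogenetic-response sweep with a planted EPSP/IPSP shape;
* round-robin tube-test contest tables driven by latent dominance ranks.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
import pandas as pd

from .markov import BehaviorSequence, DEFAULT_CATEGORY_MAP
from .pose import Arena, Cup, InteractionVector, PoseTrack, SKELETON
from .ephys import EphysRecording, StepProtocol, Sweep

__all__ = [
    "MarkovSpec",
    "PoseScenario",
    "CalciumSpec",
    "EphysArchetype",
    "gen_markov_sequence",
    "gen_pose_session",
    "gen_calcium_population",
    "gen_ephys_cell",
    "gen_tube_contests",
    "gen_interaction_events",
    "ARCHETYPES",
]


# --------------------------------------------------------------------------
# Markov behavioral sequences
# --------------------------------------------------------------------------

@dataclass
class MarkovSpec:
    """True transition structure of a synthetic behavioral sequence."""

    states: list[str]
    P_true: np.ndarray
    T: int
    category_map: dict[str, str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.P_true = np.asarray(self.P_true, dtype=float)
        k = len(self.states)
        if self.P_true.shape != (k, k):
            raise ValueError("P_true must be k x k for k states")
        if (self.P_true < 0).any() or not np.allclose(
            self.P_true.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("P_true rows must be nonnegative and sum to 1")
        if self.T < 2:
            raise ValueError("T must be at least 2")
        if self.category_map is not None:
            missing = set(self.states) - set(self.category_map)
            if missing:
                raise ValueError(f"states without category: {sorted(missing)}")


def _stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Left eigenvector for eigenvalue 1; falls back to uniform when the
    stationary distribution is not unique (reducible/periodic chains).
    """
    k = P.shape[0]
    vals, vecs = np.linalg.eig(P.T)
    close = np.flatnonzero(np.abs(vals - 1.0) < 1e-8)
    if len(close) != 1:
        return np.full(k, 1.0 / k)
    v = np.real(vecs[:, close[0]])
    v = np.abs(v)
    s = v.sum()
    if s == 0:
        return np.full(k, 1.0 / k)
    return v / s


def gen_markov_sequence(spec: MarkovSpec) -> BehaviorSequence:
    """Sample a label sequence from the chain defined by ``spec``.

    The initial state is drawn from the stationary distribution of
    ``P_true`` (uniform fallback when it is not unique), removing burn-in
    bias at small T; state t+1 is sampled from row ``P_true[state t]``.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.states)
    pi = _stationary_distribution(spec.P_true)
    # cumulative-row inverse-CDF sampling keeps the draw vectorizable
    cum = np.cumsum(spec.P_true, axis=1)
    cum[:, -1] = 1.0
    states = np.empty(spec.T, dtype=np.int64)
    states[0] = rng.choice(k, p=pi)
    u = rng.random(spec.T - 1)
    for t in range(1, spec.T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    labels = [spec.states[i] for i in states]
    cmap = spec.category_map
    if cmap is None and set(spec.states) <= set(DEFAULT_CATEGORY_MAP):
        cmap = {s: DEFAULT_CATEGORY_MAP[s] for s in spec.states}
    return BehaviorSequence(labels=labels, alphabet=list(spec.states), category_map=cmap)


# --------------------------------------------------------------------------
# Pose sessions
# --------------------------------------------------------------------------

@dataclass
class PoseScenario:
    """Three-chamber-style session layout with planted interaction bouts."""

    arena: Arena
    cups: list[Cup]
    duration: float
    frame_rate: float = 25.0
    planted_bouts: list[tuple[str, float, float]] = field(default_factory=list)
    keypoint_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        stims = {c.stimulus for c in self.cups}
        for c in self.cups:
            cx, cy = c.center
            r = c.diameter / 2
            if not (r <= cx <= self.arena.width - r and r <= cy <= self.arena.height - r):
                raise ValueError(f"cup at {c.center} lies outside the arena")
        by_stim: dict[str, list[tuple[float, float]]] = {}
        for stim, on, off in self.planted_bouts:
            if stim not in stims:
                raise ValueError(f"bout stimulus {stim!r} has no cup")
            if not (0 <= on < off <= self.duration):
                raise ValueError(f"bout ({stim}, {on}, {off}) outside session duration")
            by_stim.setdefault(stim, []).append((on, off))
        for stim, ivals in by_stim.items():
            ivals = sorted(ivals)
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping {stim} bouts")


def default_scenario(
    duration: float = 600.0,
    frame_rate: float = 25.0,
    planted_bouts: list[tuple[str, float, float]] | None = None,
    keypoint_noise_sd: float = 0.0,
    seed: int | None = None,
) -> PoseScenario:
    """Three-chamber layout: 57.5 x 22.5 cm arena, social and object cups."""
    arena = Arena(width=57.5, height=22.5)
    cups = [
        Cup(center=(9.0, 11.25), diameter=8.0, stimulus="social"),
        Cup(center=(48.5, 11.25), diameter=8.0, stimulus="object"),
    ]
    return PoseScenario(
        arena=arena,
        cups=cups,
        duration=duration,
        frame_rate=frame_rate,
        planted_bouts=planted_bouts or [],
        keypoint_noise_sd=keypoint_noise_sd,
        seed=seed,
    )


# body-axis spacing (cm) of the three keypoints the detection rule uses
_NOSE_HEAD = 1.2
_HEAD_NECK = 1.2
# nose-to-cup-center distance during a planted bout, as a fraction of the
# cup diameter (inside the 1.3x threshold with margin)
_BOUT_DIST_FRAC = 0.8
# exclusion radius outside bouts (outside the threshold with margin)
_AVOID_FRAC = 1.45


def gen_pose_session(
    scn: PoseScenario,
) -> tuple[PoseTrack, dict[str, np.ndarray]]:
    """Synthesize a keypoint track plus framewise ground-truth vectors.

    During planted bouts the nose sits at 0.8x the cup diameter from the
    cup center with the heading aimed at the cup, so the geometric rule
    holds by construction; outside bouts the animal random-walks with its
    nose kept at least 1.45x the diameter from every cup, so the rule
    fails by construction.  Gaussian jitter of ``keypoint_noise_sd`` cm is
    added to every keypoint.  Returns the track and, per stimulus, the
    boolean ground-truth interaction vector at frame resolution.
    """
    rng = np.random.default_rng(scn.seed)
    n = int(round(scn.duration * scn.frame_rate))
    cups = {c.stimulus: c for c in scn.cups}
    center = np.array([scn.arena.width / 2, scn.arena.height / 2])

    truth = {stim: np.zeros(n, dtype=bool) for stim in cups}
    bout_of_frame: list[tuple[str, int] | None] = [None] * n
    for b_idx, (stim, on, off) in enumerate(scn.planted_bouts):
        i0 = int(np.ceil(on * scn.frame_rate - 1e-9))
        i1 = int(np.ceil(off * scn.frame_rate - 1e-9))
        truth[stim][i0:i1] = True
        for i in range(i0, min(i1, n)):
            bout_of_frame[i] = (stim, b_idx)

    # per-bout approach angle: base direction from cup toward arena center,
    # jittered within +/- 30 degrees
    bout_dirs: dict[int, np.ndarray] = {}
    for b_idx, (stim, _, _) in enumerate(scn.planted_bouts):
        c = np.asarray(cups[stim].center)
        base = center - c
        ang = np.arctan2(base[1], base[0]) + rng.uniform(-np.pi / 6, np.pi / 6)
        bout_dirs[b_idx] = np.array([np.cos(ang), np.sin(ang)])

    nose = np.empty((n, 2))
    heading = np.empty((n, 2))
    pos = center.copy()
    vel = np.zeros(2)
    last_heading = np.array([1.0, 0.0])
    margin = 3.0
    for i in range(n):
        tag = bout_of_frame[i]
        if tag is not None:
            stim, b_idx = tag
            cup = cups[stim]
            u = bout_dirs[b_idx]
            c = np.asarray(cup.center)
            nose[i] = c + _BOUT_DIST_FRAC * cup.diameter * u
            heading[i] = -u  # from neck->head toward the cup
            pos = nose[i].copy()
            last_heading = heading[i]
            vel = np.zeros(2)
            continue
        # Ornstein-Uhlenbeck-ish wander pulled gently toward the center
        vel = 0.9 * vel + 0.05 * (center - pos) / 100.0 + rng.normal(0, 0.35, 2)
        pos = pos + vel
        pos[0] = np.clip(pos[0], margin, scn.arena.width - margin)
        pos[1] = np.clip(pos[1], margin, scn.arena.height - margin)
        for cup in cups.values():
            c = np.asarray(cup.center)
            d = pos - c
            dist = np.linalg.norm(d)
            keepout = _AVOID_FRAC * cup.diameter
            if dist < keepout:
                pos = c + d / (dist if dist > 0 else 1.0) * keepout
                vel = np.zeros(2)
        speed = np.linalg.norm(vel)
        if speed > 1e-6:
            last_heading = vel / speed
        nose[i] = pos
        heading[i] = last_heading

    head = nose - _NOSE_HEAD * heading
    neck = head - _HEAD_NECK * heading
    perp = np.stack([-heading[:, 1], heading[:, 0]], axis=1)

    kp: dict[str, np.ndarray] = {"nose": nose, "head": head, "neck": neck}
    kp["left_ear"] = head + 0.8 * perp
    kp["right_ear"] = head - 0.8 * perp
    kp["left_forelimb"] = neck + 1.0 * perp
    kp["right_forelimb"] = neck - 1.0 * perp
    trunk = neck - 2.0 * heading
    kp["trunk"] = trunk
    kp["left_hindlimb"] = trunk + 1.0 * perp
    kp["right_hindlimb"] = trunk - 1.0 * perp
    tail_base = trunk - 1.5 * heading
    kp["tail_base"] = tail_base
    for j, name in enumerate(("tail_1", "tail_2", "tail_3", "tail_tip"), start=1):
        kp[name] = tail_base - 1.2 * j * heading
    kp = {name: kp[name] for name in SKELETON}

    if scn.keypoint_noise_sd > 0:
        for name in kp:
            kp[name] = kp[name] + rng.normal(0, scn.keypoint_noise_sd, (n, 2))

    track = PoseTrack(
        keypoints=kp, frame_rate=scn.frame_rate, arena=scn.arena, cups=list(scn.cups)
    )
    return track, truth


def gen_interaction_events(
    duration: float,
    n_bouts: int,
    bout_duration: tuple[float, float] = (1.5, 4.0),
    min_gap: float = 6.0,
    bin_width: float = 0.040,
    stimulus: str = "social",
    seed: int | np.random.Generator | None = None,
) -> InteractionVector:
    """Random non-overlapping interaction bouts as a binned binary vector.

    Bouts are uniform in duration over ``bout_duration`` and separated by
    at least ``min_gap`` seconds, emulating trial-worthy cup visits.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = int(round(duration / bin_width))
    values = np.zeros(n_bins, dtype=np.uint8)
    durs = rng.uniform(*bout_duration, size=n_bouts)
    slack = duration - durs.sum() - min_gap * (n_bouts + 1)
    if slack <= 0:
        raise ValueError("session too short for the requested bouts")
    gaps = rng.dirichlet(np.ones(n_bouts + 1)) * slack + min_gap
    t = 0.0
    for d, g in zip(durs, gaps):
        t += g
        i0 = int(round(t / bin_width))
        i1 = int(round((t + d) / bin_width))
        values[i0:i1] = 1
        t += d
    return InteractionVector(stimulus=stimulus, values=values, bin_width=bin_width)


# --------------------------------------------------------------------------
# Calcium populations
# --------------------------------------------------------------------------

@dataclass
class CalciumSpec:
    """Population of synthetic calcium traces with planted response classes.

    ``cell_classes`` maps stimulus -> per-cell labels in
    {"excited", "inhibited", "none"}.
    """

    n_cells: int
    duration: float
    cell_classes: dict[str, list[str]]
    frame_rate: float = 20.0
    response_amplitude: float = 5.0
    transient_decay_tau: float = 0.5
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.response_amplitude < 0:
            raise ValueError("response_amplitude must be nonnegative")
        valid = {"excited", "inhibited", "none"}
        for stim, labels in self.cell_classes.items():
            if len(labels) != self.n_cells:
                raise ValueError(f"cell_classes[{stim!r}] must have n_cells entries")
            bad = set(labels) - valid
            if bad:
                raise ValueError(f"unknown cell classes: {sorted(bad)}")


def _event_onsets(events: InteractionVector) -> np.ndarray:
    v = events.values.astype(np.int8)
    d = np.diff(np.concatenate(([0], v)))
    return np.flatnonzero(d == 1) * events.bin_width


def gen_calcium_population(
    spec: CalciumSpec, events: dict[str, InteractionVector]
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Synthesize raw traces (cells x frames) plus the planted labels.

    Each trace is Gaussian noise; excited cells add an
    exponential-decay transient (GCaMP-like, default tau 0.5 s) of the
    stated amplitude at every event onset of their stimulus, inhibited
    cells subtract it.  Traces are raw — z-scoring is the analysis
    pipeline's job.
    """
    for stim, ev in events.items():
        if abs(ev.duration - spec.duration) > ev.bin_width + 1e-9:
            raise ValueError(
                f"event vector for {stim!r} spans {ev.duration:.2f} s, "
                f"session is {spec.duration:.2f} s"
            )
    unknown = set(spec.cell_classes) - set(events)
    if unknown:
        raise ValueError(f"cell classes for stimuli without events: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.frame_rate))
    traces = rng.normal(0.0, spec.noise_sd, size=(spec.n_cells, n_frames))

    t = np.arange(n_frames) / spec.frame_rate
    kernel_len = int(np.ceil(6 * spec.transient_decay_tau * spec.frame_rate))
    kernel = spec.response_amplitude * np.exp(
        -np.arange(kernel_len) / spec.frame_rate / spec.transient_decay_tau
    )
    for stim, labels in spec.cell_classes.items():
        onsets = _event_onsets(events[stim])
        onset_frames = np.round(onsets * spec.frame_rate).astype(int)
        bump = np.zeros(n_frames)
        for f in onset_frames:
            hi = min(f + kernel_len, n_frames)
            if f < n_frames:
                bump[f:hi] += kernel[: hi - f]
        for c, lab in enumerate(labels):
            if lab == "excited":
                traces[c] += bump
            elif lab == "inhibited":
                traces[c] -= bump
    _ = t
    return traces, {s: list(l) for s, l in spec.cell_classes.items()}


# --------------------------------------------------------------------------
# Ephys cells
# --------------------------------------------------------------------------

@dataclass
class EphysArchetype:
    """Intrinsic-property archetype for a synthetic neuron.

    The default archetypes mirror the qualitative cell types seen in the
    downstream targets: late-firing cells (large sag, long rheobase
    delay), regular-firing cells, pyramidal-like cells (large
    capacitance, low max rate) and fast-spiking interneuron-like cells.
    """

    name: str
    sag_mV: float
    ramp_ratio_true: float
    firing_delay_ms: float
    max_freq_hz: float
    capacitance_pF: float
    psp_type: str = "none"  # EPSP | IPSP | mixed | none
    psp_amplitude_mV: float = 0.0
    ipsp_amplitude_mV: float = 0.0
    ipsp_tau_s: float = 1.0
    noise_sd_mV: float = 0.2
    rheobase_pA: float = 100.0
    resting_mV: float = -70.0
    input_resistance_MOhm: float = 150.0
    iei_pre_s: float | None = None
    iei_post_s: float | None = None

    def __post_init__(self) -> None:
        if self.psp_type not in ("EPSP", "IPSP", "mixed", "none"):
            raise ValueError(f"unknown psp_type {self.psp_type!r}")
        has_e = self.psp_amplitude_mV > 0
        has_i = self.ipsp_amplitude_mV > 0
        expect = {"EPSP": (True, False), "IPSP": (False, True),
                  "mixed": (True, True), "none": (False, False)}[self.psp_type]
        if (has_e, has_i) != expect:
            raise ValueError(
                f"psp_type {self.psp_type!r} inconsistent with amplitudes "
                f"(EPSP={self.psp_amplitude_mV}, IPSP={self.ipsp_amplitude_mV})"
            )
        for v in (self.sag_mV, self.max_freq_hz, self.capacitance_pF):
            if v < 0 or not np.isfinite(v):
                raise ValueError("archetype magnitudes must be finite and nonnegative")
        if self.max_freq_hz < 15 or self.max_freq_hz > 400:
            raise ValueError("max_freq_hz must lie in [15, 400] for synthesis")


ARCHETYPES: dict[str, EphysArchetype] = {
    "late_firing": EphysArchetype(
        name="late_firing", sag_mV=8.0, ramp_ratio_true=2.0, firing_delay_ms=250.0,
        max_freq_hz=40.0, capacitance_pF=80.0, psp_type="EPSP",
        psp_amplitude_mV=3.0, rheobase_pA=120.0,
    ),
    "regular_firing": EphysArchetype(
        name="regular_firing", sag_mV=2.0, ramp_ratio_true=1.0, firing_delay_ms=30.0,
        max_freq_hz=80.0, capacitance_pF=120.0, psp_type="IPSP",
        ipsp_amplitude_mV=4.0, ipsp_tau_s=1.0, rheobase_pA=80.0,
    ),
    "pyramidal": EphysArchetype(
        name="pyramidal", sag_mV=3.0, ramp_ratio_true=1.2, firing_delay_ms=120.0,
        max_freq_hz=30.0, capacitance_pF=180.0, psp_type="IPSP",
        ipsp_amplitude_mV=3.0, ipsp_tau_s=1.2, rheobase_pA=140.0,
    ),
    "interneuron": EphysArchetype(
        name="interneuron", sag_mV=1.0, ramp_ratio_true=0.9, firing_delay_ms=15.0,
        max_freq_hz=150.0, capacitance_pF=60.0, psp_type="EPSP",
        psp_amplitude_mV=2.5, rheobase_pA=60.0,
    ),
}

_TAU_SAG = 0.1  # s, relaxation of the sag hyperpolarization
_TAU_CHARGE = 0.005  # s, fast charging on depolarizing steps
_SPIKE_RISE = 0.001  # s
_SPIKE_FALL = 0.0015  # s
_SPIKE_PEAK = 30.0  # mV


def _add_spikes(time: np.ndarray, vm: np.ndarray, spike_times: Sequence[float]) -> None:
    """Superimpose stylized spikes (1 ms rise to +30 mV, 1.5 ms fall)."""
    for ts in spike_times:
        m_rise = (time >= ts) & (time < ts + _SPIKE_RISE)
        m_fall = (time >= ts + _SPIKE_RISE) & (time < ts + _SPIKE_RISE + _SPIKE_FALL)
        if m_rise.any():
            frac = (time[m_rise] - ts) / _SPIKE_RISE
            vm[m_rise] = vm[m_rise] + frac * (_SPIKE_PEAK - vm[m_rise])
        if m_fall.any():
            frac = (time[m_fall] - ts - _SPIKE_RISE) / _SPIKE_FALL
            vm[m_fall] = _SPIKE_PEAK + frac * (vm[m_fall] - _SPIKE_PEAK)


def _ramp_shape(t_rel: np.ndarray, r: float) -> np.ndarray:
    """Unit deflection with early-window (100-200 ms) mean 1 and
    late-window (900-1000 ms) mean r."""
    b = (r - 1.0) / 0.8
    a = 1.0 - 0.15 * b
    return (a + b * t_rel) * (1.0 - np.exp(-t_rel / _TAU_CHARGE))


def _step_spike_times(
    arch: EphysArchetype, current: float, onset: float, duration: float
) -> list[float]:
    """Planted spike times for a suprathreshold step.

    The rheobase step fires first at the archetype's delay; higher steps
    fire earlier and faster, but never exceed the archetype's maximum
    instantaneous rate; the strongest step opens with a burst at exactly
    that rate so the planted maximum is attained.
    """
    rb = arch.rheobase_pA
    isi_min = 1.0 / arch.max_freq_hz
    if current >= 260.0 - 1e-9:
        start, isi = 0.010, isi_min
    else:
        start = (arch.firing_delay_ms / 1000.0) * rb / current
        isi = max(0.080 * rb / current, isi_min)
    times, t = [], onset + start
    while t < onset + duration - 0.005:
        times.append(t)
        t += isi
        if len(times) > 500:
            break
    return times


def gen_ephys_cell(
    arch: EphysArchetype,
    protocol: StepProtocol | None = None,
    seed: int | np.random.Generator | None = None,
    fs: float = 10_000.0,
    opto_fs: float = 2_000.0,
    with_opto: bool = True,
    with_firing: bool | None = None,
    cell: str = "",
) -> tuple[EphysRecording, dict[str, float | str | None]]:
    """Synthesize a full current-clamp recording for one archetype.

    Step sweeps are built so that the feature extractors recover the
    archetype's planted values: the -120 pA sweep carries the sag as a
    100-ms-tau relaxation on top of the ohmic deflection, depolarizing
    subthreshold sweeps share the archetype's ramp shape, the rheobase
    sweep fires first at the planted delay and the strongest sweep opens
    with a burst at the planted maximum instantaneous rate.  The -20 pA
    sweep is a pure RC charging curve with tau = R_in * C.  The
    optogenetic sweep plants the archetype's PSP shape (depressing fast
    EPSPs per pulse; a slow IPSP troughing at 0.4 s with an exact
    exponential decay of the planted tau).  Returns the recording and the
    ground-truth feature dict.
    """
    if protocol is None:
        protocol = StepProtocol()
    if -120.0 not in protocol.currents_pA:
        raise ValueError("protocol must include a -120 pA step: sag undefined without it")
    if max(protocol.currents_pA) < arch.rheobase_pA:
        raise ValueError("protocol has no suprathreshold step")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t0, t1 = protocol.step_onset, protocol.step_offset
    time = np.arange(0.0, protocol.sweep_duration, 1.0 / fs)
    in_step = (time >= t0) & (time < t1)
    t_rel = np.where(in_step, time - t0, 0.0)
    r_mV_per_pA = arch.input_resistance_MOhm / 1000.0
    tau_m = arch.input_resistance_MOhm * 1e6 * arch.capacitance_pF * 1e-12

    step_sweeps: dict[float, Sweep] = {}
    for current in protocol.currents_pA:
        vm = np.full_like(time, arch.resting_mV)
        ss = current * r_mV_per_pA
        if current < 0:
            if current == -120.0:
                # half-cosine descent (30 ms) to the sag trough, then the
                # sag relaxes away with a 100-ms tau
                trough = ss - arch.sag_mV
                t_d = 0.03
                defl = np.where(
                    t_rel < t_d,
                    trough * (1 - np.cos(np.pi * t_rel / t_d)) / 2,
                    ss - arch.sag_mV * np.exp(-(t_rel - t_d) / _TAU_SAG),
                )
            else:
                defl = ss * (1.0 - np.exp(-t_rel / tau_m))
            vm[in_step] += defl[in_step]
        elif current > 0:
            sub = min(current, arch.rheobase_pA - 20.0)
            defl = sub * r_mV_per_pA * _ramp_shape(t_rel, arch.ramp_ratio_true)
            vm[in_step] += defl[in_step]
            if current >= arch.rheobase_pA:
                _add_spikes(time, vm, _step_spike_times(arch, current, t0, t1 - t0))
        vm += rng.normal(0.0, arch.noise_sd_mV, size=vm.shape)
        step_sweeps[float(current)] = Sweep(time=time.copy(), vm=vm)

    opto_sweep = pulses = None
    if with_opto:
        ot = np.arange(0.0, 11.0, 1.0 / opto_fs)
        ov = np.full_like(ot, arch.resting_mV)
        t_on = 5.0
        pulses = t_on + np.arange(8) / 30.0
        if arch.psp_amplitude_mV > 0:
            kernel = np.zeros_like(ot)
            for k, tp in enumerate(pulses):
                dt_p = ot - tp
                m = dt_p >= 0
                kernel[m] += (0.5 ** k) * (
                    np.exp(-dt_p[m] / 0.05) - np.exp(-dt_p[m] / 0.005)
                )
            kernel *= arch.psp_amplitude_mV / kernel.max()
            ov += kernel
        if arch.ipsp_amplitude_mV > 0:
            dt_i = ot - t_on
            rise = (dt_i >= 0) & (dt_i < 0.4)
            decay = dt_i >= 0.4
            ipsp = np.zeros_like(ot)
            ipsp[rise] = -arch.ipsp_amplitude_mV * (1 - np.cos(np.pi * dt_i[rise] / 0.4)) / 2
            ipsp[decay] = -arch.ipsp_amplitude_mV * np.exp(-(dt_i[decay] - 0.4) / arch.ipsp_tau_s)
            ov += ipsp
        ov += rng.normal(0.0, arch.noise_sd_mV, size=ov.shape)
        opto_sweep = Sweep(time=ot, vm=ov)

    firing_sweep = light_onset = None
    if with_firing is None:
        with_firing = arch.iei_pre_s is not None and arch.iei_post_s is not None
    if with_firing:
        if arch.iei_pre_s is None or arch.iei_post_s is None:
            raise ValueError("firing sweep requested but archetype has no IEI values")
        ft = np.arange(0.0, 10.0, 1.0 / opto_fs)
        fv = np.full_like(ft, -60.0)
        light_onset = 5.0
        spikes = list(np.arange(0.05, light_onset, arch.iei_pre_s))
        spikes += list(np.arange(light_onset + 0.02, 10.0, arch.iei_post_s))
        _add_spikes(ft, fv, spikes)
        fv += rng.normal(0.0, arch.noise_sd_mV, size=fv.shape)
        firing_sweep = Sweep(time=ft, vm=fv)

    rec = EphysRecording(
        cell=cell or arch.name,
        step_sweeps=step_sweeps,
        protocol=protocol,
        opto_sweep=opto_sweep,
        opto_pulses=pulses,
        firing_sweep=firing_sweep,
        firing_light_onset=light_onset,
    )
    truth: dict[str, float | str | None] = {
        "sag_mV": arch.sag_mV,
        "ramp_ratio": arch.ramp_ratio_true,
        "firing_delay_ms": arch.firing_delay_ms,
        "max_freq_inst_hz": arch.max_freq_hz,
        "capacitance_pF": arch.capacitance_pF,
        "ipsp_decay_tau_s": arch.ipsp_tau_s if arch.ipsp_amplitude_mV > 0 else None,
        "psp_type": arch.psp_type,
    }
    return rec, truth


# --------------------------------------------------------------------------
# Tube-test contests
# --------------------------------------------------------------------------

def gen_tube_contests(
    latent_ranks: dict[str, float],
    days: int = 4,
    seed: int | np.random.Generator | None = None,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Round-robin contest table driven by latent dominance scores.

    Every pair of subjects meets once per day; subject a wins with
    probability ``sigmoid(scale * (rank_a - rank_b))``, so an infinite
    rank gap makes outcomes deterministic and equal ranks give fair
    coin flips.
    """
    subjects = list(latent_ranks)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for day in range(1, days + 1):
        for i, a in enumerate(subjects):
            for b in subjects[i + 1:]:
                p_a = expit(scale * (latent_ranks[a] - latent_ranks[b]))
                winner = "a" if rng.random() < p_a else "b"
                rows.append({"day": day, "subject_a": a, "subject_b": b, "winner": winner})
    return pd.DataFrame(rows, columns=["day", "subject_a", "subject_b", "winner"])
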