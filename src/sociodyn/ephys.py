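"""Intrinsic and optogenetic-response features from current-clamp sweeps.

The protocol delivers 1-s current steps in 20 pA increments from -120 pA
to +260 pA.  From these sweeps the module extracts the four baseline
properties used to separate cell types downstream:

* voltage sag — peak-minus-steady-state hyperpolarization during the
  -120 pA step, attributable to the hyperpolarization-activated cation
  current I_h;
* ramp ratio — late (900-1000 ms) over early (100-200 ms) membrane
  deflection during the largest subthreshold depolarizing step;
* firing delay — latency from step onset to the first spike at rheobase
  (the lowest suprathreshold step);
* max instantaneous firing frequency — highest 1/ISI among spike pairs
  within the first 100 ms of any depolarizing step;

plus an optional capacitance estimate from the charging curve of a small
hyperpolarizing step.  A separate sweep records the membrane response to
an 8-pulse 30-Hz optogenetic train; its EPSP/IPSP metrics (peak, trough,
IPSP decay tau, signed voltage area over 0-5.5 s) and, when available,
the change in inter-spike interval around light onset drive the
excitation/inhibition/mixed response classification.  Cells are finally
clustered on max-min-normalized baseline features with Ward linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.cluster import hierarchy

__all__ = [
    "Sweep",
    "StepProtocol",
    "EphysRecording",
    "EphysFeatureSet",
    "PspMetrics",
    "detect_spikes",
    "sag_amplitude",
    "ramp_ratio",
    "firing_delay",
    "max_inst_freq",
    "capacitance",
    "extract_features",
    "psp_metrics",
    "classify_opto_response",
    "cluster_baseline",
]


@dataclass
class Sweep:
    """One membrane-potential recording: time (s) and Vm (mV)."""

    time: np.ndarray
    vm: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.time.shape != self.vm.shape:
            raise ValueError("time and vm must have the same shape")
        if len(self.time) < 2:
            raise ValueError("sweep too short")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class StepProtocol:
    """Current-step protocol: 1-s steps, -120 to +260 pA in 20 pA steps."""

    currents_pA: tuple[float, ...] = tuple(range(-120, 261, 20))
    step_onset: float = 0.2
    step_duration: float = 1.0
    sweep_duration: float = 1.4

    @property
    def step_offset(self) -> float:
        return self.step_onset + self.step_duration


@dataclass
class EphysRecording:
    """Current-clamp sweeps for one cell.

    ``step_sweeps`` maps injected current (pA) to the membrane response;
    ``opto_sweep``/``opto_pulses`` hold the averaged response to the
    8-pulse 30-Hz light train; ``firing_sweep``/``firing_light_onset``
    hold a constant-current spiking sweep with the light onset marked.
    """

    cell: str
    step_sweeps: dict[float, Sweep]
    protocol: StepProtocol = field(default_factory=StepProtocol)
    region: str = ""
    opto_sweep: Sweep | None = None
    opto_pulses: np.ndarray | None = None
    firing_sweep: Sweep | None = None
    firing_light_onset: float | None = None


def _smooth(x: np.ndarray, fs: float, width_s: float = 0.005) -> np.ndarray:
    """Boxcar smoothing; stabilizes extremum-based measures against noise."""
    n = max(int(round(width_s * fs)), 1)
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    pad = np.pad(x, (n // 2, n - 1 - n // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_spikes(
    sweep: Sweep,
    threshold_mV: float = 0.0,
    refractory_s: float = 0.002,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Spike times as upward crossings of a voltage threshold.

    Crossings closer than the refractory period to the previous accepted
    spike are ignored; restrict to ``window`` (s) when given.
    """
    v = sweep.vm
    above = v >= threshold_mV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = sweep.time[crossings]
    if window is not None:
        times = times[(times >= window[0]) & (times < window[1])]
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def _step_window(rec: EphysRecording) -> tuple[float, float]:
    return rec.protocol.step_onset, rec.protocol.step_offset


def _baseline(sweep: Sweep, onset: float, pre_s: float = 0.1) -> float:
    m = (sweep.time >= onset - pre_s) & (sweep.time < onset)
    return float(sweep.vm[m].mean())


def sag_amplitude(rec: EphysRecording, sag_current_pA: float = -120.0) -> float:
    """Voltage sag (mV) during the -120 pA step.

    Peak = minimum (3-ms smoothed) Vm within the step; steady state =
    mean Vm over the final 200 ms of the step; sag = steady - peak >= 0.
    """
    sweep = rec.step_sweeps.get(sag_current_pA)
    if sweep is None:
        raise ValueError(f"no {sag_current_pA:g} pA sweep: sag undefined")
    t0, t1 = _step_window(rec)
    m = (sweep.time >= t0) & (sweep.time < t1)
    v = _smooth(sweep.vm, sweep.fs, 0.003)[m]
    peak = float(v.min())
    steady_m = (sweep.time >= t1 - 0.2) & (sweep.time < t1)
    steady = float(sweep.vm[steady_m].mean())
    return steady - peak


def _depolarizing_steps(rec: EphysRecording) -> list[float]:
    return sorted(i for i in rec.step_sweeps if i > 0)


def _has_spikes(rec: EphysRecording, current: float) -> bool:
    sweep = rec.step_sweeps[current]
    return len(detect_spikes(sweep, window=_step_window(rec))) > 0


def ramp_ratio(
    rec: EphysRecording,
    early: tuple[float, float] = (0.1, 0.2),
    late: tuple[float, float] = (0.9, 1.0),
) -> float | None:
    """Late/early deflection ratio on the largest subthreshold step.

    Windows are relative to step onset; deflection is measured from the
    pre-step baseline (ratios of absolute potentials near rest are
    ill-conditioned).  Returns None when every depolarizing step spikes.
    """
    t0, _ = _step_window(rec)
    sub = [i for i in _depolarizing_steps(rec) if not _has_spikes(rec, i)]
    if not sub:
        return None
    sweep = rec.step_sweeps[max(sub)]
    base = _baseline(sweep, t0)
    me = (sweep.time >= t0 + early[0]) & (sweep.time < t0 + early[1])
    ml = (sweep.time >= t0 + late[0]) & (sweep.time < t0 + late[1])
    d_early = float(sweep.vm[me].mean()) - base
    d_late = float(sweep.vm[ml].mean()) - base
    if abs(d_early) < 1e-9:
        return None
    return d_late / d_early


def firing_delay(rec: EphysRecording) -> float | None:
    """Latency (ms) from step onset to the first spike at rheobase.

    Rheobase is the lowest depolarizing step that elicits at least one
    spike.  None when no step spikes.
    """
    t0, t1 = _step_window(rec)
    for current in _depolarizing_steps(rec):
        spikes = detect_spikes(rec.step_sweeps[current], window=(t0, t1))
        if len(spikes):
            return (float(spikes[0]) - t0) * 1000.0
    return None


def max_inst_freq(rec: EphysRecording, window_s: float = 0.1) -> float | None:
    """Maximum instantaneous firing frequency (Hz) in the first 100 ms.

    Max over depolarizing steps of 1/ISI among spike pairs that both fall
    within ``window_s`` of step onset; None when no step has two such
    spikes.
    """
    t0, _ = _step_window(rec)
    best = None
    for current in _depolarizing_steps(rec):
        spikes = detect_spikes(rec.step_sweeps[current], window=(t0, t0 + window_s))
        if len(spikes) >= 2:
            f = float(1.0 / np.diff(spikes).min())
            best = f if best is None else max(best, f)
    return best


def capacitance(rec: EphysRecording, current_pA: float = -20.0) -> float | None:
    """Membrane capacitance (pF) from the charging curve of a small step.

    Fits V(t) = V0 + dV*(1 - exp(-t/tau)) over the first 150 ms of the
    ``current_pA`` step; R = |dV / I| and C = tau / R.  An approximation
    of charge-integration methods; None if the sweep is absent or the fit
    fails.
    """
    sweep = rec.step_sweeps.get(current_pA)
    if sweep is None:
        return None
    t0, _ = _step_window(rec)
    base = _baseline(sweep, t0)
    m = (sweep.time >= t0) & (sweep.time < t0 + 0.15)
    t = sweep.time[m] - t0
    v = sweep.vm[m] - base

    def charging(t, dv, tau):
        return dv * (1.0 - np.exp(-t / tau))

    try:
        (dv, tau), _ = optimize.curve_fit(
            charging, t, v, p0=(v[-1] if v[-1] != 0 else -1.0, 0.02),
            bounds=([-np.inf, 1e-5], [np.inf, 1.0]), maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return None
    r_ohm = abs(dv * 1e-3 / (current_pA * 1e-12))  # mV/pA -> ohm
    if r_ohm == 0:
        return None
    return float(tau / r_ohm * 1e12)  # F -> pF


@dataclass
class EphysFeatureSet:
    """Per-cell baseline intrinsic properties."""

    cell: str
    sag_mV: float | None = None
    ramp_ratio: float | None = None
    firing_delay_ms: float | None = None
    max_freq_inst_hz: float | None = None
    capacitance_pF: float | None = None
    region: str = ""

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sag_mV": self.sag_mV,
            "ramp_ratio": self.ramp_ratio,
            "firing_delay_ms": self.firing_delay_ms,
            "max_freq_inst_hz": self.max_freq_inst_hz,
            "capacitance_pF": self.capacitance_pF,
        }


def extract_features(rec: EphysRecording) -> EphysFeatureSet:
    """All baseline features of one recording; missing ones are None."""
    return EphysFeatureSet(
        cell=rec.cell,
        sag_mV=sag_amplitude(rec),
        ramp_ratio=ramp_ratio(rec),
        firing_delay_ms=firing_delay(rec),
        max_freq_inst_hz=max_inst_freq(rec),
        capacitance_pF=capacitance(rec),
        region=rec.region,
    )


@dataclass
class PspMetrics:
    """Optogenetically evoked postsynaptic potential metrics."""

    epsp_peak_mV: float
    ipsp_trough_mV: float
    epsp_latency_ms: float | None
    ipsp_trough_latency_ms: float | None
    ipsp_decay_tau_s: float | None
    voltage_area_mV_s: float
    has_epsp: bool
    has_ipsp: bool
    iei_pre_s: float | None = None
    iei_post_s: float | None = None


def _mean_iei(spikes: np.ndarray) -> float | None:
    if len(spikes) < 2:
        return None
    return float(np.diff(spikes).mean())


def psp_metrics(
    rec: EphysRecording,
    epsp_window_s: float = 0.1,
    area_window_s: float = 5.5,
    baseline_s: float = 5.0,
    detection_sd: float = 5.0,
) -> PspMetrics:
    """EPSP/IPSP metrics from the averaged optogenetic-response sweep.

    The 5 s before the first light pulse define the baseline (mean) and
    its noise SD.  The EPSP peak is the largest deflection above baseline
    within 100 ms of the first pulse (fast, glutamate-like window); the
    IPSP trough is the largest deflection below baseline anywhere within
    5.5 s (the IPSPs here have slow, neuropeptide-like kinetics).  A
    deflection counts as a PSP when it exceeds ``detection_sd`` baseline
    SDs (the default of 5 sits above the expected extremum of smoothed
    noise over the 5.5-s search window).  The IPSP decay tau is a single-exponential least-squares fit
    from the trough until the first return to baseline (capped at
    5.5 s).  Voltage area is the signed trapezoidal integral of
    (Vm - baseline) over [0, 5.5] s from the first pulse.  Mean
    inter-event intervals 5 s before/after light onset are attached when
    a constant-current firing sweep is present.
    """
    if rec.opto_sweep is None or rec.opto_pulses is None or len(rec.opto_pulses) == 0:
        raise ValueError("recording has no optogenetic-response sweep")
    sweep = rec.opto_sweep
    t_on = float(rec.opto_pulses[0])
    pre = (sweep.time >= t_on - baseline_s) & (sweep.time < t_on)
    if not pre.any():
        raise ValueError("need a 5 s pre-stimulus baseline")
    base = float(sweep.vm[pre].mean())
    v_smooth = _smooth(sweep.vm, sweep.fs, 0.010)
    noise_sd = float(np.std(v_smooth[pre]))
    d = v_smooth - base

    m_fast = (sweep.time >= t_on) & (sweep.time < t_on + epsp_window_s)
    m_area = (sweep.time >= t_on) & (sweep.time <= t_on + area_window_s)

    i_peak = np.flatnonzero(m_fast)[np.argmax(d[m_fast])]
    epsp_peak = float(d[i_peak])
    i_trough = np.flatnonzero(m_area)[np.argmin(d[m_area])]
    ipsp_trough = float(d[i_trough])

    thresh = detection_sd * noise_sd
    has_epsp = epsp_peak > thresh
    has_ipsp = ipsp_trough < -thresh

    epsp_latency = (float(sweep.time[i_peak]) - t_on) * 1000.0 if has_epsp else None
    ipsp_latency = (float(sweep.time[i_trough]) - t_on) * 1000.0 if has_ipsp else None

    tau = None
    if has_ipsp:
        after = np.flatnonzero((sweep.time > sweep.time[i_trough]) & (d >= 0))
        t_end = sweep.time[after[0]] if len(after) else t_on + area_window_s
        m_fit = (sweep.time >= sweep.time[i_trough]) & (
            sweep.time <= min(t_end, t_on + area_window_s)
        )
        tf = sweep.time[m_fit] - sweep.time[i_trough]
        vf = d[m_fit]
        if len(tf) >= 5:
            try:
                (amp, tau_fit), _ = optimize.curve_fit(
                    lambda t, a, tau: a * np.exp(-t / tau),
                    tf, vf, p0=(ipsp_trough, 1.0),
                    bounds=([-np.inf, 1e-4], [0.0, 60.0]), maxfev=2000,
                )
                tau = float(tau_fit)
            except (RuntimeError, ValueError):
                tau = None

    area = float(np.trapezoid(sweep.vm[m_area] - base, sweep.time[m_area]))

    iei_pre = iei_post = None
    if rec.firing_sweep is not None and rec.firing_light_onset is not None:
        t_l = rec.firing_light_onset
        spikes = detect_spikes(rec.firing_sweep)
        iei_pre = _mean_iei(spikes[(spikes >= t_l - 5.0) & (spikes < t_l)])
        iei_post = _mean_iei(spikes[(spikes >= t_l) & (spikes < t_l + 5.0)])

    return PspMetrics(
        epsp_peak_mV=epsp_peak,
        ipsp_trough_mV=ipsp_trough,
        epsp_latency_ms=epsp_latency,
        ipsp_trough_latency_ms=ipsp_latency,
        ipsp_decay_tau_s=tau,
        voltage_area_mV_s=area,
        has_epsp=has_epsp,
        has_ipsp=has_ipsp,
        iei_pre_s=iei_pre,
        iei_post_s=iei_post,
    )


def classify_opto_response(
    metrics: PspMetrics,
    use_firing: bool = True,
    resolve_mixed: bool = False,
) -> str:
    """Excitation/inhibition/mixed/none call for the light response.

    Firing data take precedence when present: a decrease in inter-event
    interval (faster firing) is an excitation, an increase an
    inhibition.  Otherwise the PSP rule applies: EPSP only -> excitation,
    IPSP only -> inhibition, both -> mixed, neither -> none.  With
    ``resolve_mixed`` (used for dendrogram annotation) a mixed response
    collapses to excitation when the total voltage area over 0-5.5 s is
    positive, inhibition when negative.
    """
    if use_firing and metrics.iei_pre_s is not None and metrics.iei_post_s is not None:
        if metrics.iei_post_s < metrics.iei_pre_s:
            return "excitation"
        if metrics.iei_post_s > metrics.iei_pre_s:
            return "inhibition"
        return "none"
    if metrics.has_epsp and metrics.has_ipsp:
        if resolve_mixed:
            return "excitation" if metrics.voltage_area_mV_s > 0 else "inhibition"
        return "mixed"
    if metrics.has_epsp:
        return "excitation"
    if metrics.has_ipsp:
        return "inhibition"
    return "none"


#: feature menus by region: amygdala/stria-terminalis cells separate on
#: sag/ramp/delay/frequency; for posterior basolateral amygdala the ramp
#: ratio is replaced by capacitance (pyramidal vs interneuron contrast)
FEATURE_MENUS: dict[str, tuple[str, ...]] = {
    "CeA": ("ramp_ratio", "max_freq_inst_hz", "firing_delay_ms", "sag_mV"),
    "BNST": ("ramp_ratio", "max_freq_inst_hz", "firing_delay_ms", "sag_mV"),
    "BLP": ("capacitance_pF", "max_freq_inst_hz", "firing_delay_ms", "sag_mV"),
}


def cluster_baseline(
    features: Sequence[EphysFeatureSet],
    feature_names: Sequence[str] | None = None,
    region: str | None = None,
    n_clusters: int = 2,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Ward-linkage clustering of cells on max-min-normalized features.

    Rows with any missing feature are dropped (their cell ids are
    reported).  Each feature is normalized to [0, 1] by its min/max; a
    constant feature is an error naming the feature.

    Returns ``(labels, linkage_matrix, used_cells)``; labels are 1-based
    over the retained cells, cut into ``n_clusters`` flat clusters.
    """
    if feature_names is None:
        feature_names = FEATURE_MENUS.get(region or "CeA", FEATURE_MENUS["CeA"])
    rows, cells = [], []
    for fs in features:
        d = fs.as_dict()
        vals = [d[name] for name in feature_names]
        if any(v is None or not np.isfinite(v) for v in vals):
            continue
        rows.append(vals)
        cells.append(fs.cell)
    X = np.asarray(rows, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 cells with complete features")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    if (span == 0).all():
        # identical cells: degenerate zero-height tree rather than an error
        Xn = np.zeros_like(X)
    else:
        for j, name in enumerate(feature_names):
            if span[j] == 0:
                raise ValueError(
                    f"constant feature {name!r}: max-min normalization undefined"
                )
        Xn = (X - lo) / span
    Z = hierarchy.linkage(Xn, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z, cells
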