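"""Intrinsic-property extraction, PSP metrics, and baseline clustering."""

import dataclasses

import numpy as np
import pytest

from sociodyn.ephys import (
    EphysFeatureSet,
    EphysRecording,
    PspMetrics,
    StepProtocol,
    Sweep,
    classify_opto_response,
    cluster_baseline,
    detect_spikes,
    extract_features,
    firing_delay,
    max_inst_freq,
    psp_metrics,
    ramp_ratio,
    sag_amplitude,
)
from sociodyn.simulate import ARCHETYPES, gen_ephys_cell

PROTO = StepProtocol()
FS = 10_000.0
TIME = np.arange(0.0, PROTO.sweep_duration, 1.0 / FS)
IN_STEP = (TIME >= PROTO.step_onset) & (TIME < PROTO.step_offset)


def flat_sweep(level=-70.0):
    return Sweep(time=TIME.copy(), vm=np.full_like(TIME, level))


def step_sweep(defl, base=-70.0):
    vm = np.full_like(TIME, base)
    vm[IN_STEP] += defl if np.isscalar(defl) else defl[IN_STEP]
    return Sweep(time=TIME.copy(), vm=vm)


def recording(sweeps):
    return EphysRecording(cell="c", step_sweeps=sweeps, protocol=PROTO)


class TestSag:
    def test_arithmetic_on_constructed_hyperpolarization(self):
        # dips to -100 mV then settles at -90 mV -> sag 10 mV
        t_rel = np.where(IN_STEP, TIME - PROTO.step_onset, 0.0)
        defl = np.where(
            t_rel < 0.03,
            (-30.0) * (1 - np.cos(np.pi * t_rel / 0.03)) / 2,
            -20.0 - 10.0 * np.exp(-(t_rel - 0.03) / 0.1),
        )
        rec = recording({-120.0: step_sweep(defl)})
        assert sag_amplitude(rec) == pytest.approx(10.0, abs=0.1)

    def test_ohmic_cell_has_zero_sag(self):
        rec = recording({-120.0: step_sweep(-18.0)})
        assert sag_amplitude(rec) == pytest.approx(0.0, abs=0.05)

    def test_missing_sweep_is_an_error(self):
        rec = recording({-100.0: step_sweep(-15.0)})
        with pytest.raises(ValueError, match="sag"):
            sag_amplitude(rec)

    def test_planted_sag_recovered_under_noise(self):
        arch = dataclasses.replace(
            ARCHETYPES["late_firing"], sag_mV=10.0, noise_sd_mV=0.2
        )
        errs = []
        for seed in range(10):
            rec, truth = gen_ephys_cell(arch, seed=seed, with_opto=False)
            errs.append(abs(sag_amplitude(rec) - truth["sag_mV"]))
        assert max(errs) < 0.5


class TestRampRatio:
    def test_flat_plateau_gives_unity(self):
        rec = recording({-120.0: step_sweep(-18.0), 40.0: step_sweep(6.0)})
        assert ramp_ratio(rec) == pytest.approx(1.0, abs=1e-6)

    def test_ramping_response_ratio_arithmetic(self):
        # early-window deflection 8 mV, late-window 12 mV -> 1.5
        t_rel = np.where(IN_STEP, TIME - PROTO.step_onset, 0.0)
        b = (12.0 - 8.0) / 0.8
        a = 8.0 - 0.15 * b
        rec = recording({40.0: step_sweep(a + b * t_rel)})
        assert ramp_ratio(rec) == pytest.approx(1.5, abs=1e-3)

    def test_no_subthreshold_step_flags_missing(self):
        vm = np.full_like(TIME, -70.0)
        vm[IN_STEP] += 10.0
        spike_idx = np.flatnonzero(IN_STEP)[1000:1010]
        vm[spike_idx] = 30.0
        rec = recording({20.0: Sweep(time=TIME.copy(), vm=vm)})
        assert ramp_ratio(rec) is None

    def test_planted_ratio_recovered_across_noise_levels(self):
        for noise in (0.1, 0.3, 0.5):
            arch = dataclasses.replace(ARCHETYPES["late_firing"], noise_sd_mV=noise)
            rec, truth = gen_ephys_cell(arch, seed=1, with_opto=False)
            assert ramp_ratio(rec) == pytest.approx(truth["ramp_ratio"], abs=0.05)


class TestFiringDelayAndFrequency:
    def spiking_sweep(self, spike_times):
        vm = np.full_like(TIME, -60.0)
        for ts in spike_times:
            m = (TIME >= ts) & (TIME < ts + 0.002)
            vm[m] = 30.0
        return Sweep(time=TIME.copy(), vm=vm)

    def test_first_spike_time_at_rheobase(self):
        rec = recording(
            {
                20.0: step_sweep(3.0),
                40.0: self.spiking_sweep([PROTO.step_onset + 0.25]),
                60.0: self.spiking_sweep([PROTO.step_onset + 0.05]),
            }
        )
        # rheobase = 40 pA (lowest spiking step), not the earlier-firing 60 pA
        assert firing_delay(rec) == pytest.approx(250.0, abs=1.0)

    def test_two_spikes_ten_ms_apart_give_100_hz(self):
        rec = recording(
            {40.0: self.spiking_sweep([PROTO.step_onset + 0.02, PROTO.step_onset + 0.03])}
        )
        assert max_inst_freq(rec) == pytest.approx(100.0, rel=0.02)

    def test_single_spike_per_step_gives_missing_frequency(self):
        rec = recording({40.0: self.spiking_sweep([PROTO.step_onset + 0.02])})
        assert max_inst_freq(rec) is None

    def test_no_spikes_anywhere_gives_missing_delay(self):
        rec = recording({40.0: step_sweep(5.0)})
        assert firing_delay(rec) is None

    def test_spike_detection_respects_refractory(self):
        sweep = self.spiking_sweep([0.5])
        # the 2-ms plateau produces one crossing, not many
        assert len(detect_spikes(sweep)) == 1

    def test_immediate_onset_archetype_fires_early(self):
        rec, truth = gen_ephys_cell(ARCHETYPES["interneuron"], seed=2, with_opto=False)
        assert firing_delay(rec) < 20.0

    def test_planted_burst_frequency_recovered(self):
        rec, truth = gen_ephys_cell(ARCHETYPES["regular_firing"], seed=3, with_opto=False)
        assert max_inst_freq(rec) == pytest.approx(truth["max_freq_inst_hz"], abs=5.0)


class TestOffsetInvariance:
    def test_features_invariant_to_constant_vm_offset(self):
        arch = ARCHETYPES["late_firing"]
        rec, _ = gen_ephys_cell(arch, seed=4, with_opto=False)
        shifted = EphysRecording(
            cell="s",
            step_sweeps={
                c: Sweep(time=s.time, vm=s.vm + 7.0) for c, s in rec.step_sweeps.items()
            },
            protocol=rec.protocol,
        )
        assert sag_amplitude(shifted) == pytest.approx(sag_amplitude(rec), abs=1e-9)
        assert ramp_ratio(shifted) == pytest.approx(ramp_ratio(rec), abs=1e-9)
        # +7 mV moves spike peaks but not their threshold crossings materially
        assert firing_delay(shifted) == pytest.approx(firing_delay(rec), abs=1.0)


class TestPspMetrics:
    def test_flat_sweep_classified_none(self):
        rec, _ = gen_ephys_cell(
            dataclasses.replace(
                ARCHETYPES["late_firing"], psp_type="none", psp_amplitude_mV=0.0
            ),
            seed=5,
        )
        m = psp_metrics(rec)
        assert not m.has_epsp and not m.has_ipsp
        assert abs(m.voltage_area_mV_s) < 0.5
        assert classify_opto_response(m) == "none"

    def test_planted_ipsp_tau_recovered(self):
        errs = []
        for seed in range(5):
            arch = dataclasses.replace(
                ARCHETYPES["regular_firing"], ipsp_tau_s=1.0, noise_sd_mV=0.1
            )
            rec, truth = gen_ephys_cell(arch, seed=seed)
            m = psp_metrics(rec)
            errs.append(abs(m.ipsp_decay_tau_s - 1.0))
        assert max(errs) < 0.1

    def test_pure_epsp_has_positive_area(self):
        rec, _ = gen_ephys_cell(ARCHETYPES["late_firing"], seed=6)
        m = psp_metrics(rec)
        assert m.has_epsp and not m.has_ipsp
        assert m.voltage_area_mV_s > 0

    def test_no_opto_sweep_is_an_error(self):
        rec, _ = gen_ephys_cell(ARCHETYPES["late_firing"], seed=7, with_opto=False)
        with pytest.raises(ValueError):
            psp_metrics(rec)


class TestOptoClassification:
    def metrics(self, **kw):
        base = dict(
            epsp_peak_mV=0.0,
            ipsp_trough_mV=0.0,
            epsp_latency_ms=None,
            ipsp_trough_latency_ms=None,
            ipsp_decay_tau_s=None,
            voltage_area_mV_s=0.0,
            has_epsp=False,
            has_ipsp=False,
        )
        base.update(kw)
        return PspMetrics(**base)

    def test_epsp_only_is_excitation(self):
        m = self.metrics(epsp_peak_mV=3.0, has_epsp=True, voltage_area_mV_s=1.0)
        assert classify_opto_response(m) == "excitation"

    def test_ipsp_only_is_inhibition(self):
        m = self.metrics(ipsp_trough_mV=-4.0, has_ipsp=True, voltage_area_mV_s=-2.0)
        assert classify_opto_response(m) == "inhibition"

    def test_mixed_with_negative_area_annotates_inhibition(self):
        m = self.metrics(
            epsp_peak_mV=2.0, ipsp_trough_mV=-4.0, has_epsp=True, has_ipsp=True,
            voltage_area_mV_s=-3.0,
        )
        assert classify_opto_response(m) == "mixed"
        assert classify_opto_response(m, resolve_mixed=True) == "inhibition"

    def test_iei_decrease_is_excitation_and_takes_precedence(self):
        m = self.metrics(
            ipsp_trough_mV=-4.0, has_ipsp=True, iei_pre_s=0.2, iei_post_s=0.1
        )
        assert classify_opto_response(m) == "excitation"
        assert classify_opto_response(m, use_firing=False) == "inhibition"

    def test_iei_increase_is_inhibition(self):
        m = self.metrics(iei_pre_s=0.1, iei_post_s=0.3)
        assert classify_opto_response(m) == "inhibition"

    def test_every_synthetic_cell_receives_exactly_one_class(self):
        for name, arch in ARCHETYPES.items():
            rec, _ = gen_ephys_cell(arch, seed=8)
            cls = classify_opto_response(psp_metrics(rec))
            assert cls in ("excitation", "inhibition", "mixed", "none")

    def test_firing_sweep_iei_extraction(self):
        arch = dataclasses.replace(
            ARCHETYPES["regular_firing"], iei_pre_s=0.2, iei_post_s=0.4
        )
        rec, _ = gen_ephys_cell(arch, seed=9)
        m = psp_metrics(rec)
        assert m.iei_pre_s == pytest.approx(0.2, abs=0.01)
        assert m.iei_post_s == pytest.approx(0.4, abs=0.01)
        assert classify_opto_response(m) == "inhibition"


class TestBaselineClustering:
    def features(self, n, sag, ramp, delay, freq, prefix):
        out = []
        rng = np.random.default_rng(hash(prefix) % 2**31)
        for i in range(n):
            out.append(
                EphysFeatureSet(
                    cell=f"{prefix}{i}",
                    sag_mV=sag + rng.normal(0, 0.1),
                    ramp_ratio=ramp + rng.normal(0, 0.01),
                    firing_delay_ms=delay + rng.normal(0, 2),
                    max_freq_inst_hz=freq + rng.normal(0, 1),
                )
            )
        return out

    def test_two_separated_archetypes_recovered_perfectly(self):
        cells = self.features(20, 8.0, 2.0, 250.0, 40.0, "late") + self.features(
            20, 2.0, 1.0, 30.0, 80.0, "reg"
        )
        labels, Z, used = cluster_baseline(cells)
        assert len(used) == 40
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_duplicated_cell_yields_zero_height_tree(self):
        one = EphysFeatureSet(
            cell="x", sag_mV=5.0, ramp_ratio=1.5, firing_delay_ms=100.0,
            max_freq_inst_hz=50.0,
        )
        cells = [dataclasses.replace(one, cell=f"x{i}") for i in range(10)]
        labels, Z, _ = cluster_baseline(cells)
        assert Z[:, 2].max() == 0.0

    def test_constant_feature_errors_naming_it(self):
        cells = self.features(5, 3.0, 1.5, 100.0, 50.0, "a")
        for c in cells:
            c.sag_mV = 4.0
        with pytest.raises(ValueError, match="sag_mV"):
            cluster_baseline(cells)

    def test_normalization_maps_extremes_to_unit_interval(self):
        cells = self.features(10, 3.0, 1.5, 100.0, 50.0, "b")
        vals = np.array([[c.sag_mV, c.ramp_ratio, c.firing_delay_ms, c.max_freq_inst_hz] for c in cells])
        labels, Z, used = cluster_baseline(cells)
        # re-derive the normalized matrix and check its range
        Xn = (vals - vals.min(0)) / (vals.max(0) - vals.min(0))
        assert Xn.min() == 0.0 and Xn.max() == 1.0

    def test_rows_with_missing_features_dropped(self):
        cells = self.features(5, 3.0, 1.5, 100.0, 50.0, "c")
        cells[0].ramp_ratio = None
        labels, Z, used = cluster_baseline(cells)
        assert len(used) == 4

    def test_blp_menu_uses_capacitance(self):
        cells = self.features(6, 3.0, 1.5, 100.0, 50.0, "d")
        for i, c in enumerate(cells):
            c.capacitance_pF = 100.0 + 10 * i
        labels, Z, used = cluster_baseline(cells, region="BLP")
        assert len(used) == 6


class TestEndToEndFeatureRecovery:
    def test_extract_features_on_all_archetypes(self):
        for name, arch in ARCHETYPES.items():
            rec, truth = gen_ephys_cell(arch, seed=10, with_opto=False)
            fs = extract_features(rec)
            assert fs.sag_mV == pytest.approx(truth["sag_mV"], abs=0.5)
            assert fs.ramp_ratio == pytest.approx(truth["ramp_ratio"], abs=0.05)
            assert fs.firing_delay_ms == pytest.approx(truth["firing_delay_ms"], abs=10.0)
            assert fs.max_freq_inst_hz == pytest.approx(truth["max_freq_inst_hz"], abs=5.0)
            assert fs.capacitance_pF == pytest.approx(truth["capacitance_pF"], rel=0.1)
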