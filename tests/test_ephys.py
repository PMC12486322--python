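"""Recording analysis: CV classes, spike detection, rates, thresholds."""

import dataclasses

import numpy as np
import pytest

from somatomap.ephys import (
    ABETA,
    ADELTA,
    ClassifierConfig,
    Epoch,
    SpikeTrain,
    StimulusProtocol,
    classify_afferent,
    classify_by_cv,
    classify_fiber,
    conduction_velocity,
    detect_spikes,
    insensitive_proportion,
    mechanical_threshold,
    phase_spike_rates,
)
from somatomap.synth import generate_fiber_response, make_fiber, synthesize_trace


class TestConductionVelocity:
    @pytest.mark.parametrize(
        "distance,delay,expected",
        [(10.0, 1.0, 10.0), (12.0, 0.77, 15.58), (8.0, 1.6, 5.0)],
    )
    def test_distance_over_delay(self, distance, delay, expected):
        assert conduction_velocity(distance, delay) == pytest.approx(
            expected, abs=0.005
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            conduction_velocity(0.0, 1.0)
        with pytest.raises(ValueError):
            conduction_velocity(5.0, -1.0)

    @pytest.mark.parametrize(
        "cv,expected", [(15.58, ABETA), (5.14, ADELTA), (10.0, ADELTA)]
    )
    def test_cv_class_boundaries(self, cv, expected):
        assert classify_by_cv(cv) == expected

    def test_band_partition_has_no_gap_or_overlap(self):
        # everything above the Aδ lower bound is exactly Aδ or Aβ
        for cv in np.linspace(1.5, 30.0, 571):
            assert classify_by_cv(float(cv)) in (ABETA, ADELTA)
        assert classify_by_cv(1.4999) == "unclassified"


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        train = detect_spikes(np.zeros(1000), 1 / 20000)
        assert len(train) == 0

    def test_injected_spikes_recovered_within_one_sample(self):
        fs = 20000.0
        injected = [0.010, 0.025, 0.040]
        _, v = synthesize_trace(injected, 0.05, fs_hz=fs, seed=1)
        train = detect_spikes(v, 1 / fs)
        assert len(train) == 3
        np.testing.assert_allclose(train.times, injected, atol=1.5 / fs)

    def test_refractory_merges_close_spikes(self):
        fs = 20000.0
        _, v = synthesize_trace([0.0100, 0.0105], 0.03, fs_hz=fs, seed=2)
        train = detect_spikes(v, 1 / fs)  # 0.5 ms apart, 1 ms refractory
        assert len(train) == 1

    def test_bad_sampling_interval_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(10), 0.0)


def two_epoch_protocol():
    return StimulusProtocol(
        epochs=(
            Epoch("ramp", 0.0, 1.0, velocity_mm_s=1.5, force_mN=40.0),
            Epoch("hold", 1.0, 3.0, force_mN=40.0),
        )
    )


class TestPhaseRates:
    def test_spikes_only_in_ramp_leave_hold_at_zero(self):
        counts = phase_spike_rates(
            SpikeTrain("f", [0.1, 0.5, 0.9]), two_epoch_protocol()
        )
        assert counts[0].count == 3
        assert counts[1].count == 0

    def test_rate_is_count_over_duration(self):
        spikes = SpikeTrain("f", np.linspace(1.05, 2.95, 10))
        counts = phase_spike_rates(spikes, two_epoch_protocol())
        assert counts[1].count == 10
        assert counts[1].rate_hz == pytest.approx(5.0)

    def test_counts_match_bruteforce_and_conserve(self, protocol, rng):
        times = np.sort(rng.uniform(0, protocol.duration_s + 1.0, 200))
        times = times[np.diff(np.concatenate([[-1], times])) > 0]
        spikes = SpikeTrain("f", times)
        counts = phase_spike_rates(spikes, protocol)
        brute_total = 0
        for ec in counts:
            brute = sum(
                1 for t in times if ec.epoch.start_s <= t < ec.epoch.end_s
            )
            assert ec.count == brute
            brute_total += brute
        outside = sum(
            1
            for t in times
            if not any(e.start_s <= t < e.end_s for e in protocol.epochs)
        )
        assert brute_total + outside == len(times)

    def test_boundary_spike_counted_once(self):
        prot = StimulusProtocol(
            epochs=(
                Epoch("ramp", 0.0, 1.0, velocity_mm_s=1.5, force_mN=40.0),
                Epoch("hold", 1.0, 2.0, force_mN=40.0),
            )
        )
        counts = phase_spike_rates(SpikeTrain("f", [1.0]), prot)
        assert [ec.count for ec in counts] == [0, 1]


class TestMechanicalThreshold:
    def vibration_protocol(self):
        return StimulusProtocol(
            epochs=(
                Epoch("vibration-ramp", 0.0, 5.0, frequency_hz=50.0,
                      amplitude_mN=50.0),
            )
        )

    def test_no_spikes_undefined(self):
        assert mechanical_threshold(
            SpikeTrain("f", []), self.vibration_protocol()
        ) is None

    def test_linear_envelope_evaluated_at_first_spike(self):
        thr = mechanical_threshold(
            SpikeTrain("f", [0.75, 1.5]), self.vibration_protocol()
        )
        assert thr == pytest.approx(7.5)

    def test_spike_outside_force_epoch_warns(self):
        prot = StimulusProtocol(
            epochs=(
                Epoch("vibration-ramp", 1.0, 5.0, amplitude_mN=50.0),
            )
        )
        with pytest.warns(UserWarning, match="undefined"):
            assert mechanical_threshold(SpikeTrain("f", [0.5]), prot) is None

    def test_synthetic_sam_threshold_recovered(self, protocol):
        # generative threshold 7.5 mN, seed-averaged recovery within 1 mN
        recovered = []
        for seed in range(20):
            model = dataclasses.replace(
                make_fiber("SAM", seed=seed), threshold_mN=7.5, seed=seed
            )
            train = generate_fiber_response(model, protocol)
            recovered.append(mechanical_threshold(train, protocol))
        assert np.mean(recovered) == pytest.approx(7.5, abs=1.0)

    def test_threshold_monotone_in_model_threshold(self, protocol):
        means = []
        for thr in (5.0, 10.0, 20.0):
            vals = []
            for seed in range(15):
                model = dataclasses.replace(
                    make_fiber("SAM", seed=seed), threshold_mN=thr, seed=seed
                )
                train = generate_fiber_response(model, protocol)
                vals.append(mechanical_threshold(train, protocol))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestClassifyAfferent:
    def counts_for(self, spikes, protocol):
        return phase_spike_rates(spikes, protocol)

    def test_ramp_only_abeta_is_ram(self):
        counts = self.counts_for(
            SpikeTrain("f", [0.2, 0.6]), two_epoch_protocol()
        )
        assert classify_afferent(counts, ABETA) == "RAM"

    def test_sustained_hold_abeta_is_sam(self):
        counts = self.counts_for(
            SpikeTrain("f", [0.2, 1.4, 2.0, 2.6]), two_epoch_protocol()
        )
        assert classify_afferent(counts, ABETA) == "SAM"

    def test_tap_only_single_spike_is_tap_unit(self, protocol):
        tap = protocol.of_kind("manual-tap")[0]
        counts = self.counts_for(
            SpikeTrain("f", [tap.start_s + 0.01]), protocol
        )
        assert classify_afferent(counts, ABETA) == "tap-unit"

    def test_totally_silent_is_mechano_insensitive(self, protocol):
        counts = self.counts_for(SpikeTrain("f", []), protocol)
        assert classify_afferent(counts, ADELTA) == "mechano-insensitive"

    def test_adelta_low_threshold_with_slow_response_is_dhair(self, protocol):
        slow = min(
            protocol.of_kind("ramp"), key=lambda e: e.velocity_mm_s
        )
        counts = self.counts_for(
            SpikeTrain("f", [slow.start_s + 0.01]), protocol
        )
        assert classify_afferent(counts, ADELTA, threshold_mN=0.5) == "D-hair"
        assert classify_afferent(counts, ADELTA, threshold_mN=5.0) == "AM"

    def test_missing_cv_class_rejected(self, protocol):
        counts = self.counts_for(SpikeTrain("f", [0.2]), protocol)
        with pytest.raises(ValueError, match="CV class"):
            classify_afferent(counts, None)


class TestEndToEndRecovery:
    @pytest.mark.parametrize(
        "label,minimum",
        [("RAM", 0.95), ("SAM", 0.95), ("mechano-insensitive", 0.95),
         ("tap-unit", 0.90)],
    )
    def test_classifier_recovers_generating_label(self, protocol, label, minimum):
        hits = 0
        n = 60
        for seed in range(n):
            model = make_fiber(label, seed=seed)
            train = generate_fiber_response(model, protocol)
            record = classify_fiber(train, protocol, cv_m_s=model.cv_m_s)
            hits += record.afferent_class == label
        assert hits / n >= minimum


class TestInsensitiveProportion:
    def test_proportions_from_counts(self):
        table, pct = insensitive_proportion({
            "control": [True] * 10 + [False] * 28,
            "stoml3": [True] * 33 + [False] * 20,
        })
        np.testing.assert_array_equal(table.counts, [[10, 28], [33, 20]])
        assert pct["control"] == pytest.approx(26.3, abs=0.05)
        assert pct["stoml3"] == pytest.approx(62.3, abs=0.05)

    def test_all_sensitive_is_zero_percent(self):
        _, pct = insensitive_proportion({
            "a": [False] * 5, "b": [False] * 7,
        })
        assert pct == {"a": 0.0, "b": 0.0}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            insensitive_proportion({"a": [], "b": [True]})

    def test_configured_fraction_recovered(self, protocol, rng):
        # a population with 60% mechano-insensitive fibres
        flags = []
        for i in range(120):
            label = "mechano-insensitive" if rng.random() < 0.6 else "RAM"
            model = make_fiber(label, seed=i)
            train = generate_fiber_response(model, protocol)
            record = classify_fiber(train, protocol, cv_m_s=model.cv_m_s)
            flags.append(record.afferent_class == "mechano-insensitive")
        frac = np.mean(flags)
        assert frac == pytest.approx(0.6, abs=3 * np.sqrt(0.6 * 0.4 / 120))
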