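"""Synthetic trace generator: determinism, signatures, session structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sealpatch import (
    BehaviorParams,
    SessionScript,
    amplitude_analyzer,
    differentiator,
    dvdt_amplitude,
    frequency_analyzer,
    generate_behavior_trace,
    generate_rssi_samples,
    generate_session,
)
from sealpatch.synthetic import default_params
from tests.conftest import noiseless_params


class TestGenerateBehaviorTrace:
    def test_deterministic_under_seed(self, behavior_label):
        a = generate_behavior_trace(default_params(behavior_label), 30.0, seed=42)
        b = generate_behavior_trace(default_params(behavior_label), 30.0, seed=42)
        assert np.array_equal(a.voltages, b.voltages)
        assert np.array_equal(a.times, b.times)

    def test_different_seeds_differ(self):
        a = generate_behavior_trace(default_params("stop"), 30.0, seed=1)
        b = generate_behavior_trace(default_params("stop"), 30.0, seed=2)
        assert not np.array_equal(a.voltages, b.voltages)

    def test_sample_count_is_floor_of_duration_over_interval(self):
        trace = generate_behavior_trace(default_params("rolling"), 30.0, seed=0)
        assert len(trace) == 187  # floor(30 / 0.16)
        exact = generate_behavior_trace(default_params("rolling"), 20.0, seed=0)
        assert len(exact) == 125  # 20 / 0.16 exactly

    def test_stop_trace_amplitude_below_stop_bound(self):
        params = BehaviorParams("stop", 0.0, 0.0, noise_sd_v=0.01, dvdt_shape="flat")
        trace = generate_behavior_trace(params, 30.0, seed=1)
        assert amplitude_analyzer(trace) < 0.1

    def test_voltages_respect_supply_rail(self):
        params = BehaviorParams(
            "flapping", 0.625, 0.55, baseline_v=0.6, noise_sd_v=0.3,
            dvdt_shape="impulsive",
        )
        trace = generate_behavior_trace(params, 30.0, seed=3)
        assert trace.voltages.min() >= 0.0
        assert trace.voltages.max() <= 3.3

    def test_nyquist_violation_rejected(self):
        params = BehaviorParams("rolling", 3.2, 0.3, dvdt_shape="sine")
        with pytest.raises(ValueError, match="Nyquist"):
            generate_behavior_trace(params, 30.0)
        # biharmonic content at 2f must also clear Nyquist
        params2 = BehaviorParams("rolling", 1.8, 0.3, dvdt_shape="biharmonic")
        with pytest.raises(ValueError, match="Nyquist"):
            generate_behavior_trace(params2, 30.0)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_behavior_trace(default_params("stop"), 0.1)

    def test_quantized_trace_lands_on_adc_grid(self):
        trace = generate_behavior_trace(
            default_params("rolling"), 30.0, seed=5, quantize_bits=8
        )
        lsb = 3.3 / 255
        codes = np.round(trace.voltages / lsb)
        assert np.allclose(trace.voltages, codes * lsb, atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BehaviorParams("walking", 1.0, 0.5)
        with pytest.raises(ValueError):
            BehaviorParams("rolling", 1.0, 0.5, dvdt_shape="square")
        with pytest.raises(ValueError):
            BehaviorParams("rolling", 1.0, 2.0, baseline_v=3.0)  # leaves rail


class TestSignatures:
    def test_noiseless_defaults_satisfy_threshold_signature(self, behavior_label):
        """Feature triple of each label's default waveform sits on the
        correct side of every split it is bound by."""
        trace = generate_behavior_trace(noiseless_params(behavior_label), 30.0, seed=8)
        n = int(round(5.0 / 0.16))
        window = trace.slice(1, 1 + n)  # interior: central differences only
        deriv = differentiator(trace)
        amp = amplitude_analyzer(window)
        d = dvdt_amplitude(deriv.slice(1, 1 + n))
        if behavior_label == "stop":
            assert amp < 0.1
            return
        freq = frequency_analyzer(window)
        if behavior_label == "rolling":
            assert freq > 1 and amp > 0.5 and d < 3
        elif behavior_label == "flapping":
            assert freq < 1 and 0.4 <= amp <= 0.6 and d > 3
        else:  # sliding
            assert freq < 1 and 0.1 < amp < 0.5 and d < 3

    def test_amplitude_monotone_in_amplitude_param(self):
        amps = [0.2, 0.4, 0.6]
        outs = []
        for a in amps:
            p = BehaviorParams("rolling", 1.25, a, noise_sd_v=0.0, dvdt_shape="biharmonic")
            outs.append(amplitude_analyzer(generate_behavior_trace(p, 30.0, seed=0)))
        assert outs[0] < outs[1] < outs[2]

    def test_frequency_monotone_in_carrier_param(self):
        freqs = [0.5, 1.0, 2.0]
        outs = []
        for f in freqs:
            p = BehaviorParams("rolling", f, 0.5, noise_sd_v=0.0, dvdt_shape="sine")
            trace = generate_behavior_trace(p, 30.0, seed=0)
            outs.append(frequency_analyzer(trace))
        assert outs[0] < outs[1] < outs[2]


class TestGenerateSession:
    def test_two_bout_session_sample_count(self):
        trace, _ = generate_session(SessionScript([("stop", 10.0), ("rolling", 10.0)]))
        assert len(trace) == 125

    @settings(derandomize=True, max_examples=20)
    @given(
        durations=st.lists(
            st.floats(min_value=1.0, max_value=20.0), min_size=1, max_size=5
        ),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_truth_partitions_timeline(self, durations, seed):
        labels = ["stop", "rolling", "flapping", "sliding"]
        entries = [(labels[i % 4], d) for i, d in enumerate(durations)]
        script = SessionScript(entries, seed=seed)
        trace, truth = generate_session(script)
        assert truth[0].t_start_s == 0.0
        assert truth[-1].t_end_s == pytest.approx(script.total_duration_s)
        for a, b in zip(truth, truth[1:]):
            assert a.t_end_s == pytest.approx(b.t_start_s)
        assert len(trace) == math.floor(script.total_duration_s / 0.16 + 1e-9)

    def test_deterministic_under_seed(self):
        script = SessionScript([("rolling", 10.0), ("sliding", 10.0)], seed=13)
        a, _ = generate_session(script)
        b, _ = generate_session(script)
        assert np.array_equal(a.voltages, b.voltages)

    def test_empty_script_rejected(self):
        with pytest.raises(ValueError):
            SessionScript([])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            SessionScript([("stop", 0.0)])


class TestGenerateRssiSamples:
    def test_level_at_zero_distance(self):
        (sample,) = generate_rssi_samples(-31.1, 6.4, [0.0])
        assert sample.rssi_dbm == pytest.approx(-31.1)

    def test_one_decay_constant_multiplies_by_e(self):
        (sample,) = generate_rssi_samples(-31.1, 6.4, [6.4])
        assert sample.rssi_dbm == pytest.approx(-31.1 * math.e, rel=1e-9)
        assert sample.rssi_dbm == pytest.approx(-84.5, abs=0.1)

    def test_replicates_identical_under_fixed_seed(self):
        tables = [
            generate_rssi_samples(-31.1, 6.4, [0, 2, 4], noise_sd_db=2.0, seed=5)
            for _ in range(5)
        ]
        first = [(s.distance_m, s.rssi_dbm) for s in tables[0]]
        assert all([(s.distance_m, s.rssi_dbm) for s in t] == first for t in tables)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_rssi_samples(-31.1, 0.0, [0.0])
        with pytest.raises(ValueError):
            generate_rssi_samples(-31.1, 6.4, [-1.0])
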