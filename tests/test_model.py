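"""Generator matrix, waveform discretization and signal prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmtkit.model import (AcquisitionTiming, Protocol, SamplingPoint,
                          discretize_waveform, equilibrium_state,
                          generator_matrix, predict_mt_signal,
                          predict_protocol, propagate)
from qmtkit.params import TissueParameters
from qmtkit.pulses import GAMMA_HZ, MTPulseSpec, TrainSpec, b1_peak_from_flip

from _ode_oracle import propagate_ode
from conftest import random_tissue


class TestGeneratorMatrix:
    def test_first_row_zero_and_equilibrium_null_vector(self, cord_tissue):
        L = generator_matrix(cord_tissue, 0.0, 2e3)
        assert np.all(L[0] == 0.0)
        m_eq = equilibrium_state(cord_tissue)
        assert np.max(np.abs(L @ m_eq)) < 1e-12

    def test_saturation_coupling_antisymmetric(self, cord_tissue):
        omega1 = 100.0
        L = generator_matrix(cord_tissue, omega1, 2e3)
        assert L[3, 2] == -omega1
        assert L[2, 3] == omega1

    def test_off_resonance_rotation_terms(self, cord_tissue):
        L = generator_matrix(cord_tissue, 0.0, 3e3)
        assert L[1, 2] == pytest.approx(2.0 * np.pi * 3e3)
        assert L[2, 1] == pytest.approx(-2.0 * np.pi * 3e3)
        assert L[1, 1] == pytest.approx(-1.0 / cord_tissue.t2f)

    def test_relaxation_block_stable_over_random_draws(self):
        # all eigenvalues of the lower-right 4x4 block have Re <= 0
        rng = np.random.default_rng(7)
        blocks = []
        for _ in range(1000):
            t = random_tissue(rng)
            omega1 = rng.uniform(0.0, 2 * np.pi * GAMMA_HZ * 13e-6)
            offset = rng.uniform(1e3, 1e5)
            blocks.append(generator_matrix(t, omega1, offset)[1:, 1:])
        eig = np.linalg.eigvals(np.array(blocks))
        assert np.max(eig.real) <= 1e-10

    def test_degenerate_bpf_rejected(self):
        with pytest.raises(ValueError):
            TissueParameters(bpf=0.0, t2f=0.05, t2b=1e-5, kfb=2.0, r1f=1.0)
        with pytest.raises(ValueError):
            TissueParameters(bpf=1.0, t2f=0.05, t2b=1e-5, kfb=2.0, r1f=1.0)


class TestDiscretizeWaveform:
    def make_train(self, n=3, tau=5e-3, gap=2e-3):
        return TrainSpec(n, gap, MTPulseSpec(5e-6, tau, 2e3))

    def test_empty_train_single_delay_segment(self):
        wf = discretize_waveform(TrainSpec(0, 0.0, MTPulseSpec(1e-6, 1e-3, 0.0)),
                                 td=0.1, eta=1e-4)
        assert wf.segments == ((0.0, 0.1),)

    def test_total_duration_invariant(self):
        train = self.make_train()
        wf = discretize_waveform(train, td=0.05, eta=1e-4)
        expected = 3 * 5e-3 + 2 * 2e-3 + 0.05
        assert wf.total_duration == pytest.approx(expected, abs=1e-15)

    def test_gaps_are_single_zero_segments(self):
        wf = discretize_waveform(self.make_train(), td=0.05, eta=1e-4)
        zero_durations = [d for w, d in wf.segments if w == 0.0]
        assert zero_durations.count(2e-3) == 2
        assert zero_durations.count(0.05) == 1

    def test_power_integral_converges_with_refinement(self):
        # integral(omega1^2 dt) at eta = 100 us within 0.5% of eta = 1 us
        train = TrainSpec(1, 0.0, MTPulseSpec(12e-6, 15e-3, 2e3))
        vals = {}
        for eta in (100e-6, 1e-6):
            wf = discretize_waveform(train, td=0.0, eta=eta)
            vals[eta] = np.sum(wf.amplitudes() ** 2 * wf.durations())
        assert vals[100e-6] == pytest.approx(vals[1e-6], rel=5e-3)

    def test_unresolvable_pulse_raises(self):
        with pytest.raises(ValueError, match="eta"):
            discretize_waveform(self.make_train(tau=1e-4), td=0.0, eta=2e-4)


class TestPropagate:
    def test_zero_amplitude_preserves_equilibrium(self, cord_tissue):
        from qmtkit.model import PiecewiseWaveform
        wf = PiecewiseWaveform(((0.0, 0.3), (0.0, 1.2)))
        m_eq = equilibrium_state(cord_tissue)
        out = propagate(wf, cord_tissue, 2e3, m_eq)
        assert np.max(np.abs(out - m_eq)) < 1e-12

    def test_segment_splitting_is_semigroup(self, cord_tissue):
        from qmtkit.model import PiecewiseWaveform
        whole = PiecewiseWaveform(((3000.0, 4e-3), (0.0, 10e-3)))
        halves = PiecewiseWaveform(((3000.0, 2e-3), (3000.0, 2e-3),
                                    (0.0, 5e-3), (0.0, 5e-3)))
        m0 = equilibrium_state(cord_tissue)
        a = propagate(whole, cord_tissue, 2e3, m0)
        b = propagate(halves, cord_tissue, 2e3, m0)
        assert np.max(np.abs(a - b)) < 1e-13

    def test_matches_adaptive_ode_oracle_on_full_train(self, cord_tissue):
        train = TrainSpec(25, 15e-3, MTPulseSpec(b1_peak_from_flip(1100, 15e-3),
                                                 15e-3, 2e3))
        wf = discretize_waveform(train, td=18e-3, eta=500e-6)
        m0 = equilibrium_state(cord_tissue)
        ours = propagate(wf, cord_tissue, 2e3, m0)
        ref = propagate_ode(wf, cord_tissue, 2e3, m0)
        assert np.abs(ours[3] - ref[3]) / np.abs(ref[3]) < 1e-4


class TestPredictSignal:
    def test_no_saturation_gives_exactly_one(self, cord_tissue, train25, timing):
        pt0 = SamplingPoint(offset=2e3, b1_peak=0.0)
        assert predict_mt_signal(cord_tissue, pt0, train25, timing) == 1.0
        empty = TrainSpec(0, 15e-3, train25.pulse)
        pt = SamplingPoint(offset=2e3, b1_peak=5e-6)
        assert predict_mt_signal(cord_tissue, pt, empty, timing) == 1.0

    def test_monotone_saturation_in_train_length(self, cord_tissue, timing):
        b1 = b1_peak_from_flip(1100.0, 15e-3)
        pt = SamplingPoint(offset=2e3, b1_peak=b1)
        signals = []
        for n in range(5, 65, 5):
            train = TrainSpec(n, 15e-3, MTPulseSpec(b1, 15e-3, 2e3))
            signals.append(predict_mt_signal(cord_tissue, pt, train, timing))
        assert np.all(np.diff(signals) <= 1e-12)

    def test_steady_state_plateau(self, cord_tissue, timing, optimized_protocol):
        p = optimized_protocol.points[11]
        s = []
        for n in (200, 201):
            train = TrainSpec(n, 15e-3, optimized_protocol.train.pulse)
            s.append(predict_mt_signal(cord_tissue, p, train, timing))
        assert abs(s[0] - s[1]) < 1e-4

    def test_signal_in_unit_interval_and_high_offset_limit(self, cord_tissue,
                                                           train25, timing):
        b1 = b1_peak_from_flip(601.0, 15e-3)
        far = SamplingPoint(offset=100e3, b1_peak=b1)
        s = predict_mt_signal(cord_tissue, far, train25, timing)
        assert 0.0 < s <= 1.0
        assert s > 0.99

    def test_discretization_refinement_stability(self, cord_tissue,
                                                 optimized_protocol):
        # eta 100 us -> 10 us changes signals by < 0.2%
        coarse = predict_protocol(cord_tissue, optimized_protocol)
        fine_timing = AcquisitionTiming(eta=10e-6)
        fine_prot = Protocol(points=optimized_protocol.points,
                             train=optimized_protocol.train, timing=fine_timing)
        fine = predict_protocol(cord_tissue, fine_prot)
        assert np.max(np.abs(coarse - fine) / fine) < 2e-3


class TestPredictProtocol:
    def test_single_point_reduces_to_signal(self, cord_tissue, train25, timing):
        pt = SamplingPoint(offset=3e3, b1_peak=8e-6)
        prot = Protocol(points=(pt,), train=train25, timing=timing)
        assert predict_protocol(cord_tissue, prot)[0] == pytest.approx(
            predict_mt_signal(cord_tissue, pt, train25, timing), abs=1e-15)

    def test_permuting_points_permutes_signals(self, cord_tissue,
                                               optimized_protocol):
        base = predict_protocol(cord_tissue, optimized_protocol)
        perm = np.arange(optimized_protocol.k)[::-1]
        shuffled = Protocol(
            points=tuple(optimized_protocol.points[i] for i in perm),
            train=optimized_protocol.train, timing=optimized_protocol.timing)
        assert np.allclose(predict_protocol(cord_tissue, shuffled), base[perm],
                           rtol=0, atol=1e-15)

    def test_cached_engine_matches_generic_propagation(self, cord_tissue,
                                                       optimized_protocol):
        # the train-propagator caching must not change results beyond 1e-12
        engine = predict_protocol(cord_tissue, optimized_protocol)
        timing = optimized_protocol.timing
        m_eq = equilibrium_state(cord_tissue)
        for i in (0, 6, 13):
            vals = []
            for td in timing.td_list:
                wf = discretize_waveform(optimized_protocol.point_train(i),
                                         td, timing.eta)
                out = propagate(wf, cord_tissue,
                                optimized_protocol.points[i].offset, m_eq)
                vals.append(2.0 * out[3])
            assert engine[i] == pytest.approx(np.mean(vals), rel=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 32 - 1))
def test_signals_normalized_for_random_tissues(seed):
    """Predicted signals always lie in (0, 1] for valid tissues/points."""
    rng = np.random.default_rng(seed)
    tissue = random_tissue(rng)
    b1 = rng.uniform(0.0, 13e-6)
    offset = rng.uniform(1e3, 1e5)
    train = TrainSpec(int(rng.integers(1, 8)), rng.uniform(1e-3, 30e-3),
                      MTPulseSpec(b1, rng.uniform(5e-3, 25e-3), offset))
    timing = AcquisitionTiming(td_list=(20e-3, 120e-3), eta=500e-6)
    s = predict_mt_signal(tissue, SamplingPoint(offset, b1), train, timing)
    assert 0.0 < s <= 1.0
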