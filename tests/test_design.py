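"""Fisher information, CRLB cost, SOMA search and protocol construction."""

import numpy as np
import pytest

from qmtkit.design import (DesignConfig, SomaConfig, b1_at_sar_cap,
                           crlb_cost, crlb_cost_from_fisher, crlb_report,
                           fisher_matrix, heuristic_sweep, make_uniform_protocol,
                           optimize_sampling, sar_normalized, soma_minimize)
from qmtkit.model import Protocol, SamplingPoint
from qmtkit.params import default_tissue_set
from qmtkit.pulses import MTPulseSpec, TrainSpec


class TestSarSurrogate:
    def test_quadratic_in_amplitude(self, train25, timing):
        u1 = sar_normalized(6e-6, train25, timing)
        u2 = sar_normalized(12e-6, train25, timing)
        assert u2 == pytest.approx(4.0 * u1, rel=1e-12)

    def test_rect_closed_form(self, timing):
        train = TrainSpec(10, 20e-3, MTPulseSpec(5e-6, 8e-3, 0.0, shape="rect"))
        from qmtkit.design import _U_CAL
        expected = 10 * (5e-6) ** 2 * 8e-3 / timing.tr(train) / _U_CAL
        assert sar_normalized(5e-6, train, timing) == pytest.approx(expected, rel=1e-12)

    def test_calibration_configuration_is_unity(self, train25, timing):
        assert sar_normalized(12e-6, train25, timing) == pytest.approx(1.0, rel=1e-12)

    def test_cap_inverts_surrogate(self, train25, timing):
        b1 = b1_at_sar_cap(train25, timing, 0.7)
        assert sar_normalized(b1, train25, timing) == pytest.approx(0.7, rel=1e-12)


class TestFisherMatrix:
    def test_duplication_additivity(self, cord_tissue, optimized_protocol):
        f1 = fisher_matrix(cord_tissue, optimized_protocol, 25.0)
        doubled = Protocol(points=optimized_protocol.points * 2,
                           train=optimized_protocol.train,
                           timing=optimized_protocol.timing)
        f2 = fisher_matrix(cord_tissue, doubled, 25.0)
        assert np.allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_snr_scaling(self, cord_tissue, optimized_protocol):
        f = fisher_matrix(cord_tissue, optimized_protocol, 25.0)
        fh = fisher_matrix(cord_tissue, optimized_protocol, 12.5)
        assert np.allclose(fh, 0.25 * f, rtol=1e-12)

    def test_symmetric_positive_semidefinite(self, cord_tissue, optimized_protocol):
        f = fisher_matrix(cord_tissue, optimized_protocol, 25.0)
        assert np.allclose(f, f.T)
        assert np.min(np.linalg.eigvalsh(f)) >= -1e-6 * np.abs(f).max()

    def test_jacobian_against_richardson_oracle(self, cord_tissue, optimized_protocol):
        # Richardson-extrapolated central differences as derivative oracle
        from qmtkit.fitting import _predict_x
        p = cord_tissue.model_vector
        r1obs = 1.0 / cord_tissue.t1obs

        def jac_at(h_rel):
            cols = []
            for j in range(4):
                for sgn in (1.0, -1.0):
                    x = p.copy()
                    x[j] *= 1.0 + sgn * h_rel
                    cols.append(_predict_x(x, optimized_protocol, r1obs, 1.0)[0])
            cols = np.array(cols).reshape(4, 2, -1)
            return np.stack([(cols[j, 0] - cols[j, 1]) / (2 * h_rel * p[j])
                             for j in range(4)], axis=1)

        j1, j2 = jac_at(1e-3), jac_at(5e-4)
        oracle = (4.0 * j2 - j1) / 3.0
        f = fisher_matrix(cord_tissue, optimized_protocol, 25.0)
        f_oracle = 25.0 ** 2 * oracle.T @ oracle
        assert np.linalg.norm(f - f_oracle) / np.linalg.norm(f_oracle) < 1e-4


class TestCrlbCost:
    def test_point_duplication_halves_cost(self, train25, timing, optimized_protocol):
        cfg = DesignConfig(tissues=default_tissue_set()[:2])
        v1 = crlb_cost(optimized_protocol.points, train25, timing, cfg)
        v2 = crlb_cost(optimized_protocol.points * 2, train25, timing, cfg)
        assert v2 == pytest.approx(v1 / 2.0, rel=1e-9)

    def test_single_weight_projects_to_bpf_crlb(self, train25, timing,
                                                optimized_protocol):
        cfg = DesignConfig(tissues=default_tissue_set()[:2], weights=(1, 0, 0, 0))
        v = crlb_cost(optimized_protocol.points, train25, timing, cfg)
        rep = crlb_report(optimized_protocol.points, train25, timing, cfg)
        assert v == pytest.approx(rep.relative_crlbs[:, 0].mean(), rel=1e-12)

    def test_linear_model_matches_ols_variance(self):
        # y = a*x + b: CRLB equals the closed-form OLS parameter variances
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        sigma = 0.1
        a, b = 2.0, 1.5
        jac = np.column_stack([x, np.ones_like(x)])
        fisher = (jac.T @ jac) / sigma ** 2
        n = x.size
        sxx = np.sum((x - x.mean()) ** 2)
        var_a = sigma ** 2 / sxx
        var_b = sigma ** 2 * np.sum(x ** 2) / (n * sxx)
        expected = var_a / a ** 2 + var_b / b ** 2
        v = crlb_cost_from_fisher(fisher[None], np.array([[a, b]]), (1, 1))
        assert v == pytest.approx(expected, abs=1e-8)

    def test_adding_a_point_never_increases_cost(self, train25, timing,
                                                 optimized_protocol):
        cfg = DesignConfig(tissues=default_tissue_set()[:1])
        base = list(optimized_protocol.points)
        v0 = crlb_cost(base, train25, timing, cfg)
        v1 = crlb_cost(base + [SamplingPoint(2500.0, 9e-6)], train25, timing, cfg)
        assert v1 <= v0 + 1e-12


class TestSoma:
    def test_sphere_benchmark(self):
        # population-level convergence on the 10-D sphere at the default
        # budget; final refinement is the job of the polish stage
        res = soma_minimize(lambda x: float(np.sum(x * x)),
                            [(-5.0, 5.0)] * 10, SomaConfig(), seed=0)
        assert np.linalg.norm(res.x) < 5e-3

    def test_result_within_bounds(self):
        bounds = [(-1.0, 2.0), (0.5, 3.0)]
        res = soma_minimize(lambda x: float(np.cos(5 * x).sum()), bounds,
                            SomaConfig(population=6, migrations=3), seed=1)
        lo, hi = np.array([-1.0, 0.5]), np.array([2.0, 3.0])
        assert np.all(res.x >= lo) and np.all(res.x <= hi)

    def test_rastrigin_seeded_success_rate(self):
        def rastrigin(x):
            return float(20 + np.sum(x * x - 10 * np.cos(2 * np.pi * x)))
        wins = sum(
            soma_minimize(rastrigin, [(-5.12, 5.12)] * 2, SomaConfig(), seed=s).cost < 1.0
            for s in range(10))
        assert wins >= 9

    def test_deterministic_given_seed(self):
        cfg = SomaConfig(population=5, migrations=2)
        f = lambda x: float(np.sum((x - 0.3) ** 2))
        r1 = soma_minimize(f, [(-1, 1)] * 3, cfg, seed=42)
        r2 = soma_minimize(f, [(-1, 1)] * 3, cfg, seed=42)
        assert np.array_equal(r1.x, r2.x) and r1.n_evals == r2.n_evals


class TestUniformProtocol:
    def test_geometric_ladder_offsets(self, train25, timing):
        prot = make_uniform_protocol(14, 400.0, 20e3, train25, timing)
        offsets = prot.offsets()[:7]
        rounded = np.round(offsets).astype(int)
        assert rounded[0] == 400 and rounded[-1] == 20000
        assert list(rounded[1:6]) == [768, 1474, 2828, 5429, 10420] or \
            list(rounded[1:6]) == [768, 1474, 2828, 5429, 10421]
        assert offsets[0] == 400.0 and offsets[-1] == 20000.0

    def test_constant_consecutive_ratio(self, train25, timing):
        prot = make_uniform_protocol(14, 400.0, 20e3, train25, timing)
        r = np.diff(np.log(prot.offsets()[:7]))
        assert np.allclose(r, r[0], rtol=1e-12)
        assert np.exp(r[0]) == pytest.approx(50.0 ** (1.0 / 6.0), rel=1e-12)

    def test_two_power_levels(self, train25, timing):
        prot = make_uniform_protocol(14, 400.0, 20e3, train25, timing)
        flips = sorted({round(p.flip_deg(15e-3)) for p in prot.points})
        assert flips == [601, 1100]

    def test_sar_fraction_levels(self, train25, timing):
        prot = make_uniform_protocol(6, 400.0, 20e3, train25, timing,
                                     sar_fracs=(0.3, 0.8))
        levels = sorted({p.b1_peak for p in prot.points})
        assert sar_normalized(levels[0], train25, timing) == pytest.approx(0.3 / 0.75)
        assert sar_normalized(levels[1], train25, timing) == pytest.approx(0.8 / 0.75)

    def test_invalid_inputs(self, train25, timing):
        with pytest.raises(ValueError):
            make_uniform_protocol(13, 400.0, 20e3, train25, timing)
        with pytest.raises(ValueError):
            make_uniform_protocol(14, 2e4, 400.0, train25, timing)


@pytest.fixture(scope="module")
def small_run(train25, timing):
    cfg = DesignConfig(
        tissues=default_tissue_set()[:3],
        soma=SomaConfig(population=6, migrations=4, path_length=1.8,
                        step=0.6, prt=0.3, polish_maxfev=100),
        seed=0)
    return optimize_sampling(6, train25, timing, cfg), cfg


class TestOptimizeSampling:

    def test_constraints_satisfied(self, small_run, train25, timing):
        (protocol, report), cfg = small_run
        for p in protocol.points:
            assert cfg.offset_bounds[0] <= p.offset <= cfg.offset_bounds[1]
            assert p.b1_peak <= cfg.b1_max + 1e-12
            assert sar_normalized(p, train25, timing) <= cfg.sar_cap + 1e-9

    def test_beats_uniform_ladder_on_same_train(self, small_run, train25, timing):
        (protocol, report), cfg = small_run
        uniform = make_uniform_protocol(6, 400.0, 20e3, train25, timing)
        v_uniform = crlb_cost(uniform.points, train25, timing, cfg)
        assert report.cost <= v_uniform

    def test_k_too_small_rejected(self, train25, timing):
        with pytest.raises(ValueError):
            optimize_sampling(3, train25, timing, DesignConfig())


def test_sweep_records_failures_and_length(train25, timing):
    cfg = DesignConfig(
        tissues=default_tissue_set()[:2],
        soma=SomaConfig(population=4, migrations=1, path_length=1.2,
                        step=0.6, prt=0.3, polish_maxfev=0),
        seed=0)
    # 50 us pulse duration is unresolvable at the 100 us discretization step
    df = heuristic_sweep("tau", [10e-3, 50e-6], train25, timing, cfg, k=6)
    assert len(df) == 2
    assert np.isfinite(df.loc[0, "cost"])
    assert np.isnan(df.loc[1, "cost"])
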