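import numpy as np
import pytest

import cmcdcm as cc
from cmcdcm.generative import (
    BoldSignal,
    DcmParameters,
    DivergenceError,
    NeuralTrajectory,
    neural_derivative,
    sample_to_scans,
    simulate_bold,
    simulate_neural,
)

from conftest import adaptive_forward_oracle, constant_regressors


def _loop_derivative(y, x, params, spec):
    """Independent elementwise-loop evaluation of A·y + C·x + Σ y_i D(i)y."""
    out = np.zeros(5)
    for i in range(5):
        for j in range(5):
            out[i] += params.a[i, j] * y[j]
        for k in range(params.c.shape[1]):
            out[i] += params.c[i, k] * x[k]
    ix = spec.regions.index
    for (m, s, t), g in params.d.items():
        out[ix(t)] += y[ix(m)] * g * y[ix(s)]
    return out


class TestNeuralDerivative:
    def test_reduces_to_linear_term_without_gains_or_input(self, spec_mod):
        p = DcmParameters(a=-0.5 * np.eye(5) + 0.1, c=np.zeros((5, 8)), d={})
        y = np.arange(5, dtype=float)
        assert np.allclose(neural_derivative(y, np.zeros(8), p, spec_mod), p.a @ y)

    def test_reduces_to_driver_term_at_zero_state(self, spec_mod):
        rng = np.random.default_rng(0)
        p = DcmParameters(
            a=-0.5 * np.eye(5), c=rng.normal(size=(5, 8)),
            d={("BG", "MTL", "PFC"): 2.0},
        )
        x = rng.normal(size=8)
        assert np.allclose(neural_derivative(np.zeros(5), x, p, spec_mod), p.c @ x)

    def test_single_gain_contributes_modulator_times_source(self, spec_mod):
        g = 0.7
        p = DcmParameters(a=-0.5 * np.eye(5), c=np.zeros((5, 8)),
                          d={("BG", "MTL", "PFC"): g})
        y = np.zeros(5)
        y[spec_mod.regions.index("BG")] = 2.0
        y[spec_mod.regions.index("MTL")] = 3.0
        dy = neural_derivative(y, np.zeros(8), p, spec_mod) - p.a @ y
        expected = np.zeros(5)
        expected[spec_mod.regions.index("PFC")] = 2.0 * g * 3.0
        assert np.allclose(dy, expected)

    def test_matches_elementwise_loop_oracle(self, spec_mod):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(scale=0.3, size=(5, 5))
            np.fill_diagonal(a, -np.abs(rng.normal(0.5, 0.1, 5)))
            p = DcmParameters(
                a=a, c=rng.normal(scale=0.1, size=(5, 8)),
                d={("BG", "MTL", "PFC"): rng.normal(), ("BG", "SENS", "PFC"): rng.normal()},
            )
            y, x = rng.normal(size=5), rng.normal(size=8)
            assert np.allclose(
                neural_derivative(y, x, p, spec_mod), _loop_derivative(y, x, p, spec_mod)
            )

    def test_nonfinite_input_rejected(self, spec_mod):
        p = DcmParameters(a=-0.5 * np.eye(5), c=np.zeros((5, 8)), d={})
        with pytest.raises(ValueError, match="non-finite"):
            neural_derivative(np.array([np.nan, 0, 0, 0, 0]), np.zeros(8), p, spec_mod)


class TestSimulateNeural:
    def test_zero_input_zero_state_is_fixed_point(self, spec_mod):
        p = DcmParameters(a=-0.5 * np.eye(5), c=np.zeros((5, 1)), d={})
        regs = constant_regressors(value=0.0, duration=20.0, dt=0.05)
        traj = simulate_neural(p, regs, spec_mod)
        assert np.all(traj.y == 0.0)

    def test_constant_unit_input_converges_to_closed_form_steady_state(self, spec_mod):
        # steady state of dy = a y + c u is -a^{-1} c u = 2.0 for a=-0.5, c=1
        c = np.zeros((5, 1))
        c[0, 0] = 1.0
        p = DcmParameters(a=-0.5 * np.eye(5), c=c, d={})
        regs = constant_regressors(value=1.0, duration=60.0, dt=0.05)
        traj = simulate_neural(p, regs, spec_mod)
        assert traj.y[-1, 0] == pytest.approx(2.0, abs=1e-3)
        assert np.all(np.abs(traj.y[-1, 1:]) < 1e-12)

    def test_step_halving_changes_endpoint_below_tolerance(self, pd_params, spec_mod):
        ends = []
        for div in (16, 32):
            regs = cc.oscillator_boxcars(duration=100.0, dt=2.5 / div)
            ends.append(simulate_neural(pd_params, regs, spec_mod).y[-1])
        assert np.max(np.abs(ends[0] - ends[1])) < 1e-3

    def test_linear_regime_scales_with_drive(self, pd_params, spec_mod):
        import dataclasses

        p1 = dataclasses.replace(pd_params, d={})
        p2 = dataclasses.replace(pd_params, c=2.0 * pd_params.c, d={})
        regs = cc.oscillator_boxcars(duration=200.0, dt=2.5 / 16)
        y1 = simulate_neural(p1, regs, spec_mod).y
        y2 = simulate_neural(p2, regs, spec_mod).y
        assert np.allclose(y2, 2.0 * y1, atol=1e-10)

    def test_unstable_coupling_raises_divergence_error(self, spec_mod):
        a = -0.5 * np.eye(5)
        a[0, 1] = a[1, 0] = 5.0   # mutual excitation beyond the decay rate
        p = DcmParameters(a=a, c=np.ones((5, 1)), d={})
        regs = constant_regressors(value=1.0, duration=60.0, dt=0.05)
        with pytest.raises(DivergenceError, match="diverged"):
            simulate_neural(p, regs, spec_mod)


class TestSimulateBold:
    def test_resting_state_is_conserved(self, spec_mod):
        p = DcmParameters(a=-0.5 * np.eye(5), c=np.zeros((5, 1)), d={})
        traj = NeuralTrajectory(y=np.zeros((400, 5)), dt=0.15625)
        bold = simulate_bold(traj, p)
        assert np.all(bold.values == 0.0)

    def test_bold_peak_lags_neural_peak(self, spec_mod):
        p = DcmParameters(a=-0.5 * np.eye(5), c=np.zeros((5, 1)), d={})
        dt = 0.125
        n = int(30.0 / dt)
        y = np.zeros((n, 5))
        peak_bin = int(2.0 / dt)
        y[peak_bin : peak_bin + 8, 0] = 1.0  # 1-second neural burst at t=2s
        bold = simulate_bold(NeuralTrajectory(y=y, dt=dt), p)
        assert np.argmax(bold.values[:, 0]) > peak_bin + 8
        assert bold.values[:, 0].max() > 0

    def test_identical_neural_traces_give_identical_bold(self, spec_mod):
        rng = np.random.default_rng(3)
        trace = 0.2 * np.sin(np.linspace(0, 6 * np.pi, 300)) + 0.05 * rng.normal(size=300)
        y = np.column_stack([trace] * 5)
        p = DcmParameters(a=-0.5 * np.eye(5), c=np.zeros((5, 1)), d={})
        bold = simulate_bold(NeuralTrajectory(y=y, dt=0.2), p)
        for j in range(1, 5):
            assert np.array_equal(bold.values[:, 0], bold.values[:, j])


class TestSampleToScans:
    def test_ten_minute_run_yields_240_scans(self, pd_params, spec_mod):
        regs = cc.oscillator_boxcars(duration=600.0, dt=2.5 / 16)
        traj = simulate_neural(pd_params, regs, spec_mod)
        bold = simulate_bold(traj, pd_params)
        rec = sample_to_scans(bold, tr=2.5, n_scans=240)
        assert rec.values.shape == (240, 5)
        assert rec.tr == 2.5
        assert rec.region_labels == ("MC", "PFC", "BG", "MTL", "SENS")

    def test_tr_equal_to_dt_is_identity(self):
        vals = np.random.default_rng(0).normal(size=(50, 5))
        rec = sample_to_scans(BoldSignal(values=vals, dt=0.5), tr=0.5, n_scans=50)
        assert np.array_equal(rec.values, vals)

    def test_constant_signal_samples_constant(self):
        bold = BoldSignal(values=np.full((100, 5), 1.25), dt=0.25)
        rec = sample_to_scans(bold, tr=2.5, n_scans=10)
        assert np.all(rec.values == 1.25)

    def test_insufficient_duration_rejected(self):
        bold = BoldSignal(values=np.zeros((100, 5)), dt=0.25)  # 25 s
        with pytest.raises(ValueError, match="scans"):
            sample_to_scans(bold, tr=2.5, n_scans=20)


class TestIntegratorFidelity:
    def test_fixed_step_matches_adaptive_oracle(self, pd_params, spec_mod):
        """Endpoint agreement with an independent adaptive RK45 reference
        on the default parameter regime (neural and BOLD, 100 s)."""
        regs = cc.oscillator_boxcars(duration=100.0, dt=2.5 / 16)
        traj = simulate_neural(pd_params, regs, spec_mod)
        bold = simulate_bold(traj, pd_params)
        t_cmp = 93.75                       # on the boxcar switch grid
        k = int(round(t_cmp / regs.dt))
        y_ref, bold_ref = adaptive_forward_oracle(pd_params, regs, spec_mod, t_cmp)
        assert np.max(np.abs(traj.y[k] - y_ref)) < 1e-3
        assert np.max(np.abs(bold.values[k] - bold_ref)) < 1e-3

    def test_compiled_batch_kernel_matches_reference_path(self, pd_params, spec_mod):
        """The inversion's fused compiled integrator and the stepwise
        reference implementation agree to round-off."""
        from cmcdcm.inversion import InversionSettings, ParameterMap, _ForwardModel

        pmap = ParameterMap.build(spec_mod)
        fwd = _ForwardModel(spec_mod, pmap, 2.5, 120, InversionSettings())
        sl = pmap.slices()
        theta = np.zeros(pmap.n_params)
        theta[sl["a"]] = pd_params.a[pmap.a_rows, pmap.a_cols]
        theta[sl["self"]] = np.log(np.diag(pd_params.a) / -0.5)
        theta[sl["c"]] = pd_params.c[pmap.c_rows, pmap.c_cols]
        theta[sl["d"]] = [pd_params.d[t] for t in spec_mod.d_masks]
        pred, ok = fwd(theta[None, :])
        assert ok[0]
        regs = cc.oscillator_boxcars(duration=300.0, dt=2.5 / 16)
        traj = simulate_neural(pd_params, regs, spec_mod)
        bold = simulate_bold(traj, pd_params)
        ref = sample_to_scans(bold, tr=2.5, n_scans=120).values
        assert np.max(np.abs(pred[0].reshape(120, 5) - ref)) < 1e-10
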