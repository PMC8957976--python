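import numpy as np
import pytest

import cmcdcm as cc


@pytest.fixture(scope="session")
def spec_mod():
    return cc.build_cmc_spec("modulatory")


@pytest.fixture(scope="session")
def spec_dir():
    return cc.build_cmc_spec("direct")


@pytest.fixture(scope="session")
def pd_params(spec_mod):
    """Ground-truth PD-profile parameters with jitter 0 (exact group means)."""
    profile = cc.default_group_profile("PD", spec_mod).with_jitter(0.0)
    return cc.draw_subject_parameters(profile, spec_mod, seed=0)


@pytest.fixture(scope="session")
def pd_recording_120(pd_params, spec_mod):
    """One 120-scan PD subject at SNR 3 (shared across inversion tests)."""
    return cc.generate_subject(pd_params, spec_mod, n_scans=120, seed=42, group="PD")


@pytest.fixture(scope="session")
def pd_posterior_120(pd_recording_120, spec_mod):
    return cc.invert_subject(pd_recording_120, spec_mod)


@pytest.fixture(scope="session")
def default_regressors():
    return cc.oscillator_boxcars(duration=600.0, dt=2.5 / 16)


def adaptive_forward_oracle(params, regs, spec, duration, rtol=1e-10):
    """Independent high-accuracy reference for the forward model.

    Integrates the joint 25-state system (5 neural + 4 balloon states per
    region) with an adaptive RK45 solver, piecewise over the segments on
    which the boxcar input is constant.  Returns (neural endpoint, BOLD
    endpoint) at time ``duration``.
    """
    from scipy.integrate import solve_ivp

    import cmcdcm as cc

    h = params.hemo
    idx, val = params.d_triples(spec)

    def rhs(_t, z, u):
        y = z[:5]
        dy = params.a @ y + u
        for (m, s, t_), g in zip(idx, val):
            dy[t_] += y[m] * g * y[s]
        out = np.empty_like(z)
        out[:5] = dy
        for j in range(5):
            s_, f_, v_, q_ = z[5 + 4 * j : 9 + 4 * j]
            fv = v_ ** (1.0 / h.alpha)
            e = 1.0 - (1.0 - h.rho) ** (1.0 / f_)
            out[5 + 4 * j] = y[j] - h.kappa * s_ - h.gamma * (f_ - 1.0)
            out[6 + 4 * j] = s_
            out[7 + 4 * j] = (f_ - fv) / h.tau
            out[8 + 4 * j] = (f_ * e / h.rho - fv * q_ / v_) / h.tau
        return out

    u_all = regs.values @ params.c.T           # (T, 5)
    # input is constant on segments bounded by the boxcar switch grid
    seg = 0.25 / max(f for f in regs.frequencies if f > 0)
    n_seg = int(round(duration / seg))
    bins_per_seg = int(round(seg / regs.dt))
    z = np.concatenate([np.zeros(5), np.tile([0.0, 1.0, 1.0, 1.0], 5)])
    for k in range(n_seg):
        u = u_all[k * bins_per_seg]
        sol = solve_ivp(
            rhs, (k * seg, (k + 1) * seg), z, args=(u,), rtol=rtol, atol=1e-12
        )
        assert sol.status == 0
        z = sol.y[:, -1]
    v = z[7::4]
    q = z[8::4]
    bold = 100.0 * h.v0 * (h.k1 * (1 - q) + h.k2 * (1 - q / v) + h.k3 * (1 - v))
    return z[:5], bold


def constant_regressors(value=1.0, n_cols=1, duration=60.0, dt=0.05):
    """A constant-input 'regressor bank' for closed-form checks."""
    n = int(round(duration / dt))
    return cc.RegressorSet(
        values=np.full((n, n_cols), float(value)),
        dt=dt,
        frequencies=(0.0,) * n_cols,
        phases=(0.0,) * n_cols,
    )
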