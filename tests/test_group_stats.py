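import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmcdcm.group_stats import (
    BpaResult,
    bayesian_parameter_average,
    cross_model_contrast,
    directional_test,
    format_comparison_table,
)
from cmcdcm.inversion import ParameterPosterior, PriorSpec


def _posterior(means, variances, labels=None):
    means = np.atleast_1d(np.asarray(means, dtype=float))
    labels = labels or tuple(f"a:R{i}→Q{i}" for i in range(means.size))
    return ParameterPosterior(
        labels=tuple(labels),
        mean=means,
        cov=np.diag(np.atleast_1d(np.asarray(variances, dtype=float))),
        free_energy=0.0,
        iterations=1,
        f_trace=[0.0],
        converged=True,
        log_noise_precision=0.0,
    )


def _vague_prior(labels):
    return PriorSpec(
        labels=tuple(labels),
        mean=np.zeros(len(labels)),
        var=np.full(len(labels), 1e8),
    )


def _bpa(labels, means, sds, group="PD", n=10):
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    return BpaResult(
        labels=tuple(labels), mean=means, sd=sds, cov=np.diag(sds**2),
        group=group, n_subjects=n,
    )


class TestBayesianParameterAverage:
    def test_single_posterior_is_returned_unchanged(self):
        post = _posterior([1.5], [0.25])
        res = bayesian_parameter_average([post], _vague_prior(post.labels))
        assert res.mean[0] == pytest.approx(1.5)
        assert res.sd[0] == pytest.approx(0.5)

    def test_precision_weighting_closed_form(self):
        posts = [_posterior([1.0], [1.0]), _posterior([3.0], [1.0])]
        res = bayesian_parameter_average(posts, _vague_prior(posts[0].labels))
        assert res.mean[0] == pytest.approx(2.0, abs=1e-4)
        assert res.sd[0] ** 2 == pytest.approx(0.5, rel=1e-3)

    def test_n_identical_posteriors_divide_variance_by_n(self):
        post = _posterior([2.0, -1.0], [0.5, 0.8])
        n = 5
        res = bayesian_parameter_average([post] * n, _vague_prior(post.labels))
        assert np.allclose(res.mean, post.mean, atol=1e-5)
        assert np.allclose(res.sd**2, np.diag(post.cov) / n, rtol=1e-3)

    def test_mismatched_index_maps_rejected(self):
        p1 = _posterior([1.0], [1.0], labels=("a:X→Y",))
        p2 = _posterior([1.0], [1.0], labels=("a:Y→X",))
        with pytest.raises(ValueError, match="index maps"):
            bayesian_parameter_average([p1, p2], _vague_prior(p1.labels))

    def test_non_positive_definite_combination_raises(self):
        # posteriors wider than the prior make the corrected precision negative
        post = _posterior([0.0], [100.0])
        prior = PriorSpec(labels=post.labels, mean=np.zeros(1), var=np.array([1.0]))
        with pytest.raises(RuntimeError, match="not positive definite"):
            bayesian_parameter_average([post] * 3, prior)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bayesian_parameter_average([], _vague_prior(("a:X→Y",)))


class TestDirectionalTest:
    def test_published_modulatory_row_reproduces(self):
        """The (μ, σ) pair for the BG-gated MTL→PFC connection gives
        p_less = 1.00 and p_greater < 0.001."""
        pd = _bpa(["d:BG|MTL→PFC"], [0.24], [0.11])
        hc = _bpa(["d:BG|MTL→PFC"], [-3.84], [0.02], group="HC")
        res = directional_test(pd, hc)
        _, p_less, p_greater = res.row("d:BG|MTL→PFC")
        assert p_less > 0.999
        assert p_greater < 0.001

    def test_identical_groups_split_the_probability(self):
        pd = _bpa(["a:X→Y"], [0.3], [0.1])
        hc = _bpa(["a:X→Y"], [0.3], [0.1], group="HC")
        res = directional_test(pd, hc)
        _, p_less, p_greater = res.row("a:X→Y")
        assert p_less == pytest.approx(0.5)
        assert p_greater == pytest.approx(0.5)

    @given(
        mu_a=st.floats(-5, 5), mu_b=st.floats(-5, 5),
        sd_a=st.floats(0.01, 2), sd_b=st.floats(0.01, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_under_group_swap(self, mu_a, mu_b, sd_a, sd_b):
        a = _bpa(["a:X→Y"], [mu_a], [sd_a])
        b = _bpa(["a:X→Y"], [mu_b], [sd_b], group="HC")
        fwd = directional_test(a, b)
        rev = directional_test(b, a)
        assert fwd.p_less[0] == pytest.approx(rev.p_greater[0], abs=1e-12)
        assert fwd.p_greater[0] == pytest.approx(rev.p_less[0], abs=1e-12)
        assert fwd.p_less[0] + fwd.p_greater[0] == pytest.approx(1.0)

    def test_zero_dispersion_rejected(self):
        a = _bpa(["a:X→Y"], [1.0], [0.0])
        b = _bpa(["a:X→Y"], [0.0], [0.0], group="HC")
        with pytest.raises(ValueError, match="dispersion"):
            directional_test(a, b)

    def test_mismatched_parameter_sets_rejected(self):
        a = _bpa(["a:X→Y"], [1.0], [0.1])
        b = _bpa(["a:Y→X"], [0.0], [0.1], group="HC")
        with pytest.raises(ValueError, match="different parameter sets"):
            directional_test(a, b)


TABLE2_ROWS = [
    # label, mu_PD, sd_PD, mu_HC, sd_HC, printed p_less, printed p_greater
    ("a:SENS→MC", -0.16, 0.002, 0.11, 0.006, "<0.001", None),
    ("a:MC→SENS", 0.07, 0.001, 0.27, 0.004, "<0.001", None),
    ("a:MTL→PFC", 0.19, 0.003, 0.31, 0.005, "<0.001", None),
    ("a:PFC→MTL", 0.28, 0.003, 0.46, 0.005, "<0.001", None),
    ("a:SENS→PFC", -0.22, 0.003, 0.10, 0.006, "<0.001", None),
    ("a:PFC→SENS", 0.08, 0.002, -0.002, 0.004, "1.00", "<0.001"),
    ("a:PFC→MC", 0.07, 0.002, 0.27, 0.006, "<0.001", None),
    ("a:PFC→BG", 0.08, 0.004, 0.13, 0.006, "<0.001", None),
]


class TestPublishedTableReproduction:
    @pytest.mark.parametrize("row", TABLE2_ROWS, ids=[r[0] for r in TABLE2_ROWS])
    def test_direct_connection_p_columns(self, row):
        label, mu_pd, sd_pd, mu_hc, sd_hc, p_less_str, p_greater_str = row
        res = directional_test(
            _bpa([label], [mu_pd], [sd_pd]), _bpa([label], [mu_hc], [sd_hc], group="HC")
        )
        _, p_less, p_greater = res.row(label)
        if p_less_str == "<0.001":
            assert p_less < 0.001
        else:
            assert f"{p_less:.2f}" == p_less_str
        if p_greater_str == "<0.001":
            assert p_greater < 0.001

    def test_sens_to_pfc_gating_row_inconsistency_is_reported_not_matched(self):
        """The published second gating row prints p_greater < 0.001, but the
        printed (μ, σ) values give z ≈ 1.25 — the recomputed p_greater is
        ~0.1.  The discrepancy is surfaced, not silently matched."""
        pd = _bpa(["d:BG|SENS→PFC"], [-1.59], [0.31])
        hc = _bpa(["d:BG|SENS→PFC"], [-2.39], [0.56], group="HC")
        res = directional_test(pd, hc)
        z, p_less, p_greater = res.row("d:BG|SENS→PFC")
        assert z == pytest.approx(1.25, abs=0.01)
        assert 0.09 < p_greater < 0.12
        assert not p_greater < 0.001

    def test_formatted_table_uses_reporting_dialect(self):
        pd = _bpa(["a:X→Y", "a:Y→X"], [0.24, -0.16], [0.11, 0.002])
        hc = _bpa(["a:X→Y", "a:Y→X"], [-3.84, 0.11], [0.02, 0.006], group="HC")
        table = format_comparison_table(pd, hc, directional_test(pd, hc))
        row0 = table.iloc[0]
        assert row0["p_less"] == "1.00"
        assert row0["p_greater"] == "<0.001"
        row1 = table.iloc[1]
        assert row1["p_less"] == "<0.001"
        assert row1["p_greater"] == "—"


class TestCrossModelContrast:
    def _paired(self, shift_mod=0.0, shift_dir=0.0):
        labels = ["a:SENS→MC", "a:MC→SENS", "d:BG|MTL→PFC"]
        pd_mod = _bpa(labels, [0.1 + shift_mod, 0.2, 0.3], [0.1] * 3)
        hc_mod = _bpa(labels, [0.0, 0.1, 0.2], [0.1] * 3, group="HC")
        dir_labels = ["a:SENS→MC", "a:MC→SENS", "a:PFC→BG"]
        pd_dir = _bpa(dir_labels, [0.1 + shift_dir, 0.2, 0.4], [0.1] * 3)
        hc_dir = _bpa(dir_labels, [0.0, 0.1, 0.3], [0.1] * 3, group="HC")
        return (pd_mod, hc_mod), (pd_dir, hc_dir)

    def test_identical_differences_have_no_disagreements(self):
        mod, direct = self._paired()
        table = cross_model_contrast(mod, direct)
        assert list(table["connection"]) == ["a:SENS→MC", "a:MC→SENS"]
        assert not table["sign_disagrees"].any()

    def test_opposite_signs_are_flagged(self):
        mod, direct = self._paired(shift_mod=0.1, shift_dir=-0.3)
        table = cross_model_contrast(mod, direct)
        assert bool(table.loc[table["connection"] == "a:SENS→MC", "sign_disagrees"].iloc[0])
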