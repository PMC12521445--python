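import math
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootmeta.pooling import (
    bootstrap_ci,
    fit_gaussian,
    pool_factor,
    pool_fixed,
    pool_mixed,
    q_test,
    select_and_pool,
    tau2_dl,
)

HAND = dict(y=np.array([0.0, 0.2, 0.4]), v=np.full(3, 0.01))


class TestPoolFixed:
    def test_symmetric_mean(self):
        rr, _ = pool_fixed([0.1, 0.3], [0.02, 0.02])
        assert rr == pytest.approx(0.2)

    def test_hand_weighted_mean(self):
        rr, var = pool_fixed(HAND["y"], HAND["v"])
        assert rr == pytest.approx(0.2)
        assert var == pytest.approx(1 / 300)

    def test_repeated_value(self):
        rr, _ = pool_fixed([0.15, 0.15, 0.15], [0.1, 0.2, 0.3])
        assert rr == pytest.approx(0.15)

    def test_requires_two_effects(self):
        with pytest.raises(ValueError):
            pool_fixed([0.1], [0.01])

    @given(
        y=st.lists(st.floats(-1, 1), min_size=2, max_size=30),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=100, deadline=None)
    def test_estimate_within_input_range(self, y, seed):
        v = np.random.default_rng(seed).uniform(0.001, 0.5, len(y))
        rr, _ = pool_fixed(y, v)
        assert min(y) - 1e-12 <= rr <= max(y) + 1e-12


class TestQTest:
    def test_identical_effects_q_zero(self):
        rr, _ = pool_fixed([0.2, 0.2, 0.2], [0.01] * 3)
        het = q_test([0.2, 0.2, 0.2], [0.01] * 3, rr)
        assert het.q_total == pytest.approx(0.0, abs=1e-12)
        assert het.p_value == pytest.approx(1.0)

    def test_hand_computed_q(self):
        het = q_test(HAND["y"], HAND["v"], 0.2)
        assert het.q_total == pytest.approx(8.0)
        assert het.df == 2
        # chi-square survival at df=2 is exp(-Q/2)
        assert het.p_value == pytest.approx(math.exp(-4.0), rel=1e-10)
        assert het.significant

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_q_invariant_under_shift(self, shift):
        y = HAND["y"] + shift
        rr, _ = pool_fixed(y, HAND["v"])
        het = q_test(y, HAND["v"], rr)
        assert het.q_total == pytest.approx(8.0, rel=1e-9)


class TestTau2DL:
    def test_truncated_at_zero(self):
        assert tau2_dl(1.0, [100.0, 100.0, 100.0]) == 0.0

    def test_hand_computed(self):
        # c = 300 - 30000/300 = 200 -> (8-2)/200
        assert tau2_dl(8.0, [100.0, 100.0, 100.0]) == pytest.approx(0.03)

    def test_matches_brute_force_formula(self, rng):
        w = rng.uniform(1, 50, 12)
        q = 25.0
        c = w.sum() - (w**2).sum() / w.sum()
        assert tau2_dl(q, w) == pytest.approx(max(0.0, (q - 11) / c), rel=1e-12)


class TestPoolMixed:
    def test_tau2_zero_reduces_to_fixed(self):
        assert pool_mixed(HAND["y"], HAND["v"], 0.0) == pool_fixed(HAND["y"], HAND["v"])

    def test_equal_weights_preserved(self):
        rr, _ = pool_mixed(HAND["y"], HAND["v"], 0.03)
        assert rr == pytest.approx(0.2)

    def test_large_tau2_approaches_unweighted_mean(self, rng):
        y = rng.normal(0, 1, 10)
        v = rng.uniform(0.001, 0.1, 10)
        rr, _ = pool_mixed(y, v, 1e9)
        assert rr == pytest.approx(float(np.mean(y)), abs=1e-6)


class TestSelectAndPool:
    def test_homogeneous_factor_stays_fixed(self):
        pe = select_and_pool([0.2, 0.2, 0.2], [0.01] * 3)
        assert pe.model == "fixed" and pe.tau2 == 0.0

    def test_heterogeneous_factor_goes_mixed(self):
        pe = select_and_pool(HAND["y"], HAND["v"], alpha=0.05)
        assert pe.model == "mixed"
        assert pe.rr_pp == pytest.approx(0.2)
        assert pe.tau2 == pytest.approx(0.03)

    def test_percent_change_consistent(self):
        pe = select_and_pool([0.1, 0.1], [0.01, 0.01])
        assert pe.percent_change == pytest.approx((math.e**0.1 - 1) * 100)

    def test_mixed_variance_never_smaller_than_fixed(self, rng):
        for _ in range(20):
            y = rng.normal(0, 0.3, 15)
            v = rng.uniform(0.001, 0.05, 15)
            _, var_fixed = pool_fixed(y, v)
            pe = select_and_pool(y, v)
            assert pe.se_param**2 >= var_fixed - 1e-15


class TestBootstrapCI:
    def test_degenerate_inputs_collapse(self):
        lo, hi = bootstrap_ci([0.1] * 5, [0.01] * 5, b=999, seed=0)
        assert lo == hi == pytest.approx(0.1)

    def test_deterministic_under_seed(self, effects):
        sub = effects.loc[effects["factor"] == "warming"]
        args = (sub["log_rr"].to_numpy(), sub["v"].to_numpy())
        a = bootstrap_ci(*args, b=1999, seed=123)
        b = bootstrap_ci(*args, b=1999, seed=123)
        assert a == b

    def test_zero_bias_reduces_to_percentile(self, rng):
        """With exactly half the bootstrap mass below the estimate (z0 = 0)
        the BC interval is the plain percentile interval."""
        from rootmeta.pooling import _bc_interval

        draws = rng.normal(0.0, 1.0, 1000)
        boot = np.concatenate([draws, -draws])  # symmetric around 0
        lo, hi = _bc_interval(boot, 0.0, alpha=0.05)
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=1e-12)
        assert hi == pytest.approx(phi, abs=1e-12)

    def test_significance_flag(self, effects):
        sub = effects.loc[effects["factor"] == "vegetated_soil"]
        pe = pool_factor(
            sub["log_rr"].to_numpy(), sub["v"].to_numpy(), b=1999, seed=1
        )
        assert pe.ci_high < 0 and pe.significant

    def test_cluster_bootstrap_runs(self, effects):
        sub = effects.loc[effects["factor"] == "grazing"]
        lo, hi = bootstrap_ci(
            sub["log_rr"].to_numpy(), sub["v"].to_numpy(), b=999, seed=3,
            study_id=sub["study_id"].to_numpy(),
        )
        assert lo < hi


class TestFitGaussian:
    def test_symmetric_values(self):
        fit = fit_gaussian([-1.0, 1.0])
        assert fit.mu == pytest.approx(0.0)

    def test_recovers_moments(self, rng):
        y = rng.normal(0.1, 0.2, 10_000)
        fit = fit_gaussian(y)
        assert fit.mu == pytest.approx(0.1, abs=3 * 0.2 / 100)
        assert fit.sigma == pytest.approx(0.2, abs=3 * 0.2 / math.sqrt(2 * 10_000))

    def test_constant_values_flagged(self):
        fit = fit_gaussian([0.3, 0.3, 0.3])
        assert fit.sigma == 0.0


@pytest.fixture(scope="module")
def metafor_fit(tmp_path_factory):
    """Fit the same effects in R's metafor (DerSimonian-Laird) as an
    independent oracle."""
    y = [0.05, -0.12, 0.30, 0.18, -0.02, 0.22, 0.09, 0.40]
    v = [0.01, 0.02, 0.015, 0.008, 0.03, 0.012, 0.02, 0.025]
    script = textwrap.dedent(
        f"""
        suppressMessages(library(metafor))
        yi <- c({",".join(map(str, y))})
        vi <- c({",".join(map(str, v))})
        fit <- rma(yi, vi, method="DL")
        cat(coef(fit), fit$tau2, fit$QE, sep="\\n")
        """
    )
    path = tmp_path_factory.mktemp("r") / "dl.R"
    path.write_text(script)
    out = subprocess.run(
        ["Rscript", "--vanilla", str(path)], capture_output=True, text=True, check=True
    )
    b, tau2, qe = map(float, out.stdout.split())
    return np.array(y), np.array(v), b, tau2, qe


def test_dl_pooling_matches_metafor(metafor_fit):
    y, v, b_ref, tau2_ref, qe_ref = metafor_fit
    rr_fixed, _ = pool_fixed(y, v)
    het = q_test(y, v, rr_fixed)
    assert het.q_total == pytest.approx(qe_ref, rel=1e-6)
    t2 = tau2_dl(het.q_total, 1.0 / v)
    assert t2 == pytest.approx(tau2_ref, rel=1e-6)
    rr, _ = pool_mixed(y, v, t2)
    assert rr == pytest.approx(b_ref, rel=1e-6)
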