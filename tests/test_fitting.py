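"""Michaelis-Menten fitting, Monte-Carlo uncertainty, identifiability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import invivokinetics as ivk
from invivokinetics.fitting import (
    DegenerateNoiseError,
    KineticDataset,
    assess_identifiability,
    fit_michaelis_menten,
    michaelis_menten,
    monte_carlo_uncertainty,
)

from conftest import MEDIUM_PANEL_S, TRUTH_K, TRUTH_VMAX


class TestPointEstimate:
    def test_noiseless_self_consistency(self, noiseless_dataset):
        fit = fit_michaelis_menten(noiseless_dataset)
        assert fit.vmax_hat == pytest.approx(TRUTH_VMAX, rel=1e-6)
        assert fit.k_half_hat == pytest.approx(TRUTH_K, rel=1e-6)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_matches_independent_optimizer(self, noisy_dataset):
        """Cross-check the point estimate against lmfit on the same data."""
        lmfit = pytest.importorskip("lmfit")
        ours = fit_michaelis_menten(noisy_dataset)

        mod = lmfit.Model(lambda s, vmax, k: vmax * s / (k + s), independent_vars=["s"])
        pars = mod.make_params(vmax=dict(value=500, min=0), k=dict(value=10, min=0))
        ref = mod.fit(noisy_dataset.rate, pars, s=noisy_dataset.substrate)
        assert ours.vmax_hat == pytest.approx(ref.params["vmax"].value, rel=1e-4)
        assert ours.k_half_hat == pytest.approx(ref.params["k"].value, rel=1e-4)

    def test_near_linear_regime_recovers_efficiency_only(self):
        # all S <= K/100: only Vmax/K is constrained; covariance is near-singular
        s = np.linspace(0.01, 0.19, 10)
        v = michaelis_menten(s, TRUTH_VMAX, TRUTH_K)
        fit = fit_michaelis_menten(KineticDataset(s, v))
        assert fit.vmax_hat / fit.k_half_hat == pytest.approx(TRUTH_VMAX / TRUTH_K, rel=1e-3)
        assert fit.cov_condition > 1e8

    def test_row_order_invariance(self, noisy_dataset):
        fit1 = fit_michaelis_menten(noisy_dataset)
        perm = np.random.default_rng(0).permutation(len(noisy_dataset))
        fit2 = fit_michaelis_menten(
            KineticDataset(noisy_dataset.substrate[perm], noisy_dataset.rate[perm])
        )
        assert fit2.vmax_hat == pytest.approx(fit1.vmax_hat, rel=1e-9)
        assert fit2.k_half_hat == pytest.approx(fit1.k_half_hat, rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3))
    def test_rescaling_equivariance(self, c):
        """Scaling substrate by c rescales K by c; scaling rates rescales Vmax."""
        rng = np.random.default_rng(123)
        s = np.repeat(MEDIUM_PANEL_S, 3)
        v = np.clip(michaelis_menten(s, TRUTH_VMAX, TRUTH_K) + rng.normal(0, 40, s.size),
                    0, None)
        base = fit_michaelis_menten(KineticDataset(s, v))
        fs = fit_michaelis_menten(KineticDataset(s * c, v))
        assert fs.k_half_hat == pytest.approx(base.k_half_hat * c, rel=1e-6)
        assert fs.vmax_hat == pytest.approx(base.vmax_hat, rel=1e-6)
        fv = fit_michaelis_menten(KineticDataset(s, v * c))
        assert fv.vmax_hat == pytest.approx(base.vmax_hat * c, rel=1e-6)
        assert fv.k_half_hat == pytest.approx(base.k_half_hat, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_michaelis_menten(KineticDataset([1.0, 2.0], [0.1, 0.2]))

    def test_dataset_invariants_enforced(self):
        with pytest.raises(ValueError):
            KineticDataset([0.0, 1.0, 2.0], [0.1, 0.2, 0.3])  # zero substrate
        with pytest.raises(ValueError):
            KineticDataset([1.0, 2.0, 3.0], [-0.1, 0.2, 0.3])  # negative rate


class TestMonteCarlo:
    def test_seeded_reproducibility_is_bit_identical(self, noisy_dataset):
        f1 = monte_carlo_uncertainty(noisy_dataset, fit_michaelis_menten(noisy_dataset),
                                     n=200, seed=7)
        f2 = monte_carlo_uncertainty(noisy_dataset, fit_michaelis_menten(noisy_dataset),
                                     n=200, seed=7)
        assert f1.mc_summary["vmax"] == f2.mc_summary["vmax"]
        assert f1.mc_summary["k_half"] == f2.mc_summary["k_half"]
        np.testing.assert_array_equal(f1.mc_samples["vmax"], f2.mc_samples["vmax"])

    def test_summary_fields_are_consistent(self, noisy_dataset):
        fit = monte_carlo_uncertainty(noisy_dataset, fit_michaelis_menten(noisy_dataset),
                                      n=400, seed=1)
        for s in fit.mc_summary.values():
            assert s.ci95_low <= s.mean <= s.ci95_high
            assert s.rsd == pytest.approx(s.sd / s.mean)

    def test_noiseless_input_raises_degenerate_noise(self, noiseless_dataset):
        fit = fit_michaelis_menten(noiseless_dataset)
        with pytest.raises(DegenerateNoiseError, match="noise_floor"):
            monte_carlo_uncertainty(noiseless_dataset, fit, n=10, seed=0)
        # a user-supplied noise floor unblocks the analysis
        out = monte_carlo_uncertainty(noiseless_dataset, fit, n=50, seed=0, noise_floor=5.0)
        assert out.n_mc == 50

    def test_interval_width_stable_when_doubling_samples(self, noisy_dataset):
        fit = fit_michaelis_menten(noisy_dataset)
        a = monte_carlo_uncertainty(noisy_dataset, fit, n=1000, seed=3).mc_summary
        fit2 = fit_michaelis_menten(noisy_dataset)
        b = monte_carlo_uncertainty(noisy_dataset, fit2, n=2000, seed=4).mc_summary
        for p in ("vmax", "k_half"):
            wa = a[p].ci95_high - a[p].ci95_low
            wb = b[p].ci95_high - b[p].ci95_low
            assert wb == pytest.approx(wa, rel=0.15)  # stochastic tolerance


class TestIdentifiability:
    def test_saturating_panel_is_identifiable(self):
        rng = np.random.default_rng(5)
        s = np.repeat(np.geomspace(1, 20 * TRUTH_K, 8), 3)  # up to 20x K
        v = michaelis_menten(s, TRUTH_VMAX, TRUTH_K) * rng.lognormal(0, 0.1, s.size)
        data = KineticDataset(s, v)
        fit = assess_identifiability(
            monte_carlo_uncertainty(data, fit_michaelis_menten(data), n=400, seed=5)
        )
        assert fit.identifiable == {"vmax": True, "k_half": True}
        assert fit.mc_summary["vmax"].rsd < 0.2
        assert fit.lower_limits is None

    def test_linear_regime_panel_flagged_with_lower_limits(self):
        # K far above the substrate span: parameters unbounded above, only
        # lower limits can be stated
        rng = np.random.default_rng(6)
        s = np.repeat(np.geomspace(4, 100, 8), 3)
        v = michaelis_menten(s, 13.0, 560.0) * rng.lognormal(0, 0.1, s.size)
        data = KineticDataset(s, v)
        fit = assess_identifiability(
            monte_carlo_uncertainty(data, fit_michaelis_menten(data), n=400, seed=6)
        )
        assert fit.identifiable["k_half"] is False
        assert fit.lower_limits is not None
        for lim in fit.lower_limits.values():
            assert np.isfinite(lim) and lim > 0

    def test_requires_monte_carlo_first(self, noisy_dataset):
        with pytest.raises(ValueError, match="monte_carlo"):
            assess_identifiability(fit_michaelis_menten(noisy_dataset))
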