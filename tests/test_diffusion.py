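"""Jump-distance mixture fitting: CDF model, AIC selection, bootstrap."""

import numpy as np
import pytest
from scipy.integrate import quad

from morphotrack import synthetic
from morphotrack.diffusion import (
    JumpSample,
    MixtureFit,
    bootstrap_fit,
    collect_jumps,
    compare_models_aic,
    empirical_cdf,
    fit_mixture,
    mixture_cdf,
    mixture_pdf,
)
from morphotrack.tracking import Track


def make_sample(distances, tau=0.0117, r_tr=1.66):
    return JumpSample(
        distances=np.asarray(distances), frame_cycle_time=tau, tracking_radius=r_tr
    )


def straight_track(n, step=0.3):
    xy = np.column_stack([np.arange(n) * step, np.zeros(n)])
    return Track(frames=np.arange(n), xy=xy)


class TestCollectJumps:
    def test_counts_and_cap(self):
        sample = collect_jumps([straight_track(3)], 0.0117)
        assert sample.n_jumps == 2
        sample = collect_jumps([straight_track(15)], 0.0117)
        assert sample.n_jumps == 10  # per-track cap

    def test_gap_jumps_excluded(self):
        tr = Track(frames=[0, 1, 3, 4], xy=[[0, 0], [0.1, 0], [0.3, 0], [0.4, 0]])
        sample = collect_jumps([tr], 0.0117)
        assert sample.n_jumps == 2  # 0->1 and 3->4 only

    def test_region_filter(self):
        a, b = straight_track(4), straight_track(4)
        a.region_label = "cavity"
        b.region_label = "interface"
        assert collect_jumps([a, b], 0.0117, region="cavity").n_jumps == 3


class TestMixtureCdf:
    def test_boundary_values(self):
        d, a = np.array([1.0]), np.array([1.0])
        assert mixture_cdf(0.0, d, a, 0.0117, 1.66)[0] == 0.0
        assert mixture_cdf(1.66, d, a, 0.0117, 1.66)[0] == 1.0
        assert mixture_cdf(5.0, d, a, 0.0117, 1.66)[0] == 1.0

    def test_reduces_to_plain_brownian_cdf_for_huge_radius(self):
        r = np.linspace(0, 1.0, 50)
        d, a, tau = np.array([2.0]), np.array([1.0]), 0.0117
        model = mixture_cdf(r, d, a, tau, 1e6)
        plain = 1 - np.exp(-(r**2) / (4 * 2.0 * tau))
        assert np.allclose(model, plain, atol=1e-12)

    def test_cdf_monotone_in_range(self):
        d = np.array([0.05, 1.0, 12.0])
        a = np.array([0.4, 0.4, 0.2])
        r = np.linspace(0, 1.66, 400)
        vals = mixture_cdf(r, d, a, 0.0117, 1.66)
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals.min() >= 0 and vals.max() <= 1

    def test_pdf_integrates_to_one(self):
        d = np.array([0.05, 1.0, 12.0])
        a = np.array([0.4, 0.4, 0.2])
        tau, r_tr = 0.0117, 1.66

        def density(r):
            return mixture_pdf(
                np.array([r]), d, a, tau, r_tr, bin_width=1.0
            )[0]

        total, _ = quad(density, 0, r_tr, limit=200)
        assert abs(total - 1.0) < 1e-6


class TestFitMixture:
    def test_single_component_recovery_within_2pct(self):
        r, _ = synthetic.generate_jumps(
            [5.0], [1.0], n_jumps=100_000, loc_noise=0.0,
            tracking_radius=1.66, seed=10,
        )
        fit = fit_mixture(make_sample(r), K=1)
        assert abs(fit.D[0] - 5.0) / 5.0 < 0.02
        assert np.isclose(fit.A.sum(), 1.0)

    def test_fit_invariant_to_jump_order(self):
        r, _ = synthetic.generate_jumps(
            [1.0, 10.0], [0.5, 0.5], n_jumps=5000, seed=11
        )
        fit1 = fit_mixture(make_sample(r), K=2)
        rng = np.random.default_rng(0)
        fit2 = fit_mixture(make_sample(rng.permutation(r)), K=2)
        assert np.allclose(fit1.D, fit2.D)
        assert np.allclose(fit1.A, fit2.A)
        assert fit1.RSS == fit2.RSS

    def test_fractions_on_simplex(self):
        r, _ = synthetic.generate_jumps(
            [0.05, 1.0, 12.0], [0.44, 0.39, 0.17], n_jumps=20_000, seed=12
        )
        for k in (2, 3):
            fit = fit_mixture(make_sample(r), K=k)
            assert np.isclose(fit.A.sum(), 1.0)
            assert (fit.A >= 0).all()
            assert np.all(np.diff(fit.D) > 0)

    def test_too_few_jumps_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(make_sample(np.full(50, 0.1)), K=1)

    def test_grid_search_oracle_agreement(self):
        # brute-force grid minimizer as an independent check of the optimum
        r, _ = synthetic.generate_jumps(
            [0.5, 8.0], [0.6, 0.4], n_jumps=10_000, loc_noise=0.0, seed=13
        )
        sample = make_sample(r)
        fit = fit_mixture(sample, K=2)
        grid_d1 = np.linspace(0.3, 0.8, 11)
        grid_d2 = np.linspace(5.0, 12.0, 15)
        grid_a = np.linspace(0.4, 0.8, 9)
        centers, cdf_emp = empirical_cdf(sample)
        best = None
        for d1 in grid_d1:
            for d2 in grid_d2:
                for a1 in grid_a:
                    model = mixture_cdf(
                        centers, np.array([d1, d2]), np.array([a1, 1 - a1]),
                        sample.frame_cycle_time, sample.tracking_radius,
                    )
                    rss = ((model - cdf_emp) ** 2).sum()
                    if best is None or rss < best[0]:
                        best = (rss, d1, d2, a1)
        _, d1, d2, a1 = best
        assert abs(fit.D[0] - d1) <= (grid_d1[1] - grid_d1[0])
        assert abs(fit.D[1] - d2) <= (grid_d2[1] - grid_d2[0])
        assert abs(fit.A[0] - a1) <= (grid_a[1] - grid_a[0])
        assert fit.RSS <= best[0] + 1e-9


class TestAic:
    def test_closed_form_arithmetic(self):
        f2 = MixtureFit(2, np.array([1.0, 5.0]), np.array([0.5, 0.5]), 1.0,
                        0.0117, 1.66, 1660, 1000)
        f3 = MixtureFit(3, np.array([1.0, 5.0, 9.0]), np.array([0.3, 0.3, 0.4]),
                        1.0, 0.0117, 1.66, 1660, 1000)
        # equal RSS: dAIC = 2*4 - 2*6 = -4
        assert compare_models_aic(f2, f3) == pytest.approx(-4.0)

    def test_nonpositive_rss_rejected(self):
        f = MixtureFit(2, np.array([1.0, 5.0]), np.array([0.5, 0.5]), 0.0,
                       0.0117, 1.66, 1660, 1000)
        with pytest.raises(ValueError):
            compare_models_aic(f, f)

    def test_model_selection_on_synthetic_mixtures(self):
        # genuine 3-component data favours K=3; 2-component data does not
        delta3, delta2 = [], []
        for seed in range(3):
            r3, _ = synthetic.generate_jumps(
                [0.05, 1.0, 12.0], [0.44, 0.39, 0.17], n_jumps=30_000,
                seed=20 + seed,
            )
            s3 = make_sample(r3)
            delta3.append(
                compare_models_aic(fit_mixture(s3, 2), fit_mixture(s3, 3))
            )
            r2, _ = synthetic.generate_jumps(
                [0.2, 8.0], [0.5, 0.5], n_jumps=30_000, loc_noise=0.0,
                seed=40 + seed,
            )
            s2 = make_sample(r2)
            delta2.append(
                compare_models_aic(fit_mixture(s2, 2), fit_mixture(s2, 3))
            )
        assert all(d > 0 for d in delta3)
        assert np.mean(delta2) <= np.mean(delta3)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        r, _ = synthetic.generate_jumps([2.0], [1.0], n_jumps=4000, seed=30)
        sample = make_sample(r)
        sd1 = bootstrap_fit(sample, 1, n_reps=10, seed=7)
        sd2 = bootstrap_fit(sample, 1, n_reps=10, seed=7)
        assert np.array_equal(sd1[0], sd2[0])
        assert np.array_equal(sd1[1], sd2[1])

    def test_sd_shrinks_with_sample_size(self):
        small, _ = synthetic.generate_jumps([2.0], [1.0], n_jumps=2000, seed=31)
        large, _ = synthetic.generate_jumps([2.0], [1.0], n_jumps=32_000, seed=32)
        sd_small = bootstrap_fit(make_sample(small), 1, n_reps=20, seed=1)[0][0]
        sd_large = bootstrap_fit(make_sample(large), 1, n_reps=20, seed=1)[0][0]
        assert sd_large < sd_small

    def test_single_rep_warns(self):
        r, _ = synthetic.generate_jumps([2.0], [1.0], n_jumps=1000, seed=33)
        with pytest.warns(UserWarning):
            bootstrap_fit(make_sample(r), 1, n_reps=1, seed=2)
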