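"""Estimator correctness against independent oracles, limits, and invariances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockmr import (
    SimulationConfig,
    egger,
    ivw,
    max_likelihood,
    presso,
    raps,
    wald_ratio,
    weighted_median,
)
from conftest import make_pairs, random_instance, triplet_pairs


# ---------------------------------------------------------------- oracles


def wls_through_origin(bx, by, sy):
    """Normal-equations weighted least squares of by on bx, no intercept."""
    w = 1.0 / np.asarray(sy) ** 2
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def wls_with_intercept(bx, by, sy):
    """Normal-equations WLS of by on [1, bx]."""
    X = np.column_stack([np.ones_like(bx), bx])
    W = np.diag(1.0 / np.asarray(sy) ** 2)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
    return float(beta[0]), float(beta[1])


def brute_weighted_median(ratios, weights):
    """Cumulative-weight interpolation computed from first principles."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    j = np.searchsorted(s, 0.5)
    frac = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
    return float(r[j - 1] + frac * (r[j] - r[j - 1]))


def grid_golden_ml(bx, sx, by, sy):
    """Grid scan plus golden-section refinement of the profile likelihood."""

    def nll(theta):
        return 0.5 * np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2))

    grid = np.linspace(-3, 3, 2001)
    i = int(np.argmin([nll(t) for t in grid]))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    for _ in range(100):
        if nll(c) < nll(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    return float((a + b) / 2)


# ---------------------------------------------------------------- wald


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx, by, sy, theta, se",
        [(0.5, 0.1, 0.05, 0.2, 0.1), (1.0, 0.37, 0.05, 0.37, 0.05),
         (-0.5, 0.1, 0.05, -0.2, 0.1)],
    )
    def test_arithmetic_and_sign(self, bx, by, sy, theta, se):
        est = wald_ratio(bx, 0.02, by, sy)
        assert est.theta == pytest.approx(theta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_beta_is_hard_error(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.02, 0.1, 0.05)


# ---------------------------------------------------------------- ivw


class TestIVW:
    def test_identical_ratios_degenerate_homogeneity(self):
        bx = np.array([0.2, 0.3, 0.4])
        pairs = make_pairs(bx, 0.01, 0.5 * bx, [0.05, 0.04, 0.06])
        fixed = ivw(pairs, model="fixed")
        random = ivw(pairs, model="random")
        assert fixed.theta == pytest.approx(0.5)
        assert fixed.extras["q"] == pytest.approx(0.0, abs=1e-20)
        assert random.se == pytest.approx(fixed.se)

    def test_matches_wls_origin_oracle(self):
        pairs = make_pairs([0.2, 0.4, 0.5], 0.01, [0.1, 0.1, 0.2], 0.05)
        est = ivw(pairs, model="fixed")
        assert est.theta == pytest.approx(
            wls_through_origin(pairs["beta_x"], pairs["beta_y"], pairs["se_y"]), abs=1e-12
        )

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(10):
            pairs, _ = random_instance(rng)
            assert ivw(pairs, model="random").se >= ivw(pairs, model="fixed").se - 1e-15

    def test_single_pair_is_hard_error(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(make_pairs([0.2], 0.01, [0.1], 0.05))


# ---------------------------------------------------------------- maximum likelihood


class TestMaxLikelihood:
    def test_reduces_to_ivw_when_exposure_noise_vanishes(self, rng):
        pairs, _ = random_instance(rng, n=6)
        pairs["se_x"] = 1e-8
        assert max_likelihood(pairs).theta == pytest.approx(
            ivw(pairs, model="fixed").theta, abs=1e-6
        )

    def test_noiseless_collinear_recovers_ratio(self):
        bx = np.array([0.2, 0.3, 0.5])
        pairs = make_pairs(bx, 0.02, 0.3 * bx, 0.05)
        assert max_likelihood(pairs).theta == pytest.approx(0.3, abs=1e-8)

    def test_matches_grid_golden_oracle(self, rng):
        for _ in range(5):
            pairs, _ = random_instance(rng, n=5)
            expected = grid_golden_ml(
                pairs["beta_x"].to_numpy(), pairs["se_x"].to_numpy(),
                pairs["beta_y"].to_numpy(), pairs["se_y"].to_numpy(),
            )
            assert max_likelihood(pairs).theta == pytest.approx(expected, abs=1e-5)


# ---------------------------------------------------------------- egger


class TestEgger:
    def test_exact_linear_recovery(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        pairs = make_pairs(bx, 0.02, 0.03 + 0.4 * bx, 0.05)
        est = egger(pairs)
        assert est.theta == pytest.approx(0.4, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.03, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        bx = np.array([0.15, 0.25, 0.35, 0.45])
        by = np.array([0.02, 0.11, 0.09, 0.21])
        sy = np.array([0.04, 0.05, 0.03, 0.06])
        est = egger(make_pairs(bx, 0.02, by, sy))
        c, slope = wls_with_intercept(bx, by, sy)
        assert est.theta == pytest.approx(slope, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(c, abs=1e-10)

    def test_orientation_invariant_to_exposure_sign(self, rng):
        pairs, _ = random_instance(rng, n=6)
        flipped = pairs.copy()
        flipped["beta_x"] = -flipped["beta_x"]
        flipped["beta_y"] = -flipped["beta_y"]
        a, b = egger(pairs), egger(flipped)
        assert a.theta == pytest.approx(b.theta, abs=1e-12)
        assert a.extras["intercept"] == pytest.approx(b.extras["intercept"], abs=1e-12)

    def test_balanced_pleiotropy_intercept_pvalues_uniform(self):
        # under balanced pleiotropy the intercept test should be calibrated
        from scipy import stats

        pvals = []
        for rep in range(300):
            cfg = SimulationConfig(
                direct_effect=0.065, pleiotropy="balanced", pleiotropy_sd=0.02,
                n_mediator_snps=0, palindromic_fraction=0.0,
            )
            pairs = triplet_pairs(cfg, seed=40_000 + rep)
            pvals.append(egger(pairs).extras["intercept_pval"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------- weighted median


class TestWeightedMedian:
    def test_middle_element_with_equal_weights(self):
        pairs = make_pairs([1.0, 1.0, 1.0], 0.01, [0.1, 0.2, 0.9], 0.05)
        assert weighted_median(pairs, n_boot=50, seed=0).theta == pytest.approx(0.2)

    def test_symmetric_masses_interpolate_to_zero(self):
        pairs = make_pairs([1.0, 1.0], 0.01, [-1.0, 1.0], 0.05)
        # two pairs fall below the estimator's minimum, so call the kernel
        from clockmr.mr import _weighted_median

        assert _weighted_median(np.array([-1.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = 5
            bx = rng.uniform(0.1, 0.6, n)
            sy = rng.uniform(0.02, 0.09, n)
            by = rng.normal(0.2 * bx, sy)
            pairs = make_pairs(bx, 0.02, by, sy)
            est = weighted_median(pairs, n_boot=50, seed=1)
            assert est.theta == pytest.approx(
                brute_weighted_median(by / bx, bx**2 / sy**2), abs=1e-12
            )

    def test_seeded_bootstrap_reproducible(self, rng):
        pairs, _ = random_instance(rng, n=6)
        a = weighted_median(pairs, n_boot=200, seed=7)
        b = weighted_median(pairs, n_boot=200, seed=7)
        assert a.se == b.se


# ---------------------------------------------------------------- raps


class TestRaps:
    def test_reduces_to_ivw_fixed(self, rng):
        pairs, _ = random_instance(rng, n=8)
        pairs["se_x"] = 1e-10
        # force near-zero overdispersion by construction: refit ys on the line
        theta0 = ivw(pairs, model="fixed").theta
        pairs["beta_y"] = theta0 * pairs["beta_x"] + 0.01 * pairs["se_y"]
        est = raps(pairs)
        assert est.extras["tau2"] == 0.0
        assert est.theta == pytest.approx(ivw(pairs, model="fixed").theta, abs=1e-4)

    def test_huber_resists_gross_outlier(self):
        cfg = SimulationConfig(direct_effect=0.065, n_mediator_snps=0, palindromic_fraction=0.0)
        closer = 0
        for rep in range(25):
            pairs = triplet_pairs(cfg, seed=60_000 + rep)
            spiked = pairs.copy()
            spiked.loc[spiked.index[0], "beta_y"] += 10 * spiked["se_y"].iloc[0]
            clean = ivw(pairs, model="fixed").theta
            d_huber = abs(raps(spiked, loss="huber").theta - clean)
            d_l2 = abs(raps(spiked, loss="l2").theta - clean)
            closer += d_huber < d_l2
        assert closer >= 20

    def test_overdispersion_recovery(self):
        # tau2 estimating equation is unbiased at the truth; the mean of
        # tau2-hat over replicates should sit near the injected value
        cfg = SimulationConfig(
            direct_effect=0.065, pleiotropy="balanced", pleiotropy_sd=0.1,
            n_snps=100, n_mediator_snps=0, palindromic_fraction=0.0, se_y=0.05,
        )
        tau2_true = 0.01
        ests = []
        for rep in range(200):
            pairs = triplet_pairs(cfg, seed=70_000 + rep)
            ests.append(raps(pairs).extras["tau2"])
        mean, sem = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - tau2_true) < 3 * sem


# ---------------------------------------------------------------- presso


class TestPresso:
    def test_seeded_determinism(self, rng):
        pairs, _ = random_instance(rng, n=8)
        a = presso(pairs, n_sim=300, seed=5)
        b = presso(pairs, n_sim=300, seed=5)
        assert a.global_pval == b.global_pval
        assert np.allclose(a.outlier_table["pval_raw"], b.outlier_table["pval_raw"])

    def test_spiked_snp_flagged_and_corrected(self):
        cfg = SimulationConfig(direct_effect=0.065, n_mediator_snps=0, palindromic_fraction=0.0)
        pairs = triplet_pairs(cfg, seed=123)
        spiked = pairs.copy()
        spike_id = spiked["snp_id"].iloc[3]
        spiked.loc[spiked.index[3], "beta_y"] += 10 * spiked["se_y"].iloc[3]
        res = presso(spiked, n_sim=500, seed=9)
        assert spike_id in res.outliers
        uncorrected = ivw(spiked).theta
        assert abs(res.estimate.theta - 0.065) < abs(uncorrected - 0.065)
        assert res.distortion_pval is not None

    def test_too_few_instruments_is_hard_error(self):
        pairs = make_pairs([0.2, 0.3, 0.4], 0.01, [0.1, 0.1, 0.2], 0.05)
        with pytest.raises(ValueError):
            presso(pairs)


# ---------------------------------------------------------------- shared invariances


ALL_ESTIMATORS = [
    ("ivw", lambda p: ivw(p)),
    ("ml", max_likelihood),
    ("egger", egger),
    ("wmedian", lambda p: weighted_median(p, n_boot=50, seed=3)),
    ("raps", lambda p: raps(p)),
]


class TestSharedInvariants:
    @pytest.mark.parametrize("name, fn", ALL_ESTIMATORS)
    def test_outcome_scale_equivariance(self, name, fn, rng):
        pairs, _ = random_instance(rng, n=7)
        c = 2.5
        scaled = pairs.copy()
        scaled["beta_y"] *= c
        scaled["se_y"] *= c
        assert fn(scaled).theta == pytest.approx(c * fn(pairs).theta, rel=1e-6)

    @pytest.mark.parametrize("name, fn", ALL_ESTIMATORS)
    def test_instrument_order_invariance(self, name, fn, rng):
        pairs, _ = random_instance(rng, n=7)
        shuffled = pairs.sample(frac=1.0, random_state=2).reset_index(drop=True)
        # numeric optimizers (ML) re-converge from permuted sums, so allow
        # float-level slack; closed-form estimators agree far tighter
        assert fn(shuffled).theta == pytest.approx(fn(pairs).theta, rel=1e-6, abs=1e-9)

    def test_noiseless_collinear_data_all_methods_agree(self):
        bx = np.array([0.15, 0.25, 0.4, 0.55])
        pairs = make_pairs(bx, 0.02, 0.3 * bx, 0.05)
        thetas = [fn(pairs).theta for _, fn in ALL_ESTIMATORS] + [
            presso(pairs, n_sim=100, seed=1).estimate.theta
        ]
        assert np.allclose(thetas, 0.3, atol=1e-6)
        assert ivw(pairs).extras["q"] == pytest.approx(0.0, abs=1e-20)

    @given(theta=st.floats(-1.0, 1.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_or_transform_is_exact_exponential(self, theta):
        pairs = make_pairs([0.2, 0.3, 0.4], 0.01, theta * np.array([0.2, 0.3, 0.4]), 0.05)
        est = ivw(pairs)
        assert est.odds_ratio == np.exp(est.theta)
        assert est.or_ci_low == np.exp(est.ci_low)
        assert est.or_ci_high == np.exp(est.ci_high)
        assert est.ci_low == pytest.approx(est.theta - 1.959964 * est.se, abs=1e-15)
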