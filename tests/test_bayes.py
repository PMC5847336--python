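"""Posterior construction: frequency posteriors from calibration bins,
correlation ratios, KDE-product combination, posterior support."""

import numpy as np
import pandas as pd
import pytest

from lm2r.bayes import (
    CorrelationPosterior,
    EmptyBinError,
    FrequencyPosterior,
    combine_posteriors,
    posterior_correlation,
    posterior_frequency,
    posterior_support,
)
from lm2r.calibration import CALIBRATION_COLUMNS


def calib_from(rows):
    return pd.DataFrame(rows, columns=CALIBRATION_COLUMNS)


def flat_calib(factor, freq, n=30, n_bp=4):
    return calib_from([(f"f{k}", 1, 20, n_bp, factor, freq) for k in range(n)])


class TestPosteriorFrequency:
    def test_degenerate_calibration_gives_its_frequency(self):
        post = posterior_frequency(0.51, flat_calib(0.5, 0.5), n_bp=4)
        assert post.median == pytest.approx(0.5)

    def test_matching_is_per_bin_and_n_bp(self):
        rows = []
        for k in range(25):
            rows.append((f"a{k}", 1, 20, 4, 0.52, 0.6))  # matching bin [0.50, 0.55)
            rows.append((f"b{k}", 1, 20, 4, 0.93, 0.9))  # far bin
            rows.append((f"c{k}", 1, 20, 8, 0.52, 0.2))  # wrong size
        post = posterior_frequency(0.51, calib_from(rows), n_bp=4)
        assert post.median == pytest.approx(0.6)
        assert post.relaxations == ()

    def test_observation_below_all_bins_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            post = posterior_frequency(-0.4, flat_calib(0.5, 0.37), n_bp=4)
        assert post.median == pytest.approx(0.37)
        assert any("clamped" in r for r in post.relaxations)
        assert "nearest populated bin" in caplog.text

    def test_starved_cell_widens_to_neighbours(self):
        rows = [(f"x{k}", 1, 20, 4, 0.47, 0.4) for k in range(25)]
        rows += [("lone", 1, 20, 4, 0.52, 0.9)]
        post = posterior_frequency(0.51, calib_from(rows), n_bp=4)
        assert any("widened" in r for r in post.relaxations)
        assert len(post.samples) == 26

    def test_empty_after_widening_raises(self):
        with pytest.raises(EmptyBinError, match="n_bp~3"):
            posterior_frequency(0.5, flat_calib(0.5, 0.5, n_bp=10), n_bp=3)

    def test_median_rank_monotone_in_factor(self, toy_calibration):
        medians = [
            posterior_frequency(f, toy_calibration, n_bp=4).median
            for f in (0.05, 0.3, 0.55, 0.8)
        ]
        assert medians == sorted(medians)

    def test_credible_interval_orders(self, toy_calibration):
        post = posterior_frequency(0.5, toy_calibration, n_bp=4)
        lo, hi = post.credible_interval()
        assert 0 <= lo <= post.median <= hi <= 1


class TestPosteriorCorrelation:
    def test_self_ratio_centers_at_one(self):
        wt = FrequencyPosterior("h1", np.linspace(0.2, 0.8, 50))
        post = posterior_correlation(wt, wt, pair_ref=("h1", "h2"))
        assert post.median == pytest.approx(1.0, abs=0.1)

    def test_exhaustive_ratio_set(self):
        wt = FrequencyPosterior("h1", np.full(10, 0.5))
        locked = FrequencyPosterior("h1|lock-h2", np.full(10, 0.05))
        post = posterior_correlation(wt, locked, pair_ref=("h1", "h2"))
        assert np.allclose(post.samples, 0.1)
        assert post.median == pytest.approx(0.1)
        assert post.support_above_1 == 0.0

    def test_published_point_medians_reproduce_strong_anticorrelation(self):
        """Locked 5% over unconditional 53% gives g ~ 0.094."""
        wt = FrequencyPosterior("P1", np.array([0.53]))
        locked = FrequencyPosterior("P1|lock-P4B", np.array([0.05]))
        post = posterior_correlation(wt, locked, pair_ref=("P1", "P4B"))
        assert post.median == pytest.approx(0.094, abs=0.001)

    def test_zero_wildtype_samples_excluded_then_error(self):
        locked = FrequencyPosterior("a", np.array([0.5]))
        mixed = FrequencyPosterior("b", np.array([0.0, 0.4]))
        post = posterior_correlation(mixed, locked, pair_ref=("a", "b"))
        assert len(post.samples) == 1
        zeros = FrequencyPosterior("b", np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="correlation undefined"):
            posterior_correlation(zeros, locked, pair_ref=("a", "b"))

    def test_cross_product_capped_with_seed(self):
        rng = np.random.default_rng(0)
        wt = FrequencyPosterior("h1", rng.uniform(0.2, 0.8, 2000))
        locked = FrequencyPosterior("h1|l", rng.uniform(0.2, 0.8, 2000))
        a = posterior_correlation(wt, locked, pair_ref=("x", "y"), max_samples=10_000, seed=1)
        b = posterior_correlation(wt, locked, pair_ref=("x", "y"), max_samples=10_000, seed=1)
        assert len(a.samples) == 10_000
        assert np.array_equal(a.samples, b.samples)


class TestCombinePosteriors:
    def uniform_posterior(self, seed, n=4000):
        rng = np.random.default_rng(seed)
        return CorrelationPosterior(("a", "b"), np.sort(rng.uniform(0, 2, n)))

    def test_combining_flat_posteriors_splits_mass_at_one(self):
        comb = combine_posteriors(self.uniform_posterior(1), self.uniform_posterior(2))
        assert comb.support_above_1 == pytest.approx(0.5, abs=0.05)

    def test_self_combination_sharpens(self):
        rng = np.random.default_rng(3)
        post = CorrelationPosterior(("a", "b"), np.sort(rng.normal(0.8, 0.2, 5000).clip(0)))
        comb = combine_posteriors(post, post)
        assert comb.median == pytest.approx(post.median, abs=0.05)
        assert np.std(comb.samples) < np.std(post.samples)

    def test_sharp_mass_dominates_broad_mass(self):
        rng = np.random.default_rng(4)
        sharp = CorrelationPosterior(("a", "b"), np.sort(rng.normal(0.1, 0.02, 2000).clip(0)))
        broad = CorrelationPosterior(("a", "b"), np.sort(rng.normal(0.3, 0.15, 2000).clip(0)))
        comb = combine_posteriors(sharp, broad)
        assert 0.1 < comb.median < 0.3
        assert comb.median < 0.2  # nearer the sharp component

    def test_commutative_on_shared_grid(self):
        a, b = self.uniform_posterior(5), self.uniform_posterior(6)
        ab = combine_posteriors(a, b)
        ba = combine_posteriors(b, a)
        assert np.array_equal(ab.grid, ba.grid)
        assert np.allclose(ab.density, ba.density)

    def test_mismatched_pairs_rejected(self):
        a = CorrelationPosterior(("a", "b"), np.array([1.0]))
        c = CorrelationPosterior(("c", "d"), np.array([1.0]))
        with pytest.raises(ValueError, match="cannot combine"):
            combine_posteriors(a, c)

    def test_disjoint_supports_flagged(self):
        rng = np.random.default_rng(8)
        lo = CorrelationPosterior(("a", "b"), np.sort(rng.normal(0.01, 0.004, 300).clip(0)))
        hi = CorrelationPosterior(("a", "b"), np.sort(rng.normal(3.9, 0.01, 300)))
        with pytest.raises(ValueError, match="disjoint|inconsistent"):
            combine_posteriors(lo, hi)


class TestPosteriorSupport:
    def test_all_samples_below_threshold(self):
        post = CorrelationPosterior(("a", "b"), np.linspace(0, 0.9, 50))
        assert posterior_support(post, 1.0) == 0.0

    def test_threshold_zero_is_total_mass(self):
        post = CorrelationPosterior(("a", "b"), np.linspace(0.1, 2, 50))
        assert posterior_support(post, 0.0) == 1.0

    def test_uniform_density_half_above_one(self):
        rng = np.random.default_rng(7)
        post = CorrelationPosterior(("a", "b"), np.sort(rng.uniform(0, 2, 5000)))
        assert posterior_support(post, 1.0) == pytest.approx(0.5, abs=0.03)
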