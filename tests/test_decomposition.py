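import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vgwas import (
    coefficient_of_variation,
    decompose,
    decompose_locus,
    genotype_moments,
    groups_from_calls,
    h2_curves,
    median_deviation_correlation,
    optimal_laf,
)

freqs = st.floats(0.01, 0.99)
means = st.floats(-100, 100)
sds = st.floats(0.0, 50.0)


class TestGenotypeMoments:
    def test_labels_by_sample_sd(self):
        g = groups_from_calls([0, 0, 2, 2])
        m = genotype_moments([0.0, 2.0, 10.0, 14.0], g)
        assert m.low.sd == pytest.approx(np.sqrt(2))
        assert m.high.sd == pytest.approx(np.sqrt(8))
        assert m.high.mean == 12.0 and not m.swapped

    def test_sd_tie_breaks_to_allele_a(self):
        g = groups_from_calls([0, 0, 2, 2])
        m = genotype_moments([0.0, 2.0, 7.0, 9.0], g)
        assert not m.swapped  # call-0 group stays "low" on an exact tie
        assert m.low.mean == 1.0

    def test_one_element_group_errors(self):
        g = groups_from_calls([0, 2, 2])
        with pytest.raises(ValueError):
            genotype_moments([1.0, 2.0, 3.0], g)


class TestDecompose:
    def test_worked_molybdenum_transporter_case(self):
        # per-genotype means 0.22/1.35 and SDs 0.10/0.59 at LAF 0.5
        d = decompose(0.5, 0.22, 1.35, 0.10, 0.59)
        assert d.h2_m == pytest.approx(0.6406, abs=5e-4)
        assert d.h2_d == pytest.approx(0.1205, abs=5e-4)
        assert d.s2_P == pytest.approx(0.49828, abs=5e-5)
        assert d.d_mu == pytest.approx(1.13) and d.d_sigma == pytest.approx(0.49)

    def test_no_heterogeneity_limit(self):
        d = decompose(0.3, 1.0, 3.0, 0.8, 0.8)
        assert d.h2_d == 0.0
        pq = 0.3 * 0.7
        assert d.h2_m == pytest.approx(pq * 4 / (pq * 4 + 0.64))

    def test_pure_variance_limit(self):
        d = decompose(0.4, 0.0, 0.0, 0.0, 2.0)
        assert d.h2_m == 0.0
        assert d.s2_eps == pytest.approx((0.6 * 2.0) ** 2)
        assert d.s2_d == pytest.approx(0.4 * 0.6 * 4.0)

    def test_zero_total_variance(self):
        d = decompose(0.5, 1.0, 1.0, 0.0, 0.0)
        assert d.s2_P == 0.0 and d.h2_m == 0.0 and d.h2_d == 0.0

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            decompose(0.0, 0, 1, 1, 2)
        with pytest.raises(ValueError):
            decompose(1.0, 0, 1, 1, 2)

    @given(p=freqs, m1=means, m2=means, s1=sds, s2=sds)
    def test_identity_and_bounds(self, p, m1, m2, s1, s2):
        d = decompose(p, m1, m2, s1, s2)
        total = d.s2_m + d.s2_d + d.s2_eps
        mixture = (
            d.p_low * d.q_high * d.d_mu**2
            + d.p_low * d.sd_low**2
            + d.q_high * d.sd_high**2
        )
        assert d.s2_P == total
        assert total == pytest.approx(mixture, rel=1e-12, abs=1e-12)
        assert d.d_sigma >= 0.0
        assert 0.0 <= d.h2_m and 0.0 <= d.h2_d
        assert d.h2_m + d.h2_d <= 1.0 + 1e-12

    @given(p=freqs, m1=means, m2=means, s1=sds, s2=sds)
    def test_label_exchange_invariance(self, p, m1, m2, s1, s2):
        a = decompose(p, m1, m2, s1, s2)
        b = decompose(1 - p, m2, m1, s2, s1)
        assert a.h2_m == pytest.approx(b.h2_m, rel=1e-12, abs=1e-12)
        assert a.h2_d == pytest.approx(b.h2_d, rel=1e-12, abs=1e-12)
        assert a.s2_P == pytest.approx(b.s2_P, rel=1e-12, abs=1e-12)

    def test_plug_in_estimates_consistent(self):
        # generating truth: LAF 0.5, means 0/1, SDs 1/2 -> h2_d = 0.25/2.75
        rng = np.random.default_rng(17)
        theo = decompose(0.5, 0.0, 1.0, 1.0, 2.0).h2_d
        est = []
        for _ in range(300):
            calls = np.where(rng.random(500) < 0.5, 0, 2).astype(np.int8)
            low = calls == 0
            y = np.where(low, 0.0, 1.0) + np.where(low, 1.0, 2.0) * rng.standard_normal(500)
            est.append(decompose_locus(y, groups_from_calls(calls)).h2_d)
        assert np.mean(est) == pytest.approx(theo, abs=0.01)


class TestOptimalLAF:
    def test_symmetric_when_no_heterogeneity(self):
        assert optimal_laf(1.3, 1.3) == 0.5

    def test_worked_value(self):
        assert optimal_laf(0.59, 0.10) == pytest.approx(0.8551, abs=1e-4)

    @given(s1=st.floats(0.05, 20), s2=st.floats(0.05, 20), d_mu=st.floats(-10, 10))
    def test_agrees_with_grid_maximization(self, s1, s2, d_mu):
        from hypothesis import assume

        sd_high, sd_low = max(s1, s2), min(s1, s2)
        assume(sd_high > 1.05 * sd_low)  # near-equal SDs make the curve flat
        grid = np.arange(1e-4, 1.0, 1e-4)
        curves = h2_curves(0.0, d_mu, sd_low, sd_high, grid)
        argmax = grid[np.argmax(curves["h2_d"].to_numpy())]
        assert optimal_laf(sd_high, sd_low) == pytest.approx(argmax, abs=2e-4)

    def test_both_sds_zero(self):
        with pytest.raises(ValueError):
            optimal_laf(0.0, 0.0)


class TestH2Curves:
    def test_maximum_at_optimal_laf_and_edge_decay(self):
        grid = np.linspace(0.001, 0.999, 999)
        curves = h2_curves(0.0, 1.0, 0.5, 1.5, grid)
        at_opt = decompose(optimal_laf(1.5, 0.5), 0.0, 1.0, 0.5, 1.5).h2_d
        assert at_opt >= curves["h2_d"].max() - 1e-12
        assert curves["h2_d"].iloc[0] < 0.01 and curves["h2_d"].iloc[-1] < 0.01
        assert (curves[["h2_m", "h2_d"]] >= 0).all().all()

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            h2_curves(0, 1, 1, 2, np.array([0.0, 0.5]))


class TestCV:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(1.36, 0.64, 0.47), (80.3, 68.2, 0.85), (125.9, 52.8, 0.42), (5.0, 0.0, 0.0)],
    )
    def test_values(self, mean, sd, expected):
        assert round(coefficient_of_variation(mean, sd), 2) == expected

    def test_zero_mean(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(0.0, 1.0)


class TestMedianDeviationCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        df = pd.DataFrame({"a": y, "b": -y})
        corr = median_deviation_correlation(df, mode="signed")
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_absolute_mode_links_dispersion(self):
        # shared dispersion process: |deviations| correlate even when the
        # signed values do not
        rng = np.random.default_rng(1)
        scale = rng.gamma(2.0, 1.0, size=400)
        df = pd.DataFrame(
            {
                "a": scale * rng.choice([-1, 1], 400),
                "b": scale * rng.choice([-1, 1], 400),
            }
        )
        corr = median_deviation_correlation(df, mode="absolute")
        assert corr.loc["a", "b"] > 0.7

    def test_independent_traits_uncorrelated(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        corr = median_deviation_correlation(df)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_insufficient_pairs_gives_nan(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, np.nan, 1.0, 2.0]}
        )
        corr = median_deviation_correlation(df)
        assert np.isnan(corr.loc["a", "b"])
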