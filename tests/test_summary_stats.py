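"""Mode, 95% interval, 2-sf rounding and flow/share tables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nanomfa import (
    interval_95,
    mode_estimate,
    round_2sf,
    run_monte_carlo,
    flow_table,
    source_receiver_table,
)
from nanomfa.summary_stats import destination_share_samples, zero_fraction


class TestInterval95:
    def test_constant_vector(self):
        assert interval_95(np.full(100, 3.7)) == (3.7, 3.7)

    def test_uniform_quantiles_recovered(self):
        x = np.random.default_rng(0).uniform(0, 1, 100_000)
        lo, hi = interval_95(x)
        assert abs(lo - 0.025) < 0.005 and abs(hi - 0.975) < 0.005

    def test_matches_sort_based_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.lognormal(rng.normal(), rng.uniform(0.1, 2), size=rng.integers(2, 500))
            lo, hi = interval_95(x)
            # brute-force: sort, then linear interpolation between order stats
            s = np.sort(x)
            for q, got in ((0.025, lo), (0.975, hi)):
                pos = q * (s.size - 1)
                i = int(np.floor(pos))
                frac = pos - i
                want = s[i] if i + 1 >= s.size else s[i] * (1 - frac) + s[i + 1] * frac
                assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            interval_95([])


class TestModeEstimate:
    def test_point_mass_samples(self):
        assert mode_estimate(np.full(100, 13.0)) == 13.0

    def test_lognormal_mode_recovered(self):
        x = np.random.default_rng(5).lognormal(0, 1, 100_000)
        assert mode_estimate(x) == pytest.approx(np.exp(-1), abs=0.05)

    def test_zero_majority_returns_zero(self):
        x = np.concatenate([np.zeros(600), np.random.default_rng(0).uniform(1, 2, 400)])
        assert mode_estimate(x) == 0.0

    def test_all_zero_returns_zero(self):
        assert mode_estimate(np.zeros(50)) == 0.0

    def test_mode_within_sample_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.lognormal(rng.normal(), rng.uniform(0.2, 2), 5000)
            m = mode_estimate(x)
            assert x.min() <= m <= x.max()

    def test_scale_equivariance_on_positive_samples(self):
        x = np.random.default_rng(8).lognormal(0, 0.7, 50_000)
        m1 = mode_estimate(x)
        m2 = mode_estimate(1000.0 * x)
        # within one log-bin width of exact equivariance
        h = 2 * (np.percentile(np.log10(x), 75) - np.percentile(np.log10(x), 25)) / x.size ** (1 / 3)
        assert abs(np.log10(m2 / (1000 * m1))) < h

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mode_estimate(np.ones(5))


class TestRound2SF:
    @pytest.mark.parametrize(
        "value, expected",
        [(1234, 1200), (0.0456, 0.046), (9.96, 10.0), (0, 0.0), (99.5, 100.0)],
    )
    def test_examples(self, value, expected):
        assert round_2sf(value) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=1e-30, max_value=1e30, allow_nan=False))
    def test_idempotent(self, x):
        once = round_2sf(x)
        assert round_2sf(once) == once

    @given(st.floats(min_value=1e-30, max_value=1e30))
    def test_within_ten_percent_of_input(self, x):
        assert abs(round_2sf(x) - x) <= 0.1 * x


class TestFlowTable:
    def test_deterministic_toy_modal_flows_exact(self, toy_chain):
        mc = run_monte_carlo(toy_chain, n_iter=100, seed=0)
        tab = flow_table(mc).set_index(["origin", "destination"])
        assert tab.loc[("stp", "sludge"), "mode_t_per_y"] == pytest.approx(90.0)
        assert tab.loc[("stp", "effluent"), "mode_t_per_y"] == pytest.approx(10.0)

    def test_modal_flow_within_sampled_range(self, toy_chain_stochastic):
        mc = run_monte_carlo(toy_chain_stochastic, n_iter=2000, seed=1)
        tab = flow_table(mc)
        for _, row in tab.iterrows():
            i = mc.edge_index(row["origin"], row["destination"])
            col = mc.edge_flows[:, i]
            assert col.min() - 1e-12 <= row["mode_t_per_y"] <= col.max() + 1e-12

    def test_shares_sum_to_hundred_per_receiver(self, toy_chain_stochastic):
        mc = run_monte_carlo(toy_chain_stochastic, n_iter=2000, seed=2)
        shares = source_receiver_table(mc)
        for _, grp in shares.groupby("receiver"):
            assert grp["share_pct"].sum() == pytest.approx(100.0)

    def test_two_point_mass_sources_split_ninety_ten(self):
        from conftest import make_toy_chain

        cfg = make_toy_chain()  # water receives sludge 90 + effluent 10
        mc = run_monte_carlo(cfg, n_iter=100, seed=0)
        shares = source_receiver_table(mc).set_index(["receiver", "source"])
        assert shares.loc[("water", "sludge"), "share_pct"] == pytest.approx(90.0)
        assert shares.loc[("water", "effluent"), "share_pct"] == pytest.approx(10.0)

    def test_destination_share_samples_on_chain(self, toy_chain):
        mc = run_monte_carlo(toy_chain, n_iter=100, seed=0)
        s = destination_share_samples(mc, "stp", ("sludge",))
        np.testing.assert_allclose(s, 0.9, atol=1e-12)


class TestZeroFraction:
    def test_counts_exact_zeros_only(self):
        x = np.array([0.0, 0.0, 1e-300, 2.0])
        assert zero_fraction(x) == 0.5
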