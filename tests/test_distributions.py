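"""Distribution sampling: correctness, support, determinism."""

import numpy as np
import pytest

from nanomfa.distributions import (
    DistributionError,
    DistributionSpec as D,
    sample_distribution,
)

N_BIG = 100_000


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSampling:
    def test_point_mass_is_constant(self):
        assert sample_distribution(D.point(5.0), 3, rng()).tolist() == [5.0, 5.0, 5.0]

    def test_uniform_mean_within_clt_bound(self):
        # E = 0.5, sd = 1/sqrt(12); 3·sd/sqrt(n) = 0.0027 < 0.005
        x = sample_distribution(D.uniform(0, 1), N_BIG, rng())
        assert abs(x.mean() - 0.5) < 0.005

    def test_triangular_mean_within_clt_bound(self):
        # E = (0+1+3)/3 = 4/3; sd² = (l²+m²+u²−lm−lu−mu)/18 = 7/18
        x = sample_distribution(D.triangular(0, 1, 3), N_BIG, rng())
        assert abs(x.mean() - 4.0 / 3.0) < 0.006

    @pytest.mark.parametrize(
        "spec",
        [
            D.uniform(0.2, 3.0),
            D.triangular(0.0, 1.0, 3.0),
            D.normal_truncated(1.0, 2.0),
            D.lognormal(0.0, 1.0),
            D.expert_mixture([D.uniform(0, 1), D.triangular(1, 2, 4)]),
            D.point(2.5),
        ],
        ids=lambda s: s.kind,
    )
    def test_ecdf_matches_analytic_cdf_at_deciles(self, spec):
        """Kolmogorov-style check: empirical CDF of 1e5 draws within 0.01
        of the analytic CDF at the analytic deciles."""
        x = np.sort(sample_distribution(spec, N_BIG, rng(7)))
        lo, hi = spec.support()
        hi = min(hi, np.quantile(x, 0.999))
        grid = np.linspace(lo, hi, 11)
        ecdf = np.searchsorted(x, grid, side="right") / x.size
        assert np.max(np.abs(ecdf - spec.cdf(grid))) < 0.01

    @pytest.mark.parametrize(
        "spec",
        [
            D.normal_truncated(0.1, 5.0),  # heavy truncation at 0
            D.lognormal(-2, 2),
            D.expert_mixture([D.normal_truncated(0.0, 1.0), D.point(0.0)]),
        ],
        ids=["truncnorm", "lognormal", "mixture"],
    )
    def test_support_is_nonnegative(self, spec):
        x = sample_distribution(spec, 20_000, rng(3))
        assert x.min() >= 0.0

    def test_draws_stay_inside_bounded_support(self):
        spec = D.triangular(0.25, 0.5, 0.75)
        x = sample_distribution(spec, 10_000, rng(1))
        assert x.min() >= 0.25 and x.max() <= 0.75

    def test_mixture_components_both_represented(self):
        spec = D.expert_mixture([D.point(1.0), D.point(2.0)])
        x = sample_distribution(spec, 1000, rng(5))
        frac_one = np.mean(x == 1.0)
        assert np.all((x == 1.0) | (x == 2.0))
        assert 0.4 < frac_one < 0.6  # equal component weights


class TestDeterminism:
    @pytest.mark.parametrize(
        "spec",
        [D.uniform(0, 1), D.normal_truncated(1, 1),
         D.expert_mixture([D.uniform(0, 1), D.lognormal(0, 1)])],
        ids=lambda s: s.kind,
    )
    def test_equal_seeds_bit_identical(self, spec):
        a = sample_distribution(spec, 1000, rng(123))
        b = sample_distribution(spec, 1000, rng(123))
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        a = sample_distribution(D.uniform(0, 1), 100, rng(1))
        b = sample_distribution(D.uniform(0, 1), 100, rng(2))
        assert not np.array_equal(a, b)


class TestValidation:
    @pytest.mark.parametrize(
        "spec, field",
        [
            (D.uniform(3, 1), "upper"),
            (D.uniform(-1, 1), "lower"),
            (D.triangular(0, 5, 3), "mode"),
            (D.normal_truncated(1, 0), "sd"),
            (D.lognormal(0, -1), "sigma"),
            (D.point(-2), "value"),
            (D.expert_mixture([]), "components"),
            (D("weibull", {"k": 2}), "kind"),
        ],
    )
    def test_problem_message_names_offending_field(self, spec, field):
        probs = spec.problems()
        assert probs and any(field in p for p in probs)

    def test_sampling_invalid_spec_raises(self):
        with pytest.raises(DistributionError, match="upper"):
            sample_distribution(D.uniform(2, 1), 10, rng())

    def test_n_zero_rejected(self):
        with pytest.raises(DistributionError, match="n"):
            sample_distribution(D.point(1), 0, rng())

    def test_nested_mixture_problems_are_prefixed(self):
        spec = D.expert_mixture([D.uniform(0, 1), D.uniform(5, 2)])
        assert any("components[1]" in p for p in spec.problems())


class TestMeanAndRoundTrip:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (D.uniform(0, 0.2), 0.1),
            (D.triangular(0, 1, 3), 4.0 / 3.0),
            (D.lognormal(0, 1), np.exp(0.5)),
            (D.expert_mixture([D.point(1), D.point(3)]), 2.0),
        ],
        ids=lambda v: getattr(v, "kind", v),
    )
    def test_analytic_mean(self, spec, expected):
        assert spec.mean() == pytest.approx(expected, rel=1e-12)

    def test_truncnorm_mean_matches_sample_mean(self):
        spec = D.normal_truncated(0.5, 1.0)
        x = sample_distribution(spec, N_BIG, rng(11))
        assert spec.mean() == pytest.approx(x.mean(), abs=3 * x.std() / np.sqrt(N_BIG))

    def test_dict_round_trip(self):
        spec = D.expert_mixture([D.uniform(0, 1, "share"), D.triangular(1, 2, 3)], "share")
        assert D.from_dict(spec.to_dict()) == spec

    def test_from_dict_unknown_kind_names_field(self):
        with pytest.raises(DistributionError, match="kind"):
            D.from_dict({"kind": "gamma", "shape": 2})
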