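"""Unit and property tests for the one-generation recursion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sexgames import (
    GenotypeDistribution,
    ModelParams,
    allele_frequencies,
    asexual_contributions,
    care_levels,
    mating_rates,
    pair_fitness,
    segregation_tensor,
    sexual_contributions,
    sexual_fraction,
    step,
)
from sexgames.core import DegenerateStateError, _step_raw, _fitness_matrix

from conftest import (
    FITNESS_EXPRESSIONS,
    enumerate_offspring,
    random_distribution,
    random_params,
)

M_NAMES = ("nn", "nc", "cc")


def unit_state(index: int) -> GenotypeDistribution:
    p = np.zeros(9)
    p[index] = 1.0
    return GenotypeDistribution(p)


simplex9 = st.lists(
    st.floats(min_value=0.0, max_value=1.0), min_size=9, max_size=9
).filter(lambda v: sum(v) > 1e-6)

params_st = st.builds(
    ModelParams,
    R=st.floats(min_value=0.0, max_value=3.0),
    m=st.floats(min_value=1.0, max_value=10.0),
    b=st.floats(min_value=0.0, max_value=1.0),
    k=st.floats(min_value=0.0, max_value=1.0),
    alpha=st.floats(min_value=0.0, max_value=1.0),
)


def normalized(values) -> GenotypeDistribution:
    arr = np.asarray(values, dtype=float)
    return GenotypeDistribution(arr / arr.sum())


class TestTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(R=-0.1, m=2.0, b=0.5, k=0.5, alpha=0.5),
            dict(R=1.0, m=0.5, b=0.5, k=0.5, alpha=0.5),
            dict(R=1.0, m=2.0, b=1.5, k=0.5, alpha=0.5),
            dict(R=1.0, m=2.0, b=0.5, k=-0.1, alpha=0.5),
            dict(R=1.0, m=2.0, b=0.5, k=0.5, alpha=2.0),
        ],
    )
    def test_params_bounds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_distribution_validates_and_renormalizes(self):
        with pytest.raises(ValueError):
            GenotypeDistribution([0.5] * 9)
        with pytest.raises(ValueError):
            GenotypeDistribution([-0.1] + [0.11] * 8 + [0.22])
        d = GenotypeDistribution(np.full(9, (1 + 5e-13) / 9))
        assert d.p.sum() == pytest.approx(1.0, abs=1e-15)

    def test_distribution_is_immutable(self):
        d = unit_state(0)
        with pytest.raises(ValueError):
            d.p[0] = 0.5


class TestSexualFraction:
    @pytest.mark.parametrize(
        "index,alpha,expected",
        [(6, 0.5, 1.0), (0, 0.7, 0.0), (3, 0.3, 0.3)],
    )
    def test_pure_states(self, index, alpha, expected):
        assert sexual_fraction(unit_state(index), alpha) == pytest.approx(expected)

    def test_mixed_state(self):
        d = normalized([1, 0, 0, 2, 0, 0, 3, 0, 0])
        # alpha-weighted heterozygotes plus all obligate sexuals
        assert sexual_fraction(d, 0.25) == pytest.approx((0.25 * 2 + 3) / 6)


class TestCareAndFitness:
    def test_care_levels(self):
        care = care_levels(ModelParams(R=1.5, m=2.0, b=0.5, k=0.5, alpha=0.5))
        assert care.male == (1.0, 0.5, 0.0)
        assert care.female == (1.0, 0.75, 0.5)

    @given(params=params_st)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_pair_fitness_matches_printed_expressions(self, params):
        for (male, female), expr in FITNESS_EXPRESSIONS.items():
            expected = expr(params.R, params.b, params.k)
            assert pair_fitness(male, female, params) == pytest.approx(
                expected, abs=1e-12
            )

    def test_heterozygote_pair_example(self):
        params = ModelParams(R=1.6, m=2.0, b=0.5, k=0.5, alpha=0.5)
        assert pair_fitness("nc", "nc", params) == pytest.approx(2.2)


class TestSegregation:
    def test_matches_gamete_enumeration_exactly(self):
        seg = segregation_tensor()
        for qm in range(6):
            for qf in range(6):
                expected = [float(f) for f in enumerate_offspring(qm, qf)]
                assert seg[qm, qf].tolist() == expected

    @pytest.mark.parametrize(
        "qm,qf,row",
        [
            # ss nn x ss nn breeds true
            (3, 3, [0, 0, 0, 0, 0, 0, 1, 0, 0]),
            # double-heterozygote cross: the classic 1:2:1 x 1:2:1 table
            (1, 1, [1 / 16, 1 / 8, 1 / 16, 1 / 8, 1 / 4, 1 / 8, 1 / 16, 1 / 8, 1 / 16]),
            # as nn x ss cc gives only single-locus heterozygotes
            (0, 5, [0, 0, 0, 0, 1 / 2, 0, 0, 1 / 2, 0]),
        ],
    )
    def test_reference_rows(self, qm, qf, row):
        assert segregation_tensor()[qm, qf].tolist() == pytest.approx(row)

    def test_rows_are_distributions(self):
        seg = segregation_tensor()
        assert np.all(seg >= 0)
        assert np.allclose(seg.sum(axis=2), 1.0, atol=0)


class TestMatingRates:
    def test_no_polygyny_potential_means_uniform_mating(self, rng):
        params = random_params(rng, m=1.0)
        rates = mating_rates(random_distribution(rng), params)
        assert rates == pytest.approx((1.0, 1.0, 1.0))

    def test_rare_polygynous_males_get_m(self):
        params = ModelParams(R=1.0, m=3.0, b=0.5, k=0.5, alpha=0.5)
        rates = mating_rates(unit_state(6), params)  # all monogamous sexuals
        assert rates.polygynous == pytest.approx(3.0)
        assert rates.monogamous == pytest.approx(1.0)

    def test_common_polygynous_males_get_one(self):
        params = ModelParams(R=1.0, m=4.0, b=0.5, k=0.5, alpha=0.5)
        rates = mating_rates(unit_state(8), params)  # all polygynous
        assert rates.polygynous == pytest.approx(1.0)
        assert rates.monogamous == pytest.approx(1.0 / 4.0)

    @given(weights=simplex9, params=params_st)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_mate_balance_identity(self, weights, params):
        """Male mating successes, weighted by male frequencies, equal the
        total proportion of females."""
        dist = normalized(weights)
        p = dist.p
        alpha = params.alpha
        rates = mating_rates(dist, params)
        lhs = (
            0.5 * (alpha * p[3] + p[6]) * rates.monogamous
            + 0.5 * (alpha * p[4] + p[7]) * rates.heterozygote
            + 0.5 * (alpha * p[5] + p[8]) * rates.polygynous
        )
        assert lhs == pytest.approx(sexual_fraction(dist, alpha) / 2, abs=1e-12)

    @given(weights=simplex9, params=params_st)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_rate_bounds_and_ordering(self, weights, params):
        rates = mating_rates(normalized(weights), params)
        assert 1.0 - 1e-12 <= rates.polygynous <= params.m + 1e-12
        assert -1e-12 <= rates.monogamous <= 1.0 + 1e-12
        low = min(rates.monogamous, rates.polygynous) - 1e-12
        high = max(rates.monogamous, rates.polygynous) + 1e-12
        assert low <= rates.heterozygote <= high

    def test_rates_decrease_with_polygynous_share(self):
        """At fixed sexual fraction, all three rates fall as the
        polygyny-weighted male share X rises."""
        params = ModelParams(R=1.0, m=3.0, b=0.5, k=0.3, alpha=0.5)
        previous = None
        for w in np.linspace(0.0, 1.0, 11):  # all sexual; X = w
            rates = mating_rates(normalized([0, 0, 0, 0, 0, 0, 1 - w, 0, w]), params)
            if previous is not None:
                assert rates.polygynous < previous.polygynous
                assert rates.heterozygote < previous.heterozygote
                assert rates.monogamous < previous.monogamous
            previous = rates

    def test_infinite_polygyny_limit(self, rng):
        """As m grows without bound, monogamous males are shut out and the
        polygynous excess tends to Y/X."""
        dist = random_distribution(rng)
        params = random_params(rng, m=1e9)
        p = dist.p
        k, alpha = params.k, params.alpha
        X = alpha * p[5] + p[8] + k * (alpha * p[4] + p[7])
        Y = alpha * p[3] + p[6] + (1 - k) * (alpha * p[4] + p[7])
        rates = mating_rates(dist, params)
        assert rates.monogamous < 1e-8
        assert rates.polygynous - 1.0 == pytest.approx(Y / X, rel=1e-6)


class TestContributions:
    def test_asexual_contributions(self):
        d = normalized([0.4, 0, 0, 0, 0.4, 0, 0, 0, 0.2])
        out = asexual_contributions(d, alpha=0.25)
        assert out[0] == pytest.approx(0.4)
        assert out[4] == pytest.approx(0.3)
        assert out[8] == 0.0
        assert np.all(asexual_contributions(d, alpha=1.0)[3:6] == 0.0)

    def test_monogamous_population_contributes_R(self):
        params = ModelParams(R=1.7, m=2.0, b=0.5, k=0.5, alpha=0.5)
        out = sexual_contributions(unit_state(6), params)
        expected = np.zeros(9)
        expected[6] = params.R
        assert out == pytest.approx(expected)

    def test_zero_when_no_sexuals(self, rng):
        d = normalized([1, 2, 3, 0, 0, 0, 0, 0, 0])
        assert np.all(sexual_contributions(d, random_params(rng)) == 0.0)

    @given(weights=simplex9, params=params_st)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_tabular_oracle(self, weights, params):
        """The vectorized contribution sum equals an explicit loop over the
        36 ordered crossings using the printed fitness expressions, the
        eta/pi mating functions and brute-force gamete enumeration."""
        dist = normalized(weights)
        p = dist.p
        R, m, b, k, alpha = params.R, params.m, params.b, params.k, params.alpha
        eff = [alpha * p[3], alpha * p[4], alpha * p[5], p[6], p[7], p[8]]
        tau = sum(eff)
        expected = np.zeros(9)
        if tau > 0:
            X = eff[2] + eff[5] + k * (eff[1] + eff[4])
            Y = eff[0] + eff[3] + (1 - k) * (eff[1] + eff[4])
            D = 1 + (m - 1) * X
            eta = (m - 1) * Y / D
            pi = (m - 1) * X / D
            rate = (1 - pi, 1 - pi * (1 - k) + eta * k, 1 + eta)
            for qm in range(6):
                for qf in range(6):
                    pair = FITNESS_EXPRESSIONS[(M_NAMES[qm % 3], M_NAMES[qf % 3])]
                    weight = eff[qm] * eff[qf] * rate[qm % 3] * pair(R, b, k) / (2 * tau)
                    for off, frac in enumerate(enumerate_offspring(qm, qf)):
                        expected[off] += weight * float(frac)
        actual = sexual_contributions(dist, params)
        assert actual == pytest.approx(expected, abs=1e-13)


class TestStep:
    def test_pure_asexual_is_fixed_point(self, rng):
        d = unit_state(0)
        params = random_params(rng)
        for _ in range(5):
            d = step(d, params)
        assert d.p == pytest.approx(unit_state(0).p)

    @given(weights=simplex9, params=params_st)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_output_is_distribution(self, weights, params):
        out = step(normalized(weights), params)
        assert np.all(out.p >= 0)
        assert out.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_state_raises(self):
        params = ModelParams(R=1.0, m=2.0, b=0.5, k=0.5, alpha=0.5)
        with pytest.raises(DegenerateStateError):
            _step_raw(np.zeros(9), params.alpha, params.m, params.k,
                      _fitness_matrix(params))


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "index,expected",
        [(6, (0.0, 1.0, 1.0, 0.0)), (4, (0.5, 0.5, 0.5, 0.5))],
    )
    def test_pure_states(self, index, expected):
        assert allele_frequencies(unit_state(index)) == pytest.approx(expected)

    def test_complementarity(self, rng):
        freqs = allele_frequencies(random_distribution(rng))
        assert freqs.a + freqs.s == pytest.approx(1.0)
        assert freqs.n + freqs.c == pytest.approx(1.0)
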