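import math

import numpy as np
import pytest

from bellcog import (
    MEASUREMENTS,
    AssumptionError,
    ElasticBand,
    RodConfig,
    chsh,
    closed_form_table,
    fit_elastic,
    maximal_violation_orientations,
    mixed_probs,
    predicted_table,
    rod_chsh,
    rod_expectation,
    rod_marginals,
    sequential_probs,
    simulate_rod,
)
from bellcog.quantum_model import BlochDirection

SQRT2 = math.sqrt(2.0)


def mc_sequential_oracle(first, second, theta, n, seed):
    """Independent brute-force mechanics: uniform break points, particle
    drawn to +1 iff the break is at or below its coordinate."""
    rng = np.random.default_rng(seed)
    br1 = rng.uniform(first.d - first.epsilon, first.d + first.epsilon, n)
    s1 = np.where(br1 <= 0.0, 1, -1)
    coord2 = -s1 * math.cos(theta)
    br2 = rng.uniform(second.d - second.epsilon, second.d + second.epsilon, n)
    s2 = np.where(br2 <= coord2, 1, -1)
    out = np.empty((2, 2))
    for i, si in ((0, 1), (1, -1)):
        for j, sj in ((0, 1), (1, -1)):
            out[i, j] = np.mean((s1 == si) & (s2 == sj))
    return out


class TestElasticBand:
    def test_parameter_domain(self):
        ElasticBand(1.0, 0.0)
        ElasticBand(0.6, 0.4)
        with pytest.raises(ValueError):
            ElasticBand(0.0, 0.0)
        with pytest.raises(ValueError):
            ElasticBand(0.8, 0.3)  # |d| > 1 - epsilon

    def test_outcome1_probability_is_break_fraction(self):
        band = ElasticBand(0.8, -0.1)
        assert band.outcome1_probability(0.0) == pytest.approx(
            (0.8 + 0.1) / 1.6
        )


class TestSequentialProbs:
    def test_uniform_bands_aligned_axes_anticorrelate(self):
        p = sequential_probs(ElasticBand(1, 0), ElasticBand(1, 0), 0.0)
        np.testing.assert_allclose(p, [[0, 0.5], [0.5, 0]], atol=1e-15)

    def test_orthogonal_axes_uniform(self):
        p = sequential_probs(ElasticBand(1, 0), ElasticBand(1, 0), math.pi / 2)
        np.testing.assert_allclose(p, 0.25, atol=1e-15)

    def test_normalization(self):
        p = sequential_probs(ElasticBand(0.9, 0.05), ElasticBand(0.8, -0.1), math.pi / 3)
        assert p.sum() == pytest.approx(1.0, abs=1e-15)
        assert (p >= 0).all()

    def test_against_monte_carlo_oracle(self):
        first, second = ElasticBand(0.9, 0.05), ElasticBand(0.8, -0.1)
        theta = math.pi / 3
        n = 400_000
        emp = mc_sequential_oracle(first, second, theta, n, seed=11)
        closed = sequential_probs(first, second, theta)
        bound = 3 * np.sqrt(closed * (1 - closed) / n)
        assert (np.abs(emp - closed) <= bound).all()

    def test_landing_assumption_enforced(self):
        with pytest.raises(AssumptionError):
            sequential_probs(ElasticBand(1, 0), ElasticBand(0.6, 0.1), 0.0)


class TestMixedProbs:
    def test_identical_symmetric_bands_are_order_independent(self):
        band = ElasticBand(0.9, 0.0)
        theta = math.pi / 3
        ab = sequential_probs(band, band, theta)
        ba = sequential_probs(band, band, theta).T
        np.testing.assert_allclose(ab, ba, atol=1e-15)
        np.testing.assert_allclose(mixed_probs(band, band, theta), ab, atol=1e-15)

    def test_is_average_of_both_orders(self):
        a, b = ElasticBand(0.8, 0.1), ElasticBand(0.8, -0.05)
        theta = math.acos(0.5)
        expected = 0.5 * (
            sequential_probs(a, b, theta) + sequential_probs(b, a, theta).T
        )
        np.testing.assert_allclose(mixed_probs(a, b, theta), expected, atol=1e-15)

    def test_matches_expanded_closed_form(self):
        """Substitution oracle: the order mixture equals its expanded
        per-cell form 1/8 (1 - dA/eA)(1 - (dB + c)/eB) + 1/8 (1 - dB/eB)
        (1 - (dA + c)/eA) for the (1,1) cell, and analogously elsewhere."""
        eA, dA, eB, dB = 0.85, 0.1, 0.9, -0.05
        c = 0.4
        theta = math.acos(c)
        p = mixed_probs(ElasticBand(eA, dA), ElasticBand(eB, dB), theta)
        p11 = (1 - dA / eA) * (1 - (dB + c) / eB) / 8 + \
              (1 - dB / eB) * (1 - (dA + c) / eA) / 8
        p22 = (1 + dA / eA) * (1 + (dB - c) / eB) / 8 + \
              (1 + dB / eB) * (1 + (dA - c) / eA) / 8
        assert p[0, 0] == pytest.approx(p11, abs=1e-15)
        assert p[1, 1] == pytest.approx(p22, abs=1e-15)

    def test_normalized_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            e1, e2 = rng.uniform(0.5, 1.0, 2)
            d1 = rng.uniform(-(1 - e1), 1 - e1)
            d2 = rng.uniform(-(1 - e2), 1 - e2)
            margin = min(e1 - abs(d1), e2 - abs(d2))
            theta = math.acos(rng.uniform(-margin, margin))
            p = mixed_probs(ElasticBand(e1, d1), ElasticBand(e2, d2), theta)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p >= -1e-15).all() and (p <= 1 + 1e-15).all()


class TestRodMarginals:
    def test_symmetric_bands_preserve_marginal_law(self):
        m = rod_marginals(ElasticBand(0.8, 0.0), ElasticBand(0.9, 0.0), 1.1)
        np.testing.assert_allclose(m, 0.5, atol=1e-15)

    def test_violation_term_magnitude(self):
        # d_B cos(theta) / (4 eps_A eps_B) with eps=0.8, d_B=0.1, cos=0.5
        left = ElasticBand(0.8, 0.0)
        right = ElasticBand(0.8, 0.1)
        m = rod_marginals(left, right, math.acos(0.5))
        assert m[0] - 0.5 == pytest.approx(0.01953125, abs=1e-12)

    def test_orthogonal_axes_remove_cross_term(self):
        """At theta = pi/2 the marginals reduce to the separated values
        (eps -+ d)/(2 eps) even for asymmetric bands."""
        left, right = ElasticBand(0.8, 0.1), ElasticBand(0.9, -0.05)
        m = rod_marginals(left, right, math.pi / 2)
        np.testing.assert_allclose(
            m,
            [(0.8 - 0.1) / 1.6, (0.8 + 0.1) / 1.6,
             (0.9 + 0.05) / 1.8, (0.9 - 0.05) / 1.8],
            atol=1e-15,
        )

    def test_consistency_with_mixed_cells(self):
        left, right = ElasticBand(0.8, 0.1), ElasticBand(0.9, -0.05)
        theta = math.acos(0.3)
        p = mixed_probs(left, right, theta)
        m = rod_marginals(left, right, theta)
        sums = [p[0].sum(), p[1].sum(), p[:, 0].sum(), p[:, 1].sum()]
        np.testing.assert_allclose(sums, m, atol=1e-12)
        assert m[0] + m[1] == pytest.approx(1.0, abs=1e-15)


class TestRodExpectationAndChsh:
    def test_uniform_band_recovers_singlet_correlation(self):
        for theta in (0.1, 0.9, 2.5):
            assert rod_expectation(ElasticBand(1, 0), theta) == pytest.approx(
                -math.cos(theta)
            )

    def test_orthogonal_axes_leave_offset_term(self):
        e = ElasticBand(0.8, 0.15)
        assert rod_expectation(e, math.pi / 2) == pytest.approx(0.15**2 / 0.8**2)

    def test_agrees_with_mixed_cells(self):
        e = ElasticBand(0.85, 0.1)
        theta = math.acos(0.5)
        p = mixed_probs(e, e, theta)
        E = p[0, 0] - p[0, 1] - p[1, 0] + p[1, 1]
        assert rod_expectation(e, theta) == pytest.approx(E, abs=1e-12)

    @pytest.mark.parametrize(
        "eps, d, expected",
        [
            (1.0, 0.0, 2 * SQRT2),
            (SQRT2 / 2, 0.0, 4.0),
            (0.9, 0.05, 2 * abs(SQRT2 / 0.9 - 0.0025 / 0.81)),
        ],
    )
    def test_maximal_violation_values(self, eps, d, expected):
        assert rod_chsh(ElasticBand(eps, d)) == pytest.approx(expected, abs=1e-12)

    def test_asymmetry_reduces_violation(self):
        eps = 0.95
        values = [rod_chsh(ElasticBand(eps, d)) for d in (0.0, 0.01, 0.03, 0.05)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_insufficient_margin_rejected(self):
        with pytest.raises(AssumptionError):
            rod_chsh(ElasticBand(0.6, 0.0))


class TestSimulator:
    def test_perfect_anticorrelation_is_exact(self):
        config = RodConfig.uniform(
            1.0, 0.0, orientations={"A": 0.0, "B": 0.0, "Ap": 0.0, "Bp": 0.0}
        )
        res = simulate_rod(config, 20_000, seed=1)
        b = res.table.block("AB")
        assert b[0, 1] + b[1, 0] == pytest.approx(1.0, abs=0)

    def test_empirical_matches_closed_form(self):
        config = RodConfig.uniform(0.9, 0.05)
        n = 100_000
        res = simulate_rod(config, n, seed=2)
        closed = closed_form_table(config)
        for m in MEASUREMENTS:
            p = closed.block(m)
            bound = 3 * np.sqrt(p * (1 - p) / n) + 1e-12
            assert (np.abs(res.table.block(m) - p) <= bound).all()
        # empirical marginals against the closed-form marginal law terms
        from bellcog.core_tables import MEASUREMENT_AXES

        for m in MEASUREMENTS:
            left, right = MEASUREMENT_AXES[m]
            marg = rod_marginals(
                config.elastics[left], config.elastics[right],
                config.relative_angle(m),
            )
            b = res.table.block(m)
            sums = np.array([b[0].sum(), b[1].sum(), b[:, 0].sum(), b[:, 1].sum()])
            bound = 3 * np.sqrt(marg * (1 - marg) / n)
            assert (np.abs(sums - marg) <= bound).all()

    def test_invalid_inputs_rejected(self):
        config = RodConfig.uniform(1.0, 0.0)
        with pytest.raises(ValueError):
            simulate_rod(config, 0, seed=1)
        bad = RodConfig.uniform(
            0.8, 0.0, orientations={"A": 0.0, "B": 0.1, "Ap": 0.0, "Bp": 0.0}
        )
        with pytest.raises(AssumptionError):
            simulate_rod(bad, 10, seed=1)

    def test_trial_records_trace_mechanics(self):
        config = RodConfig.uniform(1.0, 0.0, order_policy="first-left")
        res = simulate_rod(config, 50, seed=3, keep_records=True)
        assert len(res.records) == 50 * 4
        for rec in res.records[:50]:
            assert rec.order == "left-first"
            assert abs(rec.break_first) <= 1.0
            assert rec.outcomes[0] in (-1, 1) and rec.outcomes[1] in (-1, 1)


class TestQuantumCorrespondence:
    def test_uniform_bands_reproduce_singlet_table_for_coplanar_directions(self):
        """(epsilon, d) = (1, 0) is exactly the singlet Born model."""
        orient = maximal_violation_orientations()
        config = RodConfig.uniform(1.0, 0.0, orientations=orient)
        rod = closed_form_table(config)
        # coplanar Bloch directions at the same in-plane angles
        dirs = {
            name: BlochDirection(theta=orient[ax], phi=0.0)
            for name, ax in (("a", "A"), ("ap", "Ap"), ("b", "B"), ("bp", "Bp"))
        }
        quantum = predicted_table(dirs)
        for m in MEASUREMENTS:
            np.testing.assert_allclose(rod.block(m), quantum.block(m), atol=1e-12)
        assert chsh(rod).absS == pytest.approx(2 * SQRT2, abs=1e-12)


class TestParameterRecovery:
    def test_fit_elastic_recovers_generating_parameters(self):
        config = RodConfig.uniform(0.85, 0.08)
        n = 200_000
        res = simulate_rod(config, n, seed=9)
        fit = fit_elastic(res.table, config.orientations)
        # cell standard error ~ sqrt(p(1-p)/n) ~ 1e-3; parameter error of
        # the same order once propagated through the 16-cell least squares
        assert fit.epsilon == pytest.approx(0.85, abs=0.02)
        assert fit.d == pytest.approx(0.08, abs=0.02)
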