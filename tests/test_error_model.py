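"""Reliability, validity and attenuation arithmetic, checked against printed
design values, brute-force scans, and a Monte-Carlo regression oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expower.error_model import (
    ReliabilityQuery,
    VarianceComponents,
    attenuation_factor,
    bias_grid,
    icc,
    percent_bias,
    repeats_for_max_bias,
    repeats_for_validity,
    validity_coefficient,
)

SOL_VC = VarianceComponents(0.21, 0.72)

positive_vc = st.builds(
    VarianceComponents,
    st.floats(1e-3, 10.0),
    st.floats(1e-3, 10.0),
)


class TestICC:
    def test_case_study_components(self):
        # ICC of the bisphenol variance components rounds to 0.23
        assert icc(SOL_VC) == pytest.approx(0.21 / 0.93, abs=1e-12)
        assert round(icc(SOL_VC), 2) == 0.23

    @pytest.mark.parametrize(
        "vc, expected",
        [
            (VarianceComponents(1.0, 3.0), 0.25),
            (VarianceComponents(0.5, 0.0), 1.0),
            (VarianceComponents(0.0, 0.5), 0.0),
        ],
    )
    def test_direct_arithmetic(self, vc, expected):
        assert icc(vc) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(-0.1, 0.5)

    def test_from_icc_derives_within_variance(self):
        vc = VarianceComponents.from_icc(0.6, 0.019)
        assert vc.sigma2_within == pytest.approx(0.019 * 0.4 / 0.6)
        assert icc(vc) == pytest.approx(0.6)


class TestValidityCoefficient:
    def test_single_measurement_equals_sqrt_icc(self):
        rho = validity_coefficient(SOL_VC, 1)
        assert rho**2 == pytest.approx(0.2258, abs=5e-5)
        assert rho == pytest.approx(0.4752, abs=5e-5)

    def test_no_within_variance_gives_one(self):
        assert validity_coefficient(VarianceComponents(0.3, 0.0), 1) == 1.0

    def test_approaches_one_with_many_repeats(self):
        assert validity_coefficient(SOL_VC, 10**6) == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_m_rejected(self):
        with pytest.raises(ValueError):
            validity_coefficient(SOL_VC, 0)

    @given(vc=positive_vc, m=st.integers(1, 50))
    @settings(derandomize=True, max_examples=50)
    def test_increasing_in_m_and_icc_identity(self, vc, m):
        assert validity_coefficient(vc, m + 1) > validity_coefficient(vc, m)
        assert icc(vc) == pytest.approx(
            validity_coefficient(vc, 1) ** 2, abs=1e-12
        )


class TestRepeatsForValidity:
    # the eight published (ICC, rho) -> repeats design pairs
    @pytest.mark.parametrize(
        "icc_val, rho, m_real_expected, m_int_expected",
        [
            (0.2, 0.7, 3.84, 4),
            (0.2, 0.9, 17.05, 18),
            (0.3, 0.7, 2.24, 3),
            (0.3, 0.9, 9.95, 10),
            (0.4, 0.7, 1.44, 2),
            (0.4, 0.9, 6.39, 7),
            (0.6, 0.7, 0.64, 1),
            (0.6, 0.9, 2.84, 3),
        ],
    )
    def test_published_design_pairs(self, icc_val, rho, m_real_expected,
                                    m_int_expected):
        m_real, m_int = repeats_for_validity(ReliabilityQuery(icc_val, rho))
        assert m_real == pytest.approx(m_real_expected, abs=5e-3)
        assert m_int == m_int_expected

    @given(x=st.floats(0.05, 0.95))
    @settings(derandomize=True, max_examples=30)
    def test_rho_sqrt_icc_needs_one_repeat(self, x):
        m_real, m_int = repeats_for_validity(
            ReliabilityQuery(icc=x, rho=math.sqrt(x))
        )
        assert m_real == pytest.approx(1.0, abs=1e-9)
        assert m_int == 1

    @given(icc_val=st.floats(0.05, 0.95), rho=st.floats(0.05, 0.95))
    @settings(derandomize=True, max_examples=50)
    def test_inverse_of_validity_coefficient(self, icc_val, rho):
        """Unrounded repeats plugged back into the validity formula recover
        the requested coefficient exactly."""
        vc = VarianceComponents.from_icc(icc_val, 1.0)
        m_real, _ = repeats_for_validity(ReliabilityQuery(icc_val, rho))
        assert validity_coefficient(vc, m_real) ** 2 == pytest.approx(
            rho**2, abs=1e-9
        )

    @pytest.mark.parametrize("icc_val, rho", [(0.0, 0.7), (1.0, 0.7),
                                              (0.5, 0.0), (0.5, 1.0)])
    def test_boundaries_rejected(self, icc_val, rho):
        with pytest.raises(ValueError):
            ReliabilityQuery(icc_val, rho)


class TestAttenuation:
    def test_case_study_four_repeats(self):
        assert attenuation_factor(SOL_VC, 4) == pytest.approx(0.84 / 1.56)
        # published as 46% after integer rounding
        assert round(percent_bias(SOL_VC, 4)) == 46

    def test_single_measurement_bias_is_one_minus_icc(self):
        vc = VarianceComponents.from_icc(0.4, 0.0095)
        assert percent_bias(vc, 1) == pytest.approx(60.0)

    def test_error_free_measurements(self):
        vc = VarianceComponents(0.3, 0.0)
        assert attenuation_factor(vc, 3) == 1.0
        assert percent_bias(vc, 3) == 0.0

    def test_zero_between_variance_rejected(self):
        with pytest.raises(ValueError):
            attenuation_factor(VarianceComponents(0.0, 1.0), 2)

    @given(vc=positive_vc, m=st.integers(1, 100))
    @settings(derandomize=True, max_examples=100)
    def test_bias_and_attenuation_sum_to_100(self, vc, m):
        assert percent_bias(vc, m) + 100.0 * attenuation_factor(
            vc, m
        ) == pytest.approx(100.0, abs=1e-9)

    @given(vc=positive_vc, m=st.integers(1, 50))
    @settings(derandomize=True, max_examples=50)
    def test_bias_monotone_in_m_and_within_variance(self, vc, m):
        assert percent_bias(vc, m + 1) < percent_bias(vc, m)
        noisier = VarianceComponents(
            vc.sigma2_between, vc.sigma2_within + 0.5
        )
        assert percent_bias(noisier, m) > percent_bias(vc, m)

    def test_monte_carlo_regression_oracle(self):
        """Simulated regression of outcome on a person-mean of noisy
        measurements recovers the predicted attenuation factor.

        100k persons, m=3 repeats, true slope 0.5; the fitted slope over the
        true slope must match lambda within 2 standard errors of the fit.
        """
        rng = np.random.default_rng(20260919)
        n, m, beta = 100_000, 3, 0.5
        vc = VarianceComponents(0.4, 0.8)
        x = rng.normal(0, math.sqrt(vc.sigma2_between), n)
        w = x + rng.normal(
            0, math.sqrt(vc.sigma2_within), (m, n)
        ).mean(axis=0)
        y = beta * x + rng.normal(0, 1.0, n)
        wc = w - w.mean()
        slope = float(wc @ (y - y.mean()) / (wc @ wc))
        resid = y - y.mean() - slope * wc
        se = math.sqrt(resid @ resid / (n - 2) / (wc @ wc))
        lam = attenuation_factor(vc, m)
        assert abs(slope / beta - lam) < 2 * se / beta


class TestRepeatsForMaxBias:
    @pytest.mark.parametrize(
        "vc, bias_max, expected",
        [
            (SOL_VC, 10.0, 31),            # bias 10.26% at m=30, 9.96% at m=31
            (VarianceComponents(0.0095, 0.01425), 10.0, 14),
            (VarianceComponents(0.5, 0.5), 50.0, 1),
        ],
    )
    def test_known_solutions(self, vc, bias_max, expected):
        assert repeats_for_max_bias(vc, bias_max) == expected

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            vc = VarianceComponents(rng.uniform(0.01, 2), rng.uniform(0.01, 2))
            bias_max = rng.uniform(2, 80)
            answer = repeats_for_max_bias(vc, bias_max)
            scan = next(
                m for m in range(1, 10_000)
                if percent_bias(vc, m) <= bias_max + 1e-12
            )
            assert answer == scan

    @pytest.mark.parametrize("bad", [0.0, 100.0, -5.0])
    def test_invalid_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            repeats_for_max_bias(SOL_VC, bad)


class TestBiasGrid:
    def test_matches_componentwise_bias(self):
        frame = bias_grid([0.2, 0.5, 0.7], [1, 2, 5])
        for row in frame.itertuples():
            vc = VarianceComponents.from_icc(row.icc, 1.0)
            assert row.percent_bias == pytest.approx(
                percent_bias(vc, row.m), abs=1e-9
            )

    def test_known_cell_and_m1_row(self):
        frame = bias_grid([0.7], [1, 5]).set_index("m")
        assert frame.loc[5, "percent_bias"] == pytest.approx(
            0.3 / 3.8 * 100, abs=1e-9
        )
        assert frame.loc[1, "percent_bias"] == pytest.approx(30.0)

    def test_high_icc_bias_vanishes(self):
        frame = bias_grid([1 - 1e-9], [1, 10])
        assert (frame["percent_bias"] < 1e-5).all()

    def test_invalid_icc_rejected(self):
        with pytest.raises(ValueError):
            bias_grid([0.0], [1])
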