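import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifflkit.models import (
    DimensionalParams,
    IFFLParams,
    VariantParams,
    base_derivatives,
    dimensional_derivatives,
    hill_activation,
    nondimensionalize,
    variant_derivatives,
)
from ifflkit.signals import PulseTrain


class TestHillActivation:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (1.0, 110, 0.5),          # half-activation at the threshold
            (0.0, 110, 0.0),
            (1.05, 110, 0.9953531963934953),  # logistic(n*ln x) oracle
            (2.0, 110, 1.0),          # saturated far above threshold
            (0.5, 110, 0.0),          # negligible far below threshold
        ],
    )
    def test_values(self, x, n, expected):
        assert hill_activation(x, n) == pytest.approx(expected, abs=1e-12)

    def test_no_overflow_at_large_x(self):
        # x^110 overflows float64 already at x ~ 1.3e3^(1/110); the log-space
        # form must stay finite everywhere
        for x in (10.0, 1e6, 1e300):
            assert hill_activation(x, 110) == pytest.approx(1.0)

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(-0.1, 110)

    @given(x=st.floats(1e-3, 1e3), n=st.floats(1, 200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reciprocal_symmetry(self, x, n):
        """hill(x) + hill(1/x) = 1: the logistic form is antisymmetric in
        log space."""
        assert hill_activation(x, n) + hill_activation(1 / x, n) == \
            pytest.approx(1.0, abs=1e-12)

    @given(n=st.floats(1, 200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_x(self, n):
        xs = np.linspace(0, 3, 200)
        h = hill_activation(xs, n)
        assert np.all(np.diff(h) >= -1e-15)


class TestBaseDerivatives:
    @pytest.mark.parametrize(
        "state, phi, params, expected",
        [
            ((0.0, 0.0), 1.0, dict(beta=1.2, gamma_R=10, gamma_o=0),
             (1.2, 1.2)),  # empty system under input
            ((1.0, 1.0), 0.0, dict(beta=1.2, gamma_R=10, gamma_o=0),
             (-1.0, -5.0)),  # hill(1)=1/2 so dr = -10*0.5*1
            ((0.5, 2.0), 0.0, dict(beta=1.2, gamma_R=10, gamma_o=0.01),
             (-0.5, -0.02)),  # hill(0.5,110)~0; only basal decay remains
        ],
    )
    def test_examples(self, state, phi, params, expected):
        p = IFFLParams(n=110, **params)
        dx, dr = base_derivatives(state, 0.0, p, phi)
        assert dx == pytest.approx(expected[0], abs=1e-9)
        assert dr == pytest.approx(expected[1], abs=1e-9)

    @given(
        x=st.floats(0, 5), r=st.floats(0, 5), phi=st.floats(0, 2),
        beta=st.floats(0, 4), gR=st.floats(0, 20), go=st.floats(0, 0.2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_degradation_bounded_by_own_level(self, x, r, phi, beta, gR, go):
        """Each derivative is >= -(total degradation rate) * own level, so
        exact trajectories from nonnegative states stay nonnegative."""
        p = IFFLParams(beta=beta, gamma_R=gR, gamma_o=go, n=110)
        dx, dr = base_derivatives((x, r), 0.0, p, phi)
        assert dx >= -x - 1e-12
        assert dr >= -(gR + go) * r - 1e-12


class TestDimensionalDerivatives:
    def test_empty_system(self):
        p = DimensionalParams(k1=5, k2=5, dx=1, dR=10, dRo=0, Kx=4)
        dX, dR = dimensional_derivatives((0.0, 0.0), 0.0, p, 1.0)
        assert (dX, dR) == (5.0, 5.0)

    def test_half_activation(self):
        p = DimensionalParams(k1=5, k2=5, dx=1, dR=10, dRo=0, Kx=4)
        _, dR = dimensional_derivatives((4.0, 1.0), 0.0, p, 0.0)
        assert dR == pytest.approx(-5.0)

    def test_pure_decay(self):
        p = DimensionalParams(k1=5, k2=5, dx=1, dR=10, dRo=0, Kx=4)
        dX, _ = dimensional_derivatives((4.0, 0.0), 0.0, p, 0.0)
        assert dX == pytest.approx(-4.0)


class TestVariantDerivatives:
    def test_repression_unrepressed_production(self):
        p = VariantParams(variant="repression", beta=12.0, gamma_o=0.0)
        dx, dr = variant_derivatives((0.0, 0.0), 0.0, p, 1.0)
        assert dr == pytest.approx(12.0)
        assert dx == pytest.approx(12.0)

    def test_repression_fully_repressed(self):
        p = VariantParams(variant="repression", beta=12.0, gamma_o=0.0)
        _, dr = variant_derivatives((2.0, 0.0), 0.0, p, 1.0)
        assert dr == pytest.approx(0.0, abs=1e-12)

    def test_delay_inhibition_first_stage(self):
        p = VariantParams(variant="delay_inhibition", beta_p=1.0,
                          beta_pp=1.2, delta=1.0, gamma_R=10.0)
        dx1, dx, dr = variant_derivatives((0.0, 0.0, 0.0), 0.0, p, 1.0)
        assert dx1 == pytest.approx(1.0)
        assert dx == pytest.approx(0.0)
        assert dr == pytest.approx(1.2)

    def test_delay_activation_reporter_driven_by_intermediate(self):
        p = VariantParams(variant="delay_activation", beta_p=5.0,
                          beta_pp=1.2, gamma_R=10.0, gamma_R1=5.0)
        dx, dr1, dr = variant_derivatives((0.0, 1.0, 0.0), 0.0, p, 0.0)
        assert dx == pytest.approx(0.0)
        assert dr1 == pytest.approx(-5.0)
        assert dr == pytest.approx(1.2)  # production reads r1, not the input

    def test_positive_feedback_latch_term(self):
        p = VariantParams(variant="positive_feedback", beta=1.2,
                          gamma_R=0.01, alpha=100.0, n=110.0)
        # at x=2 the feedback is saturated: dx ~ beta*phi + alpha - x
        dx, dr = variant_derivatives((2.0, 1.0), 0.0, p, 0.0)
        assert dx == pytest.approx(98.0, abs=1e-6)
        assert dr == pytest.approx(-0.02)  # bilinear degradation gamma_R*x*r

    def test_dimension_mismatch_rejected(self):
        p = VariantParams(variant="repression", beta=12.0)
        with pytest.raises(ValueError, match="dimension"):
            variant_derivatives((0.0, 0.0, 0.0), 0.0, p, 1.0)

    def test_missing_and_foreign_parameters_rejected(self):
        with pytest.raises(ValueError, match="requires"):
            VariantParams(variant="positive_feedback", beta=1.2,
                          gamma_R=0.01)  # alpha missing
        with pytest.raises(ValueError, match="does not apply"):
            VariantParams(variant="repression", beta=12.0, alpha=100.0)


class TestNondimensionalize:
    @pytest.mark.parametrize("scale", [1.0, 100.0])
    def test_molecule_number_invariance(self, scale):
        """Scaling k1=k2 and Kx together leaves the dimensionless
        parameters unchanged (beta=1.25, gamma_R=10, gamma_o=0)."""
        dp = DimensionalParams(k1=5 * scale, k2=5 * scale, dx=1, dR=10,
                               dRo=0, Kx=4 * scale)
        p, _, _ = nondimensionalize(dp)
        assert p.beta == pytest.approx(1.25)
        assert p.gamma_R == pytest.approx(10.0)
        assert p.gamma_o == 0.0

    def test_identity_mapping(self):
        dp = DimensionalParams(k1=3, k2=3, dx=1, dR=10, dRo=0, Kx=1)
        train = PulseTrain(k=2, T=4, D=1, tau0=1)
        p, scaled, rscale = nondimensionalize(dp, train)
        assert p.beta == pytest.approx(3.0)
        assert scaled == train
        assert rscale == pytest.approx(1.0)

    def test_time_rescaling_and_round_trip(self):
        dp = DimensionalParams(k1=5, k2=7, dx=2.0, dR=10, dRo=0.3, Kx=4)
        train = PulseTrain(k=3, T=4, D=1, tau0=1)
        p, scaled, rscale = nondimensionalize(dp, train)
        assert p.beta == pytest.approx(7 / 8)
        assert p.gamma_R == pytest.approx(5.0)
        assert p.gamma_o == pytest.approx(0.15)
        assert scaled.T == pytest.approx(8.0)
        assert scaled.D == pytest.approx(2.0)
        assert scaled.tau0 == pytest.approx(2.0)
        assert rscale == pytest.approx(7 / 20)
        # invert the mapping: recover the dimensional quantities
        assert p.beta * dp.Kx * dp.dx == pytest.approx(dp.k2, rel=1e-12)
        assert p.gamma_R * dp.dx == pytest.approx(dp.dR, rel=1e-12)
        assert p.gamma_o * dp.dx == pytest.approx(dp.dRo, rel=1e-12)
        assert scaled.T / dp.dx == pytest.approx(train.T, rel=1e-12)

    def test_invalid_scale_parameters_rejected(self):
        with pytest.raises(ValueError):
            DimensionalParams(dx=0.0)
        with pytest.raises(ValueError):
            DimensionalParams(Kx=-1.0)
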