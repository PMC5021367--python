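import math

import numpy as np
import pytest

from ifflkit.analytics import (
    NoBorderError,
    border_beta,
    border_duration,
    counting_capacity,
    endpoint_closed_form,
    indefinite_counting,
    peak_basal_sequence,
    relative_duration_border,
)
from ifflkit.engine import cycle_extrema, endpoint, integrate
from ifflkit.models import IFFLParams
from ifflkit.signals import PulseTrain


class TestPeakBasalRecursion:
    def test_two_pulse_sequence(self):
        peaks, basals = peak_basal_sequence(1.2, 4, 1, 2)
        np.testing.assert_allclose(peaks, [0.7585447, 0.7724379], atol=1e-6)
        np.testing.assert_allclose(basals, [0.0, 0.0377657], atol=1e-6)

    def test_first_peak_closed_form(self):
        # peak_1 = beta*(1 - e^-D), basal_1 = 0 for any beta
        for beta, D in [(1.2, 3.0), (2.0, 0.5), (0.7, 1.0)]:
            peaks, basals = peak_basal_sequence(beta, 4.0, D, 1)
            assert peaks[0] == pytest.approx(beta * (1 - math.exp(-D)))
            assert basals[0] == 0.0

    def test_sequences_nondecreasing(self):
        peaks, basals = peak_basal_sequence(1.2, 4, 1, 30)
        assert np.all(np.diff(peaks) >= 0)
        assert np.all(np.diff(basals) >= 0)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            peak_basal_sequence(1.2, 4, 4, 3)

    def test_matches_ode_extrema_on_random_triples(self, rng):
        """Exact recursion vs numerically integrated intermediate extrema
        on 50 random (beta, T, D) triples, absolute error < 1e-6."""
        worst = 0.0
        for _ in range(50):
            beta = rng.uniform(0.2, 3.0)
            T = rng.uniform(1.0, 8.0)
            D = rng.uniform(0.1, 0.9) * T
            k = int(rng.integers(1, 5))
            train = PulseTrain(k=k, T=T, D=D)
            params = IFFLParams(beta=beta, gamma_R=10, gamma_o=0, n=110)
            traj = integrate(params, train)
            peaks, basals = cycle_extrema(traj)
            e_peaks, e_basals = peak_basal_sequence(beta, T, D, k)
            worst = max(worst,
                        np.max(np.abs(np.subtract(peaks, e_peaks))),
                        np.max(np.abs(np.subtract(basals, e_basals))))
        assert worst < 1e-6


class TestCountingCapacity:
    @pytest.mark.parametrize(
        "beta, T, D, expected",
        [
            (1.2, 4, 1.0, math.inf),   # limit 0.644 < 1/1.2
            (1.2, 4, 3.0, 1),          # first peak 1.140 > 1
            (1.2, 4, 1.75, 2),         # peaks 0.99147, 1.00963
        ],
    )
    def test_examples(self, beta, T, D, expected):
        res = counting_capacity(beta, T, D)
        assert res.nc == expected

    def test_finite_capacity_beyond_iteration_window(self):
        # peak limit barely above 1: failure arrives after many pulses,
        # found from the geometric closed form
        res = counting_capacity(3.0, 0.05, 0.02, max_pulses=10)
        assert math.isfinite(res.nc)
        assert res.nc > 10
        peaks, _ = peak_basal_sequence(3.0, 0.05, 0.02, int(res.nc))
        assert peaks[-1] > 1.0
        assert all(p <= 1.0 for p in peaks[:-1])

    def test_monotone_in_parameters(self):
        """nc is nonincreasing in beta and D, nondecreasing in T."""
        def nc(beta, T, D):
            return counting_capacity(beta, T, D).nc

        for D in (0.8, 1.2, 1.6, 1.9):
            vals = [nc(b, 4, D) for b in (1.1, 1.4, 1.8, 2.5)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))
        for beta in (1.2, 1.8):
            vals = [nc(beta, 4, D) for D in (0.4, 0.8, 1.2, 1.9)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))
            vals = [nc(beta, T, 1.5) for T in (1.8, 2.5, 4.0, 8.0)]
            assert all(a <= b for a, b in zip(vals, vals[1:]))


class TestBorders:
    def test_border_beta_value(self):
        assert border_beta(1.0) == pytest.approx(1.5820, abs=1e-4)

    def test_border_duration_value(self):
        assert border_duration(1.2) == pytest.approx(math.log(6), rel=1e-12)

    def test_mutually_inverse(self):
        for D in (0.2, 1.0, 2.5):
            assert border_duration(border_beta(D)) == pytest.approx(
                D, rel=1e-12)

    def test_large_beta_limit(self):
        assert border_duration(1e9) == pytest.approx(0.0, abs=1e-8)

    def test_no_border_below_unity(self):
        with pytest.raises(NoBorderError):
            border_duration(1.0)

    def test_border_matches_simulated_single_pulse_peak(self):
        # bisection cross-check: at D*, one pulse drives x exactly to 1
        beta = 1.2
        Dstar = border_duration(beta)
        params = IFFLParams(beta=beta, gamma_R=10, gamma_o=0, n=110)
        lo, hi = 0.5, 3.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            train = PulseTrain(k=1, T=4.0, D=mid)
            traj = integrate(params, train, train.tau0 + mid + 0.01)
            peak = cycle_extrema(traj)[0][0]
            if peak < 1.0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(Dstar, abs=1e-6)


class TestIndefiniteCounting:
    @pytest.mark.parametrize(
        "beta, T, D, expected",
        [
            (1.2, 4, 1.0, True),
            (1.2, 4, 1.9, False),
            (0.9, 4, 3.9, True),   # beta <= 1 always counts
            (1.0, 4, 3.9, True),
        ],
    )
    def test_inequality(self, beta, T, D, expected):
        assert indefinite_counting(beta, T, D) is expected

    def test_consistent_with_capacity(self):
        for beta in (0.8, 1.2, 1.7):
            for D in (0.5, 1.0, 1.7, 2.5):
                indefinite = indefinite_counting(beta, 4.0, D)
                assert indefinite == math.isinf(
                    counting_capacity(beta, 4.0, D).nc)

    def test_capacity_flips_across_border(self):
        """Just above D* a single pulse fails (nc=1); just below, either
        indefinite counting or failure only after several pulses."""
        for beta in (1.2, 2.0, 12.0):
            Dstar = border_duration(beta)
            assert counting_capacity(beta, 4.0, Dstar + 1e-6).nc == 1
            assert counting_capacity(beta, 4.0, Dstar - 1e-6).nc > 1


class TestEndpointClosedForm:
    def test_proportional_limit_at_zero_gamma_o(self):
        assert endpoint_closed_form(1.2, 0.0, 1.0, 4.0, 4, 1.0, 17.0) == \
            pytest.approx(4.8)

    def test_printed_sum_value(self):
        assert endpoint_closed_form(1.2, 0.01, 1.0, 4.0, 2, 1.0, 9.0) == \
            pytest.approx(2.2720, abs=1e-4)

    def test_empty_sum(self):
        assert endpoint_closed_form(1.2, 0.05, 1.0, 4.0, 0) == 0.0

    def test_too_early_readout_rejected(self):
        with pytest.raises(ValueError, match="tauE"):
            endpoint_closed_form(1.2, 0.01, 1.0, 4.0, 3, 1.0, 9.0)

    @pytest.mark.parametrize("gamma_o", [0.0, 0.01, 0.05])
    @pytest.mark.parametrize("k", [2, 5])
    def test_matches_integration_in_subthreshold_regime(self, gamma_o, k):
        """Closed form vs stiff ODE solution, relative error < 1e-4,
        wherever the intermediate stays below threshold."""
        beta, T, D = 1.2, 4.0, 1.0
        assert indefinite_counting(beta, T, D)
        tauE = 1.0 + k * T
        params = IFFLParams(beta=beta, gamma_R=10, gamma_o=gamma_o, n=110)
        train = PulseTrain(k=k, T=T, D=D)
        traj = integrate(params, train, tauE + 1)
        simulated = endpoint(traj, tauE)
        predicted = endpoint_closed_form(beta, gamma_o, D, T, k, 1.0, tauE)
        assert simulated == pytest.approx(predicted, rel=1e-4)


class TestRelativeDurationBorder:
    def test_printed_examples(self):
        assert relative_duration_border(2.0, 4.0) == pytest.approx(
            0.16875, abs=1e-5)
        assert relative_duration_border(12.0, 4.0) * 4.0 == pytest.approx(
            0.08535, abs=1e-5)

    def test_long_period_limit(self):
        # T -> infinity: D converges to ln(beta/(beta-1))
        for beta in (1.2, 2.0, 12.0):
            D = relative_duration_border(beta, 50.0) * 50.0
            assert D == pytest.approx(border_duration(beta), rel=1e-6)

    def test_decreasing_in_period(self):
        Ts = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        for beta in (1.2, 2.0, 12.0):
            ratios = relative_duration_border(beta, Ts)
            assert np.all(np.diff(ratios) < 0)

    def test_ordering_in_beta(self):
        # larger beta -> counting lost at shorter relative durations
        r12 = relative_duration_border(12.0, 4.0)
        r2 = relative_duration_border(2.0, 4.0)
        r1p2 = relative_duration_border(1.2, 4.0)
        assert r12 < r2 < r1p2

    def test_no_border_for_small_beta(self):
        with pytest.raises(NoBorderError):
            relative_duration_border(0.9, 4.0)
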