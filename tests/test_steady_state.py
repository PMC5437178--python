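"""Saturation law, cascade oracle, Stokes-Einstein and barrier algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfbarrier.steady_state import (
    MoleculeSpec,
    SteadyStateParams,
    StokesEinsteinContext,
    barrier_quotient,
    cascade_q,
    flow_time_for_q,
    infer_rh,
    planar_flux,
    steady_state_flux,
    steady_state_q,
    stokes_einstein_d,
)


class TestPlanarFlux:
    def test_unit_gradient(self):
        assert planar_flux(1e-6, 1.0, 0.0, 1.0) == pytest.approx(1e-6)

    def test_no_gradient_no_flux(self):
        assert planar_flux(1e-6, 0.7, 0.7, 2.0) == 0.0

    def test_doubling_length_halves_flux(self):
        assert planar_flux(1e-6, 1.0, 0.2, 2.0) == pytest.approx(
            planar_flux(1e-6, 1.0, 0.2, 1.0) / 2
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            planar_flux(1e-6, 1.0, 0.0, 0.0)


class TestSaturationLaw:
    def test_zero_time_zero_quotient_full_flux(self):
        p = SteadyStateParams(aleph=2.0, t=0.0)
        assert steady_state_q(p) == 0.0
        assert steady_state_flux(p) == 1.0

    def test_unit_exponent(self):
        p = SteadyStateParams(aleph=2.0, t=0.5)
        assert steady_state_q(p) == pytest.approx(1 - math.exp(-1), rel=1e-12)
        assert steady_state_flux(p) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_saturation_limit(self):
        assert steady_state_q(SteadyStateParams(aleph=2.0, t=1e6)) == pytest.approx(1.0)

    @given(
        aleph=st.floats(1e-3, 10.0),
        t=st.floats(0.0, 100.0),
        k=st.floats(1e-2, 10.0),
        l=st.floats(1e-2, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_q_plus_f_is_one_and_bounded(self, aleph, t, k, l):
        p = SteadyStateParams(aleph=aleph, t=t, k=k, l=l)
        q, f = steady_state_q(p), steady_state_flux(p)
        assert q + f == pytest.approx(1.0, abs=1e-15)
        assert 0.0 <= q <= 1.0  # reaches 1 only when the exponent overflows
        assert 0.0 <= f <= 1.0

    def test_q_monotone_in_each_parameter(self):
        base = dict(aleph=1.0, t=1.0, k=1.0, l=1.0)
        q0 = steady_state_q(SteadyStateParams(**base))
        for name, factor in (("aleph", 2), ("t", 2), ("k", 2)):
            q1 = steady_state_q(SteadyStateParams(**{**base, name: base[name] * factor}))
            assert q1 > q0, name
        assert steady_state_q(SteadyStateParams(**{**base, "l": 2.0})) < q0

    def test_slow_fast_ratio_increases_to_one(self):
        """Q_slow/Q_fast rises monotonically with flow time toward 1."""
        t = np.geomspace(1e-3, 8, 200)
        q_fast = -np.expm1(-2.0 * t)
        q_slow = -np.expm1(-1.23 * t)
        ratio = q_slow / q_fast
        assert np.all(np.diff(ratio) > 0)
        assert ratio[0] < 0.7
        assert ratio[-1] > 0.999


class TestCascade:
    def test_single_segment_matches_first_steady_state(self):
        # C(E1)/c_blood = aleph / (L * v)
        q = cascade_q(aleph=0.01, v=2.0, n_segments=1)
        assert q[0] == pytest.approx(0.01 / 2.0)

    def test_nondecreasing_and_bounded(self):
        q = cascade_q(aleph=0.5, v=1.0, n_segments=50)
        assert np.all(np.diff(q) >= 0)
        assert np.all(q <= 1.0)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 3.0])
    def test_converges_to_closed_form(self, lam):
        """The discrete steady-state cascade is the numerical oracle for
        the closed-form saturation law: rel. error < 1e-3 at 1e4 segments."""
        n = 10_000
        # n segments, each of exposure lam/n: v = n/lam per segment
        q = cascade_q(aleph=1.0, v=n / lam, n_segments=n)
        closed = -math.expm1(-lam)
        assert q[-1] == pytest.approx(closed, rel=1e-3)

    def test_invalid_velocity_rejected(self):
        with pytest.raises(ValueError):
            cascade_q(aleph=1.0, v=0.0, n_segments=1)


class TestStokesEinstein:
    def test_d_times_rh_constant(self):
        ctx = StokesEinsteinContext()
        prods = [stokes_einstein_d(r, ctx) * r for r in (1.0, 3.51, 12.65)]
        assert max(prods) == pytest.approx(min(prods), rel=1e-12)

    @pytest.mark.parametrize(
        "r_ref, r_x, printed",
        [(3.51, 5.29, 1.5), (3.51, 12.65, 3.6)],
    )
    def test_published_radius_quotients(self, r_ref, r_x, printed):
        """D ratios equal inverse R_H ratios; published to 2 figures."""
        ratio = stokes_einstein_d(r_ref) / stokes_einstein_d(r_x)
        assert ratio == pytest.approx(r_x / r_ref, rel=1e-12)
        assert round(ratio, 1) == printed

    def test_physiological_magnitude(self):
        # a 3.5 nm protein at body temperature diffuses at ~1e-6 cm^2/s
        assert stokes_einstein_d(3.51) == pytest.approx(1e-6, rel=0.1)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            stokes_einstein_d(0.0)


class TestBarrierAlgebra:
    def test_igg_barrier_quotient(self):
        got = barrier_quotient(2 / 1.23, 5.29 / 3.51)
        assert got == pytest.approx(1.08, abs=0.005)

    def test_igm_barrier_quotient_near_one(self):
        assert barrier_quotient(2 / 0.55, 12.65 / 3.51) == pytest.approx(1.0, abs=0.01)

    def test_identical_molecules(self):
        assert barrier_quotient(1.0, 1.0) == 1.0

    def test_free_diffusion_roundtrip(self):
        """With equal barrier factors the exchange quotient equals the
        inverse R_H quotient exactly."""
        rh_ratio = 5.29 / 3.51
        aleph_ratio = stokes_einstein_d(3.51) / stokes_einstein_d(5.29)
        assert barrier_quotient(aleph_ratio, rh_ratio) == pytest.approx(1.0, rel=1e-12)

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ValueError):
            barrier_quotient(0.0, 1.0)


class TestInferRH:
    ALBUMIN = MoleculeSpec(name="albumin", r_h=3.51, aleph_fitted=2.0)

    def test_identical_exchange_returns_reference(self):
        assert infer_rh(1.0, self.ALBUMIN) == pytest.approx(3.51)

    def test_exact_inversion_of_radius_quotient(self):
        assert infer_rh(5.29 / 3.51, self.ALBUMIN) == pytest.approx(5.29, rel=1e-12)

    def test_equal_b_assumption_overshoots_for_igg(self):
        """Under equal-B the fitted exchange ratio implies ~5.71 nm vs the
        measured 5.29 nm; the gap is exactly the barrier-factor quotient."""
        r_equal_b = infer_rh(2 / 1.23, self.ALBUMIN)
        assert r_equal_b == pytest.approx(3.51 * 2 / 1.23, rel=1e-12)
        assert r_equal_b == pytest.approx(5.71, abs=0.005)
        b_ratio = barrier_quotient(2 / 1.23, 5.29 / 3.51)
        assert infer_rh(2 / 1.23, self.ALBUMIN, assume_equal_b=False, barrier_ratio=b_ratio) \
            == pytest.approx(5.29, rel=1e-12)

    def test_missing_barrier_ratio_rejected(self):
        with pytest.raises(ValueError):
            infer_rh(1.5, self.ALBUMIN, assume_equal_b=False)


class TestFlowTime:
    def test_zero_quotient_zero_time(self):
        assert flow_time_for_q(0.0, 2.0) == 0.0

    def test_small_q_doubling(self):
        """In the small-Q regime doubling the quotient needs ~doubled flow
        time (3.5e-3 -> 7e-3 gives factor 2.002)."""
        factor = flow_time_for_q(7e-3, 2.0) / flow_time_for_q(3.5e-3, 2.0)
        assert factor == pytest.approx(2.002, abs=0.002)

    def test_tenfold_quotient_needs_tenfold_time(self):
        factor = flow_time_for_q(20e-3, 2.0) / flow_time_for_q(2e-3, 2.0)
        assert factor == pytest.approx(math.log(0.98) / math.log(0.998), rel=1e-12)
        assert factor == pytest.approx(10.09, abs=0.005)

    def test_inverse_of_saturation_law(self):
        for q in (1e-3, 0.05, 0.9):
            t = flow_time_for_q(q, 1.7, k_over_l=0.3)
            assert steady_state_q(SteadyStateParams(aleph=1.7, t=t, k=0.3)) \
                == pytest.approx(q, rel=1e-12)

    def test_saturated_quotient_rejected(self):
        with pytest.raises(ValueError):
            flow_time_for_q(1.0, 2.0)


class TestMoleculeSpec:
    def test_aleph_is_product_of_d_and_b(self):
        m = MoleculeSpec(name="x", r_h=3.5, d=1e-6, b=0.25)
        assert m.aleph_physical == pytest.approx(2.5e-7)

    def test_barrier_factor_bounds(self):
        with pytest.raises(ValueError):
            MoleculeSpec(name="x", r_h=3.5, b=1.2)

    def test_packaged_molecules(self, molecules):
        assert set(molecules) == {"albumin", "IgG", "IgA", "IgM"}
        assert molecules["albumin"].r_h == 3.51
        assert molecules["IgM"].aleph_fitted == 0.55
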