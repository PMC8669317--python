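"""Stage-matrix construction, growth transition, and density dependence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpva.demography import (
    ConvergenceError,
    DensityDependence,
    InvalidParameterError,
    VitalRates,
    build_matrix,
    density_dependent_fledging,
    growth_fraction,
    stable_stage_distribution,
)

probs = st.floats(0.05, 0.99)


def age_classified_lambda(v: VitalRates) -> float:
    """Independent oracle: expand the sub-adult stage to fixed-duration age
    classes and take the dominant eigenvalue of the full Leslie-type matrix."""
    T = v.afr - 1
    d = T + 2
    M = np.zeros((d, d))
    M[0, T] = (v.e / 2.0) * v.h * v.f * v.s0  # breeding adults -> 1-year-olds
    for j in range(T - 1):
        M[j + 1, j] = v.s1
    M[T, T - 1] = v.s1  # final sub-adult year graduates to breeding adult
    M[T, T] = v.s2 * v.b
    M[T, T + 1] = v.s3 * v.b
    M[T + 1, T] = v.s2 * (1 - v.b)
    M[T + 1, T + 1] = v.s3 * (1 - v.b)
    return float(np.max(np.linalg.eigvals(M).real))


class TestGrowthFraction:
    @pytest.mark.parametrize(
        "s1,lam,T,expected",
        [
            (0.9, 1.0, 1, 1.0),  # one-year stage: everyone graduates
            (0.8, 1.0, 3, 0.26230),  # closed form
            (1.0, 1.0, 4, 0.25),  # analytic limit 1/T at s1/lam = 1
        ],
    )
    def test_known_values(self, s1, lam, T, expected):
        assert growth_fraction(s1, lam, T) == pytest.approx(expected, abs=1e-5)

    def test_continuous_across_unit_ratio(self):
        below = growth_fraction(1.0 - 1e-6, 1.0, 5)
        above = growth_fraction(1.0 + 1e-6, 1.0, 5)
        limit = growth_fraction(1.0, 1.0, 5)
        assert below == pytest.approx(limit, abs=1e-5)
        assert above == pytest.approx(limit, abs=1e-5)

    @given(s1=probs, lam=st.floats(0.5, 1.5), T=st.integers(1, 8))
    @settings(deadline=None)
    def test_always_a_probability(self, s1, lam, T):
        g = growth_fraction(s1, lam, T)
        assert 0.0 <= g <= 1.0

    @pytest.mark.parametrize("s1,lam", [(0.0, 1.0), (0.5, 0.0), (-0.1, 1.0)])
    def test_rejects_nonpositive(self, s1, lam):
        with pytest.raises(InvalidParameterError):
            growth_fraction(s1, lam, 3)


class TestBuildMatrix:
    def test_no_reproduction_all_nonbreeding(self):
        # b=0 sends every adult to the non-breeding stage; with unit adult
        # survival the non-breeding stage is an absorbing state with lambda 1.
        v = VitalRates(s0=0.5, s1=1.0, s2=1.0, s3=1.0, b=0.0, e=2, h=0.5, f=0.5, afr=2)
        A = build_matrix(v)
        assert A.lam == pytest.approx(1.0, abs=1e-6)
        assert A.entries[2, 2] == 1.0
        assert A.entries[1, 1] == 0.0

    def test_matches_age_classified_oracle(self):
        v = VitalRates(s0=0.9, s1=0.9, s2=0.9, s3=0.9, b=0.9, e=2, h=0.7, f=0.7, afr=4)
        A = build_matrix(v)
        assert A.lam == pytest.approx(age_classified_lambda(v), abs=1e-6)

    @given(
        s0=probs, s1=probs, s2=probs, s3=probs, b=probs,
        h=probs, f=probs, afr=st.integers(2, 6),
    )
    @settings(deadline=None, max_examples=30)
    def test_age_oracle_property(self, s0, s1, s2, s3, b, h, f, afr):
        v = VitalRates(s0=s0, s1=s1, s2=s2, s3=s3, b=b, e=1.8, h=h, f=f, afr=afr)
        A = build_matrix(v)
        assert A.lam == pytest.approx(age_classified_lambda(v), abs=1e-5)

    def test_fixed_point_self_consistent(self, typical_matrix):
        dom = float(np.max(np.linalg.eigvals(typical_matrix.entries).real))
        assert abs(dom - typical_matrix.lam) < 1e-6

    @pytest.mark.parametrize("lam0", [0.5, 1.0, 1.5])
    def test_fixed_point_independent_of_start(self, typical_vitals, lam0):
        ref = build_matrix(typical_vitals, lam0=1.0)
        alt = build_matrix(typical_vitals, lam0=lam0)
        assert alt.lam == pytest.approx(ref.lam, abs=1e-5)
        assert alt.g == pytest.approx(ref.g, abs=1e-5)

    def test_structure_and_bounds(self, typical_vitals, typical_matrix):
        A = typical_matrix.entries
        v = typical_vitals
        assert A[2, 0] == 0.0 and A[0, 2] == 0.0
        assert (A >= 0).all()
        fec = (v.e / 2) * v.h * v.f * v.s0
        assert A.max() <= max(1.0, fec + 1e-12)
        # survival-only columns (no fecundity) sum to at most 1
        assert A[:, 0].sum() <= 1.0 + 1e-12
        assert A[:, 2].sum() <= 1.0 + 1e-12
        assert 0.0 <= typical_matrix.g <= 1.0

    def test_nonconvergence_reports_lambdas(self):
        v = VitalRates(s0=0.9, s1=0.9, s2=0.9, s3=0.9, b=0.9, e=2, h=0.7, f=0.7, afr=4)
        with pytest.raises(ConvergenceError) as err:
            build_matrix(v, tol=1e-15, max_iter=3)
        assert err.value.last_lambdas is not None

    def test_paper_tolerance_option(self, typical_vitals):
        loose = build_matrix(typical_vitals, tol=1e-2)
        tight = build_matrix(typical_vitals, tol=1e-6)
        assert loose.lam == pytest.approx(tight.lam, abs=1e-2)


class TestStableStageDistribution:
    def test_hand_solved_two_stage(self):
        A = np.array([[0.0, 2.0, 0.0], [0.5, 0.0, 0.0], [0.0, 0.0, 0.0]])
        ssd = stable_stage_distribution(A)
        assert ssd == pytest.approx([2 / 3, 1 / 3, 0.0], abs=1e-10)

    def test_eigen_identity(self, typical_matrix):
        ssd = stable_stage_distribution(typical_matrix)
        resid = typical_matrix.entries @ ssd - typical_matrix.lam * ssd
        assert np.abs(resid).max() < 1e-10
        assert ssd.sum() == pytest.approx(1.0)
        assert (ssd >= 0).all()

    def test_unreachable_stage_gets_zero(self):
        # b=1 keeps every adult breeding; the non-breeder stage is empty.
        v = VitalRates(s0=0.6, s1=0.8, s2=0.9, s3=0.0, b=1.0, e=1.5, h=0.75, f=0.7, afr=3)
        ssd = stable_stage_distribution(build_matrix(v))
        assert ssd[2] == pytest.approx(0.0, abs=1e-9)


class TestDensityDependentFledging:
    def test_halves_exactly_at_K(self):
        assert density_dependent_fledging(
            0.7, 1000.0, DensityDependence(theta=7.5, K=1000.0)
        ) == pytest.approx(0.35)

    def test_no_reduction_at_zero_density(self):
        assert density_dependent_fledging(0.7, 0.0, DensityDependence(7.5, 500.0)) == 0.7

    def test_negligible_at_half_K(self):
        out = density_dependent_fledging(0.7, 0.5, DensityDependence(theta=10, K=1.0))
        assert out == pytest.approx(0.69932, abs=1e-5)

    @given(theta=st.floats(5.0, 10.0), K=st.floats(10.0, 1e5))
    @settings(deadline=None)
    def test_half_reduction_at_K_for_any_theta(self, theta, K):
        dd = DensityDependence(theta=theta, K=K)
        assert density_dependent_fledging(0.7, K, dd) / 0.7 == pytest.approx(0.5, abs=1e-12)

    def test_monotone_decreasing(self):
        dd = DensityDependence(theta=7.5, K=100.0)
        vals = [density_dependent_fledging(0.7, n, dd) for n in np.linspace(0, 300, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert density_dependent_fledging(0.7, 200.0, dd) < 0.35

    def test_rejects_negative_abundance(self):
        with pytest.raises(InvalidParameterError):
            density_dependent_fledging(0.7, -1.0, DensityDependence(7.5, 100.0))
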