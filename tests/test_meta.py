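"""Unit and property tests for the IVW meta-analysis estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ivw_oracle
from gwashet import (
    CohortEffect,
    cochran_q,
    fixed_effects_ivw,
    i_squared,
    random_effects_ivw,
    samplesize_weighted_z,
    tau_squared_dl,
)
from gwashet.meta import fixed_effects_arrays, het_stats_arrays


def eff(pairs):
    return [CohortEffect(f"c{i}", x, s) for i, (x, s) in enumerate(pairs)]


TWO_STUDIES = eff([(0.1, 0.1), (0.3, 0.1)])


class TestFixedEffects:
    def test_single_study_is_identity(self):
        res = fixed_effects_ivw(eff([(0.2, 0.1)]))
        assert res.estimate == pytest.approx(0.2, rel=1e-14)
        assert res.se == pytest.approx(0.1, rel=1e-14)
        assert res.z == pytest.approx(2.0, rel=1e-14)
        assert res.het is None  # heterogeneity undefined at k=1

    def test_two_study_worked_example(self):
        res = fixed_effects_ivw(TWO_STUDIES)
        assert res.estimate == pytest.approx(0.2, abs=1e-12)
        assert res.se == pytest.approx(0.0707107, abs=1e-7)
        assert res.z == pytest.approx(2.828427, abs=1e-6)

    def test_identical_studies_symmetry(self):
        res = fixed_effects_ivw(eff([(0.5, 0.2)] * 4))
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            fixed_effects_ivw([])
        with pytest.raises(ValueError):
            CohortEffect("bad", 0.1, -0.1)

    def test_p_is_two_sided_normal(self):
        from scipy import stats

        res = fixed_effects_ivw(TWO_STUDIES)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(res.z)), rel=1e-12)


class TestHeterogeneityStats:
    def test_no_dispersion_gives_zero_q(self):
        q, df, p_q = cochran_q(eff([(0.2, 0.1), (0.2, 0.3), (0.2, 0.05)]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p_q) == (2, pytest.approx(1.0))

    @pytest.mark.parametrize(
        "pairs, expect_q, expect_df",
        [
            ([(0.1, 0.1), (0.3, 0.1)], 2.0, 1),
            ([(0.0, 0.1), (0.2, 0.1), (0.4, 0.1)], 8.0, 2),
        ],
    )
    def test_hand_worked_q(self, pairs, expect_q, expect_df):
        q, df, _ = cochran_q(eff(pairs))
        assert q == pytest.approx(expect_q, rel=1e-12)
        assert df == expect_df

    def test_q_requires_two_studies(self):
        with pytest.raises(ValueError):
            cochran_q(eff([(0.1, 0.1)]))

    def test_i_squared_branches(self):
        assert i_squared(2.0, 2) == 50.0
        assert i_squared(0.5, 3) == 0.0  # truncation at zero
        assert i_squared(0.0, 5) == 0.0  # 0/0 convention
        assert i_squared(1e12, 2) == pytest.approx(100.0, abs=1e-6)

    def test_tau2_worked_example_and_truncation(self):
        assert tau_squared_dl(TWO_STUDIES) == pytest.approx(0.01, rel=1e-12)
        assert tau_squared_dl(eff([(0.2, 0.1), (0.2, 0.1)])) == 0.0
        # Q below df truncates to zero
        assert tau_squared_dl(eff([(0.20, 0.1), (0.21, 0.1)])) == 0.0


class TestRandomEffects:
    def test_two_study_worked_example(self):
        res = random_effects_ivw(TWO_STUDIES)
        # tau2 = 0.01 so each weight is 1/(0.01+0.01) = 50
        assert res.estimate == pytest.approx(0.2, rel=1e-12)
        assert res.se == pytest.approx(0.1, rel=1e-12)
        assert res.z == pytest.approx(2.0, rel=1e-12)
        assert res.het.i2 == pytest.approx(50.0)

    def test_reduces_to_fixed_when_homogeneous(self):
        studies = eff([(0.15, 0.1), (0.15, 0.2), (0.15, 0.3)])
        fixed = fixed_effects_ivw(studies)
        random = random_effects_ivw(studies)
        assert random.estimate == pytest.approx(fixed.estimate, rel=1e-14)
        assert random.se == pytest.approx(fixed.se, rel=1e-14)

    def test_heterogeneity_widens_se(self):
        fixed = fixed_effects_ivw(TWO_STUDIES)
        random = random_effects_ivw(TWO_STUDIES)
        assert random.se > fixed.se


class TestSampleSizeZ:
    def test_single_study_identity(self):
        z, _ = samplesize_weighted_z([2.0], [1000.0])
        assert z == pytest.approx(2.0)

    def test_equal_n_same_direction(self):
        z, _ = samplesize_weighted_z([1.96, 1.96], [5e4, 5e4])
        assert z == pytest.approx(1.96 * math.sqrt(2), rel=1e-12)

    def test_opposite_directions_cancel(self):
        z, p = samplesize_weighted_z([1.5, 1.5], [1e4, 1e4], directions=[1, -1])
        assert z == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            samplesize_weighted_z([1.0, 2.0], [100.0])


finite_effects = st.lists(
    st.tuples(
        st.floats(-2, 2, allow_nan=False),
        st.floats(0.01, 2, allow_nan=False),
    ),
    min_size=2,
    max_size=12,
)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(pairs=finite_effects, seed=st.integers(0, 10**6))
def test_permutation_invariance(pairs, seed):
    """Study order never changes any meta-analysis output."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    a = random_effects_ivw(eff(pairs))
    b = random_effects_ivw(eff([pairs[i] for i in perm]))
    assert a.estimate == pytest.approx(b.estimate, rel=1e-12, abs=1e-13)
    assert a.het.q == pytest.approx(b.het.q, rel=1e-9, abs=1e-12)
    assert a.het.tau2 == pytest.approx(b.het.tau2, rel=1e-9, abs=1e-13)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(pairs=finite_effects)
def test_pooled_estimate_bounds_and_se_ordering(pairs):
    """Pooled estimates are convex combinations; fixed se <= min s_i <= random se."""
    studies = eff(pairs)
    fixed = fixed_effects_ivw(studies)
    random = random_effects_ivw(studies)
    xs = [p[0] for p in pairs]
    tol = 1e-9
    for res in (fixed, random):
        assert min(xs) - tol <= res.estimate <= max(xs) + tol
    assert fixed.se <= min(p[1] for p in pairs) + 1e-12
    assert random.se >= fixed.se - 1e-12


@settings(max_examples=60, deadline=None, derandomize=True)
@given(pairs=finite_effects, c=st.floats(0.1, 10, allow_nan=False))
def test_scale_equivariance(pairs, c):
    """Scaling all (x, s) by c scales estimate/se by c, tau2 by c^2, and
    leaves z, Q and I^2 unchanged."""
    base = random_effects_ivw(eff(pairs))
    scaled = random_effects_ivw(eff([(x * c, s * c) for x, s in pairs]))
    assert scaled.estimate == pytest.approx(base.estimate * c, rel=1e-9, abs=1e-12)
    assert scaled.se == pytest.approx(base.se * c, rel=1e-9)
    assert scaled.z == pytest.approx(base.z, rel=1e-9, abs=1e-12)
    assert scaled.het.q == pytest.approx(base.het.q, rel=1e-8, abs=1e-12)
    assert scaled.het.i2 == pytest.approx(base.het.i2, rel=1e-8, abs=1e-9)
    assert scaled.het.tau2 == pytest.approx(base.het.tau2 * c * c, rel=1e-8, abs=1e-13)


def test_matches_exact_rational_oracle():
    """Implementation agrees with the fractions-based re-evaluation to 1e-10
    relative on random instances (small version of the acceptance sweep)."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        k = rng.integers(2, 21)
        xs = rng.normal(0, 0.5, k).tolist()
        ss = rng.uniform(0.02, 1.0, k).tolist()
        expect = ivw_oracle(xs, ss)
        studies = eff(list(zip(xs, ss)))
        fixed = fixed_effects_ivw(studies)
        random = random_effects_ivw(studies)
        assert fixed.estimate == pytest.approx(expect["estimate"], rel=1e-10, abs=1e-13)
        assert fixed.se == pytest.approx(expect["se"], rel=1e-10)
        assert fixed.het.q == pytest.approx(expect["q"], rel=1e-10, abs=1e-12)
        assert fixed.het.i2 == pytest.approx(expect["i2"], rel=1e-10, abs=1e-10)
        assert fixed.het.tau2 == pytest.approx(expect["tau2"], rel=1e-10, abs=1e-14)
        assert random.estimate == pytest.approx(
            expect["estimate_random"], rel=1e-10, abs=1e-13
        )
        assert random.se == pytest.approx(expect["se_random"], rel=1e-10)


def test_vectorised_forms_agree_with_scalar_path():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 0.3, (50, 6))
    s = rng.uniform(0.05, 0.5, (50, 6))
    est, se, z = fixed_effects_arrays(x, s)
    q, i2, tau2 = het_stats_arrays(x, s)
    for i in (0, 17, 49):
        res = fixed_effects_ivw(eff(list(zip(x[i], s[i]))))
        assert est[i] == pytest.approx(res.estimate, rel=1e-12)
        assert se[i] == pytest.approx(res.se, rel=1e-12)
        assert q[i] == pytest.approx(res.het.q, rel=1e-12)
        assert i2[i] == pytest.approx(res.het.i2, rel=1e-12)
        assert tau2[i] == pytest.approx(res.het.tau2, rel=1e-12)
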