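"""Multisubject CSP: stacked problem construction, calculus, optimization."""

import numpy as np
import pytest
import scipy.linalg
from conftest import rand_cov_pair, rand_spd

from multicsp.csp import fit_bcsp
from multicsp.mtcsp import (
    MultiSubjectCSP,
    StackedFilter,
    build_augmented,
    default_init,
    fit_mtcsp_direction,
    gradient,
    hessian,
    objective,
    objective_terms,
    penalty_projectors,
    selector_matrix,
)
from multicsp.trials import CovariancePair


class TestStackedLayout:
    def test_selector_scalar_case(self):
        np.testing.assert_array_equal(selector_matrix(1, 1, 1), [[1.0, 1.0]])

    def test_selector_block_structure(self):
        E = selector_matrix(2, 2, 2)
        expected = np.hstack([np.eye(2), np.zeros((2, 2)), np.eye(2)])
        np.testing.assert_array_equal(E, expected)

    def test_selector_equals_extract(self, rng):
        S, d = 3, 4
        w = StackedFilter(rng.standard_normal((S + 1) * d), S=S, d=d)
        for s in range(1, S + 1):
            np.testing.assert_allclose(selector_matrix(s, S, d) @ w.w, w.extract(s))

    def test_selector_index_out_of_range(self):
        with pytest.raises(IndexError):
            selector_matrix(3, 2, 2)

    def test_projectors_scalar_case(self):
        D0, Ds = penalty_projectors(1, 1)
        np.testing.assert_array_equal(D0, np.diag([1.0, 0.0]))
        np.testing.assert_array_equal(Ds[0], np.diag([0.0, 1.0]))

    def test_projectors_complete_and_orthogonal(self, rng):
        S, d = 3, 2
        D0, Ds = penalty_projectors(S, d)
        total = D0 + sum(Ds)
        np.testing.assert_array_equal(total, np.eye((S + 1) * d))
        np.testing.assert_array_equal(D0 @ Ds[0], np.zeros_like(D0))
        for D in [D0] + Ds:
            np.testing.assert_array_equal(D @ D, D)
        w = rng.standard_normal((S + 1) * d)
        sf = StackedFilter(w, S=S, d=d)
        assert w @ D0 @ w == pytest.approx(np.sum(sf.w0**2))
        assert w @ Ds[1] @ w == pytest.approx(np.sum(sf.v(2) ** 2))


class TestBuildAugmented:
    def test_scalar_outer_product_expansion(self):
        cp = CovariancePair([[2.0]], [[3.0]])
        ap = build_augmented([cp], 0.0, 0.0)
        np.testing.assert_allclose(ap.sigma1_bar[0], [[2.0, 2.0], [2.0, 2.0]])
        np.testing.assert_allclose(ap.sigma2_bar[0], [[3.0, 3.0], [3.0, 3.0]])

    def test_penalties_add_to_diagonal(self):
        cp = CovariancePair([[2.0]], [[3.0]])
        ap = build_augmented([cp], 1.0, 2.0)
        np.testing.assert_allclose(
            ap.sigma2_bar[0], [[3.0, 3.0], [3.0, 3.0]] + np.diag([1.0, 2.0])
        )

    def test_quadratic_form_identity(self, rng):
        # w' S1bar w = (w0+vs)' S1 (w0+vs); w' S2bar w adds the penalties
        S, d, l1, l2 = 3, 3, 0.4, 1.7
        cps = [rand_cov_pair(d, rng) for _ in range(S)]
        ap = build_augmented(cps, l1, l2)
        for _ in range(100):
            w = rng.standard_normal((S + 1) * d)
            sf = StackedFilter(w, S=S, d=d)
            for s in range(S):
                ws = sf.extract(s + 1)
                assert w @ ap.sigma1_bar[s] @ w == pytest.approx(
                    ws @ cps[s].sigma1 @ ws, rel=1e-10
                )
                expected = (
                    ws @ cps[s].sigma2 @ ws
                    + l1 * np.sum(sf.w0**2)
                    + l2 * np.sum(sf.v(s + 1) ** 2)
                )
                assert w @ ap.sigma2_bar[s] @ w == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="share"):
            build_augmented([rand_cov_pair(2, rng), rand_cov_pair(3, rng)], 0.1, 0.1)


class TestObjective:
    def test_scalar_hand_computation(self):
        # S=1, d=1, w=(1,0): num = 2, den = 3 + l1 = 4
        ap = build_augmented([CovariancePair([[2.0]], [[3.0]])], 1.0, 0.5)
        assert objective([1.0, 0.0], ap) == pytest.approx(0.5)

    def test_degree_zero_homogeneity(self, rng):
        cps = [rand_cov_pair(3, rng) for _ in range(2)]
        ap = build_augmented(cps, 0.2, 0.8)
        w = rng.standard_normal(9)
        assert objective(2.0 * w, ap) == pytest.approx(objective(w, ap), rel=1e-12)

    def test_unpenalized_bcsp_embedding_attains_eigen_sum(self, rng):
        # with lambda = 0 and v_s = f_s - w0 the objective equals the sum
        # of per-subject top generalized eigenvalues
        cps = [rand_cov_pair(3, rng) for _ in range(3)]
        ap = build_augmented(cps, 0.0, 0.0)
        w0 = rng.standard_normal(3)
        filters = [fit_bcsp(cp).for_class(1)[0] for cp in cps]
        w = StackedFilter.from_parts(w0, [f - w0 for f in filters])
        expected = sum(
            scipy.linalg.eigh(cp.sigma1, cp.sigma2, eigvals_only=True)[-1]
            for cp in cps
        )
        assert objective(w, ap) == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_denominator_errors(self):
        cp = CovariancePair(np.eye(2), np.diag([1.0, 0.0]))
        ap = build_augmented([cp], 0.0, 0.0)
        with pytest.raises(ValueError, match="denominator"):
            objective([0.0, 1.0, 0.0, 1.0], ap)


class TestCalculus:
    def _random_problem(self, rng, S=None, d=None):
        S = S or int(rng.integers(1, 4))
        d = d or int(rng.integers(1, 4))
        cps = [rand_cov_pair(d, rng) for _ in range(S)]
        lam = rng.uniform(0.05, 2.0, size=2)
        ap = build_augmented(cps, *lam)
        w = rng.standard_normal((S + 1) * d)
        return ap, w

    def test_gradient_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(50):
            ap, w = self._random_problem(rng)
            g = gradient(w, ap)
            num = np.array(
                [
                    (objective(w + h * e, ap) - objective(w - h * e, ap)) / (2 * h)
                    for e in np.eye(w.size)
                ]
            )
            assert np.abs(g - num).max() < 1e-6 * (1.0 + np.linalg.norm(g))

    def test_gradient_orthogonal_to_iterate(self, rng):
        # Euler's identity for a degree-0 homogeneous function: w'grad = 0
        for _ in range(10):
            ap, w = self._random_problem(rng)
            g = gradient(w, ap)
            assert abs(w @ g) < 1e-10 * (1.0 + np.linalg.norm(g))

    def test_gradient_vanishes_at_embedded_eigenvector(self, rng):
        cp = rand_cov_pair(3, rng)
        ap = build_augmented([cp], 0.0, 0.0)
        f = fit_bcsp(cp).for_class(1)[0]
        w = StackedFilter.from_parts(np.zeros(3), [f])
        assert np.linalg.norm(gradient(w, ap)) < 1e-8

    def test_hessian_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(20):
            ap, w = self._random_problem(rng, S=int(rng.integers(1, 4)),
                                         d=int(rng.integers(1, 4)))
            H = hessian(w, ap)
            num = np.vstack(
                [
                    (gradient(w + h * e, ap) - gradient(w - h * e, ap)) / (2 * h)
                    for e in np.eye(w.size)
                ]
            )
            num = 0.5 * (num + num.T)
            denom = 1.0 + np.abs(H).max()
            assert np.abs(H - num).max() / denom < 1e-5

    def test_homogeneity_differential_identity(self, rng):
        # grad is homogeneous of degree -1, so H w = -grad
        for _ in range(10):
            ap, w = self._random_problem(rng)
            H = hessian(w, ap)
            g = gradient(w, ap)
            np.testing.assert_allclose(H @ w, -g, atol=1e-8 * (1 + np.abs(g).max()))

    def test_hessian_symmetric(self, rng):
        ap, w = self._random_problem(rng)
        H = hessian(w, ap)
        assert np.abs(H - H.T).max() < 1e-10


class TestFitMtcsp:
    def test_single_subject_unpenalized_recovers_eigenvalue(self, rng):
        for _ in range(5):
            cp = rand_cov_pair(4, rng)
            m = fit_mtcsp_direction([cp], 0.0, 0.0)
            top = scipy.linalg.eigh(cp.sigma1, cp.sigma2, eigvals_only=True)[-1]
            assert m.objective == pytest.approx(top, abs=1e-6 * top)

    def test_huge_lambda2_forces_shared_filter(self, rng):
        cp = rand_cov_pair(4, rng)
        m = fit_mtcsp_direction([cp] * 3, 1e-6, 1e6)
        for v in m.v:
            assert np.linalg.norm(v) < 1e-3
        w0 = m.w0 / np.linalg.norm(m.w0)
        shared = fit_bcsp(cp).for_class(1)[0]
        assert abs(w0 @ shared) > 1 - 1e-4

    def test_huge_lambda1_forces_subject_specific_filters(self, rng):
        cps = [rand_cov_pair(4, rng) for _ in range(3)]
        m = fit_mtcsp_direction(cps, 1e6, 1e-6)
        assert np.linalg.norm(m.w0) < 1e-3
        for s, cp in enumerate(cps):
            own = fit_bcsp(
                CovariancePair(cp.sigma1, cp.sigma2 + 1e-6 * np.eye(4))
            ).for_class(1)[0]
            ws = m.v[s] / np.linalg.norm(m.v[s])
            assert abs(ws @ own) > 1 - 1e-4

    def test_objective_nondecreasing_along_iterations(self, rng):
        cps = [rand_cov_pair(5, rng) for _ in range(4)]
        m = fit_mtcsp_direction(cps, 0.1, 0.1)
        objs = [e["objective"] for e in m.log]
        assert all(b >= a - 1e-10 for a, b in zip(objs, objs[1:]))

    def test_fit_invariant_to_init_scale(self, rng):
        cps = [rand_cov_pair(3, rng) for _ in range(3)]
        init = default_init(cps)
        a = fit_mtcsp_direction(cps, 0.3, 0.5, init=init)
        b = fit_mtcsp_direction(
            cps, 0.3, 0.5, init=StackedFilter(5.0 * init.w, init.S, init.d)
        )
        assert a.objective == pytest.approx(b.objective, abs=1e-6)

    def test_specific_norms_shrink_as_lambda2_grows(self, rng):
        # the w0/v norm split is nearly degenerate when one part is close
        # to zero, so monotonicity holds up to a small slack
        cps = [rand_cov_pair(4, rng) for _ in range(3)]
        prev = np.inf
        for l2 in [1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0]:
            m = fit_mtcsp_direction(cps, 0.1, l2)
            tot = sum(np.linalg.norm(v) ** 2 for v in m.v)
            assert tot <= prev + 5e-3
            prev = tot
        assert prev < 0.05  # by lambda2 = 100 the filters are nearly shared

    def test_effective_filter_reconstruction(self, rng):
        cps = [rand_cov_pair(3, rng) for _ in range(2)]
        m = fit_mtcsp_direction(cps, 0.2, 0.2)
        for s in range(1, 3):
            np.testing.assert_allclose(m.effective_filter(s), m.w0 + m.v[s - 1])

    def test_fit_improves_on_init(self, rng):
        cps = [rand_cov_pair(4, rng) for _ in range(3)]
        ap = build_augmented(cps, 0.5, 0.5)
        init = default_init(cps, kind="zeros+eps")
        start = objective(init.w / np.linalg.norm(init.w), ap)
        m = fit_mtcsp_direction(cps, 0.5, 0.5, init=init)
        assert m.objective >= start - 1e-12


def test_model_results_summary_and_filters(rng):
    cps = [rand_cov_pair(3, rng) for _ in range(3)]
    res = MultiSubjectCSP(cps, lambda1=0.1, lambda2=0.1).fit()
    assert set(res.directions) == {1, 2}
    W = res.subject_filter_matrix(2)
    assert W.shape == (2, 3)
    text = res.summary()
    assert "lambda1" in text and "subject 3" in text


def test_per_subject_ratios_consistent_with_objective(rng):
    cps = [rand_cov_pair(3, rng) for _ in range(2)]
    ap = build_augmented(cps, 0.2, 0.4)
    w = rng.standard_normal(9)
    ev = objective_terms(w, ap)
    assert ev.value == pytest.approx(ev.ratios.sum())
    assert (ev.denominators > 0).all()
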