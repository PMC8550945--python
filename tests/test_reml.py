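"""REML core: oracle equivalence against direct likelihood maximization,
test statistics, backward selection and the liability transformation."""
import numpy as np
import pytest
from scipy import optimize, stats

from famvar import (
    VarianceModel,
    backward_select,
    fit_reml,
    lrt,
    observed_to_liability,
    wald_test,
)
from famvar.matrices import RelationshipMatrix
from famvar.reml import RemlError, VarianceFit

from conftest import couple_block_matrix


def restricted_loglik(sigma, mats, y, X):
    """Independent textbook evaluation of the restricted log-likelihood."""
    n = len(y)
    V = sigma[-1] * np.eye(n)
    for s, A in zip(sigma[:-1], mats):
        V = V + s * A
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    sign2, logdet_X = np.linalg.slogdet(XtVX)
    if sign2 <= 0:
        return -np.inf
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    return -0.5 * (logdet_V + logdet_X + float(y @ P @ y))


def profiled_restricted_loglik(fracs, mats, y, X):
    """Restricted likelihood at a point of the variance-fraction simplex,
    maximized analytically over the total variance scale."""
    n, p = X.shape
    fracs = np.asarray(fracs, float)
    Vs = (1.0 - fracs.sum()) * np.eye(n)
    for f, M in zip(fracs, mats):
        Vs = Vs + f * M
    sign, logdet_V = np.linalg.slogdet(Vs)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(Vs)
    XtVX = X.T @ Vinv @ X
    sign2, logdet_X = np.linalg.slogdet(XtVX)
    if sign2 <= 0:
        return -np.inf
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    tau = float(y @ P @ y) / (n - p)
    if tau <= 0:
        return -np.inf
    return -0.5 * (logdet_V + logdet_X + (n - p) * np.log(tau) + (n - p))


def oracle_fractions(mats, y, X, k):
    """Brute-force maximization of the restricted likelihood: a grid over
    the fraction simplex (scale profiled out) plus a Nelder-Mead polish."""
    if k == 1:
        grid = [np.array([f]) for f in np.linspace(0.0, 0.995, 400)]
    else:
        axis = np.linspace(0.0, 0.995, 64)
        grid = [np.array([a, b]) for a in axis for b in axis if a + b < 0.999]
    lls = [profiled_restricted_loglik(g, mats, y, X) for g in grid]
    x0 = grid[int(np.argmax(lls))]

    def neg(theta):
        theta = np.asarray(theta)
        if (theta < 0).any() or theta.sum() >= 0.9999:
            return np.inf
        return -profiled_restricted_loglik(theta, mats, y, X)

    candidates = [(np.max(lls) if np.isfinite(np.max(lls)) else -np.inf, x0)]
    for method, opts in (
        ("Nelder-Mead", {"xatol": 1e-10, "fatol": 1e-13, "maxiter": 5000}),
        ("Powell", {"xtol": 1e-12, "ftol": 1e-13, "maxiter": 5000}),
    ):
        res = optimize.minimize(neg, x0, method=method, options=opts)
        x = np.clip(res.x, 0.0, None)
        candidates.append((profiled_restricted_loglik(x, mats, y, X), x))
        # polish the other candidate's endpoint too
        res2 = optimize.minimize(neg, candidates[-2][1], method=method, options=opts)
        x2 = np.clip(res2.x, 0.0, None)
        candidates.append((profiled_restricted_loglik(x2, mats, y, X), x2))
    best = max(candidates, key=lambda t: t[0])[1]
    return np.append(best, 1.0 - best.sum())


def make_instance(rng, n, k):
    """Random small REML instance with block-structured component matrices."""
    mats = []
    for _ in range(k):
        sizes = []
        while sum(sizes) < n:
            sizes.append(int(rng.integers(2, 5)))
        sizes[-1] -= sum(sizes) - n
        M = np.zeros((n, n))
        pos = 0
        for s in sizes:
            if s > 0:
                M[pos: pos + s, pos: pos + s] = 1.0
            pos += s
        mats.append(M)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    sigma_true = np.append(rng.uniform(0.1, 0.6, size=k), 0.5)
    V = sigma_true[-1] * np.eye(n)
    for s, A in zip(sigma_true[:-1], mats):
        V = V + s * A
    y = np.linalg.cholesky(V) @ rng.normal(size=n) + X @ np.array([1.0, 0.5])
    return mats, y, X


def as_model(mats, y, X):
    n = len(y)
    ids = np.array([f"i{j}" for j in range(n)])
    roles = ["C", "S", "F", "K", "G"]
    comps = [
        RelationshipMatrix(values=M, ids=ids, role=roles[i])
        for i, M in enumerate(mats)
    ]
    return VarianceModel(y=y, X=X, components=comps)


class TestFitOracle:
    def test_single_component_matches_grid_search(self):
        """30 individuals in 15 couple blocks, truth fraction 0.5."""
        rng = np.random.default_rng(100)
        M = couple_block_matrix(15)
        V = 0.5 * M + 0.5 * np.eye(30)
        y = np.linalg.cholesky(V) @ rng.normal(size=30)
        X = np.ones((30, 1))
        model = as_model([M], y, X)
        fit = fit_reml(model, tol=1e-10)
        n, p = 30, 1

        def profiled_ll(f):
            """Restricted likelihood maximized analytically over total scale."""
            Vs = f * M + (1 - f) * np.eye(n)
            sign, logdet_V = np.linalg.slogdet(Vs)
            Vinv = np.linalg.inv(Vs)
            XtVX = X.T @ Vinv @ X
            P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
            tau = float(y @ P @ y) / (n - p)
            return -0.5 * (logdet_V + np.linalg.slogdet(XtVX)[1]
                           + (n - p) * np.log(tau) + (n - p))

        grid = np.linspace(1e-4, 0.999, 4000)
        f_grid = grid[int(np.argmax([profiled_ll(f) for f in grid]))]
        assert abs(fit.fractions[0] - f_grid) < 1e-3

    def test_oracle_equivalence_random_instances(self):
        """AI-REML equals direct likelihood maximization on 25 instances."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for rep in range(25):
            n = int(rng.integers(24, 61))
            k = int(rng.integers(1, 3))
            mats, y, X = make_instance(rng, n, k)
            fit = fit_reml(as_model(mats, y, X), tol=1e-10)
            oracle = oracle_fractions(mats, y, X, k)
            worst = max(worst, float(np.max(np.abs(fit.fractions - oracle))))
        assert worst < 1e-3

    def test_identity_component_flagged_unidentifiable(self):
        rng = np.random.default_rng(8)
        n = 40
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        model = as_model([np.eye(n)], y, X)
        fit = fit_reml(model)
        assert (not fit.identifiable) or fit.constrained.any() or (
            fit.se_fractions[0] > 10
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        mats, y, X = make_instance(rng, 30, 2)
        fit = fit_reml(as_model(mats, y, X), tol=1e-9)
        perm = rng.permutation(30)
        mats_p = [M[np.ix_(perm, perm)] for M in mats]
        fit_p = fit_reml(as_model(mats_p, y[perm], X[perm]), tol=1e-9)
        assert abs(fit.loglik - fit_p.loglik) < 1e-6
        assert np.allclose(fit.fractions, fit_p.fractions, atol=1e-5)

    def test_id_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        ids1 = np.array([f"i{j}" for j in range(10)])
        ids2 = ids1[::-1].copy()
        m1 = RelationshipMatrix(values=np.eye(10), ids=ids1, role="C")
        m2 = RelationshipMatrix(values=np.eye(10), ids=ids2, role="S")
        with pytest.raises(RemlError):
            VarianceModel(y=rng.normal(size=10), X=np.ones((10, 1)),
                          components=[m1, m2])

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(11)
        X = np.ones((20, 2))  # duplicated intercept
        with pytest.raises(RemlError):
            VarianceModel(y=rng.normal(size=20), X=X, components=[])


class TestWald:
    def test_strong_effect(self):
        fit = _fake_fit(est=0.38, se=0.03)
        assert wald_test(fit, "C") < 1e-15

    def test_zero_estimate(self):
        fit = _fake_fit(est=0.0, se=0.03)
        assert wald_test(fit, "C") == 1.0

    def test_borderline_z(self):
        fit = _fake_fit(est=0.0588, se=0.03)
        assert abs(wald_test(fit, "C") - 0.05) < 0.001

    def test_constrained_component_reports_one(self):
        fit = _fake_fit(est=1e-7, se=0.01, constrained=True)
        assert wald_test(fit, "C") == 1.0


def _fake_fit(est, se, constrained=False):
    return VarianceFit(
        names=["C", "residual"],
        sigma2=np.array([est, 1 - est]),
        se_sigma2=np.array([se, se]),
        fractions=np.array([est, 1 - est]),
        se_fractions=np.array([se, se]),
        loglik=0.0,
        n_iter=1,
        converged=True,
        ai_matrix=np.eye(2),
        constrained=np.array([constrained, False]),
        n=100,
    )


class TestLrt:
    def test_identical_likelihoods(self):
        full = _fake_fit(0.1, 0.1)
        red = VarianceFit(
            names=["residual"], sigma2=np.array([1.0]), se_sigma2=np.array([0.1]),
            fractions=np.array([1.0]), se_fractions=np.array([0.0]), loglik=0.0,
            n_iter=1, converged=True, ai_matrix=np.eye(1),
            constrained=np.array([False]), n=100,
        )
        assert lrt(full, red) == 1.0

    def test_boundary_mixture_quantile(self):
        """Lambda = 2.706 sits at p = 0.05 under the 50:50 chi2_0/chi2_1 mix."""
        full = _fake_fit(0.1, 0.1)
        full.loglik = 2.706 / 2
        red = VarianceFit(
            names=["residual"], sigma2=np.array([1.0]), se_sigma2=np.array([0.1]),
            fractions=np.array([1.0]), se_fractions=np.array([0.0]), loglik=0.0,
            n_iter=1, converged=True, ai_matrix=np.eye(1),
            constrained=np.array([False]), n=100,
        )
        assert abs(lrt(full, red) - 0.05) < 0.001
        # sensitivity option: plain chi-square reference
        assert abs(lrt(full, red, boundary_mixture=False)
                   - stats.chi2.sf(2.706, 1)) < 1e-9

    def test_non_nested_rejected(self):
        a = _fake_fit(0.1, 0.1)
        with pytest.raises(RemlError):
            lrt(a, a)


class TestBackwardSelect:
    def test_nothing_to_drop(self):
        """Strongly supported components survive with a single trace step."""
        rng = np.random.default_rng(12)
        n = 400
        M1 = couple_block_matrix(n // 2)
        M2 = np.zeros((n, n))
        for i in range(0, n, 4):
            M2[i: i + 4, i: i + 4] = 1.0
        V = 0.35 * M1 + 0.35 * M2 + 0.3 * np.eye(n)
        y = np.linalg.cholesky(V) @ rng.normal(size=n)
        model = as_model([M1, M2], y, np.ones((n, 1)))
        fit, trace = backward_select(model)
        assert trace[-1].removed is None
        assert set(fit.names) == {"C", "S", "residual"}

    def test_null_component_removed(self):
        rng = np.random.default_rng(13)
        n = 300
        M1 = couple_block_matrix(n // 2)  # true effect
        M2 = np.zeros((n, n))  # null component
        for i in range(0, n, 3):
            M2[i: i + 3, i: i + 3] = 1.0
        V = 0.45 * M1 + 0.55 * np.eye(n)
        y = np.linalg.cholesky(V) @ rng.normal(size=n)
        model = as_model([M1, M2], y, np.ones((n, 1)))
        fit, trace = backward_select(model)
        assert "S" not in fit.names
        assert "C" in fit.names
        removed = [s.removed for s in trace if s.removed]
        assert removed == ["S"]


class TestLiabilityTransform:
    def test_zero_maps_to_zero(self):
        assert observed_to_liability(0.0, 0.3) == 0.0

    def test_symmetric_point_closed_form(self):
        """At prevalence = case fraction = 1/2 the multiplier is pi/2."""
        mult = observed_to_liability(1.0, 0.5, 0.5)
        assert abs(mult - np.pi / 2) < 1e-12

    def test_48_percent_prevalence_multiplier(self):
        mult = observed_to_liability(1.0, 0.48, 0.48)
        z = stats.norm.pdf(stats.norm.ppf(0.52))
        assert abs(mult - 0.48 * 0.52 / z**2) < 1e-12
        assert abs(mult - 1.574) < 0.005

    def test_ascertainment_adjustment_reduces_to_simple_form(self):
        K = 0.2
        simple = observed_to_liability(0.5, K, K)
        z = stats.norm.pdf(stats.norm.ppf(1 - K))
        assert abs(simple - 0.5 * K * (1 - K) / z**2) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            observed_to_liability(0.5, 0.0)
        with pytest.raises(ValueError):
            observed_to_liability(0.5, 0.5, 1.0)


class TestMonotonicity:
    def test_loglik_non_decreasing_hook(self):
        """Accepted iterations never decrease the restricted likelihood: the
        final loglik dominates the likelihood at the HE starting point."""
        rng = np.random.default_rng(14)
        mats, y, X = make_instance(rng, 50, 2)
        from famvar.reml import _he_start

        vp = float(np.var(y, ddof=1))
        start = _he_start(y, X, mats, 1e-6 * vp, vp)
        fit = fit_reml(as_model(mats, y, X), tol=1e-9)
        assert fit.loglik >= restricted_loglik(start, mats, y, X) - 1e-8
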