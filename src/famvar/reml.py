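"""Restricted maximum likelihood for multi-component variance models.

Fits Y = Xb + sum_i u_i + eps where each random effect u_i has covariance
sigma2_i * A_i for a supplied relationship matrix A_i, by average-information
(AI) REML with EM fallback steps and step-halving.  Also provides Wald and
likelihood-ratio tests, the backward stepwise component-selection loop, and
the observed-to-liability-scale transformation for binary traits.

The restricted log-likelihood is reported up to the usual additive constant:

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

from .matrices import RelationshipMatrix

RESIDUAL = "residual"


class RemlError(ValueError):
    pass


@dataclass
class VarianceModel:
    """Response, fixed-effect design and the set of relationship matrices."""

    y: np.ndarray
    X: np.ndarray
    components: list[RelationshipMatrix]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise RemlError("X rows must match length of y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise RemlError("fixed-effect design is rank deficient")
        for c in self.components:
            if c.n != n:
                raise RemlError(f"component {c.role} has {c.n} ids, response has {n}")
        if self.components:
            ref = self.components[0].ids
            for c in self.components[1:]:
                if not np.array_equal(c.ids, ref):
                    raise RemlError("relationship matrices have mismatched id ordering")
        if not self.names:
            self.names = [c.role for c in self.components]

    def drop(self, name: str) -> "VarianceModel":
        keep = [i for i, nm in enumerate(self.names) if nm != name]
        if len(keep) == len(self.names):
            raise RemlError(f"no component named {name!r}")
        return VarianceModel(
            y=self.y,
            X=self.X,
            components=[self.components[i] for i in keep],
            names=[self.names[i] for i in keep],
        )


@dataclass
class VarianceFit:
    """REML solution: estimates, SEs, likelihood and convergence metadata."""

    names: list[str]  # component names + "residual"
    sigma2: np.ndarray
    se_sigma2: np.ndarray
    fractions: np.ndarray
    se_fractions: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    ai_matrix: np.ndarray
    constrained: np.ndarray  # True where the estimate was pinned at the floor
    identifiable: bool = True
    n: int = 0

    def fraction(self, name: str) -> float:
        return float(self.fractions[self.names.index(name)])

    def se_fraction(self, name: str) -> float:
        return float(self.se_fractions[self.names.index(name)])

    def is_constrained(self, name: str) -> bool:
        return bool(self.constrained[self.names.index(name)])

    def summary(self) -> str:
        lines = [f"{'component':<10}{'sigma2':>10}{'fraction':>10}{'se':>8}"]
        for i, nm in enumerate(self.names):
            flag = "*" if self.constrained[i] else ""
            lines.append(
                f"{nm:<10}{self.sigma2[i]:>10.4f}{self.fractions[i]:>10.4f}"
                f"{self.se_fractions[i]:>8.4f}{flag}"
            )
        lines.append(f"logL = {self.loglik:.4f}  iters = {self.n_iter}  "
                     f"converged = {self.converged}")
        return "\n".join(lines)


def _sym_inv_from_cholesky(L: np.ndarray) -> np.ndarray:
    inv, info = dpotri(L, lower=1)
    if info != 0:  # pragma: no cover
        raise RemlError("matrix inversion failed")
    d = inv.diagonal().copy()
    out = inv + inv.T
    np.fill_diagonal(out, d)
    return out


@dataclass
class _FactorState:
    """Cheap (solve-based) evaluation of the restricted likelihood at sigma."""

    ll: float
    L: np.ndarray  # Cholesky factor of V
    VinvX: np.ndarray
    cf: tuple  # cho_factor of X' V^-1 X
    Py: np.ndarray


def _build_v(sigma, mats, n) -> np.ndarray:
    V = sigma[-1] * np.eye(n)
    for s, A in zip(sigma[:-1], mats):
        V += s * A
    return V


def _factorize(sigma, mats, y, X) -> _FactorState | None:
    """Likelihood via triangular solves only; None if V or X'V^-1X not PD."""
    n = len(y)
    V = _build_v(sigma, mats, n)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    rhs = np.column_stack([X, y])
    sol = cho_solve((L, True), rhs)
    VinvX, Vinvy = sol[:, :-1], sol[:, -1]
    XtVX = X.T @ VinvX
    try:
        cf = cho_factor(XtVX)
    except np.linalg.LinAlgError:
        return None
    logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Py = Vinvy - VinvX @ cho_solve(cf, X.T @ Vinvy)
    ll = -0.5 * (logdet_V + logdet_XtVX + float(y @ Py))
    return _FactorState(ll=ll, L=L, VinvX=VinvX, cf=cf, Py=Py)


def _projection(state: _FactorState) -> np.ndarray:
    """Full P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 (needed for derivatives)."""
    Vinv = _sym_inv_from_cholesky(state.L)
    return Vinv - state.VinvX @ cho_solve(state.cf, state.VinvX.T)


def _derivatives(P, Py, mats):
    """REML gradient and average information at the current point."""
    n = len(Py)
    k = len(mats)
    T = np.empty((n, k + 1))
    trPA = np.empty(k + 1)
    for i, A in enumerate(mats):
        T[:, i] = A @ Py
        trPA[i] = float(np.einsum("ij,ij->", P, A))
    T[:, k] = Py
    trPA[k] = float(np.trace(P))
    yPAPy = Py @ T
    grad = -0.5 * (trPA - yPAPy)
    AI = 0.5 * (T.T @ (P @ T))
    return grad, AI, trPA, yPAPy


def _he_start(y, X, mats, floor, vp) -> np.ndarray:
    """Haseman-Elston-style starting values.

    Least-squares fit of the fixed-effect-residualized cross-product matrix
    onto the relationship matrices (+ identity); biased but cheap, and close
    enough for AI-REML to converge in a few steps.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    u = y - X @ beta
    k = len(mats)
    M = np.empty((k + 1, k + 1))
    r = np.empty(k + 1)
    aug = list(mats)
    n = len(y)
    for i in range(k):
        r[i] = float(u @ (aug[i] @ u))
        for j in range(i, k):
            M[i, j] = M[j, i] = float(np.einsum("ij,ij->", aug[i], aug[j]))
    r[k] = float(u @ u)
    for i in range(k):
        M[i, k] = M[k, i] = float(np.trace(aug[i]))
    M[k, k] = n
    try:
        est, *_ = np.linalg.lstsq(M, r, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(k + 1, vp / (k + 1))
    est = np.clip(est, max(floor, 1e-3 * vp), 2.0 * vp)
    return est


def _residual_only_fit(y, X) -> VarianceFit:
    """Closed-form REML when no random component besides the residual."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - p) * np.log(s2) + logdet_XtX + (n - p))
    se = s2 * np.sqrt(2.0 / (n - p))
    return VarianceFit(
        names=[RESIDUAL],
        sigma2=np.array([s2]),
        se_sigma2=np.array([se]),
        fractions=np.array([1.0]),
        se_fractions=np.array([0.0]),
        loglik=ll,
        n_iter=0,
        converged=True,
        ai_matrix=np.array([[(n - p) / (2 * s2 * s2)]]),
        constrained=np.array([False]),
        n=n,
    )


def fit_reml(
    model: VarianceModel,
    tol: float = 1e-4,
    max_iter: int = 100,
    start: np.ndarray | None = None,
    constrain: bool = True,
    floor_scale: float = 1e-6,
) -> VarianceFit:
    """AI-REML with an initial EM step, step-halving and EM fallback.

    Accepted iterations never decrease the restricted log-likelihood;
    convergence is declared when the change drops below ``tol``.  With
    ``constrain`` (default) estimates are floored at
    ``floor_scale * var(y)`` GCTA-style and flagged; ``constrain=False``
    allows negative components as long as V stays positive definite (useful
    for likelihood-surface cross-checks).
    """
    y, X, mats = model.y, model.X, [c.values for c in model.components]
    n, p = X.shape
    k = len(mats)
    if n < p + k + 1:
        raise RemlError("more parameters than observations")
    if k == 0:
        return _residual_only_fit(y, X)

    vp = float(np.var(y, ddof=1))
    floor = floor_scale * vp
    if start is None:
        sigma = _he_start(y, X, mats, floor, vp)
    else:
        sigma = np.asarray(start, float).copy()
    if constrain:
        sigma = np.maximum(sigma, floor)

    state = _factorize(sigma, mats, y, X)
    if state is None:
        raise RemlError("initial variance matrix is not positive definite")
    ll = state.ll
    converged = False
    it = 0
    AI = np.eye(k + 1)
    for it in range(1, max_iter + 1):
        P = _projection(state)
        grad, AI, trPA, yPAPy = _derivatives(P, state.Py, mats)

        # AI (Newton) step on the free components; floor-pinned components
        # whose gradient pushes outward stay fixed (active-set handling)
        pinned = constrain & (sigma <= floor * (1 + 1e-9)) & (grad < 0)
        free = ~pinned
        delta = np.zeros(k + 1)
        try:
            delta[free] = np.linalg.solve(AI[np.ix_(free, free)], grad[free])
        except np.linalg.LinAlgError:
            delta = (sigma**2) * (yPAPy - trPA) / n  # EM fallback

        accepted = False
        for _ in range(30):  # step-halving
            cand = sigma + delta
            if constrain:
                cand = np.maximum(cand, floor)
            trial = _factorize(cand, mats, y, X)
            if trial is not None and trial.ll >= ll - 1e-10:
                accepted = True
                break
            delta *= 0.5
        if not accepted:
            # damped EM step, which cannot overshoot far
            delta = (sigma**2) * (yPAPy - trPA) / n
            cand = np.maximum(sigma + delta, floor) if constrain else sigma + delta
            trial = _factorize(cand, mats, y, X)
            if trial is None or trial.ll < ll - 1e-8:
                break  # no usable step; report current point, not converged
        change = trial.ll - ll
        sigma, ll, state = cand, trial.ll, trial
        if abs(change) < tol:
            converged = True
            break
    # reported curvature is the AI matrix from the last evaluated point;
    # at convergence it differs from the optimum by a sub-tol step

    pinned = (
        (sigma <= floor * (1 + 1e-9)) if constrain else np.zeros(k + 1, dtype=bool)
    )
    cond = np.linalg.cond(AI)
    identifiable = bool(cond < 1e10)
    cov = np.linalg.inv(AI) if identifiable else np.linalg.pinv(AI)
    se_sigma2 = np.sqrt(np.maximum(np.diag(cov), 0.0))

    total = sigma.sum()
    fractions = sigma / total
    # delta method for fractions f_i = sigma_i / sum(sigma)
    J = (np.eye(k + 1) * total - sigma[:, None]) / total**2
    cov_f = J @ cov @ J.T
    se_fractions = np.sqrt(np.maximum(np.diag(cov_f), 0.0))

    return VarianceFit(
        names=list(model.names) + [RESIDUAL],
        sigma2=sigma,
        se_sigma2=se_sigma2,
        fractions=fractions,
        se_fractions=se_fractions,
        loglik=ll,
        n_iter=it,
        converged=converged,
        ai_matrix=AI,
        constrained=pinned,
        identifiable=identifiable,
        n=n,
    )


# ---------------------------------------------------------------------------
# tests on fitted models
# ---------------------------------------------------------------------------

def wald_test(fit: VarianceFit, component: str, two_sided: bool = True) -> float:
    """Wald p-value for a variance fraction against its AI standard error.

    Components pinned at the constraint floor carry no usable curvature
    information; their p is reported as 1.
    """
    if component not in fit.names:
        raise RemlError(f"no component named {component!r}")
    if fit.is_constrained(component):
        return 1.0
    est, se = fit.fraction(component), fit.se_fraction(component)
    if est == 0.0:
        return 1.0
    if se == 0.0 or not np.isfinite(se):
        return 1.0
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(p if two_sided else p / 2.0)


def lrt(full: VarianceFit, reduced: VarianceFit, boundary_mixture: bool = True) -> float:
    """Likelihood-ratio test of nested variance models.

    For a single dropped component the null distribution is the 50:50
    mixture of chi2_0 and chi2_1 (the component sits on the boundary of the
    parameter space); ``boundary_mixture=False`` gives plain chi2_df.
    """
    dropped = [nm for nm in full.names if nm not in reduced.names]
    extra = [nm for nm in reduced.names if nm not in full.names]
    if extra or not dropped:
        raise RemlError("models are not nested (reduced must drop >=1 component of full)")
    lam = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(dropped)
    if boundary_mixture and df == 1:
        return float(1.0 if lam == 0.0 else 0.5 * stats.chi2.sf(lam, df=1))
    return float(stats.chi2.sf(lam, df=df) if lam > 0 else 1.0)


@dataclass
class SelectionStep:
    components: list[str]
    wald_p: dict
    lrt_p: dict  # only evaluated for Wald-non-significant candidates
    removed: str | None


def backward_select(
    model: VarianceModel,
    alpha: float = 0.05,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[VarianceFit, list[SelectionStep]]:
    """Backward stepwise pruning of variance components.

    At each step a component is a removal candidate if it is non-significant
    in BOTH the Wald test and the LRT at ``alpha``; the candidate with the
    largest (least significant) Wald p is dropped, and the loop ends when
    every remaining component is significant in at least one test.
    """
    current = model
    fit = fit_reml(current, tol=tol, max_iter=max_iter)
    if not fit.converged:
        raise RemlError("full model did not converge; cannot start selection")
    trace: list[SelectionStep] = []
    while current.names:
        wald_p = {nm: wald_test(fit, nm) for nm in current.names}
        lrt_p: dict = {}
        reduced_fits: dict = {}
        for nm in current.names:
            if wald_p[nm] < alpha:
                continue  # significant by Wald; cannot be removed
            sub = current.drop(nm)
            keep_idx = [i for i, m in enumerate(current.names) if m != nm]
            start = np.append(fit.sigma2[keep_idx], fit.sigma2[-1])
            rfit = fit_reml(sub, tol=tol, max_iter=max_iter, start=start)
            reduced_fits[nm] = rfit
            lrt_p[nm] = lrt(fit, rfit)
        candidates = [nm for nm in lrt_p if wald_p[nm] >= alpha and lrt_p[nm] >= alpha]
        if not candidates:
            trace.append(SelectionStep(list(current.names), wald_p, lrt_p, None))
            break
        worst = max(candidates, key=lambda nm: wald_p[nm])
        trace.append(SelectionStep(list(current.names), wald_p, lrt_p, worst))
        current = current.drop(worst)
        fit = reduced_fits[worst]
    else:
        trace.append(SelectionStep([], {}, {}, None))
    return fit, trace


# ---------------------------------------------------------------------------
# liability transformation
# ---------------------------------------------------------------------------

def observed_to_liability(
    fraction_obs: float, prevalence: float, case_fraction: float | None = None
) -> float:
    """Observed-scale variance fraction -> liability scale.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2), with K the population
    prevalence, P the sample case fraction and z the standard-normal density
    at the prevalence threshold.  With P = K this reduces to K(1-K)/z^2.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    P = prevalence if case_fraction is None else case_fraction
    if not (0.0 < P < 1.0):
        raise ValueError("case_fraction must be in (0, 1)")
    K = prevalence
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    return float(fraction_obs * K**2 * (1.0 - K) ** 2 / (P * (1.0 - P) * z**2))
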