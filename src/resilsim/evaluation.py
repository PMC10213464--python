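"""REML variance components and (G)BLUP for reaction-norm models.

The bivariate random-regression reaction-norm model for record ``i`` of
animal ``j`` at challenge ``x_i`` is

    y_i = mu0 + x_i * muR + a0_j + x_i * aR_j + e_i

with (a0, aR) ~ N(0, G0 (x) K) for a 2x2 genetic covariance G0 and a
relationship matrix K (pedigree NRM or genomic GRM), and heteroscedastic
independent residuals var(e_i) = var_e0 + x_i^2 * var_er (the residual
intercept and slope deviations are uncorrelated).  The phenotypic covariance
of two records is therefore

    V_ij = K[a_i, a_j] * (var_a0 + cov_a (x_i + x_j) + var_ar x_i x_j)
           + delta_ij (var_e0 + var_er x_i^2)

Variance components are estimated by average-information REML on this dense
V, with step-halving to keep the likelihood monotone and the parameters in
the feasible region.  Breeding values come from the BLUP closed form
u_hat = Cov(u, y) P y, equivalent to Henderson's mixed-model equations.

The conventional evaluation (no reaction norm) fits fixed flock effects and
a single additive animal effect; its estimated flock effects, affinely
rescaled so the best flock maps to zero challenge and the worst to Xmax,
provide the challenge proxy of the two-step approach used when the true
challenge is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .relationships import RelationshipMatrix

__all__ = [
    "VarianceEstimates",
    "UnivariateVarianceEstimates",
    "BreedingValueEstimates",
    "TwoStepResult",
    "reml_rn",
    "solve_blup_rn",
    "restricted_loglik_rn",
    "fit_conventional",
    "estimate_challenge_proxy",
    "two_step_evaluation",
]


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, RelationshipMatrix) else np.asarray(K)


@dataclass
class VarianceEstimates:
    """Bivariate RN variance components with REML metadata."""

    var_a0: float
    cov_a: float
    var_ar: float
    var_e0: float
    var_er: float
    loglik: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    feasible: bool = False
    se: np.ndarray | None = None

    @property
    def rho_a(self) -> float:
        d = np.sqrt(self.var_a0 * self.var_ar)
        return self.cov_a / d if d > 0 else np.nan

    def theta(self) -> np.ndarray:
        return np.array([self.var_a0, self.cov_a, self.var_ar,
                         self.var_e0, self.var_er])

    def report(self) -> dict:
        """JSON-serializable variance-component report with metadata."""
        return {"var_a0": float(self.var_a0), "cov_a": float(self.cov_a),
                "var_ar": float(self.var_ar), "var_e0": float(self.var_e0),
                "var_er": float(self.var_er), "rho_a": float(self.rho_a),
                "loglik": float(self.loglik),
                "n_iterations": int(self.n_iterations),
                "converged": bool(self.converged),
                "feasible": bool(self.feasible)}


@dataclass
class UnivariateVarianceEstimates:
    var_a: float
    var_e: float
    loglik: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    feasible: bool = False
    se: np.ndarray | None = None


@dataclass
class BreedingValueEstimates:
    """EBVs for every animal of the relationship matrix (phenotyped or not)."""

    a0_hat: np.ndarray | None = None
    ar_hat: np.ndarray | None = None
    a_hat: np.ndarray | None = None
    fixed_effects: np.ndarray | None = None
    flock_effects: np.ndarray | None = None
    flock_levels: np.ndarray | None = None


# ---------------------------------------------------------------------------
# generic dense AI-REML

class _Components:
    """Variance structure V(theta) = sum_k theta_k C_k over dense matrices.

    Subclasses expose the matrices implicitly: ``build`` assembles V,
    ``mult(k, R)`` applies C_k to a vector/matrix, ``traces(A)`` returns
    tr(A C_k) for all k using O(n^2) work.  The optimizer works on an
    unconstrained transform of theta (log-Cholesky for covariance blocks,
    log for variances), so feasibility holds by construction.
    """

    n_params: int
    var_mask: np.ndarray       # True where theta_k is a variance (>= 0)

    def build(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def mult(self, k: int, R: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def traces(self, A: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def from_unconstrained(self, phi: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, phi: np.ndarray) -> np.ndarray:
        """d theta / d phi at phi."""
        raise NotImplementedError


class _RNComponents(_Components):
    """Five-parameter RN structure (var_a0, cov_a, var_ar, var_e0, var_er)."""

    n_params = 5

    def __init__(self, M: np.ndarray, x: np.ndarray):
        self.M = M
        self.x = x
        self.x2 = x * x
        self.var_mask = np.array([True, False, True, True, True])

    def build(self, theta: np.ndarray) -> np.ndarray:
        t = theta
        x = self.x
        gen = t[0] + t[1] * (x[:, None] + x[None, :]) \
            + t[2] * (x[:, None] * x[None, :])
        V = self.M * gen
        V[np.diag_indices_from(V)] += t[3] + t[4] * self.x2
        return V

    def mult(self, k: int, R: np.ndarray) -> np.ndarray:
        x = self.x if R.ndim == 1 else self.x[:, None]
        x2 = self.x2 if R.ndim == 1 else self.x2[:, None]
        if k == 0:
            return self.M @ R
        if k == 1:
            return x * (self.M @ R) + self.M @ (x * R)
        if k == 2:
            return x * (self.M @ (x * R))
        if k == 3:
            return R
        return x2 * R

    def traces(self, A: np.ndarray) -> np.ndarray:
        E = A * self.M
        rs = E.sum(axis=1)
        return np.array([
            rs.sum(),
            2.0 * self.x @ rs,
            self.x @ E @ self.x,
            np.trace(A),
            float(np.diag(A) @ self.x2),
        ])

    # theta = (va0, cov, var, ve0, ver); phi = (a, b, c, d, f) with the
    # genetic G0 = L L', L = [[e^a, 0], [b, e^c]], and ve0 = e^2d, ver = e^2f
    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        va0, cov, var, ve0, ver = np.maximum(
            theta, [1e-12, -np.inf, 1e-12, 1e-12, 1e-12])
        a = 0.5 * np.log(va0)
        b = cov / np.sqrt(va0)
        rem = max(var - b * b, 1e-10 * max(var, 1.0))
        return np.array([a, b, 0.5 * np.log(rem),
                         0.5 * np.log(ve0), 0.5 * np.log(ver)])

    def from_unconstrained(self, phi: np.ndarray) -> np.ndarray:
        a, b, c, d, f = np.clip(phi, -200.0, 200.0)
        ea, ec = np.exp(2 * np.clip(a, -15, 15)), np.exp(2 * np.clip(c, -15, 15))
        sa = np.exp(np.clip(a, -15, 15))
        return np.array([ea, sa * b, b * b + ec,
                         np.exp(2 * np.clip(d, -15, 15)),
                         np.exp(2 * np.clip(f, -15, 15))])

    def jacobian(self, phi: np.ndarray) -> np.ndarray:
        a, b, c, d, f = phi
        sa, ea, ec = np.exp(a), np.exp(2 * a), np.exp(2 * c)
        J = np.zeros((5, 5))
        J[0, 0] = 2 * ea
        J[1, 0] = sa * b
        J[1, 1] = sa
        J[2, 1] = 2 * b
        J[2, 2] = 2 * ec
        J[3, 3] = 2 * np.exp(2 * d)
        J[4, 4] = 2 * np.exp(2 * f)
        return J


class _UniComponents(_Components):
    """Two-parameter animal model structure (var_a, var_e)."""

    n_params = 2

    def __init__(self, M: np.ndarray):
        self.M = M
        self.var_mask = np.array([True, True])

    def build(self, theta: np.ndarray) -> np.ndarray:
        V = theta[0] * self.M
        V[np.diag_indices_from(V)] += theta[1]
        return V

    def mult(self, k: int, R: np.ndarray) -> np.ndarray:
        return self.M @ R if k == 0 else R

    def traces(self, A: np.ndarray) -> np.ndarray:
        return np.array([float(np.sum(A * self.M)), float(np.trace(A))])

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        return 0.5 * np.log(np.maximum(theta, 1e-12))

    def from_unconstrained(self, phi: np.ndarray) -> np.ndarray:
        return np.exp(2 * np.clip(phi, -15, 15))

    def jacobian(self, phi: np.ndarray) -> np.ndarray:
        return np.diag(2 * np.exp(2 * phi))


@dataclass
class _RemlFit:
    theta: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    se: np.ndarray


def _reml_state(y, W, comps, theta):
    """Factorize V(theta) and return everything one REML iteration needs."""
    V = comps.build(theta)
    cf = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    B = cho_solve(cf, W)                     # V^-1 W
    WVW = W.T @ B
    cf_w = cho_factor(WVW)
    logdet_w = 2.0 * np.sum(np.log(np.diag(cf_w[0])))
    Vy = cho_solve(cf, y)
    beta = cho_solve(cf_w, W.T @ Vy)
    r = Vy - B @ beta                        # P y
    loglik = -0.5 * (logdet_v + logdet_w + float(y @ r))
    return cf, cf_w, B, r, beta, loglik


def _loglik_only(y, W, comps, theta) -> float:
    try:
        return _reml_state(y, W, comps, theta)[-1]
    except (LinAlgError, np.linalg.LinAlgError):
        return -np.inf


def _score_ai(y, W, comps, theta):
    """REML score vector and average-information matrix at theta."""
    n = y.shape[0]
    cf, cf_w, B, r, _, loglik = _reml_state(y, W, comps, theta)
    Vinv = cho_solve(cf, np.eye(n))
    tr_full = comps.traces(Vinv)
    # tr(P C_k) = tr(V^-1 C_k) - tr((W'V^-1W)^-1 B' C_k B)
    score = np.zeros(comps.n_params)
    T = np.empty((n, comps.n_params))
    for k in range(comps.n_params):
        CB = comps.mult(k, B)
        corr = float(np.trace(cho_solve(cf_w, B.T @ CB)))
        t_k = comps.mult(k, r)
        T[:, k] = t_k
        score[k] = -0.5 * ((tr_full[k] - corr) - float(r @ t_k))
    PT = cho_solve(cf, T)
    PT -= B @ cho_solve(cf_w, B.T @ T)
    AI = 0.5 * (T.T @ PT)
    return score, 0.5 * (AI + AI.T), loglik


_MAX_LOG_STEP = 2.0  # cap per-parameter moves on the unconstrained scale


def _ai_reml(y: np.ndarray, W: np.ndarray, comps: _Components,
             theta0: np.ndarray, tol: float = 1e-6,
             max_iter: int = 200) -> _RemlFit:
    """Average-information REML on an unconstrained parameter scale.

    Each iteration takes the AI-Newton step in the transformed coordinates
    (score and AI mapped through the Jacobian), halving the step until the
    restricted likelihood strictly improves; the components stay feasible by
    construction.  If the Newton direction stops being an ascent direction
    (typical near the correlation boundary), the fit is finished by a
    quasi-Newton polish on the same unconstrained scale with the analytic
    gradient.
    """
    phi = comps.to_unconstrained(theta0)
    loglik = _loglik_only(y, W, comps, comps.from_unconstrained(phi))
    if not np.isfinite(loglik):
        raise LinAlgError("starting values give a singular mixed-model system")
    converged = False
    se = np.full(comps.n_params, np.nan)
    it = 0
    stalled = False
    for it in range(1, max_iter + 1):
        theta = comps.from_unconstrained(phi)
        score, AI, loglik = _score_ai(y, W, comps, theta)
        g = comps.jacobian(phi).T @ score
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        H = comps.jacobian(phi).T @ AI @ comps.jacobian(phi)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H + 1e-8 * np.eye(H.shape[0]), g,
                                    rcond=None)[0]
        delta = np.clip(delta, -_MAX_LOG_STEP, _MAX_LOG_STEP)
        step, new_phi, new_loglik = 1.0, None, None
        for _ in range(20):
            cand = phi + step * delta
            ll = _loglik_only(y, W, comps, comps.from_unconstrained(cand))
            if ll > loglik + 1e-12 * max(1.0, abs(loglik)):
                new_phi, new_loglik = cand, ll
                break
            step *= 0.5
        if new_phi is None:
            stalled = True
            break
        d_ll = abs(new_loglik - loglik)
        d_phi = np.max(np.abs(new_phi - phi))
        phi, loglik = new_phi, new_loglik
        if d_ll < tol and d_phi < tol:
            converged = True
            break
    if stalled:
        phi, loglik, converged = _quasi_newton_polish(y, W, comps, phi, tol)
    theta = comps.from_unconstrained(phi)
    # SEs from the inverse AI matrix (original scale) at the solution
    try:
        _, AI, loglik = _score_ai(y, W, comps, theta)
        cov = np.linalg.pinv(AI)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except (LinAlgError, np.linalg.LinAlgError):
        pass
    return _RemlFit(theta=theta, loglik=loglik, n_iterations=it,
                    converged=converged, se=se)


def _quasi_newton_polish(y, W, comps, phi0, tol):
    """Finish a stalled AI-Newton fit with L-BFGS-B on the same scale."""
    from scipy.optimize import minimize

    def negloglik_and_grad(phi):
        theta = comps.from_unconstrained(phi)
        try:
            score, _, ll = _score_ai(y, W, comps, theta)
        except (LinAlgError, np.linalg.LinAlgError):
            return 1e30, np.zeros_like(phi)
        if not np.isfinite(ll):
            return 1e30, np.zeros_like(phi)
        return -ll, -(comps.jacobian(phi).T @ score)

    res = minimize(negloglik_and_grad, phi0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 100, "ftol": tol * 1e-2,
                            "gtol": tol})
    phi = res.x
    ll = _loglik_only(y, W, comps, comps.from_unconstrained(phi))
    return phi, ll, bool(res.success)


# ---------------------------------------------------------------------------
# reaction-norm model

def _rn_design(x: np.ndarray) -> np.ndarray:
    if np.ptp(x) > 0:
        return np.column_stack([np.ones_like(x), x])
    return np.ones((x.shape[0], 1))


def _rn_start(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    W = _rn_design(x)
    beta, *_ = np.linalg.lstsq(W, y, rcond=None)
    s2 = float(np.var(y - W @ beta))
    mean_x2 = float(np.mean(x * x))
    v0 = s2 / 4 if mean_x2 > 0 else s2 / 2
    vr = s2 / (4 * mean_x2) if mean_x2 > 0 else 0.0
    return np.array([v0, 0.0, vr, v0, vr])


def reml_rn(y: np.ndarray, x: np.ndarray, animal: np.ndarray,
            K: RelationshipMatrix | np.ndarray,
            start: VarianceEstimates | None = None, tol: float = 1e-6,
            max_iter: int = 200) -> VarianceEstimates:
    """AI-REML for the bivariate RN model.

    ``animal`` holds row indices into K for each record.  With fewer than two
    distinct challenge values the slope is unidentifiable and the fit
    degrades to the univariate animal model (slope components fixed at 0).
    The genetic correlation is estimated freely.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    animal = np.asarray(animal, dtype=np.int64)
    Km = _as_matrix(K)
    M = Km[np.ix_(animal, animal)]
    scale = float(np.var(y)) or 1.0
    if np.ptp(x) == 0:
        # degenerate single-trait case: univariate animal model on A0
        comps_u = _UniComponents(M)
        theta0 = np.full(2, scale / 2) if start is None \
            else np.array([start.var_a0, start.var_e0])
        fit = _ai_reml(y, np.ones((y.shape[0], 1)), comps_u, theta0,
                       tol=tol, max_iter=max_iter)
        var_a, var_e = fit.theta
        feasible = fit.converged and min(var_a, var_e) >= 1e-8 * scale
        se = np.array([fit.se[0], np.nan, np.nan, fit.se[1], np.nan])
        return VarianceEstimates(var_a0=var_a, cov_a=0.0, var_ar=0.0,
                                 var_e0=var_e, var_er=0.0,
                                 loglik=fit.loglik,
                                 n_iterations=fit.n_iterations,
                                 converged=fit.converged, feasible=feasible,
                                 se=se)
    comps = _RNComponents(M, x)
    theta0 = _rn_start(y, x) if start is None else start.theta()
    fit = _ai_reml(y, _rn_design(x), comps, theta0, tol=tol,
                   max_iter=max_iter)
    t = fit.theta
    pinned = bool(np.any(t[comps.var_mask] < 1e-8 * scale))
    rho_bad = False
    if t[0] > 0 and t[2] > 0:
        rho_bad = abs(t[1] / np.sqrt(t[0] * t[2])) > 1 - 1e-8
    feasible = fit.converged and not pinned and not rho_bad
    return VarianceEstimates(var_a0=t[0], cov_a=t[1], var_ar=t[2],
                             var_e0=t[3], var_er=t[4], loglik=fit.loglik,
                             n_iterations=fit.n_iterations,
                             converged=fit.converged, feasible=feasible,
                             se=fit.se)


def restricted_loglik_rn(y, x, animal, K, vc: VarianceEstimates) -> float:
    """Restricted log-likelihood of the RN model at given components."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    animal = np.asarray(animal, dtype=np.int64)
    Km = _as_matrix(K)
    comps = _RNComponents(Km[np.ix_(animal, animal)], x)
    return _loglik_only(y, _rn_design(x), comps, vc.theta())


def solve_blup_rn(y, x, animal, K, vc: VarianceEstimates
                  ) -> BreedingValueEstimates:
    """Exact BLUP of (a0, aR) for every animal in K given the components.

    Uses the closed form u_hat = Cov(u, y) P y, identical to solving
    Henderson's mixed-model equations with per-record residual weights
    1 / (var_e0 + x^2 var_er).
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    animal = np.asarray(animal, dtype=np.int64)
    Km = _as_matrix(K)
    comps = _RNComponents(Km[np.ix_(animal, animal)], x)
    W = _rn_design(x)
    _, _, _, r, beta, _ = _reml_state(y, W, comps, vc.theta())
    Ka = Km[:, animal]
    a0_hat = Ka @ ((vc.var_a0 + vc.cov_a * x) * r)
    ar_hat = Ka @ ((vc.cov_a + vc.var_ar * x) * r)
    return BreedingValueEstimates(a0_hat=a0_hat, ar_hat=ar_hat,
                                  fixed_effects=beta)


# ---------------------------------------------------------------------------
# conventional model and two-step proxy

def _flock_design(flock: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(flock, return_inverse=True)
    n = flock.shape[0]
    W = np.ones((n, levels.size))
    W[:, 1:] = (codes[:, None] == np.arange(1, levels.size)[None, :])
    return W, levels


def fit_conventional(y, flock, animal, K, tol: float = 1e-6,
                     max_iter: int = 200
                     ) -> tuple[UnivariateVarianceEstimates,
                                BreedingValueEstimates]:
    """Fixed-flock animal model: y = mu + F_l + a_j + e.

    Flock effects are fixed, expressed relative to the first flock level
    (F_1 = 0).  Returns univariate REML components and BLUP estimates,
    including EBVs for unphenotyped animals in K.
    """
    y = np.asarray(y, dtype=np.float64)
    flock = np.asarray(flock)
    animal = np.asarray(animal, dtype=np.int64)
    Km = _as_matrix(K)
    M = Km[np.ix_(animal, animal)]
    comps = _UniComponents(M)
    W, levels = _flock_design(flock)
    beta0, *_ = np.linalg.lstsq(W, y, rcond=None)
    s2 = float(np.var(y - W @ beta0)) or float(np.var(y)) or 1.0
    fit = _ai_reml(y, W, comps, np.array([s2 / 2, s2 / 2]), tol=tol,
                   max_iter=max_iter)
    var_a, var_e = fit.theta
    scale = float(np.var(y)) or 1.0
    feasible = fit.converged and min(var_a, var_e) >= 1e-8 * scale
    vc = UnivariateVarianceEstimates(var_a=var_a, var_e=var_e,
                                     loglik=fit.loglik,
                                     n_iterations=fit.n_iterations,
                                     converged=fit.converged,
                                     feasible=feasible, se=fit.se)
    _, _, _, r, beta, _ = _reml_state(y, W, comps, fit.theta)
    a_hat = Km[:, animal] @ (var_a * r)
    flock_effects = np.concatenate([[0.0], beta[1:]])
    return vc, BreedingValueEstimates(a_hat=a_hat, fixed_effects=beta,
                                      flock_effects=flock_effects,
                                      flock_levels=levels)


def estimate_challenge_proxy(flock_effects: np.ndarray,
                             xmax: float) -> np.ndarray:
    """Affine map of estimated flock effects onto [0, xmax], reversed.

    The flock with the highest average performance (largest effect) gets
    proxy challenge 0; the lowest gets xmax.
    """
    f = np.asarray(flock_effects, dtype=np.float64)
    if f.size < 2:
        raise ValueError("need at least two flocks to rescale")
    span = f.max() - f.min()
    if span <= 0:
        raise ValueError("all flock effects equal: proxy undefined")
    return (f.max() - f) / span * xmax


@dataclass
class TwoStepResult:
    step1_vc: UnivariateVarianceEstimates
    step1_ebv: BreedingValueEstimates
    proxy_by_flock: np.ndarray
    x_proxy: np.ndarray
    vc: VarianceEstimates
    ebv: BreedingValueEstimates = field(default=None)


def two_step_evaluation(y, flock, animal, K, xmax: float,
                        tol: float = 1e-6,
                        max_iter: int = 200) -> TwoStepResult:
    """Unknown-challenge RN evaluation.

    Step 1 fits the conventional fixed-flock model; its flock effects are
    rescaled into a challenge proxy (same value for every record of a
    flock).  Step 2 runs the RN REML + BLUP on the proxy.  The two error
    sources of the approach — flock-effect estimation error and the loss of
    within-flock heterogeneity — arise naturally from this composition.
    """
    flock = np.asarray(flock)
    vc1, ebv1 = fit_conventional(y, flock, animal, K, tol=tol,
                                 max_iter=max_iter)
    proxy = estimate_challenge_proxy(ebv1.flock_effects, xmax)
    codes = np.searchsorted(ebv1.flock_levels, flock)
    x_proxy = proxy[codes]
    vc = reml_rn(y, x_proxy, animal, K, tol=tol, max_iter=max_iter)
    ebv = solve_blup_rn(y, x_proxy, animal, K, vc)
    return TwoStepResult(step1_vc=vc1, step1_ebv=ebv1, proxy_by_flock=proxy,
                         x_proxy=x_proxy, vc=vc, ebv=ebv)
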