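"""REML / BLUP machinery for the reaction-norm and conventional models."""

import numpy as np
import pytest
from scipy import optimize, stats

import resilsim as rs
from resilsim.evaluation import VarianceEstimates


def _toy_records():
    """3-animal pedigree (founder pair + offspring), 4 records, known X."""
    sire = np.array([-1, -1, 0])
    dam = np.array([-1, -1, 1])
    K = rs.build_nrm(sire, dam)
    y = np.array([10.3, 8.1, 9.4, 6.2])
    x = np.array([0.2, 1.5, 0.7, 1.9])
    animal = np.array([0, 1, 2, 2])
    vc = VarianceEstimates(var_a0=0.3, cov_a=-0.1, var_ar=0.2,
                           var_e0=0.8, var_er=0.5, feasible=True)
    return y, x, animal, K, vc


def test_blup_matches_hand_built_mixed_model_equations():
    """The closed-form BLUP equals Henderson's MME solved by direct inversion
    on a toy where everything can be assembled by hand."""
    y, x, animal, K, vc = _toy_records()
    A = K.values
    n, q = y.size, A.shape[0]
    W = np.column_stack([np.ones(n), x])
    Za = np.zeros((n, q))
    Za[np.arange(n), animal] = 1.0
    Z = np.hstack([Za, x[:, None] * Za])
    G0 = np.array([[vc.var_a0, vc.cov_a], [vc.cov_a, vc.var_ar]])
    G = np.kron(G0, A)
    Rinv = np.diag(1.0 / (vc.var_e0 + vc.var_er * x ** 2))
    C = np.block([[W.T @ Rinv @ W, W.T @ Rinv @ Z],
                  [Z.T @ Rinv @ W, Z.T @ Rinv @ Z + np.linalg.inv(G)]])
    rhs = np.concatenate([W.T @ Rinv @ y, Z.T @ Rinv @ y])
    sol = np.linalg.solve(C, rhs)
    ebv = rs.solve_blup_rn(y, x, animal, K, vc)
    assert np.allclose(ebv.fixed_effects, sol[:2], atol=1e-10)
    assert np.allclose(ebv.a0_hat, sol[2:2 + q], atol=1e-10)
    assert np.allclose(ebv.ar_hat, sol[2 + q:], atol=1e-10)


def test_blup_invariant_to_scaling_all_components():
    y, x, animal, K, vc = _toy_records()
    ebv1 = rs.solve_blup_rn(y, x, animal, K, vc)
    vc2 = VarianceEstimates(2 * vc.var_a0, 2 * vc.cov_a, 2 * vc.var_ar,
                            2 * vc.var_e0, 2 * vc.var_er, feasible=True)
    ebv2 = rs.solve_blup_rn(y, x, animal, K, vc2)
    assert np.allclose(ebv1.a0_hat, ebv2.a0_hat)
    assert np.allclose(ebv1.ar_hat, ebv2.ar_hat)
    assert np.allclose(ebv1.fixed_effects, ebv2.fixed_effects)


def test_unrelated_unphenotyped_animal_gets_zero_ebv():
    y, x, animal, _, vc = _toy_records()
    K = np.eye(4)
    K[:3, :3] = rs.build_nrm(np.array([-1, -1, 0]),
                             np.array([-1, -1, 1])).values
    ebv = rs.solve_blup_rn(y, x, animal, K, vc)
    assert ebv.a0_hat[3] == pytest.approx(0.0, abs=1e-12)
    assert ebv.ar_hat[3] == pytest.approx(0.0, abs=1e-12)


def test_blup_equivariant_under_challenge_shift():
    """Shifting X by -c while transforming the genetic covariance by
    T = [[1, c], [0, 1]] re-expresses the same model: slopes unchanged,
    intercepts shifted by c * slope (homoscedastic residual case)."""
    y, x, animal, K, _ = _toy_records()
    c = 0.8
    G0 = np.array([[0.3, -0.1], [-0.1, 0.2]])
    T = np.array([[1.0, c], [0.0, 1.0]])
    G0s = T @ G0 @ T.T
    vc = VarianceEstimates(G0[0, 0], G0[0, 1], G0[1, 1], 0.8, 0.0,
                           feasible=True)
    vcs = VarianceEstimates(G0s[0, 0], G0s[0, 1], G0s[1, 1], 0.8, 0.0,
                            feasible=True)
    ebv = rs.solve_blup_rn(y, x, animal, K, vc)
    ebv_s = rs.solve_blup_rn(y, x - c, animal, K, vcs)
    assert np.allclose(ebv_s.ar_hat, ebv.ar_hat, atol=1e-10)
    assert np.allclose(ebv_s.a0_hat, ebv.a0_hat + c * ebv.ar_hat, atol=1e-10)


def _simulate_rn(seed, n_sires=30, n_off=8, nrec=3, params=None):
    params = params or rs.TraitParams()
    rng = np.random.default_rng(seed)
    q = n_sires * (1 + n_off)
    sire = np.concatenate([np.full(n_sires, -1),
                           np.repeat(np.arange(n_sires), n_off)])
    dam = np.full(q, -1)
    K = rs.build_nrm(sire, dam)
    cA = np.linalg.cholesky(K.values + 1e-10 * np.eye(q))
    u = cA @ rng.standard_normal((q, 2)) @ np.linalg.cholesky(
        params.genetic_covariance).T
    animal = np.tile(np.arange(q), nrec)
    x = rng.uniform(0, 2, size=animal.size)
    e = rng.normal(0, np.sqrt(params.var_e0), animal.size) \
        + x * rng.normal(0, np.sqrt(params.var_er), animal.size)
    y = params.mu0 + u[animal, 0] + x * (params.muR + u[animal, 1]) + e
    return y, x, animal, K, u


def test_reml_solution_not_worse_than_truth():
    """The restricted likelihood at the REML solution is at least as high as
    at the generating parameters (optimality)."""
    y, x, animal, K, _ = _simulate_rn(0)
    vc = rs.reml_rn(y, x, animal, K)
    truth = VarianceEstimates(0.1, -0.05, 0.1, 0.9, 0.9)
    assert vc.loglik >= rs.restricted_loglik_rn(y, x, animal, K, truth) - 1e-6


def test_degenerate_zero_challenge_matches_univariate_oracle():
    """With all X = 0 the RN fit degrades to the univariate animal model and
    must agree with an independently coded direct REML optimizer."""
    params = rs.TraitParams(muR=0.0, var_a0=0.3, var_e0=0.7, var_ar=0.0,
                            var_er=0.0, rho_a=0.0)
    rng = np.random.default_rng(42)
    n_sires, n_off = 25, 8
    q = n_sires * (1 + n_off)
    sire = np.concatenate([np.full(n_sires, -1),
                           np.repeat(np.arange(n_sires), n_off)])
    K = rs.build_nrm(sire, np.full(q, -1))
    cA = np.linalg.cholesky(K.values + 1e-10 * np.eye(q))
    u = np.sqrt(params.var_a0) * (cA @ rng.standard_normal(q))
    animal = np.tile(np.arange(q), 2)
    y = params.mu0 + u[animal] + rng.normal(0, np.sqrt(params.var_e0),
                                            animal.size)
    x = np.zeros_like(y)
    vc = rs.reml_rn(y, x, animal, K)
    assert vc.cov_a == 0.0 and vc.var_ar == 0.0 and vc.var_er == 0.0

    # independent oracle: direct Nelder-Mead on the restricted likelihood
    M = K.values[np.ix_(animal, animal)]
    ones = np.ones((y.size, 1))

    def negll(logtheta):
        va, ve = np.exp(logtheta)
        V = va * M + ve * np.eye(y.size)
        sign, logdet = np.linalg.slogdet(V)
        Vinv = np.linalg.inv(V)
        WVW = ones.T @ Vinv @ ones
        P = Vinv - Vinv @ ones @ np.linalg.inv(WVW) @ ones.T @ Vinv
        return 0.5 * (logdet + np.log(WVW[0, 0]) + y @ P @ y)

    res = optimize.minimize(negll, np.log([0.2, 0.8]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    va_o, ve_o = np.exp(res.x)
    assert vc.var_a0 == pytest.approx(va_o, rel=1e-3)
    assert vc.var_e0 == pytest.approx(ve_o, rel=1e-3)
    assert vc.loglik == pytest.approx(-res.fun, abs=1e-5)


def test_reml_recovers_components_in_simulation():
    """Estimates across simulated replicates centre on the generating values
    (moderate n, so a generous band per component)."""
    ests = [rs.reml_rn(*_simulate_rn(s)[:4]).theta() for s in range(4)]
    mean = np.mean(ests, axis=0)
    truth = np.array([0.1, -0.05, 0.1, 0.9, 0.9])
    assert np.allclose(mean, truth, atol=np.array([0.1, 0.08, 0.1, 0.1, 0.1]))


def test_challenge_proxy_affine_map():
    proxy = rs.estimate_challenge_proxy(np.array([5.0, 2.0, -1.0]), xmax=2.0)
    assert np.allclose(proxy, [0.0, 1.0, 2.0])
    proxy2 = rs.estimate_challenge_proxy(np.array([0.3, -0.7]), xmax=2.0)
    assert set(np.round(proxy2, 12)) == {0.0, 2.0}
    # monotone: proxy ranking reverses the flock-effect ranking
    f = np.array([0.1, 2.3, -0.4, 1.1])
    p = rs.estimate_challenge_proxy(f, xmax=2.0)
    assert np.array_equal(np.argsort(p), np.argsort(-f))


def test_challenge_proxy_errors():
    with pytest.raises(ValueError):
        rs.estimate_challenge_proxy(np.array([1.0]), xmax=2.0)
    with pytest.raises(ValueError):
        rs.estimate_challenge_proxy(np.array([1.0, 1.0]), xmax=2.0)


def test_conventional_model_single_flock_reduces_to_mean_plus_animal():
    y, x, animal, K, _ = _toy_records()
    flock = np.zeros(y.size, dtype=int)
    vc, ebv = rs.fit_conventional(y, flock, animal, K)
    assert ebv.flock_effects.tolist() == [0.0]
    assert ebv.fixed_effects.size == 1
    assert ebv.a_hat.size == K.n


def test_conventional_flock_effects_recover_challenge_ordering():
    """Estimated fixed flock effects decrease with the flock's true mean
    challenge (performance drops by muR per challenge unit)."""
    params = rs.TraitParams()
    rng = np.random.default_rng(3)
    n, n_flocks = 800, 8
    flock_means = np.linspace(0.2, 1.8, n_flocks)
    flock = rng.integers(0, n_flocks, size=n)
    x = flock_means[flock] + rng.uniform(-0.1, 0.1, n)
    a = rng.normal(0, np.sqrt(params.var_a0), n)
    y = params.mu0 + a + x * params.muR \
        + rng.normal(0, np.sqrt(params.var_e0), n)
    vc, ebv = rs.fit_conventional(y, flock, np.arange(n), np.eye(n))
    rho = stats.spearmanr(ebv.flock_effects, flock_means).statistic
    assert rho == pytest.approx(-1.0, abs=1e-12)
    proxy = rs.estimate_challenge_proxy(ebv.flock_effects, xmax=2.0)
    assert stats.pearsonr(proxy, flock_means).statistic > 0.98


def test_two_step_assigns_one_proxy_per_flock():
    y, x, animal, K, _ = _toy_records()
    flock = np.array([0, 1, 0, 1])
    res = rs.two_step_evaluation(y, flock, animal, K, xmax=2.0)
    assert res.x_proxy[0] == res.x_proxy[2]
    assert res.x_proxy[1] == res.x_proxy[3]
    assert set(np.round(res.proxy_by_flock, 12)) == {0.0, 2.0}


def test_two_step_approaches_known_x_when_flocks_homogeneous():
    """With many flocks, tiny within-flock spread and strong flock signal,
    the proxy is nearly an affine image of the true challenge and the
    resulting EBV correlate closely with the known-X EBVs."""
    params = rs.TraitParams()
    y, x, animal, K, u = _simulate_rn(1, nrec=2)
    # records binned into 12 near-homogeneous flocks along x
    flock = np.digitize(x, np.quantile(x, np.linspace(0, 1, 13)[1:-1]))
    res = rs.two_step_evaluation(y, flock, animal, K, xmax=2.0)
    vc = rs.reml_rn(y, x, animal, K)
    ebv = rs.solve_blup_rn(y, x, animal, K, vc)
    assert stats.pearsonr(res.x_proxy, x).statistic > 0.9
    assert stats.pearsonr(res.ebv.ar_hat, ebv.ar_hat).statistic > 0.75
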