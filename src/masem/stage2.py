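"""Stage 2 of two-stage meta-analytic SEM: fitting the path model.

Two routes, matching the two classes of stage-1 pooling:

* ``fit_ml`` (univariate route) treats the pooled correlation matrix as if
  it were a sample covariance matrix observed on the total sample size N
  and minimizes the normal-theory ML discrepancy over all 9 free
  parameters (gamma11, gamma12, gamma21, beta21, phi11, phi22, phi12,
  psi11, psi22). This deliberately mirrors the common applied practice for
  univariate pooling; the pooled matrix is not a sample covariance matrix
  of N observations, which is exactly the behaviour the simulation
  harness is built to quantify.

* ``fit_wls`` (multivariate route) fits the correlation structure
  rho(theta) of the standardized model (5 free parameters; disturbance
  variances derived from the unit-variance constraints) by weighted least
  squares, with the stage-1 asymptotic covariance of the pooled vector as
  the weight matrix (asymptotically distribution-free / ADF estimation).

Both routes give an over-identification test with 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import (
    PathParams,
    corr_to_vec,
    derived_disturbances,
    implied_corr_jacobian,
    implied_corr_vector,
    implied_covariance,
)

__all__ = ["Stage2Result", "fit_ml", "fit_wls", "derived_psi"]

ML_PARAM_NAMES = (
    "gamma11",
    "gamma12",
    "gamma21",
    "beta21",
    "phi11",
    "phi22",
    "phi12",
    "psi11",
    "psi22",
)
WLS_PARAM_NAMES = ("gamma11", "gamma12", "gamma21", "beta21", "phi12", "psi11", "psi22")


@dataclass
class Stage2Result:
    """Path-model estimates, standard errors and the df=1 fit statistic."""

    route: str
    estimates: dict[str, float]
    ses: dict[str, float]
    chisq: float
    df: int
    p: float
    converged: bool
    extras: dict = field(default_factory=dict)


def derived_psi(theta: np.ndarray) -> tuple[float, float]:
    """Disturbance variances implied by the unit-variance constraints at theta."""
    psi11, psi22 = derived_disturbances(theta)
    if psi11 <= 0.0 or psi22 <= 0.0:
        raise ValueError("inadmissible theta: derived disturbance variance <= 0")
    return psi11, psi22


def _params9(x: np.ndarray) -> PathParams:
    g11, g12, g21, b21, ph11, ph22, ph12, ps1, ps2 = x
    return PathParams(
        gamma=np.array([[g11, g12], [g21, 0.0]]),
        beta=np.array([[0.0, 0.0], [b21, 0.0]]),
        phi=np.array([[ph11, ph12], [ph12, ph22]]),
        psi=np.diag([ps1, ps2]),
    )


def _dsigma9(x: np.ndarray) -> np.ndarray:
    """Analytic derivatives dSigma/dtheta_j, shape (9, 4, 4)."""
    g11, g12, g21, b21, ph11, ph22, ph12, ps1, ps2 = x
    G = np.array([[g11, g12], [g21, 0.0]])
    Phi = np.array([[ph11, ph12], [ph12, ph22]])
    A = np.array([[1.0, 0.0], [b21, 1.0]])  # (I - B)^-1 for strictly lower B

    def assemble(dtop, dcross, dphi):
        d = np.zeros((4, 4))
        d[:2, :2] = dtop
        d[:2, 2:] = dcross
        d[2:, :2] = dcross.T
        d[2:, 2:] = dphi
        return d

    out = np.zeros((9, 4, 4))
    PhiGt = Phi @ G.T
    # gamma elements (1,1), (1,2), (2,1)
    for j, (r, c) in enumerate(((0, 0), (0, 1), (1, 0))):
        E = np.zeros((2, 2))
        E[r, c] = 1.0
        dM = E @ PhiGt + PhiGt.T @ E.T
        out[j] = assemble(A @ dM @ A.T, A @ E @ Phi, np.zeros((2, 2)))
    # beta21: dA = A E21 A
    E21 = np.array([[0.0, 0.0], [1.0, 0.0]])
    dA = A @ E21 @ A
    M = G @ PhiGt + np.diag([ps1, ps2])
    out[3] = assemble(dA @ M @ A.T + A @ M @ dA.T, dA @ G @ Phi, np.zeros((2, 2)))
    # phi11, phi22, phi12
    for j, dPhi in zip(
        (4, 5, 6),
        (
            np.array([[1.0, 0.0], [0.0, 0.0]]),
            np.array([[0.0, 0.0], [0.0, 1.0]]),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
        ),
    ):
        out[j] = assemble(A @ G @ dPhi @ G.T @ A.T, A @ G @ dPhi, dPhi)
    # psi11, psi22
    for j, i in zip((7, 8), (0, 1)):
        E = np.zeros((2, 2))
        E[i, i] = 1.0
        out[j] = assemble(A @ E @ A.T, np.zeros((2, 2)), np.zeros((2, 2)))
    return out


def _fml_and_grad(x: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    """F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - 4 and its gradient."""
    sigma = implied_covariance(_params9(x))
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10 + float(x @ x), np.zeros(9)
    siginv = np.linalg.inv(sigma)
    _, logdetS = np.linalg.slogdet(S)
    f = 2.0 * np.log(np.diag(L)).sum() - logdetS + float(np.sum(S * siginv)) - 4.0
    Gmat = siginv - siginv @ S @ siginv  # dF/dSigma (symmetric convention)
    dsig = _dsigma9(x)
    grad = np.einsum("ij,kij->k", Gmat, dsig)
    return float(f), grad


def fit_ml(
    pooled: np.ndarray,
    total_n: float,
    *,
    n_multiplier: str = "n-1",
    max_restarts: int = 10,
) -> Stage2Result:
    """Normal-theory ML fit of the 9-parameter path model to a pooled matrix.

    chisq = (N-1) * F_ML at the optimum (``n_multiplier='n'`` uses N instead),
    df = 10 - 9 = 1. Standard errors come from the inverse Hessian of
    (N-1)/2 * F_ML, obtained by finite differences of the analytic gradient.
    """
    S = np.asarray(pooled, dtype=float)
    mult = float(total_n) - 1.0 if n_multiplier == "n-1" else float(total_n)
    x0 = np.array([0.1, 0.1, 0.1, 0.1, 1.0, 1.0, 0.1, 1.0, 1.0])
    bounds = [(-5, 5)] * 4 + [(1e-6, 10), (1e-6, 10), (-5, 5), (1e-6, 10), (1e-6, 10)]

    best = None
    rng = np.random.default_rng(zlib_seed(S))
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.2, size=9)
        start[4:6] = np.abs(start[4:6]) + 1e-3
        start[7:9] = np.abs(start[7:9]) + 1e-3
        res = optimize.minimize(
            _fml_and_grad,
            start,
            args=(S,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if res.success and res.fun < 1e8:
            break
    res = best
    xhat = res.x
    fmin = float(max(res.fun, 0.0))
    converged = bool(res.success and res.fun < 1e8 and min(xhat[7], xhat[8]) > 1e-5)

    # SEs from the observed information (mult/2) * hessian(F)
    H = np.empty((9, 9))
    h = 1e-5
    for j in range(9):
        xp = xhat.copy()
        xp[j] += h
        _, gp = _fml_and_grad(xp, S)
        xp[j] -= 2 * h
        _, gm = _fml_and_grad(xp, S)
        H[:, j] = (gp - gm) / (2 * h)
    H = (mult / 2.0) * (H + H.T) / 2.0
    ses = np.full(9, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            ses = np.sqrt(d)
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    chisq = mult * fmin
    return Stage2Result(
        route="ML",
        estimates=dict(zip(ML_PARAM_NAMES, xhat)),
        ses=dict(zip(ML_PARAM_NAMES, ses)),
        chisq=float(chisq),
        df=1,
        p=float(stats.chi2.sf(chisq, df=1)),
        converged=converged,
        extras={"fmin": fmin, "n_multiplier": mult},
    )


def zlib_seed(arr: np.ndarray) -> int:
    """Deterministic small seed derived from an array's bytes (for restarts)."""
    import zlib

    return zlib.crc32(np.ascontiguousarray(arr).tobytes()) & 0x7FFFFFFF


def _psi_jacobians(theta: np.ndarray) -> np.ndarray:
    """2x5 Jacobian of the derived disturbance variances w.r.t. theta."""
    g11, g12, g21, b21, ph = theta
    c1 = g11 + g12 * ph
    c2 = g12 + g11 * ph
    J = np.zeros((2, 5))
    J[0] = -2.0 * np.array([c1, c2, 0.0, 0.0, g11 * g12])
    J[1] = -np.array(
        [
            2.0 * g21 * b21,
            2.0 * g21 * b21 * ph,
            2.0 * g21 + 2.0 * b21 * c1,
            2.0 * b21 + 2.0 * g21 * c1,
            2.0 * g21 * b21 * g12,
        ]
    )
    return J


def fit_wls(
    pooled: np.ndarray,
    acov: np.ndarray,
    *,
    theta0: np.ndarray | None = None,
) -> Stage2Result:
    """WLS (ADF) fit of the 5-parameter correlation structure to a pooled vector.

    Minimizes (r - rho(theta))' acov^-1 (r - rho(theta)); the weight matrix
    already carries the sample-size scale, so the minimum itself is the
    chi-square (df = 6 - 5 = 1). Free-parameter SEs come from
    (J' acov^-1 J)^-1; the derived disturbance variances are reported with
    delta-method SEs.
    """
    r = np.asarray(pooled, dtype=float)
    acov = np.asarray(acov, dtype=float)
    W = np.linalg.inv(acov)
    C = np.linalg.cholesky((W + W.T) / 2.0).T  # C'C = W

    def resid(theta):
        return C @ (r - implied_corr_vector(theta))

    def jac(theta):
        return -C @ implied_corr_jacobian(theta)

    x0 = theta0 if theta0 is not None else np.array([0.1, 0.1, 0.1, 0.1, 0.1])
    res = optimize.least_squares(
        resid,
        x0,
        jac=jac,
        bounds=([-3, -3, -3, -3, -0.999], [3, 3, 3, 3, 0.999]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
    )
    theta = res.x
    chisq = float(2.0 * res.cost)
    psi11, psi22 = derived_disturbances(theta)
    converged = bool(res.status > 0) and min(psi11, psi22) > 0.0

    J = implied_corr_jacobian(theta)
    ses = np.full(7, np.nan)
    try:
        cov_theta = np.linalg.inv(J.T @ W @ J)
        d = np.diag(cov_theta)
        if np.all(d > 0):
            ses[:5] = np.sqrt(d)
            Jpsi = _psi_jacobians(theta)
            ses[5:] = np.sqrt(np.einsum("ij,jk,ik->i", Jpsi, cov_theta, Jpsi))
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    estimates = dict(zip(WLS_PARAM_NAMES, np.concatenate([theta, [psi11, psi22]])))
    return Stage2Result(
        route="WLS",
        estimates=estimates,
        ses=dict(zip(WLS_PARAM_NAMES, ses)),
        chisq=chisq,
        df=1,
        p=float(stats.chi2.sf(chisq, df=1)),
        converged=converged,
        extras={"theta": theta, "cost": float(res.cost)},
    )
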