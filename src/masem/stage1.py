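"""Stage 1 of two-stage meta-analytic SEM: pooling and homogeneity testing.

Four synthesis methods are implemented.

Univariate methods (each correlation pooled on its own):

* UNIr — sample-size-weighted mean of raw correlations (Hunter–Schmidt).
* UNIz — (n-3)-weighted mean of Fisher-z values, back-transformed
  (Hedges–Olkin).

Both test homogeneity with the Bonferroni-adjusted at-least-one (BA1) rule:
an element-wise heterogeneity chi-square with k-1 df for each of the six
correlations, rejecting overall homogeneity when any element's p-value
falls below alpha/6.

Multivariate methods (the six correlations pooled jointly):

* MGLS — generalized least squares on the stacked correlation vectors with
  large-sample (Olkin–Siotani) weight matrices evaluated at a common
  plug-in correlation vector ("modified" GLS), with the Q_GLS residual
  chi-square on 6(k-1) df.
* TSSEM — multigroup normal maximum likelihood under the constraint that
  every study shares one correlation matrix (group-specific scale factors
  absorb variance differences), with the likelihood-ratio statistic
  against the saturated model on 6(k-1) df.

Both multivariate methods return the asymptotic covariance of the pooled
vector, which stage 2 uses as the WLS weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import PAIR_INDICES, corr_to_vec, vec_to_corr
from .simulate import StudySet

__all__ = [
    "Stage1Result",
    "pool_unir",
    "pool_uniz",
    "homogeneity_ba1",
    "olkin_siotani_acov",
    "pool_mgls",
    "pool_tssem",
]


@dataclass
class Stage1Result:
    """Pooled correlation vector plus the homogeneity test for one method."""

    method: str
    pooled: np.ndarray
    stat: float
    df: int
    p: float
    reject: bool
    acov: np.ndarray | None = None
    per_element_stat: np.ndarray | None = None
    per_element_p: np.ndarray | None = None
    converged: bool = True
    total_n: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def pooled_matrix(self) -> np.ndarray:
        return vec_to_corr(self.pooled)


def _study_arrays(studies: StudySet) -> tuple[np.ndarray, np.ndarray]:
    ns = np.asarray(studies.sizes, dtype=float)
    rs = np.stack([corr_to_vec(R) for R in studies.matrices])
    return ns, rs


def homogeneity_ba1(
    studies: StudySet, scale: str = "z", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Element-wise BA1 homogeneity test; returns (Q per element, p, reject).

    z-scale: Q_ij = sum_k (n_k - 3) (z_ijk - zbar_ij)^2
    r-scale: Q_ij = sum_k (n_k - 1) (r_ijk - rbar_ij)^2 / (1 - rbar_ij^2)^2

    Each Q has k-1 df; overall homogeneity is rejected when the smallest
    element-wise p-value is below alpha / 6.
    """
    ns, rs = _study_arrays(studies)
    k = len(ns)
    if k < 2:
        raise ValueError("homogeneity test undefined for fewer than 2 studies")
    if scale == "z":
        w = ns - 3.0
        zs = np.arctanh(rs)
        zbar = w @ zs / w.sum()
        q = (w[:, None] * (zs - zbar) ** 2).sum(axis=0)
    elif scale == "r":
        rbar = ns @ rs / ns.sum()
        q = ((ns[:, None] - 1.0) * (rs - rbar) ** 2).sum(axis=0) / (1.0 - rbar**2) ** 2
    else:
        raise ValueError("scale must be 'z' or 'r'")
    p = stats.chi2.sf(q, df=k - 1)
    reject = bool(p.min() < alpha / 6.0)
    return q, p, reject


def pool_unir(studies: StudySet, alpha: float = 0.05) -> Stage1Result:
    """Hunter–Schmidt pooling: element-wise n-weighted mean of raw correlations."""
    ns, rs = _study_arrays(studies)
    pooled = ns @ rs / ns.sum()
    q, p_elem, reject = homogeneity_ba1(studies, scale="r", alpha=alpha)
    return Stage1Result(
        method="UNIr",
        pooled=pooled,
        stat=float(q.max()),
        df=len(ns) - 1,
        p=float(p_elem.min()),
        reject=reject,
        per_element_stat=q,
        per_element_p=p_elem,
        total_n=studies.total_n,
    )


def pool_uniz(studies: StudySet, alpha: float = 0.05) -> Stage1Result:
    """Hedges–Olkin pooling: (n-3)-weighted mean in Fisher-z, back-transformed."""
    ns, rs = _study_arrays(studies)
    if np.any(np.abs(rs) >= 1.0):
        raise ValueError("Fisher z undefined for |r| = 1")
    w = ns - 3.0
    pooled = np.tanh(w @ np.arctanh(rs) / w.sum())
    q, p_elem, reject = homogeneity_ba1(studies, scale="z", alpha=alpha)
    return Stage1Result(
        method="UNIz",
        pooled=pooled,
        stat=float(q.max()),
        df=len(ns) - 1,
        p=float(p_elem.min()),
        reject=reject,
        per_element_stat=q,
        per_element_p=p_elem,
        total_n=studies.total_n,
    )


def olkin_siotani_acov(rho: np.ndarray, n: float) -> np.ndarray:
    """Large-sample covariance of the 6 sample correlations of one study of size n.

    Entry for element pairs (a,b) and (c,d):

        [ 1/2 r_ab r_cd (r_ac^2 + r_ad^2 + r_bc^2 + r_bd^2)
          + r_ac r_bd + r_ad r_bc
          - (r_ab r_ac r_ad + r_ab r_bc r_bd + r_cd r_ac r_bc + r_cd r_ad r_bd) ] / n

    whose diagonal reduces to (1 - r_ab^2)^2 / n.
    """
    R = vec_to_corr(rho)
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 0:
        raise ValueError("correlation vector does not form a positive-definite matrix")
    V = np.empty((6, 6))
    for i, (a, b) in enumerate(PAIR_INDICES):
        for j, (c, d) in enumerate(PAIR_INDICES):
            if j < i:
                continue
            V[i, j] = V[j, i] = (
                0.5 * R[a, b] * R[c, d] * (R[a, c] ** 2 + R[a, d] ** 2 + R[b, c] ** 2 + R[b, d] ** 2)
                + R[a, c] * R[b, d]
                + R[a, d] * R[b, c]
                - (
                    R[a, b] * (R[a, c] * R[a, d] + R[b, c] * R[b, d])
                    + R[c, d] * (R[a, c] * R[b, c] + R[a, d] * R[b, d])
                )
            )
    return V / float(n)


def pool_mgls(
    studies: StudySet, alpha: float = 0.05, *, common_weights: bool = True
) -> Stage1Result:
    """GLS pooling of stacked correlation vectors with Olkin–Siotani weights.

    With ``common_weights`` (the modified GLS) every study's weight matrix is
    the large-sample covariance evaluated at the UNIr-pooled plug-in vector,
    scaled by its own sample size; otherwise each study uses its own
    correlations (traditional GLS). Q_GLS is the GLS residual chi-square on
    6(k-1) df.
    """
    ns, rs = _study_arrays(studies)
    k = len(ns)
    if k < 2:
        raise ValueError("need at least 2 studies")
    if common_weights:
        rtilde = ns @ rs / ns.sum()
        Vinv = np.linalg.inv(olkin_siotani_acov(rtilde, 1.0))
        weights = [ns[i] * Vinv for i in range(k)]
    else:
        weights = []
        for i in range(k):
            try:
                weights.append(np.linalg.inv(olkin_siotani_acov(rs[i], ns[i])))
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(f"singular weight matrix for study {i}") from None
    wsum = np.sum(weights, axis=0)
    acov = np.linalg.inv(wsum)
    pooled = acov @ np.sum([W @ r for W, r in zip(weights, rs)], axis=0)
    resid = rs - pooled
    q = float(sum(resid[i] @ weights[i] @ resid[i] for i in range(k)))
    df = 6 * (k - 1)
    p = float(stats.chi2.sf(q, df=df))
    return Stage1Result(
        method="MGLS",
        pooled=pooled,
        stat=q,
        df=df,
        p=p,
        reject=bool(p < alpha),
        acov=acov,
        total_n=studies.total_n,
    )


# ---------------------------------------------------------------------------
# TSSEM stage 1: multigroup ML with a common correlation matrix
# ---------------------------------------------------------------------------


def _tssem_unpack(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Split the parameter vector into (rho 6-vector, k x 4 scale factors)."""
    return x[:6], np.exp(x[6:].reshape(k, 4))


def _tssem_fmin_and_grad(
    x: np.ndarray, S: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted ML discrepancy F = sum_g w_g [ln|Sig_g| - ln|S_g| + tr(S_g Sig_g^-1) - 4]
    for Sig_g = D_g R D_g, with its analytic gradient.

    S : (k, 4, 4) stack of sample matrices (log-dets precomputed by caller as
        part of the constant; here only the x-dependent part is returned, so
        the caller adds the -ln|S_g| - 4 constant).
    """
    k = S.shape[0]
    rho, D = _tssem_unpack(x, k)
    R = vec_to_corr(rho)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return 1e10 + 1e6 * float(rho @ rho), np.zeros_like(x)
    logdetR = 2.0 * np.log(np.diag(L)).sum()
    Rinv = np.linalg.inv(R)

    # Sig_g^-1 = (1/d 1/d') * Rinv ; ln|Sig_g| = logdetR + 2 sum log d_g
    Dinv = 1.0 / D
    Siginv = Dinv[:, :, None] * Dinv[:, None, :] * Rinv[None, :, :]
    logdet = logdetR + 2.0 * np.log(D).sum(axis=1)
    tr = np.einsum("gij,gji->g", S, Siginv)
    f = float(w @ (logdet + tr))

    # G_g = w_g (Siginv - Siginv S_g Siginv) = dF/dSig_g
    G = w[:, None, None] * (Siginv - np.einsum("gij,gjk,gkl->gil", Siginv, S, Siginv))
    Sig = D[:, :, None] * D[:, None, :] * R[None, :, :]
    # d/d rho_m : sum_g 2 * (D_g G_g D_g)[pair m]
    DGD = D[:, :, None] * D[:, None, :] * G
    DGDsum = DGD.sum(axis=0)
    rows = [p[0] for p in PAIR_INDICES]
    cols = [p[1] for p in PAIR_INDICES]
    grad_rho = 2.0 * DGDsum[rows, cols]
    # d/d log d_gi : 2 (G_g Sig_g)_ii
    grad_logd = 2.0 * np.einsum("gij,gji->gi", G, Sig)
    return f, np.concatenate([grad_rho, grad_logd.ravel()])


def pool_tssem(
    studies: StudySet,
    alpha: float = 0.05,
    *,
    compute_acov: bool = True,
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> Stage1Result:
    """Pool by multigroup ML with one common correlation matrix across studies.

    Minimizes the sample-size-weighted ML discrepancy over the 6 common
    correlations and k*4 group scale factors (optimized on the log scale,
    started at the UNIr pooled vector and unit scales). The homogeneity
    statistic is the likelihood-ratio chi-square against the saturated
    model, N * F_min, on 6(k-1) df. The asymptotic covariance of the pooled
    vector is the correlation block of the inverse observed information.
    """
    ns, rs = _study_arrays(studies)
    k = len(ns)
    if k < 2:
        raise ValueError("need at least 2 studies")
    S = np.stack(studies.matrices)
    sign, logdetS = np.linalg.slogdet(S)
    if np.any(sign <= 0):
        raise ValueError("every study correlation matrix must be positive definite")
    N = float(ns.sum())
    w = ns / N
    const = float(w @ logdetS) + 4.0

    x0 = np.concatenate([ns @ rs / N, np.zeros(4 * k)])
    fun = lambda x: _tssem_fmin_and_grad(x, S, w)
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol},
    )
    fmin = res.fun - const
    rho_hat = res.x[:6]
    converged = bool(res.success) and fmin > -1e-6
    stat = float(max(N * fmin, 0.0))
    df = 6 * (k - 1)
    p = float(stats.chi2.sf(stat, df=df))

    acov = None
    if compute_acov:
        # observed information of the log-likelihood is (N/2) * hessian of F;
        # central finite differences of the analytic gradient.
        m = res.x.size
        H = np.empty((m, m))
        h = 1e-5
        for j in range(m):
            xp = res.x.copy()
            xp[j] += h
            _, gp = fun(xp)
            xp[j] -= 2 * h
            _, gm = fun(xp)
            H[:, j] = (gp - gm) / (2 * h)
        H = (H + H.T) / 2.0
        try:
            info_inv = np.linalg.inv((N / 2.0) * H)
            acov = info_inv[:6, :6]
            acov = (acov + acov.T) / 2.0
            if np.any(np.linalg.eigvalsh(acov) <= 0):
                acov = None
                converged = False
        except np.linalg.LinAlgError:
            converged = False

    return Stage1Result(
        method="TSSEM",
        pooled=rho_hat,
        stat=stat,
        df=df,
        p=p,
        reject=bool(p < alpha),
        acov=acov,
        converged=converged,
        total_n=studies.total_n,
        extras={"fmin": float(fmin), "n_iter": int(res.nit)},
    )
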