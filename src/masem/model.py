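"""Recursive four-variable path model and its implied correlation structure.

The model has two exogenous variables (X1, X2), a mediator (Y1) and an
outcome (Y2):

    Y = Gamma X + B Y + zeta,   Cov(X) = Phi,   Cov(zeta) = Psi (diagonal)

with Gamma the 2x2 matrix of X->Y effects (gamma22 structurally zero),
B strictly lower triangular (only beta21, the Y1->Y2 path, may be nonzero),
so the model is recursive and over-identified with one degree of freedom.

Variables are ordered (Y1, Y2, X1, X2) throughout, and the six distinct
correlations of a 4x4 matrix are vectorized in the fixed order

    (rho21, rho31, rho41, rho32, rho42, rho43)

i.e. column-major over the strict lower triangle by (row, col) pairs
(2,1),(3,1),(4,1),(3,2),(4,2),(4,3) in 1-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PathParams",
    "VAR_NAMES",
    "PAIR_INDICES",
    "TRUE_PARAMS",
    "TRUE_THETA",
    "SIGMA",
    "SIGMA_PRIME",
    "corr_to_vec",
    "vec_to_corr",
    "implied_covariance",
    "implied_corr_vector",
    "sigma_prime",
]

VAR_NAMES = ("Y1", "Y2", "X1", "X2")

#: (row, col) 0-based index pairs defining the correlation-vector order
#: (rho21, rho31, rho41, rho32, rho42, rho43).
PAIR_INDICES = ((1, 0), (2, 0), (3, 0), (2, 1), (3, 1), (3, 2))

_ROWS = np.array([p[0] for p in PAIR_INDICES])
_COLS = np.array([p[1] for p in PAIR_INDICES])


@dataclass(frozen=True)
class PathParams:
    """Structural parameters (Gamma, B, Phi, Psi) of the path model.

    gamma : 2x2 effects of X on Y; element (2,2) is structurally zero.
    beta  : 2x2 effects among Y; strictly lower triangular.
    phi   : 2x2 symmetric positive-definite covariance of X.
    psi   : 2x2 diagonal nonnegative disturbance covariance.
    """

    gamma: np.ndarray
    beta: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gamma", "beta", "phi", "psi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if any(getattr(self, n).shape != (2, 2) for n in ("gamma", "beta", "phi", "psi")):
            raise ValueError("all parameter matrices must be 2x2")
        if not np.allclose(np.triu(self.beta), 0.0):
            raise ValueError("beta must be strictly lower triangular (recursive model)")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError("phi must be symmetric")
        if not np.allclose(self.psi, np.diag(np.diag(self.psi))) or np.any(np.diag(self.psi) < 0):
            raise ValueError("psi must be diagonal with nonnegative entries")


def corr_to_vec(R: np.ndarray) -> np.ndarray:
    """Extract the 6 distinct correlations in the fixed vectorization order."""
    R = np.asarray(R, dtype=float)
    return R[_ROWS, _COLS].copy()


def vec_to_corr(vec: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal 4x4 matrix from its 6-vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (6,):
        raise ValueError("correlation vector must have length 6")
    R = np.eye(4)
    R[_ROWS, _COLS] = vec
    R[_COLS, _ROWS] = vec
    return R


def implied_covariance(params: PathParams) -> np.ndarray:
    """Model-implied covariance matrix in variable order (Y1, Y2, X1, X2).

    Uses the block formula for a recursive model with A = (I - B)^-1:

        [[ A (Gamma Phi Gamma' + Psi) A',  A Gamma Phi ],
         [ Phi Gamma' A',                  Phi         ]]

    Raises ValueError if I - B is singular (non-recursive specification).
    """
    I = np.eye(2)
    imb = I - params.beta
    if abs(np.linalg.det(imb)) < 1e-12:
        raise ValueError("I - B is singular: non-recursive model specification")
    A = np.linalg.inv(imb)
    top = A @ (params.gamma @ params.phi @ params.gamma.T + params.psi) @ A.T
    cross = A @ params.gamma @ params.phi
    sigma = np.empty((4, 4))
    sigma[:2, :2] = top
    sigma[:2, 2:] = cross
    sigma[2:, :2] = cross.T
    sigma[2:, 2:] = params.phi
    return (sigma + sigma.T) / 2.0


def derived_disturbances(theta: np.ndarray) -> tuple[float, float]:
    """Disturbance variances (psi11, psi22) making all implied variances 1.

    theta = (gamma11, gamma12, gamma21, beta21, phi12) with phi11 = phi22 = 1.
    Solved recursively: Var(Y1) = 1 fixes psi11, then Var(Y2) = 1 fixes psi22
    using Cov(X1, Y1) = gamma11 + gamma12 * phi12.
    """
    g11, g12, g21, b21, ph = np.asarray(theta, dtype=float)
    psi11 = 1.0 - (g11 * g11 + g12 * g12 + 2.0 * g11 * g12 * ph)
    c1 = g11 + g12 * ph  # Cov(X1, Y1) when Var(Y1)=1
    psi22 = 1.0 - (g21 * g21 + b21 * b21 + 2.0 * g21 * b21 * c1)
    return float(psi11), float(psi22)


def params_from_theta(theta: np.ndarray) -> PathParams:
    """PathParams for the standardized model (unit variances) at free vector theta."""
    g11, g12, g21, b21, ph = np.asarray(theta, dtype=float)
    psi11, psi22 = derived_disturbances(theta)
    if psi11 <= 0.0 or psi22 <= 0.0:
        raise ValueError(
            f"inadmissible theta: derived disturbance variances ({psi11:.4g}, {psi22:.4g}) "
            "must be positive"
        )
    return PathParams(
        gamma=np.array([[g11, g12], [g21, 0.0]]),
        beta=np.array([[0.0, 0.0], [b21, 0.0]]),
        phi=np.array([[1.0, ph], [ph, 1.0]]),
        psi=np.diag([psi11, psi22]),
    )


def implied_corr_vector(theta: np.ndarray) -> np.ndarray:
    """The 6 correlations implied by the standardized model at free vector theta.

    Closed form (with c1 = g11 + g12*ph, c2 = g12 + g11*ph):

        rho21 = b21 + g21*c1        rho31 = c1        rho41 = c2
        rho32 = g21 + b21*c1        rho42 = g21*ph + b21*c2
        rho43 = ph
    """
    g11, g12, g21, b21, ph = np.asarray(theta, dtype=float)
    c1 = g11 + g12 * ph
    c2 = g12 + g11 * ph
    return np.array(
        [
            b21 + g21 * c1,
            c1,
            c2,
            g21 + b21 * c1,
            g21 * ph + b21 * c2,
            ph,
        ]
    )


def implied_corr_jacobian(theta: np.ndarray) -> np.ndarray:
    """6x5 Jacobian of implied_corr_vector with respect to theta."""
    g11, g12, g21, b21, ph = np.asarray(theta, dtype=float)
    c1 = g11 + g12 * ph
    c2 = g12 + g11 * ph
    return np.array(
        [
            [g21, g21 * ph, c1, 1.0, g21 * g12],
            [1.0, ph, 0.0, 0.0, g12],
            [ph, 1.0, 0.0, 0.0, g11],
            [b21, b21 * ph, 1.0, c1, b21 * g12],
            [b21 * ph, b21, ph, c2, g21 + b21 * g11],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )


#: Population parameter values generating the homogeneous-population matrix.
TRUE_PARAMS = PathParams(
    gamma=np.array([[0.4, 0.5], [0.3, 0.0]]),
    beta=np.array([[0.0, 0.0], [0.5, 0.0]]),
    phi=np.array([[1.0, 0.2], [0.2, 1.0]]),
    psi=np.diag([0.51, 0.51]),
)

#: Free-parameter vector (gamma11, gamma12, gamma21, beta21, phi12) of TRUE_PARAMS.
TRUE_THETA = np.array([0.4, 0.5, 0.3, 0.5, 0.2])

#: Common population correlation matrix (homogeneous studies).
SIGMA = vec_to_corr([0.65, 0.50, 0.58, 0.55, 0.35, 0.20])

#: Second fixed population correlation matrix used for heterogeneous studies.
SIGMA_PRIME = vec_to_corr([0.45, 0.30, 0.40, 0.35, 0.19, 0.15])


def sigma_prime() -> np.ndarray:
    """The second fixed population correlation matrix (a copy)."""
    return SIGMA_PRIME.copy()
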