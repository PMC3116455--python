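"""Semantic smoothing and kernel construction.

Count vectors are smoothed as ``(X + eps) S`` where ``S`` is a semantic
matrix (HAL: N x N, BEAGLE: N x D) and ``eps`` is added to every entry
so the semantic structure reaches features absent from a sentence.
Smoothed rows feed cosine, Gaussian or polynomial Gram matrices that can
be fused by convex combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

KERNEL_KINDS = ("cosine", "gaussian", "polynomial")

PSD_TOL = 1e-8
INVALID_TOL = 1e-6
SIMPLEX_TOL = 1e-10


class KernelError(ValueError):
    pass


class InvalidKernelError(KernelError):
    pass


@dataclass
class SmoothedData:
    """Rows of ``(X + eps) S``; with S = I and eps = 0 this is X itself."""

    XS: np.ndarray
    epsilon: float


@dataclass
class KernelMatrix:
    K: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.K.shape


@dataclass
class CompositeKernel:
    members: list[KernelMatrix]
    beta: np.ndarray

    @property
    def K(self) -> np.ndarray:
        return combined_matrix([m.K for m in self.members], self.beta)


def smooth(X, S=None, epsilon: float = 0.01) -> SmoothedData:
    """Compute ``(X + eps * J) S``.  ``S=None`` means the identity."""
    if epsilon < 0:
        raise KernelError(f"epsilon must be >= 0, got {epsilon}")
    Xd = np.asarray(X.X if hasattr(X, "X") else X, dtype=np.float64)
    Xe = Xd + epsilon
    if S is None:
        return SmoothedData(XS=Xe, epsilon=epsilon)
    if sp.issparse(S):
        if Xe.shape[1] != S.shape[0]:
            raise KernelError(
                f"X has {Xe.shape[1]} columns but S has {S.shape[0]} rows"
            )
        XS = np.asarray((S.T @ Xe.T).T)
    else:
        S = np.asarray(S, dtype=np.float64)
        if Xe.shape[1] != S.shape[0]:
            raise KernelError(
                f"X has {Xe.shape[1]} columns but S has {S.shape[0]} rows"
            )
        XS = Xe @ S
    return SmoothedData(XS=XS, epsilon=epsilon)


def _rows(A) -> np.ndarray:
    if isinstance(A, SmoothedData):
        return A.XS
    return np.asarray(A, dtype=np.float64)


def kernel_cosine(A, Bq=None) -> KernelMatrix:
    """kappa(a, b) = a.b / (|a||b|), with 0 wherever either row is zero."""
    A = _rows(A)
    B = A if Bq is None else _rows(Bq)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(denom > 0, (A @ B.T) / np.where(denom > 0, denom, 1.0), 0.0)
    return KernelMatrix(K=K, kind="cosine")


def kernel_gaussian(A, Bq=None, theta: float = 0.1) -> KernelMatrix:
    """kappa(a, b) = exp(-theta * |a - b|^2)."""
    if theta <= 0:
        raise KernelError(f"theta must be > 0, got {theta}")
    A = _rows(A)
    B = A if Bq is None else _rows(Bq)
    sq = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return KernelMatrix(K=np.exp(-theta * sq), kind="gaussian", params={"theta": theta})


def kernel_poly(A, Bq=None, degree: int = 2) -> KernelMatrix:
    """kappa(a, b) = (a.b + 1)^degree."""
    if degree < 1:
        raise KernelError(f"degree must be >= 1, got {degree}")
    A = _rows(A)
    B = A if Bq is None else _rows(Bq)
    return KernelMatrix(
        K=(A @ B.T + 1.0) ** degree, kind="polynomial", params={"degree": degree}
    )


def make_kernel(kind: str, A, Bq=None, **params) -> KernelMatrix:
    if kind == "cosine":
        return kernel_cosine(A, Bq)
    if kind == "gaussian":
        return kernel_gaussian(A, Bq, theta=params.get("theta", 0.1))
    if kind == "polynomial":
        return kernel_poly(A, Bq, degree=params.get("degree", 2))
    raise KernelError(f"unknown kernel kind {kind!r}")


def check_simplex(beta, n: int | None = None) -> np.ndarray:
    beta = np.asarray(beta, dtype=np.float64)
    if n is not None and len(beta) != n:
        raise KernelError(f"expected {n} weights, got {len(beta)}")
    if np.any(beta < -SIMPLEX_TOL) or abs(beta.sum() - 1.0) > SIMPLEX_TOL:
        raise KernelError(f"weights {beta} are not on the probability simplex")
    return np.clip(beta, 0.0, None)


def combined_matrix(matrices: list[np.ndarray], beta) -> np.ndarray:
    beta = check_simplex(beta, len(matrices))
    shape = matrices[0].shape
    for K in matrices[1:]:
        if K.shape != shape:
            raise KernelError("member kernels differ in shape")
    out = np.zeros(shape)
    for b, K in zip(beta, matrices):
        out += b * K
    return out


def combine_kernels(members: list[KernelMatrix], beta) -> CompositeKernel:
    """Convex combination sum_s beta_s K_s (beta on the simplex)."""
    if not members:
        raise KernelError("no member kernels")
    beta = check_simplex(beta, len(members))
    # validate shapes eagerly
    combined_matrix([m.K for m in members], beta)
    return CompositeKernel(members=list(members), beta=beta)


@dataclass
class KernelDiagnostics:
    asymmetry: float
    min_eigenvalue: float
    jitter_added: float
    K: np.ndarray


def validate_kernel(K: np.ndarray) -> KernelDiagnostics:
    """Symmetrise, report the spectrum floor, and jitter tiny negatives.

    Raises ``InvalidKernelError`` when the minimum eigenvalue is below
    -1e-6 — that is a broken Gram matrix, not numerical noise.
    """
    K = np.asarray(K, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise KernelError("kernel must be a square matrix")
    asym = float(np.max(np.abs(K - K.T))) if K.size else 0.0
    Ks = 0.5 * (K + K.T)
    min_eig = float(np.linalg.eigvalsh(Ks)[0]) if K.size else 0.0
    if min_eig < -INVALID_TOL:
        raise InvalidKernelError(f"minimum eigenvalue {min_eig:.3e} < -{INVALID_TOL}")
    jitter = 0.0
    if -PSD_TOL < min_eig < 0:
        jitter = PSD_TOL
        Ks = Ks + jitter * np.eye(K.shape[0])
    elif min_eig <= -PSD_TOL:
        # between -1e-6 and -1e-8: lift the spectrum just above zero
        jitter = -min_eig + PSD_TOL
        Ks = Ks + jitter * np.eye(K.shape[0])
    return KernelDiagnostics(
        asymmetry=asym, min_eigenvalue=min_eig, jitter_added=jitter, K=Ks
    )
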