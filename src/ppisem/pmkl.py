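"""Probabilistic multiple kernel learning.

A multinomial-probit generalised linear model over a convex combination
of Gram matrices, fitted by variational Bayes with truncated-Gaussian
auxiliary variables.  Per-class weight vectors over the training points
carry a unit-scale Gaussian prior; the kernel combination weights live
on the probability simplex with a (near-flat) Dirichlet prior and are
either held fixed or estimated by maximising the variational bound.

All truncated-Gaussian expectations are evaluated by Gauss-Hermite
quadrature in log space (log-scale Mills ratios), which is stable far
into the tails where naive pdf/cdf ratios overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp

from .kernels import (
    CompositeKernel,
    InvalidKernelError,
    KernelError,
    KernelMatrix,
    check_simplex,
)

_QUAD_POINTS = 80
_EIG_FLOOR = -1e-6  # spectrum below this is a broken kernel, not jitter
_DIRICHLET_ALPHA = 1.01  # near-flat prior; breaks exact ties toward uniform

_LOG_2PI = np.log(2.0 * np.pi)


class PMKLError(ValueError):
    pass


class DegenerateLabelsError(PMKLError):
    pass


def _quad_nodes() -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(_QUAD_POINTS)
    u = np.sqrt(2.0) * x
    logw = np.log(w) - 0.5 * np.log(np.pi)
    return u, logw


_U_NODES, _LOGW = _quad_nodes()


def _as_matrices(kernels) -> list[np.ndarray]:
    if isinstance(kernels, (KernelMatrix, np.ndarray)):
        kernels = [kernels]
    if isinstance(kernels, CompositeKernel):
        kernels = kernels.members
    out = []
    for K in kernels:
        A = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=np.float64)
        out.append(np.asarray(A, dtype=np.float64))
    if not out:
        raise PMKLError("no kernels supplied")
    return out


@dataclass
class Prediction:
    """Posterior predictive class probabilities; rows sum to one."""

    probabilities: np.ndarray
    classes: np.ndarray

    @property
    def scores(self) -> np.ndarray:
        """Probability column for the positive class (label 1 when present,
        otherwise the last class)."""
        cls = list(self.classes)
        col = cls.index(1) if 1 in cls else len(cls) - 1
        return self.probabilities[:, col]

    @property
    def hard_labels(self) -> np.ndarray:
        return self.classes[np.argmax(self.probabilities, axis=1)]


@dataclass
class PMKLModel:
    beta: np.ndarray
    mu: np.ndarray  # M x C posterior weight means
    classes: np.ndarray
    mode: str
    convergence_trace: list[float]
    seed: int
    n_kernels: int
    # posterior covariance summary: shared across classes
    _sigma_U: np.ndarray | None = field(default=None, repr=False)
    _sigma_d: np.ndarray | None = field(default=None, repr=False)  # eigvals of I+K^2
    _sigma: np.ndarray | None = field(default=None, repr=False)

    @property
    def weight_posterior(self) -> dict:
        """Mean and covariance-trace summary of the weight posterior."""
        if self._sigma_d is not None:
            tr = float(np.sum(1.0 / self._sigma_d))
        else:
            tr = float(np.trace(self._sigma))
        return {"mean": self.mu, "covariance_trace": tr}

    def sigma_quad(self, A: np.ndarray) -> np.ndarray:
        """diag(A Sigma A^T) for a rows-by-train matrix A."""
        if self._sigma_d is not None:
            AU = A @ self._sigma_U
            return np.einsum("ij,ij->i", AU / self._sigma_d, AU)
        return np.einsum("ij,ij->i", A @ self._sigma, A)


# ---------------------------------------------------------------------------
# truncated-Gaussian machinery
# ---------------------------------------------------------------------------


def _cone_log_terms(m: np.ndarray, t: np.ndarray):
    """Per-sample log normaliser and log-cdf grid for the probit cone.

    ``a[q, n, j] = u_q + m[n, t_n] - m[n, j]``; ``Stot[q, n]`` is the sum
    of log Phi(a) over j != t_n and ``logZ[n]`` its quadrature average —
    the probability that class t_n wins under independent unit-variance
    Gaussians centred at m[n].
    """
    M, C = m.shape
    m_t = m[np.arange(M), t]  # (M,)
    a = _U_NODES[:, None, None] + (m_t[None, :, None] - m[None, :, :])  # (Q,M,C)
    logphi_a = log_ndtr(a)
    # subtract the j = t_n column (a there equals u, same for every n)
    log_phi_u = log_ndtr(_U_NODES)  # (Q,)
    Stot = logphi_a.sum(axis=2) - log_phi_u[:, None]  # (Q,M)
    logZ = logsumexp(Stot + _LOGW[:, None], axis=0)  # (M,)
    return a, logphi_a, Stot, logZ


def _update_auxiliary(m: np.ndarray, t: np.ndarray):
    """Posterior means of the cone-truncated auxiliary variables."""
    M, C = m.shape
    a, logphi_a, Stot, logZ = _cone_log_terms(m, t)
    log_npdf_a = -0.5 * a**2 - 0.5 * _LOG_2PI
    # log E_u[ pdf(a_k) * prod_{j != i,k} Phi(a_j) ] for every k
    inner = log_npdf_a + Stot[:, :, None] - logphi_a
    lognum = logsumexp(inner + _LOGW[:, None, None], axis=0)  # (M,C)
    delta = np.exp(lognum - logZ[:, None])  # m_k - ytilde_k for k != i
    ytilde = m - delta
    rows = np.arange(M)
    ytilde[rows, t] = m[rows, t] + (delta.sum(axis=1) - delta[rows, t])
    return ytilde, logZ


def _class_probabilities(m: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """P(argmax_j y_j = c) with y_j ~ N(m_j, scale^2) i.i.d. per row."""
    M, C = m.shape
    ms = m / scale[:, None]
    probs = np.empty((M, C))
    for c in range(C):
        t = np.full(M, c)
        _, _, _, logZ = _cone_log_terms(ms, t)
        probs[:, c] = np.exp(logZ)
    probs = np.clip(probs, 1e-300, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _spectral_posterior(K: np.ndarray):
    """Eigendecompose K; return pieces of Sigma = (I + K^2)^-1."""
    lam, U = np.linalg.eigh(0.5 * (K + K.T))
    if lam[0] < _EIG_FLOOR:
        raise InvalidKernelError(
            f"combined kernel has eigenvalue {lam[0]:.3e} < {_EIG_FLOOR}"
        )
    lam = np.clip(lam, 0.0, None)
    d = 1.0 + lam**2
    return U, lam, d


def _maximise_beta(
    beta: np.ndarray,
    Ks: list[np.ndarray],
    ytilde: np.ndarray,
    alpha: float = _DIRICHLET_ALPHA,
    multistart: bool = False,
) -> np.ndarray:
    """Simplex-constrained bound-ascent step for the combination weights.

    The weight posterior is optimised out analytically, so the objective
    is the marginal evidence of the linear-Gaussian submodel with the
    auxiliary targets ``ytilde`` held fixed:

        -1/2 [ sum_c y_c' (I + K(b)^2)^-1 y_c + C logdet(I + K(b)^2) ]
        + (alpha - 1) sum_s log b_s

    Ascending it jointly with the subsequent q(W) refresh keeps the
    overall variational bound non-decreasing.
    """
    S = len(beta)
    if S == 1:
        return np.array([1.0])
    M, C = ytilde.shape
    I = np.eye(M)
    cache: dict[bytes, tuple[float, np.ndarray]] = {}

    def _eval(x):
        K = sum(b * Kmat for b, Kmat in zip(x, Ks))
        K = 0.5 * (K + K.T)
        Minv = np.linalg.inv(I + K @ K)
        sign, logdet_Minv = np.linalg.slogdet(Minv)
        V = Minv @ ytilde  # (M, C)
        val = float(np.sum(ytilde * V)) - C * float(logdet_Minv)
        val -= 2.0 * (alpha - 1.0) * float(np.sum(np.log(x)))
        KMinv = K @ Minv
        grad = np.empty(S)
        for s, Kmat in enumerate(Ks):
            # d/db_s of y'M^-1 y with dM/db_s = K_s K + K K_s
            AsV = Kmat @ (K @ V) + K @ (Kmat @ V)
            grad[s] = -float(np.sum(V * AsV))
            grad[s] += 2.0 * C * float(np.sum(KMinv * Kmat))
            grad[s] -= 2.0 * (alpha - 1.0) / x[s]
        return val, grad

    def neg_and_grad(x):
        key = np.asarray(x).tobytes()
        if key not in cache:
            cache[key] = _eval(np.asarray(x, dtype=np.float64))
        return cache[key]

    x0 = np.clip(beta, 1e-6, None)
    x0 = x0 / x0.sum()
    # the objective is non-convex with near-corner optima; on the first
    # update also try every corner as a starting point
    starts = [x0]
    if multistart:
        for s in range(S):
            corner = np.full(S, 0.05 / (S - 1))
            corner[s] = 0.95
            starts.append(corner)
    best_x, best_val = x0, neg_and_grad(x0)[0]
    for start in starts:
        res = minimize(
            lambda x: neg_and_grad(x)[0],
            start,
            jac=lambda x: neg_and_grad(x)[1],
            method="SLSQP",
            bounds=[(1e-9, 1.0)] * S,
            constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
            options={"maxiter": 40, "ftol": 1e-9},
        )
        cand = np.clip(res.x, 1e-12, None)
        cand /= cand.sum()
        val = neg_and_grad(cand)[0]
        if val < best_val:  # safeguard: never step downhill overall
            best_x, best_val = cand, val
    return best_x


def fit(
    train_kernels,
    labels,
    mode: str = "fixed",
    fixed_beta=None,
    max_iter: int = 60,
    tol: float = 1e-6,
    seed: int = 0,
) -> PMKLModel:
    """Variational-Bayes fit of the multinomial-probit MKL model.

    ``mode='fixed'`` keeps the combination weights at ``fixed_beta``
    (uniform by default); ``mode='infer'`` re-estimates them each sweep
    by maximising the variational bound over the simplex.  The recorded
    ``convergence_trace`` is non-decreasing up to numerical slack.
    """
    Ks = _as_matrices(train_kernels)
    S = len(Ks)
    M = Ks[0].shape[0]
    for K in Ks:
        if K.shape != (M, M):
            raise PMKLError("training kernels must share an M x M shape")
    y = np.asarray(labels)
    if y.shape != (M,):
        raise PMKLError(f"labels must have length {M}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelsError("need at least two classes in the labels")
    C = len(classes)
    t = np.searchsorted(classes, y)

    if mode not in ("fixed", "infer"):
        raise PMKLError(f"mode must be 'fixed' or 'infer', got {mode!r}")
    if fixed_beta is None:
        beta = np.full(S, 1.0 / S)
    else:
        beta = check_simplex(fixed_beta, S)

    spectral = mode == "fixed"  # K constant -> one eigendecomposition
    K = sum(b * Kmat for b, Kmat in zip(beta, Ks))
    U = lam = d = sigma = None
    if spectral:
        U, lam, d = _spectral_posterior(K)
        tr_sigma = float(np.sum(1.0 / d))
        logdet_sigma = float(-np.sum(np.log(d)))
        tr_KSK = float(np.sum(lam**2 / d))
    else:
        for Kmat in Ks:
            ev = np.linalg.eigvalsh(0.5 * (Kmat + Kmat.T))[0]
            if ev < _EIG_FLOOR:
                raise InvalidKernelError(
                    f"member kernel has eigenvalue {ev:.3e} < {_EIG_FLOOR}"
                )

    mu = np.zeros((M, C))
    m = np.zeros((M, C))
    trace: list[float] = []
    bound_prev = -np.inf
    I = np.eye(M)
    beta_burnin = 3  # let the auxiliary targets mature before moving beta

    for it in range(max_iter):
        # --- q(Y): truncated-Gaussian auxiliary update (exact coordinate step)
        ytilde, logZ = _update_auxiliary(m, t)
        m_old = m

        # --- beta: ascend the bound jointly with the implied optimal q(W)
        if mode == "infer" and S > 1 and it >= beta_burnin:
            beta = _maximise_beta(beta, Ks, ytilde, multistart=it == beta_burnin)
            K = sum(b * Kmat for b, Kmat in zip(beta, Ks))

        # --- q(W): Gaussian posterior over per-class weights
        if spectral:
            proj = U.T @ ytilde  # (M, C)
            mu = U @ (proj * (lam / d)[:, None])
            m = U @ (proj * (lam**2 / d)[:, None])
        else:
            Ksym = 0.5 * (K + K.T)
            sigma = np.linalg.inv(I + Ksym @ Ksym)
            mu = sigma @ (Ksym @ ytilde)
            m = Ksym @ mu
            tr_sigma = float(np.trace(sigma))
            sign, logdet_sigma = np.linalg.slogdet(sigma)
            logdet_sigma = float(logdet_sigma)
            tr_KSK = float(np.einsum("ij,jk,ki->", Ksym, sigma, Ksym))

        # --- variational bound of the current (q(Y), q(W), beta)
        quad = float(np.sum((ytilde - m) ** 2) - np.sum((ytilde - m_old) ** 2))
        kl = 0.5 * (
            C * tr_sigma + float(np.sum(mu**2)) - C * M - C * logdet_sigma
        )
        bound = float(np.sum(logZ)) - 0.5 * (C * tr_KSK + quad) - kl
        if mode == "infer":
            bound += (_DIRICHLET_ALPHA - 1.0) * float(np.sum(np.log(np.clip(beta, 1e-12, None))))
        trace.append(bound)
        if abs(bound - bound_prev) < tol * (1.0 + abs(bound)):
            break
        bound_prev = bound

    return PMKLModel(
        beta=beta,
        mu=mu,
        classes=classes,
        mode=mode,
        convergence_trace=trace,
        seed=seed,
        n_kernels=S,
        _sigma_U=U if spectral else None,
        _sigma_d=d if spectral else None,
        _sigma=None if spectral else sigma,
    )


def predict(model: PMKLModel, test_kernels) -> Prediction:
    """Posterior predictive class probabilities from cross-kernels
    (rows: test points, columns: training points)."""
    Ks = _as_matrices(test_kernels)
    if len(Ks) != model.n_kernels:
        raise PMKLError(
            f"model was trained on {model.n_kernels} kernels, got {len(Ks)}"
        )
    M_train = model.mu.shape[0]
    shape = Ks[0].shape
    for K in Ks:
        if K.shape != shape or K.shape[1] != M_train:
            raise PMKLError(
                f"cross-kernels must share shape (n_test, {M_train})"
            )
    Kstar = sum(b * K for b, K in zip(model.beta, Ks))
    m_star = Kstar @ model.mu
    var = 1.0 + model.sigma_quad(Kstar)
    probs = _class_probabilities(m_star, np.sqrt(var))
    return Prediction(probabilities=probs, classes=model.classes)


def inferred_weights(model: PMKLModel) -> dict:
    """Kernel weights with a ranking report (infer-mode models only)."""
    if model.mode != "infer":
        raise PMKLError("kernel weights were fixed, not inferred")
    order = np.argsort(model.beta)[::-1]
    return {
        "beta": model.beta,
        "ranking": [int(i) for i in order],
        "top_kernel": int(order[0]),
    }
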