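"""Word co-occurrence models built from unlabelled text.

Two models produce smoothing matrices over a fixed target vocabulary:

* HAL — a sliding window of length ``L`` passes over each sentence; the
  last word in the window is the target and each preceding in-window
  word at distance ``l`` contributes score ``L - l + 1``.  The directed
  matrix plus its transpose gives the symmetric similarity matrix.
* BEAGLE — every basis word gets a random Gaussian "environmental"
  vector of dimension ``D``; a target word's row accumulates, over all
  sentences containing it, the sum of the environmental vectors of the
  co-occurring words.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .corpus import Vocabulary


class SemanticModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# HAL
# ---------------------------------------------------------------------------


@dataclass
class HALMatrix:
    """Directed windowed co-occurrence counts over the target vocabulary.

    ``H_o[t, b]`` holds the summed score of basis word ``b`` occurring
    within the window before target ``t``.  Per-distance raw-count
    components ``C_l`` (l = 1..L-1) are kept so any distance reweighting
    is reconstructable: ``H_o = sum_l (L - l + 1) * C_l``.
    """

    H_o: sp.csr_matrix
    L: int
    vocabulary: Vocabulary = field(repr=False)
    components: dict[int, sp.csr_matrix] | None = None


def _token_index_stream(
    corpus: list[list[str]], vocab: Vocabulary
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten sentences to (token index, sentence id) arrays.

    Out-of-vocabulary tokens keep a slot (index -1) so window distances
    are counted over the raw token stream, but contribute no counts.
    """
    idx: list[int] = []
    sent: list[int] = []
    f2i = vocab.feature_to_index
    for k, sentence in enumerate(corpus):
        for tok in sentence:
            idx.append(f2i.get(tok, -1))
            sent.append(k)
    return np.asarray(idx, dtype=np.int64), np.asarray(sent, dtype=np.int64)


def build_hal(
    corpus: list[list[str]],
    targets: Vocabulary,
    L: int,
    cross_sentences: bool = False,
    keep_components: bool = True,
) -> HALMatrix:
    """Slide a length-``L`` window over the corpus and accumulate scores.

    The window does not cross sentence boundaries unless
    ``cross_sentences`` is set (sentences are the classification unit).
    """
    if L < 1:
        raise SemanticModelError(f"window length must be >= 1, got {L}")
    if len(targets) == 0:
        raise SemanticModelError("target vocabulary is empty")
    N = len(targets)
    idx, sent = _token_index_stream(corpus, targets)
    components: dict[int, sp.csr_matrix] = {}
    H_o = sp.csr_matrix((N, N), dtype=np.float64)
    for l in range(1, L):
        if len(idx) > l:
            t = idx[l:]
            b = idx[:-l]
            ok = (t >= 0) & (b >= 0)
            if not cross_sentences:
                ok &= sent[l:] == sent[:-l]
            t, b = t[ok], b[ok]
        else:
            t = b = np.empty(0, dtype=np.int64)
        C_l = sp.coo_matrix(
            (np.ones(len(t)), (t, b)), shape=(N, N), dtype=np.float64
        ).tocsr()
        if keep_components:
            components[l] = C_l
        H_o = H_o + (L - l + 1) * C_l
    return HALMatrix(
        H_o=H_o.tocsr(),
        L=L,
        vocabulary=targets,
        components=components if keep_components else None,
    )


def combine_hal(h: HALMatrix) -> sp.csr_matrix:
    """Symmetric similarity matrix H = H_o + H_o^T."""
    return (h.H_o + h.H_o.T).tocsr()


def hal_distance_matrix(h: HALMatrix, l: int) -> sp.csr_matrix:
    """Symmetrised raw co-occurrence counts at exact window distance ``l``."""
    if h.components is None:
        raise SemanticModelError("HAL matrix was built without components")
    if not 1 <= l <= h.L - 1:
        raise SemanticModelError(
            f"distance l={l} out of range [1, {h.L - 1}] for window length {h.L}"
        )
    C_l = h.components[l]
    return (C_l + C_l.T).tocsr()


def hal_oracle(
    corpus: list[list[str]], targets: Vocabulary, L: int
) -> np.ndarray:
    """Direct per-sentence pair enumeration — the slow reference H_o."""
    N = len(targets)
    H = np.zeros((N, N))
    f2i = targets.feature_to_index
    for sentence in corpus:
        for i, tok in enumerate(sentence):
            t = f2i.get(tok)
            if t is None:
                continue
            for l in range(1, L):
                if i - l < 0:
                    break
                b = f2i.get(sentence[i - l])
                if b is not None:
                    H[t, b] += L - l + 1
    return H


# ---------------------------------------------------------------------------
# BEAGLE
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentalVectors:
    """Random Gaussian vectors, one per basis word; sigma = 1/sqrt(D) so
    the expected squared row norm is 1."""

    E: np.ndarray
    basis_to_index: dict[str, int]
    D: int
    seed: int


@dataclass
class BeagleMatrix:
    """Accumulated context vectors per target word (|T| x D)."""

    B: np.ndarray
    D: int
    seed: int
    vocabulary: Vocabulary = field(repr=False)


def build_environment(
    corpus: list[list[str]],
    targets: Vocabulary,
    D: int,
    seed: int,
    max_basis: int | None = None,
) -> EnvironmentalVectors:
    """Assign environmental vectors to basis words.

    The basis is every unique corpus word that co-occurs in a sentence
    with at least one target, in order of first encounter, truncated to
    the first ``max_basis``.  Row generation order is the encounter
    order, so the result is bit-reproducible given (corpus, seed).
    """
    if D < 1:
        raise SemanticModelError(f"D must be >= 1, got {D}")
    basis_to_index: dict[str, int] = {}
    for sentence in corpus:
        if not any(tok in targets for tok in sentence):
            continue
        for tok in sentence:
            if tok not in basis_to_index:
                if max_basis is not None and len(basis_to_index) >= max_basis:
                    continue
                basis_to_index[tok] = len(basis_to_index)
    rng = np.random.default_rng(seed)
    E = rng.normal(0.0, 1.0 / np.sqrt(D), size=(len(basis_to_index), D))
    return EnvironmentalVectors(E=E, basis_to_index=basis_to_index, D=D, seed=seed)


def build_beagle(
    corpus: list[list[str]],
    targets: Vocabulary,
    D: int = 4096,
    seed: int = 0,
    max_basis: int | None = None,
    env: EnvironmentalVectors | None = None,
) -> BeagleMatrix:
    """Sequentially accumulate sentence context vectors per target.

    For each sentence and each target occurrence in it, the sum of the
    environmental vectors of the other words in the sentence is added to
    the target's row.  Other occurrences of the same word type do
    contribute; the occurrence's own vector does not.
    """
    if not corpus:
        raise SemanticModelError("empty corpus")
    if env is None:
        env = build_environment(corpus, targets, D, seed, max_basis)
    if env.D != D:
        raise SemanticModelError("environment dimensionality mismatch")
    N = len(targets)
    B = np.zeros((N, D))
    f2i = targets.feature_to_index
    b2i = env.basis_to_index
    E = env.E
    for sentence in corpus:
        t_idx = [f2i[tok] for tok in sentence if tok in f2i]
        if not t_idx:
            continue
        b_idx = np.asarray(
            [b2i[tok] for tok in sentence if tok in b2i], dtype=np.int64
        )
        context_sum = E[b_idx].sum(axis=0) if len(b_idx) else np.zeros(D)
        for tok in sentence:
            t = f2i.get(tok)
            if t is None:
                continue
            own = E[b2i[tok]] if tok in b2i else 0.0
            B[t] += context_sum - own
    return BeagleMatrix(B=B, D=D, seed=seed, vocabulary=targets)


def random_projection(X: np.ndarray, D: int, seed: int) -> np.ndarray:
    """Project columns through an i.i.d. Gaussian matrix with sigma = 1/sqrt(D),
    preserving pairwise distances in expectation."""
    if D < 1:
        raise SemanticModelError(f"D must be >= 1, got {D}")
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    R = rng.normal(0.0, 1.0 / np.sqrt(D), size=(X.shape[1], D))
    return X @ R
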