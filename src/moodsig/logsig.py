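"""Truncated signatures and log-signatures of piecewise-linear paths.

The signature of a path :math:`X : [a,b] \\to \\mathbb{R}^d` is the infinite
collection of its iterated integrals

.. math::

    S(X)_{a,b}^{i_1,\\dots,i_k}
        = \\int_{a<t_1<\\dots<t_k<b} dX^{i_1}_{t_1} \\cdots dX^{i_k}_{t_k},

organised by level :math:`k` and truncated here at a finite level ``p``.  For a
piecewise-linear path the signature is the Chen (concatenation) product of the
tensor exponentials of the segment increments, which is how :func:`path_signature`
evaluates it.  The log-signature is the tensor logarithm of the signature; it
lives in the free Lie algebra and is coordinatised on the Lyndon-word basis by
:func:`logsig`.

A deliberately slow nested-Riemann-sum oracle, :func:`brute_force_coefficient`,
evaluates individual iterated integrals directly from the definition and is used
to verify the algebraic implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PathPoints",
    "TruncatedTensor",
    "LyndonBasis",
    "LogSigFeature",
    "tensor_identity",
    "segment_signature",
    "tensor_mul",
    "tensor_exp",
    "tensor_log",
    "path_signature",
    "lyndon_words",
    "witt_dimension",
    "logsig",
    "brute_force_coefficient",
]


def _as_path(points) -> np.ndarray:
    """Validate and coerce a point sequence to a (n, d) float array."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("a path must be a sequence of equal-length vectors")
    if arr.shape[0] < 2:
        raise ValueError("a path needs at least 2 points")
    return arr


#: Alias used in signatures below: any (n, d) array-like with n >= 2.
PathPoints = np.ndarray


@dataclass
class TruncatedTensor:
    """Element of the tensor algebra over ``d`` letters truncated at level ``p``.

    ``levels[k]`` is the level-``k`` coefficient array of shape ``(d,) * k``
    (level 0 is a scalar).  A signature tensor has level-0 coefficient exactly 1.
    """

    levels: list[np.ndarray]
    d: int
    p: int

    def coefficient(self, multi_index: Sequence[int]) -> float:
        """Coefficient for a 1-based multi-index ``(i1, ..., ik)``."""
        idx = tuple(i - 1 for i in multi_index)
        if any(i < 0 or i >= self.d for i in idx):
            raise IndexError(f"multi-index {multi_index} out of range for d={self.d}")
        k = len(idx)
        if k > self.p:
            raise IndexError(f"level {k} exceeds truncation level {self.p}")
        return float(self.levels[k][idx]) if k else float(self.levels[0])

    def truncate(self, q: int) -> "TruncatedTensor":
        if q > self.p:
            raise ValueError("cannot extend truncation level")
        return TruncatedTensor([lv.copy() for lv in self.levels[: q + 1]], self.d, q)

    def allclose(self, other: "TruncatedTensor", atol: float = 1e-10) -> bool:
        return self.d == other.d and self.p == other.p and all(
            np.allclose(a, b, atol=atol) for a, b in zip(self.levels, other.levels)
        )


def tensor_identity(d: int, p: int) -> TruncatedTensor:
    """The neutral element: level-0 coefficient 1, all higher levels 0."""
    levels = [np.ones(())] + [np.zeros((d,) * k) for k in range(1, p + 1)]
    return TruncatedTensor(levels, d, p)


def segment_signature(increment, p: int) -> TruncatedTensor:
    """Signature of a single linear segment with the given increment.

    The level-``k`` part is the tensor power ``increment^{⊗k} / k!`` — the
    tensor exponential of the level-1 element.
    """
    inc = np.asarray(increment, dtype=float)
    if inc.ndim != 1 or inc.size == 0:
        raise ValueError("increment must be a non-empty 1-D vector")
    if p < 1:
        raise ValueError("truncation level p must be >= 1")
    d = inc.size
    levels = [np.ones(())]
    power = np.ones(())
    for k in range(1, p + 1):
        power = np.multiply.outer(power, inc)
        levels.append(power / factorial(k))
    return TruncatedTensor(levels, d, p)


def _check_compatible(A: TruncatedTensor, B: TruncatedTensor) -> None:
    if A.d != B.d or A.p != B.p:
        raise ValueError(
            f"incompatible tensors: (d={A.d}, p={A.p}) vs (d={B.d}, p={B.p})"
        )


def tensor_mul(A: TruncatedTensor, B: TruncatedTensor) -> TruncatedTensor:
    """Truncated tensor-algebra (Chen concatenation) product.

    Level ``k`` of the product is :math:`\\sum_{j=0}^{k} A_j \\otimes B_{k-j}`.
    """
    _check_compatible(A, B)
    p = A.p
    levels = []
    for k in range(p + 1):
        acc = np.zeros((A.d,) * k)
        for j in range(k + 1):
            acc = acc + np.multiply.outer(A.levels[j], B.levels[k - j])
        levels.append(acc)
    return TruncatedTensor(levels, A.d, p)


def tensor_exp(A: TruncatedTensor) -> TruncatedTensor:
    """Tensor exponential of an element with zero level-0 part."""
    if not np.isclose(float(A.levels[0]), 0.0):
        raise ValueError("tensor_exp expects a level-0 coefficient of 0")
    result = tensor_identity(A.d, A.p)
    term = tensor_identity(A.d, A.p)
    for n in range(1, A.p + 1):
        term = tensor_mul(term, A)
        for k in range(A.p + 1):
            result.levels[k] = result.levels[k] + term.levels[k] / factorial(n)
    return result


def tensor_log(A: TruncatedTensor) -> TruncatedTensor:
    """Tensor logarithm of a group-like element (level-0 coefficient 1).

    Evaluates the truncated series
    :math:`\\log(1 + x) = \\sum_{n\\ge 1} (-1)^{n+1} x^{\\otimes n} / n`
    with :math:`x = A - 1`; the series terminates at level ``p`` because ``x``
    has no level-0 part.
    """
    if not np.isclose(float(A.levels[0]), 1.0):
        raise ValueError("tensor_log requires a level-0 coefficient of 1")
    x = TruncatedTensor(
        [np.zeros(())] + [lv.copy() for lv in A.levels[1:]], A.d, A.p
    )
    result = TruncatedTensor(
        [np.zeros(())] + [np.zeros((A.d,) * k) for k in range(1, A.p + 1)], A.d, A.p
    )
    term = tensor_identity(A.d, A.p)
    for n in range(1, A.p + 1):
        term = tensor_mul(term, x)
        sign = 1.0 if n % 2 == 1 else -1.0
        for k in range(A.p + 1):
            result.levels[k] = result.levels[k] + sign * term.levels[k] / n
    return result


def path_signature(points, p: int) -> TruncatedTensor:
    """Signature of the piecewise-linear path through ``points``, truncated at ``p``.

    Computed as the Chen product over segments of the segment tensor
    exponentials; the level-1 part therefore equals the total increment.
    Consecutive duplicate points contribute the identity and are harmless.
    """
    if p < 1:
        raise ValueError("truncation level p must be >= 1")
    path = _as_path(points)
    d = path.shape[1]
    sig = tensor_identity(d, p)
    for inc in np.diff(path, axis=0):
        sig = tensor_mul(sig, segment_signature(inc, p))
    return sig


# ---------------------------------------------------------------------------
# Lyndon basis


@lru_cache(maxsize=None)
def _lyndon_words_cached(d: int, p: int) -> tuple[tuple[int, ...], ...]:
    # Duval's algorithm over the alphabet {1, ..., d}, then stable-sorted by
    # (length, lexicographic) so level-1 words come first.
    words: list[tuple[int, ...]] = []
    w = [0]
    while w:
        w[-1] += 1
        words.append(tuple(w))
        m = len(w)
        while len(w) < p:
            w.append(w[len(w) - m])
        while w and w[-1] == d:
            w.pop()
    words.sort(key=lambda u: (len(u), u))
    return tuple(words)


@dataclass(frozen=True)
class LyndonBasis:
    """Lyndon words over ``{1..d}`` of length <= ``p``, sorted by (length, lex).

    A word is Lyndon when it is strictly smaller than every proper rotation of
    itself; the Lyndon words of length <= p index a basis of the free Lie
    algebra truncated at level p, of dimension given by the Witt formula.
    """

    d: int
    p: int
    words: tuple[tuple[int, ...], ...] = field(init=False)

    def __post_init__(self):
        if self.d < 1 or self.p < 1:
            raise ValueError("d and p must both be >= 1")
        object.__setattr__(self, "words", _lyndon_words_cached(self.d, self.p))

    def __len__(self) -> int:
        return len(self.words)


def lyndon_words(d: int, p: int) -> LyndonBasis:
    """All Lyndon words over the alphabet ``{1..d}`` of length at most ``p``."""
    return LyndonBasis(d, p)


def _mobius(n: int) -> int:
    result, m = 1, n
    q = 2
    while q * q <= m:
        if m % q == 0:
            m //= q
            if m % q == 0:
                return 0
            result = -result
        q += 1
    if m > 1:
        result = -result
    return result


def witt_dimension(d: int, p: int) -> int:
    """Witt formula: Σ_{k<=p} (1/k) Σ_{m|k} μ(m) d^{k/m}, the dimension of the
    free Lie algebra over d letters truncated at level p."""
    return sum(
        sum(_mobius(m) * d ** (k // m) for m in range(1, k + 1) if k % m == 0) // k
        for k in range(1, p + 1)
    )


def _standard_factorization(w: tuple[int, ...]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    # Longest proper Lyndon suffix v gives the standard factorization w = u v.
    lynd = None
    for i in range(1, len(w)):
        v = w[i:]
        if all(v < v[j:] + v[:j] for j in range(1, len(v))):
            lynd = i
            break
    assert lynd is not None
    return w[:lynd], w[lynd:]


@lru_cache(maxsize=None)
def _bracket_expansion(w: tuple[int, ...]) -> dict[tuple[int, ...], float]:
    """Tensor-word expansion of the standard bracketing of a Lyndon word."""
    if len(w) == 1:
        return {w: 1.0}
    u, v = _standard_factorization(w)
    eu, ev = _bracket_expansion(u), _bracket_expansion(v)
    out: dict[tuple[int, ...], float] = {}
    for a, ca in eu.items():
        for b, cb in ev.items():
            out[a + b] = out.get(a + b, 0.0) + ca * cb
            out[b + a] = out.get(b + a, 0.0) - ca * cb
    return {k: c for k, c in out.items() if c != 0.0}


@lru_cache(maxsize=None)
def _lyndon_solve_matrix(d: int, k: int) -> tuple[tuple[tuple[int, ...], ...], np.ndarray]:
    """Change-of-basis data for level k: Lyndon words (lex order) and the
    unitriangular matrix M with M[j, i] = coefficient of tensor word w_j in the
    expanded standard bracketing of Lyndon word w_i."""
    words = [w for w in _lyndon_words_cached(d, k) if len(w) == k]
    words.sort()
    index = {w: j for j, w in enumerate(words)}
    M = np.zeros((len(words), len(words)))
    for i, w in enumerate(words):
        for word, coeff in _bracket_expansion(w).items():
            j = index.get(word)
            if j is not None:
                M[j, i] = coeff
    return tuple(words), M


@dataclass
class LogSigFeature:
    """Log-signature coordinates on the Lyndon-word basis."""

    coords: np.ndarray
    basis: LyndonBasis

    def as_dict(self) -> dict[tuple[int, ...], float]:
        return {w: float(c) for w, c in zip(self.basis.words, self.coords)}


def logsig(points, p: int) -> LogSigFeature:
    """Log-signature of a piecewise-linear path on the Lyndon basis.

    The tensor logarithm of the path signature is a Lie element; its
    coordinates in the Lyndon basis are recovered level by level by solving the
    unitriangular system that expresses the expanded standard bracketings in
    tensor words.  Level-1 coordinates equal the per-channel total increments.
    """
    sig = path_signature(points, p)
    L = tensor_log(sig)
    basis = lyndon_words(sig.d, p)
    coords_by_word: dict[tuple[int, ...], float] = {}
    for k in range(1, p + 1):
        words, M = _lyndon_solve_matrix(sig.d, k)
        if not words:
            continue
        rhs = np.array([L.levels[k][tuple(i - 1 for i in w)] for w in words])
        sol = np.linalg.solve(M, rhs)
        coords_by_word.update(zip(words, sol))
    coords = np.array([coords_by_word[w] for w in basis.words])
    return LogSigFeature(coords=coords, basis=basis)


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_coefficient(points, multi_index: Iterable[int], n_steps: int = 10000) -> float:
    """Directly evaluate one iterated-integral coefficient by nested Riemann sums.

    The time grid is uniform within each segment and refined so that segment
    endpoints are grid points, which removes discretisation bias at kinks.
    Each nesting level integrates the running inner integral against the
    channel increments with trapezoid (midpoint-in-value) evaluation, which is
    second-order convergent — the first-order bias of a pure left-endpoint sum
    is too large at level 3 for usefully small grids.  Slow by construction;
    used only as an independent oracle in tests.
    """
    path = _as_path(points)
    idx = tuple(int(i) - 1 for i in multi_index)
    if any(i < 0 or i >= path.shape[1] for i in idx):
        raise IndexError("multi-index out of range")
    n_seg = path.shape[0] - 1
    per_seg = max(1, int(np.ceil(n_steps / n_seg)))
    # Piecewise-linear refinement: per_seg equal sub-steps inside each segment.
    pieces = [path[0:1]]
    for s in range(n_seg):
        frac = np.linspace(0.0, 1.0, per_seg + 1)[1:, None]
        pieces.append(path[s] + frac * (path[s + 1] - path[s]))
    grid = np.vstack(pieces)
    integral = np.ones(grid.shape[0])
    for i in idx:
        dX = np.diff(grid[:, i])
        avg = 0.5 * (integral[:-1] + integral[1:])
        integral = np.concatenate([[0.0], np.cumsum(avg * dX)])
    return float(integral[-1])
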