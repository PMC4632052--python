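"""Luria-Delbrück mutant-count model with constant (Dirac) division times.

Under synchronous, deterministic cell divisions, the descendants of a single
mutation form a clone whose final size is a power of two.  If the mutant
grows at a rate ``b`` relative to the wild type (``b = 1``: equal fitness),
the asymptotic clone-size law is

    P(clone size = 2**k) = q_k = 2**(-k/b) * (1 - 2**(-1/b)),   k = 0, 1, ...

i.e. a geometric law on powers of two; ``b = 1`` recovers Haldane's
``q_k = 2**-(k+1)``.  The total number of mutants in a culture is a compound
Poisson sum of a Poisson(``m``) number of such clones, with probability
generating function

    G(s) = exp(m * (psi_b(s) - 1)),      psi_b(s) = sum_k q_k * s**(2**k).

``m`` is the expected number of mutation *events* per culture.  All counts
here are plated mutant counts; partial plating is handled downstream by the
Stewart correction (:mod:`flucrate.corrections`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "CloneSizeLaw",
    "MutantCountModel",
    "clone_size_pmf",
    "clone_size_pgf",
    "mutant_count_pgf",
    "mutant_count_pmf",
    "mutant_count_cdf",
]

_LN2 = math.log(2.0)
#: smallest useful log-argument before exp() underflows to 0.
_EXP_UNDERFLOW = -745.0


def _check_fitness(b: float) -> None:
    if not (b > 0.0) or not math.isfinite(b):
        raise InvalidParameterError(f"mutant relative fitness b must be > 0, got {b!r}")


def clone_size_pmf(b: float, k) -> float | np.ndarray:
    """Probability that a single mutant clone reaches size ``2**k``.

    Parameters
    ----------
    b
        Mutant relative fitness (> 0).
    k
        Number of doublings the clone completes (integer >= 0, scalar or
        array).

    Returns
    -------
    ``q_k = 2**(-k/b) * (1 - 2**(-1/b))``.
    """
    _check_fitness(b)
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise InvalidParameterError("clone doubling count k must be >= 0")
    # 1 - 2**(-1/b) via expm1 stays accurate for b >> 1 where 2**(-1/b) -> 1.
    log_r = -_LN2 / b
    head = -math.expm1(log_r)
    with np.errstate(under="ignore"):
        q = np.exp(k_arr * log_r) * head
    return float(q) if np.isscalar(k) or k_arr.ndim == 0 else q


@dataclass(frozen=True)
class CloneSizeLaw:
    """Distribution of one clone's final size (a power of two) at fitness ``b``.

    ``probabilities[k]`` is ``q_k``; the truncation index ``K`` is the
    smallest k whose geometric tail mass falls below ``tail_tol``.
    """

    b: float
    tail_tol: float = 1e-12
    probabilities: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check_fitness(self.b)
        if not (0.0 < self.tail_tol < 1.0):
            raise InvalidParameterError("tail_tol must be in (0, 1)")
        # tail mass beyond index K-1 is r**K with r = 2**(-1/b)
        log_r = -_LN2 / self.b
        n_terms = max(1, int(math.ceil(math.log(self.tail_tol) / log_r)) + 1)
        object.__setattr__(
            self, "probabilities", np.asarray(clone_size_pmf(self.b, np.arange(n_terms)))
        )

    @property
    def truncation_index(self) -> int:
        return len(self.probabilities) - 1

    def pmf(self, k) -> float | np.ndarray:
        return clone_size_pmf(self.b, k)

    def pgf(self, s: float) -> float:
        return clone_size_pgf(s, self.b, tail_tol=self.tail_tol)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw clone sizes ``2**K`` with ``K`` geometric; capped at ``2**62``."""
        p_head = -math.expm1(-_LN2 / self.b)
        k = rng.geometric(p_head, size=size) - 1
        np.clip(k, 0, 62, out=k)  # int64 headroom; beyond any countable plate
        return np.int64(1) << k.astype(np.int64)


def clone_size_pgf(s: float, b: float, tail_tol: float = 1e-12) -> float:
    """Clone-size PGF ``psi_b(s) = sum_k q_k * s**(2**k)`` for ``s`` in [0, 1].

    The series is truncated once the remaining geometric mass (an upper bound
    on the remaining sum, since ``s**(2**k) <= 1``) drops below ``tail_tol``.
    """
    _check_fitness(b)
    if not (0.0 <= s <= 1.0):
        raise InvalidParameterError(f"PGF argument s must be in [0, 1], got {s!r}")
    if s == 0.0:
        return 0.0  # clones have size >= 1
    if s == 1.0:
        return 1.0
    log_s = math.log(s)
    log_r = -_LN2 / b
    n_terms = max(1, int(math.ceil(math.log(tail_tol) / log_r)) + 1)
    k = np.arange(n_terms)
    with np.errstate(under="ignore"):
        # s**(2**k) decays doubly exponentially; floor the exponent at the
        # underflow threshold instead of computing astronomically small terms.
        exponent = np.maximum(np.ldexp(log_s, k), _EXP_UNDERFLOW)
        terms = np.exp(k * log_r + exponent)
    return float(-math.expm1(log_r) * terms.sum())


def mutant_count_pgf(s: float, m: float, b: float, tail_tol: float = 1e-12) -> float:
    """Mutant-count PGF ``G(s) = exp(m * (psi_b(s) - 1))``."""
    if m < 0 or not math.isfinite(m):
        raise InvalidParameterError(f"mean mutations per culture m must be >= 0, got {m!r}")
    if m == 0.0:
        return 1.0
    return math.exp(m * (clone_size_pgf(s, b, tail_tol) - 1.0))


def mutant_count_pmf(
    m: float, b: float, nmax: int, tail_tol: float = 1e-12
) -> np.ndarray:
    """Compound-Poisson pmf ``p_0 .. p_nmax`` by Panjer recursion.

    ``p_0 = exp(-m)`` and, for ``n >= 1``,

        p_n = (m / n) * sum_{k: 2**k <= n} 2**k * q_k * p_{n - 2**k}.

    The recursion involves only positive terms and is numerically stable;
    cost is ``O(nmax * log nmax)``.  The mass not covered by ``p_0..p_nmax``
    is ``1 - sum(p)`` (the model's genuine tail).
    """
    if m < 0 or not math.isfinite(m):
        raise InvalidParameterError(f"mean mutations per culture m must be >= 0, got {m!r}")
    _check_fitness(b)
    if nmax < 0:
        raise InvalidParameterError("nmax must be >= 0")
    p = np.zeros(nmax + 1)
    p[0] = math.exp(-m)
    if m == 0.0 or nmax == 0:
        return p
    n_pows = nmax.bit_length()  # powers of two <= nmax
    pow2 = np.int64(1) << np.arange(n_pows)
    weights = pow2 * np.asarray(clone_size_pmf(b, np.arange(n_pows)))
    for n in range(1, nmax + 1):
        kn = n.bit_length()
        p[n] = (m / n) * np.dot(weights[:kn], p[n - pow2[:kn]])
    return p


def mutant_count_cdf(
    m: float, b: float, nmax: int, tail_tol: float = 1e-12
) -> np.ndarray:
    """Running sum of :func:`mutant_count_pmf`; last entry is ``1 - tail``."""
    return np.cumsum(mutant_count_pmf(m, b, nmax, tail_tol))


@dataclass(frozen=True)
class MutantCountModel:
    """Compound-Poisson Luria-Delbrück distribution of plated mutants.

    Parameters
    ----------
    m
        Mean number of mutation events per culture (>= 0).
    b
        Mutant relative fitness (> 0).
    """

    m: float
    b: float
    tail_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.m < 0 or not math.isfinite(self.m):
            raise InvalidParameterError("m must be >= 0 and finite")
        _check_fitness(self.b)

    def pgf(self, s: float) -> float:
        return mutant_count_pgf(s, self.m, self.b, self.tail_tol)

    def pmf(self, nmax: int) -> np.ndarray:
        return mutant_count_pmf(self.m, self.b, nmax, self.tail_tol)

    def cdf(self, nmax: int) -> np.ndarray:
        return mutant_count_cdf(self.m, self.b, nmax, self.tail_tol)

    def tail_mass(self, nmax: int) -> float:
        return float(max(0.0, 1.0 - self.pmf(nmax).sum()))

    def clone_law(self) -> CloneSizeLaw:
        return CloneSizeLaw(self.b, self.tail_tol)
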