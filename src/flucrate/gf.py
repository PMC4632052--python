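"""Empirical probability generating function (GF) estimation of (m, b).

The empirical PGF of observed mutant counts ``X_1..X_n`` is

    g-hat(s) = (1/n) * sum_i s**X_i,

which is finite for any finite counts — this is what makes the GF method
robust to "jackpot" cultures whose enormous counts destabilise maximum
likelihood.  Matching g-hat to the model PGF ``G(s) = exp(m*(psi_b(s)-1))``
at a few points in (0, 1) gives closed-form estimating equations:

* fitness ``b`` solves
  ``ln g-hat(s1) / ln g-hat(s2) = (psi_b(s1)-1) / (psi_b(s2)-1)``
  (the right-hand side is monotone in b, so a bracketing bisection works);
* ``m = ln g-hat(s3) / (psi_b(s3) - 1)`` at the solved (or user-fixed) b.

Confidence limits come from the delta method: the empirical PGF vector has
covariance ``Cov(g-hat(u), g-hat(v)) = (g-hat(u*v) - g-hat(u) g-hat(v))/n``,
which is pushed through the estimator map with a central-difference
Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from . import corrections, gof as gof_mod
from .dataset import FluctuationDataset
from .exceptions import (
    EmptyDatasetError,
    EstimationError,
    GofUnavailableError,
    InvalidParameterError,
    UnidentifiableError,
)
from .ld_model import clone_size_pgf

__all__ = [
    "GFConfig",
    "EstimateResult",
    "empirical_pgf",
    "estimate_b",
    "estimate_m",
    "compute_ci",
    "estimate",
]


@dataclass(frozen=True)
class GFConfig:
    """Tuning constants of the GF estimator.

    ``s1 < s2`` are the PGF evaluation points for the fitness equation and
    ``s3`` the point for m.  The defaults (0.8, 0.9, 0.9) were chosen by a
    simulation study over m in 1..8 and b in 0.5..2 (see the methods note):
    points near 1 keep ``g-hat`` well away from 0 even when every culture
    carries many mutants, where small-s points degenerate into a noisy
    function of the single smallest count.
    """

    s1: float = 0.8
    s2: float = 0.9
    s3: float = 0.9
    b_min: float = 0.05
    b_max: float = 20.0
    b_tol: float = 1e-6
    max_iter: int = 200
    confidence: float = 0.95
    tail_tol: float = 1e-12
    min_expected: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.s1 < self.s2 < 1.0):
            raise InvalidParameterError("need 0 < s1 < s2 < 1")
        if not (0.0 < self.s3 < 1.0):
            raise InvalidParameterError("need 0 < s3 < 1")
        if not (0.0 < self.b_min < self.b_max):
            raise InvalidParameterError("need 0 < b_min < b_max")
        if not (0.0 < self.confidence < 1.0):
            raise InvalidParameterError("confidence must be in (0, 1)")


@dataclass(frozen=True)
class EstimateResult:
    """The full numerical report of a fluctuation-assay fit.

    ``None`` marks a quantity that is genuinely not available (e.g. fitness
    limits when b was user-fixed, or a chi-square that could not be formed)
    — never a silent zero.
    """

    m: float
    b: float
    b_was_fixed: bool
    m_lower: Optional[float]
    m_upper: Optional[float]
    b_lower: Optional[float]
    b_upper: Optional[float]
    m_corr: float
    cl_lower: Optional[float]  # 95% limits on m_corr
    cl_upper: Optional[float]
    mu: float
    mu_corr: float
    z: float
    n_cultures: int
    n_mean: float  # mean plated cells per culture
    n_sd: float  # sd of plated cells per culture
    chi2: Optional[float]
    chi2_dof: Optional[int]
    chi2_pval: Optional[float]
    fit_warning: Optional[bool]
    gof: Optional["gof_mod.GofResult"]

    def to_dict(self) -> dict:
        """Stable machine-readable report (JSON-friendly key names)."""
        return {
            "m": self.m,
            "mu": self.mu,
            "m_corr": self.m_corr,
            "mu_corr": self.mu_corr,
            "cl_lower": self.cl_lower,
            "cl_upper": self.cl_upper,
            "b": self.b,
            "b_lower": self.b_lower,
            "b_upper": self.b_upper,
            "b_was_fixed": self.b_was_fixed,
            "n_cultures": self.n_cultures,
            "n_mean": self.n_mean,
            "n_sd": self.n_sd,
            "z": self.z,
            "chi2": self.chi2,
            "chi2_dof": self.chi2_dof,
            "chi2_pval": self.chi2_pval,
            "warning": self.fit_warning,
        }


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, FluctuationDataset):
        return counts.mutants
    arr = np.asarray(counts)
    if arr.ndim != 1 or len(arr) == 0:
        raise EmptyDatasetError("counts must be a non-empty 1-d array")
    return arr.astype(np.int64)


def empirical_pgf(counts, s: float) -> float:
    """``(1/n) * sum_i s**X_i`` with the ``0**0 = 1`` convention.

    Counts are sorted before summation so the value is bit-identical under
    any permutation of the cultures.
    """
    arr = np.sort(_as_counts(counts))
    if not (0.0 <= s <= 1.0):
        raise InvalidParameterError(f"PGF argument s must be in [0, 1], got {s!r}")
    with np.errstate(under="ignore"):
        return float(np.mean(np.power(float(s), arr)))


def _log_pgf_ratio_model(b: float, config: GFConfig) -> float:
    """(psi_b(s1) - 1) / (psi_b(s2) - 1), the model side of the b equation."""
    num = clone_size_pgf(config.s1, b, config.tail_tol) - 1.0
    den = clone_size_pgf(config.s2, b, config.tail_tol) - 1.0
    return num / den


def estimate_b(counts, config: GFConfig | None = None) -> float:
    """Solve the two-point GF equation for the mutant relative fitness.

    Raises
    ------
    UnidentifiableError
        When all counts are zero (the empirical PGF is identically 1).
    EstimationError
        When the data ratio falls outside the model ratio's range over
        ``[b_min, b_max]`` (no sign change to bisect).
    """
    config = config or GFConfig()
    arr = _as_counts(counts)
    g1 = empirical_pgf(arr, config.s1)
    g2 = empirical_pgf(arr, config.s2)
    if g1 >= 1.0 or g2 >= 1.0:
        raise UnidentifiableError(
            "all mutant counts are zero: fitness b is unidentifiable"
        )
    if g1 <= 0.0 or g2 <= 0.0:  # impossible for finite counts, guarded anyway
        raise EstimationError("empirical PGF vanished; cannot form log ratio")
    target = math.log(g1) / math.log(g2)

    def f(b: float) -> float:
        return _log_pgf_ratio_model(b, config) - target

    f_lo, f_hi = f(config.b_min), f(config.b_max)
    if f_lo < f_hi:
        raise EstimationError(
            "model PGF ratio is not decreasing over the fitness bracket; "
            "widen [b_min, b_max] or check s1 < s2"
        )
    if f_lo * f_hi > 0:
        raise EstimationError(
            f"fitness not identifiable in [{config.b_min}, {config.b_max}]: "
            f"data log-PGF ratio {target:.4g} outside the model range "
            f"[{_log_pgf_ratio_model(config.b_max, config):.4g}, "
            f"{_log_pgf_ratio_model(config.b_min, config):.4g}]"
        )
    return float(
        optimize.bisect(
            f, config.b_min, config.b_max, xtol=config.b_tol, maxiter=config.max_iter
        )
    )


def estimate_m(counts, b: float, config: GFConfig | None = None) -> float:
    """``m = ln g-hat(s3) / (psi_b(s3) - 1)`` at fitness ``b`` (>= 0 always)."""
    config = config or GFConfig()
    if not (b > 0):
        raise InvalidParameterError(f"fitness b must be > 0, got {b!r}")
    arr = _as_counts(counts)
    g3 = empirical_pgf(arr, config.s3)
    if g3 >= 1.0:
        return 0.0
    denom = clone_size_pgf(config.s3, b, config.tail_tol) - 1.0
    return float(math.log(g3) / denom)


def _pgf_covariance(counts: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Covariance matrix of the empirical PGF at ``points``.

    ``Cov(g-hat(u), g-hat(v)) = (g-hat(u v) - g-hat(u) g-hat(v)) / n``.
    """
    n = len(counts)
    g = np.array([empirical_pgf(counts, s) for s in points])
    cov = np.empty((len(points), len(points)))
    for i, u in enumerate(points):
        for j, v in enumerate(points):
            cov[i, j] = (empirical_pgf(counts, u * v) - g[i] * g[j]) / n
    return cov


def _solve_from_pgf_values(
    g_values: np.ndarray, points: np.ndarray, config: GFConfig, b_fixed: Optional[float]
) -> np.ndarray:
    """Map empirical-PGF values at ``points`` to the parameter vector.

    Returns ``[m]`` when b is fixed, else ``[m, b]``.  ``points`` is
    ``[s3]`` or ``[s1, s2, s3]`` (s3 may coincide with s2; values must
    match positions).
    """
    if b_fixed is not None:
        b = b_fixed
        g3 = g_values[0]
    else:
        g1, g2, g3 = g_values
        target = math.log(g1) / math.log(g2)

        def f(b_: float) -> float:
            return _log_pgf_ratio_model(b_, config) - target

        b = float(
            optimize.bisect(
                f, config.b_min, config.b_max, xtol=config.b_tol, maxiter=config.max_iter
            )
        )
    denom = clone_size_pgf(config.s3, b, config.tail_tol) - 1.0
    m = math.log(g3) / denom
    return np.array([m]) if b_fixed is not None else np.array([m, b])


def compute_ci(
    counts,
    m: float,
    b: float,
    config: GFConfig | None = None,
    b_fixed: bool = False,
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """Delta-method confidence limits ``(m_lower, m_upper, b_lower, b_upper)``.

    Lower limits are clamped at 0.  Returns ``(None, None, None, None)``
    when the interval cannot be formed (all-zero data, or the numerical
    Jacobian stepped outside the identifiable region).
    """
    config = config or GFConfig()
    arr = _as_counts(counts)
    if b_fixed:
        points = np.array([config.s3])
    else:
        points = np.array([config.s1, config.s2, config.s3])
    g = np.array([empirical_pgf(arr, s) for s in points])
    if np.any(g >= 1.0):
        return (None, None, None, None)  # all-zero counts: no curvature
    try:
        cov_g = _pgf_covariance(arr, points)
        # central-difference Jacobian of the estimator map
        n_par = 1 if b_fixed else 2
        jac = np.empty((n_par, len(points)))
        b_arg = b if b_fixed else None
        for j in range(len(points)):
            h = 1e-5 * g[j]
            g_plus, g_minus = g.copy(), g.copy()
            g_plus[j] += h
            g_minus[j] -= h
            theta_plus = _solve_from_pgf_values(g_plus, points, config, b_arg)
            theta_minus = _solve_from_pgf_values(g_minus, points, config, b_arg)
            jac[:, j] = (theta_plus - theta_minus) / (2.0 * h)
        cov_theta = jac @ cov_g @ jac.T
        variances = np.diag(cov_theta)
        if np.any(~np.isfinite(variances)) or np.any(variances < 0):
            return (None, None, None, None)
        half = stats.norm.ppf(0.5 + config.confidence / 2.0) * np.sqrt(variances)
    except (EstimationError, ValueError, RuntimeError):
        return (None, None, None, None)
    m_lower, m_upper = max(0.0, m - half[0]), m + half[0]
    if b_fixed:
        return (m_lower, m_upper, None, None)
    b_lower, b_upper = max(0.0, b - half[1]), b + half[1]
    return (m_lower, m_upper, b_lower, b_upper)


def estimate(
    dataset: FluctuationDataset,
    b_known: Optional[float] = None,
    z: float = 1.0,
    config: GFConfig | None = None,
) -> EstimateResult:
    """Full fluctuation-assay analysis: point estimates, limits, rates, fit.

    Parameters
    ----------
    dataset
        Parsed (mutants, cells) pairs.
    b_known
        Experimentally measured mutant relative fitness; when given, only m
        is estimated (``b_was_fixed`` is set).  When ``None``, b is solved
        from the GF equations first.
    z
        Plating efficiency in (0, 1]; enters only through the Stewart
        correction and the derived mean total cells per culture.
    """
    config = config or GFConfig()
    counts = dataset.mutants
    if b_known is not None and not (0.0 < b_known < math.inf):
        raise InvalidParameterError(f"fixed fitness must satisfy 0 < b < inf, got {b_known!r}")
    summary = corrections.summarize_dataset(dataset, z)

    b_fixed = b_known is not None
    b = b_known if b_fixed else estimate_b(counts, config)
    m = estimate_m(counts, b, config)
    m_lower, m_upper, b_lower, b_upper = compute_ci(counts, m, b, config, b_fixed=b_fixed)

    factor = corrections.stewart_factor(z)
    m_corr = m * factor
    mu = corrections.mutation_rate(m, summary.plated_mean)
    mu_corr = corrections.mutation_rate(m_corr, summary.total_mean)
    cl_lower = None if m_lower is None else m_lower * factor
    cl_upper = None if m_upper is None else m_upper * factor

    try:
        gof_result = gof_mod.chi_square_test(
            counts,
            m,
            b,
            n_fitted_params=1 if b_fixed else 2,
            min_expected=config.min_expected,
        )
        chi2, dof, pval = gof_result.chi2, gof_result.dof, gof_result.pval
        warning = gof_result.warning
    except GofUnavailableError:
        gof_result, chi2, dof, pval, warning = None, None, None, None, None

    return EstimateResult(
        m=m,
        b=float(b),
        b_was_fixed=b_fixed,
        m_lower=m_lower,
        m_upper=m_upper,
        b_lower=None if b_fixed else b_lower,
        b_upper=None if b_fixed else b_upper,
        m_corr=m_corr,
        cl_lower=cl_lower,
        cl_upper=cl_upper,
        mu=mu,
        mu_corr=mu_corr,
        z=z,
        n_cultures=summary.n_cultures,
        n_mean=summary.plated_mean,
        n_sd=summary.plated_sd,
        chi2=chi2,
        chi2_dof=dof,
        chi2_pval=pval,
        fit_warning=warning,
        gof=gof_result,
    )
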