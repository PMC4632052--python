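"""Pearson chi-square goodness-of-fit of counts to the fitted model.

Observed mutant counts are binned into contiguous count ranges, merged
left-to-right until each bin's expected frequency under the fitted
compound-Poisson model reaches ``min_expected`` (Cochran's rule, default 5);
the final bin is the open tail, whose expected mass is ``n * (1 - cdf)``
computed exactly rather than by truncating the heavy tail.  The test is run
on plated counts at the uncorrected (m, b) — the plating-efficiency
correction is a post-hoc rescaling of m and does not change the fitted
distribution of what was actually plated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .dataset import FluctuationDataset
from .exceptions import GofUnavailableError, InvalidParameterError
from .ld_model import mutant_count_cdf, mutant_count_pmf

__all__ = ["CountBin", "GofResult", "make_bins", "chi_square_test", "cdf_overlay"]

#: p-value threshold below which the fit is flagged as unreliable.
WARNING_PVAL = 0.01


@dataclass(frozen=True)
class CountBin:
    """Counts ``lo..hi`` inclusive; ``hi = None`` marks the open tail bin."""

    lo: int
    hi: Optional[int]
    observed: int
    expected: float


@dataclass(frozen=True)
class GofResult:
    chi2: float
    dof: int
    pval: float
    bins: tuple[CountBin, ...]
    warning: bool


def _as_counts(data) -> np.ndarray:
    if isinstance(data, FluctuationDataset):
        return data.mutants
    return np.asarray(data, dtype=np.int64)


def make_bins(
    observed_counts,
    model_pmf: np.ndarray,
    min_expected: float = 5.0,
) -> list[CountBin]:
    """Greedy left-to-right binning with an exact open tail bin.

    ``model_pmf`` covers counts ``0..len(model_pmf)-1``; observed counts and
    model mass beyond it fall into the tail bin.  A trailing bin that cannot
    reach ``min_expected`` is merged into the bin before it.

    Raises
    ------
    GofUnavailableError
        When fewer than 2 bins reach ``min_expected`` expected cultures.
    """
    counts = _as_counts(observed_counts)
    n = len(counts)
    if n < 1:
        raise GofUnavailableError("no cultures")
    if min_expected <= 0:
        raise InvalidParameterError("min_expected must be > 0")
    cover = len(model_pmf)
    in_range = counts[counts < cover]
    obs_freq = np.bincount(in_range, minlength=cover)
    beyond = int(np.sum(counts >= cover))

    bins: list[CountBin] = []
    lo, acc_exp, acc_obs = 0, 0.0, 0
    for v in range(cover):
        acc_exp += n * float(model_pmf[v])
        acc_obs += int(obs_freq[v])
        if acc_exp >= min_expected:
            bins.append(CountBin(lo=lo, hi=v, observed=acc_obs, expected=acc_exp))
            lo, acc_exp, acc_obs = v + 1, 0.0, 0
    tail_expected = n * max(0.0, 1.0 - float(model_pmf.sum())) + acc_exp
    tail_observed = acc_obs + beyond
    if bins and tail_expected < min_expected:
        last = bins.pop()
        tail = CountBin(
            lo=last.lo,
            hi=None,
            observed=last.observed + tail_observed,
            expected=last.expected + tail_expected,
        )
    else:
        tail = CountBin(lo=lo, hi=None, observed=tail_observed, expected=tail_expected)
    bins.append(tail)
    if len(bins) < 2:
        raise GofUnavailableError(
            f"fewer than 2 bins reach an expected frequency of {min_expected}; "
            "too few cultures for a chi-square test"
        )
    return bins


def _pmf_for_binning(
    m: float, b: float, max_obs: int, n: int, min_expected: float
) -> np.ndarray:
    """Model pmf long enough that everything past it belongs in the tail bin.

    Grows the Panjer recursion geometrically and stops once the remaining
    expected frequency ``n * (1 - cdf)`` drops below ``min_expected`` — a
    single jackpot culture must not force an enormous recursion.
    """
    nmax = min(max_obs, 512)
    while True:
        pmf = mutant_count_pmf(m, b, nmax)
        if nmax >= max_obs or n * (1.0 - pmf.sum()) < min_expected:
            return pmf
        nmax = min(max_obs, nmax * 4)


def chi_square_test(
    data,
    m: float,
    b: float,
    n_fitted_params: int = 2,
    min_expected: float = 5.0,
) -> GofResult:
    """Pearson chi-square of observed counts against the fitted (m, b) model.

    ``dof = #bins - 1 - n_fitted_params`` floored at 1 (``n_fitted_params``
    is 2 when b was estimated from the same data, 1 when b was user-fixed,
    0 when testing externally supplied parameters).  ``warning`` is set
    exactly when ``pval < 0.01``.
    """
    counts = _as_counts(data)
    if len(counts) == 0:
        raise GofUnavailableError("no cultures")
    if n_fitted_params not in (0, 1, 2):
        raise InvalidParameterError("n_fitted_params must be 0, 1 or 2")
    if m == 0.0:
        # degenerate model: point mass at zero mutants
        if np.all(counts == 0):
            bins = (CountBin(0, None, len(counts), float(len(counts))),)
            return GofResult(chi2=0.0, dof=1, pval=1.0, bins=bins, warning=False)
        raise GofUnavailableError("a model with m = 0 cannot explain nonzero counts")
    pmf = _pmf_for_binning(m, b, int(counts.max()), len(counts), min_expected)
    bins = make_bins(counts, pmf, min_expected=min_expected)
    obs = np.array([bn.observed for bn in bins], dtype=float)
    exp = np.array([bn.expected for bn in bins], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    dof = max(len(bins) - 1 - n_fitted_params, 1)
    pval = float(stats.chi2.sf(chi2, dof))
    return GofResult(
        chi2=chi2, dof=dof, pval=pval, bins=tuple(bins), warning=pval < WARNING_PVAL
    )


def cdf_overlay(data, m: float, b: float):
    """Coordinates for the fitted-vs-empirical CDF plot.

    Returns ``(x, empirical_cdf, model_cdf)`` over integer counts
    ``0..max(observed)``; both are step functions evaluated at each count.
    """
    counts = _as_counts(data)
    if len(counts) == 0:
        raise GofUnavailableError("no cultures")
    xmax = int(counts.max())
    x = np.arange(xmax + 1)
    ecdf = np.cumsum(np.bincount(counts, minlength=xmax + 1)) / len(counts)
    if m == 0.0:
        mcdf = np.ones_like(x, dtype=float)
    else:
        mcdf = mutant_count_cdf(m, b, xmax)
    return x, ecdf, mcdf
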