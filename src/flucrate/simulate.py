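"""Synthetic fluctuation assays under the Dirac Luria-Delbrück model.

Two independent samplers are provided:

* a fast compound-Poisson sampler (:func:`sample_culture`,
  :func:`simulate_assay`) that draws a Poisson(m) number of clones with
  power-of-two sizes from the asymptotic clone-size law and binomially
  thins them by the plating efficiency z; and
* a direct-generation oracle (:func:`direct_generation_sim`) that grows a
  population through discrete synchronous doublings, placing mutations at
  cell divisions — no compound-Poisson shortcut, valid for b = 1 — used to
  validate the clone-size law and the fast sampler against first
  principles.

:func:`dispersion_study` runs the estimator-recovery grid (values of m and
b crossed with numbers of parallel cultures) and reports per-cell 95%
dispersion ellipses of the estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import gf
from .dataset import FluctuationDataset
from .exceptions import EstimationError, InvalidParameterError
from .ld_model import CloneSizeLaw, mutant_count_pmf

__all__ = [
    "SimulationSpec",
    "binned_tv_distance",
    "sample_culture",
    "sample_counts",
    "simulate_assay",
    "direct_generation_sim",
    "dispersion_study",
    "DispersionStudyResult",
]

#: default mean plated cells per culture: a 500 uL culture at 6e6 cells/mL.
DEFAULT_PLATED_MEAN = 3e6


def _validate(m: float, b: float, z: float) -> None:
    if m < 0 or not math.isfinite(m):
        raise InvalidParameterError(f"m must be >= 0, got {m!r}")
    if not (b > 0):
        raise InvalidParameterError(f"b must be > 0, got {b!r}")
    if not (0.0 < z <= 1.0):
        raise InvalidParameterError(f"z must be in (0, 1], got {z!r}")


def sample_counts(
    m: float, b: float, z: float, n_cultures: int, rng: np.random.Generator
) -> np.ndarray:
    """Vector of plated mutant counts for ``n_cultures`` independent cultures.

    Per culture: ``K ~ Poisson(m)`` clones, sizes i.i.d. from
    :class:`CloneSizeLaw` (powers of two, capped at ``2**62``), total
    thinned ``Binomial(total, z)``.
    """
    _validate(m, b, z)
    if n_cultures < 1:
        raise InvalidParameterError("n_cultures must be >= 1")
    n_clones = rng.poisson(m, size=n_cultures)
    total = int(n_clones.sum())
    counts = np.zeros(n_cultures, dtype=np.int64)
    if total > 0:
        sizes = CloneSizeLaw(b).sample(total, rng)
        starts = np.concatenate(([0], np.cumsum(n_clones)[:-1]))
        # reduceat cannot take a start index == len(sizes); clip, then zero
        # out the empty segments (clipped starts only occur for those).
        sums = np.add.reduceat(sizes, np.minimum(starts, total - 1))
        sums[n_clones == 0] = 0
        counts = sums
    if z < 1.0:
        counts = rng.binomial(counts, z)
    return counts.astype(np.int64)


def sample_culture(m: float, b: float, z: float, rng: np.random.Generator) -> int:
    """Plated mutant count of a single culture (see :func:`sample_counts`)."""
    return int(sample_counts(m, b, z, 1, rng)[0])


def simulate_assay(
    m: float,
    b: float,
    z: float,
    n_cultures: int,
    plated_mean: float = DEFAULT_PLATED_MEAN,
    cv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> FluctuationDataset:
    """A full synthetic assay: mutant counts plus plated cell numbers.

    ``cv`` is the coefficient of variation of the (lognormal) plated cell
    numbers across cultures; ``cv = 0`` gives identical cell numbers.
    """
    _validate(m, b, z)
    if plated_mean <= 0:
        raise InvalidParameterError("plated_mean must be > 0")
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    counts = sample_counts(m, b, z, n_cultures, rng)
    if cv == 0.0:
        cells = np.full(n_cultures, float(plated_mean))
    else:
        sigma2 = math.log1p(cv * cv)
        mu_log = math.log(plated_mean) - sigma2 / 2.0
        cells = rng.lognormal(mean=mu_log, sigma=math.sqrt(sigma2), size=n_cultures)
    return FluctuationDataset(counts, cells, source="<simulated>")


def direct_generation_sim(
    mu: float,
    n_generations: int,
    n0: int,
    rng: np.random.Generator,
    size: Optional[int] = None,
):
    """First-principles fluctuation simulation by synchronous doublings (b = 1).

    The wild-type population doubles each generation from ``n0`` cells;
    mutations strike newborn cells, ``Poisson(mu * cells_born)`` per
    generation, and a mutation in generation ``i`` (of ``g``) yields a final
    clone of ``2**(g - i)`` cells.  The expected number of mutation events
    is ``mu * (n0 * 2**g - n0)``, so choose ``mu`` as ``m / N_final``.

    Returns a single culture's mutant count, or an array of ``size``
    independent cultures when ``size`` is given.
    """
    if mu < 0:
        raise InvalidParameterError("mutation rate mu must be >= 0")
    if n_generations < 1 or n0 < 1:
        raise InvalidParameterError("need n_generations >= 1 and n0 >= 1")
    n_final = n0 << n_generations
    if n_final > 2**53:
        raise InvalidParameterError("population size overflows double precision")
    if mu * n_final > 50:
        raise InvalidParameterError(
            "mu * N_final too large for the no-double-mutant approximation"
        )
    n_draws = 1 if size is None else size
    total = np.zeros(n_draws, dtype=np.int64)
    for i in range(1, n_generations + 1):
        born = n0 << (i - 1)
        n_mut = rng.poisson(mu * born, size=n_draws)
        total += n_mut.astype(np.int64) << (n_generations - i)
    return int(total[0]) if size is None else total


def binned_tv_distance(
    counts: np.ndarray, m: float, b: float, cap: int = 2**14
) -> float:
    """Total-variation distance between sampled counts and the Panjer pmf.

    Computed on a dyadic partition {0}, {1}, {2,3}, {4..7}, ..., tail: at
    heavy-tailed (m, b) the integer-resolution empirical pmf never resolves
    below Monte-Carlo noise at feasible sample sizes, while dyadic bins make
    the distance an honest measure of sampler/recursion agreement.
    """
    counts = np.asarray(counts)
    pmf = mutant_count_pmf(m, b, cap - 1)
    edges = np.array([0, 1] + [2**k for k in range(1, cap.bit_length())])
    p_bins = [pmf[0]] + [
        float(pmf[edges[i] : edges[i + 1]].sum()) for i in range(1, len(edges) - 1)
    ]
    p_bins.append(max(0.0, 1.0 - float(pmf.sum())))
    f_bins = [float(np.mean(counts == 0))] + [
        float(np.mean((counts >= edges[i]) & (counts < edges[i + 1])))
        for i in range(1, len(edges) - 1)
    ]
    f_bins.append(float(np.mean(counts >= cap)))
    return 0.5 * float(np.abs(np.array(p_bins) - np.array(f_bins)).sum())


@dataclass(frozen=True)
class SimulationSpec:
    """Grid description for a dispersion study.

    Defaults mirror the standard benchmark for this estimator: every
    combination of m in {1, 2, 4, 8} and b in {0.5, 1, 2}, assays of 16 to
    384 parallel cultures, 200 replicates per grid cell, full plating.
    """

    m_values: Sequence[float] = (1.0, 2.0, 4.0, 8.0)
    b_values: Sequence[float] = (0.5, 1.0, 2.0)
    n_cultures: Sequence[int] = (16, 32, 48, 96, 192, 384)
    replicates: int = 200
    z: float = 1.0
    plated_mean: float = DEFAULT_PLATED_MEAN
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.m_values):
            raise InvalidParameterError("all m values must be >= 0")
        if any(b <= 0 for b in self.b_values):
            raise InvalidParameterError("all b values must be > 0")
        if not (0.0 < self.z <= 1.0):
            raise InvalidParameterError("z must be in (0, 1]")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")


@dataclass(frozen=True)
class DispersionStudyResult:
    """Long-format estimates plus per-cell 95% dispersion ellipses.

    ``table`` columns: m_true, b_true, n_cultures, rep, m_hat, b_hat
    (NaN where a replicate's estimation failed).  ``ellipses`` columns:
    the grid cell, the mean vector and covariance of (m_hat, b_hat), and
    ``area95`` — the area of the 95% concentration ellipse,
    ``pi * chi2_{2,0.95} * sqrt(det cov)``.
    """

    table: pd.DataFrame
    ellipses: pd.DataFrame


def _ellipse_area(cov: np.ndarray, level: float = 0.95) -> float:
    det = float(np.linalg.det(cov))
    if det < 0:
        det = 0.0
    return math.pi * stats.chi2.ppf(level, df=2) * math.sqrt(det)


def dispersion_study(
    spec: SimulationSpec, config: Optional[gf.GFConfig] = None
) -> DispersionStudyResult:
    """Estimator recovery over the (m, b, n_cultures) grid.

    All randomness flows from ``spec.seed``; identical spec gives a
    bit-identical table.  Replicates whose estimation fails (fitness not
    identifiable at very small assays) are recorded as NaN, never aborted.
    """
    config = config or gf.GFConfig()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for m_true in spec.m_values:
        for b_true in spec.b_values:
            for n in spec.n_cultures:
                for rep in range(spec.replicates):
                    counts = sample_counts(m_true, b_true, spec.z, n, rng)
                    try:
                        b_hat = gf.estimate_b(counts, config)
                        m_hat = gf.estimate_m(counts, b_hat, config)
                    except EstimationError:
                        m_hat, b_hat = math.nan, math.nan
                    rows.append((m_true, b_true, n, rep, m_hat, b_hat))
    table = pd.DataFrame(
        rows, columns=["m_true", "b_true", "n_cultures", "rep", "m_hat", "b_hat"]
    )
    ell_rows = []
    for (m_true, b_true, n), grp in table.groupby(["m_true", "b_true", "n_cultures"]):
        ok = grp.dropna(subset=["m_hat", "b_hat"])
        if len(ok) >= 3:
            mean_m, mean_b = float(ok["m_hat"].mean()), float(ok["b_hat"].mean())
            cov = np.cov(ok["m_hat"], ok["b_hat"], ddof=1)
            area = _ellipse_area(cov)
            cov_mm, cov_mb, cov_bb = cov[0, 0], cov[0, 1], cov[1, 1]
        else:
            mean_m = mean_b = cov_mm = cov_mb = cov_bb = area = math.nan
        ell_rows.append(
            (m_true, b_true, n, len(ok), mean_m, mean_b, cov_mm, cov_mb, cov_bb, area)
        )
    ellipses = pd.DataFrame(
        ell_rows,
        columns=[
            "m_true",
            "b_true",
            "n_cultures",
            "n_ok",
            "mean_m",
            "mean_b",
            "cov_mm",
            "cov_mb",
            "cov_bb",
            "area95",
        ],
    )
    return DispersionStudyResult(table=table, ellipses=ellipses)
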