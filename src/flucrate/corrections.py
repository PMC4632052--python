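"""Plating-efficiency correction and conversion of m to mutation rates.

When only a fraction ``z`` of each culture is plated on selective medium,
mutants in the unplated fraction go unobserved and the fitted mean number of
mutations per culture underestimates the truth.  The Stewart correction
inflates the estimate:

    m_corr = m * (z - 1) / (z * ln z),        0 < z < 1,

with the factor -> 1 as z -> 1 (removable singularity) and -> infinity as
z -> 0+.  Mutation rates are then

    mu      = m / mean plated cells per culture      (N_p-bar)
    mu_corr = m_corr / mean total cells per culture  (N_t-bar = N_p-bar / z)

Users enter *plated* cells, so the mean total culture size is derived as
``N_t-bar = N_p-bar / z`` — worth keeping in mind when z comes from an
imprecise dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import FluctuationDataset
from .exceptions import InvalidParameterError

__all__ = [
    "DatasetSummary",
    "stewart_factor",
    "correct_m",
    "mutation_rate",
    "summarize_dataset",
]


@dataclass(frozen=True)
class DatasetSummary:
    """Cell-number summary of a fluctuation assay.

    Attributes
    ----------
    n_cultures
        Number of parallel cultures.
    plated_mean
        Mean plated cells per culture (N_p-bar).
    total_mean
        Mean total cells per culture, N_t-bar = N_p-bar / z.
    plated_sd
        Sample standard deviation (n-1 denominator) of plated cells (sigma_Nc).
    z
        Plating efficiency used to derive ``total_mean``.
    """

    n_cultures: int
    plated_mean: float
    total_mean: float
    plated_sd: float
    z: float


def _check_z(z: float) -> None:
    if not (0.0 < z <= 1.0):
        raise InvalidParameterError(f"plating efficiency z must be in (0, 1], got {z!r}")


def stewart_factor(z: float) -> float:
    """Multiplicative correction ``(z - 1) / (z * ln z)``; exactly 1 at z = 1."""
    _check_z(z)
    if z == 1.0:
        return 1.0
    return (z - 1.0) / (z * math.log(z))


def correct_m(m: float, z: float) -> float:
    """Plating-efficiency-corrected mean mutations per culture, ``m_corr >= m``."""
    if m < 0:
        raise InvalidParameterError(f"m must be >= 0, got {m!r}")
    return m * stewart_factor(z)


def mutation_rate(m: float, mean_cells: float) -> float:
    """Mutations per cell per division: ``m / mean_cells``.

    Pass the mean *plated* cells with the uncorrected m, and the mean *total*
    cells with the corrected m.
    """
    if not (mean_cells > 0):
        raise InvalidParameterError(f"mean cell number must be > 0, got {mean_cells!r}")
    if m < 0:
        raise InvalidParameterError(f"m must be >= 0, got {m!r}")
    return m / mean_cells


def summarize_dataset(dataset: FluctuationDataset, z: float = 1.0) -> DatasetSummary:
    """Cell-number summary: n, N_p-bar, sigma_Nc and the derived N_t-bar."""
    _check_z(z)
    cells = dataset.cells
    plated_mean = float(np.mean(cells))
    plated_sd = float(np.std(cells, ddof=1)) if len(cells) > 1 else 0.0
    return DatasetSummary(
        n_cultures=len(dataset),
        plated_mean=plated_mean,
        total_mean=plated_mean / z,
        plated_sd=plated_sd,
        z=z,
    )
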