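"""Classic published fluctuation-assay datasets, transcribed from the literature.

Only mutant counts printed as individual-culture values in the original
report are included; summary-only tables are not reconstructed.
"""

from __future__ import annotations

import numpy as np

from .dataset import FluctuationDataset

__all__ = ["luria_delbruck_1943"]

# Luria & Delbrück (1943), Genetics 28:491-511, Table 2: number of
# phage-T1-resistant bacteria in individual E. coli cultures.  The five
# experiments whose cultures are listed individually (nos. 1, 10, 11, 15
# and 21; 9 + 8 + 10 + 10 + 5 = 42 cultures) are pooled here, the standard
# sample used when benchmarking joint (m, b) estimators on these data.
_LD_EXPERIMENT_COUNTS = {
    1: (10, 18, 125, 10, 14, 27, 3, 17, 17),
    10: (29, 41, 17, 20, 31, 30, 7, 17),
    11: (30, 10, 40, 45, 183, 12, 173, 23, 57, 51),
    15: (6, 5, 10, 8, 24, 13, 165, 15, 6, 10),
    21: (38, 28, 35, 107, 13),
}

#: Approximate cells per plated sample in the 1943 experiments: 0.2 mL
#: aliquots of cultures grown to ~9e8 cells/mL.  The original table reports
#: culture sizes only to this precision; the inferred mutation rate scales
#: directly with this number.
_LD_CELLS_PER_CULTURE = 1.8e8


def luria_delbruck_1943(cells_per_culture: float = _LD_CELLS_PER_CULTURE) -> FluctuationDataset:
    """Pooled 42-culture phage-resistance assay of Luria & Delbrück (1943).

    Mutant counts are the individual-culture values of Table 2 of the
    original report (experiments 1, 10, 11, 15, 21).  Per-culture plated
    cell numbers were not printed there; all cultures are assigned
    ``cells_per_culture`` (default 1.8e8, see module source), so treat the
    derived rate — though not m or b — as order-of-magnitude.
    """
    counts = np.concatenate([np.asarray(v) for v in _LD_EXPERIMENT_COUNTS.values()])
    cells = np.full(len(counts), float(cells_per_culture))
    return FluctuationDataset(counts, cells, source="luria_delbruck_1943")
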