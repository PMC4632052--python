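"""Fluctuation-assay dataset container and the two-column text dialect.

The input format is the paste-friendly dialect used by fluctuation-assay
calculators: one row per parallel culture, two whitespace- or tab-separated
fields, ``N_mutants`` (mutant colonies on the selective plate, integer >= 0)
and ``N_cells`` (viable cells plated from that culture, > 0, scientific
notation allowed).  Blank lines, Windows line endings and one optional
header row are tolerated.
"""

from __future__ import annotations

import numpy as np

from .exceptions import EmptyDatasetError, ParseError, ValidationError

__all__ = ["FluctuationDataset", "parse_counts", "serialize_counts"]


class FluctuationDataset:
    """Per-culture (mutant count, plated cells) pairs — the experimental unit.

    Attributes
    ----------
    mutants : ndarray of int64
        Mutant colonies counted on each selective plate.
    cells : ndarray of float
        Viable cells plated from each culture.
    source : str
        Provenance note (filename, "<stdin>", ...).
    """

    __slots__ = ("mutants", "cells", "source")

    def __init__(self, mutants, cells, source: str = "<memory>"):
        mutants = np.asarray(mutants)
        cells = np.asarray(cells, dtype=float)
        if mutants.ndim != 1 or cells.ndim != 1 or len(mutants) != len(cells):
            raise ValidationError("mutants and cells must be 1-d arrays of equal length")
        if len(mutants) == 0:
            raise EmptyDatasetError("a fluctuation dataset needs at least one culture")
        if np.any(mutants != np.floor(mutants)) or np.any(mutants < 0):
            raise ValidationError("mutant counts must be non-negative integers")
        if np.any(~np.isfinite(cells)) or np.any(cells <= 0):
            raise ValidationError("plated cell numbers must be positive and finite")
        self.mutants = mutants.astype(np.int64)
        self.cells = cells
        self.source = source
        self.mutants.setflags(write=False)
        self.cells.setflags(write=False)

    def __len__(self) -> int:
        return len(self.mutants)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FluctuationDataset)
            and np.array_equal(self.mutants, other.mutants)
            and np.array_equal(self.cells, other.cells)
        )

    def __repr__(self) -> str:
        return (
            f"FluctuationDataset(n={len(self)}, "
            f"max_mutants={int(self.mutants.max())}, source={self.source!r})"
        )


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def parse_counts(text: str, source: str = "<memory>") -> FluctuationDataset:
    """Parse the two-column paste dialect into a :class:`FluctuationDataset`.

    A single leading header row is skipped when either of its fields is
    non-numeric.  Errors name the offending 1-based line number.
    """
    if not text or not text.strip():
        raise EmptyDatasetError("empty input: expected rows of 'N_mutants N_cells'")
    mutants: list[int] = []
    cells: list[float] = []
    first_data_row = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ParseError(
                f"line {lineno}: expected 2 fields (N_mutants N_cells), got {len(tokens)}"
            )
        if first_data_row and not (_is_number(tokens[0]) and _is_number(tokens[1])):
            first_data_row = False  # header row
            continue
        first_data_row = False
        for tok in tokens:
            if not _is_number(tok):
                raise ParseError(f"line {lineno}: non-numeric field {tok!r}")
        n_mut, n_cells = float(tokens[0]), float(tokens[1])
        if n_mut < 0 or n_mut != int(n_mut):
            raise ValidationError(
                f"line {lineno}: N_mutants must be a non-negative integer, got {tokens[0]!r}"
            )
        if n_cells <= 0:
            raise ValidationError(f"line {lineno}: N_cells must be > 0, got {tokens[1]!r}")
        mutants.append(int(n_mut))
        cells.append(n_cells)
    if not mutants:
        raise EmptyDatasetError("no data rows found")
    return FluctuationDataset(mutants, cells, source=source)


def serialize_counts(dataset: FluctuationDataset) -> str:
    """Normalize a dataset to tab-delimited two-column text (lossless)."""
    # repr() is the shortest digit string that round-trips the float exactly
    lines = [f"{int(m)}\t{float(c)!r}" for m, c in zip(dataset.mutants, dataset.cells)]
    return "\n".join(lines) + "\n"
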