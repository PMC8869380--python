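"""Carbon-source utilization scanning.

For each candidate carbon source and each uptake level, the model grows on a
fixed background medium (amino acids, vitamins, lipid, trace oxygen) with
only that carbon opened among the scanned set; the resulting growth-rate
matrix is the in-silico analogue of a phenotypic carbon-utilization array.
Each row must be non-decreasing in uptake (more substrate never hurts an LP
maximum), and the zero-uptake column is identical across carbons because the
constraint sets coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MetabolicModel
from .errors import MediumError
from .fba import solve_fba
from .medium import MediumSpec, apply_medium

__all__ = ["DEFAULT_UPTAKE_LEVELS", "GrowthMatrix", "scan_carbons", "rank_carbons"]

#: Uptake grid in mmol gDCW^-1 h^-1.
DEFAULT_UPTAKE_LEVELS = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 20.0, 24.0)


@dataclass(frozen=True)
class GrowthMatrix:
    carbons: tuple[str, ...]
    uptake_levels: tuple[float, ...]
    growth: np.ndarray  # carbons x levels, h^-1

    def row(self, carbon: str) -> np.ndarray:
        return self.growth[self.carbons.index(carbon)]


def scan_carbons(
    model: MetabolicModel,
    carbons: list[str] | tuple[str, ...],
    levels: tuple[float, ...] = DEFAULT_UPTAKE_LEVELS,
    background: MediumSpec | None = None,
) -> GrowthMatrix:
    """One FBA solve per (carbon, uptake level).

    ``background`` supplies the non-carbon nutrients; any scanned carbon it
    names is closed before opening the current one, so carbons are tested
    strictly one at a time.
    """
    if background is None:
        background = MediumSpec({}, "empty")
    exchange_ids = {r.id for r in model.reactions if r.kind == "exchange"}
    unknown = sorted(set(carbons) - exchange_ids)
    if unknown:
        raise MediumError(f"unknown carbon exchanges: {unknown}")
    base = background.without(carbons)
    growth = np.zeros((len(carbons), len(levels)))
    for i, carbon in enumerate(carbons):
        for j, level in enumerate(levels):
            medium = base.with_uptake(carbon, level)
            sol = solve_fba(apply_medium(model, medium), validate=False)
            growth[i, j] = sol.growth_rate if sol.optimal else 0.0
    return GrowthMatrix(tuple(carbons), tuple(float(v) for v in levels), growth)


def rank_carbons(matrix: GrowthMatrix, at_level: float) -> list[tuple[str, float]]:
    """Carbons in descending growth order at one uptake level; ties broken
    lexicographically by carbon id."""
    if at_level not in matrix.uptake_levels:
        raise ValueError(
            f"uptake level {at_level!r} not scanned; levels are "
            f"{matrix.uptake_levels}"
        )
    j = matrix.uptake_levels.index(at_level)
    pairs = [(c, float(matrix.growth[i, j])) for i, c in enumerate(matrix.carbons)]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))
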