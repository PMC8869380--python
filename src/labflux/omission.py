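"""Single and double nutrient-omission analysis.

A nutrient is *essential* when removing its uptake abolishes growth
(LP infeasible or optimum below the zero tolerance — a medium missing a
biomass precursor usually yields an optimum of exactly zero rather than an
infeasible LP). It is *preferable* when growth survives but falls below
0.005 h^-1, and *non-essential* otherwise (strict inequality at the
threshold: growth of exactly 0.005 classifies preferable).

Double omission scans unordered pairs — by default only pairs of
single-omission-viable nutrients — and flags *synthetic-essential* pairs:
both members individually dispensable, the joint omission lethal. That is
the signature of substitutable nutrients (one convertible into the other,
e.g. glutamine/glutamate via glutamine synthetase).

``omission_factor`` scales the omitted nutrient's uptake instead of closing
it: 0 (default) is a true omission; 0.5 halves the rate for sensitivity-
style scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .core import MetabolicModel
from .errors import MediumError
from .fba import solve_fba
from .medium import MediumSpec, apply_medium

__all__ = [
    "PANEL_SIZE", "NutrientPanel", "OmissionOutcome", "classify_growth",
    "single_omission", "double_omission",
    "ESSENTIAL", "PREFERABLE", "NON_ESSENTIAL",
    "GROWTH_ZERO_TOL", "PREFERABLE_THRESHOLD",
]

ESSENTIAL = "essential"
PREFERABLE = "preferable"
NON_ESSENTIAL = "non_essential"

#: Growth below this is treated as zero (essential), h^-1.
GROWTH_ZERO_TOL = 1e-9
#: Growth below this (but above zero) marks a preferable nutrient, h^-1.
PREFERABLE_THRESHOLD = 0.005

#: The canonical omission panel covers the 20 proteinogenic amino acids plus
#: 5 B vitamins (thiamin, nicotinate, pantothenate, pyridoxamine, biotin).
PANEL_SIZE = 25


@dataclass(frozen=True)
class NutrientPanel:
    """Ordered panel of nutrient exchange ids to omit (exactly 25)."""

    exchange_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.exchange_ids) != PANEL_SIZE:
            raise ValueError(
                f"nutrient panel must list exactly {PANEL_SIZE} exchanges, "
                f"got {len(self.exchange_ids)}"
            )
        if len(set(self.exchange_ids)) != len(self.exchange_ids):
            raise ValueError("nutrient panel contains duplicates")


@dataclass(frozen=True)
class OmissionOutcome:
    omitted: frozenset[str]
    growth_rate: float  # NaN when the LP is infeasible
    classification: str
    synthetic_essential: bool = False


def classify_growth(
    growth: float,
    feasible: bool = True,
    zero_tol: float = GROWTH_ZERO_TOL,
    preferable_threshold: float = PREFERABLE_THRESHOLD,
) -> str:
    """Pure classification rule on a growth rate."""
    if not feasible or growth < zero_tol:
        return ESSENTIAL
    if growth < preferable_threshold:
        return PREFERABLE
    return NON_ESSENTIAL


def _check_panel(panel: NutrientPanel, base: MediumSpec) -> None:
    missing = [x for x in panel.exchange_ids if base.uptakes.get(x, 0.0) <= 0]
    if missing:
        raise MediumError(
            f"panel nutrients absent from base medium (or at zero uptake): {missing}"
        )


def _growth_under(model: MetabolicModel, medium: MediumSpec) -> tuple[float, bool]:
    sol = solve_fba(apply_medium(model, medium), validate=False)
    if sol.status == "infeasible":
        return float("nan"), False
    return sol.growth_rate, True


def single_omission(
    model: MetabolicModel,
    panel: NutrientPanel,
    base: MediumSpec,
    omission_factor: float = 0.0,
) -> list[OmissionOutcome]:
    """Omit (or down-scale) each panel nutrient in turn; classify growth.

    Returns outcomes in panel order. Requires every panel nutrient present
    at positive uptake in the base medium.
    """
    _check_panel(panel, base)
    outcomes = []
    for nutrient in panel.exchange_ids:
        growth, feasible = _growth_under(model, base.scaled(nutrient, omission_factor))
        outcomes.append(OmissionOutcome(
            omitted=frozenset([nutrient]),
            growth_rate=growth,
            classification=classify_growth(growth, feasible),
        ))
    return outcomes


def double_omission(
    model: MetabolicModel,
    panel: NutrientPanel,
    base: MediumSpec,
    restrict_to: Iterable[str] | None = None,
    omission_factor: float = 0.0,
    singles: Sequence[OmissionOutcome] | None = None,
) -> list[OmissionOutcome]:
    """Omit nutrients two at a time and flag synthetic-essential pairs.

    By default the pair search space is the single-omission viable
    (non-essential or preferable) nutrients; pass ``restrict_to`` to scan an
    explicit subset, e.g. the full panel. Pairs containing a single-essential
    nutrient are trivially lethal and never flagged synthetic-essential.
    Precomputed ``singles`` may be supplied to avoid re-running them.
    """
    _check_panel(panel, base)
    if singles is None:
        singles = single_omission(model, panel, base, omission_factor)
    single_class = {next(iter(o.omitted)): o.classification for o in singles}
    if restrict_to is None:
        candidates = [x for x in panel.exchange_ids
                      if single_class[x] != ESSENTIAL]
    else:
        candidates = [x for x in panel.exchange_ids if x in set(restrict_to)]
    outcomes = []
    for a, b in combinations(candidates, 2):
        medium = base.scaled(a, omission_factor).scaled(b, omission_factor)
        growth, feasible = _growth_under(model, medium)
        classification = classify_growth(growth, feasible)
        both_viable = (single_class[a] != ESSENTIAL
                       and single_class[b] != ESSENTIAL)
        outcomes.append(OmissionOutcome(
            omitted=frozenset([a, b]),
            growth_rate=growth,
            classification=classification,
            synthetic_essential=(classification == ESSENTIAL and both_viable),
        ))
    return outcomes
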