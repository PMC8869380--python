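"""Flux balance analysis, percent-error validation and GAM fitting.

FBA maximizes the biomass objective flux subject to the steady-state mass
balance ``S v = 0`` and the flux bounds; the optimum is the predicted
specific growth rate in h^-1. The LP is solved with HiGHS via
:func:`scipy.optimize.linprog`, which is deterministic on a single thread.

Only the objective value is promised to be unique: the flux vector of a
degenerate LP is one optimal vertex among many, and downstream analyses
consume only the objective.

GAM fitting exploits that growth is monotone non-increasing in the
growth-associated ATP maintenance: bisection on GAM, reassembling the
biomass reaction at each iterate, converges to the GAM whose simulated
growth matches the measurement.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .core import MetabolicModel, stoichiometric_matrix, validate_model
from .errors import FitError, LabfluxError, SolverError
from .medium import BiomassComposition, MediumSpec, apply_medium, assemble_biomass

__all__ = ["FluxSolution", "solve_fba", "percent_error", "fit_gam",
           "FEASIBILITY_TOL", "REPORT_TOL"]

#: LP feasibility tolerance (bound violations), standard double precision.
FEASIBILITY_TOL = 1e-9
#: Tolerance for reporting/comparing objective values.
REPORT_TOL = 1e-6


@dataclass(frozen=True)
class FluxSolution:
    """Outcome of one FBA solve.

    ``growth_rate`` is the objective (biomass) flux for optimal solves and
    NaN otherwise; ``fluxes`` maps every reaction id to its flux in the
    returned optimal vertex.
    """

    status: str  # optimal | infeasible | unbounded | failed
    growth_rate: float
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_reaction_id: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_LINPROG_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_fba(model: MetabolicModel, validate: bool = True) -> FluxSolution:
    """Maximize the objective reaction's flux subject to S v = 0 and bounds.

    Solver failures surface as status ``"failed"`` (never a silent zero);
    infeasible and unbounded statuses are reported faithfully.
    """
    if validate:
        validate_model(model)
    sm = stoichiometric_matrix(model)
    n = len(sm.reaction_ids)
    c = np.zeros(n)
    c[sm.reaction_ids.index(model.objective_reaction_id)] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        c, A_eq=sm.S, b_eq=np.zeros(len(sm.metabolite_ids)), bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _LINPROG_STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, growth_rate=float("nan"),
                            objective_reaction_id=model.objective_reaction_id)
    fluxes = dict(zip(sm.reaction_ids, (float(v) for v in res.x)))
    return FluxSolution(
        status="optimal", growth_rate=float(-res.fun), fluxes=fluxes,
        objective_reaction_id=model.objective_reaction_id,
    )


def percent_error(simulated: float, measured: float) -> float:
    """``|simulated - measured| / measured * 100``; measured must be > 0."""
    if measured <= 0:
        raise LabfluxError(f"measured growth must be > 0, got {measured!r}")
    return abs(simulated - measured) / measured * 100.0


def fit_gam(
    model: MetabolicModel,
    composition: BiomassComposition,
    medium: MediumSpec,
    measured_growth: float,
    bounds: tuple[float, float] = (0.0, 100.0),
    tol: float = 1e-8,
    max_iter: int = 100,
    **biomass_kwargs,
) -> float:
    """Fit growth-associated maintenance by monotone bisection.

    At each iterate the biomass reaction is reassembled from ``composition``
    with the candidate GAM (keeping the model's objective reaction id) and
    FBA is run under ``medium``. Requires growth at ``gam_lo`` to bracket the
    measurement from above and growth at ``gam_hi`` from below. Returns the
    GAM whose simulated growth is within ``tol`` (h^-1) of the measurement.
    """
    if measured_growth <= 0:
        raise FitError(f"measured growth must be > 0, got {measured_growth!r}")
    gam_lo, gam_hi = bounds
    if not gam_lo < gam_hi:
        raise FitError(f"invalid GAM bracket {bounds!r}")
    constrained = apply_medium(model, medium)

    def growth_at(gam: float) -> float:
        candidate = constrained.copy()
        comp = dataclasses.replace(composition, gam=gam)
        biomass = assemble_biomass(
            comp, reaction_id=candidate.objective_reaction_id, **biomass_kwargs
        )
        for i, r in enumerate(candidate.reactions):
            if r.id == candidate.objective_reaction_id:
                candidate.reactions[i] = biomass
                break
        sol = solve_fba(candidate, validate=False)
        if sol.status == "infeasible":
            raise FitError(f"model infeasible at GAM {gam!r}")
        if not sol.optimal:
            raise SolverError(f"solver status {sol.status!r} at GAM {gam!r}")
        return sol.growth_rate

    mu_lo = growth_at(gam_lo)
    mu_hi = growth_at(gam_hi)
    if abs(mu_lo - measured_growth) <= tol:
        return gam_lo
    if abs(mu_hi - measured_growth) <= tol:
        return gam_hi
    if not (mu_lo >= measured_growth >= mu_hi):
        raise FitError(
            f"measured growth {measured_growth!r} not bracketed: growth at "
            f"GAM {gam_lo!r} is {mu_lo!r}, at GAM {gam_hi!r} is {mu_hi!r}"
        )
    lo, hi = gam_lo, gam_hi
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mu = growth_at(mid)
        if abs(mu - measured_growth) <= tol:
            return mid
        if mu > measured_growth:
            lo = mid  # growth too high -> GAM too cheap -> move right
        else:
            hi = mid
    return mid


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """Max-norm of S v for an optimal solution; a solver sanity check."""
    if not solution.optimal:
        return math.nan
    sm = stoichiometric_matrix(model)
    v = np.array([solution.fluxes[rid] for rid in sm.reaction_ids])
    return float(np.max(np.abs(sm.S @ v))) if len(v) else 0.0
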