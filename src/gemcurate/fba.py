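"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA solves ``maximize c.v  s.t.  S.v = 0,  lb <= v <= ub`` — the classical
steady-state constraint-based formulation — with the HiGHS solvers behind
:func:`scipy.optimize.linprog`.  FVA minimizes and maximizes each reaction
flux over the same polytope, optionally pinned near a prior optimum.

Only the optimal objective value is canonical: linear programs routinely
have degenerate alternative optima, so the returned flux vector is *one*
optimal solution, not a unique one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .network import (
    DEFAULT_BOUND,
    Network,
    Reaction,
    build_stoichiometric_matrix,
)

__all__ = [
    "BiomassSpec",
    "ScenarioConfig",
    "FluxResult",
    "FluxRange",
    "attach_biomass",
    "fba_optimize",
    "flux_variability",
    "DEFAULT_TOL",
]

#: Default tolerance on LP optima and steady-state residuals.
DEFAULT_TOL = 1e-9

_LP_METHOD = "highs"


@dataclass
class BiomassSpec:
    """Biomass objective: consumed precursors carry negative coefficients."""

    components: dict[str, float]
    objective_id: str = "bio1"

    def __post_init__(self) -> None:
        if not any(c < 0 for c in self.components.values()):
            raise ValueError(
                "biomass spec needs at least one consumed precursor "
                "(negative coefficient)"
            )


@dataclass
class ScenarioConfig:
    """Named set of bound overrides (e.g. photon/CO2/O2 exchange limits)."""

    name: str
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.bound_overrides.items():
            if lb > ub:
                raise ValueError(f"override for {rid!r}: lower > upper")


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded | error
    objective_value: float | None
    fluxes: dict[str, float]
    residual: float | None
    solver: str = "scipy-highs"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "objective_value": self.objective_value,
            "fluxes": self.fluxes,
            "residual": self.residual,
            "solver": self.solver,
        }


@dataclass
class FluxRange:
    minimum: float
    maximum: float
    indeterminate: bool = False


def _bounds_vector(
    net: Network, scenario: ScenarioConfig | None = None
) -> list[tuple[float, float]]:
    overrides = scenario.bound_overrides if scenario is not None else {}
    for rid in overrides:
        if rid not in net.reactions:
            raise KeyError(f"scenario overrides unknown reaction {rid!r}")
    return [
        overrides.get(rid, (rxn.lower_bound, rxn.upper_bound))
        for rid, rxn in net.reactions.items()
    ]


def _solve(
    c: np.ndarray,
    A_eq: sp.spmatrix,
    bounds: list[tuple[float, float]],
    A_ub: sp.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds,
        method=_LP_METHOD,
    )


def attach_biomass(net: Network, spec: BiomassSpec) -> Network:
    """Return a copy of ``net`` with an irreversible biomass reaction added."""
    if spec.objective_id in net.reactions:
        raise ValueError(f"objective id {spec.objective_id!r} already exists")
    missing = [m for m in spec.components if m not in net.metabolites]
    if missing:
        raise ValueError(f"biomass components missing from network: {missing}")
    out = net.copy()
    out.add_reaction(
        Reaction(
            id=spec.objective_id,
            name="biomass objective",
            stoichiometry=dict(spec.components),
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
    )
    return out


def fba_optimize(
    net: Network,
    objective_id: str,
    scenario: ScenarioConfig | None = None,
    tol: float = DEFAULT_TOL,
) -> FluxResult:
    """Maximize the flux of ``objective_id`` at steady state."""
    if objective_id not in net.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in network")
    S = build_stoichiometric_matrix(net)
    rids = list(net.reactions)
    c = np.zeros(len(rids))
    c[rids.index(objective_id)] = -1.0  # linprog minimizes
    res = _solve(c, S, _bounds_vector(net, scenario))
    if res.status == 2:
        return FluxResult("infeasible", None, {}, None)
    if res.status == 3:
        return FluxResult("unbounded", None, {}, None)
    if not res.success:
        return FluxResult("error", None, {}, None)
    v = res.x
    residual = float(np.abs(S @ v).max()) if len(v) else 0.0
    return FluxResult(
        status="optimal",
        objective_value=float(-res.fun),
        fluxes=dict(zip(rids, (float(x) for x in v))),
        residual=residual,
    )


def flux_variability(
    net: Network,
    reactions: Iterable[str] | None = None,
    frac_of_optimum: float = 0.0,
    objective_id: str | None = None,
    scenario: ScenarioConfig | None = None,
    tol: float = DEFAULT_TOL,
) -> dict[str, FluxRange]:
    """Per-reaction attainable flux range over the steady-state polytope.

    With ``frac_of_optimum > 0`` an objective constraint
    ``v_obj >= frac * optimum`` is added (requires ``objective_id``).
    An LP failure on a subproblem flags that reaction ``indeterminate``
    rather than silently reporting a zero range.
    """
    S = build_stoichiometric_matrix(net)
    rids = list(net.reactions)
    idx = {rid: i for i, rid in enumerate(rids)}
    targets = list(reactions) if reactions is not None else rids
    bounds = _bounds_vector(net, scenario)
    A_ub = None
    b_ub = None
    if frac_of_optimum > 0:
        if objective_id is None:
            raise ValueError("frac_of_optimum > 0 requires objective_id")
        opt = fba_optimize(net, objective_id, scenario=scenario, tol=tol)
        if opt.status != "optimal":
            raise RuntimeError(
                f"FVA with frac_of_optimum: prior FBA status {opt.status}"
            )
        row = np.zeros(len(rids))
        row[idx[objective_id]] = -1.0  # -v_obj <= -frac*opt
        A_ub = sp.csr_matrix(row)
        b_ub = np.array([-frac_of_optimum * opt.objective_value])
    out: dict[str, FluxRange] = {}
    for rid in targets:
        c = np.zeros(len(rids))
        c[idx[rid]] = 1.0
        lo = _solve(c, S, bounds, A_ub, b_ub)
        hi = _solve(-c, S, bounds, A_ub, b_ub)
        if not (lo.success and hi.success):
            out[rid] = FluxRange(np.nan, np.nan, indeterminate=True)
            continue
        out[rid] = FluxRange(float(lo.fun), float(-hi.fun))
    return out
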