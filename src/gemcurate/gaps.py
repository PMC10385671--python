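"""Network-pathology classification: gap finding and blocked reactions.

A reconstruction draft typically contains metabolites that cannot carry
steady-state production or consumption flux.  This module partitions them
into the classical gap-find classes:

* **root no-production** — no reaction can ever produce the metabolite in any
  orientation its bounds permit (a purely topological condition);
* **downstream no-production** — topologically producible, but the linear
  program routing its production into a temporary sink attains no flux above
  tolerance (the pathology is inherited from upstream);
* **root no-consumption / upstream no-consumption** — the symmetric classes
  on the consumption side;
* **blocked reactions** — reactions whose flux-variability range is {0}.

The canonical producibility test is LP-based; a boolean reachability
propagation from exchange-touched seeds is available as a fast pre-filter
(anything it cannot reach is guaranteed non-producible, never the converse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .fba import DEFAULT_TOL, _bounds_vector, _solve, flux_variability
from .network import DEFAULT_BOUND, Network, build_stoichiometric_matrix

__all__ = [
    "GapReport",
    "producibility_test",
    "production_gaps",
    "classify_gaps",
    "find_blocked_reactions",
    "active_blocked_fractions",
    "reachable_metabolites",
]


@dataclass
class GapReport:
    root_no_production: set[str] = field(default_factory=set)
    downstream_no_production: set[str] = field(default_factory=set)
    root_no_consumption: set[str] = field(default_factory=set)
    upstream_no_consumption: set[str] = field(default_factory=set)
    blocked_reactions: set[str] = field(default_factory=set)
    indeterminate_reactions: set[str] = field(default_factory=set)
    tol: float = DEFAULT_TOL

    @property
    def all_gaps(self) -> set[str]:
        """Union of the production-side gap classes."""
        return self.root_no_production | self.downstream_no_production

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "root_no_production": sorted(self.root_no_production),
            "downstream_no_production": sorted(self.downstream_no_production),
            "root_no_consumption": sorted(self.root_no_consumption),
            "upstream_no_consumption": sorted(self.upstream_no_consumption),
            "all_gaps": sorted(self.all_gaps),
            "blocked_reactions": sorted(self.blocked_reactions),
            "indeterminate_reactions": sorted(self.indeterminate_reactions),
            "tol": self.tol,
            "counts": {
                "allGaps": len(self.all_gaps),
                "rootGaps": len(self.root_no_production),
                "downstreamGaps": len(self.downstream_no_production),
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _can_produce(rxn, met_id: str) -> bool:
    """Can the reaction produce ``met_id`` in some bound-permitted direction?"""
    coef = rxn.stoichiometry.get(met_id)
    if coef is None:
        return False
    return (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0)


def _can_consume(rxn, met_id: str) -> bool:
    coef = rxn.stoichiometry.get(met_id)
    if coef is None:
        return False
    return (coef < 0 and rxn.upper_bound > 0) or (coef > 0 and rxn.lower_bound < 0)


def _sink_lp(
    net: Network,
    met_ids: list[str],
    tol: float,
    side: str,
) -> set[str]:
    """Metabolites in ``met_ids`` that can carry flux into (side='production')
    or out of (side='consumption') a temporary bounded sink at steady state.

    Solved in batches: one sink column per undecided metabolite, maximizing
    the summed sink flux; metabolites whose sink is active above tolerance
    are settled, and the LP is re-run over the remainder until it stalls.
    Correctness: if a metabolite is individually producible, the individual
    certificate is feasible for the batch LP, so the batch optimum stays
    above tolerance until every producible metabolite has been settled.
    """
    S = build_stoichiometric_matrix(net).tocsc()
    met_idx = net.metabolite_index()
    bounds = _bounds_vector(net)
    n_rxn = len(bounds)
    sign = -1.0 if side == "production" else 1.0
    undecided = list(met_ids)
    feasible: set[str] = set()
    while undecided:
        k = len(undecided)
        cols = sp.csc_matrix(
            (
                [sign] * k,
                ([met_idx[m] for m in undecided], list(range(k))),
            ),
            shape=(S.shape[0], k),
        )
        A = sp.hstack([S, cols], format="csc")
        # cap sink fluxes so the batch LP cannot be unbounded
        all_bounds = bounds + [(0.0, 1.0)] * k
        c = np.zeros(n_rxn + k)
        c[n_rxn:] = -1.0
        res = _solve(c, A, all_bounds)
        if not res.success:
            break
        sinks = res.x[n_rxn:]
        newly = [m for m, s in zip(undecided, sinks) if s > tol]
        if not newly:
            if -res.fun > tol:
                # Degenerate optimum spread below per-sink tolerance:
                # settle the remainder with individual LPs.
                for m in undecided:
                    if m in _sink_lp_single(net, m, tol, side, S, met_idx, bounds):
                        feasible.add(m)
            break
        feasible.update(newly)
        undecided = [m for m in undecided if m not in feasible]
    return feasible


def _sink_lp_single(net, met, tol, side, S, met_idx, bounds) -> set[str]:
    sign = -1.0 if side == "production" else 1.0
    col = sp.csc_matrix(
        ([sign], ([met_idx[met]], [0])), shape=(S.shape[0], 1)
    )
    A = sp.hstack([S, col], format="csc")
    c = np.zeros(len(bounds) + 1)
    c[-1] = -1.0
    res = _solve(c, A, bounds + [(0.0, 1.0)])
    if res.success and -res.fun > tol:
        return {met}
    return set()


def producibility_test(
    net: Network, met: str, tol: float = DEFAULT_TOL
) -> bool:
    """LP producibility of a single metabolite.

    True iff a steady-state flux exists that routes production of ``met``
    into a temporary sink with flux above ``tol`` (every other metabolite
    balanced, all bounds respected).  The network is not modified.
    """
    if met not in net.metabolites:
        raise KeyError(f"metabolite {met!r} not in network")
    return met in _sink_lp(net, [met], tol, "production")


def consumability_test(
    net: Network, met: str, tol: float = DEFAULT_TOL
) -> bool:
    """Symmetric test: a temporary source supplies ``met``; can the network
    consume it at steady state?"""
    if met not in net.metabolites:
        raise KeyError(f"metabolite {met!r} not in network")
    return met in _sink_lp(net, [met], tol, "consumption")


def reachable_metabolites(
    net: Network, seeds: Iterable[str] | None = None
) -> set[str]:
    """Boolean fixpoint propagation from exchange-touched seed metabolites.

    A reaction fires once all metabolites on one of its bound-permitted
    consuming sides are reachable; its products become reachable.  The
    complement of the result is a *subset* of the LP-non-producible set
    (reachability ignores flux balance, so it can only over-approximate
    producibility).
    """
    if seeds is None:
        seeds = {
            m
            for rid in net.exchanges
            for m in net.reactions[rid].stoichiometry
        }
    reached = set(seeds)
    changed = True
    while changed:
        changed = False
        for rxn in net.reactions.values():
            directions = []
            if rxn.upper_bound > 0:
                directions.append(1)
            if rxn.lower_bound < 0:
                directions.append(-1)
            for d in directions:
                subs = [m for m, c in rxn.stoichiometry.items() if d * c < 0]
                prods = [m for m, c in rxn.stoichiometry.items() if d * c > 0]
                if all(m in reached for m in subs):
                    new = [m for m in prods if m not in reached]
                    if new:
                        reached.update(new)
                        changed = True
    return reached


def production_gaps(
    net: Network, tol: float = DEFAULT_TOL
) -> tuple[set[str], set[str]]:
    """(root, downstream) no-production sets only — no blocked-reaction scan.

    The fast path for gap-filling candidate evaluation, where only the
    production-side gap count matters.
    """
    root_prod: set[str] = set()
    for mid in net.metabolites:
        if not any(_can_produce(r, mid) for r in net.reactions.values()):
            root_prod.add(mid)
    prod_candidates = [m for m in net.metabolites if m not in root_prod]
    producible = _sink_lp(net, prod_candidates, tol, "production")
    downstream_prod = {m for m in prod_candidates if m not in producible}
    return root_prod, downstream_prod


def classify_gaps(net: Network, tol: float = DEFAULT_TOL) -> GapReport:
    """Partition metabolites into root/downstream no-production and
    root/upstream no-consumption classes; populate blocked reactions."""
    root_prod, downstream_prod = production_gaps(net, tol)
    root_cons: set[str] = set()
    for mid in net.metabolites:
        if not any(_can_consume(r, mid) for r in net.reactions.values()):
            root_cons.add(mid)
    cons_candidates = [m for m in net.metabolites if m not in root_cons]
    consumable = _sink_lp(net, cons_candidates, tol, "consumption")
    upstream_cons = {m for m in cons_candidates if m not in consumable}
    blocked, indeterminate = _blocked_scan(net, tol)
    return GapReport(
        root_no_production=root_prod,
        downstream_no_production=downstream_prod,
        root_no_consumption=root_cons,
        upstream_no_consumption=upstream_cons,
        blocked_reactions=blocked,
        indeterminate_reactions=indeterminate,
        tol=tol,
    )


def _open_exchanges(net: Network) -> Network:
    """Copy of the network with every exchange opened to symmetric default
    bounds, the convention used for the blocked-reaction scan."""
    out = net.copy()
    for rid in out.exchanges:
        rxn = out.reactions[rid]
        rxn.lower_bound = -DEFAULT_BOUND
        rxn.upper_bound = DEFAULT_BOUND
    return out


def _blocked_scan(net: Network, tol: float) -> tuple[set[str], set[str]]:
    opened = _open_exchanges(net)
    ranges = flux_variability(opened, frac_of_optimum=0.0, tol=tol)
    blocked: set[str] = set()
    indeterminate: set[str] = set()
    for rid, rng in ranges.items():
        if rng.indeterminate:
            indeterminate.add(rid)
        elif abs(rng.minimum) <= tol and abs(rng.maximum) <= tol:
            blocked.add(rid)
    return blocked, indeterminate


def find_blocked_reactions(net: Network, tol: float = DEFAULT_TOL) -> set[str]:
    """Reactions whose flux range is {0} with all exchanges opened.

    A reaction whose variability subproblem fails to solve is flagged
    indeterminate (dropped from the result), never silently blocked.
    """
    blocked, _ = _blocked_scan(net, tol)
    return blocked


def active_blocked_fractions(
    net: Network, tol: float = DEFAULT_TOL
) -> tuple[float, float]:
    """(active_percent, blocked_percent), each rounded to 2 decimals."""
    n = len(net.reactions)
    if n == 0:
        return (100.0, 0.0)
    blocked = find_blocked_reactions(net, tol)
    blocked_pct = 100.0 * len(blocked) / n
    return (round(100.0 - blocked_pct, 2), round(blocked_pct, 2))
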