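"""Independent oracles used by the test suite.

``exact_lp_max`` is a self-contained two-phase simplex over exact rational
arithmetic (:class:`fractions.Fraction`, Bland's rule), written specifically
so that producibility and FBA results from the package's HiGHS-based path
can be checked against an implementation that shares no code, no solver and
no floating-point arithmetic with it.

``to_cobra`` converts a network to a COBRApy model (GLPK backend), giving a
third, externally maintained formulation for dual-solver agreement checks.
"""

from __future__ import annotations

from fractions import Fraction

from gemcurate.network import Metabolite, Network, Reaction


# ----------------------------------------------------------------------
# Exact rational simplex
# ----------------------------------------------------------------------

def _simplex_loop(rows, rhs, basis, obj, allowed):
    """Maximize obj.x on the current tableau with Bland's rule.

    ``allowed`` restricts entering columns.  Returns the objective value of
    the final basic solution.
    """
    n_cols = len(obj)
    while True:
        # reduced costs for nonbasic allowed columns
        basic = set(basis)
        enter = None
        for col in range(n_cols):
            if col in basic or col not in allowed:
                continue
            rc = obj[col] - sum(
                obj[basis[r]] * rows[r][col] for r in range(len(rows))
            )
            if rc > 0:
                enter = col
                break  # Bland: smallest index with positive reduced cost
        if enter is None:
            return sum(obj[basis[r]] * rhs[r] for r in range(len(rows)))
        # ratio test (Bland tie-break: smallest basis index)
        leave = None
        best = None
        for r in range(len(rows)):
            a = rows[r][enter]
            if a > 0:
                ratio = rhs[r] / a
                if best is None or ratio < best or (
                    ratio == best and basis[r] < basis[leave]
                ):
                    best = ratio
                    leave = r
        if leave is None:
            raise RuntimeError("unbounded LP in exact simplex (bounded box expected)")
        piv = rows[leave][enter]
        rows[leave] = [x / piv for x in rows[leave]]
        rhs[leave] = rhs[leave] / piv
        for r in range(len(rows)):
            if r != leave and rows[r][enter] != 0:
                f = rows[r][enter]
                rows[r] = [a - f * b for a, b in zip(rows[r], rows[leave])]
                rhs[r] -= f * rhs[leave]
        basis[leave] = enter


def exact_lp_max(c, A, b, bounds):
    """Maximize ``c.x`` subject to ``A x = b`` and finite box bounds.

    All inputs are coerced to Fractions.  Returns ``(status, value)`` with
    status 'optimal' or 'infeasible'; the feasible region is a box-bounded
    polytope so the unbounded case cannot occur.
    """
    n = len(c)
    m = len(A)
    c = [Fraction(x) for x in c]
    lo = [Fraction(bnd[0]) for bnd in bounds]
    hi = [Fraction(bnd[1]) for bnd in bounds]
    d = [hi[i] - lo[i] for i in range(n)]
    if any(x < 0 for x in d):
        return "infeasible", None
    n_cols = 2 * n + m  # y, slack, artificial
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    basis: list[int] = []
    for i in range(n):  # y_i + s_i = d_i
        row = [Fraction(0)] * n_cols
        row[i] = Fraction(1)
        row[n + i] = Fraction(1)
        rows.append(row)
        rhs.append(d[i])
        basis.append(n + i)
    for j in range(m):
        bj = Fraction(b[j]) - sum(Fraction(A[j][i]) * lo[i] for i in range(n))
        row = [Fraction(A[j][i]) for i in range(n)] + [Fraction(0)] * (n + m)
        if bj < 0:
            row = [-x for x in row]
            bj = -bj
        row[2 * n + j] = Fraction(1)
        rows.append(row)
        rhs.append(bj)
        basis.append(2 * n + j)

    artificials = set(range(2 * n, n_cols))
    phase1_obj = [Fraction(0)] * n_cols
    for col in artificials:
        phase1_obj[col] = Fraction(-1)
    val = _simplex_loop(rows, rhs, basis, phase1_obj, allowed=set(range(n_cols)))
    if val < 0:
        return "infeasible", None
    # pivot any lingering zero-valued artificial out of the basis
    for r in range(len(rows)):
        if basis[r] in artificials:
            for col in range(2 * n):
                if rows[r][col] != 0:
                    piv = rows[r][col]
                    rows[r] = [x / piv for x in rows[r]]
                    rhs[r] = rhs[r] / piv
                    for rr in range(len(rows)):
                        if rr != r and rows[rr][col] != 0:
                            f = rows[rr][col]
                            rows[rr] = [
                                a - f * bb for a, bb in zip(rows[rr], rows[r])
                            ]
                            rhs[rr] -= f * rhs[r]
                    basis[r] = col
                    break
    phase2_obj = [Fraction(0)] * n_cols
    for i in range(n):
        phase2_obj[i] = c[i]
    allowed = set(range(2 * n))  # artificials may not re-enter
    val = _simplex_loop(rows, rhs, basis, phase2_obj, allowed)
    offset = sum(c[i] * lo[i] for i in range(n))
    return "optimal", val + offset


# ----------------------------------------------------------------------
# Network-level oracle wrappers
# ----------------------------------------------------------------------

def _lp_data(net: Network, extra_cols: dict[str, Fraction] | None = None):
    """Equality system S.v = 0 as nested Fraction lists, plus bounds."""
    met_ids = list(net.metabolites)
    met_idx = {m: i for i, m in enumerate(met_ids)}
    rids = list(net.reactions)
    n = len(rids) + (1 if extra_cols else 0)
    A = [[Fraction(0)] * n for _ in met_ids]
    for j, rid in enumerate(rids):
        for mid, coef in net.reactions[rid].stoichiometry.items():
            A[met_idx[mid]][j] = Fraction(coef)
    bounds = [
        (Fraction(r.lower_bound), Fraction(r.upper_bound))
        for r in net.reactions.values()
    ]
    if extra_cols:
        for mid, coef in extra_cols.items():
            A[met_idx[mid]][n - 1] = Fraction(coef)
        bounds.append((Fraction(0), Fraction(1)))
    b = [Fraction(0)] * len(met_ids)
    return A, b, bounds, rids


def oracle_producible(net: Network, met: str, tol=Fraction(1, 10**9)) -> bool:
    """Exact-arithmetic producibility: temporary unit-capped sink on ``met``."""
    A, b, bounds, _ = _lp_data(net, extra_cols={met: Fraction(-1)})
    c = [Fraction(0)] * len(bounds)
    c[-1] = Fraction(1)
    status, val = exact_lp_max(c, A, b, bounds)
    return status == "optimal" and val > tol


def oracle_fba_max(net: Network, objective_id: str):
    """Exact-arithmetic FBA optimum for one reaction's flux."""
    A, b, bounds, rids = _lp_data(net)
    c = [Fraction(0)] * len(bounds)
    c[rids.index(objective_id)] = Fraction(1)
    status, val = exact_lp_max(c, A, b, bounds)
    return status, val


# ----------------------------------------------------------------------
# COBRApy conversion (independent solver: GLPK)
# ----------------------------------------------------------------------

def to_cobra(net: Network):
    import cobra

    model = cobra.Model("oracle")
    mets = {
        mid: cobra.Metabolite(mid, compartment=m.compartment)
        for mid, m in net.metabolites.items()
    }
    rxns = []
    for rid, rxn in net.reactions.items():
        r = cobra.Reaction(rid)
        r.lower_bound = rxn.lower_bound
        r.upper_bound = rxn.upper_bound
        rxns.append(r)
    model.add_reactions(rxns)
    for rid, rxn in net.reactions.items():
        model.reactions.get_by_id(rid).add_metabolites(
            {mets[mid]: float(coef) for mid, coef in rxn.stoichiometry.items()}
        )
    return model


def cobra_fba_max(net: Network, objective_id: str) -> tuple[str, float | None]:
    model = to_cobra(net)
    model.objective = objective_id
    sol = model.optimize()
    if sol.status != "optimal":
        return sol.status, None
    return "optimal", float(sol.objective_value)


# ----------------------------------------------------------------------
# Random tiny networks for exhaustive comparisons
# ----------------------------------------------------------------------

def random_tiny_network(rng, max_mets: int = 5, max_rxns: int = 8) -> Network:
    """Small random network with mixed reversibilities and a few exchanges;
    integer stoichiometry so exact oracles stay exact."""
    n_mets = int(rng.integers(2, max_mets + 1))
    n_rxns = int(rng.integers(2, max_rxns + 1))
    net = Network()
    met_ids = [f"m{i}_c" for i in range(n_mets)]
    for mid in met_ids:
        net.add_metabolite(Metabolite(id=mid))
    bound_choices = [(0.0, 10.0), (-10.0, 10.0), (-10.0, 0.0), (0.0, 5.0)]
    for j in range(n_rxns):
        lb, ub = bound_choices[int(rng.integers(len(bound_choices)))]
        if rng.random() < 0.35:
            mid = met_ids[int(rng.integers(n_mets))]
            stoich = {mid: Fraction(-1)}
        else:
            size = int(rng.integers(2, min(3, n_mets) + 1))
            chosen = rng.choice(n_mets, size=size, replace=False)
            stoich = {}
            for k in chosen:
                coef = int(rng.choice([-2, -1, 1, 2]))
                stoich[met_ids[int(k)]] = Fraction(coef)
        net.add_reaction(
            Reaction(
                id=f"r{j}",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
            )
        )
    return net
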