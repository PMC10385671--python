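"""Compartmentalized metabolic network representation and topology metrics.

A genome-scale metabolic reconstruction (GEM) is held here as an ordered
collection of metabolites and stoichiometric reactions.  Metabolite
identifiers follow the ModelSEED convention: a base compound token suffixed
with a one-letter compartment code (``cpd00001_c``).  The suffix is
authoritative for compartment assignment; a declared compartment field that
conflicts with it is a validation error.

Stoichiometric coefficients are stored as exact rationals
(:class:`fractions.Fraction`), so that a write/read round trip reproduces the
network coefficient-by-coefficient.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import scipy.sparse as sp

__all__ = [
    "Metabolite",
    "Reaction",
    "Network",
    "TopologyReport",
    "NetworkValidationError",
    "NetworkParseError",
    "DEFAULT_COMPARTMENTS",
    "DEFAULT_BOUND",
    "load_network",
    "write_network",
    "build_stoichiometric_matrix",
    "topology_metrics",
    "annotate_gene_coverage",
]

#: Default flux bound magnitude when a file or caller does not specify one.
DEFAULT_BOUND = 1000.0

#: Pre-registered compartment codes.  Nine codes have conventional plant-GEM
#: names; ``u`` is "unknown" and ``e``/``j`` are registered with placeholder
#: names (they occur in published compartment lists without a definition).
DEFAULT_COMPARTMENTS: dict[str, str] = {
    "c": "cytosol",
    "d": "stroma",
    "g": "Golgi",
    "v": "vacuole",
    "w": "cell wall",
    "x": "peroxisome",
    "m": "mitochondria",
    "n": "nucleus",
    "r": "endoplasmic reticulum",
    "e": "compartment e (unspecified)",
    "j": "compartment j (unspecified)",
    "u": "unknown",
}


class NetworkValidationError(ValueError):
    """A network object violates a structural invariant."""


class NetworkParseError(ValueError):
    """A network file cannot be parsed into a valid network."""


_MET_ID_RE = re.compile(r"^(?P<base>\S+)_(?P<comp>[A-Za-z])$")


def split_compartment(met_id: str) -> tuple[str, str]:
    """Split a suffixed metabolite id into (base, compartment code).

    Raises :class:`NetworkValidationError` if the id carries no one-letter
    compartment suffix.
    """
    m = _MET_ID_RE.match(met_id)
    if m is None:
        raise NetworkValidationError(
            f"metabolite id {met_id!r} lacks a '_<compartment>' suffix"
        )
    return m.group("base"), m.group("comp")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = ""

    def __post_init__(self) -> None:
        base, comp = split_compartment(self.id)
        if not self.compartment:
            self.compartment = comp
        elif self.compartment != comp:
            raise NetworkValidationError(
                f"metabolite {self.id!r}: declared compartment "
                f"{self.compartment!r} conflicts with id suffix {comp!r}"
            )


@dataclass
class Reaction:
    """A stoichiometric reaction.  Negative coefficients are consumed."""

    id: str
    name: str = ""
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_association: str | None = None
    ec_numbers: list[str] = field(default_factory=list)
    subsystem: str | None = None

    def __post_init__(self) -> None:
        self.stoichiometry = {
            k: Fraction(v) for k, v in self.stoichiometry.items()
        }
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower_bound > upper_bound"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def compartments(self) -> set[str]:
        return {split_compartment(m)[1] for m in self.stoichiometry}

    @property
    def is_transport(self) -> bool:
        """True when the participating metabolites span >= 2 compartments."""
        return len(self.compartments()) >= 2


class Network:
    """Ordered metabolite/reaction collections plus a compartment registry.

    Exchange reactions (boundary uptake/secretion) are detected structurally:
    a reaction with exactly one metabolite in its stoichiometry.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        compartments: Mapping[str, str] | None = None,
    ) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.compartments: dict[str, str] = dict(
            compartments if compartments is not None else DEFAULT_COMPARTMENTS
        )
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise NetworkValidationError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise NetworkValidationError(
                f"metabolite {met.id!r}: compartment code "
                f"{met.compartment!r} is not registered"
            )
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise NetworkValidationError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise NetworkValidationError(
                f"reaction {rxn.id!r} has empty stoichiometry"
            )
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise NetworkValidationError(
                    f"reaction {rxn.id!r} references undeclared "
                    f"metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        return self.reactions.pop(rxn_id)

    def copy(self) -> "Network":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- structure ----------------------------------------------------
    @property
    def exchanges(self) -> list[str]:
        return [
            rid
            for rid, rxn in self.reactions.items()
            if len(rxn.stoichiometry) == 1
        ]

    def metabolite_index(self) -> dict[str, int]:
        return {mid: i for i, mid in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {rid: i for i, rid in enumerate(self.reactions)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        if list(self.metabolites) != list(other.metabolites):
            return False
        if list(self.reactions) != list(other.reactions):
            return False
        for mid, met in self.metabolites.items():
            o = other.metabolites[mid]
            if (met.name, met.formula, met.charge, met.compartment) != (
                o.name,
                o.formula,
                o.charge,
                o.compartment,
            ):
                return False
        for rid, rxn in self.reactions.items():
            o = other.reactions[rid]
            if rxn.stoichiometry != o.stoichiometry:
                return False
            if (rxn.lower_bound, rxn.upper_bound) != (o.lower_bound, o.upper_bound):
                return False
            if (rxn.name, rxn.gene_association, rxn.ec_numbers, rxn.subsystem) != (
                o.name,
                o.gene_association,
                o.ec_numbers,
                o.subsystem,
            ):
                return False
        return True


@dataclass
class TopologyReport:
    n_metabolites: int
    n_reactions: int
    n_gpr: int
    n_transport: int
    total_entries: int
    nnz: int
    sparsity_percent: float
    per_compartment: dict[str, int]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ----------------------------------------------------------------------
# Equation dialect
# ----------------------------------------------------------------------

_TERM_RE = re.compile(r"^\((?P<coef>[^)]+)\)\s*(?P<met>\S+)$")


def _parse_side(side: str, rxn_id: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split(" + "):
        term = term.strip()
        m = _TERM_RE.match(term)
        if m is None:
            raise NetworkParseError(
                f"reaction {rxn_id!r}: cannot parse equation term {term!r}"
            )
        try:
            coef = Fraction(m.group("coef").strip())
        except (ValueError, ZeroDivisionError) as exc:
            raise NetworkParseError(
                f"reaction {rxn_id!r}: bad coefficient in term {term!r}"
            ) from exc
        met = m.group("met")
        out[met] = out.get(met, Fraction(0)) + coef
    return out


def parse_equation(equation: str, rxn_id: str = "?") -> tuple[dict[str, Fraction], bool]:
    """Parse ``(1) a_c + (2) b_c <=> (1) c_d`` into stoichiometry + reversibility.

    ``<=>`` marks a reversible reaction, ``=>`` forward-only.  Consumed
    metabolites get negative coefficients.
    """
    if "<=>" in equation:
        arrow, reversible = "<=>", True
    elif "=>" in equation:
        arrow, reversible = "=>", False
    else:
        raise NetworkParseError(
            f"reaction {rxn_id!r}: equation lacks '=>' or '<=>': {equation!r}"
        )
    left, right = equation.split(arrow, 1)
    stoich: dict[str, Fraction] = {}
    for met, coef in _parse_side(left, rxn_id).items():
        stoich[met] = stoich.get(met, Fraction(0)) - coef
    for met, coef in _parse_side(right, rxn_id).items():
        stoich[met] = stoich.get(met, Fraction(0)) + coef
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise NetworkParseError(f"reaction {rxn_id!r}: empty net stoichiometry")
    return stoich, reversible


def format_equation(stoich: Mapping[str, Fraction], reversible: bool) -> str:
    lhs = [
        f"({-c}) {m}" for m, c in stoich.items() if c < 0
    ]
    rhs = [f"({c}) {m}" for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# ----------------------------------------------------------------------
# Tabular I/O
# ----------------------------------------------------------------------

_MET_COLUMNS = ["id", "name", "formula", "charge", "compartment"]
_RXN_COLUMNS = [
    "id",
    "name",
    "equation",
    "lower_bound",
    "upper_bound",
    "gpr",
    "ec_numbers",
    "subsystem",
]


def _read_tsv(path: Path, columns: list[str]) -> list[dict[str, str]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise NetworkParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header != columns:
        raise NetworkParseError(
            f"{path}: expected header {columns!r}, found {header!r}"
        )
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        vals = line.split("\t")
        if len(vals) != len(columns):
            raise NetworkParseError(
                f"{path}: row has {len(vals)} fields, expected {len(columns)}: "
                f"{line!r}"
            )
        rows.append(dict(zip(columns, vals)))
    return rows


def _load_tabular(directory: Path) -> Network:
    met_path = directory / "metabolites.tsv"
    rxn_path = directory / "reactions.tsv"
    compartments = dict(DEFAULT_COMPARTMENTS)
    comp_path = directory / "compartments.tsv"
    if comp_path.exists():
        for line in comp_path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            code, _, name = line.partition("\t")
            compartments[code.strip()] = name.strip()
    net = Network(compartments=compartments)
    for row in _read_tsv(met_path, _MET_COLUMNS):
        try:
            net.add_metabolite(
                Metabolite(
                    id=row["id"],
                    name=row["name"],
                    formula=row["formula"] or None,
                    charge=int(row["charge"]) if row["charge"] else None,
                    compartment=row["compartment"],
                )
            )
        except NetworkValidationError as exc:
            raise NetworkParseError(str(exc)) from exc
    for row in _read_tsv(rxn_path, _RXN_COLUMNS):
        stoich, reversible = parse_equation(row["equation"], row["id"])
        lb = float(row["lower_bound"]) if row["lower_bound"] else (
            -DEFAULT_BOUND if reversible else 0.0
        )
        ub = float(row["upper_bound"]) if row["upper_bound"] else DEFAULT_BOUND
        try:
            net.add_reaction(
                Reaction(
                    id=row["id"],
                    name=row["name"],
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gene_association=row["gpr"] or None,
                    ec_numbers=[e for e in row["ec_numbers"].split(";") if e],
                    subsystem=row["subsystem"] or None,
                )
            )
        except NetworkValidationError as exc:
            raise NetworkParseError(str(exc)) from exc
    return net


def _load_sbml(path: Path) -> Network:
    """Read-only SBML Level 3 ingestion (fbc bounds honored when present)."""
    import libsbml

    doc = libsbml.readSBMLFromString(path.read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise NetworkParseError(
            f"{path}: SBML parse error: "
            f"{doc.getError(0).getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkParseError(f"{path}: no model element")
    compartments = dict(DEFAULT_COMPARTMENTS)
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        compartments[comp.getId()] = comp.getName() or comp.getId()
    net = Network(compartments=compartments)
    for i in range(model.getNumSpecies()):
        sp_ = model.getSpecies(i)
        sid = sp_.getId()
        if sid.startswith("M_"):
            sid = sid[2:]
        net.add_metabolite(
            Metabolite(id=sid, name=sp_.getName() or "", compartment="")
        )
    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = rxn.getId()
        if rid.startswith("R_"):
            rid = rid[2:]
        stoich: dict[str, Fraction] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            sid = ref.getSpecies()
            sid = sid[2:] if sid.startswith("M_") else sid
            stoich[sid] = stoich.get(sid, Fraction(0)) - Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**6)
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            sid = ref.getSpecies()
            sid = sid[2:] if sid.startswith("M_") else sid
            stoich[sid] = stoich.get(sid, Fraction(0)) + Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**6)
        fbc = rxn.getPlugin("fbc")
        lb = ub = None
        if fbc is not None:
            lb_id = fbc.getLowerFluxBound()
            ub_id = fbc.getUpperFluxBound()
            lb = params.get(lb_id) if lb_id else None
            ub = params.get(ub_id) if ub_id else None
        reversible = rxn.getReversible()
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        net.add_reaction(
            Reaction(
                id=rid,
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
            )
        )
    return net


def load_network(path: str | Path, dialect: str = "tabular") -> Network:
    """Load a network from ``path`` under the named dialect.

    ``tabular``: a directory containing ``metabolites.tsv`` and
    ``reactions.tsv`` (plus an optional ``compartments.tsv`` registering
    non-default codes).  ``sbml``: an SBML Level 3 file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tabular":
        return _load_tabular(path)
    if dialect == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_network(net: Network, directory: str | Path) -> None:
    """Write the tabular dialect; ``load_network`` reads it back identically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    met_lines = ["\t".join(_MET_COLUMNS)]
    for met in net.metabolites.values():
        met_lines.append(
            "\t".join(
                [
                    met.id,
                    met.name,
                    met.formula or "",
                    "" if met.charge is None else str(met.charge),
                    met.compartment,
                ]
            )
        )
    (directory / "metabolites.tsv").write_text("\n".join(met_lines) + "\n")
    rxn_lines = ["\t".join(_RXN_COLUMNS)]
    for rxn in net.reactions.values():
        rxn_lines.append(
            "\t".join(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(rxn.stoichiometry, rxn.reversible),
                    repr(rxn.lower_bound),
                    repr(rxn.upper_bound),
                    rxn.gene_association or "",
                    ";".join(rxn.ec_numbers),
                    rxn.subsystem or "",
                ]
            )
        )
    (directory / "reactions.tsv").write_text("\n".join(rxn_lines) + "\n")
    comp_lines = [f"{code}\t{name}" for code, name in net.compartments.items()]
    (directory / "compartments.tsv").write_text("\n".join(comp_lines) + "\n")


# ----------------------------------------------------------------------
# Topology
# ----------------------------------------------------------------------

def build_stoichiometric_matrix(net: Network) -> sp.csc_matrix:
    """The metabolites x reactions matrix S with signed coefficients."""
    met_idx = net.metabolite_index()
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(net.reactions.values()):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_idx[met_id])
            cols.append(j)
            data.append(float(coef))
    return sp.csc_matrix(
        (data, (rows, cols)), shape=(len(net.metabolites), len(net.reactions))
    )


def topology_metrics(net: Network) -> TopologyReport:
    """Counts and sparsity of the stoichiometric matrix.

    ``sparsity_percent`` is the percentage of non-zero entries, truncated to
    3 decimals (the truncation convention matches how genome-scale sparsity
    figures are conventionally printed; e.g. 0.302857% reports as 0.302).
    A transport reaction spans >= 2 distinct compartment codes.
    ``per_compartment`` counts each reaction once in every compartment its
    metabolites touch.
    """
    n_met = len(net.metabolites)
    n_rxn = len(net.reactions)
    nnz = sum(len(r.stoichiometry) for r in net.reactions.values())
    total = n_met * n_rxn
    per_comp: dict[str, int] = {}
    n_transport = 0
    n_gpr = 0
    for rxn in net.reactions.values():
        comps = rxn.compartments()
        if len(comps) >= 2:
            n_transport += 1
        if rxn.gene_association:
            n_gpr += 1
        for code in comps:
            per_comp[code] = per_comp.get(code, 0) + 1
    sparsity = math.floor(1000.0 * 100.0 * nnz / total) / 1000.0 if total else 0.0
    return TopologyReport(
        n_metabolites=n_met,
        n_reactions=n_rxn,
        n_gpr=n_gpr,
        n_transport=n_transport,
        total_entries=total,
        nnz=nnz,
        sparsity_percent=sparsity,
        per_compartment=dict(sorted(per_comp.items())),
    )


def annotate_gene_coverage(total_genes: int, coding_genes: int) -> int:
    """Protein-coding share of an annotation, as a whole percent."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if not 0 <= coding_genes <= total_genes:
        raise ValueError("coding_genes must be within [0, total_genes]")
    return round(100.0 * coding_genes / total_genes)
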