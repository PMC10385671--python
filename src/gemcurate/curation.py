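"""Candidate-reaction curation: alias renaming, iterative gap filling,
EC-number pathway coverage, and KO annotation summaries.

The gap-filling loop mirrors a manual bottom-up curation cycle: candidate
reactions harvested from external databases or literature are translated
into the reconstruction's ModelSEED-style nomenclature, integrated one at a
time, and the network is re-evaluated after each addition.  Selection is
greedy — the candidate that most reduces the production-gap count is added
at each iteration, ties broken lexicographically on reaction id, so the loop
is deterministic.  A candidate that would *increase* the gap count is
rejected and logged, never silently accepted.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

from .fba import DEFAULT_TOL
from .gaps import classify_gaps, production_gaps
from .network import (
    DEFAULT_BOUND,
    Metabolite,
    Network,
    Reaction,
    parse_equation,
    split_compartment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateReaction",
    "AliasTable",
    "CurationReport",
    "PathwaySpec",
    "rename_candidates",
    "integrate_candidates",
    "coverage_check",
    "summarize_ko_annotation",
    "ec_matches",
]

_NAMESPACES = {"KEGG", "MetaCyc", "literature", "other"}
_KO_RE = re.compile(r"^K\d{5}$")
_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass
class CandidateReaction:
    external_id: str
    source_namespace: str = "other"
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    target_compartment: str = "c"
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    ec_numbers: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(
                f"candidate {self.external_id!r} has empty stoichiometry"
            )
        if self.source_namespace not in _NAMESPACES:
            raise ValueError(
                f"candidate {self.external_id!r}: unknown namespace "
                f"{self.source_namespace!r}"
            )
        self.stoichiometry = {
            k: Fraction(v) for k, v in self.stoichiometry.items()
        }


class AliasTable:
    """Functional map (namespace, external id) -> internal ModelSEED-style id.

    Holds both compound and reaction aliases, distinguished by ``kind``.
    """

    def __init__(self) -> None:
        self._compounds: dict[tuple[str, str], str] = {}
        self._reactions: dict[tuple[str, str], str] = {}

    def add(self, namespace: str, external_id: str, internal_id: str, kind: str) -> None:
        table = self._compounds if kind == "compound" else self._reactions
        key = (namespace, external_id)
        if key in table and table[key] != internal_id:
            raise ValueError(
                f"alias table not functional: {key} maps to both "
                f"{table[key]!r} and {internal_id!r}"
            )
        table[key] = internal_id

    def compound(self, namespace: str, external_id: str) -> str | None:
        return self._compounds.get((namespace, external_id))

    def reaction(self, namespace: str, external_id: str) -> str | None:
        return self._reactions.get((namespace, external_id))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AliasTable":
        """Read ``aliases.tsv`` with columns namespace, external_id,
        internal_id, kind."""
        table = cls()
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        expected = ["namespace", "external_id", "internal_id", "kind"]
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for line in lines[1:]:
            if not line.strip():
                continue
            ns, ext, internal, kind = line.split("\t")
            table.add(ns, ext, internal, kind)
        return table

    @classmethod
    def identity(cls, compound_ids: Iterable[str], namespace: str = "other") -> "AliasTable":
        table = cls()
        for cid in compound_ids:
            table.add(namespace, cid, cid, "compound")
        return table


@dataclass
class CurationReport:
    iterations: list[dict] = field(default_factory=list)
    delta_active_reactions: int = 0
    delta_metabolites: int = 0
    unmapped_candidates: list[str] = field(default_factory=list)
    rejected_candidates: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class PathwaySpec:
    """EC-number checklist for one pathway (precursor enzymes to verify)."""

    name: str
    entries: list[dict] = field(default_factory=list)  # {label, ec_number}

    def __post_init__(self) -> None:
        for entry in self.entries:
            ec = entry.get("ec_number", "")
            if not _EC_RE.match(ec):
                raise ValueError(
                    f"pathway {self.name!r}: malformed EC string {ec!r} "
                    f"in entry {entry.get('label')!r}"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> list["PathwaySpec"]:
        """Read a TSV with columns pathway, enzyme_label, ec_number."""
        lines = Path(path).read_text().splitlines()
        expected = ["pathway", "enzyme_label", "ec_number"]
        if lines[0].split("\t") != expected:
            raise ValueError(f"{path}: expected header {expected}")
        grouped: dict[str, list[dict]] = {}
        order: list[str] = []
        for line in lines[1:]:
            if not line.strip():
                continue
            pathway, label, ec = line.split("\t")
            if pathway not in grouped:
                grouped[pathway] = []
                order.append(pathway)
            grouped[pathway].append({"label": label, "ec_number": ec})
        return [cls(name=p, entries=grouped[p]) for p in order]


# ----------------------------------------------------------------------
# Alias renaming
# ----------------------------------------------------------------------

def rename_candidates(
    cands: list[CandidateReaction],
    aliases: AliasTable,
    policy: str = "skip",
) -> tuple[list[CandidateReaction], list[CandidateReaction]]:
    """Translate candidate stoichiometries into internal compartment-suffixed
    metabolite ids.

    Every external compound id must resolve through the alias table; the
    internal id then gains the candidate's ``target_compartment`` suffix.
    Candidates with unresolvable compounds are routed per ``policy``:
    ``skip`` collects them in the unmapped list, ``fail`` raises with every
    unmapped key listed.
    """
    if policy not in {"skip", "fail"}:
        raise ValueError(f"unknown policy {policy!r}")
    renamed: list[CandidateReaction] = []
    unmapped: list[CandidateReaction] = []
    all_missing: list[tuple[str, str]] = []
    for cand in cands:
        missing = [
            ext
            for ext in cand.stoichiometry
            if aliases.compound(cand.source_namespace, ext) is None
        ]
        if missing:
            unmapped.append(cand)
            all_missing.extend((cand.external_id, m) for m in missing)
            logger.warning(
                "candidate %s: unmapped compounds %s", cand.external_id, missing
            )
            continue
        new_stoich = {
            f"{aliases.compound(cand.source_namespace, ext)}_{cand.target_compartment}": coef
            for ext, coef in cand.stoichiometry.items()
        }
        internal_rid = aliases.reaction(cand.source_namespace, cand.external_id)
        renamed.append(
            CandidateReaction(
                external_id=internal_rid or cand.external_id,
                source_namespace=cand.source_namespace,
                stoichiometry=new_stoich,
                target_compartment=cand.target_compartment,
                lower_bound=cand.lower_bound,
                upper_bound=cand.upper_bound,
                ec_numbers=list(cand.ec_numbers),
                provenance=cand.provenance,
            )
        )
    if all_missing and policy == "fail":
        raise KeyError(
            "unmapped compound keys: "
            + ", ".join(f"{rid}:{met}" for rid, met in all_missing)
        )
    return renamed, unmapped


def _candidate_to_reaction(cand: CandidateReaction) -> Reaction:
    return Reaction(
        id=cand.external_id,
        name=cand.provenance or cand.external_id,
        stoichiometry=dict(cand.stoichiometry),
        lower_bound=cand.lower_bound,
        upper_bound=cand.upper_bound,
        ec_numbers=list(cand.ec_numbers),
    )


def _add_candidate(net: Network, cand: CandidateReaction) -> Network:
    out = net.copy()
    for met_id in cand.stoichiometry:
        if met_id not in out.metabolites:
            out.add_metabolite(Metabolite(id=met_id))
    out.add_reaction(_candidate_to_reaction(cand))
    return out


def integrate_candidates(
    net: Network,
    cands: list[CandidateReaction],
    tol: float = DEFAULT_TOL,
    max_iter: int = 20,
) -> tuple[Network, CurationReport]:
    """Greedy iterative gap filling.

    At each iteration every remaining candidate is tentatively integrated and
    the production-gap count recomputed; the candidate with the largest
    reduction is accepted (ties: lexicographic id).  The loop stops when no
    candidate reduces the gap count, the gaps reach zero, or ``max_iter``
    iterations have run.  The report records per-iteration gap/blocked
    counts and the final deltas of active (non-blocked) reactions and of
    metabolites versus the input network.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    base_report = classify_gaps(net, tol)
    n_active_before = len(net.reactions) - len(base_report.blocked_reactions)
    n_met_before = len(net.metabolites)
    current = net
    current_report = base_report
    remaining = sorted(cands, key=lambda c: c.external_id)
    report = CurationReport()
    for _ in range(max_iter):
        gaps_before = len(current_report.all_gaps)
        if gaps_before == 0 or not remaining:
            break
        best: tuple[int, str] | None = None
        best_net: Network | None = None
        best_cand: CandidateReaction | None = None
        for cand in remaining:
            if cand.external_id in current.reactions:
                continue
            trial = _add_candidate(current, cand)
            # selection only needs the production-side gap count; the full
            # report (incl. blocked scan) is recomputed once per acceptance
            root, downstream = production_gaps(trial, tol)
            key = (len(root) + len(downstream), cand.external_id)
            if best is None or key < best:
                best = key
                best_net = trial
                best_cand = cand
        if best is None or best[0] >= gaps_before:
            if best is not None and best[0] > gaps_before and best_cand is not None:
                report.rejected_candidates.append(best_cand.external_id)
                logger.info(
                    "candidate %s rejected: would raise gap count %d -> %d",
                    best_cand.external_id,
                    gaps_before,
                    best[0],
                )
            break
        assert best_net is not None and best_cand is not None
        accepted_report = classify_gaps(best_net, tol)
        report.iterations.append(
            {
                "added": [best_cand.external_id],
                "gaps_before": gaps_before,
                "gaps_after": len(accepted_report.all_gaps),
                "blocked_before": len(current_report.blocked_reactions),
                "blocked_after": len(accepted_report.blocked_reactions),
            }
        )
        current = best_net
        current_report = accepted_report
        remaining = [c for c in remaining if c.external_id != best_cand.external_id]
    n_active_after = len(current.reactions) - len(
        current_report.blocked_reactions
    )
    report.delta_active_reactions = n_active_after - n_active_before
    report.delta_metabolites = len(current.metabolites) - n_met_before
    return current, report


# ----------------------------------------------------------------------
# EC coverage
# ----------------------------------------------------------------------

def ec_matches(a: str, b: str) -> bool:
    """EC equality with '-' wildcards: a dash on either side matches any
    value at that position."""
    for pattern, ec in ((a, b),):
        if not _EC_RE.match(pattern) or not _EC_RE.match(ec):
            raise ValueError(f"malformed EC string in comparison: {a!r} vs {b!r}")
    pa = a.split(".")
    pb = b.split(".")
    return all(x == y or x == "-" or y == "-" for x, y in zip(pa, pb))


def coverage_check(net: Network, spec: PathwaySpec) -> list[dict]:
    """One row per pathway entry: is some network reaction annotated with a
    matching EC number?  Order-preserving."""
    network_ecs = sorted(
        {ec for rxn in net.reactions.values() for ec in rxn.ec_numbers}
    )
    for ec in network_ecs:
        if not _EC_RE.match(ec):
            raise ValueError(f"network carries malformed EC annotation {ec!r}")
    rows = []
    for entry in spec.entries:
        ec = entry["ec_number"]
        included = any(ec_matches(ec, net_ec) for net_ec in network_ecs)
        rows.append(
            {
                "label": entry["label"],
                "ec_number": ec,
                "included": "yes" if included else "no",
            }
        )
    return rows


# ----------------------------------------------------------------------
# KO annotation summary
# ----------------------------------------------------------------------

def summarize_ko_annotation(
    table: Mapping[str, Iterable[str]],
    category_map: Mapping[str, str],
) -> dict[str, int]:
    """Distinct-gene counts per KO functional category.

    ``table`` maps gene id -> KO tokens (K00001 style).  Genes without any
    valid KO are excluded; a gene whose KOs span several categories counts
    once in each.  Malformed KO tokens produce a warning and are skipped.
    """
    gene_sets: dict[str, set[str]] = {}
    for gene, kos in table.items():
        for ko in kos:
            if not _KO_RE.match(ko):
                logger.warning("gene %s: malformed KO token %r skipped", gene, ko)
                continue
            category = category_map.get(ko)
            if category is None:
                continue
            gene_sets.setdefault(category, set()).add(gene)
    return {cat: len(genes) for cat, genes in sorted(gene_sets.items())}


# ----------------------------------------------------------------------
# Candidate file I/O
# ----------------------------------------------------------------------

def load_candidates(path: str | Path) -> list[CandidateReaction]:
    """Read ``candidates.tsv``: the reactions.tsv equation dialect plus a
    namespace and target_compartment column."""
    lines = Path(path).read_text().splitlines()
    expected = [
        "external_id",
        "namespace",
        "equation",
        "target_compartment",
        "lower_bound",
        "upper_bound",
        "ec_numbers",
        "provenance",
    ]
    if lines[0].split("\t") != expected:
        raise ValueError(f"{path}: expected header {expected}")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        vals = dict(zip(expected, line.split("\t")))
        stoich, reversible = parse_equation(vals["equation"], vals["external_id"])
        lb = float(vals["lower_bound"]) if vals["lower_bound"] else (
            -DEFAULT_BOUND if reversible else 0.0
        )
        ub = float(vals["upper_bound"]) if vals["upper_bound"] else DEFAULT_BOUND
        out.append(
            CandidateReaction(
                external_id=vals["external_id"],
                source_namespace=vals["namespace"],
                stoichiometry=stoich,
                target_compartment=vals["target_compartment"],
                lower_bound=lb,
                upper_bound=ub,
                ec_numbers=[e for e in vals["ec_numbers"].split(";") if e],
                provenance=vals["provenance"],
            )
        )
    return out
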