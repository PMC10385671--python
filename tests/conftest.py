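from fractions import Fraction
from pathlib import Path

import pytest

from gemcurate.curation import CandidateReaction
from gemcurate.metabolomics import LibraryEntry, load_reference_library
from gemcurate.network import Metabolite, Network, Reaction, format_equation


def build_network(reactions: dict, bounds: dict | None = None) -> Network:
    """Compact network builder: ``reactions`` maps rid -> stoichiometry dict;
    ``bounds`` maps rid -> (lb, ub), defaulting to irreversible 0..1000."""
    net = Network()
    mets = {m for stoich in reactions.values() for m in stoich}
    for mid in sorted(mets):
        net.add_metabolite(Metabolite(id=mid))
    for rid, stoich in reactions.items():
        lb, ub = (bounds or {}).get(rid, (0.0, 1000.0))
        net.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )
    return net


@pytest.fixture
def chain_network() -> Network:
    """EX_A (uptake capped at 10) -> A -> B -> EX_B."""
    return build_network(
        {
            "EX_a": {"a_c": -1},
            "r_ab": {"a_c": -1, "b_c": 1},
            "EX_b": {"b_c": -1},
        },
        bounds={"EX_a": (-10.0, 1000.0)},
    )


@pytest.fixture
def broken_chain_network() -> Network:
    """Three-step chain with the uptake removed: A is a root no-production
    gap; B and C inherit the pathology downstream."""
    return build_network(
        {
            "r_ab": {"a_c": -1, "b_c": 1},
            "r_bc": {"b_c": -1, "c_c": 1},
            "EX_c": {"c_c": -1},
        }
    )


@pytest.fixture(scope="session")
def reference_rows() -> list[dict]:
    return load_reference_library()


@pytest.fixture(scope="session")
def reference_library(reference_rows) -> list[LibraryEntry]:
    return [
        LibraryEntry(
            name=r["compound"],
            formula=r["formula"],
            compound_class=r["compound_class"],
        )
        for r in reference_rows
    ]


def write_candidates_tsv(cands: list[CandidateReaction], path: Path) -> None:
    """Serialize candidates in the candidates.tsv dialect."""
    header = (
        "external_id\tnamespace\tequation\ttarget_compartment\t"
        "lower_bound\tupper_bound\tec_numbers\tprovenance"
    )
    lines = [header]
    for c in cands:
        stoich = {m: Fraction(v) for m, v in c.stoichiometry.items()}
        eq = format_equation(stoich, c.lower_bound < 0 < c.upper_bound)
        lines.append(
            f"{c.external_id}\t{c.source_namespace}\t{eq}\t"
            f"{c.target_compartment}\t{c.lower_bound!r}\t{c.upper_bound!r}\t"
            f"{';'.join(c.ec_numbers)}\t{c.provenance}"
        )
    path.write_text("\n".join(lines) + "\n")
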