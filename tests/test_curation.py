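"""Alias renaming, gap-filling integration, EC coverage, KO summaries."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from conftest import build_network
from gemcurate.curation import (
    AliasTable,
    CandidateReaction,
    PathwaySpec,
    coverage_check,
    ec_matches,
    integrate_candidates,
    rename_candidates,
    summarize_ko_annotation,
)
from gemcurate.gaps import classify_gaps
from gemcurate.synthetic import NetworkGenSpec, generate_network


def _alias_table():
    table = AliasTable()
    table.add("KEGG", "C00022", "cpd00020", "compound")
    table.add("KEGG", "C00024", "cpd00022", "compound")
    table.add("KEGG", "R00226", "rxn00250", "reaction")
    return table


class TestAliasTable:
    def test_non_functional_mapping_rejected(self):
        table = AliasTable()
        table.add("KEGG", "C00022", "cpd00020", "compound")
        with pytest.raises(ValueError, match="functional"):
            table.add("KEGG", "C00022", "cpd99999", "compound")

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "aliases.tsv"
        path.write_text(
            "namespace\texternal_id\tinternal_id\tkind\n"
            "KEGG\tC00022\tcpd00020\tcompound\n"
            "KEGG\tR00226\trxn00250\treaction\n"
        )
        table = AliasTable.from_tsv(path)
        assert table.compound("KEGG", "C00022") == "cpd00020"
        assert table.reaction("KEGG", "R00226") == "rxn00250"


class TestRenameCandidates:
    def test_fully_mapped_candidate_is_renamed(self):
        cand = CandidateReaction(
            external_id="R00226",
            source_namespace="KEGG",
            stoichiometry={"C00022": -1, "C00024": 1},
            target_compartment="m",
        )
        renamed, unmapped = rename_candidates([cand], _alias_table())
        assert unmapped == []
        assert renamed[0].external_id == "rxn00250"
        assert renamed[0].stoichiometry == {
            "cpd00020_m": Fraction(-1),
            "cpd00022_m": Fraction(1),
        }

    def test_unknown_compound_skipped_by_default(self):
        cand = CandidateReaction(
            external_id="Rx",
            source_namespace="KEGG",
            stoichiometry={"C99999": -1},
        )
        renamed, unmapped = rename_candidates([cand], _alias_table())
        assert renamed == []
        assert [c.external_id for c in unmapped] == ["Rx"]

    def test_fail_policy_lists_all_unmapped_keys(self):
        cands = [
            CandidateReaction(
                external_id=f"R{i}",
                source_namespace="KEGG",
                stoichiometry={f"C9999{i}": -1},
            )
            for i in range(2)
        ]
        with pytest.raises(KeyError, match="C99990.*C99991"):
            rename_candidates(cands, _alias_table(), policy="fail")

    @pytest.mark.parametrize("seed", range(3))
    def test_identity_aliases_change_only_suffixes(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"cpd{int(rng.integers(10, 99)):05d}" for _ in range(4)]
        cand = CandidateReaction(
            external_id="rxnX",
            source_namespace="other",
            stoichiometry={cid: int(c) for cid, c in
                           zip(ids, rng.choice([-2, -1, 1, 2], size=4))},
            target_compartment="v",
        )
        table = AliasTable.identity(ids)
        renamed, _ = rename_candidates([cand], table)
        for ext, coef in cand.stoichiometry.items():
            assert renamed[0].stoichiometry[f"{ext}_v"] == coef


class TestIntegrateCandidates:
    def test_planted_gap_closed_in_one_iteration(self):
        net, truth = generate_network(NetworkGenSpec(planted_gaps=1, seed=4))
        assert len(classify_gaps(net).all_gaps) == 1
        curated, report = integrate_candidates(net, truth.closing_candidates)
        assert len(report.iterations) == 1
        assert report.iterations[0]["gaps_before"] == 1
        assert report.iterations[0]["gaps_after"] == 0
        assert report.delta_active_reactions >= 1
        assert classify_gaps(curated).all_gaps == set()

    def test_empty_pool_echoes_input_state(self, chain_network):
        curated, report = integrate_candidates(chain_network, [])
        assert report.iterations == []
        assert report.delta_active_reactions == 0
        assert report.delta_metabolites == 0
        assert curated == chain_network

    @pytest.mark.parametrize("k", [2, 3])
    def test_generator_ground_truth_recovered(self, k):
        net, truth = generate_network(
            NetworkGenSpec(planted_gaps=k, seed=10 + k)
        )
        initial = len(classify_gaps(net).all_gaps)
        curated, report = integrate_candidates(net, truth.closing_candidates)
        final = len(classify_gaps(curated).all_gaps)
        assert final == initial - k
        # planted closing reactions reference existing compounds only
        assert report.delta_metabolites == 0
        assert len(report.iterations) == k

    def test_deterministic_given_ordering_rule(self):
        net, truth = generate_network(NetworkGenSpec(planted_gaps=3, seed=6))
        r1 = integrate_candidates(net, truth.closing_candidates)[1]
        r2 = integrate_candidates(net, truth.closing_candidates)[1]
        assert r1.iterations == r2.iterations

    def test_gap_count_nonincreasing_across_iterations(self):
        net, truth = generate_network(NetworkGenSpec(planted_gaps=4, seed=8))
        _, report = integrate_candidates(net, truth.closing_candidates)
        counts = [it["gaps_before"] for it in report.iterations] + [
            report.iterations[-1]["gaps_after"]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_gap_free_network_short_circuits(self, chain_network):
        cand = CandidateReaction(
            external_id="rxn_extra",
            source_namespace="other",
            stoichiometry={"a_c": -1, "b_c": 1},
        )
        curated, report = integrate_candidates(chain_network, [cand])
        assert report.iterations == []
        assert "rxn_extra" not in curated.reactions

    def test_harmful_candidate_rejected_and_logged(self, broken_chain_network):
        # the candidate's substrate is itself unproducible, so integrating
        # it would add a fourth production gap to the three existing ones
        bad = CandidateReaction(
            external_id="rxn_bad",
            source_namespace="other",
            stoichiometry={"orphan_c": -1, "b_c": 1},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
        curated, report = integrate_candidates(broken_chain_network, [bad])
        assert report.iterations == []
        assert "rxn_bad" not in curated.reactions
        assert report.rejected_candidates == ["rxn_bad"]


class TestCoverageCheck:
    def _net_with_ecs(self, ecs):
        net = build_network({"r1": {"a_c": -1, "b_c": 1}})
        net.reactions["r1"].ec_numbers = list(ecs)
        return net

    def test_exact_match_reported_yes(self):
        net = self._net_with_ecs(["6.4.1.2"])
        spec = PathwaySpec(
            name="fatty acid biosynthesis",
            entries=[{"label": "ACACA; acetyl-CoA carboxylase", "ec_number": "6.4.1.2"}],
        )
        rows = coverage_check(net, spec)
        assert rows == [
            {
                "label": "ACACA; acetyl-CoA carboxylase",
                "ec_number": "6.4.1.2",
                "included": "yes",
            }
        ]

    def test_absent_enzyme_reported_no(self):
        net = self._net_with_ecs(["1.1.1.1"])
        spec = PathwaySpec(
            name="p", entries=[{"label": "x", "ec_number": "2.4.1.115"}]
        )
        assert coverage_check(net, spec)[0]["included"] == "no"

    def test_wildcard_matches_any_final_field(self):
        net = self._net_with_ecs(["2.3.1.16"])
        spec = PathwaySpec(name="p", entries=[{"label": "x", "ec_number": "2.3.1.-"}])
        assert coverage_check(net, spec)[0]["included"] == "yes"

    def test_wildcard_semantics_match_string_expansion_oracle(self):
        """ec_matches against brute-force expansion of dash wildcards over a
        toy EC universe."""
        universe = [
            f"{a}.{b}.{c}.{d}"
            for a, b, c, d in itertools.product("12", "13", "14", "156")
        ]
        patterns = ["1.1.1.1", "1.1.1.-", "2.-.4.5", "-.-.-.-", "1.3.4.6"]
        for pat in patterns:
            expansion = {
                ec
                for ec in universe
                if all(
                    p == "-" or p == f
                    for p, f in zip(pat.split("."), ec.split("."))
                )
            }
            assert {ec for ec in universe if ec_matches(pat, ec)} == expansion

    def test_malformed_ec_rejected_with_entry_name(self):
        with pytest.raises(ValueError, match="badlabel"):
            PathwaySpec(
                name="p", entries=[{"label": "badlabel", "ec_number": "6.4.1"}]
            )

    def test_one_ordered_row_per_entry(self):
        net = self._net_with_ecs(["1.1.1.1"])
        entries = [
            {"label": f"e{i}", "ec_number": "1.1.1.1"} for i in range(5)
        ]
        rows = coverage_check(net, PathwaySpec(name="p", entries=entries))
        assert [r["label"] for r in rows] == [f"e{i}" for i in range(5)]


class TestKoSummary:
    def test_small_histogram(self):
        table = {"g1": ["K00001"], "g2": ["K00002"], "g3": ["K00001", "K00003"]}
        cats = {"K00001": "carbohydrate", "K00002": "lipid", "K00003": "lipid"}
        assert summarize_ko_annotation(table, cats) == {
            "carbohydrate": 2,
            "lipid": 2,
        }

    def test_empty_table(self):
        assert summarize_ko_annotation({}, {}) == {}

    def test_malformed_ko_token_skipped(self):
        table = {"g1": ["K1", "K00001"]}
        cats = {"K00001": "carbohydrate"}
        assert summarize_ko_annotation(table, cats) == {"carbohydrate": 1}

    def test_random_table_matches_brute_force_groupby(self):
        rng = np.random.default_rng(3)
        kos = [f"K{i:05d}" for i in range(20)]
        cats = {ko: f"cat{int(rng.integers(4))}" for ko in kos}
        table = {
            f"g{i}": list(
                rng.choice(kos, size=int(rng.integers(0, 4)), replace=False)
            )
            for i in range(50)
        }
        expected: dict[str, set[str]] = {}
        for gene, gkos in table.items():
            for ko in gkos:
                expected.setdefault(cats[ko], set()).add(gene)
        assert summarize_ko_annotation(table, cats) == {
            cat: len(g) for cat, g in sorted(expected.items())
        }
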