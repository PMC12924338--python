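import numpy as np
import pandas as pd
import pytest

from orgloc.reconstruction import (
    PathwayDefinition,
    build_matrix,
    filter_community,
    flag_contaminants,
    pathway_completeness,
    shared_lineages,
)
from orgloc.synthetic import generate_community_table


def evidence_row(species="sp", enzyme="E1", found=True, tax="eukaryote",
                 protein_id=""):
    return {"species": species, "enzyme_id": enzyme, "homolog_found": found,
            "best_hit_taxonomy": tax, "protein_id": protein_id}


class TestContaminants:
    def test_eukaryote_hit_unchanged(self):
        out = flag_contaminants(pd.DataFrame([evidence_row()]))
        assert not out["contaminant_only"].iloc[0]

    def test_prokaryote_only_downgraded(self):
        out = flag_contaminants(
            pd.DataFrame([evidence_row(tax="prokaryote")])
        )
        assert out["contaminant_only"].iloc[0]

    def test_mixed_paralogs_keep_eukaryotic_evidence(self):
        frame = pd.DataFrame([
            evidence_row(enzyme="E1", tax="prokaryote"),
            evidence_row(enzyme="E1", tax="eukaryote"),
            evidence_row(enzyme="E2", tax="prokaryote"),
        ])
        out = flag_contaminants(frame)
        assert out["contaminant_only"].tolist() == [False, False, True]

    def test_oracle_recount_on_random_table(self, rng):
        taxa = ["eukaryote", "prokaryote", "unknown"]
        rows = [
            evidence_row(
                species=f"sp{rng.integers(2)}",
                enzyme=f"E{rng.integers(10)}",
                found=bool(rng.integers(2)),
                tax=str(rng.choice(taxa)),
            )
            for _ in range(300)
        ]
        frame = pd.DataFrame(rows)
        out = flag_contaminants(frame)
        # independent per-row recount
        for idx, row in frame.iterrows():
            if not row["homolog_found"]:
                assert not out.loc[idx, "contaminant_only"]
                continue
            group = frame.loc[
                (frame["species"] == row["species"])
                & (frame["enzyme_id"] == row["enzyme_id"])
                & frame["homolog_found"]
            ]
            expected = (group["best_hit_taxonomy"] == "prokaryote").all()
            assert out.loc[idx, "contaminant_only"] == bool(expected)


PATHWAY = PathwayDefinition(
    "toy", ("E1", "E2", "E3"), expected_compartment={"E1": "plastid"}
)


def consensus_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "assigned", "rule_fired"])


class TestMatrix:
    def test_consistent_when_consensus_matches_expectation(self):
        evidence = pd.DataFrame([evidence_row(enzyme="E1", protein_id="p1")])
        consensus = consensus_frame([("p1", "plastid", "unanimity")])
        matrix = build_matrix(evidence, [PATHWAY], consensus)
        cell = matrix.set_index("enzyme_id").loc["E1"]
        assert cell["status"] == "present_consistent"
        assert cell["localization"] == "plastid"

    def test_unassigned_consensus(self):
        evidence = pd.DataFrame([evidence_row(enzyme="E1", protein_id="p1")])
        consensus = consensus_frame([("p1", "unassigned", "none")])
        matrix = build_matrix(evidence, [PATHWAY], consensus)
        assert matrix.set_index("enzyme_id").loc["E1", "status"] == \
            "present_unassigned"

    def test_truncated_consensus(self):
        evidence = pd.DataFrame([evidence_row(enzyme="E2", protein_id="p1")])
        consensus = consensus_frame([("p1", "unassigned", "truncated")])
        matrix = build_matrix(evidence, [PATHWAY], consensus)
        assert matrix.set_index("enzyme_id").loc["E2", "status"] == \
            "present_truncated"

    def test_no_expectation_accepts_any_assignment(self):
        evidence = pd.DataFrame([evidence_row(enzyme="E2", protein_id="p1")])
        consensus = consensus_frame([("p1", "mitochondrion", "unanimity")])
        matrix = build_matrix(evidence, [PATHWAY], consensus)
        cell = matrix.set_index("enzyme_id").loc["E2"]
        assert cell["status"] == "present_consistent"
        assert cell["localization"] == "mitochondrion"

    def test_missing_evidence_is_absent(self):
        evidence = pd.DataFrame([evidence_row(enzyme="E1", protein_id="p1")])
        matrix = build_matrix(evidence, [PATHWAY])
        assert matrix.set_index("enzyme_id").loc["E3", "status"] == "absent"

    def test_row_order_invariance_and_oracle(self, rng):
        enzymes = [f"E{i}" for i in range(1, 4)]
        statuses = ["eukaryote", "prokaryote"]
        rows, cons_rows = [], []
        for i in range(200):
            pid = f"p{i}"
            rows.append(evidence_row(
                species=f"sp{rng.integers(3)}",
                enzyme=str(rng.choice(enzymes)),
                found=bool(rng.integers(4) > 0),
                tax=str(rng.choice(statuses)),
                protein_id=pid,
            ))
            cons_rows.append((
                pid,
                str(rng.choice(["plastid", "mitochondrion", "unassigned"])),
                str(rng.choice(["unanimity", "none", "truncated"])),
            ))
        evidence = pd.DataFrame(rows)
        consensus = consensus_frame(cons_rows)
        matrix = build_matrix(evidence, [PATHWAY], consensus)
        shuffled = evidence.sample(frac=1, random_state=7).reset_index(
            drop=True)
        matrix2 = build_matrix(shuffled, [PATHWAY], consensus)
        pd.testing.assert_frame_equal(matrix, matrix2)
        # independent per-cell recount of the status ordering
        cmap = {r[0]: (r[1], r[2]) for r in cons_rows}
        rank = ["present_consistent", "present_unassigned",
                "present_truncated", "contaminant_only", "absent"]
        for row in matrix.itertuples(index=False):
            group = evidence.loc[
                (evidence["species"] == row.species)
                & (evidence["enzyme_id"] == row.enzyme_id)
            ]
            expected = ["absent"]
            for g in group.itertuples(index=False):
                if not g.homolog_found:
                    expected.append("absent")
                elif g.best_hit_taxonomy == "prokaryote":
                    expected.append("contaminant_only")
                else:
                    assigned, rule = cmap[g.protein_id]
                    if rule == "truncated":
                        expected.append("present_truncated")
                    elif assigned == "unassigned":
                        expected.append("present_unassigned")
                    elif row.enzyme_id == "E1" and assigned != "plastid":
                        expected.append("present_unassigned")
                    else:
                        expected.append("present_consistent")
            assert row.status == min(expected, key=rank.index)


class TestCompleteness:
    def build(self, statuses):
        evidence = []
        consensus = []
        for i, (enzyme, status) in enumerate(statuses.items()):
            pid = f"p{i}"
            if status == "absent":
                evidence.append(evidence_row(enzyme=enzyme, found=False,
                                             tax="unknown"))
            elif status == "contaminant_only":
                evidence.append(evidence_row(enzyme=enzyme, tax="prokaryote"))
            else:
                evidence.append(evidence_row(enzyme=enzyme, protein_id=pid))
                consensus.append((pid, "plastid", "unanimity"))
        return build_matrix(
            pd.DataFrame(evidence),
            [PathwayDefinition("adi", tuple(statuses))],
            consensus_frame(consensus),
        )

    def test_missing_enzyme_makes_pathway_incomplete(self):
        # arginine deiminase pathway lacking its third enzyme
        matrix = self.build({
            "arginine_deiminase": "present",
            "ornithine_transcarbamylase": "present",
            "carbamate_kinase": "absent",
        })
        pw = PathwayDefinition(
            "adi", ("arginine_deiminase", "ornithine_transcarbamylase",
                    "carbamate_kinase"),
        )
        fraction, complete, missing = pathway_completeness(matrix, pw, "sp")
        assert fraction == pytest.approx(2 / 3)
        assert not complete
        assert missing == ["carbamate_kinase"]

    def test_all_present_is_complete(self):
        matrix = self.build({"E1": "present", "E2": "present", "E3": "present"})
        pw = PathwayDefinition("adi", ("E1", "E2", "E3"))
        fraction, complete, missing = pathway_completeness(matrix, pw, "sp")
        assert fraction == 1.0 and complete and missing == []

    def test_contaminant_counts_as_absent(self):
        matrix = self.build({"E1": "present", "E2": "contaminant_only"})
        pw = PathwayDefinition("adi", ("E1", "E2"))
        fraction, complete, missing = pathway_completeness(matrix, pw, "sp")
        assert fraction == pytest.approx(0.5)
        assert missing == ["E2"]

    def test_empty_evidence_gives_zero_fraction(self):
        matrix = build_matrix(
            pd.DataFrame([evidence_row(found=False, tax="unknown")]),
            [PATHWAY],
        )
        fraction, complete, _ = pathway_completeness(matrix, PATHWAY, "sp")
        assert fraction == 0.0 and not complete

    def test_monotone_in_presence(self):
        pw = PathwayDefinition("adi", ("E1", "E2", "E3"))
        f_partial, _, _ = pathway_completeness(
            self.build({"E1": "present", "E2": "absent", "E3": "absent"}),
            pw, "sp")
        f_more, _, _ = pathway_completeness(
            self.build({"E1": "present", "E2": "present", "E3": "absent"}),
            pw, "sp")
        assert f_more >= f_partial


class TestCommunityFilter:
    def table(self, values):
        return pd.DataFrame({
            "lineage": [f"L{i}" for i in range(len(values))],
            "culture_A": values,
        })

    def test_threshold_arithmetic(self):
        _, counts = filter_community(self.table([0.50, 0.30, 0.195, 0.005]))
        assert counts["culture_A"] == 3

    def test_boundary_value_retained(self):
        retained, counts = filter_community(self.table([0.99, 0.01]))
        assert counts["culture_A"] == 2

    def test_threshold_zero_retains_everything(self):
        _, counts = filter_community(self.table([0.9, 0.05, 0.05]), 0.0)
        assert counts["culture_A"] == 3

    def test_threshold_above_max_retains_nothing(self):
        _, counts = filter_community(self.table([0.6, 0.4]), 0.7)
        assert counts["culture_A"] == 0

    def test_generator_loop_counts(self):
        table = generate_community_table(n_lineages=18, n_noise=5,
                                         n_shared=7, seed=51)
        _, counts = filter_community(table)
        assert counts == {"culture_A": 13, "culture_B": 13}


class TestSharedLineages:
    def test_disjoint_cultures_share_nothing(self):
        table = pd.DataFrame({
            "lineage": ["L1", "L2"],
            "culture_A": [1.0, 0.0],
            "culture_B": [0.0, 1.0],
        })
        assert shared_lineages(table, ("culture_A", "culture_B")) == set()

    def test_identical_cultures_share_all_retained(self):
        table = pd.DataFrame({
            "lineage": ["L1", "L2", "L3"],
            "culture_A": [0.6, 0.395, 0.005],
            "culture_B": [0.6, 0.395, 0.005],
        })
        assert shared_lineages(table, ("culture_A", "culture_B")) == \
            {"L1", "L2"}

    def test_generator_loop_recovers_planted_shared_set(self):
        table = generate_community_table(n_lineages=18, n_noise=5,
                                         n_shared=7, seed=52)
        shared = shared_lineages(table, ("culture_A", "culture_B"))
        planted = {f"shared{i:02d}" for i in range(1, 8)}
        assert shared == planted

    def test_oxygen_preference_restriction(self):
        table = generate_community_table(seed=53)
        anaerobic = shared_lineages(
            table, ("culture_A", "culture_B"),
            oxygen_preference={"anaerobic_or_microaerophilic"},
        )
        assert anaerobic == shared_lineages(table, ("culture_A", "culture_B"))
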