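"""CP/ACP partitioning and Score1/Score2/Res-score partner scoring."""

import math

import numpy as np
import pytest

from pathsynergy import (
    PathwaySignature,
    combination_score,
    partition_cp_acp,
    res_score,
    resistance_pathways,
    select_disease_pathways,
)
from pathsynergy.synergy import CPPartition

from test_ranking import make_sig

# Sign-structure fixture mirroring the anchor drug's first-instance heatmap:
# six pathways the anchor reverses (opposite sign to the disease) and five it
# fails to reverse (same sign) — the latter are the expected CPs.
ACP_NAMES = (
    "PLK1 signaling events",
    "Resolution of Sister Chromatid Cohesion",
    "Kinesins",
    "Cell Cycle",
    "Phosphorylation of Emi 1",
    "Hedgehog Signaling Pathway",
)
CP_NAMES = (
    "Notch signaling",
    "Superpathway of steroid hormone biosynthesis",
    "Calcineurin-regulated NFAT-dependent transcription in lymphocytes",
    "Chromosome Maintenance",
    "Metabolism",
)


def anchor_fixture():
    acp_disease = (4.0, -3.8, 3.6, -4.2, 3.9, -3.5)
    cp_disease = (3.5, -3.2, 3.8, -3.0, 3.3)
    disease_z = dict(zip(ACP_NAMES, acp_disease))
    disease_z.update(zip(CP_NAMES, cp_disease))
    # anchor reverses the ACPs (opposite sign) and correlates on the CPs
    anchor_z = {name: -0.8 * z for name, z in zip(ACP_NAMES, acp_disease)}
    anchor_z.update({name: 0.9 * z for name, z in zip(CP_NAMES, cp_disease)})
    return make_sig("disease", disease_z), make_sig("anchor-1", anchor_z)


class TestPartition:
    def test_perfect_reversal_all_acp(self):
        dps = select_disease_pathways(make_sig("d", {"P1": 3.0, "P2": -3.0}))
        anchor = make_sig("a", {"P1": -3.0, "P2": 3.0})
        part = partition_cp_acp(anchor, dps)
        assert part.acp == {"P1", "P2"} and part.cp == frozenset()

    def test_perfect_correlation_all_cp(self):
        dps = select_disease_pathways(make_sig("d", {"P1": 3.0, "P2": -3.0}))
        anchor = make_sig("a", {"P1": 3.0, "P2": -3.0})
        part = partition_cp_acp(anchor, dps)
        assert part.cp == {"P1", "P2"} and part.acp == frozenset()

    def test_weak_anchor_is_undetermined(self):
        dps = select_disease_pathways(make_sig("d", {"P1": 3.0, "P2": -3.0}))
        anchor = make_sig("a", {"P1": 1.0, "P2": -3.0})
        part = partition_cp_acp(anchor, dps, compound_threshold=2.58)
        assert part.undetermined == {"P1"} and part.cp == {"P2"}
        # threshold 0 reproduces the pure sign rule
        pure = partition_cp_acp(anchor, dps, compound_threshold=0.0)
        assert pure.cp == {"P1", "P2"} and pure.undetermined == frozenset()

    def test_reproduces_named_cp_set(self):
        disease, anchor = anchor_fixture()
        part = partition_cp_acp(anchor, select_disease_pathways(disease))
        assert part.cp == frozenset(CP_NAMES)
        assert part.acp == frozenset(ACP_NAMES)
        assert part.undetermined == frozenset()

    def test_exact_partition_invariant(self):
        disease, anchor = anchor_fixture()
        dps = select_disease_pathways(disease)
        part = partition_cp_acp(anchor, dps)
        union = part.acp | part.cp | part.undetermined
        assert union == set(dps.selected)
        assert len(part.acp) + len(part.cp) + len(part.undetermined) == len(union)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            CPPartition("a", frozenset({"P1"}), frozenset({"P1"}), frozenset())

    def test_anchor_missing_all_selected_errors(self):
        dps = select_disease_pathways(make_sig("d", {"P1": 3.0}))
        anchor = make_sig("a", {"Q1": 3.0})
        with pytest.raises(ValueError, match="none of the selected"):
            partition_cp_acp(anchor, dps)


class TestCombinationScore:
    def setup_method(self):
        self.disease, self.anchor = anchor_fixture()
        self.dps = select_disease_pathways(self.disease)
        self.part = partition_cp_acp(self.anchor, self.dps)

    def test_negated_disease_scores_minus_one_on_any_subset(self):
        neg = make_sig("neg", {p: -z for p, z in self.disease.z_net.items()})
        for subset in (self.part.cp, self.part.acp, self.dps.selected):
            score, _ = combination_score(neg, self.dps, subset)
            assert score == pytest.approx(-1.0)

    def test_orthogonal_vector_matches_hand_pearson(self):
        subset = sorted(self.part.cp)
        values = [1.0, -1.0, 2.0, -2.0, 0.0]
        candidate = make_sig("c", dict(zip(subset, values)))
        y = [self.dps.z_disease[p] for p in subset]
        mx, my = np.mean(values), np.mean(y)
        cov = float(np.sum((np.array(values) - mx) * (np.array(y) - my)))
        expected = cov / (
            math.sqrt(sum((v - mx) ** 2 for v in values))
            * math.sqrt(sum((v - my) ** 2 for v in y))
        )
        score, _ = combination_score(candidate, self.dps, subset)
        assert score == pytest.approx(expected, abs=1e-12)

    def test_candidate_identical_to_anchor_correlates_on_cp(self):
        score, _ = combination_score(self.anchor, self.dps, self.part.cp)
        assert score is not None and score > 0.0

    def test_small_subset_undefined(self):
        score, reason = combination_score(self.anchor, self.dps, {"Notch signaling"})
        assert score is None and "required pathways" in reason


class TestResistance:
    def test_definition_example(self):
        # CP set {A,B,C}: A significant only in focal, B also in one other,
        # C not significant in focal -> resistance set is exactly {A}
        dps = select_disease_pathways(make_sig("focal", {"A": 3.0, "B": 3.0, "C": 2.0,
                                                         "D": -4.0}))
        part = CPPartition("anchor", frozenset(), frozenset({"A", "B", "C"}), frozenset({"D"}))
        other = make_sig("other", {"A": 0.5, "B": 3.2, "C": 0.1, "D": 0.0})
        rps = resistance_pathways(dps, [other], [part])
        assert rps.pathways == {"A"}

    def test_no_other_cell_lines_errors(self):
        dps = select_disease_pathways(make_sig("focal", {"A": 3.0}))
        part = CPPartition("anchor", frozenset(), frozenset({"A"}), frozenset())
        with pytest.raises(ValueError, match="other cell-line"):
            resistance_pathways(dps, [], [part])

    def test_named_three_pathway_fixture(self):
        # focal-line-specific subset of the anchor CPs across five cell lines
        specific = (
            "Notch signaling",
            "Superpathway of steroid hormone biosynthesis",
            "MAPK targets/Nuclear events mediated by MAP kinases",
        )
        shared = ("FOXA1 transcription factor network", "TGF Beta Signaling Pathway")
        cp_union = frozenset(specific) | frozenset(shared)
        disease_z = {p: 3.5 for p in cp_union}
        dps = select_disease_pathways(make_sig("focal", disease_z))
        part1 = CPPartition("anchor-1", frozenset(), frozenset(specific[:2]) | {shared[0]},
                            frozenset())
        part2 = CPPartition("anchor-2", frozenset(), frozenset(specific[2:]) | {shared[1]},
                            frozenset())
        others = [
            make_sig(cell, {p: (3.4 if p in shared else 0.4) for p in cp_union})
            for cell in ("BXPC3", "MiaPaca2", "HPAFII", "HS766T")
        ]
        rps = resistance_pathways(dps, others, [part1, part2])
        assert rps.pathways == frozenset(specific)
        assert rps.pathways <= part1.cp | part2.cp  # subset of the anchors' CPs

    def test_res_score_reverser_hits_minus_one(self):
        dps = select_disease_pathways(make_sig("focal", {"A": 3.0, "B": -3.0, "C": 4.0,
                                                         "D": 3.2}))
        part = CPPartition("anchor", frozenset({"D"}), frozenset({"A", "B", "C"}),
                           frozenset())
        other = make_sig("other", {"A": 0.0, "B": 0.0, "C": 0.0, "D": 3.0})
        rps = resistance_pathways(dps, [other], [part])
        assert rps.pathways == {"A", "B", "C"}
        reverser = make_sig("partner", {"A": -3.0, "B": 3.0, "C": -4.0, "D": 0.1})
        score, _ = res_score(reverser, dps, rps)
        assert score == pytest.approx(-1.0)

    def test_empty_resistance_set_gives_undefined_score(self):
        dps = select_disease_pathways(make_sig("focal", {"A": 3.0, "B": -3.0, "C": 4.0}))
        part = CPPartition("anchor", frozenset(), frozenset({"A", "B", "C"}), frozenset())
        other = make_sig("other", {"A": 3.0, "B": -3.0, "C": 4.0})  # nothing specific
        rps = resistance_pathways(dps, [other], [part])
        assert rps.pathways == frozenset()
        score, reason = res_score(make_sig("x", {"A": 1.0}), dps, rps)
        assert score is None and "empty" in reason
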