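import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from pmed.knowledge_base import (
    BiomarkerRule,
    Drug,
    DrugTargetEntry,
    KnowledgeBase,
    Method,
    NetworkEdge,
    ResponseSignature,
    SensitivitySignature,
)
from pmed.predictors import (
    DEGSelection,
    Direction,
    MethodPrediction,
    biomarker_rules_predict,
    connectivity_score,
    network_activity_predict,
    response_signature_predict,
    select_degs,
    sensitivity_signature_predict,
    target_expression_predict,
)
from conftest import make_profile


def kb_over(genes, **stores) -> KnowledgeBase:
    drugs = {d: Drug(d, d.upper()) for d in stores.pop("drug_ids", ["dA"])}
    kb = KnowledgeBase(drugs=drugs, gene_universe=frozenset(genes), **stores)
    kb.validate()
    return kb


class TestSelectDegs:
    def test_threshold_classification(self):
        degs = select_degs(make_profile({"g1": 2.5, "g2": -2.1, "g3": 1.0}))
        assert degs.up_genes == {"g1"} and degs.down_genes == {"g2"}

    def test_cap_keeps_largest_abs_z(self):
        z = {f"g{i:03d}": 2.0 + i * 0.001 for i in range(600)}
        degs = select_degs(make_profile(z), cap=500)
        assert len(degs.up_genes) == 500
        expected = set(sorted(z, key=lambda g: -z[g])[:500])
        assert degs.up_genes == expected

    def test_cap_tie_break_is_lexicographic(self):
        z = {"gB": 3.0, "gA": 3.0, "gC": -3.0}
        degs = select_degs(make_profile(z), cap=2)
        assert degs.all_genes == {"gA", "gB"}

    def test_all_below_threshold_is_empty(self):
        degs = select_degs(make_profile({"g1": 1.9, "g2": -1.5}))
        assert not degs.all_genes

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            DEGSelection(frozenset({"g"}), frozenset({"g"}))

    def test_non_positive_cap_rejected(self):
        with pytest.raises(ValueError):
            select_degs(make_profile({"g1": 2.5}), cap=0)


class TestBiomarkerRules:
    def test_indication_uses_upper_tail_of_max_qualifying_z(self):
        kb = kb_over(["geneB"], rules=[
            BiomarkerRule("r1", "geneB", "greater", 2.0, "indicate", "dA")])
        (pred,) = biomarker_rules_predict(make_profile({"geneB": 3.0}), kb)
        assert pred.direction is Direction.indicated
        assert pred.score == 3.0
        assert pred.p_value == pytest.approx(1.3499e-3, rel=1e-3)

    def test_contraindication_emitted_separately(self):
        kb = kb_over(["geneR"], rules=[
            BiomarkerRule("r1", "geneR", "greater", 1.0, "contraindicate", "dA")])
        (pred,) = biomarker_rules_predict(make_profile({"geneR": 1.5}), kb)
        assert pred.direction is Direction.contraindicated

    def test_no_firing_rule_means_no_prediction(self):
        kb = kb_over(["geneB"], rules=[
            BiomarkerRule("r1", "geneB", "greater", 2.0, "indicate", "dA")])
        assert biomarker_rules_predict(make_profile({"geneB": 1.0}), kb) == []

    def test_less_comparator_fires_below_threshold(self):
        kb = kb_over(["geneL"], rules=[
            BiomarkerRule("r1", "geneL", "less", -2.0, "indicate", "dA")])
        (pred,) = biomarker_rules_predict(make_profile({"geneL": -3.5}), kb)
        assert pred.score == 3.5

    def test_monotone_in_qualifying_z(self):
        kb = kb_over(["g"], rules=[
            BiomarkerRule("r1", "g", "greater", 2.0, "indicate", "dA")])
        p = [biomarker_rules_predict(make_profile({"g": z}), kb)[0] for z in (2.5, 3.5)]
        assert p[1].score >= p[0].score and p[1].p_value <= p[0].p_value


class TestTargetExpression:
    kb = kb_over(["gA", "gB"], targets=[
        DrugTargetEntry("dA", "gA", "inhibits"), DrugTargetEntry("dA", "gB", "inhibits")])

    def test_qualifying_target_drives_score(self):
        (pred,) = target_expression_predict(make_profile({"gA": 3.5, "gB": 1.0}), self.kb)
        assert pred.score == 3.5
        assert ("gA", 3.5) in pred.evidence and all(g != "gB" for g, _ in pred.evidence)

    def test_threshold_is_a_strict_floor_at_three(self):
        assert target_expression_predict(make_profile({"gA": 2.9, "gB": 1.0}), self.kb) == []
        (pred,) = target_expression_predict(make_profile({"gA": 3.0, "gB": 1.0}), self.kb)
        assert pred.score == 3.0

    def test_activating_targets_never_indicate(self):
        kb = kb_over(["gA"], targets=[DrugTargetEntry("dA", "gA", "activates")])
        assert target_expression_predict(make_profile({"gA": 5.0}), kb) == []

    def test_monotone_in_target_z(self):
        lo = target_expression_predict(make_profile({"gA": 3.1, "gB": 0.0}), self.kb)[0]
        hi = target_expression_predict(make_profile({"gA": 4.1, "gB": 0.0}), self.kb)[0]
        assert hi.score >= lo.score and hi.p_value <= lo.p_value


GENES6 = [f"g{i}" for i in range(1, 7)]
SIG6 = ResponseSignature("dA", "i1", tuple(GENES6))


class TestConnectivityScore:
    def test_hand_computed_value_up_only(self):
        # up at ranks {1, 5} of 6: a = b = 1/3, tie resolved to -b
        degs = DEGSelection(frozenset({"g1", "g5"}), frozenset())
        assert connectivity_score(degs, SIG6) == pytest.approx(-1 / 3)

    def test_extremal_concordance_is_the_maximum(self):
        degs = DEGSelection(frozenset({"g1", "g2"}), frozenset({"g5", "g6"}))
        best = connectivity_score(degs, SIG6)
        assert best == pytest.approx(0.75)
        for up in itertools.combinations(GENES6, 2):
            for down in itertools.combinations(set(GENES6) - set(up), 2):
                score = connectivity_score(
                    DEGSelection(frozenset(up), frozenset(down)), SIG6)
                assert score <= best + 1e-12

    def test_antisymmetric_under_up_down_swap(self):
        degs = DEGSelection(frozenset({"g1", "g4"}), frozenset({"g2", "g6"}))
        swapped = DEGSelection(degs.down_genes, degs.up_genes)
        assert connectivity_score(degs, SIG6) == pytest.approx(
            -connectivity_score(swapped, SIG6))

    def test_invariant_under_relabeling_non_set_genes(self):
        degs = DEGSelection(frozenset({"g1"}), frozenset({"g6"}))
        relabeled = ResponseSignature("dA", "i1", ("g1", "g3", "g2", "g5", "g4", "g6"))
        assert connectivity_score(degs, SIG6) == connectivity_score(degs, relabeled)

    def test_gene_outside_universe_rejected(self):
        degs = DEGSelection(frozenset({"gX"}), frozenset())
        with pytest.raises(ValueError, match="gX"):
            connectivity_score(degs, SIG6)

    @given(st.data())
    def test_bounds(self, data):
        n = data.draw(st.integers(min_value=2, max_value=12))
        genes = [f"g{i}" for i in range(n)]
        k_up = data.draw(st.integers(min_value=0, max_value=n // 2))
        k_down = data.draw(st.integers(min_value=0 if k_up else 1, max_value=n - max(k_up, 1)))
        perm = data.draw(st.permutations(genes))
        degs = DEGSelection(frozenset(perm[:k_up]), frozenset(perm[k_up:k_up + k_down]))
        sig = ResponseSignature("dA", "i1", tuple(data.draw(st.permutations(genes))))
        assert -1 <= connectivity_score(degs, sig) <= 1


class TestResponseSignaturePredict:
    def test_pure_reversal_scores_at_the_bottom(self):
        kb = kb_over(GENES6, response_signatures=[SIG6])
        degs = DEGSelection(frozenset({"g5", "g6"}), frozenset({"g1", "g2"}))
        (pred,) = response_signature_predict(degs, kb, n_perm=500, seed=0)
        assert pred.score == pytest.approx(-0.75)
        assert pred.p_value <= 0.05

    def test_mimicking_drug_excluded(self):
        kb = kb_over(GENES6, response_signatures=[SIG6])
        degs = DEGSelection(frozenset({"g1", "g2"}), frozenset({"g5", "g6"}))
        assert response_signature_predict(degs, kb, n_perm=200, seed=0) == []

    def test_permutation_p_matches_enumeration_up_only(self):
        genes = [f"g{i}" for i in range(1, 6)]
        sig = ResponseSignature("dA", "i1", tuple(genes))
        kb = kb_over(genes, response_signatures=[sig])
        degs = DEGSelection(frozenset({"g4"}), frozenset())
        n_perm = 10_000
        (pred,) = response_signature_predict(degs, kb, n_perm=n_perm, seed=3)
        scores = [
            connectivity_score(DEGSelection(frozenset({g}), frozenset()), sig)
            for g in genes
        ]
        p_exact = np.mean([s <= pred.score + 1e-12 for s in scores])
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(pred.p_value - p_exact) <= 3 * se + 1 / n_perm

    def test_score_is_mean_over_instances(self):
        rev = ResponseSignature("dA", "i2", tuple(reversed(GENES6)))
        kb = kb_over(GENES6, response_signatures=[SIG6, rev])
        degs = DEGSelection(frozenset({"g5", "g6"}), frozenset({"g1", "g2"}))
        s1 = connectivity_score(degs, SIG6)
        s2 = connectivity_score(degs, rev)
        preds = response_signature_predict(degs, kb, n_perm=100, seed=0)
        if (s1 + s2) / 2 < 0:
            assert preds[0].score == pytest.approx((s1 + s2) / 2)
        else:
            assert preds == []

    def test_same_seed_reproduces_p(self):
        kb = kb_over(GENES6, response_signatures=[SIG6])
        degs = DEGSelection(frozenset({"g6"}), frozenset())
        a = response_signature_predict(degs, kb, n_perm=300, seed=11)
        b = response_signature_predict(degs, kb, n_perm=300, seed=11)
        assert [(p.drug_id, p.p_value) for p in a] == [(p.drug_id, p.p_value) for p in b]

    def test_empty_degs_rejected(self):
        kb = kb_over(GENES6, response_signatures=[SIG6])
        with pytest.raises(ValueError):
            response_signature_predict(DEGSelection(frozenset(), frozenset()), kb)


class TestSensitivitySignature:
    def test_closed_form_example(self):
        z = make_profile({"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0})
        kb = kb_over(["g1", "g2", "g3", "g4"], sensitivity_signatures=[
            SensitivitySignature("dA", {"g3": 1, "g4": 1})])
        (pred,) = sensitivity_signature_predict(z, kb)
        assert pred.score == pytest.approx(1.0954, abs=1e-4)
        assert pred.p_value == pytest.approx(float(sps.norm.sf(pred.score)), rel=1e-12)

    def test_whole_universe_set_scores_zero_and_is_excluded(self):
        z = make_profile({"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0})
        kb = kb_over(["g1", "g2", "g3", "g4"], sensitivity_signatures=[
            SensitivitySignature("dA", {g: 1 for g in ["g1", "g2", "g3", "g4"]})])
        assert sensitivity_signature_predict(z, kb) == []

    def test_upshifted_resistance_set_scores_negative(self):
        z = make_profile({"g1": 5.0, "g2": 6.0, "g3": 0.0, "g4": -1.0, "g5": 0.5})
        kb = kb_over(list(z.values), sensitivity_signatures=[
            SensitivitySignature("dA", {"g1": -1, "g2": -1})])
        assert sensitivity_signature_predict(z, kb) == []

    def test_shift_invariance_with_mixed_signs(self):
        base = {"g1": 1.2, "g2": -0.5, "g3": 2.2, "g4": 0.3, "g5": -1.7}
        kb = kb_over(list(base), sensitivity_signatures=[
            SensitivitySignature("dA", {"g1": 1, "g5": -1})])
        (a,) = sensitivity_signature_predict(make_profile(base), kb)
        shifted = {g: v + 7.3 for g, v in base.items()}
        (b,) = sensitivity_signature_predict(make_profile(shifted), kb)
        assert a.score == pytest.approx(b.score, rel=1e-12)

    def test_degenerate_profile_rejected(self):
        z = make_profile({"g1": 1.0, "g2": 1.0})
        kb = kb_over(["g1", "g2"], sensitivity_signatures=[
            SensitivitySignature("dA", {"g1": 1, "g2": 1})])
        with pytest.raises(ValueError, match="degenerate"):
            sensitivity_signature_predict(z, kb)


class TestNetworkActivity:
    genes20 = [f"n{i:02d}" for i in range(20)]

    def kb(self, edges, targets=None):
        return kb_over(
            self.genes20,
            network=edges,
            targets=targets or [DrugTargetEntry("dA", "n00", "inhibits")],
        )

    def test_fully_concordant_regulon_hits_combinatorial_p(self):
        edges = [NetworkEdge("n00", f"n{i:02d}", +1, True) for i in (1, 2, 3, 4)]
        degs = DEGSelection(frozenset({"n01", "n02", "n03", "n04"}), frozenset())
        (pred,) = network_activity_predict(degs, self.kb(edges))
        assert pred.p_value == pytest.approx(1 / math.comb(20, 4), rel=1e-9)
        assert pred.score == pytest.approx(-math.log10(1 / math.comb(20, 4)))

    def test_empty_deg_selection_predicts_nothing(self):
        edges = [NetworkEdge("n00", "n01", +1, True)]
        degs = DEGSelection(frozenset(), frozenset())
        assert network_activity_predict(degs, self.kb(edges)) == []

    def test_balanced_sign_blocks_activity(self):
        edges = [NetworkEdge("n00", f"n{i:02d}", +1, True) for i in (1, 2, 3, 4)]
        degs = DEGSelection(frozenset({"n01", "n02"}), frozenset({"n03", "n04"}))
        assert network_activity_predict(degs, self.kb(edges)) == []

    def test_non_transcriptional_edges_ignored(self):
        edges = [NetworkEdge("n00", f"n{i:02d}", +1, False) for i in (1, 2, 3, 4)]
        degs = DEGSelection(frozenset({"n01", "n02", "n03", "n04"}), frozenset())
        assert network_activity_predict(degs, self.kb(edges)) == []

    def test_target_absent_from_network_is_non_evaluable(self):
        edges = [NetworkEdge("n05", "n01", +1, True)]
        degs = DEGSelection(frozenset({"n01"}), frozenset())
        assert network_activity_predict(degs, self.kb(edges)) == []


class TestMethodPredictionInvariants:
    def test_p_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            MethodPrediction("d", Method.target_expression, 1.0, 0.0)

    def test_only_biomarker_rules_contraindicate(self):
        with pytest.raises(ValueError):
            MethodPrediction("d", Method.target_expression, 1.0, 0.5,
                             Direction.contraindicated)
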