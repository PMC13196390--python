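"""Sign propagation, the three mechanism searches, and recovery scoring."""

import dataclasses

import networkx as nx
import pandas as pd
import pytest

from pepwire import (AnalysisConfig, AnnotationIndex, CausalEdge,
                     CausalNetwork, FeatureAnnotation, MechanismAssignment,
                     SiteAnnotation, SiteIndex, ValidationError,
                     assign_mechanism1, assign_mechanism2, assign_mechanism3,
                     evaluate_recovery, predict_mechanism2_signs,
                     propagate_perturbation_sign)
from pepwire.simulate import GroundTruth, MechanismLabel


class TestSignPropagation:
    def test_two_activating_edges_transmit_inhibition(self):
        path = [CausalEdge("K", "A", 1), CausalEdge("A", "B", 1)]
        assert propagate_perturbation_sign(path) == -1

    def test_one_inhibitory_edge_flips_the_sign(self):
        path = [CausalEdge("K", "A", 1), CausalEdge("A", "B", -1)]
        assert propagate_perturbation_sign(path) == +1

    def test_empty_path_returns_the_perturbation_itself(self):
        assert propagate_perturbation_sign([]) == -1
        assert propagate_perturbation_sign([], initial_sign=1) == 1

    def test_non_contiguous_path_errors(self):
        path = [CausalEdge("K", "A", 1), CausalEdge("B", "C", 1)]
        with pytest.raises(ValidationError, match="contiguous"):
            propagate_perturbation_sign(path)


class TestStabilitySignAlgebra:
    # hand-derived truth table: (effect, site phospho sign) ->
    #   (protein sign, peptide sign)
    TRUTH = {
        ("stabilizes_protein", +1): (+1, -1),
        ("stabilizes_protein", -1): (-1, +1),
        ("destabilizes_protein", +1): (-1, +1),
        ("destabilizes_protein", -1): (+1, -1),
    }

    @pytest.mark.parametrize("effect,phospho", sorted(TRUTH))
    def test_all_combinations_match_truth_table(self, effect, phospho):
        assert predict_mechanism2_signs(phospho, effect) == \
            self.TRUTH[(effect, phospho)]

    def test_non_stability_effect_rejected(self):
        with pytest.raises(ValidationError):
            predict_mechanism2_signs(1, "activates_protein")


# ---------------------------------------------------------------------------
# a hand-built minimal study for contract cases

def _diff_frame(layer, rows):
    """rows: (feature_id, treatment, log2FC, significant)"""
    columns = ["feature_id", "layer", "treatment", "log2FC", "t_statistic",
               "p_value", "adj_p_value", "significant", "direction"]
    return pd.DataFrame([
        {"feature_id": f, "layer": layer, "treatment": t, "log2FC": fc,
         "t_statistic": 0.0, "p_value": 0.0, "adj_p_value": 0.0,
         "significant": sig, "direction":
             ("up" if fc > 0 else "down") if sig else "none"}
        for f, t, fc, sig in rows], columns=columns)


class MiniStudy:
    """One M1-style motif: DRUG -| KIN (activating edge) -> site T10 on PROT,
    carried by phospho-peptide PEP_p.  Inhibition propagates as -1."""

    def __init__(self, edge_sign=1, chain_len=1):
        nodes = {"DRUG": dict(is_kinase=True, is_druggable=True),
                 "KIN": dict(is_kinase=True), "PROT": {}}
        edges = []
        previous = "DRUG"
        for i in range(chain_len - 1):
            hop = f"HOP{i}"
            nodes[hop] = dict(is_kinase=True)
            edges.append(CausalEdge(previous, hop, 1, "phosphorylation"))
            previous = hop
        edges.append(CausalEdge(previous, "KIN", edge_sign, "phosphorylation",
                                ("T", 161)))
        edges.append(CausalEdge("KIN", "PROT", 1, "phosphorylation", ("T", 10)))
        self.network = CausalNetwork.from_parts(nodes, edges)
        self.sites = SiteIndex([
            SiteAnnotation("KIN", "T", 161, "activates_protein", (previous,)),
            SiteAnnotation("PROT", "T", 10, None, ("KIN",)),
        ])
        self.annotations = AnnotationIndex([
            FeatureAnnotation("PEP_p", "phospho_hla_peptide",
                              peptide_sequence="AAAAAAAAA",
                              source_proteins=("PROT",),
                              site=("PROT", "T", 10)),
            FeatureAnnotation("KIN_T161", "phosphosite",
                              source_proteins=("KIN",),
                              site=("KIN", "T", 161)),
        ])
        self.inhibitor_map = {"drugA": frozenset({"DRUG"})}

    def run_m1(self, pep_sign, kinase_site_sign=None, cfg=None):
        cfg = cfg or AnalysisConfig()
        pep = _diff_frame("phospho_immunopeptidome",
                          [("PEP_p", "drugA", 2.0 * pep_sign, True)])
        phospho_rows = []
        if kinase_site_sign is not None:
            phospho_rows.append(("KIN_T161", "drugA", 2.0 * kinase_site_sign,
                                 True))
        phospho = _diff_frame("phosphoproteome", phospho_rows)
        return assign_mechanism1(pep, self.annotations, self.sites,
                                 self.network, self.inhibitor_map, phospho, cfg)


class TestMechanism1Contracts:
    def test_matching_signs_are_consistent(self):
        # inhibition -> KIN activity down -> peptide down
        (a,) = MiniStudy().run_m1(pep_sign=-1, kinase_site_sign=-1)
        assert a.predicted_peptide_sign == -1
        assert a.consistent
        assert a.causal_path == ("DRUG", "KIN", "PROT")
        assert a.supporting_signs["kinase_activity"] == (-1, -1)

    def test_flipped_observed_peptide_is_inconsistent(self):
        (a,) = MiniStudy().run_m1(pep_sign=+1, kinase_site_sign=-1)
        assert a.predicted_peptide_sign == -1
        assert not a.consistent

    def test_inhibitory_edge_predicts_upregulation(self):
        (a,) = MiniStudy(edge_sign=-1).run_m1(pep_sign=+1, kinase_site_sign=+1)
        assert a.predicted_peptide_sign == +1 and a.consistent

    def test_lenient_tolerates_unmeasured_support_strict_does_not(self):
        lenient = AnalysisConfig(consistency_mode="lenient")
        strict = AnalysisConfig(consistency_mode="strict")
        (a,) = MiniStudy().run_m1(pep_sign=-1, kinase_site_sign=None,
                                  cfg=lenient)
        assert a.consistent
        (b,) = MiniStudy().run_m1(pep_sign=-1, kinase_site_sign=None,
                                  cfg=strict)
        assert not b.consistent

    def test_path_beyond_step_cap_yields_no_assignment(self):
        study = MiniStudy(chain_len=3)  # DRUG -> HOP0 -> HOP1 -> KIN: 3 steps
        assert study.run_m1(pep_sign=-1) == []

    def test_raising_the_cap_never_removes_assignments(self):
        study = MiniStudy(chain_len=2)
        caps = [1, 2, 3, 4]
        counts = [len(study.run_m1(pep_sign=-1,
                                   cfg=AnalysisConfig(m1_max_steps=c)))
                  for c in caps]
        assert counts == sorted(counts)
        assert counts[-1] == 1


class TestPlantedRecovery:
    def _assignments(self, noiseless_study, noiseless_diffs, analysis):
        ann = AnnotationIndex(noiseless_study.annotations)
        sites = SiteIndex(noiseless_study.artifacts.site_annotations)
        net = noiseless_study.artifacts.network
        imap = noiseless_study.artifacts.inhibitor_map
        m1 = assign_mechanism1(noiseless_diffs["phospho_immunopeptidome"],
                               ann, sites, net, imap,
                               noiseless_diffs["phosphoproteome"], analysis)
        m2 = assign_mechanism2(noiseless_diffs["immunopeptidome"], ann, sites,
                               net, imap, noiseless_diffs["phosphoproteome"],
                               noiseless_diffs["proteome"], analysis)
        m3 = assign_mechanism3(noiseless_diffs["immunopeptidome"],
                               noiseless_diffs["proteome"],
                               noiseless_diffs["phosphoproteome"],
                               noiseless_study.artifacts.tf_targets, sites,
                               ann, net, imap, analysis)
        return m1, m2, m3

    def test_zero_noise_recovery_is_exact_per_mechanism(self, noiseless_study,
                                                        noiseless_diffs,
                                                        analysis):
        m1, m2, m3 = self._assignments(noiseless_study, noiseless_diffs,
                                       analysis)
        report = evaluate_recovery([*m1, *m2, *m3], noiseless_study.truth)
        for mech in ("M1", "M2", "M3"):
            score = report.per_mechanism[mech]
            assert score.precision == 1.0 and score.recall == 1.0, mech

    def test_every_emitted_path_exists_in_the_network(self, noiseless_study,
                                                      noiseless_diffs,
                                                      analysis):
        graph = nx.DiGraph(noiseless_study.artifacts.network.graph)
        for group in self._assignments(noiseless_study, noiseless_diffs,
                                       analysis):
            for a in group:
                for u, v in zip(a.causal_path, a.causal_path[1:]):
                    assert graph.has_edge(u, v), (a.mechanism, a.causal_path)

    def test_propagation_matches_generator_bookkeeping(self, noiseless_study):
        """Cross-module oracle: the generator's expected peptide sign equals
        sign propagation along its own planted path (with the stability flip
        applied for M2)."""
        net = noiseless_study.artifacts.network
        sites = SiteIndex(noiseless_study.artifacts.site_annotations)
        tf_targets = noiseless_study.artifacts.tf_targets.set_index(
            ["tf_id", "target_id"])["sign"]
        for label in noiseless_study.truth.mechanism_labels:
            path = label.path
            edges = []
            for u, v in zip(path, path[1:]):
                sign = sorted(net.edge_signs(u, v))[0]
                edges.append(CausalEdge(u, v, sign))
            propagated = propagate_perturbation_sign(edges)
            if label.mechanism == "M1":
                expected = propagated
            elif label.mechanism == "M2":
                site_ann = [s for s in sites.stability_sites(path[-1])][0]
                # propagation into the site, then the stability flip
                _, expected = predict_mechanism2_signs(
                    propagated, site_ann.functional_effect)
            else:
                # path ends at the target; TF activity is the propagated sign
                # up to the TF times the signed TF->target relation
                expected = propagated
            assert expected == label.expected_sign, label


class TestRecoveryScoring:
    def _truth(self, n=10):
        labels = [MechanismLabel(f"PEP{i}", "drugA", "M1", ("K", "P"), -1)
                  for i in range(n)]
        return GroundTruth(mechanism_labels=labels)

    def _assignment(self, pep, consistent=True):
        return MechanismAssignment(
            peptide_feature_id=pep, treatment="drugA", mechanism="M1",
            causal_path=("K", "P"), predicted_peptide_sign=-1,
            observed_peptide_sign=-1, consistent=consistent)

    def test_perfect_recovery(self):
        truth = self._truth()
        assignments = [self._assignment(f"PEP{i}") for i in range(10)]
        report = evaluate_recovery(assignments, truth)
        assert report.overall.precision == report.overall.recall == 1.0

    def test_nine_correct_one_spurious(self):
        truth = self._truth()
        assignments = [self._assignment(f"PEP{i}") for i in range(9)]
        assignments.append(self._assignment("SPURIOUS"))
        report = evaluate_recovery(assignments, truth)
        assert report.overall.precision == pytest.approx(0.9)
        assert report.overall.recall == pytest.approx(0.9)

    def test_empty_assignments_flag_undefined_precision(self):
        report = evaluate_recovery([], self._truth())
        assert report.overall.recall == 0.0
        assert report.overall.precision == 1.0
        assert report.overall.precision_undefined

    def test_inconsistent_assignments_do_not_count(self):
        truth = self._truth(n=2)
        assignments = [self._assignment("PEP0"),
                       self._assignment("PEP1", consistent=False)]
        report = evaluate_recovery(assignments, truth)
        assert report.overall.recall == pytest.approx(0.5)
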