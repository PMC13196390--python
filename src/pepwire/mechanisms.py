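"""Three-mechanism assignment of drug-modulated HLA-I peptides.

A kinase-inhibitor perturbation enters the causal network as a -1 (loss of
activity) at the inhibited kinase and propagates along directed signed edges:
the predicted sign of any downstream readout is the initial sign times the
product of edge signs along the path.

Mechanism 1 (direct peptide phosphorylation): a significantly modulated
phosphorylated HLA-I peptide whose phosphosite has an upstream kinase that is
itself reachable from an inhibited kinase.  The predicted peptide sign is the
propagated phospho sign at the site.

Mechanism 2 (source-protein stability): a significantly modulated HLA-I
peptide whose source protein carries a stability-regulating phosphosite.
Propagation gives the site's phospho sign; the stability change is that sign
times +1 (stabilizing site) or -1 (destabilizing site); a more stable protein
is degraded less, so peptide supply moves opposite to stability
(peptide sign = -stability sign).

Mechanism 3 (transcriptional regulation): a transcription factor reachable
from an inhibited kinase, its activity read from the propagated phospho sign
at its activity site (flipped for inhibitory sites); each signed TF->target
relation predicts the target protein and hence its peptides.

Consistency verdicts compare predictions to the observed differential signs.
In ``lenient`` mode only the peptide sign must match, and supporting layers
(upstream-kinase activation-site phospho, site phospho, protein abundance)
are checked only when measured and significant; in ``strict`` mode every
supporting observation must be present and matching.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import AnalysisConfig
from .errors import ValidationError
from .model import AnnotationIndex, FeatureAnnotation
from .network import CausalEdge, CausalNetwork, SiteAnnotation, SiteIndex
from .quant import significant_sign_map

logger = logging.getLogger("pepwire")

MECHANISMS = ("M1", "M2", "M3")

ASSIGNMENT_COLUMNS = (
    "peptide_feature_id", "treatment", "mechanism", "causal_path",
    "upstream_kinase", "source_protein", "site", "tf",
    "predicted_peptide_sign", "observed_peptide_sign", "supporting_signs",
    "n_paths_agree", "n_paths_disagree", "consistent", "mode", "flags")


@dataclass
class MechanismAssignment:
    """One peptide x treatment x mechanism explanation."""

    peptide_feature_id: str
    treatment: str
    mechanism: str
    causal_path: tuple[str, ...]
    predicted_peptide_sign: int
    observed_peptide_sign: Optional[int]
    upstream_kinase: Optional[str] = None
    source_protein: Optional[str] = None
    site: Optional[tuple[str, str, int]] = None
    tf: Optional[str] = None
    supporting_signs: dict = field(default_factory=dict)
    n_paths_agree: int = 0
    n_paths_disagree: int = 0
    consistent: bool = False
    mode: str = "lenient"
    flags: tuple[str, ...] = ()

    def to_record(self) -> dict:
        return {
            "peptide_feature_id": self.peptide_feature_id,
            "treatment": self.treatment,
            "mechanism": self.mechanism,
            "causal_path": "->".join(self.causal_path),
            "upstream_kinase": self.upstream_kinase,
            "source_protein": self.source_protein,
            "site": "" if self.site is None else
                    f"{self.site[0]}:{self.site[1]}:{self.site[2]}",
            "tf": self.tf,
            "predicted_peptide_sign": self.predicted_peptide_sign,
            "observed_peptide_sign": self.observed_peptide_sign,
            "supporting_signs": ";".join(
                f"{k}={e}|{'NA' if o is None else o}"
                for k, (e, o) in sorted(self.supporting_signs.items())),
            "n_paths_agree": self.n_paths_agree,
            "n_paths_disagree": self.n_paths_disagree,
            "consistent": self.consistent,
            "mode": self.mode,
            "flags": ",".join(self.flags),
        }


def assignments_frame(assignments: Sequence[MechanismAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.to_record() for a in assignments],
                        columns=list(ASSIGNMENT_COLUMNS))


# ---------------------------------------------------------------------------
# sign propagation

def propagate_perturbation_sign(path: Sequence[CausalEdge],
                                initial_sign: int = -1) -> int:
    """Propagate a perturbation sign along a contiguous directed edge path.

    Returns ``initial_sign`` times the product of edge signs; the empty path
    returns ``initial_sign`` itself (the perturbed node's own activity, -1
    under inhibition).
    """
    sign = initial_sign
    for i, edge in enumerate(path):
        if i and path[i - 1].target != edge.source:
            raise ValidationError(
                f"path is not contiguous at {path[i - 1].target!r} -> "
                f"{edge.source!r}")
        sign *= edge.sign
    return sign


def _hop_signs(network: CausalNetwork, u: str, v: str) -> frozenset[int]:
    signs = network.edge_signs(u, v)
    if not signs:
        raise ValidationError(f"no edge {u!r}->{v!r} in the network")
    return signs


def path_sign_products(network: CausalNetwork,
                       node_path: Sequence[str]) -> frozenset[int]:
    """All achievable edge-sign products along a node path (parallel edges
    with different signs yield several products).  The single-node path has
    product +1."""
    products = {1}
    for u, v in zip(node_path, node_path[1:]):
        hop = _hop_signs(network, u, v)
        products = {p * s for p in products for s in hop}
    return frozenset(products)


def shortest_signed_paths(network: CausalNetwork, sources: Iterable[str],
                          target: str, max_steps: int
                          ) -> list[tuple[tuple[str, ...], int]]:
    """All shortest directed node paths (as (path, sign-product) pairs) from
    any source to ``target`` with at most ``max_steps`` edges.

    If the target is itself a source the empty path (single node, product +1)
    is returned.  Paths are enumerated breadth-first; every (path, product)
    combination over parallel edges is reported.
    """
    graph = network.graph
    sources = [s for s in sources if s in graph]
    if target not in graph:
        return []
    if target in sources:
        return [((target,), 1)]
    # breadth-first layers from the source set, keeping all shortest predecessors
    preds: dict[str, set[str]] = {}
    depth = {s: 0 for s in sources}
    frontier = list(sources)
    found_at = None
    level = 0
    while frontier and (found_at is None) and level < max_steps:
        level += 1
        nxt = []
        for u in frontier:
            for v in graph.successors(u):
                if v in depth and depth[v] < level:
                    continue
                if v not in depth:
                    depth[v] = level
                    nxt.append(v)
                preds.setdefault(v, set()).add(u)
        if target in depth and depth[target] == level:
            found_at = level
        frontier = nxt
    if found_at is None:
        return []

    paths: list[tuple[str, ...]] = []

    def backtrack(node: str, suffix: tuple[str, ...]) -> None:
        if depth[node] == 0:
            paths.append((node,) + suffix)
            return
        for p in sorted(preds[node]):
            if depth[p] == depth[node] - 1:
                backtrack(p, (node,) + suffix)

    backtrack(target, ())
    out = []
    for node_path in paths:
        for product in sorted(path_sign_products(network, node_path)):
            out.append((node_path, product))
    return out


# ---------------------------------------------------------------------------
# observation helpers

def observed_kinase_activity(kinase: str, site_index: SiteIndex,
                             annotations: AnnotationIndex,
                             phospho_signs: Mapping[tuple[str, str], int],
                             treatment: str) -> tuple[Optional[int], bool]:
    """Read a kinase's activity sign from its annotated activity-site
    phosphosites in the phosphoproteome (inhibitory sites flip the sign).
    Returns (sign or None, tie_flag); the majority sign wins, ties are None.
    """
    votes = []
    for site_ann in site_index.activity_sites(kinase):
        feature = annotations.site_to_phosphosite_feature.get(site_ann.site)
        if feature is None:
            continue
        observed = phospho_signs.get((feature, treatment))
        if observed is None:
            continue
        flip = -1 if site_ann.functional_effect == "inhibits_protein" else 1
        votes.append(observed * flip)
    if not votes:
        return None, False
    tally = Counter(votes)
    (top_sign, top_n), = tally.most_common(1)
    if len(tally) > 1 and tally[1] == tally[-1]:
        return None, True
    return top_sign, False


def _supporting_ok(supporting: Mapping[str, tuple[int, Optional[int]]],
                   mode: str) -> bool:
    for expected, observed in supporting.values():
        if observed is None:
            if mode == "strict":
                return False
            continue
        if observed != expected:
            return False
    return True


def _finalize(candidates, observed, supporting_for, mode):
    """Pick the representative candidate and the consistency verdict.

    ``candidates`` are (path, predicted_sign, context) tuples; an agreeing
    candidate (predicted == observed) is preferred, shorter paths first.
    Returns (representative, n_agree, n_disagree, consistent).
    """
    ordered = sorted(candidates, key=lambda c: (len(c[0]), c[0]))
    n_agree = sum(1 for c in ordered if observed is not None and c[1] == observed)
    n_disagree = len(ordered) - n_agree
    consistent = False
    representative = ordered[0]
    for cand in ordered:
        if observed is not None and cand[1] == observed:
            supporting = supporting_for(cand)
            if _supporting_ok(supporting, mode):
                representative = cand
                consistent = True
                break
    else:
        supporting = supporting_for(representative)
    return representative, supporting, n_agree, n_disagree, consistent


def _inhibited_sources(network: CausalNetwork,
                       inhibitor_map: Mapping[str, frozenset[str]],
                       treatment: str) -> frozenset[str]:
    sources: set[str] = set()
    for kinase in inhibitor_map.get(treatment, frozenset()):
        sources |= network.expand_members(kinase)
    return frozenset(sources)


def _phospho_edge_sign(network: CausalNetwork, kinase: str,
                       site: tuple[str, str, int]) -> tuple[int, tuple[str, ...]]:
    """Sign of the kinase's phosphorylation edge onto (protein, residue, pos);
    defaults to +1 with a flag when the network lacks the residue-level edge."""
    protein, residue, position = site
    signs = network.phospho_edge_signs(kinase, protein, (residue, position))
    if not signs:
        signs = network.phospho_edge_signs(kinase, protein)
    if not signs:
        return 1, ("phospho_edge_missing",)
    return sorted(signs)[0], ()


# ---------------------------------------------------------------------------
# mechanism 1: direct phosphorylation of the presented peptide

def assign_mechanism1(phospho_pep_results: pd.DataFrame,
                      annotations: AnnotationIndex,
                      site_annotations: SiteIndex,
                      network: CausalNetwork,
                      inhibitor_map: Mapping[str, frozenset[str]],
                      phospho_results: pd.DataFrame,
                      cfg: AnalysisConfig) -> list[MechanismAssignment]:
    pep_signs = significant_sign_map(phospho_pep_results)
    phospho_signs = significant_sign_map(phospho_results)
    assignments: list[MechanismAssignment] = []
    skipped = 0
    for (feature_id, treatment), observed in sorted(pep_signs.items()):
        ann = annotations.get(feature_id)
        if ann is None or ann.site is None:
            skipped += 1
            continue
        site_ann = site_annotations.get(ann.site)
        upstream = site_ann.upstream_kinases if site_ann else ()
        if not upstream:
            skipped += 1
            continue
        sources = _inhibited_sources(network, inhibitor_map, treatment)
        candidates = []
        for kinase in upstream:
            edge_sign, edge_flags = _phospho_edge_sign(network, kinase, ann.site)
            for node_path, product in shortest_signed_paths(
                    network, sources, kinase, cfg.m1_max_steps):
                activity = -1 * product
                predicted = activity * edge_sign
                full_path = node_path + (ann.site[0],)
                candidates.append((full_path, predicted,
                                   {"kinase": kinase, "activity": activity,
                                    "flags": edge_flags}))
        if not candidates:
            continue

        def supporting_for(cand):
            kinase = cand[2]["kinase"]
            obs, _tie = observed_kinase_activity(
                kinase, site_annotations, annotations, phospho_signs, treatment)
            return {"kinase_activity": (cand[2]["activity"], obs)}

        rep, supporting, n_agree, n_disagree, consistent = _finalize(
            candidates, observed, supporting_for, cfg.consistency_mode)
        assignments.append(MechanismAssignment(
            peptide_feature_id=feature_id, treatment=treatment, mechanism="M1",
            causal_path=rep[0], predicted_peptide_sign=rep[1],
            observed_peptide_sign=observed,
            upstream_kinase=rep[2]["kinase"],
            source_protein=ann.site[0], site=ann.site,
            supporting_signs=supporting, n_paths_agree=n_agree,
            n_paths_disagree=n_disagree, consistent=consistent,
            mode=cfg.consistency_mode, flags=rep[2]["flags"]))
    if skipped:
        logger.info("mechanism 1: skipped %d significant phospho-peptides "
                    "without usable site annotation", skipped)
    return assignments


# ---------------------------------------------------------------------------
# mechanism 2: source-protein stability

_STABILITY_MULT = {"stabilizes_protein": 1, "destabilizes_protein": -1}


def predict_mechanism2_signs(site_phospho_sign: int,
                             functional_effect: str) -> tuple[int, int]:
    """(predicted protein sign, predicted peptide sign) from the stability
    site's phospho sign and its annotated effect.

    stability sign = phospho sign x (+1 stabilizing / -1 destabilizing);
    protein follows stability; peptide supply is anti-correlated with
    stability (a stabler protein is degraded less).
    """
    mult = _STABILITY_MULT.get(functional_effect)
    if mult is None:
        raise ValidationError(
            f"{functional_effect!r} is not a stability effect")
    stability = site_phospho_sign * mult
    return stability, -stability


def assign_mechanism2(pep_results: pd.DataFrame,
                      annotations: AnnotationIndex,
                      site_annotations: SiteIndex,
                      network: CausalNetwork,
                      inhibitor_map: Mapping[str, frozenset[str]],
                      phospho_results: pd.DataFrame,
                      protein_results: pd.DataFrame,
                      cfg: AnalysisConfig) -> list[MechanismAssignment]:
    pep_signs = significant_sign_map(pep_results)
    phospho_signs = significant_sign_map(phospho_results)
    protein_signs = significant_sign_map(protein_results)
    assignments: list[MechanismAssignment] = []
    skipped_sites = 0
    for (feature_id, treatment), observed in sorted(pep_signs.items()):
        ann = annotations.get(feature_id)
        if ann is None:
            continue
        sources = _inhibited_sources(network, inhibitor_map, treatment)
        candidates = []
        for protein in ann.source_proteins:
            for site_ann in site_annotations.stability_sites(protein):
                if not site_ann.upstream_kinases:
                    skipped_sites += 1
                    continue
                for kinase in site_ann.upstream_kinases:
                    edge_sign, edge_flags = _phospho_edge_sign(
                        network, kinase, site_ann.site)
                    for node_path, product in shortest_signed_paths(
                            network, sources, kinase, cfg.m2_max_steps):
                        activity = -1 * product
                        site_sign = activity * edge_sign
                        protein_sign, peptide_sign = predict_mechanism2_signs(
                            site_sign, site_ann.functional_effect)
                        full_path = node_path + (protein,)
                        candidates.append((full_path, peptide_sign, {
                            "kinase": kinase, "activity": activity,
                            "site_ann": site_ann, "site_sign": site_sign,
                            "protein_sign": protein_sign, "protein": protein,
                            "flags": edge_flags}))
        if not candidates:
            continue

        def supporting_for(cand):
            ctx = cand[2]
            site_feature = annotations.site_to_phosphosite_feature.get(
                ctx["site_ann"].site)
            site_obs = phospho_signs.get((site_feature, treatment)) \
                if site_feature else None
            prot_obs = protein_signs.get((ctx["protein"], treatment))
            kin_obs, _tie = observed_kinase_activity(
                ctx["kinase"], site_annotations, annotations, phospho_signs,
                treatment)
            return {"site_phospho": (ctx["site_sign"], site_obs),
                    "protein_abundance": (ctx["protein_sign"], prot_obs),
                    "kinase_activity": (ctx["activity"], kin_obs)}

        rep, supporting, n_agree, n_disagree, consistent = _finalize(
            candidates, observed, supporting_for, cfg.consistency_mode)
        ctx = rep[2]
        assignments.append(MechanismAssignment(
            peptide_feature_id=feature_id, treatment=treatment, mechanism="M2",
            causal_path=rep[0], predicted_peptide_sign=rep[1],
            observed_peptide_sign=observed, upstream_kinase=ctx["kinase"],
            source_protein=ctx["protein"], site=ctx["site_ann"].site,
            supporting_signs=supporting, n_paths_agree=n_agree,
            n_paths_disagree=n_disagree, consistent=consistent,
            mode=cfg.consistency_mode, flags=ctx["flags"]))
    if skipped_sites:
        logger.info("mechanism 2: skipped %d stability sites without an "
                    "upstream kinase", skipped_sites)
    return assignments


# ---------------------------------------------------------------------------
# mechanism 3: transcriptional regulation

def assign_mechanism3(pep_results: pd.DataFrame,
                      protein_results: pd.DataFrame,
                      phospho_results: pd.DataFrame,
                      tf_targets: pd.DataFrame,
                      site_annotations: SiteIndex,
                      annotations: AnnotationIndex,
                      network: CausalNetwork,
                      inhibitor_map: Mapping[str, frozenset[str]],
                      cfg: AnalysisConfig) -> list[MechanismAssignment]:
    pep_signs = significant_sign_map(pep_results)
    phospho_signs = significant_sign_map(phospho_results)
    protein_signs = significant_sign_map(protein_results)

    # significant peptides grouped by (source protein, treatment)
    peptides_by_protein: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for (feature_id, treatment), observed in pep_signs.items():
        ann = annotations.get(feature_id)
        if ann is None:
            continue
        for protein in ann.source_proteins:
            peptides_by_protein.setdefault((protein, treatment), []).append(
                (feature_id, observed))

    targets_by_tf: dict[str, list[tuple[str, int]]] = {}
    for _, row in tf_targets.iterrows():
        targets_by_tf.setdefault(row["tf_id"], []).append(
            (row["target_id"], int(row["sign"])))

    treatments = sorted(inhibitor_map)
    assignments: list[MechanismAssignment] = []
    for treatment in treatments:
        sources = _inhibited_sources(network, inhibitor_map, treatment)
        for tf in network.tf_nodes():
            tf_paths = shortest_signed_paths(network, sources, tf,
                                             cfg.m3_max_steps)
            if not tf_paths:
                continue
            activity_sites = site_annotations.activity_sites(tf)
            # each (path, product, activity-site interpretation) is a candidate
            tf_candidates = []
            for node_path, product in tf_paths:
                phospho_sign = -1 * product
                if activity_sites:
                    for site_ann in activity_sites:
                        mult = -1 if site_ann.functional_effect == "inhibits_protein" else 1
                        tf_candidates.append((node_path, phospho_sign,
                                              phospho_sign * mult, site_ann, ()))
                else:
                    tf_candidates.append((node_path, phospho_sign, phospho_sign,
                                          None, ("no_activity_site",)))
            for target, reg_sign in sorted(targets_by_tf.get(tf, [])):
                for feature_id, observed in sorted(
                        peptides_by_protein.get((target, treatment), [])):
                    candidates = []
                    for node_path, phospho_sign, activity, site_ann, flags in tf_candidates:
                        predicted = activity * reg_sign
                        full_path = node_path + (target,)
                        candidates.append((full_path, predicted, {
                            "tf": tf, "phospho_sign": phospho_sign,
                            "activity": activity, "site_ann": site_ann,
                            "target": target, "protein_sign": predicted,
                            "flags": flags}))

                    def supporting_for(cand):
                        ctx = cand[2]
                        supp = {}
                        if ctx["site_ann"] is not None:
                            site_feature = annotations.site_to_phosphosite_feature.get(
                                ctx["site_ann"].site)
                            site_obs = phospho_signs.get((site_feature, treatment)) \
                                if site_feature else None
                            supp["tf_site_phospho"] = (ctx["phospho_sign"], site_obs)
                        supp["protein_abundance"] = (
                            ctx["protein_sign"],
                            protein_signs.get((ctx["target"], treatment)))
                        return supp

                    rep, supporting, n_agree, n_disagree, consistent = _finalize(
                        candidates, observed, supporting_for,
                        cfg.consistency_mode)
                    ctx = rep[2]
                    assignments.append(MechanismAssignment(
                        peptide_feature_id=feature_id, treatment=treatment,
                        mechanism="M3", causal_path=rep[0],
                        predicted_peptide_sign=rep[1],
                        observed_peptide_sign=observed, tf=ctx["tf"],
                        source_protein=ctx["target"],
                        site=None if ctx["site_ann"] is None else ctx["site_ann"].site,
                        supporting_signs=supporting, n_paths_agree=n_agree,
                        n_paths_disagree=n_disagree, consistent=consistent,
                        mode=cfg.consistency_mode, flags=ctx["flags"]))
    return assignments


# ---------------------------------------------------------------------------
# recovery scoring against planted ground truth

@dataclass(frozen=True)
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    n_true_positive: int
    n_predicted: int
    n_planted: int
    precision_undefined: bool = False


@dataclass(frozen=True)
class RecoveryReport:
    overall: RecoveryScore
    per_mechanism: dict


def _score(predicted: set, planted: set) -> RecoveryScore:
    tp = len(predicted & planted)
    undefined = len(predicted) == 0
    precision = 1.0 if undefined else tp / len(predicted)
    recall = 0.0 if not planted else tp / len(planted)
    f1 = 0.0 if precision + recall == 0 else \
        2 * precision * recall / (precision + recall)
    return RecoveryScore(precision=precision, recall=recall, f1=f1,
                         n_true_positive=tp, n_predicted=len(predicted),
                         n_planted=len(planted),
                         precision_undefined=undefined)


def evaluate_recovery(assignments: Sequence[MechanismAssignment],
                      truth) -> RecoveryReport:
    """Precision/recall of consistent assignments against the generator's
    planted mechanism labels, per mechanism and overall.

    A (peptide, treatment, mechanism) triple is a true positive iff it was
    planted and the assignment is consistent.  Empty predictions score
    precision 1.0 by convention, flagged via ``precision_undefined``.
    """
    predicted = {(a.peptide_feature_id, a.treatment, a.mechanism)
                 for a in assignments if a.consistent}
    planted = {(l.peptide_id, l.treatment, l.mechanism)
               for l in truth.mechanism_labels}
    per_mechanism = {}
    for mech in MECHANISMS:
        per_mechanism[mech] = _score(
            {p for p in predicted if p[2] == mech},
            {p for p in planted if p[2] == mech})
    return RecoveryReport(overall=_score(predicted, planted),
                          per_mechanism=per_mechanism)
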