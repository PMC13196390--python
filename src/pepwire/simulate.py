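"""Synthetic multi-omic study generator with planted ground truth.

Emulates a four-condition (untreated control plus three kinase inhibitors),
triplicate immunopeptidomics study: a signed causal network carrying planted
mechanism motifs, four log2 intensity layers with treatment effects routed
through those motifs, intensity-dependent (left-censored) missingness, and a
disease-cohort / benign-tissue presence structure with planted
tumor-associated antigens.  Every random draw flows from ``rng_seed`` so that
identical configs reproduce identical artifacts byte for byte.

Three motif templates, one per mechanism:

* M1 - inhibited kinase -> upstream kinase -> phosphosite carried by a
  phosphorylated HLA-I peptide (direct peptide phosphorylation);
* M2 - inhibited kinase -> upstream kinase -> stability-regulating
  phosphosite on a source protein whose HLA-I peptide moves opposite to the
  protein's stability;
* M3 - inhibited kinase -> (optional intermediate kinase) -> transcription
  factor with an activity site -> signed TF->target relations whose target
  proteins and derived peptides follow TF activity.

The planted effect sign of every feature is the sign-propagation product of
its motif, so mechanism consistency holds by construction; the ground-truth
ledger records every planted effect, mechanism label, tumor-associated
antigen and cancer-testis antigen for recovery scoring.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import LAYERS
from .errors import ConfigError, ValidationError
from .model import (AnnotationIndex, FeatureAnnotation, IntensityMatrix,
                    SampleDesign)
from .network import (CausalEdge, CausalNetwork, SiteAnnotation,
                      validate_tf_targets)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: HLA-I alleles used for synthetic binder calls (a B-lymphoid allele set).
ALLELES = ("HLA-A*02:01", "HLA-A*30:01", "HLA-B*15:10", "HLA-B*18:01",
           "HLA-C*03:04", "HLA-C*12:03")

APPM_TARGETS = ("APPM_TAP1", "APPM_TAPBP", "APPM_B2M")


def derive_seed(base_seed: int, label: str) -> int:
    """Stable child seed below 2**31 from a base seed and a stage label."""
    return zlib.crc32(f"{base_seed}:{label}".encode()) % (2 ** 31)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic generator.

    The default design mirrors a four-condition, triplicate kinase-inhibitor
    study (BCR-ABL, SFK and JNK inhibition).  Background layer sizes are
    desk-scale reductions of the real layers; ~20% of background features are
    drug-modulated with |log2FC| between 2 and 10, matching the observed
    fraction and effect range of modulated peptides, and mechanism-motif
    features carry |log2FC| = 4 (16-fold, mid-range of the exemplified
    mechanism peptides).
    """

    n_background_nodes: int = 200
    n_motifs_per_mechanism: int = 10
    n_background_peptides: int = 2000
    n_background_phospho_peptides: int = 30
    n_background_proteins: int = 800
    n_background_phosphosites: int = 1500
    background_modulated_fraction: float = 0.2
    background_effect_min: float = 2.0
    background_effect_max: float = 10.0
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    replicate_noise_sd: float = 0.5
    planted_effect_log2: float = 4.0
    missing_p_max: float = 0.3
    missing_midpoint: Optional[float] = None  # default: baseline 5th percentile
    missing_slope: float = 1.0
    cohort_size: int = 21
    benign_size: int = 30
    n_planted_taas: int = 25
    n_decoy_shared: int = 50
    n_cta_proteins: int = 5
    taa_cohort_presence_p: float = 0.1
    decoy_presence_p: float = 0.3
    benign_background_p: float = 0.15
    nonbinder_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background_nodes", "n_background_peptides",
                     "n_background_proteins", "n_background_phosphosites",
                     "n_background_phospho_peptides", "cohort_size",
                     "benign_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        for name in ("background_modulated_fraction", "missing_p_max",
                     "taa_cohort_presence_p", "decoy_presence_p",
                     "benign_background_p", "nonbinder_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.planted_effect_log2 <= 0.5:
            raise ConfigError("planted_effect_log2 must exceed the 0.5 "
                              "fold-change threshold by construction")
        if self.background_effect_min <= 0.5:
            raise ConfigError("background_effect_min must exceed 0.5")
        if self.replicate_noise_sd < 0 or self.baseline_log2_sd < 0:
            raise ConfigError("standard deviations must be >= 0")

    def design(self) -> SampleDesign:
        return SampleDesign.default()

    def inhibitor_map(self) -> dict[str, frozenset[str]]:
        return {"imatinib": frozenset({"BCR_ABL"}),
                "PP2": frozenset({"SFK"}),
                "SP600125": frozenset({"JNK"})}


@dataclass(frozen=True)
class PlantedEffect:
    layer: str
    feature_id: str
    treatment: str
    log2fc: float


@dataclass(frozen=True)
class MechanismLabel:
    peptide_id: str
    treatment: str
    mechanism: str
    path: tuple[str, ...]
    expected_sign: int


@dataclass
class GroundTruth:
    """The generator's ledger of everything it planted."""

    planted_effects: list[PlantedEffect] = field(default_factory=list)
    mechanism_labels: list[MechanismLabel] = field(default_factory=list)
    planted_taa_ids: frozenset[str] = frozenset()
    planted_cta_proteins: frozenset[str] = frozenset()

    def effects_for(self, layer: str) -> dict[tuple[str, str], float]:
        return {(e.feature_id, e.treatment): e.log2fc
                for e in self.planted_effects if e.layer == layer}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_effects": [[e.layer, e.feature_id, e.treatment, e.log2fc]
                                for e in self.planted_effects],
            "mechanism_labels": [[l.peptide_id, l.treatment, l.mechanism,
                                  list(l.path), l.expected_sign]
                                 for l in self.mechanism_labels],
            "planted_taa_ids": sorted(self.planted_taa_ids),
            "planted_cta_proteins": sorted(self.planted_cta_proteins),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_effects=[PlantedEffect(*e[:3], float(e[3]))
                             for e in payload["planted_effects"]],
            mechanism_labels=[MechanismLabel(l[0], l[1], l[2], tuple(l[3]),
                                             int(l[4]))
                              for l in payload["mechanism_labels"]],
            planted_taa_ids=frozenset(payload["planted_taa_ids"]),
            planted_cta_proteins=frozenset(payload["planted_cta_proteins"]))


@dataclass(frozen=True)
class PlannedFeature:
    """A motif feature scheduled for the omics simulation."""

    feature_id: str
    layer: str
    kind: str
    sequence: Optional[str] = None
    source_proteins: tuple[str, ...] = ()
    site: Optional[tuple[str, str, int]] = None
    effects: tuple[tuple[str, float], ...] = ()


@dataclass
class NetworkArtifacts:
    """Everything :func:`generate_causal_network` emits."""

    network: CausalNetwork
    site_annotations: list[SiteAnnotation]
    tf_targets: pd.DataFrame
    inhibitor_map: dict[str, frozenset[str]]
    appm_targets: tuple[str, ...]
    truth: GroundTruth
    planned: list[PlannedFeature]
    design: SampleDesign


def _random_peptide(rng: np.random.Generator, used: set[str], length: int = 9) -> str:
    while True:
        seq = "".join(rng.choice(AMINO_ACIDS, size=length))
        if seq not in used:
            used.add(seq)
            return seq


def generate_causal_network(cfg: SimulationConfig) -> NetworkArtifacts:
    """Build the signed causal network with planted mechanism motifs.

    Per treatment and mechanism the generator plants
    ``n_motifs_per_mechanism`` independent motifs rooted at that treatment's
    inhibited kinase (family nodes are rooted at a member, exercising family
    expansion).  Druggable kinases are wired into the antigen-presentation
    machinery (APPM) target nodes so the proximity screen can recover them;
    background nodes form a disconnected random subgraph.
    """
    if cfg.n_motifs_per_mechanism < 1:
        raise ConfigError("n_motifs_per_mechanism must be >= 1 (zero motifs "
                          "leaves nothing to recover)")
    rng = np.random.default_rng(derive_seed(cfg.rng_seed, "network"))
    design = cfg.design()
    inhibitor_map = cfg.inhibitor_map()
    mag = cfg.planted_effect_log2
    used_sequences: set[str] = set()

    nodes: dict[str, dict] = {}
    edges: list[CausalEdge] = []
    sites: list[SiteAnnotation] = []
    tf_rows: list[dict] = []
    truth = GroundTruth()
    planned: list[PlannedFeature] = []

    def add_node(node_id, **attrs):
        if node_id not in nodes:
            nodes[node_id] = attrs

    # inhibited/druggable kinases; the SFK family node exposes members
    add_node("BCR_ABL", is_kinase=True, is_druggable=True)
    add_node("JNK", is_kinase=True, is_druggable=True)
    add_node("LCK", is_kinase=True)
    add_node("FYN", is_kinase=True)
    add_node("SFK", is_kinase=True, is_druggable=True,
             family_members=("LCK", "FYN"))
    for target in APPM_TARGETS:
        add_node(target)
    # wiring into the antigen-presentation machinery: the SFK family is the
    # best-connected regulator, the others reach fewer members
    for kinase, n_appm in (("SFK", 3), ("LCK", 2), ("FYN", 2),
                           ("BCR_ABL", 2), ("JNK", 2)):
        for target in APPM_TARGETS[:n_appm]:
            edges.append(CausalEdge(kinase, target,
                                    int(rng.choice([-1, 1])), "other"))
    for member in ("LCK", "FYN"):
        edges.append(CausalEdge("SFK", member, 1, "other"))
    # pathway periphery: nodes at graded distances so that the Z score of the
    # druggable kinases is negative (closer than average)
    previous = APPM_TARGETS[0]
    for i in range(6):
        peri = f"PERI_{i}"
        add_node(peri)
        edges.append(CausalEdge(peri, previous, int(rng.choice([-1, 1])),
                                "other"))
        previous = peri
    # druggable decoys: one far from the pathway, one disconnected
    add_node("KIN_FAR", is_kinase=True, is_druggable=True)
    edges.append(CausalEdge("KIN_FAR", "PERI_2", 1, "other"))
    add_node("KIN_ORPHAN", is_kinase=True, is_druggable=True)

    # treatment -> the motif root kinase (family inhibition hits a member)
    motif_root = {"imatinib": "BCR_ABL", "PP2": "LCK", "SP600125": "JNK"}

    def plant(feature: PlannedFeature) -> None:
        planned.append(feature)
        for treatment, lfc in feature.effects:
            truth.planted_effects.append(PlantedEffect(
                feature.layer, feature.feature_id, treatment, lfc))

    def add_activation_site(kinase: str, upstream: str) -> SiteAnnotation:
        ann = SiteAnnotation(kinase, "T", 161, "activates_protein", (upstream,))
        sites.append(ann)
        return ann

    for treatment in design.treatments:
        root = motif_root[treatment]
        for i in range(cfg.n_motifs_per_mechanism):
            # --- mechanism 1: direct peptide phosphorylation ------------
            up = f"K1_{treatment}_{i}"
            add_node(up, is_kinase=True)
            s1 = int(rng.choice([-1, 1]))
            edges.append(CausalEdge(root, up, s1, "phosphorylation", ("T", 161)))
            act_site = add_activation_site(up, root)
            protein = f"P1_{treatment}_{i}"
            add_node(protein)
            edges.append(CausalEdge(up, protein, 1, "phosphorylation", ("T", 305)))
            sites.append(SiteAnnotation(protein, "T", 305, None, (up,)))
            activity = -s1
            pep_sign = activity  # phospho edge sign +1
            seq = _random_peptide(rng, used_sequences)
            pep_id = f"{seq}_T305p"
            plant(PlannedFeature(f"{act_site.label}", "phosphoproteome",
                                 "phosphosite", source_proteins=(up,),
                                 site=act_site.site,
                                 effects=((treatment, activity * mag),)))
            plant(PlannedFeature(pep_id, "phospho_immunopeptidome",
                                 "phospho_hla_peptide", sequence=seq,
                                 source_proteins=(protein,),
                                 site=(protein, "T", 305),
                                 effects=((treatment, pep_sign * mag),)))
            plant(PlannedFeature(protein, "proteome", "protein",
                                 source_proteins=(protein,), effects=()))
            truth.mechanism_labels.append(MechanismLabel(
                pep_id, treatment, "M1", (root, up, protein), pep_sign))

            # --- mechanism 2: source-protein stability ------------------
            up2 = f"K2_{treatment}_{i}"
            add_node(up2, is_kinase=True)
            s2 = int(rng.choice([-1, 1]))
            edges.append(CausalEdge(root, up2, s2, "phosphorylation", ("T", 161)))
            act_site2 = add_activation_site(up2, root)
            protein2 = f"P2_{treatment}_{i}"
            add_node(protein2)
            effect_kind = str(rng.choice(["stabilizes_protein",
                                          "destabilizes_protein"]))
            edges.append(CausalEdge(up2, protein2, 1, "phosphorylation", ("S", 39)))
            sites.append(SiteAnnotation(protein2, "S", 39, effect_kind, (up2,)))
            activity2 = -s2
            site_sign = activity2
            stability = site_sign * (1 if effect_kind == "stabilizes_protein" else -1)
            protein_sign = stability
            pep_sign2 = -stability
            seq2 = _random_peptide(rng, used_sequences)
            plant(PlannedFeature(act_site2.label, "phosphoproteome",
                                 "phosphosite", source_proteins=(up2,),
                                 site=act_site2.site,
                                 effects=((treatment, activity2 * mag),)))
            plant(PlannedFeature(f"{protein2}_S39", "phosphoproteome",
                                 "phosphosite", source_proteins=(protein2,),
                                 site=(protein2, "S", 39),
                                 effects=((treatment, site_sign * mag),)))
            plant(PlannedFeature(protein2, "proteome", "protein",
                                 source_proteins=(protein2,),
                                 effects=((treatment, protein_sign * mag),)))
            plant(PlannedFeature(seq2, "immunopeptidome", "hla_peptide",
                                 sequence=seq2, source_proteins=(protein2,),
                                 effects=((treatment, pep_sign2 * mag),)))
            truth.mechanism_labels.append(MechanismLabel(
                seq2, treatment, "M2", (root, up2, protein2), pep_sign2))

            # --- mechanism 3: transcriptional regulation ----------------
            tf = f"TF_{treatment}_{i}"
            add_node(tf, is_tf=True)
            two_step = i % 2 == 1
            if two_step:
                mid = f"K3_{treatment}_{i}"
                add_node(mid, is_kinase=True)
                sa = int(rng.choice([-1, 1]))
                sb = int(rng.choice([-1, 1]))
                edges.append(CausalEdge(root, mid, sa, "phosphorylation",
                                        ("T", 161)))
                edges.append(CausalEdge(mid, tf, sb, "phosphorylation",
                                        ("S", 727)))
                path: tuple[str, ...] = (root, mid, tf)
                product = sa * sb
                tf_upstream = mid
            else:
                sa = int(rng.choice([-1, 1]))
                edges.append(CausalEdge(root, tf, sa, "phosphorylation",
                                        ("S", 727)))
                path = (root, tf)
                product = sa
                tf_upstream = root
            sites.append(SiteAnnotation(tf, "S", 727, "activates_protein",
                                        (tf_upstream,)))
            phospho_sign = -product
            tf_activity = phospho_sign  # activating site
            plant(PlannedFeature(f"{tf}_S727", "phosphoproteome", "phosphosite",
                                 source_proteins=(tf,), site=(tf, "S", 727),
                                 effects=((treatment, phospho_sign * mag),)))
            for j in range(2):
                target = f"G_{treatment}_{i}_{j}"
                add_node(target)
                reg = int(rng.choice([-1, 1]))
                tf_rows.append({"tf_id": tf, "target_id": target, "sign": reg})
                edges.append(CausalEdge(tf, target, reg, "transcriptional"))
                prot_sign = tf_activity * reg
                seq3 = _random_peptide(rng, used_sequences)
                plant(PlannedFeature(target, "proteome", "protein",
                                     source_proteins=(target,),
                                     effects=((treatment, prot_sign * mag),)))
                plant(PlannedFeature(seq3, "immunopeptidome", "hla_peptide",
                                     sequence=seq3, source_proteins=(target,),
                                     effects=((treatment, prot_sign * mag),)))
                truth.mechanism_labels.append(MechanismLabel(
                    seq3, treatment, "M3", path + (target,), prot_sign))

    # background subgraph, disconnected from the motifs and the pathway
    background = [f"BG_{k}" for k in range(cfg.n_background_nodes)]
    for k, node in enumerate(background):
        add_node(node, is_kinase=k % 5 == 0, is_tf=k % 37 == 0)
    n_bg_edges = 2 * cfg.n_background_nodes
    for _ in range(n_bg_edges):
        u, v = rng.choice(cfg.n_background_nodes, size=2, replace=False)
        edges.append(CausalEdge(background[u], background[v],
                                int(rng.choice([-1, 1])), "other"))

    network = CausalNetwork.from_parts(nodes, edges)
    tf_targets = validate_tf_targets(
        pd.DataFrame(tf_rows, columns=["tf_id", "target_id", "sign"]), network)
    return NetworkArtifacts(network=network, site_annotations=sites,
                            tf_targets=tf_targets,
                            inhibitor_map=inhibitor_map,
                            appm_targets=APPM_TARGETS, truth=truth,
                            planned=planned, design=design)


# ---------------------------------------------------------------------------
# intensity layers

def _simulate_matrix(layer: str, design: SampleDesign, feature_ids: Sequence[str],
                     effects: Mapping[tuple[str, str], float],
                     cfg: SimulationConfig,
                     rng: np.random.Generator) -> IntensityMatrix:
    n = len(feature_ids)
    baselines = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    columns = {}
    feature_pos = {f: i for i, f in enumerate(feature_ids)}
    effect_vectors = {cond: np.zeros(n) for cond in design.conditions}
    for (feature_id, treatment), lfc in effects.items():
        effect_vectors[treatment][feature_pos[feature_id]] += lfc
    for cond in design.conditions:
        for sample in design.samples_for(cond):
            noise = rng.normal(0.0, cfg.replicate_noise_sd, n) \
                if cfg.replicate_noise_sd > 0 else np.zeros(n)
            columns[sample] = baselines + effect_vectors[cond] + noise
    data = pd.DataFrame(columns, index=pd.Index(feature_ids, name="feature_id"))
    data = data[list(design.sample_ids)]
    return IntensityMatrix(layer=layer, data=data, design=design, scale="log2")


def _plant_background_effects(layer: str, feature_ids: Sequence[str],
                              design: SampleDesign, cfg: SimulationConfig,
                              rng: np.random.Generator,
                              truth: GroundTruth) -> None:
    """Drug-modulate a random fraction of background features, independently
    per treatment, recording every effect in the ground truth."""
    for treatment in design.treatments:
        modulated = rng.random(len(feature_ids)) < cfg.background_modulated_fraction
        magnitudes = rng.uniform(cfg.background_effect_min,
                                 cfg.background_effect_max, len(feature_ids))
        signs = rng.choice([-1.0, 1.0], len(feature_ids))
        for idx in np.flatnonzero(modulated):
            truth.planted_effects.append(PlantedEffect(
                layer, feature_ids[idx], treatment,
                float(signs[idx] * magnitudes[idx])))


def simulate_omics_layers(artifacts: NetworkArtifacts, cfg: SimulationConfig
                          ) -> tuple[dict[str, IntensityMatrix],
                                     list[FeatureAnnotation], GroundTruth]:
    """Simulate the four intensity layers around the planted motifs.

    Feature baselines are Normal(baseline_log2_mean, baseline_log2_sd);
    replicates add Normal(0, replicate_noise_sd); planted effects shift the
    treated-condition mean only (homoscedastic noise).  Returns complete
    (missingness-free) matrices; apply :func:`apply_missingness` afterwards.
    """
    rng = np.random.default_rng(derive_seed(cfg.rng_seed, "omics"))
    design = artifacts.design
    truth = artifacts.truth

    annotations: list[FeatureAnnotation] = []
    layer_features: dict[str, list[str]] = {layer: [] for layer in LAYERS}
    used_sequences = {p.sequence for p in artifacts.planned if p.sequence}
    seen_ids: dict[str, set[str]] = {layer: set() for layer in LAYERS}

    def register(feature_id: str, layer: str, kind: str, **kwargs) -> None:
        if feature_id in seen_ids[layer]:
            return
        seen_ids[layer].add(feature_id)
        layer_features[layer].append(feature_id)
        annotations.append(FeatureAnnotation(feature_id=feature_id,
                                             feature_kind=kind, **kwargs))

    def binder_calls(rng: np.random.Generator, force_binder: bool = False
                     ) -> tuple[tuple[str, str], ...]:
        if not force_binder and rng.random() < cfg.nonbinder_fraction:
            return ((str(rng.choice(ALLELES)), "non"),)
        allele = str(rng.choice(ALLELES))
        cls = "strong" if rng.random() < 0.6 else "weak"
        calls = [(allele, cls)]
        if rng.random() < 0.3:
            other = str(rng.choice(ALLELES))
            if other != allele:
                calls.append((other, "weak"))
        return tuple(calls)

    # motif features first (annotations carry the motif biology)
    for feature in artifacts.planned:
        extra = {}
        if feature.kind in ("hla_peptide", "phospho_hla_peptide"):
            extra = {"allele_binding": binder_calls(rng, force_binder=True),
                     "immunogenicity": float(rng.uniform(0.2, 1.0))}
        register(feature.feature_id, feature.layer, feature.kind,
                 peptide_sequence=feature.sequence,
                 source_proteins=feature.source_proteins, site=feature.site,
                 **extra)

    # background proteins and their peptides
    proteins = [f"PROT_{k:04d}" for k in range(cfg.n_background_proteins)]
    for protein in proteins:
        register(protein, "proteome", "protein", source_proteins=(protein,))
    for _ in range(cfg.n_background_peptides):
        seq = _random_peptide(rng, used_sequences)
        protein = proteins[int(rng.integers(len(proteins)))]
        register(seq, "immunopeptidome", "hla_peptide", peptide_sequence=seq,
                 source_proteins=(protein,),
                 allele_binding=binder_calls(rng),
                 immunogenicity=float(rng.uniform(0.0, 1.0)))
    for k in range(cfg.n_background_phospho_peptides):
        seq = _random_peptide(rng, used_sequences)
        protein = proteins[int(rng.integers(len(proteins)))]
        position = int(rng.integers(10, 500))
        register(f"{seq}_S{position}p", "phospho_immunopeptidome",
                 "phospho_hla_peptide", peptide_sequence=seq,
                 source_proteins=(protein,), site=(protein, "S", position),
                 allele_binding=binder_calls(rng),
                 immunogenicity=float(rng.uniform(0.0, 1.0)))
    background_site_ids = []
    for k in range(cfg.n_background_phosphosites):
        protein = proteins[int(rng.integers(len(proteins)))]
        position = int(rng.integers(10, 2000))
        feature_id = f"{protein}_S{position}"
        if feature_id in seen_ids["phosphoproteome"]:
            continue
        register(feature_id, "phosphoproteome", "phosphosite",
                 source_proteins=(protein,), site=(protein, "S", position))
        background_site_ids.append(feature_id)

    # drug-modulate part of the background, per layer
    motif_ids = {p.feature_id for p in artifacts.planned}
    for layer in LAYERS:
        background_ids = [f for f in layer_features[layer]
                          if f not in motif_ids]
        _plant_background_effects(layer, background_ids, design, cfg, rng, truth)

    matrices = {}
    for layer in LAYERS:
        matrices[layer] = _simulate_matrix(
            layer, design, layer_features[layer], truth.effects_for(layer),
            cfg, rng)
    return matrices, annotations, truth


def simulate_null_matrix(layer: str, design: SampleDesign, n_features: int,
                         cfg: SimulationConfig, seed: int) -> IntensityMatrix:
    """A background-only matrix with no planted effects (global null)."""
    rng = np.random.default_rng(seed)
    feature_ids = [f"NULL_{k:05d}" for k in range(n_features)]
    return _simulate_matrix(layer, design, feature_ids, {}, cfg, rng)


def apply_missingness(matrix: IntensityMatrix, cfg: SimulationConfig,
                      seed: Optional[int] = None) -> IntensityMatrix:
    """Left-censored (intensity-dependent) missingness.

    Each cell goes missing independently with probability
    ``missing_p_max * sigmoid((midpoint - x) / slope)``; the midpoint
    defaults to the matrix's 5th percentile, so low-abundance values censor
    preferentially, emulating the detection floor that MinProb imputation
    presumes.
    """
    if cfg.missing_p_max == 0:
        return matrix
    if seed is None:
        seed = derive_seed(cfg.rng_seed, f"missing:{matrix.layer}")
    rng = np.random.default_rng(seed)
    values = matrix.data.to_numpy()
    midpoint = cfg.missing_midpoint
    if midpoint is None:
        midpoint = float(np.nanpercentile(values, 5))
    p_missing = cfg.missing_p_max * expit((midpoint - values) / cfg.missing_slope)
    mask = rng.random(values.shape) < p_missing
    data = matrix.data.mask(pd.DataFrame(mask, index=matrix.data.index,
                                         columns=matrix.data.columns))
    return matrix.with_data(data)


# ---------------------------------------------------------------------------
# cohort / benign presence and binder calls

@dataclass
class CohortArtifacts:
    cohort_presence: dict[str, int]
    benign_presence: dict[str, int]
    cta_proteins: tuple[str, ...]
    binder_table: pd.DataFrame


def generate_cohort_presence(annotations: Sequence[FeatureAnnotation],
                             truth: GroundTruth, cfg: SimulationConfig
                             ) -> CohortArtifacts:
    """Disease-cohort and benign-tissue presence with planted antigens.

    Planted tumor-associated antigens (TAAs) are binder peptides seen in at
    least one cohort sample and in no benign sample; roughly half are chosen
    among peptides planted to go UP under at least one treatment (the
    recoverable putative TAAs).  A decoy set of binders appears in both
    cohorts; all other peptides are absent from the disease cohort, so the
    planted TAA set is exactly recoverable by set algebra.  Cancer-testis
    antigen (CTA) proteins are background source proteins, around half of
    whose peptides also show up in benign tissue.
    """
    rng = np.random.default_rng(derive_seed(cfg.rng_seed, "cohort"))
    peptides = [a for a in annotations if a.feature_kind == "hla_peptide"]
    binder_rows = []
    for ann in peptides:
        for allele, cls in ann.allele_binding:
            binder_rows.append({"peptide": ann.peptide_sequence,
                                "allele": allele, "binder_class": cls})
    binder_table = pd.DataFrame(binder_rows,
                                columns=["peptide", "allele", "binder_class"])

    binders = {a.peptide_sequence for a in peptides
               if a.best_binder_class in ("strong", "weak")}
    up_effects = {e.feature_id for e in truth.planted_effects
                  if e.layer == "immunopeptidome" and e.log2fc > 0}
    sequence_of = {a.feature_id: a.peptide_sequence for a in peptides}
    up_sequences = sorted({sequence_of[f] for f in up_effects
                           if f in sequence_of} & binders)
    other_binders = sorted(binders - set(up_sequences))

    n_up = min(len(up_sequences), (cfg.n_planted_taas + 1) // 2)
    n_other = min(len(other_binders), cfg.n_planted_taas - n_up)
    taa_up = [up_sequences[i] for i in
              rng.choice(len(up_sequences), size=n_up, replace=False)] \
        if n_up else []
    taa_other = [other_binders[i] for i in
                 rng.choice(len(other_binders), size=n_other, replace=False)] \
        if n_other else []
    planted_taas = frozenset(taa_up) | frozenset(taa_other)

    remaining = sorted(binders - planted_taas)
    n_decoys = min(cfg.n_decoy_shared, len(remaining))
    decoys = frozenset(remaining[i] for i in
                       rng.choice(len(remaining), size=n_decoys, replace=False))

    cohort: dict[str, int] = {}
    benign: dict[str, int] = {}
    for seq in sorted(planted_taas):
        cohort[seq] = 1 + int(rng.binomial(cfg.cohort_size - 1,
                                           cfg.taa_cohort_presence_p))
        benign[seq] = 0
    for seq in sorted(decoys):
        cohort[seq] = 1 + int(rng.binomial(cfg.cohort_size - 1,
                                           cfg.decoy_presence_p))
        benign[seq] = 1 + int(rng.binomial(cfg.benign_size - 1,
                                           cfg.decoy_presence_p))

    # cancer-testis antigens: background proteins with >= 1 peptide
    protein_peptides: dict[str, list[str]] = {}
    for ann in peptides:
        for protein in ann.source_proteins:
            if protein.startswith("PROT_"):
                protein_peptides.setdefault(protein, []).append(
                    ann.peptide_sequence)
    candidates = sorted(protein_peptides)
    n_cta = min(cfg.n_cta_proteins, len(candidates))
    cta_proteins = tuple(sorted(
        candidates[i] for i in rng.choice(len(candidates), size=n_cta,
                                          replace=False)))
    for protein in cta_proteins:
        for k, seq in enumerate(sorted(protein_peptides[protein])):
            if seq in planted_taas:
                continue
            if k % 2 == 0:  # about half of CTA peptides also in benign tissue
                benign[seq] = max(benign.get(seq, 0),
                                  1 + int(rng.binomial(cfg.benign_size - 1,
                                                       cfg.benign_background_p)))

    # everything else: absent from the disease cohort, sporadic in benign
    for ann in peptides:
        seq = ann.peptide_sequence
        if seq in cohort:
            continue
        cohort[seq] = 0
        if seq not in benign:
            benign[seq] = int(rng.binomial(
                cfg.benign_size, cfg.benign_background_p)) \
                if rng.random() < 0.5 else 0

    truth.planted_taa_ids = planted_taas
    truth.planted_cta_proteins = frozenset(cta_proteins)
    return CohortArtifacts(cohort_presence=cohort, benign_presence=benign,
                           cta_proteins=cta_proteins,
                           binder_table=binder_table)


# ---------------------------------------------------------------------------
# one-call study bundle

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    design: SampleDesign
    artifacts: NetworkArtifacts
    matrices: dict[str, IntensityMatrix]
    annotations: list[FeatureAnnotation]
    cohort: CohortArtifacts
    truth: GroundTruth


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate the full synthetic study: network, four layers (with
    missingness applied), annotations, cohort structure and ground truth."""
    artifacts = generate_causal_network(cfg)
    matrices, annotations, truth = simulate_omics_layers(artifacts, cfg)
    matrices = {layer: apply_missingness(m, cfg)
                for layer, m in matrices.items()}
    cohort = generate_cohort_presence(annotations, truth, cfg)
    return SyntheticStudy(config=cfg, design=artifacts.design,
                          artifacts=artifacts, matrices=matrices,
                          annotations=annotations, cohort=cohort, truth=truth)
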