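"""End-to-end orchestration: simulate -> preprocess -> diff -> proximity ->
mechanisms -> antigens, as one reproducible run.

A single global seed is fanned out to per-stage child seeds by a stable
derivation, so any stage can be rerun in isolation; every intermediate
artifact is materialized in the output directory and the run manifest records
per-table row counts and content digests.  Reruns with the same config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import antigens as antigens_mod
from . import io as io_mod
from . import mechanisms as mech_mod
from . import proximity as prox_mod
from . import quant
from .config import LAYERS, AnalysisConfig, config_from_mapping, parse_flat_config
from .errors import PepwireError
from .model import AnnotationIndex, SampleDesign
from .network import SiteIndex
from .simulate import (GroundTruth, SimulationConfig, derive_seed,
                       simulate_study)

logger = logging.getLogger("pepwire")

#: file-mode input keys -> file names expected in the input directory
FILE_INPUTS = {
    **{f"matrix_{layer}": f"matrix_{layer}.tsv" for layer in LAYERS},
    "network_edges": "network_edges.tsv",
    "network_nodes": "network_nodes.tsv",
    "site_annotations": "site_annotations.tsv",
    "tf_targets": "tf_targets.tsv",
    "inhibitor_map": "inhibitor_map.tsv",
    "feature_annotations": "feature_annotations.tsv",
    "cohort_presence": "cohort_presence.tsv",
    "benign_presence": "benign_presence.tsv",
    "binder_table": "binder_table.tsv",
    "cta_proteins": "cta_proteins.txt",
    "proximity_targets": "proximity_targets.txt",
}

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_ANALYSIS_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def load_run_config(path) -> tuple[AnalysisConfig, SimulationConfig]:
    """Read one flat key-value file holding both analysis and simulation
    settings (keys are routed by field name; unknown keys error)."""
    pairs = parse_flat_config(path)
    analysis = config_from_mapping(
        AnalysisConfig, pairs, ignore=frozenset(_SIM_FIELDS - _ANALYSIS_FIELDS))
    sim = config_from_mapping(
        SimulationConfig, pairs, ignore=frozenset(_ANALYSIS_FIELDS - _SIM_FIELDS))
    return analysis, sim


def _config_echo(analysis: AnalysisConfig, sim: Optional[SimulationConfig]) -> dict:
    echo = {f"analysis.{k}": v for k, v in dataclasses.asdict(analysis).items()}
    if sim is not None:
        echo.update({f"sim.{k}": v for k, v in dataclasses.asdict(sim).items()})
    return echo


def run_differential(matrices, analysis: AnalysisConfig, seed: int):
    """Preprocess (filter + impute) and test all layers; returns
    (per-layer result frames, per-layer imputed matrices)."""
    results = {}
    imputed = {}
    for layer, matrix in matrices.items():
        filtered = quant.log2_and_filter(matrix, analysis)
        complete = quant.impute_minprob(filtered, analysis,
                                        seed=derive_seed(seed, f"impute:{layer}"))
        results[layer] = quant.differential_test(complete, analysis)
        imputed[layer] = complete
    return results, imputed


def assign_all_mechanisms(study, diff_results, analysis: AnalysisConfig):
    """Run all three mechanism searches over a synthetic study's differential
    results; returns the combined assignment list."""
    ann_index = AnnotationIndex(study.annotations)
    site_index = SiteIndex(study.artifacts.site_annotations)
    network = study.artifacts.network
    inhibitor_map = study.artifacts.inhibitor_map
    return [
        *mech_mod.assign_mechanism1(
            diff_results["phospho_immunopeptidome"], ann_index, site_index,
            network, inhibitor_map, diff_results["phosphoproteome"], analysis),
        *mech_mod.assign_mechanism2(
            diff_results["immunopeptidome"], ann_index, site_index, network,
            inhibitor_map, diff_results["phosphoproteome"],
            diff_results["proteome"], analysis),
        *mech_mod.assign_mechanism3(
            diff_results["immunopeptidome"], diff_results["proteome"],
            diff_results["phosphoproteome"], study.artifacts.tf_targets,
            site_index, ann_index, network, inhibitor_map, analysis),
    ]


def score_mechanism_recovery(sim: SimulationConfig,
                             analysis: Optional[AnalysisConfig] = None):
    """Simulate a study, run the differential and mechanism stages, and score
    recovery against the planted truth.  Returns (RecoveryReport, study)."""
    analysis = analysis or AnalysisConfig()
    study = simulate_study(sim)
    diff_results, _ = run_differential(study.matrices, analysis,
                                       seed=sim.rng_seed)
    assignments = assign_all_mechanisms(study, diff_results, analysis)
    return mech_mod.evaluate_recovery(assignments, study.truth), study


def run_pipeline(out_dir, seed: int = 0,
                 analysis: Optional[AnalysisConfig] = None,
                 sim: Optional[SimulationConfig] = None,
                 input_dir=None,
                 config_path=None) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Synthetic mode (default): the study is generated from ``sim`` (seed
    overrides ``sim.rng_seed``) and recovery against the planted ground truth
    is scored.  File mode (``input_dir`` given): all inputs are read from
    that directory using the io-module dialects; every expected file is
    checked upfront and a missing one aborts with a failure manifest naming
    it.  Returns the run manifest.
    """
    if config_path is not None:
        analysis, sim = load_run_config(config_path)
    analysis = analysis or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, message: str):
        manifest = {"status": "failed", "stage": stage, "error": message}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise PepwireError(f"pipeline stage {stage!r} failed: {message}")

    truth: Optional[GroundTruth] = None
    if input_dir is None:
        # ---- synthetic mode -------------------------------------------
        sim = dataclasses.replace(sim or SimulationConfig(), rng_seed=seed)
        study = simulate_study(sim)
        design = study.design
        matrices = study.matrices
        annotations = study.annotations
        network = study.artifacts.network
        site_annotations = study.artifacts.site_annotations
        tf_targets = study.artifacts.tf_targets
        inhibitor_map = study.artifacts.inhibitor_map
        proximity_targets = frozenset(study.artifacts.appm_targets)
        cohort_presence = study.cohort.cohort_presence
        benign_presence = study.cohort.benign_presence
        binder_table = study.cohort.binder_table
        cta_proteins = study.cohort.cta_proteins
        truth = study.truth
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        for layer, matrix in matrices.items():
            io_mod.write_intensity_matrix(matrix, inputs / f"matrix_{layer}.tsv")
        io_mod.write_causal_network(network, inputs / "network_edges.tsv",
                                    inputs / "network_nodes.tsv")
        io_mod.write_site_annotations(site_annotations,
                                      inputs / "site_annotations.tsv")
        io_mod.write_tf_targets(tf_targets, inputs / "tf_targets.tsv")
        io_mod.write_inhibitor_map(inhibitor_map, inputs / "inhibitor_map.tsv")
        io_mod.write_feature_annotations(annotations,
                                         inputs / "feature_annotations.tsv")
        io_mod.write_presence_counts(cohort_presence,
                                     inputs / "cohort_presence.tsv")
        io_mod.write_presence_counts(benign_presence,
                                     inputs / "benign_presence.tsv")
        io_mod.write_binder_table(binder_table, inputs / "binder_table.tsv")
        io_mod.write_peptide_list(cta_proteins, inputs / "cta_proteins.txt")
        io_mod.write_peptide_list(proximity_targets,
                                  inputs / "proximity_targets.txt")
        truth.to_json(inputs / "ground_truth.json")
    else:
        # ---- file mode ------------------------------------------------
        input_dir = Path(input_dir)
        missing = [name for name, fname in FILE_INPUTS.items()
                   if not (input_dir / fname).exists()]
        if missing:
            fail("load_inputs", f"missing input files: "
                 f"{[FILE_INPUTS[m] for m in missing]}")
        design = SampleDesign.default()
        try:
            matrices = {layer: io_mod.read_intensity_matrix(
                input_dir / f"matrix_{layer}.tsv", layer, design, scale="log2")
                for layer in LAYERS}
            network = io_mod.read_causal_network(
                input_dir / "network_edges.tsv", input_dir / "network_nodes.tsv")
            site_annotations = io_mod.read_site_annotations(
                input_dir / "site_annotations.tsv")
            tf_targets = io_mod.read_tf_targets(input_dir / "tf_targets.tsv")
            inhibitor_map = io_mod.read_inhibitor_map(
                input_dir / "inhibitor_map.tsv")
            annotations = io_mod.read_feature_annotations(
                input_dir / "feature_annotations.tsv")
            cohort_presence = io_mod.read_presence_counts(
                input_dir / "cohort_presence.tsv")
            benign_presence = io_mod.read_presence_counts(
                input_dir / "benign_presence.tsv")
            binder_table = io_mod.read_binder_table(
                input_dir / "binder_table.tsv")
            cta_proteins = io_mod.read_peptide_list(
                input_dir / "cta_proteins.txt")
            proximity_targets = io_mod.read_peptide_list(
                input_dir / "proximity_targets.txt")
        except PepwireError as exc:
            fail("load_inputs", str(exc))

    # ---- differential stage -------------------------------------------
    try:
        diff_results, _ = run_differential(matrices, analysis, seed)
    except PepwireError as exc:
        fail("differential", str(exc))
    diff_long = pd.concat(list(diff_results.values()), ignore_index=True)
    counts = quant.summarize_counts(diff_long)

    # ---- proximity screen ---------------------------------------------
    try:
        prox_table = prox_mod.proximity_table(network, proximity_targets,
                                              analysis)
    except PepwireError as exc:
        fail("proximity", str(exc))
    candidates = prox_mod.select_candidate_kinases(prox_table)

    # ---- mechanisms -----------------------------------------------------
    ann_index = AnnotationIndex(annotations)
    site_index = SiteIndex(site_annotations)
    try:
        m1 = mech_mod.assign_mechanism1(
            diff_results["phospho_immunopeptidome"], ann_index, site_index,
            network, inhibitor_map, diff_results["phosphoproteome"], analysis)
        m2 = mech_mod.assign_mechanism2(
            diff_results["immunopeptidome"], ann_index, site_index, network,
            inhibitor_map, diff_results["phosphoproteome"],
            diff_results["proteome"], analysis)
        m3 = mech_mod.assign_mechanism3(
            diff_results["immunopeptidome"], diff_results["proteome"],
            diff_results["phosphoproteome"], tf_targets, site_index,
            ann_index, network, inhibitor_map, analysis)
    except PepwireError as exc:
        fail("mechanisms", str(exc))
    assignments = [*m1, *m2, *m3]

    # ---- antigens -------------------------------------------------------
    try:
        binders = antigens_mod.binder_set(
            binder_table, strong_only=analysis.strong_binders_only)
        taa_set = antigens_mod.identify_taas(
            binders, cohort_presence, benign_presence,
            min_cohort_samples=analysis.min_cohort_samples)
        putative = antigens_mod.select_putative_taas(
            taa_set, diff_results["immunopeptidome"], ann_index)
        cta_table = antigens_mod.cta_crosstab(
            annotations, cta_proteins, cohort_presence, benign_presence)
        taa_report = antigens_mod.taa_modulation_report(
            taa_set, diff_results["immunopeptidome"], ann_index)
    except PepwireError as exc:
        fail("antigens", str(exc))

    # ---- results bundle -------------------------------------------------
    results = {
        "differential": diff_long,
        "differential_counts": counts,
        "proximity": prox_table.replace([float("inf")], "inf"),
        "mechanism_assignments": mech_mod.assignments_frame(assignments),
        "taa_peptides": pd.DataFrame({"peptide": sorted(taa_set)}),
        "putative_taa_peptides": pd.DataFrame({"peptide": sorted(putative)}),
        "cta_crosstab": cta_table,
        "taa_modulation": taa_report,
    }
    recovery = None
    if truth is not None:
        recovery = mech_mod.evaluate_recovery(assignments, truth)
        results["mechanism_recovery"] = pd.DataFrame(
            [{"mechanism": mech, "precision": s.precision, "recall": s.recall,
              "f1": s.f1, "n_true_positive": s.n_true_positive,
              "n_predicted": s.n_predicted, "n_planted": s.n_planted}
             for mech, s in [*recovery.per_mechanism.items(),
                             ("overall", recovery.overall)]])
    manifest = io_mod.write_results_bundle(
        results, out, config=_config_echo(analysis, sim), seed=seed)
    manifest["status"] = "ok"
    manifest["selected_kinases"] = candidates
    manifest["stages"] = ["simulate" if input_dir is None else "load_inputs",
                          "differential", "proximity", "mechanisms",
                          "antigens", "bundle"]
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
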