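"""Generator determinism, planted sign algebra, missingness, and presence."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pepwire import (ConfigError, SimulationConfig, apply_missingness,
                     generate_causal_network, identify_taas,
                     simulate_null_matrix, simulate_omics_layers,
                     simulate_study)
from pepwire.antigens import binder_set
from pepwire.network import SiteIndex

from conftest import small_sim_config


class TestDeterminism:
    def test_same_seed_reproduces_network_and_layers(self):
        cfg = small_sim_config(rng_seed=29)
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert a.artifacts.network == b.artifacts.network
        for layer in a.matrices:
            pd.testing.assert_frame_equal(a.matrices[layer].data,
                                          b.matrices[layer].data,
                                          check_exact=True)
        assert a.truth.planted_taa_ids == b.truth.planted_taa_ids

    def test_different_seeds_differ(self):
        a = simulate_study(small_sim_config(rng_seed=1))
        b = simulate_study(small_sim_config(rng_seed=2))
        assert a.artifacts.network != b.artifacts.network


class TestMotifStructure:
    def test_zero_motifs_rejected(self):
        with pytest.raises((ConfigError, ValueError)):
            generate_causal_network(small_sim_config(n_motifs_per_mechanism=0))

    def test_kinase_to_site_paths_respect_two_step_cap(self, small_study):
        """Every M1/M2 label's inhibited-kinase -> upstream-kinase segment
        (path minus the source protein) is at most two steps."""
        for label in small_study.truth.mechanism_labels:
            if label.mechanism in ("M1", "M2"):
                assert len(label.path) - 2 <= 2

    def test_every_planted_path_exists_by_independent_dfs(self, small_study):
        graph = nx.DiGraph(small_study.artifacts.network.graph)
        for label in small_study.truth.mechanism_labels:
            for u, v in zip(label.path, label.path[1:]):
                assert graph.has_edge(u, v), label

    def test_mechanism_paths_start_at_an_inhibited_kinase(self, small_study):
        net = small_study.artifacts.network
        roots_by_treatment = {
            t: frozenset().union(*(net.expand_members(k) for k in ks))
            for t, ks in small_study.artifacts.inhibitor_map.items()}
        for label in small_study.truth.mechanism_labels:
            assert label.path[0] in roots_by_treatment[label.treatment]

    def test_m2_sign_algebra_planted_consistently(self, small_study):
        """Destabilizing site: protein moves opposite to the site phospho and
        the peptide opposite to the protein (and mirrored for stabilizing)."""
        sites = SiteIndex(small_study.artifacts.site_annotations)
        effects = {(e.layer, e.feature_id, e.treatment): e.log2fc
                   for e in small_study.truth.planted_effects}
        checked = 0
        for label in small_study.truth.mechanism_labels:
            if label.mechanism != "M2":
                continue
            protein = label.path[-1]
            (site_ann,) = sites.stability_sites(protein)
            site_fc = effects[("phosphoproteome", site_ann.label,
                               label.treatment)]
            prot_fc = effects[("proteome", protein, label.treatment)]
            pep_fc = effects[("immunopeptidome", label.peptide_id,
                              label.treatment)]
            flip = 1 if site_ann.functional_effect == "stabilizes_protein" else -1
            assert np.sign(prot_fc) == flip * np.sign(site_fc)
            assert np.sign(pep_fc) == -np.sign(prot_fc)
            assert np.sign(pep_fc) == label.expected_sign
            checked += 1
        assert checked == 3 * small_study.config.n_motifs_per_mechanism


class TestIntensityModel:
    def test_zero_noise_replicates_equal_condition_means(self):
        cfg = small_sim_config(replicate_noise_sd=0.0, missing_p_max=0.0)
        matrix = simulate_null_matrix("immunopeptidome", cfg.design(), 50,
                                      cfg, seed=5)
        values = matrix.data.to_numpy()
        assert np.ptp(values, axis=1).max() == 0.0

    def test_planted_effect_recovered_in_expectation(self):
        """Monte-Carlo oracle: the empirical log2FC of the first M1 peptide,
        aligned to its planted sign, averages to the planted magnitude within
        three standard errors over 50 independent noise realizations."""
        recovered = []
        for seed in range(50):
            cfg = small_sim_config(rng_seed=100 + seed, missing_p_max=0.0)
            study = simulate_study(cfg)
            label = next(l for l in study.truth.mechanism_labels
                         if l.mechanism == "M1")
            matrix = study.matrices["phospho_immunopeptidome"]
            treated = matrix.data.loc[
                label.peptide_id,
                list(matrix.design.samples_for(label.treatment))]
            control = matrix.data.loc[
                label.peptide_id,
                list(matrix.design.samples_for(matrix.design.control))]
            recovered.append(label.expected_sign *
                             (treated.mean() - control.mean()))
        recovered = np.asarray(recovered)
        sem = recovered.std(ddof=1) / np.sqrt(len(recovered))
        magnitude = small_sim_config().planted_effect_log2
        assert abs(recovered.mean() - magnitude) < 3 * sem

    def test_planted_magnitudes_exceed_fc_threshold(self, small_study):
        for effect in small_study.truth.planted_effects:
            assert abs(effect.log2fc) > 0.5


class TestMissingness:
    def _uniform_matrix(self, cfg, value, n=1000):
        matrix = simulate_null_matrix("immunopeptidome", cfg.design(), n,
                                      dataclasses.replace(
                                          cfg, baseline_log2_sd=0.0,
                                          replicate_noise_sd=0.0,
                                          baseline_log2_mean=value),
                                      seed=3)
        return matrix

    def test_zero_rate_leaves_matrix_unchanged(self):
        cfg = small_sim_config(missing_p_max=0.0)
        matrix = self._uniform_matrix(cfg, 25.0, n=50)
        assert apply_missingness(matrix, cfg) is matrix

    def test_saturated_rate_far_below_midpoint(self):
        """For values far below the censoring midpoint the empirical missing
        rate approaches missing_p_max (binomial CI over 12,000 cells)."""
        cfg = small_sim_config(missing_p_max=0.3, missing_midpoint=25.0)
        matrix = self._uniform_matrix(cfg, 15.0)  # 10 log2 units below
        out = apply_missingness(matrix, cfg, seed=9)
        n_cells = out.data.size
        rate = out.n_missing() / n_cells
        se = np.sqrt(0.3 * 0.7 / n_cells)
        assert abs(rate - 0.3) < 4 * se

    def test_missingness_is_monotone_in_intensity(self):
        cfg = small_sim_config(missing_p_max=0.3, missing_midpoint=25.0)
        rates = []
        for value in (20.0, 24.0, 28.0):
            out = apply_missingness(self._uniform_matrix(cfg, value), cfg,
                                    seed=11)
            rates.append(out.n_missing() / out.data.size)
        assert rates[0] >= rates[1] >= rates[2]


class TestCohortPresence:
    def test_planted_taas_are_absent_from_benign(self, small_study):
        for peptide in small_study.truth.planted_taa_ids:
            assert small_study.cohort.benign_presence[peptide] == 0
            assert small_study.cohort.cohort_presence[peptide] >= 1

    def test_identify_taas_returns_exactly_the_planted_set(self, small_study):
        binders = binder_set(small_study.cohort.binder_table)
        taas = identify_taas(binders, small_study.cohort.cohort_presence,
                             small_study.cohort.benign_presence)
        assert taas == small_study.truth.planted_taa_ids

    def test_decoy_binders_shared_with_benign_are_excluded(self, small_study):
        shared = {p for p, n in small_study.cohort.benign_presence.items()
                  if n > 0 and small_study.cohort.cohort_presence.get(p, 0) > 0}
        assert shared  # the generator plants a shared decoy set
        assert not shared & small_study.truth.planted_taa_ids
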