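"""Tumor-associated antigen (TAA) set logic and cancer-testis antigen tables.

A TAA is an MHC-I-binding peptide detected in at least one disease-cohort
sample and in no benign-tissue sample.  Putative TAAs are the subset whose
presentation is significantly increased by at least one treatment.  Peptide
identity across datasets is the exact amino-acid string, case-normalized.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import AnnotationIndex, FeatureAnnotation

CTA_COLUMNS = ("source_protein", "peptide", "n_cohort", "n_benign")


def binder_set(binder_table: pd.DataFrame, strong_only: bool = False) -> frozenset[str]:
    """Peptides with at least one strong (or weak, unless restricted) call."""
    classes = ("strong",) if strong_only else ("strong", "weak")
    chosen = binder_table[binder_table["binder_class"].isin(classes)]
    return frozenset(p.upper() for p in chosen["peptide"])


def identify_taas(binder_peptides: Iterable[str],
                  cohort_presence: Mapping[str, int],
                  benign_presence: Mapping[str, int],
                  min_cohort_samples: int = 1) -> frozenset[str]:
    """Binder peptides present in >= ``min_cohort_samples`` cohort samples
    and absent from every benign sample."""
    binders = frozenset(p.upper() for p in binder_peptides)
    return frozenset(
        p for p in binders
        if cohort_presence.get(p, 0) >= min_cohort_samples
        and benign_presence.get(p, 0) == 0)


def select_putative_taas(taa_set: Iterable[str], pep_results: pd.DataFrame,
                         annotations: Optional[AnnotationIndex] = None
                         ) -> frozenset[str]:
    """TAAs significantly up-regulated under at least one treatment.

    Differential results are keyed by feature id; when an annotation index is
    given, peptide sequences are mapped through it, otherwise the feature id
    is taken to be the sequence itself.
    """
    taas = frozenset(p.upper() for p in taa_set)
    feature_of = {}
    for seq in taas:
        if annotations is not None and seq in annotations.feature_by_sequence:
            feature_of[annotations.feature_by_sequence[seq]] = seq
        else:
            feature_of[seq] = seq
    up = pep_results[pep_results["significant"] &
                     (pep_results["direction"] == "up")]
    return frozenset(feature_of[f] for f in up["feature_id"] if f in feature_of)


def cta_crosstab(annotations: Sequence[FeatureAnnotation],
                 cta_proteins: Iterable[str],
                 cohort_presence: Mapping[str, int],
                 benign_presence: Mapping[str, int]) -> pd.DataFrame:
    """One row per peptide derived from a cancer-testis antigen protein, with
    its cohort and benign sample counts; rows ordered by (protein, peptide)."""
    ctas = frozenset(cta_proteins)
    rows = []
    for ann in annotations:
        if ann.feature_kind != "hla_peptide" or not ann.peptide_sequence:
            continue
        seq = ann.peptide_sequence.upper()
        for protein in ann.source_proteins:
            if protein in ctas:
                rows.append({"source_protein": protein, "peptide": seq,
                             "n_cohort": int(cohort_presence.get(seq, 0)),
                             "n_benign": int(benign_presence.get(seq, 0))})
    table = pd.DataFrame(rows, columns=list(CTA_COLUMNS))
    return table.sort_values(["source_protein", "peptide"],
                             ignore_index=True)


def taa_modulation_report(taa_set: Iterable[str], pep_results: pd.DataFrame,
                          annotations: AnnotationIndex) -> pd.DataFrame:
    """Long-format table of every TAA x treatment with its fold change,
    adjusted p-value, strongest-affinity allele and immunogenicity score
    (volcano/heatmap-ready)."""
    taas = sorted(p.upper() for p in taa_set)
    indexed = pep_results.set_index(["feature_id", "treatment"])
    treatments = sorted(pep_results["treatment"].unique())
    rows = []
    for seq in taas:
        feature_id = annotations.feature_by_sequence.get(seq, seq)
        ann = annotations.get(feature_id)
        for treatment in treatments:
            try:
                record = indexed.loc[(feature_id, treatment)]
            except KeyError:
                continue
            rows.append({
                "peptide": seq, "treatment": treatment,
                "log2FC": float(record["log2FC"]),
                "adj_p_value": float(record["adj_p_value"]),
                "significant": bool(record["significant"]),
                "direction": str(record["direction"]),
                "best_allele": ann.best_allele if ann else None,
                "immunogenicity": ann.immunogenicity if ann else None,
            })
    return pd.DataFrame(rows, columns=["peptide", "treatment", "log2FC",
                                       "adj_p_value", "significant",
                                       "direction", "best_allele",
                                       "immunogenicity"])
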