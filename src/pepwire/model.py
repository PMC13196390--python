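"""Shared data model: study design, intensity matrices, feature annotations.

The common currency of all four omic layers is the :class:`IntensityMatrix`,
a features x samples grid of (log2) intensities held in a pandas DataFrame
with ``NaN`` as the explicit missing marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import LAYERS
from .errors import ValidationError

FEATURE_KINDS = ("hla_peptide", "phospho_hla_peptide", "protein", "phosphosite")
BINDER_CLASSES = ("strong", "weak", "non")

#: A phosphosite location: (protein id, one-letter residue, 1-based position).
Site = tuple[str, str, int]


@dataclass(frozen=True)
class SampleDesign:
    """Conditions, replicates and the sample-id naming scheme.

    Sample ids are ``{condition}_{replicate}`` with replicates numbered from 1.
    Exactly one condition is the control; all others are treatments.
    """

    conditions: tuple[str, ...]
    control: str
    replicates: int

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("duplicate condition labels")
        if self.control not in self.conditions:
            raise ValidationError(
                f"control condition {self.control!r} not among conditions")
        if self.replicates < 2:
            raise ValidationError("every condition needs >= 2 replicates")

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.control)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(
            f"{c}_{r}" for c in self.conditions
            for r in range(1, self.replicates + 1))

    def samples_for(self, condition: str) -> tuple[str, ...]:
        if condition not in self.conditions:
            raise ValidationError(f"unknown condition {condition!r}")
        return tuple(f"{condition}_{r}" for r in range(1, self.replicates + 1))

    def condition_of(self, sample_id: str) -> str:
        cond, _, rep = sample_id.rpartition("_")
        if cond not in self.conditions or not rep.isdigit() \
                or not (1 <= int(rep) <= self.replicates):
            raise ValidationError(f"sample id {sample_id!r} not in design")
        return cond

    @classmethod
    def default(cls) -> "SampleDesign":
        """Four conditions (untreated control plus three kinase inhibitors),
        biological triplicates."""
        return cls(conditions=("control", "imatinib", "PP2", "SP600125"),
                   control="control", replicates=3)


@dataclass
class IntensityMatrix:
    """A features x samples intensity grid for one omic layer.

    ``data`` is indexed by feature id with one column per sample id (in design
    order); ``NaN`` marks a missing value.  ``scale`` records whether values
    are raw intensities or log2-transformed.
    """

    layer: str
    data: pd.DataFrame
    design: SampleDesign
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if tuple(self.data.columns) != self.design.sample_ids:
            raise ValidationError(
                "matrix columns do not match the design sample ids: "
                f"{list(self.data.columns)} vs {list(self.design.sample_ids)}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.scale == "log2":
            values = self.data.to_numpy()
            if np.isinf(values).any():
                raise ValidationError("log2 matrix contains non-finite values")

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def n_features(self) -> int:
        return len(self.data.index)

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def with_data(self, data: pd.DataFrame, scale: Optional[str] = None) -> "IntensityMatrix":
        return IntensityMatrix(layer=self.layer, data=data, design=self.design,
                               scale=self.scale if scale is None else scale)


@dataclass(frozen=True)
class FeatureAnnotation:
    """Identity and biology of one quantified feature.

    Peptide features carry their amino-acid sequence and source protein(s);
    phospho features additionally carry a :data:`Site`; HLA peptides may carry
    per-allele binder calls and a predicted immunogenicity score in [0, 1].
    """

    feature_id: str
    feature_kind: str
    peptide_sequence: Optional[str] = None
    source_proteins: tuple[str, ...] = ()
    site: Optional[Site] = None
    allele_binding: tuple[tuple[str, str], ...] = ()
    immunogenicity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.feature_kind!r}")
        if self.feature_kind in ("hla_peptide", "phospho_hla_peptide"):
            if not self.source_proteins:
                raise ValidationError(
                    f"peptide feature {self.feature_id!r} has no source protein")
        if self.feature_kind in ("phospho_hla_peptide", "phosphosite") and self.site is None:
            raise ValidationError(
                f"phospho feature {self.feature_id!r} lacks a site")
        if self.site is not None and self.site[2] < 1:
            raise ValidationError(
                f"site position must be 1-based, got {self.site}")
        for _, binder_class in self.allele_binding:
            if binder_class not in BINDER_CLASSES:
                raise ValidationError(f"unknown binder class {binder_class!r}")
        if self.immunogenicity is not None and not (0.0 <= self.immunogenicity <= 1.0):
            raise ValidationError("immunogenicity must lie in [0, 1]")

    @property
    def best_binder_class(self) -> Optional[str]:
        """Strongest binder call across alleles (strong < weak < non)."""
        order = {"strong": 0, "weak": 1, "non": 2}
        calls = sorted((order[c], c) for _, c in self.allele_binding)
        return calls[0][1] if calls else None

    @property
    def best_allele(self) -> Optional[str]:
        order = {"strong": 0, "weak": 1, "non": 2}
        calls = sorted((order[c], a) for a, c in self.allele_binding)
        return calls[0][1] if calls else None


class AnnotationIndex:
    """Lookup helper over a collection of :class:`FeatureAnnotation`."""

    def __init__(self, annotations: Iterable[FeatureAnnotation]) -> None:
        self.by_id: dict[str, FeatureAnnotation] = {}
        self.site_to_phosphosite_feature: dict[Site, str] = {}
        self.peptides_by_protein: dict[str, list[str]] = {}
        self.feature_by_sequence: dict[str, str] = {}
        for ann in annotations:
            if ann.feature_id in self.by_id:
                raise ValidationError(f"duplicate feature id {ann.feature_id!r}")
            self.by_id[ann.feature_id] = ann
            if ann.feature_kind == "phosphosite" and ann.site is not None:
                self.site_to_phosphosite_feature[ann.site] = ann.feature_id
            if ann.feature_kind == "hla_peptide":
                for prot in ann.source_proteins:
                    self.peptides_by_protein.setdefault(prot, []).append(ann.feature_id)
                if ann.peptide_sequence:
                    self.feature_by_sequence[ann.peptide_sequence] = ann.feature_id

    def __getitem__(self, feature_id: str) -> FeatureAnnotation:
        return self.by_id[feature_id]

    def get(self, feature_id: str) -> Optional[FeatureAnnotation]:
        return self.by_id.get(feature_id)
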