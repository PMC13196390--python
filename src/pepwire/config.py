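"""Analysis configuration and the flat key-value config file dialect.

The config file format is deliberately minimal: one ``key = value`` pair per
line, ``#`` starts a comment, blank lines are ignored.  Unknown keys are a hard
error so that a typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from .errors import ConfigError

#: The four quantified omic layers, in pipeline order.
LAYERS = (
    "immunopeptidome",
    "phospho_immunopeptidome",
    "proteome",
    "phosphoproteome",
)

CONSISTENCY_MODES = ("strict", "lenient")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the analysis stages.

    Parameters
    ----------
    fc_threshold:
        Minimum absolute log2 fold change for a feature to be called
        significant (paired with the FDR cut).
    fdr_threshold:
        Benjamini-Hochberg adjusted p-value cut-off.
    detection_min:
        A feature is retained if it is observed in at least this many
        replicates of at least one condition.
    imputation_q:
        Quantile of each sample's observed intensities used as the mean of
        the left-censored (MinProb) imputation distribution.
    imputation_sd_scale:
        The imputation draw's standard deviation, as a fraction of the
        sample's observed standard deviation.
    m1_max_steps / m2_max_steps / m3_max_steps:
        Causal-path step caps for the three mechanism searches (edges between
        the inhibited kinase and the upstream kinase / transcription factor).
    proximity_max_path_len:
        Length cap for simple-path counting in the proximity screen.
    consistency_mode:
        ``lenient`` requires only the peptide sign to match the prediction
        (supporting layers are checked when measured and significant);
        ``strict`` additionally requires every supporting layer to be
        measured, significant and sign-matching.
    welch:
        Use Welch's unequal-variance t-test instead of the pooled Student
        t-test.
    strong_binders_only:
        Restrict the binder set used for antigen identification to strong
        binders (default keeps strong and weak calls).
    min_cohort_samples:
        Minimum number of disease-cohort samples a peptide must appear in to
        qualify as a tumor-associated antigen.
    rng_seed:
        Seed for the stages that draw random numbers (imputation).
    """

    fc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    detection_min: int = 2
    imputation_q: float = 0.01
    imputation_sd_scale: float = 0.3
    m1_max_steps: int = 2
    m2_max_steps: int = 2
    m3_max_steps: int = 3
    proximity_max_path_len: int = 4
    consistency_mode: str = "lenient"
    welch: bool = False
    strong_binders_only: bool = False
    min_cohort_samples: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ConfigError("fc_threshold and fdr_threshold must be positive")
        if not (0.0 < self.imputation_q < 0.5):
            raise ConfigError("imputation_q must lie in (0, 0.5)")
        if self.imputation_sd_scale <= 0:
            raise ConfigError("imputation_sd_scale must be positive")
        if self.detection_min < 1:
            raise ConfigError("detection_min must be >= 1")
        for name in ("m1_max_steps", "m2_max_steps", "m3_max_steps",
                     "proximity_max_path_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.consistency_mode not in CONSISTENCY_MODES:
            raise ConfigError(
                f"consistency_mode must be one of {CONSISTENCY_MODES}, "
                f"got {self.consistency_mode!r}")
        if self.min_cohort_samples < 1:
            raise ConfigError("min_cohort_samples must be >= 1")


def _coerce(value: str, target_type: type) -> Any:
    if target_type is bool:
        lowered = value.lower()
        if lowered in ("true", "1", "yes"):
            return True
        if lowered in ("false", "0", "no"):
            return False
        raise ConfigError(f"cannot interpret {value!r} as a boolean")
    if target_type is int:
        return int(value)
    if target_type is float:
        return float(value)
    return value


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` file into a string-to-string mapping."""
    pairs: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in pairs:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        pairs[key] = value
    return pairs


def config_from_mapping(cls, mapping: Mapping[str, str], *, ignore: frozenset = frozenset()):
    """Build a config dataclass from string key/value pairs.

    Unknown keys (not a field of ``cls`` and not in ``ignore``) raise
    :class:`ConfigError`.
    """
    fields = {f.name: f.type for f in dataclasses.fields(cls)}
    type_map = {"int": int, "float": float, "bool": bool, "str": str}
    kwargs: dict[str, Any] = {}
    for key, value in mapping.items():
        if key in ignore:
            continue
        if key not in fields:
            raise ConfigError(f"unknown config key {key!r} for {cls.__name__}")
        ftype = fields[key]
        ftype = type_map.get(ftype, ftype) if isinstance(ftype, str) else ftype
        if ftype not in (int, float, bool, str):
            raise ConfigError(f"config key {key!r} is not settable from a flat file")
        kwargs[key] = _coerce(value, ftype)
    return cls(**kwargs)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a flat key-value file."""
    return config_from_mapping(AnalysisConfig, parse_flat_config(path))
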