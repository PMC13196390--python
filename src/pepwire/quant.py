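"""Preprocessing and per-treatment differential analysis.

The stage order mirrors standard label-free practice: log2 transform,
detection filter (a feature must be seen in at least ``detection_min``
replicates of at least one condition), left-censored MinProb imputation, then
per-treatment two-sample t-tests against the control with Benjamini-Hochberg
correction within each (layer, treatment) family.  A feature is significant
when |log2FC| exceeds ``fc_threshold`` AND the adjusted p-value is below
``fdr_threshold``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import ValidationError
from .model import IntensityMatrix

logger = logging.getLogger("pepwire")

DIFF_COLUMNS = ("feature_id", "layer", "treatment", "log2FC", "t_statistic",
                "p_value", "adj_p_value", "significant", "direction")


def log2_and_filter(matrix: IntensityMatrix, cfg: AnalysisConfig) -> IntensityMatrix:
    """Log2-transform raw intensities and apply the detection filter.

    A matrix already on the log2 scale is filtered without re-transforming.
    Features failing the detection rule (observed in fewer than
    ``cfg.detection_min`` replicates of every condition) are dropped; the
    dropped count is logged.
    """
    data = matrix.data
    if matrix.scale == "raw":
        present = data.to_numpy()
        bad = (present <= 0) & ~np.isnan(present)
        if bad.any():
            rows = data.index[bad.any(axis=1)].tolist()
            raise ValidationError(
                f"non-positive raw intensity in features {rows[:5]}")
        data = np.log2(data)

    detected = pd.DataFrame(
        {cond: data[list(matrix.design.samples_for(cond))].notna().sum(axis=1)
         for cond in matrix.design.conditions})
    keep = (detected >= cfg.detection_min).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("detection filter (%s): dropped %d of %d features",
                    matrix.layer, dropped, len(keep))
    return IntensityMatrix(layer=matrix.layer, data=data.loc[keep],
                           design=matrix.design, scale="log2")


def impute_minprob(matrix: IntensityMatrix, cfg: AnalysisConfig,
                   seed: int | None = None) -> IntensityMatrix:
    """Left-censored imputation: missing cells in sample ``s`` are drawn from
    ``Normal(mu_s, sigma_s)`` with ``mu_s`` the ``imputation_q`` quantile of
    the sample's observed values and ``sigma_s = imputation_sd_scale * sd`` of
    the observed values.

    Observed cells are returned bitwise unchanged; the draw is deterministic
    under ``seed`` (falling back to ``cfg.rng_seed``).
    """
    if matrix.scale != "log2":
        raise ValidationError("impute_minprob expects a log2-scale matrix")
    if matrix.n_missing() == 0:
        return matrix
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    data = matrix.data.copy()
    for sample in data.columns:
        column = data[sample]
        observed = column.dropna()
        n_missing = int(column.isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValidationError(
                f"sample {sample!r} has {len(observed)} observed values; "
                "the imputation quantile is undefined")
        mu = float(observed.quantile(cfg.imputation_q))
        sigma = cfg.imputation_sd_scale * float(observed.std(ddof=1))
        draws = rng.normal(mu, sigma, size=n_missing)
        data.loc[column.isna(), sample] = draws
    return matrix.with_data(data)


def differential_test(matrix: IntensityMatrix, cfg: AnalysisConfig) -> pd.DataFrame:
    """Two-sided two-sample t-tests of every treatment against the control.

    Requires a complete (imputed) log2 matrix.  Returns one row per
    (feature, treatment) with log2FC (treatment mean - control mean),
    t statistic, raw and BH-adjusted p-values (adjusted within this layer and
    treatment), the significance call and its direction.

    Features with zero pooled variance (degenerate noiseless data) get p = 0
    when the group means differ and p = 1 when they coincide, with a logged
    warning.
    """
    if matrix.scale != "log2":
        raise ValidationError("differential_test expects a log2-scale matrix")
    if matrix.n_missing():
        raise ValidationError(
            f"matrix has {matrix.n_missing()} missing cells; impute first")
    design = matrix.design
    control = matrix.data[list(design.samples_for(design.control))].to_numpy()
    frames = []
    for treatment in design.treatments:
        treated = matrix.data[list(design.samples_for(treatment))].to_numpy()
        with warnings.catch_warnings():
            # zero-variance rows are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p_value = stats.ttest_ind(treated, control, axis=1,
                                              equal_var=not cfg.welch)
        log2fc = treated.mean(axis=1) - control.mean(axis=1)
        degenerate = (treated.std(axis=1) == 0) & (control.std(axis=1) == 0)
        if degenerate.any():
            logger.warning("differential_test (%s/%s): %d features with zero "
                           "pooled variance", matrix.layer, treatment,
                           int(degenerate.sum()))
            p_value = np.where(degenerate, np.where(log2fc != 0, 0.0, 1.0),
                               p_value)
            t_stat = np.where(degenerate,
                              np.where(log2fc > 0, np.inf,
                                       np.where(log2fc < 0, -np.inf, 0.0)),
                              t_stat)
        _, adj_p, _, _ = multipletests(p_value, alpha=cfg.fdr_threshold,
                                       method="fdr_bh")
        significant = (np.abs(log2fc) > cfg.fc_threshold) & \
                      (adj_p < cfg.fdr_threshold)
        direction = np.where(significant,
                             np.where(log2fc > 0, "up", "down"), "none")
        frames.append(pd.DataFrame({
            "feature_id": matrix.feature_ids,
            "layer": matrix.layer,
            "treatment": treatment,
            "log2FC": log2fc,
            "t_statistic": t_stat,
            "p_value": p_value,
            "adj_p_value": adj_p,
            "significant": significant,
            "direction": direction,
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_counts(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(layer, treatment) counts of up/down significant features."""
    if results.empty:
        raise ValidationError("summarize_counts needs a non-empty result table")
    rows = []
    for (layer, treatment), group in results.groupby(["layer", "treatment"],
                                                     sort=True):
        significant = group[group["significant"]]
        up = int((significant["direction"] == "up").sum())
        down = int((significant["direction"] == "down").sum())
        rows.append({"layer": layer, "treatment": treatment, "up": up,
                     "down": down, "total_significant": up + down})
    return pd.DataFrame(rows, columns=["layer", "treatment", "up", "down",
                                       "total_significant"])


def significant_sign_map(results: pd.DataFrame) -> dict[tuple[str, str], int]:
    """(feature_id, treatment) -> +1/-1 for significant rows only.

    Non-significant observations carry no sign (they are simply absent from
    the map and read back as ``None``).
    """
    significant = results.loc[results["significant"].astype(bool)]
    signs = np.where(significant["log2FC"].to_numpy() > 0, 1, -1)
    return {(f, t): int(s) for f, t, s in zip(significant["feature_id"],
                                              significant["treatment"], signs)}
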