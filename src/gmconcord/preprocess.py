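"""Standardized metabolomics preprocessing.

Stage order for one dataset: multiplicative median scaling across batches
(when more than one batch is present), probabilistic quotient normalization
(reference drawn from normal samples when available, otherwise from all
tumour samples), log2 transform, per-tissue missingness filtering (features
with more than 80% missing values in a tissue group are dropped), and
minimum-value imputation per feature. Every action is recorded in a
:class:`PreprocessReport` so the pipeline can be audited.

Transcriptomics matrices are assumed to arrive already normalized (TPM or
RMA-style) and pass through untouched apart from an optional log2 transform
handled by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, GmcError, OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    dataset_id: str
    batch_factors: dict = field(default_factory=dict)  # (feature, batch) -> factor
    pqn_dilution: dict = field(default_factory=dict)  # sample -> factor
    pqn_reference_features: list = field(default_factory=list)
    dropped_features: list = field(default_factory=list)  # (feature, reason)
    imputed_cells: dict = field(default_factory=dict)  # feature -> count
    stages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "stages": self.stages,
            "n_batch_factors": len(self.batch_factors),
            "pqn_dilution": self.pqn_dilution,
            "n_pqn_reference_features": len(self.pqn_reference_features),
            "dropped_features": self.dropped_features,
            "imputed_cells": self.imputed_cells,
        }


def _require_linear(matrix: OmicsMatrix, op: str) -> None:
    if matrix.scale_state != "linear":
        raise GmcError(f"{op} requires a linear-scale matrix, "
                       f"got {matrix.scale_state}")


def median_scale_batches(
    matrix: OmicsMatrix,
    batches: pd.Series | dict,
    report: PreprocessReport | None = None,
) -> OmicsMatrix:
    """Per metabolite, rescale each batch so its median matches the global
    median. With a single batch the matrix is returned unchanged.

    A batch whose median is zero for some metabolite is left unscaled for
    that metabolite (warning logged).
    """
    _require_linear(matrix, "median_scale_batches")
    report = report if report is not None else PreprocessReport(matrix.dataset_id)
    batches = pd.Series(batches).reindex(matrix.sample_ids).fillna("")
    labels = batches.unique()
    if len(labels) < 2:
        report.stages.append("median_scale_batches: single batch, identity")
        return matrix
    df = matrix.data.copy()
    for feat in df.index:
        row = df.loc[feat]
        global_med = row.median(skipna=True)
        if not np.isfinite(global_med):
            continue
        for b in labels:
            cols = batches.index[batches == b]
            vals = row[cols]
            bmed = vals.median(skipna=True)
            if not np.isfinite(bmed):
                continue
            if bmed == 0:
                logger.warning(
                    "%s: batch %r median is 0 for %r; left unscaled",
                    matrix.dataset_id, b, feat,
                )
                continue
            factor = global_med / bmed
            df.loc[feat, cols] = vals * factor
            report.batch_factors[(feat, b)] = factor
    report.stages.append(f"median_scale_batches: {len(labels)} batches")
    return OmicsMatrix(matrix.dataset_id, matrix.omics_kind, df, "linear")


def pqn_normalize(
    matrix: OmicsMatrix,
    reference_samples,
    config: AnalysisConfig | None = None,
    report: PreprocessReport | None = None,
) -> OmicsMatrix:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-metabolite median over
    ``reference_samples``, restricted to metabolites whose missing fraction
    among the reference samples is below ``pqn_reference_missing_max``.
    Each sample's dilution factor is the median of (sample value /
    reference value) over jointly non-missing reference metabolites, and
    the whole sample is divided by it.
    """
    _require_linear(matrix, "pqn_normalize")
    config = config or AnalysisConfig()
    report = report if report is not None else PreprocessReport(matrix.dataset_id)
    reference_samples = [s for s in reference_samples if s in matrix.data.columns]
    if not reference_samples:
        raise GmcError(f"{matrix.dataset_id}: no PQN reference samples")
    ref_block = matrix.data[reference_samples]
    miss_frac = ref_block.isna().mean(axis=1)
    eligible = miss_frac.index[miss_frac < config.pqn_reference_missing_max]
    if len(eligible) < 3:
        raise GmcError(
            f"{matrix.dataset_id}: only {len(eligible)} metabolites eligible "
            "for the PQN reference (< 3): reference unreliable"
        )
    reference = ref_block.loc[eligible].median(axis=1, skipna=True)
    reference = reference[reference > 0]
    df = matrix.data.copy()
    for s in df.columns:
        quot = df.loc[reference.index, s] / reference
        quot = quot[np.isfinite(quot)]
        if len(quot) == 0:
            logger.warning(
                "%s: sample %r shares no reference metabolites; factor 1",
                matrix.dataset_id, s,
            )
            factor = 1.0
        else:
            factor = float(quot.median())
        if factor <= 0:
            logger.warning(
                "%s: non-positive dilution factor for %r; factor 1",
                matrix.dataset_id, s,
            )
            factor = 1.0
        df[s] = df[s] / factor
        report.pqn_dilution[s] = factor
    report.pqn_reference_features = list(reference.index)
    report.stages.append(
        f"pqn_normalize: {len(reference)} reference metabolites, "
        f"{len(reference_samples)} reference samples"
    )
    return OmicsMatrix(matrix.dataset_id, matrix.omics_kind, df, "linear")


def log2_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Elementwise log2; requires linear state and strictly positive values."""
    _require_linear(matrix, "log2_transform")
    vals = matrix.data.to_numpy(dtype=float)
    bad = (vals <= 0) & np.isfinite(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GmcError(
            f"{matrix.dataset_id}: non-positive value at feature "
            f"{matrix.data.index[i]!r}, sample {matrix.data.columns[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(vals), index=matrix.data.index, columns=matrix.data.columns
    )
    out.index.name = matrix.data.index.name
    return OmicsMatrix(matrix.dataset_id, matrix.omics_kind, out, "log2")


def filter_missingness(
    matrix: OmicsMatrix,
    sample_ids=None,
    config: AnalysisConfig | None = None,
    report: PreprocessReport | None = None,
    reason: str = "missingness",
) -> OmicsMatrix:
    """Drop features whose missing fraction over ``sample_ids`` (default:
    all samples) is strictly greater than ``missing_drop_fraction``."""
    config = config or AnalysisConfig()
    report = report if report is not None else PreprocessReport(matrix.dataset_id)
    cols = (
        [s for s in sample_ids if s in matrix.data.columns]
        if sample_ids is not None
        else list(matrix.data.columns)
    )
    if not cols:
        return matrix
    frac = matrix.data[cols].isna().mean(axis=1)
    dropped = frac.index[frac > config.missing_drop_fraction]
    for f in dropped:
        report.dropped_features.append((f, reason))
        logger.info("%s: dropped %r (%s, %.0f%% missing)",
                    matrix.dataset_id, f, reason, 100 * frac[f])
    kept = matrix.data.drop(index=dropped)
    return OmicsMatrix(matrix.dataset_id, matrix.omics_kind, kept,
                       matrix.scale_state)


def impute_minimum(
    matrix: OmicsMatrix, report: PreprocessReport | None = None
) -> OmicsMatrix:
    """Replace each feature's missing cells with that feature's minimum
    observed value in the dataset. Fails on an all-missing feature, which
    the missingness filter should already have removed."""
    report = report if report is not None else PreprocessReport(matrix.dataset_id)
    df = matrix.data.copy()
    for feat in df.index:
        row = df.loc[feat]
        n_missing = int(row.isna().sum())
        if n_missing == 0:
            continue
        if n_missing == len(row):
            raise GmcError(
                f"{matrix.dataset_id}: feature {feat!r} is entirely missing "
                "at imputation (filter contract violated)"
            )
        df.loc[feat] = row.fillna(row.min(skipna=True))
        report.imputed_cells[feat] = n_missing
    report.stages.append(
        f"impute_minimum: {sum(report.imputed_cells.values())} cells"
    )
    return OmicsMatrix(matrix.dataset_id, matrix.omics_kind, df,
                       matrix.scale_state)


def preprocess_dataset(
    matrix: OmicsMatrix,
    annotations: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Run the full standardized pipeline on one metabolomics dataset.

    ``annotations`` indexes sample_id with columns tissue and batch. The PQN
    reference uses only normal samples when any are annotated, otherwise all
    tumour samples. The missingness filter runs once per tissue group and a
    feature is removed when it exceeds the threshold in any group.
    """
    config = config or AnalysisConfig()
    report = PreprocessReport(matrix.dataset_id)
    ann = annotations.reindex(matrix.sample_ids)
    if ann["tissue"].isna().any():
        missing = list(ann.index[ann["tissue"].isna()])[:5]
        raise GmcError(
            f"{matrix.dataset_id}: unannotated samples, e.g. {missing}"
        )

    m = median_scale_batches(matrix, ann["batch"], report)

    normal = list(ann.index[ann["tissue"] == "normal"])
    tumour = list(ann.index[ann["tissue"] == "tumour"])
    reference = normal if normal else tumour
    report.stages.append(
        "pqn reference: " + ("normal samples" if normal else "all tumour samples")
    )
    m = pqn_normalize(m, reference, config, report)
    m = log2_transform(m)

    for tissue, cols in (("normal", normal), ("tumour", tumour)):
        if cols:
            m = filter_missingness(
                m, cols, config, report, reason=f"missingness_{tissue}"
            )
    m = impute_minimum(m, report)
    return m, report
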