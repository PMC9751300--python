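"""Abundance normalization: TIC centering, QC-reference normalization, z-scores.

The chain is raw → TIC → reference → z-score.  TIC (total-ion-current)
normalization removes per-run global intensity differences by centering each
sample's log2 profile on the grand mean:

    P'_ij = P_ij − ( mean_j(P_ij) − grand_mean )

Reference normalization then expresses each specimen's abundances relative to
the temporally nearest pooled-QC run, absorbing slow drift over a long
acquisition.  Z-scoring standardizes each protein across locations so maps of
different proteins share one display scale.

Missing cells are excluded from every mean/sd and stay missing in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridio import QCSet, QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    """Per-sample offsets subtracted by a normalization step (log2 units)."""

    method_tag: str
    grand_mean: float
    per_sample_offset: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"offset_log2": pd.Series(self.per_sample_offset)}
        ).rename_axis("sample_id")
        df.attrs["grand_mean"] = self.grand_mean
        df.attrs["method_tag"] = self.method_tag
        return df


def tic_normalize(q: QuantMatrix) -> tuple[QuantMatrix, NormalizationReport]:
    """Center every sample's log2 profile on the grand mean.

    The grand mean is taken over all observed cells, so it is exactly
    conserved by the transformation even with unbalanced missingness.
    Requires ``scale_tag == 'log2_raw'``; every sample needs at least one
    observed cell.
    """
    if q.scale_tag != "log2_raw":
        raise ValueError(f"tic_normalize expects scale_tag 'log2_raw', got {q.scale_tag!r}")
    vals = q.values
    obs_per_sample = vals.notna().sum(axis=1)
    if (obs_per_sample == 0).any():
        bad = obs_per_sample.index[obs_per_sample == 0][0]
        raise ValueError(f"sample {bad!r} has no observed values; cannot TIC-normalize")
    grand_mean = float(np.nanmean(vals.to_numpy()))
    sample_means = vals.mean(axis=1, skipna=True)
    offsets = sample_means - grand_mean
    out = vals.sub(offsets, axis=0)
    report = NormalizationReport(
        method_tag="tic",
        grand_mean=grand_mean,
        per_sample_offset=offsets.to_dict(),
    )
    return q.with_values(out, "log2_tic"), report


def reference_normalize(q: QuantMatrix, qc: QCSet) -> QuantMatrix:
    """Subtract, per specimen, the matching QC run's log2 abundances.

    Each specimen is paired with its temporally nearest QC run
    (``qc.batch_of_specimen``).  For a protein missing in the assigned QC run
    the offset falls back to that protein's median across all QC runs; a
    protein absent from every QC run is left unchanged and logged.  Log2
    subtraction is equivalent to a ratio on the linear scale.
    """
    if q.scale_tag != "log2_tic":
        raise ValueError(
            f"reference_normalize expects scale_tag 'log2_tic', got {q.scale_tag!r}"
        )
    if qc.quant.n_samples == 0:
        raise ValueError("empty QCSet")
    if not qc.batch_of_specimen:
        raise ValueError("QCSet has no specimen->QC assignment; call assign_specimens first")
    missing_assign = [s for s in q.sample_ids if s not in qc.batch_of_specimen]
    if missing_assign:
        raise ValueError(f"no QC assignment for specimen(s) {missing_assign[:3]}")

    qc_vals = qc.quant.values  # qc runs x features
    qc_median = qc_vals.median(axis=0, skipna=True)  # per-feature fallback

    shared = [f for f in q.feature_ids if f in set(qc.quant.feature_ids)]
    never_in_qc = [f for f in shared if qc_vals[f].notna().sum() == 0]
    absent = sorted(set(q.feature_ids) - set(shared)) + never_in_qc
    if absent:
        logger.warning(
            "%d feature(s) absent from every QC run left unchanged (e.g. %s)",
            len(absent),
            absent[:3],
        )
    usable = [f for f in shared if f not in set(never_in_qc)]

    out = q.values.copy()
    # offset matrix: one row per specimen = its QC run's profile with median fallback
    for spec in q.sample_ids:
        qc_id = qc.batch_of_specimen[spec]
        offs = qc_vals.loc[qc_id, usable]
        offs = offs.fillna(qc_median[usable])
        out.loc[spec, usable] = out.loc[spec, usable] - offs
    return q.with_values(out, "log2_ref")


def zscore(q: QuantMatrix) -> QuantMatrix:
    """Standardize each feature across samples (sample sd, divisor n−1).

    Features with zero variance or fewer than two observed values get z = 0
    at every observed cell (with a logged warning) so their maps render flat
    instead of vanishing.
    """
    vals = q.values
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    n_obs = vals.notna().sum(axis=0)
    degenerate = (n_obs < 2) | (sd == 0) | sd.isna()
    if degenerate.any():
        bad = list(vals.columns[degenerate])
        logger.warning(
            "%d feature(s) with zero variance or <2 observations z-scored to 0 "
            "(e.g. %s)",
            len(bad),
            bad[:3],
        )
    safe_sd = sd.where(~degenerate, 1.0)
    z = vals.sub(mean, axis=1).div(safe_sd, axis=1)
    z.loc[:, degenerate] = z.loc[:, degenerate].where(vals.loc[:, degenerate].isna(), 0.0)
    return q.with_values(z, "zscore")
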