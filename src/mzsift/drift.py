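"""QC-anchored correction of injection-order sensitivity drift.

Pooled QC aliquots injected throughout the sequence sample the instrument's
sensitivity trajectory. For every feature detected (non-filled, nonzero) in
every QC injection, a linear model of log10 abundance versus injection index
is fitted on the QC samples only and used to extrapolate the drift across
the whole sequence; the fitted trend is subtracted from all samples and the
result is re-anchored at the QC mean so corrected values keep the original
scale. Features not detected in every QC are passed through unchanged.

Both the single global line (default) and piecewise interpolation between
consecutive QC pairs are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import FeatureTable

__all__ = ["DriftModel", "fit_drift", "correct", "qc_diagnostics"]


@dataclass(frozen=True)
class DriftModel:
    """Per-feature linear drift of log10 abundance vs injection index,
    fitted on QC samples; ``eligible`` is False when the feature was not
    detected in every QC sample (no correction is applied then)."""

    feature: str
    slope: float
    intercept: float
    eligible: bool


def _qc_detected_mask(table: FeatureTable, qc_ids: list[str]) -> np.ndarray:
    """Detected-in-every-QC eligibility, using pre-fill detection flags when
    the table carries them, else nonzero abundance in every QC column."""
    flags = table.abundance.attrs.get("fill_flags")
    if flags is not None:
        sub = flags[qc_ids].to_numpy()
        return ~sub.any(axis=1)
    vals = table.abundance[qc_ids].to_numpy(dtype=float)
    return (vals > (0.0 if not table.log_transformed else -np.inf)).all(axis=1)


def fit_drift(table: FeatureTable,
              exclude_qc: list[str] | None = None) -> list[DriftModel]:
    """Ordinary least squares of QC log10 abundance on injection index,
    per eligible feature.

    ``exclude_qc`` drops named QC injections from the fit (the manual
    escape hatch for a QC with a gross sensitivity loss). At least three
    QC samples must remain.
    """
    if not table.log_transformed:
        raise ValueError("fit_drift expects a log10-transformed table")
    qc_ids = [s for s in table.type_columns("qc")
              if not exclude_qc or s not in exclude_qc]
    if len(qc_ids) < 3:
        raise ValueError(f"need >= 3 QC samples to fit drift, have {len(qc_ids)}")
    idx = table.samples.loc[qc_ids, "injection_index"].to_numpy(dtype=float)
    eligible = _qc_detected_mask(table, qc_ids)
    vals = table.abundance[qc_ids].to_numpy(dtype=float)
    models = []
    for i, fname in enumerate(table.feature_names):
        if eligible[i]:
            slope, intercept = np.polyfit(idx, vals[i], 1)
            models.append(DriftModel(fname, float(slope), float(intercept), True))
        else:
            models.append(DriftModel(fname, 0.0, 0.0, False))
    return models


def correct(table: FeatureTable, models: list[DriftModel],
            piecewise: bool = False) -> FeatureTable:
    """Remove the fitted QC drift trend from all samples.

    Default: corrected = observed - slope * injection_index + (QC-mean
    re-anchoring), extrapolating the single global QC line across the whole
    sequence. ``piecewise=True`` instead interpolates the QC log-abundance
    profile between consecutive QC injections and subtracts that.
    Ineligible features are returned bit-identical.
    """
    out = table.copy()
    by_name = {m.feature: m for m in models}
    inj = table.injection_index
    qc_ids = table.type_columns("qc")
    qc_pos = [table.sample_ids.index(s) for s in qc_ids]
    vals = out.abundance.to_numpy(dtype=float)
    for i, fname in enumerate(table.feature_names):
        m = by_name.get(fname)
        if m is None or not m.eligible:
            continue
        row = vals[i]
        if piecewise:
            qx = inj[qc_pos]
            qy = row[qc_pos]
            order = np.argsort(qx)
            trend = np.interp(inj, qx[order], qy[order])
            corrected = row - trend + qy.mean()
        else:
            corrected = row - m.slope * inj
            anchor = row[qc_pos].mean() - corrected[qc_pos].mean()
            corrected = corrected + anchor
        vals[i] = corrected
    out.abundance = pd.DataFrame(vals, index=out.abundance.index,
                                 columns=out.abundance.columns)
    return out


def qc_diagnostics(before: FeatureTable, after: FeatureTable,
                   models: list[DriftModel] | None = None,
                   outlier_factor: float = 5.0) -> dict:
    """QC dispersion before/after correction and QC outlier flags.

    Per feature, dispersion over the QC injections is summarised as the
    standard deviation of log10 abundance (equivalently, a CV on the raw
    scale). Reports the fraction of (eligible) features whose QC dispersion
    improved, and flags QC injections whose total intensity deviates from
    the median QC by more than ``outlier_factor``-fold (the "sensitivity
    loss" pattern that justifies manual exclusion).
    """
    qc_ids = before.type_columns("qc")
    b = before.abundance[qc_ids].to_numpy(dtype=float)
    a = after.abundance[qc_ids].to_numpy(dtype=float)
    sd_before = b.std(axis=1, ddof=1)
    sd_after = a.std(axis=1, ddof=1)
    if models is not None:
        mask = np.array([m.eligible for m in models])
    else:
        mask = np.ones(len(sd_before), dtype=bool)
    improved = (sd_after[mask] < sd_before[mask] - 1e-15)
    delta = sd_after - sd_before
    # per-QC total signal on the raw scale
    raw = np.power(10.0, b) if before.log_transformed else b
    totals = raw.sum(axis=0)
    med = np.median(totals)
    outliers = [qc_ids[j] for j, t in enumerate(totals)
                if t < med / outlier_factor or t > med * outlier_factor]
    return {
        "qc_ids": qc_ids,
        "sd_before": sd_before,
        "sd_after": sd_after,
        "delta": delta,
        "n_eligible": int(mask.sum()),
        "improved_fraction": float(improved.mean()) if mask.any() else 0.0,
        "outlier_qcs": outliers,
    }
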