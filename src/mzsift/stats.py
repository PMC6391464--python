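"""Group-comparison statistics and the significance filter.

The filtering recipe, in order: signed fold changes and Welch two-sample
t-tests for the three pairwise group comparisons (Blank-Low, Blank-High,
Low-High) computed on raw abundances; a feature survives if |FC| > 1.5 AND
p < 0.001 in the *same* comparison, and its retention time lies inside the
[60, 600] s window (the chromatographic equilibration and wash phases are
excluded). Only after filtering are zeros replaced by the global minimum
positive abundance (surrogate LOD) and abundances log10-transformed.

No multiple-testing correction is applied by default — the raw p < 0.001
gate is the procedure being reproduced; a Benjamini-Hochberg option exists
behind an off-by-default flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .table import FeatureTable

__all__ = [
    "COMPARISONS",
    "ComparisonResult",
    "FilterVerdict",
    "signed_fold_change",
    "welch_t",
    "compare_groups",
    "apply_filters",
    "transform_abundances",
]

#: The three pairwise group comparisons, as (reference, treatment).
COMPARISONS = (("Blank", "Low"), ("Blank", "High"), ("Low", "High"))


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    pair: str                   # e.g. "Blank-High"
    fold_change: float          # signed; +inf / -inf / nan sentinels allowed
    p_value: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class FilterVerdict:
    feature: str
    passed: bool
    passing_pairs: tuple[str, ...]
    rt_ok: bool


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Signed fold change of b relative to a.

    Ratio r = b/a expressed as r when r >= 1 and -1/r otherwise, so that
    thresholds like "|FC| > 1.5" are symmetric for increases and decreases.
    Degenerate cases: both means zero -> nan (undefined, never passes any
    filter); a = 0, b > 0 -> +inf (passes any FC threshold; the p-value
    still gates); b = 0, a > 0 -> -inf.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("group means must be non-negative")
    if mean_a == 0 and mean_b == 0:
        return float("nan")
    if mean_a == 0:
        return float("inf")
    if mean_b == 0:
        return float("-inf")
    r = mean_b / mean_a
    return r if r >= 1.0 else -1.0 / r


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p). Requires at least two
    observations per group. Zero pooled variance with equal means gives
    t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("inf") if x.mean() > y.mean() else float("-inf"), \
            float(len(x) + len(y) - 2), 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_groups(table: FeatureTable,
                   comparisons=COMPARISONS) -> pd.DataFrame:
    """Fold change and Welch-t p-value per feature per group comparison.

    Computed on the table's abundances as given (conventionally raw, since
    the transformation step follows filtering in this workflow).
    """
    cols = {}
    for a, b in comparisons:
        for g in (a, b):
            if g not in cols:
                ids = table.group_columns(g)
                if not ids:
                    raise ValueError(f"group {g!r} has no samples")
                cols[g] = table.abundance[ids].to_numpy(dtype=float)
    rows = []
    for i, fname in enumerate(table.feature_names):
        for a, b in comparisons:
            xa, xb = cols[a][i], cols[b][i]
            fc = signed_fold_change(float(xa.mean()), float(xb.mean()))
            _, _, p = welch_t(xa, xb)
            rows.append(ComparisonResult(fname, f"{a}-{b}", fc, p,
                                         float(xa.mean()), float(xb.mean())))
    return pd.DataFrame([r.__dict__ for r in rows])


def apply_filters(table: FeatureTable, fc_thresh: float = 1.5,
                  p_thresh: float = 0.001,
                  rt_window: tuple[float, float] = (60.0, 600.0),
                  fdr: bool = False,
                  ) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    """Significance filter: |FC| > fc_thresh with p < p_thresh in the same
    comparison, and RT inside ``rt_window`` (inclusive on both ends).

    Returns (filtered table, verdicts DataFrame, comparisons DataFrame).
    With ``fdr=True`` p-values are Benjamini-Hochberg adjusted across all
    features x comparisons before thresholding (off by default; the
    reference procedure gates on raw p-values).
    """
    comp = compare_groups(table)
    pcol = "p_value"
    if fdr:
        comp = comp.copy()
        comp["p_adj"] = sps.false_discovery_control(
            comp["p_value"].fillna(1.0).clip(0, 1))
        pcol = "p_adj"
    rt = table.features["rt"]
    verdict_rows = []
    for fname in table.feature_names:
        sub = comp[comp["feature"] == fname]
        passing = tuple(
            r.pair for r in sub.itertuples(index=False)
            if np.isfinite(getattr(r, pcol))
            and getattr(r, pcol) < p_thresh
            and (np.isinf(r.fold_change) or abs(r.fold_change) > fc_thresh)
            and not np.isnan(r.fold_change)
        )
        rt_ok = bool(rt_window[0] <= rt[fname] <= rt_window[1])
        verdict_rows.append(FilterVerdict(fname, bool(passing) and rt_ok,
                                          passing, rt_ok))
    verdicts = pd.DataFrame([v.__dict__ for v in verdict_rows])
    keep = verdicts.loc[verdicts["passed"], "feature"].tolist()
    return table.subset(keep), verdicts, comp


def transform_abundances(table: FeatureTable) -> FeatureTable:
    """Replace zeros with the global minimum positive abundance (surrogate
    limit of detection), then log10-transform elementwise."""
    if table.log_transformed:
        raise ValueError("table is already log-transformed")
    vals = table.values()
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("all abundances are zero; nothing to transform")
    lod = float(pos.min())
    out = table.copy()
    filled = np.where(vals > 0, vals, lod)
    out.abundance = pd.DataFrame(np.log10(filled),
                                 index=table.abundance.index,
                                 columns=table.abundance.columns)
    out.log_transformed = True
    return out


def volcano_data(comp: pd.DataFrame) -> pd.DataFrame:
    """FC vs -log10 p coordinates per comparison, for volcano plots."""
    out = comp.copy()
    out["neg_log10_p"] = -np.log10(out["p_value"].clip(lower=1e-300))
    return out
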