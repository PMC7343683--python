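"""Agreement and test-retest reliability statistics for binding estimates.

Agreement between two sets of estimates (e.g. two analysis pipelines treated
as k = 2 "raters") is summarised by Pearson's r, the intraclass correlation
ICC(A,1) and the percentage bias.  Test-retest performance over two sessions
is summarised by the mean, coefficient of variation (CV), ICC(A,1), the
within-subject coefficient of variation (WSCV) and the absolute variability
(AV).

ICC(A,1) is the two-way, absolute-agreement, single-measurement intraclass
correlation,

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),

where MS_R, MS_C and MS_E are the row (subject), column (session/rater) and
error mean squares of the two-way ANOVA decomposition, n the number of
subjects and k the number of observations per subject.  WSCV is
sqrt(MS_W) / grand mean * 100 with MS_W the within-subject mean square; AV is
2 |X1 - X2| / |X1 + X2| * 100 per subject.

Long-format estimate tables use the columns
``subject  session  region  model  estimate``.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ValidationError

KEY_COLS = ["subject", "session", "region", "model"]


# ---------------------------------------------------------------------------
# two-way ANOVA decomposition and ICC(A,1)
# ---------------------------------------------------------------------------

def _as_matrix(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValidationError("ratings matrix must be 2-D (subjects x sessions)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError(f"ratings matrix needs n >= 2 and k >= 2, got {m.shape}")
    if np.isnan(m).any():
        raise ValidationError("ratings matrix must be complete (no missing cells)")
    return m


@dataclass
class AnovaDecomposition:
    """Two-way mean squares of an n x k complete ratings matrix."""

    ms_r: float
    ms_c: float
    ms_e: float
    ms_w: float
    grand_mean: float
    n: int
    k: int


def anova_decompose(m) -> AnovaDecomposition:
    """Two-way ANOVA decomposition (rows = subjects, columns = sessions)."""
    m = _as_matrix(m)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_r = k * np.sum((row_means - grand) ** 2)
    ss_c = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((m - grand) ** 2)
    ss_e = max(ss_tot - ss_r - ss_c, 0.0)
    ms_w = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
    return AnovaDecomposition(
        ms_r=float(ss_r / (n - 1)),
        ms_c=float(ss_c / (k - 1)),
        ms_e=float(ss_e / ((n - 1) * (k - 1))),
        ms_w=float(ms_w),
        grand_mean=float(grand),
        n=n, k=k,
    )


def icc_a1(m) -> float:
    """ICC(A,1): two-way, absolute-agreement, single-measurement ICC."""
    d = anova_decompose(m)
    denom = d.ms_r + (d.k - 1) * d.ms_e + (d.k / d.n) * (d.ms_c - d.ms_e)
    if denom == 0:
        _warnings.warn("icc_a1: zero denominator (no variance); returning NaN")
        return float("nan")
    return float((d.ms_r - d.ms_e) / denom)


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def bias_percent(x_a, x_b) -> float:
    """Percentage change of mean(x_a) relative to mean(x_b)."""
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    if x_a.size != x_b.size:
        raise ValidationError("bias_percent: vectors must have equal length")
    mb = x_b.mean()
    if mb == 0:
        raise ValidationError("bias_percent: reference mean is zero")
    return float((x_a.mean() - mb) / mb * 100.0)


def cv_percent(x) -> float:
    """Coefficient of variation: sample SD (n-1) over mean, percent."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValidationError("cv_percent: need n >= 2")
    mu = x.mean()
    if mu == 0:
        raise ValidationError("cv_percent: zero mean")
    return float(x.std(ddof=1) / mu * 100.0)


def wscv_percent(m) -> float:
    """Within-subject CV: sqrt(MS_W) over the grand mean, percent."""
    d = anova_decompose(m)
    if d.grand_mean == 0:
        raise ValidationError("wscv_percent: zero grand mean")
    return float(np.sqrt(d.ms_w) / d.grand_mean * 100.0)


def av_percent(x1, x2):
    """Absolute variability 2|X1 - X2| / |X1 + X2| * 100 per subject.

    Returns ``(per_subject, mean)``; subjects with X1 + X2 = 0 get NaN with a
    warning.  Symmetric in session order.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.size != x2.size:
        raise ValidationError("av_percent: vectors must have equal length")
    denom = np.abs(x1 + x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        av = 2.0 * np.abs(x1 - x2) / denom * 100.0
    if np.any(denom == 0):
        _warnings.warn("av_percent: zero session sum for some subjects; NaN emitted")
        av = np.where(denom == 0, np.nan, av)
    return av, float(np.nanmean(av))


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def _check_long(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in KEY_COLS + ["estimate"] if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")
    return df


def agreement_report(tool_a: pd.DataFrame, tool_b: pd.DataFrame) -> pd.DataFrame:
    """Per region x model agreement between two estimate tables.

    Rows are matched on (subject, session, region, model); the two tools act
    as k = 2 raters in the ICC.  Unmatched keys raise an error listing them.
    """
    a = _check_long(tool_a, "tool_a")
    b = _check_long(tool_b, "tool_b")
    merged = a.merge(b, on=KEY_COLS, how="outer", suffixes=("_a", "_b"),
                     indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if not bad.empty:
        keys = bad[KEY_COLS].to_records(index=False).tolist()
        raise ValidationError(f"agreement_report: unmatched keys: {keys[:10]}")
    rows = []
    for (region, model), grp in merged.groupby(["region", "model"], sort=True):
        va = grp["estimate_a"].to_numpy(float)
        vb = grp["estimate_b"].to_numpy(float)
        r = float(stats.pearsonr(va, vb)[0]) if va.size >= 3 else np.nan
        rows.append({
            "region": region, "model": model, "n": va.size,
            "pearson_r": r,
            "icc": icc_a1(np.column_stack([va, vb])),
            "bias_percent": bias_percent(va, vb),
        })
    return pd.DataFrame(rows)


def trt_report(test: pd.DataFrame, retest: pd.DataFrame) -> pd.DataFrame:
    """Per region x model test-retest table: mean, CV, ICC, WSCV, AV.

    ``test`` and ``retest`` are long-format tables for session 1 and 2 (in
    chronological order); subjects missing either session are dropped with a
    warning.
    """
    t = _check_long(test, "test")
    r = _check_long(retest, "retest")
    keys = ["subject", "region", "model"]
    merged = t.merge(r, on=keys, suffixes=("_1", "_2"), how="outer",
                     indicator=True)
    incomplete = merged[merged["_merge"] != "both"]
    if not incomplete.empty:
        _warnings.warn(
            f"trt_report: {incomplete['subject'].nunique()} subject(s) missing a "
            "session were excluded")
        merged = merged[merged["_merge"] == "both"]
    rows = []
    for (region, model), grp in merged.groupby(["region", "model"], sort=True):
        x1 = grp["estimate_1"].to_numpy(float)
        x2 = grp["estimate_2"].to_numpy(float)
        m = np.column_stack([x1, x2])
        _, av_mean = av_percent(x1, x2)
        rows.append({
            "region": region, "model": model, "n": x1.size,
            "mean": float(m.mean()),
            "cv_percent": cv_percent(m.ravel()),
            "icc": icc_a1(m),
            "wscv_percent": wscv_percent(m),
            "av_percent": av_mean,
        })
    return pd.DataFrame(rows)


def flag_outliers(values: pd.DataFrame, z_thresh: float = 5.0,
                  change_thresh: float = 500.0,
                  combine: str = "and") -> pd.DataFrame:
    """Flag aberrant estimates in a subject x session table.

    A value is flagged when it lies more than ``z_thresh`` leave-one-out
    standard deviations from the mean of the rest of the sample AND shows
    more than a ``change_thresh`` percent increase over the same subject's
    other measurement (``combine="or"`` relaxes the rule to either
    criterion).  Requires at least 3 subjects.
    """
    if combine not in ("and", "or"):
        raise ValidationError("flag_outliers: combine must be 'and' or 'or'")
    needed = ["subject", "session", "value"]
    missing = [c for c in needed if c not in values.columns]
    if missing:
        raise ValidationError(f"flag_outliers: missing columns {missing}")
    if values["subject"].nunique() < 3:
        raise ValidationError("flag_outliers: need >= 3 subjects")
    vals = values["value"].to_numpy(float)
    subjects = values["subject"].to_numpy()
    out = values.copy()
    z = np.full(vals.size, np.nan)
    change = np.full(vals.size, np.nan)
    for i in range(vals.size):
        # "rest of the sample" excludes the subject's own measurements
        rest = vals[subjects != subjects[i]]
        sd = rest.std(ddof=1)
        z[i] = np.abs(vals[i] - rest.mean()) / sd if sd > 0 else np.inf
        own = vals[(subjects == subjects[i])
                   & (np.arange(vals.size) != i)]
        if own.size:
            other_val = float(own[0])
            if other_val != 0:
                change[i] = (vals[i] - other_val) / abs(other_val) * 100.0
    z_flag = z > z_thresh
    c_flag = change > change_thresh
    out["loo_z"] = z
    out["change_percent"] = change
    out["flag"] = (z_flag & c_flag) if combine == "and" else (z_flag | c_flag)
    return out
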