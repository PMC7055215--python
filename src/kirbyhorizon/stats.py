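"""Statistics linking discounting and exploration measures.

Paired t-tests compare first-free-choice measures across horizons; Cohen's d
is reported both as d_av (mean difference over the root-mean-square of the
two condition SDs) and d_z (mean difference over the SD of the differences).
Individual differences are related by Pearson correlations between the six
discounting measures (the five ks log10-transformed; the "today" count raw)
and the ten task measures, with p-values from the t transform of r. The
sample-size helper inverts the Fisher-z power approximation for a
correlation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSummary",
    "paired_t",
    "paired_t_from_summary",
    "cohen_d_av",
    "cohen_d_z",
    "CorrelationCell",
    "pearson_cell",
    "correlation_table",
    "discount_measures_for_correlation",
    "TASK_MEASURES",
    "DISCOUNT_MEASURES",
    "fisher_n_for_r",
    "summary_table",
]

#: Task-measure columns correlated against discounting (Table-3 layout).
TASK_MEASURES = [
    "directed",
    "random",
    "p_high_info_h1",
    "p_high_info_h6",
    "p_low_mean_h1",
    "p_low_mean_h6",
    "accuracy_h1",
    "accuracy_h6",
    "rt_h1",
    "rt_h6",
]

#: Discounting measures used in the correlation grid (ks on log10 scale).
DISCOUNT_MEASURES = [
    "log_k_overall",
    "log_k_small",
    "log_k_medium",
    "log_k_large",
    "log_k_geomean",
    "n_today",
]


@dataclass(frozen=True)
class PairedSummary:
    """Paired-comparison summary: t statistic and both effect sizes."""

    n: int
    mean_a: float
    mean_b: float
    mean_diff: float
    sd_a: float
    sd_b: float
    sd_diff: float
    t: float
    df: int
    p: float
    d_av: float
    d_z: float
    degenerate: bool = False


def cohen_d_av(mean_diff: float, sd_a: float, sd_b: float) -> float:
    """Effect size against the RMS of the two condition SDs."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("condition SDs must be positive")
    return mean_diff / math.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)


def cohen_d_z(mean_diff: float, sd_diff: float) -> float:
    """Effect size against the SD of the paired differences."""
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    return mean_diff / sd_diff


def paired_t_from_summary(
    mean_diff: float,
    sd_diff: float,
    n: int,
    mean_a: float = math.nan,
    mean_b: float = math.nan,
    sd_a: float = math.nan,
    sd_b: float = math.nan,
) -> PairedSummary:
    """Paired t-test from summary statistics (two-tailed)."""
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    df = n - 1
    if sd_diff == 0:
        # identical pairs: define 0/0 as 0; a nonzero constant shift has
        # infinite t -- both flagged degenerate
        zero = mean_diff == 0
        return PairedSummary(
            n=n, mean_a=mean_a, mean_b=mean_b, mean_diff=mean_diff,
            sd_a=sd_a, sd_b=sd_b, sd_diff=0.0,
            t=0.0 if zero else math.inf * math.copysign(1, mean_diff),
            df=df, p=1.0 if zero else 0.0,
            d_av=(cohen_d_av(mean_diff, sd_a, sd_b)
                  if sd_a > 0 and sd_b > 0 else (0.0 if zero else math.nan)),
            d_z=0.0 if zero else math.nan, degenerate=True,
        )
    t = mean_diff / (sd_diff / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    d_av = math.nan
    if sd_a > 0 and sd_b > 0:
        d_av = cohen_d_av(mean_diff, sd_a, sd_b)
    return PairedSummary(
        n=n, mean_a=mean_a, mean_b=mean_b, mean_diff=mean_diff,
        sd_a=sd_a, sd_b=sd_b, sd_diff=sd_diff,
        t=t, df=df, p=p, d_av=d_av, d_z=cohen_d_z(mean_diff, sd_diff),
    )


def paired_t(a, b) -> PairedSummary:
    """Paired t-test on raw vectors (b - a is the tested difference)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d vectors of equal length")
    d = b - a
    return paired_t_from_summary(
        mean_diff=float(d.mean()),
        sd_diff=float(d.std(ddof=1)),
        n=len(a),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )


@dataclass(frozen=True)
class CorrelationCell:
    """One Pearson correlation with its two-tailed p and pair count."""

    r: float
    p: float
    n: int


def pearson_cell(x, y, min_n: int = 4) -> CorrelationCell:
    """Pairwise-complete Pearson correlation; NaN cell below ``min_n``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < min_n:
        return CorrelationCell(r=math.nan, p=math.nan, n=n)
    r, p = sps.pearsonr(x[ok], y[ok])
    return CorrelationCell(r=float(r), p=float(p), n=n)


def discount_measures_for_correlation(scores: pd.DataFrame) -> pd.DataFrame:
    """Six discounting measures ready for correlation (log10 ks, raw count)."""
    out = pd.DataFrame({"subject_id": scores["subject_id"]})
    for col in ("k_overall", "k_small", "k_medium", "k_large", "k_geomean"):
        out["log_" + col] = np.log10(scores[col])
    out["n_today"] = scores["n_today"]
    return out


def correlation_table(
    discount: pd.DataFrame,
    task: pd.DataFrame,
    *,
    min_n: int = 4,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Pearson grid: discounting measures (rows) x task measures (columns).

    Inputs are aligned on ``subject_id``; each cell is computed on pairwise-
    complete observations. Returns a long frame with one row per cell
    (columns discount_measure, task_measure, r, p, n, and p_bonferroni when
    requested; the correction is off by default).
    """
    merged = discount.merge(task, on="subject_id", how="inner")
    rows = []
    d_cols = [c for c in DISCOUNT_MEASURES if c in merged.columns]
    t_cols = [c for c in TASK_MEASURES if c in merged.columns]
    if not d_cols or not t_cols:
        raise ValueError("no recognised measure columns to correlate")
    for dc in d_cols:
        for tc in t_cols:
            cell = pearson_cell(merged[dc], merged[tc], min_n=min_n)
            rows.append({
                "discount_measure": dc, "task_measure": tc,
                "r": cell.r, "p": cell.p, "n": cell.n,
            })
    out = pd.DataFrame(rows)
    if bonferroni:
        m = out["p"].notna().sum()
        out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    return out


def fisher_n_for_r(
    r: float, alpha: float = 0.05, power: float = 0.8, tails: int = 2
) -> int:
    """Smallest n detecting correlation ``r`` under the Fisher-z approximation.

    n = ceil(((z_alpha + z_beta) / atanh(r))^2 + 3), floored at 4 so the
    t-based p-value keeps at least one degree of freedom beyond the
    2 lost to estimating the correlation.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must be strictly between 0 and 1")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    z_a = sps.norm.ppf(1.0 - alpha / tails)
    z_b = sps.norm.ppf(power)
    zr = math.atanh(r)
    n = math.ceil(((z_a + z_b) / zr) ** 2 + 3.0)
    return max(int(n), 4)


def summary_table(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Min/max/mean/SD summary rows for the given measure columns."""
    rows = []
    for c in columns:
        v = pd.to_numeric(df[c], errors="coerce")
        rows.append({
            "measure": c,
            "min": v.min(), "max": v.max(),
            "mean": v.mean(), "sd": v.std(ddof=1),
        })
    return pd.DataFrame(rows)
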