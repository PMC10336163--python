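"""Cohort-level statistics on classified populations.

Pearson chi-square tests on 2x2 contingency tables of cell counts (no
continuity correction), the Rayleigh test of circular uniformity, and
tabulated per-class summaries. Generic nonparametric comparisons (rank-sum,
signed-rank, Kruskal-Wallis, Kolmogorov-Smirnov) are deliberately left to
scipy.stats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._circular import rayleigh_test  # noqa: F401  (re-exported)


def chi_square_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], df = 1.

    Rows are groups, columns trait present/absent. No Yates continuity
    correction: chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        raise ValueError("zero marginal: chi-square undefined")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(chi2.sf(stat, df=1))
    return float(stat), p, 1


_SUMMARY_METRICS = (
    "spike_width_us", "mean_rate", "peak_rate", "ic", "ir", "peak_isi_ms",
    "dir_info", "loc_info", "loc_sparsity", "s_score", "abs_ahv_score",
)


def cohort_summary(reports, group_key: str = "group") -> pd.DataFrame:
    """Per-class (x optional group tag) counts and mean +/- SEM of metrics.

    `reports` is an iterable of CellReport; each report's metrics dict is
    scanned for the standard summary metrics, missing ones are skipped.
    Boolean flags (bursting, speed_tuned, ahv_tuned, precessing) are
    tabulated as proportions. SEM is reported as NaN for single-cell
    classes.
    """
    rows = []
    for r in reports:
        row = {"cell_id": r.cell_id, "label": r.label,
               "group": r.metrics.get(group_key, "all"),
               "bursting": r.bursting, "speed_tuned": r.speed_tuned,
               "ahv_tuned": r.ahv_tuned, "precessing": r.precessing}
        for m in _SUMMARY_METRICS:
            if m in r.metrics and r.metrics[m] is not None:
                row[m] = r.metrics[m]
        rows.append(row)
    df = pd.DataFrame(rows)
    out = []
    for (label, group), grp in df.groupby(["label", "group"]):
        rec = {"label": label, "group": group, "n": len(grp)}
        for m in _SUMMARY_METRICS:
            if m in grp:
                vals = grp[m].dropna().to_numpy(float)
                rec[f"{m}_mean"] = vals.mean() if vals.size else np.nan
                rec[f"{m}_sem"] = (vals.std(ddof=1) / np.sqrt(vals.size)
                                   if vals.size > 1 else np.nan)
        for flag in ("bursting", "speed_tuned", "ahv_tuned", "precessing"):
            vals = grp[flag].dropna()
            rec[f"{flag}_prop"] = float(vals.mean()) if len(vals) else np.nan
        out.append(rec)
    return pd.DataFrame(out).set_index(["label", "group"]).sort_index()
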