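"""Statistical procedures: donor-equal-weight Pearson correlation and CV% precision.

Osteochondral samples are pseudoreplicates: several cores come from the
same donor knee.  To remove the pseudoreplication, every sample is weighted
by the reciprocal of its donor's sample count, so each donor contributes
one unit of weight regardless of how many cores were taken.  Significance
uses a t statistic with (number of donors - 2) degrees of freedom.

The alternative of collapsing each donor to its mean before an unweighted
correlation is available as ``method="donor_mean"``; the weighted form is
the default because it preserves within-donor spread of both grade and
metric.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

log = logging.getLogger(__name__)


def donor_weighted_pearson(
    table: pd.DataFrame,
    metric: str,
    grade_col: str = "grade",
    donor_col: str = "donor_id",
    method: str = "weighted",
) -> dict:
    """Pearson correlation of ``metric`` against the severity grade with
    donors weighted equally.

    Returns ``{"r": ..., "p": ..., "n_donors": ...}``.  Rows with a missing
    metric or grade are dropped pairwise (logged).  Requires at least three
    donors and nonzero variance in both variables.
    """
    if method not in ("weighted", "donor_mean"):
        raise ValueError("method must be 'weighted' or 'donor_mean'")
    cols = [donor_col, grade_col, metric]
    df = table[cols].copy()
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        log.info("dropped %d rows with missing %s/%s", n_before - len(df), metric, grade_col)
    n_donors = df[donor_col].nunique()
    if n_donors < 3:
        raise ValueError(f"need >= 3 donors with complete data, got {n_donors}")

    if method == "donor_mean":
        agg = df.groupby(donor_col)[[grade_col, metric]].mean()
        x = agg[metric].to_numpy(float)
        y = agg[grade_col].to_numpy(float)
        w = np.ones(len(agg))
    else:
        x = df[metric].to_numpy(float)
        y = df[grade_col].to_numpy(float)
        w = 1.0 / df.groupby(donor_col)[grade_col].transform("size").to_numpy(float)

    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in metric or grade: correlation undefined")
    r = float(cov / np.sqrt(vx * vy))
    r = max(-1.0, min(1.0, r))
    dof = n_donors - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r ** 2))
        p = float(2.0 * sp_stats.t.sf(abs(t), dof))
    return {"r": r, "p": p, "n_donors": int(n_donors)}


def cv_percent(repeats) -> float:
    """Coefficient of variation, 100 * sample SD / mean, of repeated measures."""
    values = np.asarray(list(repeats), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 repeated values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero mean: CV% undefined")
    return float(100.0 * values.std(ddof=1) / mean)
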