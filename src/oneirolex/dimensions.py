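"""Aggregation of multi-rater Likert scores for the 16 semantic dimensions.

Each verbal report is rated on a 9-point Likert scale by several raters
(three LLM raters in the original protocol) for every hypothesis-driven
dimension; the per-report value is the median across raters.  Pairwise
rater agreement is quantified by Spearman rank correlation over shared
reports.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["aggregate_rater_scores", "rater_agreement"]


def aggregate_rater_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Median across raters, one row per report and one column per dimension.

    With an even number of raters the midpoint of the two central values is
    used (plain median).  A (report, dimension) pair with no score at all
    becomes a missing cell with a warning; a missing single rater simply
    leaves the median of the remaining raters.
    """
    if not scores["score"].between(1, 9).all():
        raise ValueError("scores must lie in 1..9")
    table = (scores.groupby(["report_id", "dimension"])["score"]
             .median().unstack("dimension"))
    if table.isna().any().any():
        n = int(table.isna().sum().sum())
        warnings.warn(f"{n} (report, dimension) cell(s) have no rater score",
                      RuntimeWarning)
    table.index.name = "report_id"
    return table


def rater_agreement(scores: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Pairwise Spearman correlations between raters for one dimension.

    Each pair is correlated over the reports both raters scored (at least 3
    required); a rater giving constant scores yields an undefined (NaN)
    correlation.  The result is symmetric with unit diagonal.
    """
    sub = scores[scores["dimension"] == dimension]
    if sub.empty:
        raise ValueError(f"no scores for dimension {dimension!r}")
    wide = sub.pivot(index="report_id", columns="rater_id", values="score")
    raters = list(wide.columns)
    out = pd.DataFrame(np.eye(len(raters)), index=raters, columns=raters)
    for a, b in itertools.combinations(raters, 2):
        pair = wide[[a, b]].dropna()
        if len(pair) < 3:
            rho = np.nan
        elif pair[a].nunique() == 1 or pair[b].nunique() == 1:
            rho = np.nan
        else:
            rho = spearmanr(pair[a], pair[b]).statistic
        out.loc[a, b] = out.loc[b, a] = rho
    return out
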