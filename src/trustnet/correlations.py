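"""Survey-item Pearson correlations and cross-layer Spearman rank correlations.

Two complementary views of agreement between trust dimensions:

* Before network construction, the per-dyad coded responses (-1..+1) to the
  seven trust items, plus their mean as a combined column, are correlated
  pairwise (Pearson).  A correlation of one means each respondent gave the
  same response to both questions for everyone they named.
* After network construction, the node rankings by weighted in-degree or
  betweenness are compared between layers (Spearman), restricted to the
  top-k nodes of each measure so that ranks are taken over nodes with
  meaningfully distinct, positive scores rather than the mass of isolates
  at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layers import code_likert
from .survey import N_DIMENSIONS, SurveyRecord

COMBINED_COLUMN = "combined"


def dyad_matrix(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """One row per (respondent, alter) dyad; columns are the coded responses
    (-1..+1) for trust dimensions 1..7 plus the combined column (their mean).

    Collaboration is deliberately excluded: its 6-level intensity scale is
    not commensurate with the agreement coding.
    """
    index = []
    rows = []
    for rec in records:
        for alter, ratings in zip(rec.alters, rec.trust):
            codes = [code_likert(r) for r in ratings]
            index.append((rec.respondent_id, alter))
            rows.append(codes + [sum(codes) / N_DIMENSIONS])
    columns = [f"trust_{d}" for d in range(1, N_DIMENSIONS + 1)] + [COMBINED_COLUMN]
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["respondent", "alter"]),
        columns=columns,
    )


def pearson_matrix(m: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and two-sided p from the t approximation) between
    every pair of columns of a dyad-response matrix.

    Returns ``(r, p)`` DataFrames; entries involving a zero-variance column
    are NaN (undefined), and the diagonal of ``r`` is 1.
    """
    if len(m) < 3:
        raise ValueError(f"need >= 3 dyads for correlations, got {len(m)}")
    cols = list(m.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        r.loc[a, a] = 1.0
        p.loc[a, a] = 0.0
        for b in cols[i + 1:]:
            x, y = m[a].to_numpy(float), m[b].to_numpy(float)
            if np.var(x) == 0 or np.var(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


@dataclass(frozen=True)
class RankCorrelationReport:
    """Spearman rank agreement between two layers' node scores over the
    intersection of their top-k node sets."""

    rho: float | None
    pvalue: float | None
    n_common: int
    included: bool  # significant below p < 0.05
    note: str = ""


def _top_k(scores: Mapping, k: int) -> list:
    """Top-k nodes by score among positive scores; ties broken by stable
    node-id order so the selection is deterministic."""
    positive = [(v, s) for v, s in scores.items() if s > 0]
    positive.sort(key=lambda vs: (-vs[1], str(vs[0])))
    return [v for v, _ in positive[:k]]


def top_k_spearman(
    scores_a: Mapping,
    scores_b: Mapping,
    k: int = 20,
    mode: str = "intersection",
) -> RankCorrelationReport:
    """Spearman rank correlation between two node-score maps, restricted to
    their top-k nodes.

    ``mode='intersection'`` (default) keeps nodes in the top-k of *both*
    measures so both rank vectors are defined over the same set;
    ``mode='union'`` keeps nodes in either top-k (nodes absent from one
    map score 0 there).  Average ranks handle ties.  Fewer than 3 common
    nodes yields an undefined report with a diagnostic note.
    """
    top_a, top_b = set(_top_k(scores_a, k)), set(_top_k(scores_b, k))
    if mode == "intersection":
        common = sorted(top_a & top_b, key=str)
    elif mode == "union":
        common = sorted(top_a | top_b, key=str)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(common) < 3:
        return RankCorrelationReport(
            rho=None,
            pvalue=None,
            n_common=len(common),
            included=False,
            note=f"only {len(common)} node(s) shared by the top-{k} sets",
        )
    x = [float(scores_a.get(v, 0.0)) for v in common]
    y = [float(scores_b.get(v, 0.0)) for v in common]
    res = stats.spearmanr(x, y)
    rho, pvalue = float(res.statistic), float(res.pvalue)
    if np.isnan(rho):
        return RankCorrelationReport(
            rho=None, pvalue=None, n_common=len(common), included=False,
            note="zero rank variance on the common set",
        )
    return RankCorrelationReport(
        rho=rho, pvalue=pvalue, n_common=len(common), included=bool(pvalue < 0.05)
    )
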