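"""Dynamic brush assay scoring and generic group comparisons.

Paw-brushing responses are scored 0-3 per trial (0 = no movement or brief
withdrawal < 1 s; 1 = sustained lifting >= 2 s; 2 = lateral
kicking/flinching; 3 = licking), collected in three 3-minute periods.
The allodynia score is the mean over periods of each period's maximum
score; a mouse is classified allodynic when the score exceeds 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .synthetic import stream

ALLODYNIA_CUTOFF = 1.5
VALID_SCORES = (0, 1, 2, 3)
N_PERIODS = 3


@dataclass
class BehaviorScoreSheet:
    mouse_id: str
    period_scores: list          # list of per-period score lists
    period_maxima: list = field(default_factory=list)
    allodynia_score: float = np.nan
    allodynic: bool = False


def score_dynamic_brush(period_scores: Sequence[Sequence[int]],
                        mouse_id: str = "") -> BehaviorScoreSheet:
    """Aggregate per-period brush scores into an allodynia score."""
    if len(period_scores) != N_PERIODS:
        raise ValueError(
            f"expected {N_PERIODS} scoring periods, got {len(period_scores)}")
    maxima = []
    for k, scores in enumerate(period_scores):
        if len(scores) == 0:
            raise ValueError(f"period {k} has no scores")
        for s in scores:
            if s not in VALID_SCORES:
                raise ValueError(
                    f"period {k}: score {s!r} outside {VALID_SCORES}")
        maxima.append(max(scores))
    score = float(np.mean(maxima))
    return BehaviorScoreSheet(mouse_id, [list(p) for p in period_scores],
                              maxima, score, score > ALLODYNIA_CUTOFF)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   method: str = "rank_sum", n_boot: int = 10_000,
                   seed: int = None, alternative: str = "two-sided") -> dict:
    """Two-group comparison: rank-sum test or bootstrap mean-difference CI.

    Returns ``{"statistic", "p"}`` for ``rank_sum`` or
    ``{"mean_diff", "ci_low", "ci_high"}`` for ``bootstrap_mean_diff``
    (difference is a - b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if method == "rank_sum":
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            warnings.warn("all values tied; p set to 1")
            return {"statistic": np.nan, "p": 1.0}
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        return {"statistic": float(res.statistic), "p": float(res.pvalue)}
    if method == "bootstrap_mean_diff":
        if seed is None:
            raise ValueError("an explicit seed is required for the bootstrap")
        rng = stream(seed, "compare_groups")
        diffs = np.empty(n_boot)
        for k in range(n_boot):
            diffs[k] = (rng.choice(a, a.size, replace=True).mean()
                        - rng.choice(b, b.size, replace=True).mean())
        lo, hi = np.quantile(diffs, [0.025, 0.975])
        return {"mean_diff": float(a.mean() - b.mean()),
                "ci_low": float(lo), "ci_high": float(hi)}
    raise ValueError(f"unknown method {method!r}")


def load_behavior_table(df) -> list:
    """Per-mouse score sheets from a long table (mouse_id, period, score)."""
    sheets = []
    for mouse, g in df.groupby("mouse_id"):
        periods = [g.loc[g["period"] == p, "score"].astype(int).tolist()
                   for p in sorted(g["period"].unique())]
        sheets.append(score_dynamic_brush(periods, mouse_id=str(mouse)))
    return sheets
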