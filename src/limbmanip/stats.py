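"""Nonparametric muscle-wise comparisons.

Per (metric, phase) cell, every unordered pair of muscles is compared
with a two-sided Wilcoxon rank-sum test on one value per participant
(the participant's trial mean).  Significance is declared against a
Bonferroni-corrected threshold alpha / n_pairs; with 4 muscles that is
0.05 / 6 = 0.00833.

Small samples (combined n <= 12) get an exact p by enumerating all
rank assignments over midranks, which remains valid under ties; larger
samples use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "EXACT_MAX_N",
    "RankSumResult",
    "ComparisonResult",
    "rank_sum_test",
    "bonferroni",
    "compare_muscles",
]

#: combined sample size at or below which the exact null distribution is
#: enumerated (C(12,6) = 924 assignments at worst).
EXACT_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample (midranks)
    pvalue: float
    exact: bool


@dataclass(frozen=True)
class ComparisonResult:
    metric: str | None
    phase: str | None
    muscle_a: str
    muscle_b: str
    statistic: float
    p_raw: float
    alpha: float
    bonferroni_threshold: float

    @property
    def significant(self) -> bool:
        return self.p_raw < self.bonferroni_threshold


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sstats.rankdata(pooled, method="average")


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W (sum of midranks of ``a``) and a
    two-sided p value: exact by full enumeration for combined n <=
    ``EXACT_MAX_N``, otherwise the tie-corrected normal approximation
    with continuity correction (via the equivalent Mann-Whitney U).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    na, n = len(a), len(a) + len(b)
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(np.sum(ranks[:na]))

    if n <= EXACT_MAX_N:
        mu = na * (n + 1) / 2.0
        dev = abs(w_obs - mu)
        total = 0
        hits = 0
        for idx in combinations(range(n), na):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
        return RankSumResult(w_obs, hits / total, exact=True)

    res = sstats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankSumResult(w_obs, float(res.pvalue), exact=False)


def bonferroni(pairs: int, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / pairs (6 pairs at alpha=0.05 -> 0.00833)."""
    if pairs < 1:
        raise ValueError("need at least one comparison")
    return alpha / pairs


def compare_muscles(
    samples: dict[str, np.ndarray],
    alpha: float = 0.05,
    metric: str | None = None,
    phase: str | None = None,
) -> list[ComparisonResult]:
    """All pairwise rank-sum comparisons between muscles.

    ``samples`` maps muscle name to one value per participant.  The
    Bonferroni family is the C(k, 2) pairs within this (metric, phase)
    cell.
    """
    muscles = list(samples)
    if len(muscles) < 2:
        raise ValueError("need at least two muscles to compare")
    pairs = list(combinations(muscles, 2))
    threshold = bonferroni(len(pairs), alpha)
    out = []
    for ma, mb in pairs:
        res = rank_sum_test(samples[ma], samples[mb])
        out.append(
            ComparisonResult(
                metric=metric,
                phase=phase,
                muscle_a=ma,
                muscle_b=mb,
                statistic=res.statistic,
                p_raw=res.pvalue,
                alpha=alpha,
                bonferroni_threshold=threshold,
            )
        )
    return out


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric,
            "phase": r.phase,
            "muscle_a": r.muscle_a,
            "muscle_b": r.muscle_b,
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "threshold": r.bonferroni_threshold,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def write_comparisons_tsv(results: list[ComparisonResult], path) -> None:
    comparisons_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
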