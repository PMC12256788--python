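"""Threshold calibration and group statistics for phenotype similarity scores.

The positive class is the mtDNA-disease group; both nuclear groups
(nuclear-mitochondrial and nuclear-other) are pooled as negatives.  The
prediction rule is ``score >= threshold ⇒ mtDNA``, so lowering the threshold
raises sensitivity — the screening use case is a highly sensitive pick-up of
possible mtDNA disease ahead of manual curation.

AUC is computed through the Mann–Whitney identity (ties counted 0.5) and its
95% CI by the DeLong method.  Youden's J = sensitivity + specificity − 1
selects the "optimal" cut-off; ties go to the smaller threshold (higher
sensitivity).  Tier boundaries default to the calibrated screening values:
low < 0.3 <= medium < 0.5 <= high.

Group differences use Kruskal–Wallis with tie correction followed by Dunn's
pairwise z tests on pooled ranks with Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

POSITIVE_GROUP = "mtDNA"
GROUPS = ("mtDNA", "nuclear_mito", "nuclear_other")

__all__ = [
    "POSITIVE_GROUP",
    "GROUPS",
    "LabeledScore",
    "RocResult",
    "YoudenPoint",
    "GroupComparison",
    "roc",
    "youden_optimal",
    "sens_spec_at",
    "classify_tier",
    "kruskal_dunn",
]


@dataclass(frozen=True)
class LabeledScore:
    """One subject's similarity score with its diagnostic group label."""

    subject_id: str
    score: float
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group {self.group!r} not in {GROUPS}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def _split(scores: Sequence[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.score for s in scores if s.group == POSITIVE_GROUP])
    neg = np.array([s.score for s in scores if s.group != POSITIVE_GROUP])
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    return pos, neg


@dataclass
class RocResult:
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float
    youden_j: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class YoudenPoint:
    threshold: float
    sens: float
    spec: float
    j: float


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    # AUC = U / (n1*n2) with ties at 0.5, via midranks of the pooled sample.
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values, normal-quantile CI."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc(scores: Sequence[LabeledScore]) -> RocResult:
    """Full ROC over midpoint candidate thresholds, AUC, DeLong 95% CI, Youden.

    Candidate thresholds are the midpoints between adjacent distinct scores
    bracketed by ∓∞ sentinels, so every achievable confusion table appears
    exactly once.
    """
    pos, neg = _split(scores)
    distinct = np.unique(np.concatenate([pos, neg]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.array([])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    auc = _mann_whitney_auc(pos, neg)
    ci = _delong_ci(pos, neg, auc)

    j = sens + spec - 1.0
    best = _first_max(j)
    return RocResult(
        thresholds=thresholds, sens=sens, spec=spec, auc=auc, auc_ci=ci,
        youden_threshold=float(thresholds[best]), youden_j=float(j[best]),
        n_pos=len(pos), n_neg=len(neg),
    )


_J_TIE_TOL = 1e-9  # distinct J values are >= 1/(n1*n2) apart; rounding is ~1e-16


def _first_max(j: np.ndarray) -> int:
    """Index of the smallest threshold whose J ties the maximum."""
    return int(np.argmax(j >= j.max() - _J_TIE_TOL))


def youden_optimal(r: RocResult) -> YoudenPoint:
    """Threshold maximizing J = sens + spec − 1; ties -> smallest threshold."""
    j = r.sens + r.spec - 1.0
    best = _first_max(j)
    n_tied = int(np.sum(j >= j.max() - _J_TIE_TOL))
    if n_tied > 1:
        logger.info("Youden J tied at %d thresholds; choosing the smallest "
                    "(maximal sensitivity)", n_tied)
    return YoudenPoint(threshold=float(r.thresholds[best]),
                       sens=float(r.sens[best]), spec=float(r.spec[best]),
                       j=float(j[best]))


def sens_spec_at(scores: Sequence[LabeledScore], threshold: float,
                 inclusive: bool = True) -> tuple[float, float]:
    """Sensitivity and specificity of ``score >= threshold ⇒ positive``.

    ``inclusive=False`` switches to a strict ``>`` comparison.
    """
    pos, neg = _split(scores)
    if inclusive:
        return float((pos >= threshold).mean()), float((neg < threshold).mean())
    return float((pos > threshold).mean()), float((neg <= threshold).mean())


def classify_tier(score: float, low_cut: float = 0.3,
                  high_cut: float = 0.5) -> str:
    """Map a similarity score to its triage tier: low < 0.3 <= medium < 0.5 <= high."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if not 0.0 < low_cut < high_cut < 1.0:
        raise ValueError("tier boundaries must satisfy 0 < low_cut < high_cut < 1")
    if score < low_cut:
        return "low"
    if score < high_cut:
        return "medium"
    return "high"


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adj: float


@dataclass
class GroupComparison:
    kw_h: float
    kw_p: float
    pairwise: list[PairwiseComparison]


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal–Wallis H (tie-corrected) plus Dunn's post hoc z tests.

    Dunn's z for groups i, j uses pooled midranks:

        z = (r̄_i − r̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) )

    with the tie term T = Σ(t³ − t) / (12(N − 1)).  Two-sided normal
    p-values, Bonferroni-adjusted over all pairs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    h, p = stats.kruskal(*[arrays[g] for g in labels])

    pooled = np.concatenate([arrays[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for g in labels:
        k = len(arrays[g])
        mean_ranks[g] = float(ranks[offset:offset + k].mean())
        sizes[g] = k
        offset += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(labels, 2))
    k_pairs = len(pairs)
    results = []
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    for g1, g2 in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        results.append(PairwiseComparison(
            pair=(g1, g2), z=float(z), p_raw=p_raw,
            p_adj=min(1.0, p_raw * k_pairs)))
    return GroupComparison(kw_h=float(h), kw_p=float(p), pairwise=results)
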