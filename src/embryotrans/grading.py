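"""Numerical grading of rat E4.5 blastocysts.

Classical Gardner-style grades combine an expansion stage (1-4) with letter
qualities for the inner cell mass (ICM) and trophectoderm (TE).  Letter
grades are awkward for group statistics, so this module converts them to a
single integer embryo score (ES)::

    ES = EXS + ICMS + TS

where EXS is the expansion stage (1-4), ICMS maps A=3, B=2, C=1 (ICM quality
is weighted highest because it best predicts live birth), and TS maps
A or B = 2, C = 1.  The score therefore spans 3 (a "1CC" embryo) to 9
(reached by "4AA" and, because TE qualities A and B score alike, "4AB").

The module also computes the litter-level non-viability rate (unchanged 1CC
embryos after culture / litter size), chance-corrected inter-rater agreement
(weighted Cohen's kappa) for score validation, and rank-based group
comparisons of scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EmbryoGrade",
    "KappaResult",
    "GroupComparison",
    "ALL_GRADES",
    "parse_grade",
    "embryo_score",
    "score_grade",
    "nonviable_rate",
    "weighted_kappa",
    "compare_score_groups",
]

_ICM_SCORE = {"A": 3, "B": 2, "C": 1}
_TE_SCORE = {"A": 2, "B": 2, "C": 1}
_VALID_EXPANSION = (1, 2, 3, 4)
_VALID_LETTERS = ("A", "B", "C")


@dataclass(frozen=True)
class EmbryoGrade:
    """A parsed blastocyst grade: expansion stage plus ICM and TE letters."""

    expansion: int
    icm: str
    te: str

    def __post_init__(self) -> None:
        if self.expansion not in _VALID_EXPANSION:
            raise ValueError(
                f"expansion stage must be 1-4, got {self.expansion!r}"
            )
        if self.icm not in _VALID_LETTERS:
            raise ValueError(f"ICM letter must be A, B or C, got {self.icm!r}")
        if self.te not in _VALID_LETTERS:
            raise ValueError(f"TE letter must be A, B or C, got {self.te!r}")

    def __str__(self) -> str:  # round-trips through parse_grade
        return f"{self.expansion}{self.icm}{self.te}"


#: All 36 valid grade strings (4 expansion stages x 3 ICM x 3 TE letters).
ALL_GRADES: tuple[str, ...] = tuple(
    f"{e}{i}{t}"
    for e, i, t in itertools.product(_VALID_EXPANSION, _VALID_LETTERS, _VALID_LETTERS)
)


def parse_grade(grade_string: str) -> EmbryoGrade:
    """Parse a grade string such as ``"4AA"`` or ``"3AB"``.

    The first character is the expansion stage, the first letter the ICM
    quality and the second letter the TE quality (Gardner convention).

    Raises
    ------
    ValueError
        If the string is not exactly one digit followed by two letters, or
        any component is outside its valid range.
    """
    if not isinstance(grade_string, str) or len(grade_string.strip()) != 3:
        raise ValueError(f"malformed grade string: {grade_string!r}")
    s = grade_string.strip().upper()
    if not s[0].isdigit():
        raise ValueError(f"malformed grade string: {grade_string!r}")
    return EmbryoGrade(expansion=int(s[0]), icm=s[1], te=s[2])


def embryo_score(grade: EmbryoGrade) -> int:
    """Numerical embryo score ES = EXS + ICMS + TS, an integer in [3, 9]."""
    return grade.expansion + _ICM_SCORE[grade.icm] + _TE_SCORE[grade.te]


def score_grade(grade_string: str) -> int:
    """Parse and score a grade string in one step."""
    return embryo_score(parse_grade(grade_string))


def nonviable_rate(litter: pd.DataFrame) -> float:
    """Fraction of a litter's embryos that are non-viable after culture.

    Non-viable means graded ``1CC`` post-culture with no change in morphology
    or cell count during culture.  The input frame needs columns
    ``grade_post`` and ``changed_in_culture`` (boolean); each row is one
    embryo of a single litter.

    Raises
    ------
    ValueError
        If the litter is empty.
    """
    if len(litter) == 0:
        raise ValueError("cannot compute non-viable rate of an empty litter")
    post = litter["grade_post"].map(lambda g: str(parse_grade(g)))
    changed = litter["changed_in_culture"].astype(bool)
    nonviable = (post == "1CC") & ~changed
    return float(nonviable.sum()) / float(len(litter))


@dataclass(frozen=True)
class KappaResult:
    """Weighted Cohen's kappa between two raters on an ordinal scale."""

    kappa: float
    n_items: int
    weighting: str


def _kappa_weights(levels: np.ndarray, weighting: str) -> np.ndarray:
    d = np.abs(levels[:, None] - levels[None, :]).astype(float)
    if weighting == "linear":
        return d
    if weighting == "quadratic":
        return d**2
    raise ValueError(f"unknown weighting {weighting!r}")


def weighted_kappa(
    scores_a,
    scores_b,
    weighting: str = "linear",
) -> KappaResult:
    """Chance-corrected agreement between two aligned rating columns.

    kappa = 1 - (observed weighted disagreement) / (chance weighted
    disagreement), with disagreement weights given by the absolute (linear)
    or squared (quadratic) distance between the numeric score levels.
    Chance disagreement uses the outer product of the two raters' marginal
    distributions.

    Raises
    ------
    ValueError
        If fewer than 2 items, lengths differ, or both raters are constant
        and identical (chance disagreement is zero, kappa undefined).
    """
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater columns must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 rated items")
    levels = np.unique(np.concatenate([a, b]))
    w = _kappa_weights(levels, weighting)
    ia = np.searchsorted(levels, a)
    ib = np.searchsorted(levels, b)
    observed = np.zeros((len(levels), len(levels)))
    np.add.at(observed, (ia, ib), 1.0)
    observed /= n
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    chance_disagreement = float((w * expected).sum())
    if chance_disagreement == 0.0:
        raise ValueError(
            "kappa undefined: both raters constant and identical "
            "(zero chance disagreement)"
        )
    obs_disagreement = float((w * observed).sum())
    kappa = 1.0 - obs_disagreement / chance_disagreement
    return KappaResult(kappa=kappa, n_items=n, weighting=weighting)


@dataclass(frozen=True)
class GroupComparison:
    """Rank-based comparison of score distributions across labeled groups."""

    test: str
    statistic: float
    p_value: float
    groups: dict = field(default_factory=dict)  # label -> (n, median, q1, q3)


def compare_score_groups(scores_by_group: dict) -> GroupComparison:
    """Nonparametric comparison of two or more groups of scores.

    Two groups are compared with the Mann-Whitney U rank-sum test, more than
    two with Kruskal-Wallis.  Per-group medians and quartiles are reported
    alongside the test.

    Raises
    ------
    ValueError
        If fewer than 2 groups or any group is empty.
    """
    labels = list(scores_by_group)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to compare")
    arrays = []
    summaries = {}
    for lab in labels:
        arr = np.asarray(scores_by_group[lab], dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {lab!r} is empty")
        arrays.append(arr)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        summaries[lab] = (int(arr.size), float(med), float(q1), float(q3))
    if len(arrays) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        test = "mann-whitney-u"
    else:
        res = stats.kruskal(*arrays)
        test = "kruskal-wallis"
    return GroupComparison(
        test=test,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        groups=summaries,
    )
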