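"""Group-level inference: paired t-tests with Cohen's d, one-way
repeated-measures ANOVA with partial eta squared and Greenhouse–Geisser
sphericity correction, Cousineau–Morey within-subject SEM, per-TR uncorrected
significance masks, and the mean ROI response timecourse.

Comparisons against chance in the within-relevance decoding scheme are
one-tailed (accuracy cannot drop below chance there); everything else is
two-tailed by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .dataset import PatternDataset

__all__ = [
    "StatsError",
    "TTestResult",
    "AnovaResult",
    "paired_t",
    "rm_anova_oneway",
    "within_subject_sem",
    "per_tr_uncorrected",
    "roi_mean_timecourse",
]

_TAILS = ("two-sided", "greater", "less")


class StatsError(ValueError):
    """Degenerate input to a statistical procedure."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    tail: str


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    p: float
    eta_p2: float
    gg_epsilon: float


def paired_t(
    x: Sequence[float],
    y: Union[Sequence[float], float] = 0.0,
    tail: str = "two-sided",
) -> TTestResult:
    """Paired (or one-sample vs. a constant) t-test with Cohen's d.

    ``d = mean(diff) / sd(diff)``; ``tail`` is the alternative for x - y.
    """
    if tail not in _TAILS:
        raise StatsError(f"unknown tail {tail!r}; expected one of {_TAILS}")
    x = np.asarray(x, dtype=float)
    if np.isscalar(y) or np.asarray(y).ndim == 0:
        diff = x - float(y)
    else:
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise StatsError("paired samples must have equal length")
        diff = x - y
    n = diff.size
    if n < 2:
        raise StatsError("need at least 2 paired observations")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise StatsError("zero-variance difference: t undefined")
    m = diff.mean()
    t = m / (sd / np.sqrt(n))
    df = n - 1
    if tail == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif tail == "greater":
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)
    return TTestResult(t=float(t), df=df, p=float(min(max(p, np.finfo(float).tiny), 1.0)), d=float(m / sd), tail=tail)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the condition covariance matrix."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    eig = np.linalg.eigvalsh(Sc)
    eig = np.clip(eig, 0.0, None)
    num = eig.sum() ** 2
    den = (k - 1) * (eig ** 2).sum()
    if den <= 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (k - 1)), 1.0))


def rm_anova_oneway(
    data: np.ndarray,
    sphericity: str = "auto",
    gg_threshold: float = 0.75,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions table.

    Partial eta squared is SS_condition / (SS_condition + SS_error).  With
    ``sphericity="auto"`` the Greenhouse–Geisser correction is applied when
    the estimated epsilon falls below ``gg_threshold`` (and there are more
    than two conditions); "always"/"never" force the choice.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise StatsError("data must be subjects x conditions")
    if np.isnan(data).any():
        raise StatsError("missing cells: the RM-ANOVA table must be complete")
    S, C = data.shape
    if S < 2 or C < 2:
        raise StatsError("need at least 2 subjects and 2 conditions")
    grand = data.mean()
    col = data.mean(axis=0)
    row = data.mean(axis=1)
    ss_cond = S * ((col - grand) ** 2).sum()
    ss_subj = C * ((row - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = C - 1, (C - 1) * (S - 1)
    if ss_cond <= 0:
        return AnovaResult(0.0, float(df1), float(df2), 1.0, 0.0, 1.0)
    if ss_err <= 0:
        raise StatsError("zero error sum of squares: F undefined")
    F = (ss_cond / df1) / (ss_err / df2)
    eta = ss_cond / (ss_cond + ss_err)
    eps = _gg_epsilon(data) if C > 2 else 1.0
    apply_gg = sphericity == "always" or (sphericity == "auto" and eps < gg_threshold)
    if sphericity not in ("auto", "always", "never"):
        raise StatsError(f"unknown sphericity policy {sphericity!r}")
    if apply_gg and C > 2:
        dfn, dfd, used_eps = df1 * eps, df2 * eps, eps
    else:
        dfn, dfd, used_eps = float(df1), float(df2), 1.0
    p = float(sps.f.sf(F, dfn, dfd))
    return AnovaResult(float(F), float(dfn), float(dfd), p, float(eta), used_eps)


def within_subject_sem(data: np.ndarray) -> np.ndarray:
    """Cousineau–Morey within-subject SEM per condition.

    Subject means are removed and the grand mean restored before computing the
    per-condition SEM, with the Morey bias factor sqrt(C / (C - 1)).  A single
    condition degrades to the classical SEM (with a warning).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise StatsError("data must be subjects x conditions")
    if np.isnan(data).any():
        raise StatsError("missing cells")
    S, C = data.shape
    if C == 1:
        warnings.warn("single condition: returning the classical SEM")
        return data.std(axis=0, ddof=1) / np.sqrt(S)
    norm = data - data.mean(axis=1, keepdims=True) + data.mean()
    sem = norm.std(axis=0, ddof=1) / np.sqrt(S)
    return sem * np.sqrt(C / (C - 1.0))


def per_tr_uncorrected(
    timecourses: np.ndarray,
    chance: float = 1.0 / 3.0,
    tail: str = "greater",
    alpha: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-TR t-test vs. chance; returns (mask p < alpha, p-values), uncorrected."""
    tcs = np.asarray(timecourses, dtype=float)
    if tcs.ndim != 2:
        raise StatsError("timecourses must be subjects x TRs")
    pvals = np.array(
        [paired_t(tcs[:, j], chance, tail=tail).p for j in range(tcs.shape[1])]
    )
    return pvals < alpha, pvals


def roi_mean_timecourse(
    datasets: Union[PatternDataset, Sequence[PatternDataset]],
) -> Dict[str, np.ndarray]:
    """Mean ROI response per TR: voxels and trials averaged per subject, then
    the group mean with the within-subject SEM across subjects."""
    if isinstance(datasets, PatternDataset):
        datasets = [datasets]
    per_subject = np.stack([ds.patterns.mean(axis=(0, 2)) for ds in datasets])
    if per_subject.shape[0] > 1:
        sem = within_subject_sem(per_subject)
    else:
        sem = np.zeros(per_subject.shape[1])
    return {
        "mean": per_subject.mean(axis=0),
        "sem": sem,
        "per_subject": per_subject,
    }
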