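"""Category decoding with within- and cross-relevance train/test schemes.

Three cross-validation schemes are provided:

``loro``
    Standard leave-one-run-out CV within one relevance condition (the
    two-condition experiment's scheme): train on all but one run, test on the
    held-out run, average the fold accuracies.

``balanced_loro``
    The three-condition experiment's modified CV.  With 9 runs and 4 trials
    per condition per run, each training set holds 32 trials whose category
    counts are a permutation of (10, 11, 11).  For each held-out run, one
    trial of each of the two surplus categories is excluded from training —
    rotating the excluded trials so every surplus trial sits out exactly once
    — giving 11 fits per fold, 99 per TR, each trained on 30 trials
    (10 per category) and scored with balanced accuracy.

``train_all_cross``
    Cross-relevance transfer: train on every trial of one condition, test on
    every trial of another, in both directions; the direction average is the
    headline statistic.  Below-chance transfer indicates systematically
    anti-correlated patterns across relevance.

Chance level is 1/3 for the three-category designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dataset import PatternDataset
from .logistic import OneVsRestLogistic

__all__ = [
    "DecodingError",
    "DecodingScheme",
    "DecodingTimecourse",
    "CrossRelevanceAccuracy",
    "within_scheme",
    "cross_scheme",
    "fit_ovr_logistic",
    "balanced_accuracy",
    "loro_within",
    "balanced_folds",
    "balanced_loro",
    "cross_relevance",
    "decode_timecourse",
    "interval_average",
]

_CV_KINDS = ("loro", "balanced_loro", "train_all_cross")


class DecodingError(ValueError):
    """Invalid decoding request or dataset for the requested scheme."""


@dataclass(frozen=True)
class DecodingScheme:
    """Train/test relevance conditions plus the CV variant."""

    train_condition: str
    test_condition: str
    cv: str = "loro"
    label: str = ""

    def __post_init__(self):
        if self.cv not in _CV_KINDS:
            raise DecodingError(f"unknown cv {self.cv!r}; expected one of {_CV_KINDS}")
        within = self.train_condition == self.test_condition
        if self.cv == "train_all_cross" and within:
            raise DecodingError(
                "cross-relevance scheme requires distinct train/test conditions"
            )
        if self.cv != "train_all_cross" and not within:
            raise DecodingError(
                "within-relevance scheme requires train_condition == test_condition"
            )
        if not self.label:
            lab = (
                f"within-{self.train_condition}"
                if within
                else f"cross-{self.train_condition}-{self.test_condition}"
            )
            object.__setattr__(self, "label", lab)

    @property
    def is_within(self) -> bool:
        return self.train_condition == self.test_condition


def within_scheme(condition: str, cv: str = "loro") -> DecodingScheme:
    return DecodingScheme(condition, condition, cv)


def cross_scheme(cond_a: str, cond_b: str) -> DecodingScheme:
    return DecodingScheme(cond_a, cond_b, "train_all_cross")


@dataclass
class DecodingTimecourse:
    """Per-TR accuracy for one scheme and one subject."""

    accuracy: np.ndarray
    scheme: DecodingScheme
    subject_id: str
    n_fits: np.ndarray
    trs: np.ndarray
    chance_level: float = 1.0 / 3.0

    def __post_init__(self):
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise DecodingError("accuracies must lie in [0, 1]")


@dataclass(frozen=True)
class CrossRelevanceAccuracy:
    """Both transfer directions and their average."""

    train_a_test_b: float
    train_b_test_a: float
    mean: float


def fit_ovr_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 5000,
    ridge: float = 1e-4,
) -> OneVsRestLogistic:
    """Fit the one-vs-rest IRLS logistic classifier (see :mod:`.logistic`)."""
    return OneVsRestLogistic(ridge=ridge, max_iter=max_iter).fit(X, y)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class correct-classification rates (classes in y_true)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    accs = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(accs))


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _condition_view(ds: PatternDataset, condition: str):
    idx = ds.index(condition)
    if idx.size == 0:
        raise DecodingError(f"condition {condition!r} not present in dataset")
    return idx, ds.labels(idx), ds.runs_of(idx)


def loro_within(
    ds: PatternDataset,
    condition: str,
    tr: int,
    *,
    metric: str = "accuracy",
    standardize: bool = False,
    ridge: float = 1e-4,
    max_iter: int = 5000,
    return_folds: bool = False,
):
    """Leave-one-run-out accuracy within one relevance condition at one TR."""
    idx, y, runs = _condition_view(ds, condition)
    uruns = np.unique(runs)
    if uruns.size < 2:
        raise DecodingError(f"condition {condition!r} has fewer than 2 runs")
    X = ds.at_tr(tr, idx)
    fold_accs = []
    for run in uruns:
        tr_mask = runs != run
        ytr = y[tr_mask]
        if np.unique(ytr).size < 2:
            raise DecodingError(
                f"training fold leaving out run {run} contains a single category"
            )
        Xtr, Xte = X[tr_mask], X[~tr_mask]
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        model = fit_ovr_logistic(Xtr, ytr, max_iter=max_iter, ridge=ridge)
        pred = model.predict(Xte)
        if metric == "balanced":
            fold_accs.append(balanced_accuracy(y[~tr_mask], pred))
        else:
            fold_accs.append(float(np.mean(pred == y[~tr_mask])))
    mean = float(np.mean(fold_accs))
    return (mean, fold_accs) if return_folds else mean


def balanced_folds(
    ds: PatternDataset, condition: str
) -> Iterator[Tuple[int, int, np.ndarray, np.ndarray]]:
    """Yield (left_out_run, repetition, train_idx, test_idx) for the balanced CV.

    Training indices are 30 trials (10 per category) obtained from the
    (10, 11, 11) fold by excluding one trial of each surplus category;
    repetitions rotate the excluded trials so every surplus trial is excluded
    exactly once.
    """
    idx, y, runs = _condition_view(ds, condition)
    uruns = np.unique(runs)
    cats = np.unique(y)
    for run in uruns:
        train = idx[runs != run]
        test = idx[runs == run]
        ytr = ds.labels(train)
        counts = {c: int(np.sum(ytr == c)) for c in cats}
        if sorted(counts.values()) != [10, 11, 11]:
            raise DecodingError(
                f"fold leaving out run {run}: per-category training counts "
                f"{counts} are not a permutation of (10, 11, 11)"
            )
        surplus = [c for c in cats if counts[c] == 11]
        occ = {c: train[ytr == c] for c in surplus}
        for rep in range(11):
            excl = {int(occ[c][rep]) for c in surplus}
            keep = np.array([i for i in train if i not in excl], dtype=int)
            yield int(run), rep, keep, test


def balanced_loro(
    ds: PatternDataset,
    condition: str,
    tr: int,
    *,
    standardize: bool = False,
    ridge: float = 1e-4,
    max_iter: int = 5000,
    return_n_fits: bool = False,
):
    """Balanced-CV balanced accuracy within one condition at one TR."""
    X_all = ds.at_tr(tr)
    y_all = ds.labels()
    scores = []
    for _run, _rep, train, test in balanced_folds(ds, condition):
        Xtr, Xte = X_all[train], X_all[test]
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        model = fit_ovr_logistic(Xtr, y_all[train], max_iter=max_iter, ridge=ridge)
        scores.append(balanced_accuracy(y_all[test], model.predict(Xte)))
    mean = float(np.mean(scores))
    return (mean, len(scores)) if return_n_fits else mean


def cross_relevance(
    ds: PatternDataset,
    cond_train: str,
    cond_test: str,
    tr: int,
    *,
    run_split: bool = False,
    standardize: bool = False,
    ridge: float = 1e-4,
    max_iter: int = 5000,
) -> CrossRelevanceAccuracy:
    """Cross-relevance transfer accuracy at one TR, both directions + average.

    By default the classifier is trained on all trials of the training
    condition and tested on all trials of the test condition (train and test
    trials are disjoint by condition).  ``run_split=True`` switches to a
    leave-one-run-out variant for sensitivity analysis: train on the training
    condition's trials outside the held-out run, test on the test condition's
    trials inside it.
    """
    if cond_train == cond_test:
        raise DecodingError(
            "cross-relevance requires two distinct conditions; "
            "use a within-relevance scheme instead"
        )

    def one_direction(a: str, b: str) -> float:
        idx_a, y_a, runs_a = _condition_view(ds, a)
        idx_b, y_b, runs_b = _condition_view(ds, b)
        Xa, Xb = ds.at_tr(tr, idx_a), ds.at_tr(tr, idx_b)
        if not run_split:
            Xtr, Xte = (Xa, Xb)
            if standardize:
                Xtr, Xte = _standardize(Xtr, Xte)
            model = fit_ovr_logistic(Xtr, y_a, max_iter=max_iter, ridge=ridge)
            return float(np.mean(model.predict(Xte) == y_b))
        accs = []
        for run in np.unique(runs_b):
            tr_mask = runs_a != run
            te_mask = runs_b == run
            Xtr, Xte = Xa[tr_mask], Xb[te_mask]
            if standardize:
                Xtr, Xte = _standardize(Xtr, Xte)
            model = fit_ovr_logistic(Xtr, y_a[tr_mask], max_iter=max_iter, ridge=ridge)
            accs.append(float(np.mean(model.predict(Xte) == y_b[te_mask])))
        return float(np.mean(accs))

    ab = one_direction(cond_train, cond_test)
    ba = one_direction(cond_test, cond_train)
    return CrossRelevanceAccuracy(ab, ba, (ab + ba) / 2.0)


def decode_timecourse(
    ds: PatternDataset,
    scheme: DecodingScheme,
    trs: Optional[Sequence[int]] = None,
    **kwargs,
) -> DecodingTimecourse:
    """Apply a decoding scheme at every TR (or the listed 1-based TRs)."""
    trs = np.arange(1, ds.n_trs + 1) if trs is None else np.asarray(trs, dtype=int)
    acc = np.empty(trs.size)
    n_fits = np.empty(trs.size, dtype=int)
    n_runs = np.unique(ds.runs_of(ds.index(scheme.train_condition))).size
    for i, tr in enumerate(trs):
        try:
            if scheme.cv == "loro":
                acc[i] = loro_within(ds, scheme.train_condition, int(tr), **kwargs)
                n_fits[i] = n_runs
            elif scheme.cv == "balanced_loro":
                acc[i], n_fits[i] = balanced_loro(
                    ds, scheme.train_condition, int(tr), return_n_fits=True, **kwargs
                )
            else:
                res = cross_relevance(
                    ds, scheme.train_condition, scheme.test_condition, int(tr), **kwargs
                )
                acc[i] = res.mean
                n_fits[i] = 2
        except DecodingError as err:
            raise DecodingError(f"TR {tr}: {err}") from err
    return DecodingTimecourse(
        accuracy=acc,
        scheme=scheme,
        subject_id=ds.subject_id,
        n_fits=n_fits,
        trs=trs,
        chance_level=ds.chance_level,
    )


def interval_average(
    tc, intervals: Mapping[str, Sequence[int]]
) -> Dict[str, float]:
    """Mean accuracy over each named interval of 1-based TR indices."""
    if isinstance(tc, DecodingTimecourse):
        values = tc.accuracy
        trs = tc.trs
    else:
        values = np.asarray(tc, dtype=float)
        trs = np.arange(1, values.size + 1)
    pos = {int(t): i for i, t in enumerate(trs)}
    out = {}
    for name, members in intervals.items():
        members = list(members)
        if not members:
            raise DecodingError(f"interval {name!r} is empty")
        try:
            idx = [pos[int(t)] for t in members]
        except KeyError as err:
            raise DecodingError(
                f"interval {name!r} references TR {err.args[0]} outside the timecourse"
            ) from None
        out[name] = float(np.mean(values[idx]))
    return out
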