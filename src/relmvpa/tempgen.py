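"""Cross-temporal generalization and 2-D cluster-based permutation testing.

A generalization matrix holds the accuracy of a classifier trained at one TR
and tested at every TR, using the scheme's own cross-validation so train and
test trials never overlap — the diagonal therefore reproduces the per-TR
decoding timecourse exactly.  Group-level inference against chance uses a
two-dimensional cluster-based sign-flip permutation test: per-cell one-sample
t statistics are thresholded, 4-connected supra-threshold cells form clusters
scored by their summed t (cluster mass), and the null distribution of the
maximum cluster mass is built by randomly sign-flipping each subject's
(matrix - chance) deviation.  For small samples the Monte-Carlo sampling is
replaced by exhaustive enumeration of all 2^n sign assignments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .dataset import PatternDataset
from .decoding import (
    DecodingError,
    DecodingScheme,
    _condition_view,
    _standardize,
    balanced_folds,
    fit_ovr_logistic,
    balanced_accuracy,
)

__all__ = [
    "GeneralizationMatrix",
    "Cluster",
    "ClusterResult",
    "cross_temporal_matrix",
    "cluster_permutation_2d",
]


@dataclass
class GeneralizationMatrix:
    """Train-TR x test-TR accuracy matrix for one scheme and subject."""

    accuracy: np.ndarray
    scheme: DecodingScheme
    subject_id: str
    trs: np.ndarray

    def __post_init__(self):
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.accuracy.ndim != 2 or self.accuracy.shape[0] != self.accuracy.shape[1]:
            raise DecodingError("generalization matrix must be square")


def cross_temporal_matrix(
    ds: PatternDataset,
    scheme: DecodingScheme,
    trs: Optional[Sequence[int]] = None,
    *,
    standardize: bool = False,
    ridge: float = 1e-4,
    max_iter: int = 5000,
) -> GeneralizationMatrix:
    """Accuracy of models trained at each TR and tested at all TRs."""
    trs = np.arange(1, ds.n_trs + 1) if trs is None else np.asarray(trs, dtype=int)
    T = trs.size
    acc = np.zeros((T, T))

    def eval_fold(train_idx, test_idx, y_train, y_test, balanced: bool):
        """Fit at every train TR once, test at every test TR."""
        out = np.empty((T, T))
        for i, tri in enumerate(trs):
            Xtr = ds.at_tr(int(tri), train_idx)
            mu = sd = None
            if standardize:
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                Xtr = (Xtr - mu) / sd
            model = fit_ovr_logistic(Xtr, y_train, max_iter=max_iter, ridge=ridge)
            for j, trj in enumerate(trs):
                Xte = ds.at_tr(int(trj), test_idx)
                if standardize:
                    Xte = (Xte - mu) / sd
                pred = model.predict(Xte)
                out[i, j] = (
                    balanced_accuracy(y_test, pred)
                    if balanced
                    else float(np.mean(pred == y_test))
                )
        return out

    if scheme.cv == "loro":
        idx, y, runs = _condition_view(ds, scheme.train_condition)
        uruns = np.unique(runs)
        if uruns.size < 2:
            raise DecodingError("need at least 2 runs for leave-one-run-out")
        folds = []
        for run in uruns:
            m = runs != run
            if np.unique(y[m]).size < 2:
                raise DecodingError(
                    f"training fold leaving out run {run} contains a single category"
                )
            folds.append(eval_fold(idx[m], idx[~m], y[m], y[~m], balanced=False))
        acc = np.mean(folds, axis=0)
    elif scheme.cv == "balanced_loro":
        y_all = ds.labels()
        folds = [
            eval_fold(train, test, y_all[train], y_all[test], balanced=True)
            for _r, _k, train, test in balanced_folds(ds, scheme.train_condition)
        ]
        acc = np.mean(folds, axis=0)
    else:  # train_all_cross
        a, b = scheme.train_condition, scheme.test_condition
        idx_a, y_a, _ = _condition_view(ds, a)
        idx_b, y_b, _ = _condition_view(ds, b)
        ab = eval_fold(idx_a, idx_b, y_a, y_b, balanced=False)
        ba = eval_fold(idx_b, idx_a, y_b, y_a, balanced=False)
        acc = (ab + ba) / 2.0
    return GeneralizationMatrix(acc, scheme, ds.subject_id, trs)


@dataclass
class Cluster:
    """One supra-threshold cluster with its permutation p-value."""

    cells: List[Tuple[int, int]]
    mass: float
    p: float
    tail: str


@dataclass
class ClusterResult:
    clusters: List[Cluster]
    alpha: float
    cluster_alpha: float
    n_permutations: int
    tail: str
    tmap: np.ndarray
    df: int
    excluded_cells: List[Tuple[int, int]] = field(default_factory=list)
    exhaustive: bool = False

    def significant_clusters(self) -> List[Cluster]:
        """Clusters surviving family-wise correction (alpha split across tails
        for two-sided testing)."""
        level = self.alpha / 2.0 if self.tail == "two-sided" else self.alpha
        return [c for c in self.clusters if c.p <= level]

    def significance_mask(self) -> np.ndarray:
        mask = np.zeros(self.tmap.shape, dtype=bool)
        for c in self.significant_clusters():
            for cell in c.cells:
                mask[cell] = True
        return mask


def _as_stack(matrices) -> np.ndarray:
    mats = [
        m.accuracy if isinstance(m, GeneralizationMatrix) else np.asarray(m, float)
        for m in matrices
    ]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("matrices are not congruent")
    return np.stack(mats)


def _tmaps_for_flips(flips, diffs, sumsq, n):
    """Vectorised per-cell t statistics for a batch of sign-flip assignments."""
    means = flips @ diffs / n
    var = (sumsq - n * means ** 2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def _max_cluster_mass(tmap, thresh, structure, exclude_mask):
    supra = (tmap > thresh) & ~exclude_mask
    if not supra.any():
        return 0.0
    lab, nlab = ndimage.label(supra, structure=structure)
    masses = ndimage.sum_labels(tmap, lab, index=np.arange(1, nlab + 1))
    return float(np.max(masses))


def cluster_permutation_2d(
    matrices,
    chance: float = 1.0 / 3.0,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    n_perm: int = 10000,
    tail: str = "two-sided",
    seed: Optional[int] = None,
    connectivity: int = 4,
    exhaustive: Optional[bool] = None,
) -> ClusterResult:
    """2-D cluster-based sign-flip permutation test of accuracy vs. chance.

    Parameters
    ----------
    matrices
        Per-subject GeneralizationMatrix objects or arrays, all congruent.
    chance
        The chance accuracy subtracted before sign flipping (1/3 here).
    cluster_alpha
        Cluster-forming threshold: cells with one-tailed p below this enter
        clusters (applied per tail).
    alpha
        Family-wise significance level used by ``significant_clusters``
        (split across tails for two-sided testing).
    n_perm
        Monte-Carlo permutations; if ``2**n_subjects <= n_perm`` (or
        ``exhaustive=True``) all sign assignments are enumerated instead.
    tail
        "positive", "negative" or "two-sided".
    connectivity
        4 (edge-adjacent, default) or 8 (plus diagonals).

    Zero-variance cells cannot carry a t statistic; they are excluded from
    cluster formation with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("positive", "negative", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    data = _as_stack(matrices)
    S = data.shape[0]
    if S < 2:
        raise ValueError("need at least 2 subjects")
    shape = data.shape[1:]
    diffs = (data - chance).reshape(S, -1)
    df = S - 1

    sd = diffs.std(axis=0, ddof=1)
    exclude = sd <= 1e-12 * max(1.0, float(np.abs(diffs).max()))
    if exclude.any():
        warnings.warn(
            f"{int(exclude.sum())} zero-variance cells excluded from cluster formation"
        )
    exclude_mask = exclude.reshape(shape)
    excluded_cells = [tuple(c) for c in np.argwhere(exclude_mask)]

    mean = diffs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = mean / (sd / np.sqrt(S))
    t_obs[~np.isfinite(t_obs)] = 0.0
    tmap = t_obs.reshape(shape)

    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")

    use_exhaustive = exhaustive if exhaustive is not None else (2 ** S <= n_perm)
    if use_exhaustive:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=S)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([1.0, -1.0], size=(n_perm, S))
    sumsq = (diffs ** 2).sum(axis=0)
    t_null = _tmaps_for_flips(flips, diffs, sumsq, S)

    thresh = sps.t.ppf(1.0 - cluster_alpha, df)
    tails = ("positive", "negative") if tail == "two-sided" else (tail,)
    clusters: List[Cluster] = []
    for tl in tails:
        sign = 1.0 if tl == "positive" else -1.0
        signed = sign * tmap
        supra = (signed > thresh) & ~exclude_mask
        null_max = np.array(
            [
                _max_cluster_mass(
                    sign * t_null[k].reshape(shape), thresh, structure, exclude_mask
                )
                for k in range(t_null.shape[0])
            ]
        )
        if supra.any():
            lab, nlab = ndimage.label(supra, structure=structure)
            for li in range(1, nlab + 1):
                cells = [tuple(c) for c in np.argwhere(lab == li)]
                mass = float(signed[lab == li].sum())
                # tolerance keeps the identity permutation counted despite
                # float noise between the vectorised and direct t paths
                tol = 1e-8 * max(1.0, abs(mass))
                ge = int(np.sum(null_max >= mass - tol))
                if use_exhaustive:
                    p = ge / null_max.size
                else:
                    p = (ge + 1) / (null_max.size + 1)
                clusters.append(Cluster(cells, sign * mass, p, tl))
    return ClusterResult(
        clusters=clusters,
        alpha=alpha,
        cluster_alpha=cluster_alpha,
        n_permutations=int(flips.shape[0]),
        tail=tail,
        tmap=tmap,
        df=df,
        excluded_cells=excluded_cells,
        exhaustive=use_exhaustive,
    )
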