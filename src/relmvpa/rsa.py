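"""Representational dissimilarity analysis over exemplar x relevance patterns.

An RDM cell is 1 - Spearman rho between the voxel patterns of two
(condition, category, exemplar) combinations.  RDMs are built per run —
averaging each combination's trials within the run — then averaged cellwise
over the runs in which both members occur, then over the TRs of an interval.
For the two-condition experiment the matrix is 24 x 24 (3 categories x 4
exemplars x 2 relevance levels).

The headline statistic contrasts the mean between-relevance dissimilarity of
same-category pairs against different-category pairs; on the Fisher scale the
underlying rho of each contributing cell is atanh-transformed (dissimilarity
-atanh(rho)) before any averaging, which keeps the transform inside its
domain.  A rank transform to [0, 1] and classical (Torgerson) MDS support the
standard visualisations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import rankdata

from .dataset import PatternDataset

__all__ = [
    "RSAError",
    "RDM",
    "DissimilarityContrast",
    "exemplar_patterns",
    "compute_rdm",
    "rank_transform",
    "classical_mds",
    "same_vs_diff_contrast",
]

Label = Tuple[str, int, int]  # (condition, category, exemplar)

_RHO_CLIP = 1.0 - 1e-12


class RSAError(ValueError):
    """Invalid RSA request or unusable coverage."""


@dataclass
class RDM:
    """Labelled square dissimilarity matrix (d = 1 - Spearman rho).

    ``d_fisher`` carries the same aggregation applied to -atanh(rho); it is
    ``None`` for matrices that no longer track the underlying correlations
    (e.g. after a rank transform).
    """

    labels: List[Label]
    d: np.ndarray
    scope: str
    n_runs_averaged: int
    d_fisher: Optional[np.ndarray] = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise RSAError("dissimilarity matrix does not match the labels")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise RSAError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise RSAError("dissimilarity matrix must have a zero diagonal")

    @property
    def side(self) -> int:
        return len(self.labels)


@dataclass
class DissimilarityContrast:
    """Same- vs different-category mean dissimilarity across two relevance levels."""

    same_category_mean: float
    diff_category_mean: float
    difference: float
    scale: str
    relevance_pair: Tuple[str, str]


def _label_order(ds: PatternDataset, conditions: Sequence[str]) -> List[Label]:
    cats = [int(c) for c in ds.categories]
    exs = sorted({t.exemplar for t in ds.design})
    return [(cond, cat, ex) for cond in conditions for cat in cats for ex in exs]


def exemplar_patterns(
    ds: PatternDataset,
    tr: int,
    conditions: Optional[Sequence[str]] = None,
):
    """Per-run mean pattern for each (condition, category, exemplar) combination.

    Returns ``(labels, per_run)`` where ``per_run[run]`` is an array
    ``(len(labels), n_voxels)`` with NaN rows for combinations absent from
    that run (missingness is data, not an error).
    """
    conditions = list(conditions) if conditions is not None else ds.conditions
    labels = _label_order(ds, conditions)
    pos = {lab: i for i, lab in enumerate(labels)}
    X = ds.at_tr(tr)
    per_run: Dict[int, np.ndarray] = {}
    counts: Dict[int, np.ndarray] = {}
    for i, t in enumerate(ds.design):
        key = (t.condition, t.category, t.exemplar)
        if key not in pos:
            continue
        if t.run not in per_run:
            per_run[t.run] = np.zeros((len(labels), ds.n_voxels))
            counts[t.run] = np.zeros(len(labels))
        per_run[t.run][pos[key]] += X[i]
        counts[t.run][pos[key]] += 1
    for run in per_run:
        c = counts[run]
        with np.errstate(invalid="ignore"):
            per_run[run] = per_run[run] / c[:, None]
        per_run[run][c == 0] = np.nan
    return labels, per_run


def _run_rdm(patterns: np.ndarray):
    """(d, fisher) matrices for one run's (label, voxel) patterns; NaN where
    either member is missing."""
    present = ~np.isnan(patterns[:, 0])
    n = patterns.shape[0]
    d = np.full((n, n), np.nan)
    f = np.full((n, n), np.nan)
    if present.sum() < 2:
        return d, f
    ranked = np.apply_along_axis(rankdata, 1, patterns[present])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = np.corrcoef(ranked)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -_RHO_CLIP, _RHO_CLIP)
    np.fill_diagonal(rho, 1.0)
    ix = np.where(present)[0]
    sub_d = 1.0 - rho
    sub_f = -np.arctanh(np.clip(rho, -1.0 + 1e-7, 1.0 - 1e-7))
    np.fill_diagonal(sub_d, 0.0)
    np.fill_diagonal(sub_f, 0.0)
    d[np.ix_(ix, ix)] = sub_d
    f[np.ix_(ix, ix)] = sub_f
    return d, f


def compute_rdm(
    ds: PatternDataset,
    trs: Union[int, Sequence[int]],
    conditions: Optional[Sequence[str]] = None,
    per_run: bool = True,
    scope: Optional[str] = None,
) -> RDM:
    """RDM at one TR or averaged over an interval's TRs (1-based indices).

    With ``per_run=True`` (default) a dissimilarity is computed within each
    run for every pair of combinations present in that run, averaged over the
    contributing runs, then over TRs; a pair that never shares a run raises an
    error.  ``per_run=False`` averages each combination's patterns over all
    runs first and computes a single correlation matrix per TR (useful for
    designs whose runs hold too few combinations for per-run coverage).
    """
    tr_list = [int(trs)] if np.isscalar(trs) else [int(t) for t in trs]
    conditions = list(conditions) if conditions is not None else ds.conditions
    labels = _label_order(ds, conditions)
    n = len(labels)
    acc_d = np.zeros((n, n))
    acc_f = np.zeros((n, n))
    n_runs = 0
    for k, tr in enumerate(tr_list):
        lab, per_run_pats = exemplar_patterns(ds, tr, conditions)
        n_runs = len(per_run_pats)
        if per_run:
            sum_d = np.zeros((n, n))
            sum_f = np.zeros((n, n))
            cnt = np.zeros((n, n))
            for run in sorted(per_run_pats):
                d, f = _run_rdm(per_run_pats[run])
                ok = ~np.isnan(d)
                sum_d[ok] += d[ok]
                sum_f[ok] += f[ok]
                cnt += ok
            uncovered = (cnt == 0) & ~np.eye(n, dtype=bool)
            if uncovered.any():
                i, j = np.argwhere(uncovered)[0]
                raise RSAError(
                    f"no run contains both {labels[i]} and {labels[j]}: cell has "
                    "zero contributing runs (consider per_run=False)"
                )
            cnt[cnt == 0] = 1.0
            tr_d, tr_f = sum_d / cnt, sum_f / cnt
        else:
            stacks = list(per_run_pats.values())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled = np.nanmean(np.stack(stacks), axis=0)
            if np.isnan(pooled[:, 0]).any():
                i = int(np.where(np.isnan(pooled[:, 0]))[0][0])
                raise RSAError(f"combination {labels[i]} absent from every run")
            tr_d, tr_f = _run_rdm(pooled)
        acc_d += tr_d
        acc_f += tr_f
    acc_d /= len(tr_list)
    acc_f /= len(tr_list)
    # enforce exact symmetry/zero diagonal against float accumulation error
    acc_d = (acc_d + acc_d.T) / 2.0
    acc_f = (acc_f + acc_f.T) / 2.0
    np.fill_diagonal(acc_d, 0.0)
    np.fill_diagonal(acc_f, 0.0)
    scope = scope or (f"TR {tr_list[0]}" if len(tr_list) == 1 else f"TRs {tr_list}")
    return RDM(labels, acc_d, scope, n_runs, acc_f)


def rank_transform(rdm: RDM) -> RDM:
    """Replace each cell by its rank among the upper-triangle cells, scaled to
    [0, 1] (average ranks for ties; all-equal input maps to 0.5 everywhere)."""
    n = rdm.side
    iu = np.triu_indices(n, k=1)
    vals = rdm.d[iu]
    if vals.size == 0:
        return RDM(rdm.labels, rdm.d.copy(), rdm.scope + " (rank)", rdm.n_runs_averaged)
    ranks = rankdata(vals)
    scaled = (ranks - 1.0) / (vals.size - 1.0) if vals.size > 1 else np.full(1, 0.5)
    out = np.zeros_like(rdm.d)
    out[iu] = scaled
    out = out + out.T
    return RDM(rdm.labels, out, rdm.scope + " (rank)", rdm.n_runs_averaged)


def classical_mds(rdm: Union[RDM, np.ndarray], k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates, items x k.

    Double-centres the squared dissimilarities and embeds along the top
    eigenvectors; negative eigenvalues are truncated.  Coordinates are defined
    up to rotation/reflection.
    """
    D = rdm.d if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise RSAError("classical MDS needs a symmetric square matrix")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise RSAError("classical MDS needs a zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0.0) * 1e-12 + 1e-15
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} dimensions"
        )
        k = n_pos
    if k == 0:
        return np.zeros((n, max(1, k)))
    return eigvec[:, :k] * np.sqrt(eigval[:k])


def same_vs_diff_contrast(
    rdm: RDM,
    relevance_pair: Tuple[str, str],
    scale: str = "fisher",
) -> DissimilarityContrast:
    """Same- vs different-category mean dissimilarity across two relevance levels.

    Restricts to cells pairing one combination from each relevance level; the
    same-category mean pools the three same-category blocks, the
    different-category mean the off-category blocks.  ``scale="fisher"`` uses
    the -atanh(rho) aggregation, ``scale="raw"`` the plain 1 - rho cells.
    """
    if scale not in ("raw", "fisher"):
        raise RSAError(f"unknown scale {scale!r}")
    mat = rdm.d_fisher if scale == "fisher" else rdm.d
    if mat is None:
        raise RSAError("this RDM does not carry Fisher-scale values")
    conds = [lab[0] for lab in rdm.labels]
    cats = np.array([lab[1] for lab in rdm.labels])
    a, b = relevance_pair
    rows = np.array([c == a for c in conds])
    cols = np.array([c == b for c in conds])
    if not rows.any():
        raise RSAError(f"relevance level {a!r} absent from RDM labels")
    if not cols.any():
        raise RSAError(f"relevance level {b!r} absent from RDM labels")
    block = mat[np.ix_(rows, cols)]
    same = cats[rows][:, None] == cats[cols][None, :]
    same_mean = float(block[same].mean())
    diff_mean = float(block[~same].mean())
    return DissimilarityContrast(
        same_category_mean=same_mean,
        diff_category_mean=diff_mean,
        difference=same_mean - diff_mean,
        scale=scale,
        relevance_pair=(a, b),
    )
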