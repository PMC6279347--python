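"""Synthetic voxel-pattern generation with relevance-dependent gain and inversion.

The generative model for the pattern of one trial at one TR is

    pattern(trial, tr) = a(cond, tr) * s(cond, tr) * P(cat, ex)
                         + b(cond, tr) * P0(cat) + noise

where ``P(cat, ex)`` is an exemplar pattern (unit-norm category prototype
``P0`` plus exemplar jitter), ``a >= 0`` is a relevance- and phase-dependent
gain, ``s`` in [-1, 1] is the *inversion coefficient* — ``s = -1`` models a
category code that is sign-flipped (anti-correlated) relative to its
currently-relevant form — and ``b >= 0`` is a display-evoked component active
while a search display of the trial's own category is on screen.  Noise is
i.i.d. Gaussian across voxels, optionally AR(1) across TRs.

Two paths produce per-trial, per-TR voxel t-patterns:

* :func:`simulate_t_patterns` — draws the pattern model directly (fast path);
* :func:`simulate_bold_and_glm` — synthesises a BOLD time series (neural
  schedule convolved with a double-gamma HRF plus noise) and fits a per-trial
  OLS GLM with one boxcar regressor per TR, returning t = beta/SE, mirroring
  the single-trial GLM applied to real data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .dataset import PatternDataset
from .design import ExperimentProfile, TrialDesign, _resolve_profile

__all__ = [
    "SimulationError",
    "SimulationParams",
    "default_schedules",
    "default_params",
    "DEFAULT_INTERVALS",
    "make_category_patterns",
    "simulate_t_patterns",
    "simulate_bold_and_glm",
    "double_gamma_hrf",
]

TR_SECONDS = 2.0

#: Default three-TR analysis windows (1-based TR indices), covering the 8-s
#: delay / search epochs shifted by the hemodynamic lag.
DEFAULT_INTERVALS = {
    "exp2": {"Delay": (5, 6, 7), "Search 1": (9, 10, 11), "Search 2": (13, 14, 15)},
    "exp1": {"Delay": (4, 5, 6), "Search 1": (8, 9, 10), "Search 2": (12, 13, 14)},
}


class SimulationError(ValueError):
    """Invalid simulation parameters or schedules."""


Schedule = Dict[str, np.ndarray]


@dataclass
class SimulationParams:
    """Knobs of the generative pattern model.

    ``amplitude``, ``inversion`` and ``stimulus_drive`` map each condition to a
    per-TR array (gain a, sign s, display drive b).  They must cover every
    (condition, TR) of the design they are used with.
    """

    amplitude: Schedule
    inversion: Schedule
    stimulus_drive: Schedule
    n_voxels: int = 160
    exemplar_jitter_sd: float = 0.3
    noise_sd: float = 0.5
    ar1_coeff: float = 0.3
    hrf_peak: float = 6.0
    hrf_undershoot: float = 16.0
    hrf_ratio: float = 1.0 / 6.0
    category_patterns_seed: Optional[int] = None
    seed: int = 0

    def digest(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        payload = json.dumps(self.__dict__, sort_keys=True, default=enc)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _window(n_trs: int, lo: int, hi: int, value: float) -> np.ndarray:
    """Array of length n_trs with ``value`` on 0-based slots [lo, hi)."""
    a = np.zeros(n_trs)
    a[lo:hi] = value
    return a


def default_schedules(
    experiment: Union[str, ExperimentProfile] = "exp2",
    amplitude_scale: float = 1.0,
    inversion_search: float = -1.0,
):
    """Stock schedules reproducing the task's relevance dynamics.

    The current template is strongly active from cue through the first search
    (during which its category is on screen); the prospective template is
    active during the delay, carries the inversion coefficient
    ``inversion_search`` while the first search display is up, and returns to
    an upright, display-driven code for the second search; the irrelevant item
    is weakly active during the delay only and silent afterwards.  In the
    two-condition experiment the no-longer-relevant current template also
    inverts during the second search.

    Returns ``(amplitude, inversion, stimulus_drive)`` schedule dicts.
    """
    prof = _resolve_profile(experiment)
    T = prof.n_trs
    a: Schedule = {}
    s: Schedule = {}
    b: Schedule = {}
    if prof.name == "exp2":
        a["current"] = _window(T, 2, 12, 1.0)
        s["current"] = np.ones(T)
        b["current"] = _window(T, 8, 11, 1.0)
        a["prospective"] = _window(T, 2, 8, 0.8) + _window(T, 8, 12, 0.6) + _window(T, 12, T, 1.0)
        s["prospective"] = np.ones(T)
        s["prospective"][8:12] = inversion_search
        b["prospective"] = _window(T, 12, 15, 1.0)
        a["irrelevant"] = _window(T, 2, 8, 0.6)
        s["irrelevant"] = np.ones(T)
        b["irrelevant"] = np.zeros(T)
    elif prof.name == "exp1":
        a["current"] = _window(T, 1, 11, 1.0) + _window(T, 11, 14, 0.4)
        s["current"] = np.ones(T)
        s["current"][11:14] = inversion_search
        b["current"] = _window(T, 7, 10, 1.0)
        a["prospective"] = _window(T, 1, 7, 0.8) + _window(T, 7, 11, 0.6) + _window(T, 11, T, 1.0)
        s["prospective"] = np.ones(T)
        s["prospective"][7:11] = inversion_search
        b["prospective"] = _window(T, 11, 14, 1.0)
    else:  # pragma: no cover - profiles are closed
        raise SimulationError(f"no default schedules for profile {prof.name}")
    for cond in a:
        a[cond] = a[cond] * amplitude_scale
        b[cond] = b[cond] * amplitude_scale
    return a, s, b


def default_params(
    experiment: Union[str, ExperimentProfile] = "exp2",
    amplitude_scale: float = 1.0,
    inversion_search: float = -1.0,
    **overrides,
) -> SimulationParams:
    """SimulationParams with the stock schedules for an experiment profile."""
    a, s, b = default_schedules(experiment, amplitude_scale, inversion_search)
    return SimulationParams(amplitude=a, inversion=s, stimulus_drive=b, **overrides)


def make_category_patterns(
    n_voxels: int,
    n_categories: int = 3,
    n_exemplars: int = 4,
    exemplar_jitter_sd: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Category/exemplar pattern bank, shape (category, exemplar, voxel).

    Each category prototype is an independent unit-normalised Gaussian vector;
    exemplar patterns add voxelwise jitter scaled so the jitter vector's
    expected norm is ``exemplar_jitter_sd`` relative to the unit prototype.
    """
    if n_voxels < 1:
        raise SimulationError("n_voxels must be >= 1")
    if exemplar_jitter_sd < 0:
        raise SimulationError("exemplar_jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    protos = rng.standard_normal((n_categories, n_voxels))
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)
    jitter = rng.standard_normal((n_categories, n_exemplars, n_voxels))
    jitter *= exemplar_jitter_sd / np.sqrt(n_voxels)
    return protos[:, None, :] + jitter


def _check_schedules(params: SimulationParams, design: Sequence[TrialDesign]) -> int:
    n_trs = design[0].n_trs
    conds = sorted({t.condition for t in design})
    for name, sched in (
        ("amplitude", params.amplitude),
        ("inversion", params.inversion),
        ("stimulus_drive", params.stimulus_drive),
    ):
        for cond in conds:
            if cond not in sched:
                raise SimulationError(f"{name} schedule missing condition {cond!r}")
            arr = np.asarray(sched[cond], dtype=float)
            if arr.shape[0] < n_trs:
                raise SimulationError(
                    f"{name} schedule for condition {cond!r} covers only "
                    f"{arr.shape[0]} TRs; TR {arr.shape[0] + 1} of {n_trs} missing"
                )
    return n_trs


def _signal_matrix(
    trial: TrialDesign, params: SimulationParams, bank: np.ndarray, n_trs: int
) -> np.ndarray:
    """Noise-free (TR, voxel) neural pattern for one trial."""
    a = np.asarray(params.amplitude[trial.condition], dtype=float)[:n_trs]
    s = np.asarray(params.inversion[trial.condition], dtype=float)[:n_trs]
    b = np.asarray(params.stimulus_drive[trial.condition], dtype=float)[:n_trs]
    p_ex = bank[trial.category - 1, trial.exemplar - 1]
    proto = bank[trial.category - 1].mean(axis=0)
    proto = proto / max(np.linalg.norm(proto), 1e-12)
    return np.outer(a * s, p_ex) + np.outer(b, proto)


def _ar1_noise(rng, shape, noise_sd: float, ar1: float) -> np.ndarray:
    """(trial, TR, voxel) noise, AR(1) along the TR axis, unit marginal sd."""
    white = rng.standard_normal(shape) * noise_sd
    if ar1 <= 0:
        return white
    out = np.empty_like(white)
    out[:, 0] = white[:, 0]
    c = np.sqrt(1.0 - ar1 ** 2)
    for t in range(1, shape[1]):
        out[:, t] = ar1 * out[:, t - 1] + c * white[:, t]
    return out


def simulate_t_patterns(
    design: Sequence[TrialDesign],
    params: SimulationParams,
    subject_id: str = "sim",
) -> PatternDataset:
    """Draw per-trial, per-TR voxel patterns directly from the pattern model."""
    if not design:
        raise SimulationError("empty design")
    if not (0 <= params.ar1_coeff < 1):
        raise SimulationError("ar1_coeff must be in [0, 1)")
    n_trs = _check_schedules(params, design)
    bank_seed = (
        params.category_patterns_seed
        if params.category_patterns_seed is not None
        else params.seed
    )
    bank = make_category_patterns(
        params.n_voxels,
        exemplar_jitter_sd=params.exemplar_jitter_sd,
        seed=bank_seed,
    )
    rng = np.random.default_rng(params.seed)
    noise = _ar1_noise(
        rng, (len(design), n_trs, params.n_voxels), params.noise_sd, params.ar1_coeff
    )
    patterns = np.empty((len(design), n_trs, params.n_voxels))
    for i, trial in enumerate(design):
        patterns[i] = _signal_matrix(trial, params, bank, n_trs) + noise[i]
    return PatternDataset(
        patterns=patterns,
        design=list(design),
        subject_id=subject_id,
        provenance={"generator": "simulate_t_patterns", "params": params.digest()},
    )


def double_gamma_hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Gamma shapes equal the peak/undershoot delays (unit scale), so the
    response peaks ~``peak - 1`` s after onset with an undershoot around
    ``undershoot`` s, amplitude ratio ``ratio``.
    """
    t = np.asarray(t, dtype=float)
    h = sps.gamma.pdf(t, peak) - ratio * sps.gamma.pdf(t, undershoot)
    h[t < 0] = 0.0
    return h


def _trial_design_matrix(n_trs: int, tail_trs: int, params: SimulationParams):
    """Design matrix with one HRF-convolved 1-TR boxcar regressor per TR."""
    dt = 0.1
    n_time = n_trs + tail_trs
    fine_t = np.arange(0, (n_time + 1) * TR_SECONDS, dt)
    h = double_gamma_hrf(fine_t, params.hrf_peak, params.hrf_undershoot, params.hrf_ratio)
    box = np.ones(int(round(TR_SECONDS / dt)))
    reg_fine = np.convolve(h, box)[: fine_t.size] * dt
    stride = int(round(TR_SECONDS / dt))
    X = np.zeros((n_time, n_trs))
    for j in range(n_trs):
        shifted = np.zeros(fine_t.size)
        shifted[j * stride :] = reg_fine[: fine_t.size - j * stride]
        X[:, j] = shifted[::stride][:n_time]
    if np.linalg.matrix_rank(X) < n_trs:
        raise SimulationError("rank-deficient GLM design matrix")
    return X


def simulate_bold_and_glm(
    design: Sequence[TrialDesign],
    params: SimulationParams,
    subject_id: str = "sim",
    tail_trs: int = 8,
) -> PatternDataset:
    """Simulate BOLD time series per trial and fit the per-trial TR-wise GLM.

    Each trial's voxel time series is the neural schedule convolved with the
    double-gamma HRF plus white Gaussian noise, sampled on the TR grid with
    ``tail_trs`` extra samples after trial offset so the OLS residual has
    positive degrees of freedom.  Returns t = beta/SE per voxel per TR.
    """
    if not design:
        raise SimulationError("empty design")
    if params.noise_sd <= 0:
        raise SimulationError(
            "noise_sd must be > 0 on the GLM path (t = beta/SE is undefined "
            "with zero residual variance)"
        )
    if tail_trs < 1:
        raise SimulationError("tail_trs must be >= 1 (residual df)")
    n_trs = _check_schedules(params, design)
    bank_seed = (
        params.category_patterns_seed
        if params.category_patterns_seed is not None
        else params.seed
    )
    bank = make_category_patterns(
        params.n_voxels, exemplar_jitter_sd=params.exemplar_jitter_sd, seed=bank_seed
    )
    X = _trial_design_matrix(n_trs, tail_trs, params)
    n_time = X.shape[0]
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    diag = np.diag(xtx_inv)
    dof = n_time - n_trs

    rng = np.random.default_rng(params.seed)
    patterns = np.empty((len(design), n_trs, params.n_voxels))
    for i, trial in enumerate(design):
        M = _signal_matrix(trial, params, bank, n_trs)  # (TR, voxel)
        Y = X @ M + rng.standard_normal((n_time, params.n_voxels)) * params.noise_sd
        beta = pinv @ Y
        resid = Y - X @ beta
        sigma2 = (resid ** 2).sum(axis=0) / dof
        if np.any(sigma2 <= 0):
            raise SimulationError("zero residual variance: t-values undefined")
        se = np.sqrt(np.outer(diag, sigma2))
        patterns[i] = beta / se
    return PatternDataset(
        patterns=patterns,
        design=list(design),
        subject_id=subject_id,
        provenance={
            "generator": "simulate_bold_and_glm",
            "params": params.digest(),
            "regressors_per_trial": n_trs,
            "tail_trs": tail_trs,
        },
    )
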