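"""Balanced experimental designs for the two-search working-memory task.

A trial presents an object drawn from one of three categories (four exemplars
each); a cue renders the remembered object *current* (search it first),
*prospective* (search it second) or — in the three-condition experiment —
*irrelevant* (never searched).  Designs are balanced per run over relevance
conditions and, as far as 12-trial runs allow, over condition × category
combinations, with exact equality across the full experiment.

Two stock profiles are provided:

``exp1``
    8 runs × 12 trials (96 trials), conditions {current, prospective},
    15 TRs per trial.  Every run holds exactly 2 trials of each
    condition × category combination.

``exp2``
    9 runs × 12 trials (108 trials), conditions {current, prospective,
    irrelevant}, 16 TRs per trial.  Each run holds 4 trials per condition;
    within a run the per-condition category counts are a rotation of
    (2, 1, 1), rotated across runs so that every condition × category
    combination totals 12 trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "ExperimentProfile",
    "TrialDesign",
    "EXP1",
    "EXP2",
    "PROFILES",
    "generate_design",
    "design_frame",
    "check_design_balance",
]


class DesignError(ValueError):
    """A requested design cannot satisfy the balance constraints."""


@dataclass(frozen=True)
class ExperimentProfile:
    """Constants describing one experiment's run/trial/TR structure."""

    name: str
    n_runs: int
    trials_per_run: int
    n_trs: int
    conditions: tuple
    n_categories: int = 3
    n_exemplars: int = 4


EXP1 = ExperimentProfile("exp1", 8, 12, 15, ("current", "prospective"))
EXP2 = ExperimentProfile("exp2", 9, 12, 16, ("current", "prospective", "irrelevant"))
PROFILES = {"exp1": EXP1, "exp2": EXP2}


@dataclass(frozen=True)
class TrialDesign:
    """Metadata of a single trial."""

    trial_id: int
    run: int
    condition: str
    category: int
    exemplar: int
    target_present: bool
    n_trs: int


def _resolve_profile(experiment: Union[str, ExperimentProfile]) -> ExperimentProfile:
    if isinstance(experiment, ExperimentProfile):
        return experiment
    try:
        return PROFILES[experiment]
    except KeyError:
        raise DesignError(
            f"unknown experiment {experiment!r}; expected one of {sorted(PROFILES)}"
        ) from None


def _category_counts(
    run: int, cond_index: int, per_cond: int, n_categories: int
) -> List[int]:
    """Per-category trial counts for one condition in one run.

    The ``per_cond % n_categories`` surplus trials are assigned to categories by
    rotating the starting category with both run and condition index, which
    equalises the condition × category totals across runs.
    """
    base, leftover = divmod(per_cond, n_categories)
    counts = [base] * n_categories
    for k in range(leftover):
        counts[(run + cond_index + k) % n_categories] += 1
    return counts


# Exemplar-pair table for designs with 2 trials per combination per run over
# 8 runs (the exp1 case): each row is one combination's per-run exemplar pair.
# Every row holds each exemplar exactly 4 times and contains all 6 exemplar
# pairs, and every pair of rows jointly covers all 16 (exemplar, exemplar)
# combinations within some run — so the per-run RDM convention has a
# contributing run for every cell of the 24 x 24 matrix.
_PAIR_TABLE_8RUNS = (
    ((3, 4), (1, 2), (1, 3), (2, 4), (1, 4), (2, 4), (1, 3), (2, 3)),
    ((1, 3), (2, 3), (1, 4), (1, 2), (1, 4), (2, 3), (2, 4), (3, 4)),
    ((1, 3), (2, 3), (1, 2), (1, 2), (3, 4), (2, 4), (3, 4), (1, 4)),
    ((1, 3), (2, 3), (1, 3), (1, 4), (2, 4), (1, 2), (3, 4), (2, 4)),
    ((3, 4), (1, 3), (1, 4), (2, 3), (1, 3), (2, 4), (2, 4), (1, 2)),
    ((1, 2), (1, 3), (2, 3), (2, 4), (1, 4), (3, 4), (3, 4), (1, 2)),
)


def _exemplar_sequences(
    totals: dict, per_run_counts: dict, n_runs: int, n_exemplars: int, rng
) -> dict:
    """Exemplar assignment per (condition-index, category): list per run.

    Returns mapping (ci, cat) -> list of per-run exemplar lists.  Totals are
    kept as equal as a balanced multiset allows; in the 8-run, 2-per-run,
    4-exemplar case a fixed coverage table (seeded relabelings of
    ``_PAIR_TABLE_8RUNS``) guarantees that every exemplar pair of every
    combination pair shares at least one run.
    """
    keys = sorted(totals)
    use_table = (
        n_exemplars == 4
        and n_runs == 8
        and len(keys) <= len(_PAIR_TABLE_8RUNS)
        and all(c == 2 for key in keys for c in per_run_counts[key])
    )
    out = {}
    if use_table:
        row_of = rng.permutation(len(_PAIR_TABLE_8RUNS))
        col_order = rng.permutation(n_runs)
        for k, key in enumerate(keys):
            # independent exemplar relabelling per combination preserves both
            # the balance and the pairwise coverage of the table
            relabel = rng.permutation(4) + 1
            row = _PAIR_TABLE_8RUNS[row_of[k]]
            out[key] = [
                [int(relabel[e - 1]) for e in row[col_order[r]]]
                for r in range(n_runs)
            ]
        return out
    for key in keys:
        total = totals[key]
        counts = per_run_counts[key]
        base, extra = divmod(total, n_exemplars)
        pool = list(np.repeat(np.arange(1, n_exemplars + 1), base))
        # surplus exemplars chosen by rotation on the combination, so totals
        # stay equal across the design wherever divisibility allows
        offset = (key[0] + key[1]) % n_exemplars
        pool += [((offset + k) % n_exemplars) + 1 for k in range(extra)]
        pool = [int(x) for x in rng.permutation(pool)]
        seqs, pos = [], 0
        for c in counts:
            seqs.append(pool[pos : pos + c])
            pos += c
        out[key] = seqs
    return out


def generate_design(
    experiment: Union[str, ExperimentProfile] = "exp2",
    n_runs: Optional[int] = None,
    trials_per_run: Optional[int] = None,
    seed: int = 0,
    n_trs: Optional[int] = None,
) -> List[TrialDesign]:
    """Generate a balanced trial design.

    Parameters
    ----------
    experiment
        ``"exp1"``, ``"exp2"`` or an :class:`ExperimentProfile`.
    n_runs, trials_per_run, n_trs
        Override the profile constants (defaults reproduce the profile).
    seed
        Seeds exemplar assignment, target-present placement and within-run
        trial order; the balance structure itself is deterministic.

    Raises
    ------
    DesignError
        If the requested sizes cannot be balanced (e.g. ``trials_per_run``
        not divisible by the number of conditions).
    """
    prof = _resolve_profile(experiment)
    n_runs = prof.n_runs if n_runs is None else int(n_runs)
    trials_per_run = (
        prof.trials_per_run if trials_per_run is None else int(trials_per_run)
    )
    n_trs = prof.n_trs if n_trs is None else int(n_trs)
    if n_runs < 0 or trials_per_run < 0:
        raise DesignError("n_runs and trials_per_run must be non-negative")
    if n_runs == 0 or trials_per_run == 0:
        return []

    conds = prof.conditions
    C, E = prof.n_categories, prof.n_exemplars
    if trials_per_run % len(conds):
        raise DesignError(
            f"trials_per_run={trials_per_run} is not divisible by the "
            f"{len(conds)} conditions {conds}"
        )
    per_cond = trials_per_run // len(conds)
    if per_cond % C and n_runs % C:
        raise DesignError(
            f"cannot equalise condition x category totals: {per_cond} trials "
            f"per condition per run leaves a surplus and n_runs={n_runs} is "
            f"not a multiple of {C}"
        )

    rng = np.random.default_rng(seed)

    counts = {}  # (run, ci) -> per-category counts
    per_run_counts = {}  # (ci, cat) -> list over runs
    totals = {}
    for r in range(n_runs):
        for ci in range(len(conds)):
            cc = _category_counts(r, ci, per_cond, C)
            counts[(r, ci)] = cc
            for cat in range(C):
                per_run_counts.setdefault((ci, cat), []).append(cc[cat])
    for key, lst in per_run_counts.items():
        totals[key] = int(sum(lst))

    exemplars = _exemplar_sequences(totals, per_run_counts, n_runs, E, rng)

    trials: List[TrialDesign] = []
    trial_id = 1
    for r in range(n_runs):
        run_trials = []
        for ci, cond in enumerate(conds):
            for cat in range(C):
                for ex in exemplars[(ci, cat)][r]:
                    run_trials.append((cond, cat + 1, int(ex)))
        n = len(run_trials)
        present = np.zeros(n, dtype=bool)
        present[: n // 2 + (n % 2) * (r % 2)] = True
        present = present[rng.permutation(n)]
        order = rng.permutation(n)
        for k, idx in enumerate(order):
            cond, cat, ex = run_trials[idx]
            trials.append(
                TrialDesign(
                    trial_id=trial_id,
                    run=r + 1,
                    condition=cond,
                    category=cat,
                    exemplar=ex,
                    target_present=bool(present[k]),
                    n_trs=n_trs,
                )
            )
            trial_id += 1
    return trials


def design_frame(design: Sequence[TrialDesign]) -> pd.DataFrame:
    """Tabular view of a design (one row per trial)."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in design],
            "run": [t.run for t in design],
            "condition": [t.condition for t in design],
            "category": [t.category for t in design],
            "exemplar": [t.exemplar for t in design],
            "target_present": [t.target_present for t in design],
            "n_trs": [t.n_trs for t in design],
        }
    )


def check_design_balance(
    design: Sequence[TrialDesign], profile: Union[str, ExperimentProfile]
) -> None:
    """Assert the design invariants of the given profile (raises DesignError)."""
    prof = _resolve_profile(profile)
    df = design_frame(design)
    per_cond_run = df.groupby(["run", "condition"]).size()
    expected = prof.trials_per_run // len(prof.conditions)
    if not (per_cond_run == expected).all():
        raise DesignError("unequal condition counts within a run")
    combo = df.groupby(["condition", "category"]).size()
    if combo.nunique() != 1:
        raise DesignError("unequal condition x category totals across the design")
    if prof.name == "exp2":
        for (run, cond), grp in df.groupby(["run", "condition"]):
            cnt = sorted(grp.groupby("category").size().reindex(
                range(1, prof.n_categories + 1), fill_value=0))
            if cnt != [1, 1, 2]:
                raise DesignError(
                    f"run {run} condition {cond}: category counts {cnt} "
                    "are not a permutation of (2,1,1)"
                )
    if prof.name == "exp1":
        per = df.groupby(["run", "condition", "category"]).size()
        if not (per == 2).all():
            raise DesignError("exp1: condition x category counts per run differ from 2")
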