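"""Configuration-driven orchestration: simulate -> decode -> tempgen -> rsa ->
stats -> report.

A :class:`RunConfig` (built from YAML/JSON or a dict) fixes the experiment
profile, the simulated cohort, the decoding schemes, the analysis intervals
and a master seed.  Per-subject seeds are derived deterministically from the
master seed, so re-running a configuration reproduces every number exactly;
every output directory carries a manifest with the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import PatternDataset
from .decoding import (
    DecodingScheme,
    decode_timecourse,
    interval_average,
)
from .design import PROFILES, generate_design
from .rsa import compute_rdm, same_vs_diff_contrast
from .simulate import (
    DEFAULT_INTERVALS,
    SimulationParams,
    default_params,
    simulate_bold_and_glm,
    simulate_t_patterns,
)
from .stats import paired_t, rm_anova_oneway, roi_mean_timecourse, within_subject_sem
from .tempgen import cluster_permutation_2d, cross_temporal_matrix

logger = logging.getLogger("relmvpa")

__all__ = ["ConfigError", "RunConfig", "validate_config", "run_pipeline"]

_STAGES = ("simulate", "decode", "tempgen", "rsa", "stats", "report")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def _default_schemes(experiment: str) -> List[dict]:
    conds = list(PROFILES[experiment].conditions)
    cv = "balanced_loro" if experiment == "exp2" else "loro"
    schemes = [{"type": "within", "condition": c, "cv": cv} for c in conds]
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            schemes.append({"type": "cross", "train": conds[i], "test": conds[j]})
    return schemes


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulated-cohort analysis."""

    experiment: str = "exp2"
    n_subjects: int = 24
    n_runs: Optional[int] = None
    trials_per_run: Optional[int] = None
    sim: Dict = field(default_factory=dict)  # SimulationParams overrides
    amplitude_scale: float = 1.0
    inversion_search: float = -1.0
    intervals: Optional[Dict[str, List[int]]] = None
    schemes: Optional[List[dict]] = None
    rsa_pairs: Optional[List[List[str]]] = None
    rsa_per_run: bool = True
    within_chance_tail: str = "greater"
    tempgen_scheme: Optional[dict] = None
    tempgen_n_perm: int = 1000
    glm_path: bool = False
    save_datasets: bool = False
    outdir: str = "relmvpa_out"
    seed: int = 0

    def __post_init__(self):
        if self.intervals is None:
            self.intervals = {
                k: list(v) for k, v in DEFAULT_INTERVALS.get(self.experiment, {}).items()
            }
        if self.schemes is None and self.experiment in PROFILES:
            self.schemes = _default_schemes(self.experiment)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _scheme_from_spec(spec: dict) -> DecodingScheme:
    kind = spec.get("type")
    if kind == "within":
        return DecodingScheme(
            spec["condition"], spec["condition"], spec.get("cv", "loro")
        )
    if kind == "cross":
        return DecodingScheme(spec["train"], spec["test"], "train_all_cross")
    raise ConfigError(f"unknown scheme type {kind!r} in {spec}")


def validate_config(config: RunConfig) -> List[str]:
    """Return a list of violations (empty when the config is valid)."""
    errs: List[str] = []
    if config.experiment not in PROFILES:
        errs.append(f"unknown experiment {config.experiment!r}")
        return errs
    prof = PROFILES[config.experiment]
    n_trs = prof.n_trs
    tpr = config.trials_per_run or prof.trials_per_run
    if config.n_subjects < 1:
        errs.append("n_subjects must be >= 1")
    if tpr % len(prof.conditions):
        errs.append(
            f"trials_per_run={tpr} not divisible by {len(prof.conditions)} conditions"
        )
    for name, members in (config.intervals or {}).items():
        if not members:
            errs.append(f"interval {name!r} is empty")
        for t in members or []:
            if not 1 <= int(t) <= n_trs:
                errs.append(f"interval {name!r}: TR {t} outside 1..{n_trs}")
    for spec in config.schemes or []:
        try:
            sch = _scheme_from_spec(spec)
        except (ConfigError, ValueError) as e:
            errs.append(str(e))
            continue
        for cond in {sch.train_condition, sch.test_condition}:
            if cond not in prof.conditions:
                errs.append(f"scheme {sch.label!r}: unknown condition {cond!r}")
    for pair in config.rsa_pairs or []:
        if len(pair) != 2:
            errs.append(f"rsa pair {pair!r} must name two relevance levels")
        for cond in pair:
            if cond not in prof.conditions:
                errs.append(f"rsa pair {pair!r}: unknown condition {cond!r}")
    if config.within_chance_tail not in ("greater", "two-sided", "less"):
        errs.append(f"unknown within_chance_tail {config.within_chance_tail!r}")
    return errs


def _subject_seeds(master_seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def simulate_cohort(config: RunConfig) -> List[PatternDataset]:
    """Simulate the cohort's datasets (deterministic in the master seed)."""
    prof = PROFILES[config.experiment]
    datasets = []
    for i, seed in enumerate(_subject_seeds(config.seed, config.n_subjects)):
        design = generate_design(
            config.experiment,
            n_runs=config.n_runs,
            trials_per_run=config.trials_per_run,
            seed=seed,
        )
        params = default_params(
            config.experiment,
            amplitude_scale=config.amplitude_scale,
            inversion_search=config.inversion_search,
            seed=seed,
            **config.sim,
        )
        sim = simulate_bold_and_glm if config.glm_path else simulate_t_patterns
        datasets.append(sim(design, params, subject_id=f"sub-{i + 1:02d}"))
    return datasets


def run_pipeline(config: RunConfig, stages: Optional[Sequence[str]] = None) -> dict:
    """Execute the requested stages and write tidy CSV/JSON outputs.

    Returns a dict of the in-memory results (DataFrames and result objects).
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid configuration: " + "; ".join(violations))
    stages = set(stages or _STAGES)
    unknown = stages - set(_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    logger.info("simulating %d subjects (%s)", config.n_subjects, config.experiment)
    datasets = simulate_cohort(config)
    results["datasets"] = datasets
    if config.save_datasets and "simulate" in stages:
        for ds in datasets:
            ds.to_hdf5(out / f"{ds.subject_id}.h5")

    chance = datasets[0].chance_level
    schemes = [_scheme_from_spec(s) for s in (config.schemes or [])]

    if "decode" in stages or "stats" in stages:
        rows, interval_rows = [], []
        for ds in datasets:
            for sch in schemes:
                try:
                    tc = decode_timecourse(ds, sch)
                except Exception as err:
                    raise RuntimeError(
                        f"stage decode failed for subject {ds.subject_id}, "
                        f"scheme {sch.label}: {err}"
                    ) from err
                for tr, a, nf in zip(tc.trs, tc.accuracy, tc.n_fits):
                    rows.append(
                        dict(subject=ds.subject_id, scheme=sch.label, tr=int(tr),
                             accuracy=a, n_fits=int(nf))
                    )
                for name, val in interval_average(tc, config.intervals).items():
                    interval_rows.append(
                        dict(subject=ds.subject_id, scheme=sch.label,
                             interval=name, accuracy=val)
                    )
        tc_df = pd.DataFrame(rows)
        iv_df = pd.DataFrame(interval_rows)
        results["timecourses"] = tc_df
        results["interval_accuracy"] = iv_df
        if "decode" in stages:
            tc_df.to_csv(out / "decoding_timecourses.csv", index=False,
                         float_format="%.10g")
            iv_df.to_csv(out / "interval_accuracy.csv", index=False,
                         float_format="%.10g")

    if "stats" in stages:
        stat_rows = []
        for (scheme, interval), grp in results["interval_accuracy"].groupby(
            ["scheme", "interval"]
        ):
            vals = grp.sort_values("subject")["accuracy"].to_numpy()
            tail = (
                config.within_chance_tail
                if scheme.startswith("within") else "two-sided"
            )
            try:
                res = paired_t(vals, chance, tail=tail)
            except Exception:
                continue
            stat_rows.append(
                dict(experiment=config.experiment, scheme=scheme, interval=interval,
                     mean_accuracy=float(vals.mean()), t=res.t, df=res.df,
                     p=res.p, d=res.d, tail=res.tail)
            )
        stats_df = pd.DataFrame(stat_rows)
        results["interval_stats"] = stats_df
        stats_df.to_csv(out / "interval_stats.csv", index=False, float_format="%.10g")

        within = [s.label for s in schemes if s.is_within]
        if len(within) >= 2:
            anova_rows = []
            for interval in config.intervals:
                piv = (
                    results["interval_accuracy"]
                    .query("interval == @interval and scheme in @within")
                    .pivot(index="subject", columns="scheme", values="accuracy")
                )
                res = rm_anova_oneway(piv.to_numpy())
                anova_rows.append(
                    dict(interval=interval, F=res.F, df_num=res.df_num,
                         df_den=res.df_den, p=res.p, eta_p2=res.eta_p2,
                         gg_epsilon=res.gg_epsilon)
                )
            anova_df = pd.DataFrame(anova_rows)
            results["anova"] = anova_df
            anova_df.to_csv(out / "interval_anova.csv", index=False,
                            float_format="%.10g")

        bold = roi_mean_timecourse(datasets)
        bold_df = pd.DataFrame(
            {"tr": np.arange(1, bold["mean"].size + 1),
             "mean_t": bold["mean"], "ws_sem": bold["sem"]}
        )
        results["bold_timecourse"] = bold_df
        bold_df.to_csv(out / "bold_timecourse.csv", index=False, float_format="%.10g")

    if "tempgen" in stages:
        spec = config.tempgen_scheme or next(
            (s for s in (config.schemes or []) if s.get("type") == "cross"),
            (config.schemes or [{}])[0],
        )
        sch = _scheme_from_spec(spec)
        mats = [cross_temporal_matrix(ds, sch) for ds in datasets]
        stack = np.stack([m.accuracy for m in mats])
        np.savetxt(out / "tempgen_group_mean.csv", stack.mean(axis=0), delimiter=",")
        cluster = None
        if len(datasets) >= 2:
            cluster = cluster_permutation_2d(
                mats, chance=chance, n_perm=config.tempgen_n_perm,
                seed=config.seed,
            )
            summary = [
                dict(tail=c.tail, mass=c.mass, p=c.p, n_cells=len(c.cells),
                     cells=[list(map(int, cell)) for cell in c.cells])
                for c in cluster.clusters
            ]
            (out / "tempgen_clusters.json").write_text(
                json.dumps(
                    {"scheme": sch.label, "n_permutations": cluster.n_permutations,
                     "clusters": summary},
                    indent=2,
                )
            )
        results["tempgen"] = {"matrices": mats, "clusters": cluster}

    if "rsa" in stages:
        pairs = config.rsa_pairs
        if pairs is None:
            conds = list(PROFILES[config.experiment].conditions)
            pairs = [
                [conds[i], conds[j]]
                for i in range(len(conds))
                for j in range(i + 1, len(conds))
            ]
        rsa_rows = []
        for ds in datasets:
            for interval, trs in config.intervals.items():
                for pair in pairs:
                    rdm = compute_rdm(
                        ds, trs, conditions=list(pair),
                        per_run=config.rsa_per_run, scope=interval,
                    )
                    con = same_vs_diff_contrast(rdm, (pair[0], pair[1]))
                    rsa_rows.append(
                        dict(subject=ds.subject_id, interval=interval,
                             pair=f"{pair[0]}-{pair[1]}",
                             same=con.same_category_mean,
                             different=con.diff_category_mean,
                             difference=con.difference, scale=con.scale)
                    )
        rsa_df = pd.DataFrame(rsa_rows)
        results["rsa_contrasts"] = rsa_df
        rsa_df.to_csv(out / "rsa_contrasts.csv", index=False, float_format="%.10g")
        rsa_stats = []
        for (interval, pair), grp in rsa_df.groupby(["interval", "pair"]):
            diffs = grp.sort_values("subject")["difference"].to_numpy()
            try:
                res = paired_t(diffs, 0.0, tail="two-sided")
            except Exception:
                continue
            rsa_stats.append(
                dict(interval=interval, pair=pair, mean_difference=diffs.mean(),
                     t=res.t, df=res.df, p=res.p, d=res.d)
            )
        pd.DataFrame(rsa_stats).to_csv(
            out / "rsa_stats.csv", index=False, float_format="%.10g"
        )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
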