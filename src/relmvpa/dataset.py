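"""The PatternDataset container: per-trial x per-TR voxel t-value patterns.

This is the currency passed between every pipeline stage.  Patterns are stored
as a dense float array ``(n_trials, n_trs, n_voxels)`` together with the trial
design and provenance.  Datasets round-trip through HDF5, and per-TR t-maps
from a real experiment can be ingested from NIfTI volumes plus a TSV trial
table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .design import TrialDesign

__all__ = ["DatasetError", "PatternDataset"]


class DatasetError(ValueError):
    """Inconsistent pattern data."""


@dataclass
class PatternDataset:
    """Per-trial, per-TR voxel patterns (t-values) plus design and provenance."""

    patterns: np.ndarray
    design: List[TrialDesign]
    subject_id: str = "sim"
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 3:
            raise DatasetError("patterns must be (n_trials, n_trs, n_voxels)")
        if not np.all(np.isfinite(self.patterns)):
            raise DatasetError("patterns contain non-finite values")
        if self.patterns.shape[0] != len(self.design):
            raise DatasetError(
                f"{self.patterns.shape[0]} pattern rows but {len(self.design)} trials"
            )
        if self.design and self.patterns.shape[1] != self.design[0].n_trs:
            raise DatasetError(
                f"TR axis ({self.patterns.shape[1]}) does not match the design's "
                f"n_trs ({self.design[0].n_trs})"
            )

    # -- basic views ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_trs(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]

    @property
    def conditions(self) -> List[str]:
        seen = []
        for t in self.design:
            if t.condition not in seen:
                seen.append(t.condition)
        return seen

    @property
    def categories(self) -> np.ndarray:
        return np.unique([t.category for t in self.design])

    @property
    def chance_level(self) -> float:
        """1 / number of distinct categories in the design."""
        return 1.0 / len(self.categories)

    def design_frame(self) -> pd.DataFrame:
        from .design import design_frame

        return design_frame(self.design)

    def index(self, condition: Optional[str] = None) -> np.ndarray:
        """Trial indices (0-based), optionally restricted to a condition."""
        if condition is None:
            return np.arange(self.n_trials)
        idx = np.array(
            [i for i, t in enumerate(self.design) if t.condition == condition],
            dtype=int,
        )
        return idx

    def labels(self, idx: Optional[np.ndarray] = None) -> np.ndarray:
        cats = np.array([t.category for t in self.design])
        return cats if idx is None else cats[idx]

    def runs_of(self, idx: Optional[np.ndarray] = None) -> np.ndarray:
        runs = np.array([t.run for t in self.design])
        return runs if idx is None else runs[idx]

    def at_tr(self, tr: int, idx: Optional[np.ndarray] = None) -> np.ndarray:
        """Trial x voxel matrix at a 1-based TR index."""
        if not 1 <= tr <= self.n_trs:
            raise DatasetError(f"TR {tr} out of range 1..{self.n_trs}")
        block = self.patterns[:, tr - 1, :]
        return block if idx is None else block[idx]

    # -- persistence ---------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        df = self.design_frame()
        with h5py.File(path, "w") as f:
            f.create_dataset("patterns", data=self.patterns, compression="gzip")
            g = f.create_group("design")
            for col in df.columns:
                data = df[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                g.create_dataset(col, data=data)
            f.attrs["subject_id"] = self.subject_id
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def from_hdf5(cls, path) -> "PatternDataset":
        import h5py

        with h5py.File(path, "r") as f:
            patterns = f["patterns"][()]
            g = f["design"]
            cols = {k: g[k][()] for k in g}
            design = []
            n = len(cols["trial_id"])
            for i in range(n):
                design.append(
                    TrialDesign(
                        trial_id=int(cols["trial_id"][i]),
                        run=int(cols["run"][i]),
                        condition=cols["condition"][i].decode()
                        if isinstance(cols["condition"][i], bytes)
                        else str(cols["condition"][i]),
                        category=int(cols["category"][i]),
                        exemplar=int(cols["exemplar"][i]),
                        target_present=bool(cols["target_present"][i]),
                        n_trs=int(cols["n_trs"][i]),
                    )
                )
            return cls(
                patterns=patterns,
                design=design,
                subject_id=str(f.attrs.get("subject_id", "sim")),
                provenance=json.loads(f.attrs.get("provenance", "{}")),
            )

    @classmethod
    def from_nifti(
        cls,
        trial_images: Sequence,
        trial_table,
        mask=None,
        subject_id: str = "ingest",
    ) -> "PatternDataset":
        """Ingest per-trial 4-D t-map NIfTIs (TR along the 4th axis).

        ``trial_table`` is a TSV path or DataFrame with columns trial_id, run,
        condition, category, exemplar (optional target_present).  ``mask`` is
        an optional 3-D NIfTI whose non-zero voxels are retained.
        """
        import nibabel as nib

        if not isinstance(trial_table, pd.DataFrame):
            trial_table = pd.read_csv(trial_table, sep="\t")
        required = {"trial_id", "run", "condition", "category", "exemplar"}
        missing = required - set(trial_table.columns)
        if missing:
            raise DatasetError(f"trial table missing columns: {sorted(missing)}")
        if len(trial_images) != len(trial_table):
            raise DatasetError(
                f"{len(trial_images)} images for {len(trial_table)} table rows"
            )
        mask_arr = None
        if mask is not None:
            mask_img = mask if hasattr(mask, "get_fdata") else nib.load(str(mask))
            mask_arr = np.asarray(mask_img.get_fdata()) > 0
        rows = []
        for img in trial_images:
            img = img if hasattr(img, "get_fdata") else nib.load(str(img))
            data = np.asarray(img.get_fdata())
            if data.ndim != 4:
                raise DatasetError("each trial image must be 4-D (x, y, z, TR)")
            flat = (
                data[mask_arr].T if mask_arr is not None
                else data.reshape(-1, data.shape[3]).T
            )
            rows.append(flat)  # (TR, voxel)
        patterns = np.stack(rows)
        n_trs = patterns.shape[1]
        design = []
        for _, r in trial_table.iterrows():
            design.append(
                TrialDesign(
                    trial_id=int(r["trial_id"]),
                    run=int(r["run"]),
                    condition=str(r["condition"]),
                    category=int(r["category"]),
                    exemplar=int(r["exemplar"]),
                    target_present=bool(r.get("target_present", False)),
                    n_trs=n_trs,
                )
            )
        return cls(
            patterns=patterns,
            design=design,
            subject_id=subject_id,
            provenance={"generator": "from_nifti"},
        )
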