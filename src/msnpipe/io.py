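"""File formats and pipeline configuration.

Interchange formats are deliberately plain and diffable:

* thickness — long-format TSV with columns
  ``subject_id, roi, vertex_index, thickness_mm``;
* cohort — CSV with ``subject_id, adi, age, sex, education_years,
  practice`` plus the six cognitive-score columns;
* MSN matrices — dense CSV with an ROI-labelled header, or an edge list;
* configuration — YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import DK_ROI_LABELS, N_ROIS
from .divergence import GridSpec
from .graph import SparsityScheme
from .msn import MSNMatrix, SubjectThickness
from .synthetic import COGNITIVE_SCORES

__all__ = [
    "PipelineConfig",
    "write_thickness_tsv",
    "read_thickness_table",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_msn_csv",
    "read_msn_csv",
    "write_msn_edge_list",
]

THICKNESS_COLUMNS = ("subject_id", "roi", "vertex_index", "thickness_mm")
COHORT_BASE_COLUMNS = ("subject_id", "adi", "age", "sex", "education_years", "practice")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis, with study defaults.

    Defaults: 0-6 mm x 256-point PDF grid; sparsity sweep 0.05-0.50 step
    0.05; 100 random reference networks; 10,000 bootstrap iterations;
    significance tiers 0.05 / 0.01 / 0.005.
    """

    thickness_path: str = ""
    cohort_path: str = ""
    output_dir: str = "msnpipe_output"
    grid_lower: float = 0.0
    grid_upper: float = 6.0
    grid_points: int = 256
    sparsity_levels: tuple[float, ...] = SparsityScheme().levels
    n_random: int = 100
    n_boot: int = 10_000
    alpha_cognitive: float = 0.05
    alpha_report: float = 0.01
    alpha_candidate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid()          # validates grid fields
        self.scheme()        # validates sparsity levels
        if self.n_random < 1:
            raise ValueError(f"n_random must be >= 1, got {self.n_random}")
        if self.n_boot < 100:
            raise ValueError(f"n_boot must be >= 100, got {self.n_boot}")

    def grid(self) -> GridSpec:
        return GridSpec(self.grid_lower, self.grid_upper, self.grid_points)

    def scheme(self) -> SparsityScheme:
        return SparsityScheme(tuple(self.sparsity_levels))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sparsity_levels"] = list(self.sparsity_levels)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "sparsity_levels" in data:
            data["sparsity_levels"] = tuple(data["sparsity_levels"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# thickness tables
# ---------------------------------------------------------------------------

def write_thickness_tsv(subjects, path) -> None:
    """Write subjects' vertex thickness values as long-format TSV."""
    frames = []
    for s in subjects:
        for roi, values in s.roi_values.items():
            frames.append(pd.DataFrame({
                "subject_id": s.subject_id,
                "roi": roi,
                "vertex_index": np.arange(len(values)),
                "thickness_mm": values,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_thickness_table(path) -> tuple[list[SubjectThickness], dict[str, str]]:
    """Parse a long-format thickness TSV into per-subject structures.

    Rows may arrive in any order.  Returns ``(subjects, rejections)``
    where *rejections* maps subject_id -> reason for subjects that do not
    carry a complete, valid 68-ROI profile.  Malformed rows (non-numeric
    or non-positive thickness, unknown ROI labels) raise with the
    offending line numbers.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in THICKNESS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"thickness table is missing columns: {missing}")
    thick = pd.to_numeric(df["thickness_mm"], errors="coerce")
    bad = df.index[~(thick > 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
        raise ValueError(
            f"non-positive or non-numeric thickness_mm at line(s) {lines}"
            + (" ..." if len(bad) > 5 else "")
        )
    unknown = df.loc[~df["roi"].isin(DK_ROI_LABELS)]
    if len(unknown):
        raise ValueError(
            f"unknown ROI labels: {sorted(unknown['roi'].unique().tolist())}"
        )
    subjects: list[SubjectThickness] = []
    rejections: dict[str, str] = {}
    for sid, group in df.groupby("subject_id", sort=True):
        rois = {
            roi: sub.sort_values("vertex_index")["thickness_mm"].to_numpy()
            for roi, sub in group.groupby("roi")
        }
        if len(rois) < N_ROIS:
            rejections[str(sid)] = f"only {len(rois)} of {N_ROIS} ROIs present"
            continue
        subjects.append(SubjectThickness(str(sid), rois))
    return subjects, rejections


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path, require_scores: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    ADI must be coded 0 (low) / 1 (high); the six cognitive-score columns
    are required unless ``require_scores=False``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if require_scores:
        missing_scores = [c for c in COGNITIVE_SCORES if c not in df.columns]
        if missing_scores:
            raise ValueError(f"cohort table is missing cognitive scores: {missing_scores}")
    adi = df["adi"]
    if not adi.isin([0, 1]).all():
        bad = sorted(adi[~adi.isin([0, 1])].unique().tolist())
        raise ValueError(f"adi must be coded 0/1, found values {bad}")
    return df


# ---------------------------------------------------------------------------
# MSN matrices
# ---------------------------------------------------------------------------

def write_msn_csv(msn: MSNMatrix, path) -> None:
    pd.DataFrame(msn.values, index=msn.roi_order, columns=msn.roi_order).to_csv(path)


def read_msn_csv(path, subject_id: str | None = None) -> MSNMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    sid = subject_id or Path(path).stem
    return MSNMatrix(sid, df.to_numpy(), tuple(df.columns))


def write_msn_edge_list(msn: MSNMatrix, path) -> None:
    i, j = np.triu_indices(len(msn.roi_order), 1)
    pd.DataFrame({
        "roi_a": np.asarray(msn.roi_order)[i],
        "roi_b": np.asarray(msn.roi_order)[j],
        "jsse": msn.values[i, j],
    }).to_csv(path, index=False)
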