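"""Synthetic cohorts with known ground truth.

The real study population (a cognitively unimpaired cohort dichotomised
into low/high neighbourhood-disadvantage groups by ADI decile) is not
public, so every downstream stage is exercised on simulated data that
reproduces the published marginal structure:

* demographics — 450 low-ADI / 74 high-ADI subjects, age 62.96 +/- 8.37 y,
  group-specific education and sex mix, practice counts with median 0;
* cognitive scores — six tests generated from a linear model in ADI, age,
  sex (male = 1), education and practice, with the published regression
  coefficients as the default generating truth and residual scatter
  back-derived from the published standard errors;
* cortical thickness — per-region Gaussian vertex samples (truncated at
  0.1 mm) whose location/spread shifts by ADI group in designated regions,
  so the similarity-network stages see a real group contrast;
* mediation test bed — a feature-level dataset (exposure, mediator,
  outcome, covariates) with known path coefficients a, b, c'.

All randomness flows from a single root seed through named substreams
(:class:`numpy.random.SeedSequence`), so fixtures are bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .atlas import DK_ROI_LABELS, N_ROIS
from .msn import SubjectThickness

__all__ = [
    "CohortConfig",
    "ROISpec",
    "ThicknessShift",
    "MediationGroundTruth",
    "ScoreModel",
    "COGNITIVE_SCORES",
    "DEFAULT_SCORE_MODELS",
    "generate_cohort",
    "generate_subject_thickness",
    "generate_cohort_thickness",
    "generate_mediation_dataset",
]

COGNITIVE_SCORES = ("mPACC", "CF", "WAIS_DS", "TMTt", "SMD", "RAVLT_L")


@dataclass(frozen=True)
class ScoreModel:
    """Generating linear model for one cognitive score.

    ``score = intercept + b_adi*ADI + b_age*age + b_sex*sex(male=1)
    + b_edu*education + b_practice*practice + N(0, sigma^2)``.
    """

    intercept: float
    b_adi: float
    b_age: float
    b_sex: float
    b_edu: float
    b_practice: float
    sigma: float

    def null(self) -> "ScoreModel":
        """Same model with the ADI effect removed."""
        return replace(self, b_adi=0.0)


# Default generating coefficients mirror the published association table;
# sigma is back-derived from the reported SE of the ADI coefficient at
# n=524 with the 450/74 group split: se ~= sigma*sqrt(1/450 + 1/74)
# => sigma ~= se / 0.1254.
DEFAULT_SCORE_MODELS: dict[str, ScoreModel] = {
    "mPACC": ScoreModel(1.26, -0.47, -0.05, -0.49, 0.12, 0.10, 1.04),
    "CF": ScoreModel(26.67, -1.58, -0.16, 0.41, 0.37, 0.25, 5.50),
    "WAIS_DS": ScoreModel(86.74, -3.63, -0.62, -2.95, 0.55, 0.47, 10.77),
    "TMTt": ScoreModel(6.98, 18.47, 1.70, 1.46, -2.98, -2.97, 34.93),
    "SMD": ScoreModel(12.36, -1.66, -0.07, -0.79, 0.34, 0.01, 4.07),
    "RAVLT_L": ScoreModel(61.17, -1.83, -0.40, -6.10, 0.85, 1.20, 8.69),
}


@dataclass(frozen=True)
class CohortConfig:
    """Demographic structure of a simulated cohort.

    Defaults mirror the published cohort: 450 low-ADI and 74 high-ADI
    participants, age 62.96 +/- 8.37 years, education 16.63 +/- 2.38
    (low) vs 15.33 +/- 2.45 (high) years, female fraction 0.637 vs 0.757,
    practice counts in 0-7.
    """

    n_low_adi: int = 450
    n_high_adi: int = 74
    age_mean: float = 62.96
    age_sd: float = 8.37
    education_by_group: tuple[tuple[float, float], tuple[float, float]] = (
        (16.63, 2.38),
        (15.33, 2.45),
    )
    female_fraction_by_group: tuple[float, float] = (0.637, 0.757)
    practice_range: tuple[int, int] = (0, 7)
    score_models: dict[str, ScoreModel] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MODELS)
    )
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("n_low_adi", "n_high_adi"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.age_sd <= 0:
            raise ValueError(f"age_sd must be > 0, got {self.age_sd}")
        for g, (_, sd) in enumerate(self.education_by_group):
            if sd <= 0:
                raise ValueError(f"education_by_group[{g}] sd must be > 0, got {sd}")
        for g, f in enumerate(self.female_fraction_by_group):
            if not 0 <= f <= 1:
                raise ValueError(
                    f"female_fraction_by_group[{g}] must be in [0, 1], got {f}"
                )
        lo, hi = self.practice_range
        if not (0 <= lo <= hi):
            raise ValueError(f"practice_range must satisfy 0 <= lo <= hi, got {self.practice_range}")
        unknown = set(self.score_models) - set(COGNITIVE_SCORES)
        if unknown:
            raise ValueError(f"score_models contains unknown scores: {sorted(unknown)}")

    def null_cognition(self) -> "CohortConfig":
        """Copy of the config with every ADI->score effect set to zero."""
        return replace(
            self, score_models={k: m.null() for k, m in self.score_models.items()}
        )


@dataclass(frozen=True)
class ThicknessShift:
    """ADI-group change in a region's thickness distribution."""

    loc_delta: float = 0.0   # mm added to the mean in the high-ADI group
    scale_factor: float = 1.0  # multiplier on the SD in the high-ADI group

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError(f"scale_factor must be > 0, got {self.scale_factor}")


def _default_baselines() -> tuple[np.ndarray, np.ndarray]:
    # fixed per-region baseline table (frozen generator constant, not a
    # user-facing source of randomness): means ~U(2.1, 3.1) mm, SDs
    # ~U(0.18, 0.30) mm, plausible for cortical grey matter
    rng = np.random.default_rng(68)
    means = rng.uniform(2.1, 3.1, N_ROIS)
    sds = rng.uniform(0.18, 0.30, N_ROIS)
    return means, sds


@dataclass(frozen=True)
class ROISpec:
    """Generating parameters for per-region vertex thickness samples."""

    roi_names: tuple[str, ...] = DK_ROI_LABELS
    vertex_counts: tuple[int, ...] | int = 400
    baseline_mean: tuple[float, ...] | None = None
    baseline_sd: tuple[float, ...] | None = None
    group_shift_rois: dict[str, ThicknessShift] = field(
        default_factory=lambda: {
            "lh-lateralorbitofrontal": ThicknessShift(loc_delta=0.15, scale_factor=1.3),
            "lh-fusiform": ThicknessShift(loc_delta=-0.12, scale_factor=0.75),
        }
    )
    truncation_mm: float = 0.1

    def __post_init__(self) -> None:
        names = tuple(self.roi_names)
        if len(names) != N_ROIS or len(set(names)) != N_ROIS:
            raise ValueError(
                f"roi_names must be {N_ROIS} unique labels, got {len(names)}"
            )
        object.__setattr__(self, "roi_names", names)
        counts = self.vertex_counts
        if np.isscalar(counts):
            counts = (int(counts),) * N_ROIS
        else:
            counts = tuple(int(c) for c in counts)
        if len(counts) != N_ROIS:
            raise ValueError(f"vertex_counts must have length {N_ROIS}")
        if any(c < 10 for c in counts):
            raise ValueError("vertex_counts must all be >= 10")
        object.__setattr__(self, "vertex_counts", counts)
        dmeans, dsds = _default_baselines()
        means = dmeans if self.baseline_mean is None else np.asarray(self.baseline_mean, float)
        sds = dsds if self.baseline_sd is None else np.asarray(self.baseline_sd, float)
        if means.shape != (N_ROIS,) or sds.shape != (N_ROIS,):
            raise ValueError(f"baseline_mean/baseline_sd must have length {N_ROIS}")
        if np.any((means <= 0.5) | (means >= 5.5)):
            raise ValueError("baseline_mean values must lie in (0.5, 5.5) mm")
        if np.any(sds <= 0):
            raise ValueError("baseline_sd values must be > 0")
        object.__setattr__(self, "baseline_mean", tuple(means))
        object.__setattr__(self, "baseline_sd", tuple(sds))
        unknown = set(self.group_shift_rois) - set(names)
        if unknown:
            raise ValueError(f"group_shift_rois not in roi_names: {sorted(unknown)}")


@dataclass(frozen=True)
class MediationGroundTruth:
    """True path coefficients for the feature-level mediation test bed."""

    a_true: float = 0.5
    b_true: float = 0.4
    c_prime_true: float = 0.2
    noise_sd_mediator: float = 1.0
    noise_sd_outcome: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": -0.1, "education": 0.05}
    )

    def __post_init__(self) -> None:
        if self.noise_sd_mediator < 0:
            raise ValueError(f"noise_sd_mediator must be >= 0, got {self.noise_sd_mediator}")
        if self.noise_sd_outcome < 0:
            raise ValueError(f"noise_sd_outcome must be >= 0, got {self.noise_sd_outcome}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _practice_counts(rng: np.random.Generator, n: int, lo: int, hi: int) -> np.ndarray:
    """Right-skewed prior-exposure counts (geometric, p=0.5, clipped),
    reproducing a median of 0 over the 0-7 range."""
    return np.clip(rng.geometric(0.5, n) - 1 + lo, lo, hi)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort table (one row per subject).

    Columns: ``subject_id, adi (0 low / 1 high), age, sex (1 male /
    0 female), education_years, practice`` and the six cognitive scores.
    Deterministic for a fixed config seed; *seed* overrides the config's.
    """
    config = config or CohortConfig()
    root = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(root))
    sizes = (config.n_low_adi, config.n_high_adi)
    frames = []
    for group, n in enumerate(sizes):
        edu_mean, edu_sd = config.education_by_group[group]
        female = rng.random(n) < config.female_fraction_by_group[group]
        frames.append(pd.DataFrame({
            "adi": group,
            "age": rng.normal(config.age_mean, config.age_sd, n),
            "sex": (~female).astype(int),  # male = 1, female = 0
            "education_years": np.clip(rng.normal(edu_mean, edu_sd, n), 6.0, None),
            "practice": _practice_counts(rng, n, *config.practice_range),
        }))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(df))])
    for score in COGNITIVE_SCORES:
        m = config.score_models.get(score)
        if m is None:
            continue
        df[score] = (
            m.intercept
            + m.b_adi * df["adi"]
            + m.b_age * df["age"]
            + m.b_sex * df["sex"]
            + m.b_edu * df["education_years"]
            + m.b_practice * df["practice"]
            + rng.normal(0.0, m.sigma, len(df))
        )
    return df


def generate_subject_thickness(
    roi_spec: ROISpec,
    adi: int,
    subject_seed: int | np.random.SeedSequence | np.random.Generator,
    subject_id: str = "S0000",
) -> SubjectThickness:
    """Draw per-region vertex thickness vectors for one subject.

    Regions listed in ``roi_spec.group_shift_rois`` have their generating
    mean/SD offset when ``adi == 1``; all values are drawn from a Gaussian
    truncated below at ``roi_spec.truncation_mm`` so thickness stays
    positive.
    """
    if adi not in (0, 1):
        raise ValueError(f"adi must be 0 or 1, got {adi}")
    rng = (
        subject_seed
        if isinstance(subject_seed, np.random.Generator)
        else np.random.default_rng(subject_seed)
    )
    values: dict[str, np.ndarray] = {}
    for i, roi in enumerate(roi_spec.roi_names):
        mu = roi_spec.baseline_mean[i]
        sd = roi_spec.baseline_sd[i]
        if adi == 1 and roi in roi_spec.group_shift_rois:
            shift = roi_spec.group_shift_rois[roi]
            mu = mu + shift.loc_delta
            sd = sd * shift.scale_factor
        a = (roi_spec.truncation_mm - mu) / sd
        values[roi] = truncnorm.rvs(
            a, np.inf, loc=mu, scale=sd, size=roi_spec.vertex_counts[i],
            random_state=rng,
        )
    return SubjectThickness(subject_id, values)


def generate_cohort_thickness(
    cohort: pd.DataFrame,
    roi_spec: ROISpec | None = None,
    seed: int | None = 0,
) -> list[SubjectThickness]:
    """Thickness samples for every subject of a cohort table.

    Subjects get independent substreams spawned from the root *seed*, so
    any subset of subjects is reproducible in isolation.
    """
    roi_spec = roi_spec or ROISpec()
    streams = np.random.SeedSequence(seed).spawn(len(cohort))
    return [
        generate_subject_thickness(roi_spec, int(row.adi), ss, row.subject_id)
        for (_, row), ss in zip(cohort.iterrows(), streams)
    ]


def generate_mediation_dataset(
    n: int,
    truth: MediationGroundTruth | None = None,
    seed: int | None = 0,
    high_adi_fraction: float = 74 / 524,
) -> pd.DataFrame:
    """Feature-level mediation test bed with known path coefficients.

    ``M = a*ADI + covariates + noise`` and
    ``Y = c'*ADI + b*M + covariates + noise``, so the true indirect
    effect is ``a*b`` and the true total effect is ``c' + a*b``.
    Covariates (age, sex, education) enter both equations with the slopes
    in ``truth.covariate_effects``.
    """
    if n < 10:
        raise ValueError(f"n must be >= 10, got {n}")
    truth = truth or MediationGroundTruth()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    adi = (rng.random(n) < high_adi_fraction).astype(int)
    covs = {
        "age": rng.normal(62.96, 8.37, n),
        "sex": (rng.random(n) < 0.345).astype(int),
        "education": rng.normal(16.45, 2.43, n),
    }
    cov_term = sum(
        slope * covs[name] for name, slope in truth.covariate_effects.items()
    )
    if np.isscalar(cov_term):
        cov_term = np.zeros(n)
    m = truth.a_true * adi + cov_term + rng.normal(0, truth.noise_sd_mediator, n)
    y = (
        truth.c_prime_true * adi
        + truth.b_true * m
        + cov_term
        + rng.normal(0, truth.noise_sd_outcome, n)
    )
    return pd.DataFrame({"adi": adi, "mediator": m, "outcome": y, **covs})
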