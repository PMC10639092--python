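"""Cohort records and the synthetic-cohort configuration.

A cohort holds one record per subject: group membership (healthy control,
stroke without post-stroke epilepsy, stroke with post-stroke epilepsy),
demographics, lesion descriptors, anti-epileptic drug (AED) use and raw
cognitive test scores.  :func:`generate_cohort` draws a synthetic cohort
whose marginal structure mimics a young-stroke follow-up study: ages
centred near 49 years, all four lesion-side categories present, larger
lesions and more frequent AED use in the epilepsy group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataAlignmentError
from .parcellation import DEFAULT_HUB_REGIONS, DEFAULT_MODULES

GROUPS = ("control", "stroke_nopse", "stroke_pse")
STROKE_GROUPS = ("stroke_nopse", "stroke_pse")
LESION_SIDES = ("left", "right", "bilateral", "none")
SEXES = ("male", "female")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age_years: float
    sex: str
    lesion_side: str = "none"
    lesion_volume_ml: float = 0.0
    aed_use: bool = False
    raw_cognitive_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"group: unknown value {self.group!r}")
        if self.sex not in SEXES:
            raise ConfigurationError(f"sex: unknown value {self.sex!r}")
        if self.lesion_side not in LESION_SIDES:
            raise ConfigurationError(f"lesion_side: unknown value {self.lesion_side!r}")
        if self.lesion_volume_ml < 0:
            raise ConfigurationError("lesion_volume_ml: must be non-negative")
        if self.group == "control" and (
            self.lesion_side != "none" or self.lesion_volume_ml != 0
        ):
            raise ConfigurationError(
                "lesion_side/lesion_volume_ml: controls must have no lesion"
            )


class CohortTable:
    """Ordered collection of :class:`SubjectRecord` with unique ids."""

    def __init__(self, subjects: Sequence[SubjectRecord]):
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise DataAlignmentError("subject_ids must be unique")
        self.subjects: list[SubjectRecord] = list(subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __getitem__(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def group(self, *groups: str) -> "CohortTable":
        """Subset by group label(s), preserving order."""
        return CohortTable([s for s in self.subjects if s.group in groups])

    def copy(self) -> "CohortTable":
        return CohortTable([replace(s, raw_cognitive_scores=dict(s.raw_cognitive_scores))
                            for s in self.subjects])

    def to_frame(self) -> pd.DataFrame:
        """One row per subject; raw scores expanded as ``score_<test>``."""
        rows = []
        for s in self.subjects:
            row = asdict(s)
            scores = row.pop("raw_cognitive_scores")
            for test, value in scores.items():
                row[f"score_{test}"] = value
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        subjects = []
        score_cols = [c for c in frame.columns if c.startswith("score_")]
        for _, row in frame.iterrows():
            scores = {
                c[len("score_"):]: float(row[c])
                for c in score_cols
                if pd.notna(row[c])
            }
            subjects.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    age_years=float(row["age_years"]),
                    sex=str(row["sex"]),
                    lesion_side=str(row["lesion_side"]),
                    lesion_volume_ml=float(row["lesion_volume_ml"]),
                    aed_use=bool(row["aed_use"]),
                    raw_cognitive_scores=scores,
                )
            )
        return cls(subjects)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class SimulationConfig:
    """All tunables of the synthetic cohort generator.

    The defaults define the reference study conditions: three groups,
    repetition time 1.87 s, 200 retained volumes (plus 4 dummy volumes),
    block-modular resting-state covariance with strong hub-incident
    couplings, an interhemispheric connectivity reduction shared by both
    stroke groups (the canonical remote effect of a unilateral infarct),
    and an additional attenuation of contralesional default-mode hub
    edges concentrated in the epilepsy group (``pse_attenuation``), so
    the expected group ordering is PSE < no-PSE < controls.
    """

    n_per_group: int = 30
    t_volumes: int = 200
    tr_seconds: float = 1.87
    n_dummy_volumes: int = 4
    module_assignment: Mapping[str, int] | None = None  # region name -> community
    hub_regions: tuple[str, ...] = DEFAULT_HUB_REGIONS
    pse_attenuation: float = 0.3
    nopse_hub_fraction: float = 0.05  # noPSE hub attenuation as a fraction of pse_attenuation
    within_module_r: float = 0.15
    between_module_r: float = 0.02
    hub_gain: float = 0.70
    max_r: float = 0.85
    interhemispheric_attenuation: float = 0.20
    noise_sd: float = 0.05
    ar1_phi: float = 0.0
    cognition_beta: float = 0.47
    cognition_noise_sd: float = 0.88
    cognition_age_slope: float = -0.02
    lesion_side_probs: tuple[float, float, float, float] = (0.45, 0.45, 0.05, 0.05)
    age_mean: float = 49.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (18.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group: must be >= 1")
        if self.t_volumes < 50:
            raise ConfigurationError("t_volumes: must be >= 50")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds: must be > 0")
        if self.n_dummy_volumes < 0:
            raise ConfigurationError("n_dummy_volumes: must be >= 0")
        if not 0.0 <= self.pse_attenuation <= 1.0:
            raise ConfigurationError("pse_attenuation: must be in [0, 1]")
        if not 0.0 <= self.nopse_hub_fraction <= 1.0:
            raise ConfigurationError("nopse_hub_fraction: must be in [0, 1]")
        if not 0.0 <= self.interhemispheric_attenuation <= 1.0:
            raise ConfigurationError("interhemispheric_attenuation: must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ConfigurationError("ar1_phi: must be in [0, 1)")
        if self.cognition_noise_sd < 0:
            raise ConfigurationError("cognition_noise_sd: must be >= 0")
        probs = self.lesion_side_probs
        if len(probs) != 4 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                "lesion_side_probs: must be 4 non-negative values summing to 1"
            )
        if not -1e-12 < self.between_module_r <= self.within_module_r < 1:
            raise ConfigurationError(
                "within_module_r/between_module_r: need 0 <= between <= within < 1"
            )
        if self.hub_gain < 0:
            raise ConfigurationError("hub_gain: must be >= 0")
        if not 0 < self.max_r < 1:
            raise ConfigurationError("max_r: must be in (0, 1)")

    @property
    def modules(self) -> Mapping[str, int]:
        return self.module_assignment if self.module_assignment is not None else DEFAULT_MODULES


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG: the root seed plus integer stage/subject
    keys are fed to a :class:`numpy.random.SeedSequence` entropy list, so
    any subject/stage stream is reproducible independently of cohort size."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# stage codes for the seed fan-out (documented part of the scheme)
STAGE_COHORT = 1
STAGE_BOLD = 2
STAGE_COGNITION = 3


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a synthetic cohort: ``3 * n_per_group`` subjects.

    Ages are truncated-normal (mean 49, sd 10, clipped to [18, 70] by
    redrawing); sexes Bernoulli(0.5); stroke subjects get a lesion side
    from ``lesion_side_probs`` (left/right/bilateral/none) and a
    log-normal lesion volume whose scale is larger in the epilepsy group;
    AED use is frequent only in the epilepsy group.  Deterministic given
    the config seed.
    """
    rng = child_rng(config.seed, STAGE_COHORT)
    subjects: list[SubjectRecord] = []
    idx = 0
    for group in GROUPS:
        for _ in range(config.n_per_group):
            idx += 1
            age = float(rng.normal(config.age_mean, config.age_sd))
            lo, hi = config.age_range
            while not lo <= age <= hi:
                age = float(rng.normal(config.age_mean, config.age_sd))
            sex = SEXES[int(rng.integers(0, 2))]
            if group == "control":
                side, volume, aed = "none", 0.0, False
            else:
                side = LESION_SIDES[
                    int(rng.choice(4, p=np.asarray(config.lesion_side_probs)))
                ]
                if side == "none":
                    volume = 0.0
                else:
                    # log-normal volumes; epilepsy lesions are larger on average
                    mu = 3.7 if group == "stroke_pse" else 2.5
                    volume = float(np.exp(rng.normal(mu, 1.0)))
                p_aed = 0.57 if group == "stroke_pse" else 0.035
                aed = bool(rng.random() < p_aed)
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{idx:03d}",
                    group=group,
                    age_years=round(age, 2),
                    sex=sex,
                    lesion_side=side,
                    lesion_volume_ml=round(volume, 2),
                    aed_use=aed,
                )
            )
    return CohortTable(subjects)
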