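"""Synthetic BOLD cohort generator.

Each subject's resting-state signal is a multivariate normal draw from a
block-modular ground-truth correlation matrix (regions in the same
community correlate more strongly than regions in different communities).
Stroke groups carry two planted effects: a reduction of interhemispheric
coupling (the canonical remote effect of a unilateral infarct, shared by
both stroke groups) and an additional attenuation of the covariance
entries incident to default-mode hub nodes of the hemisphere
*contralateral* to the lesion, strong in the epilepsy group and weak
(``nopse_hub_fraction``) in the group without epilepsy.  Cognitive scores are
generated afterwards, with the processing-speed domain linearly coupled
to a supplied nodal network metric (by default the contralesional
precuneus) and all other domains pure noise.

No haemodynamic convolution is applied: every downstream stage consumes
only the second-order structure of the signal, so a plain (optionally
AR(1)-smoothed) Gaussian process suffices.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np

from .cleaning import ConfoundMatrix, TimeSeriesMatrix
from .cohort import (
    STAGE_BOLD,
    STAGE_COGNITION,
    CohortTable,
    SimulationConfig,
    SubjectRecord,
    child_rng,
)
from .exceptions import DataAlignmentError, InternalError
from .parcellation import Parcellation

CONFOUND_LABELS = (
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "wm_mean",
    "csf_mean",
)

#: Synthetic neuropsychological battery: (test name, domain, orientation).
#: Orientation +1 means higher raw score = better performance; -1 means
#: the test is scored in time/errors (higher = worse), exercising the
#: sign alignment of the Z-scoring step.
TEST_BATTERY: tuple[tuple[str, str, int], ...] = (
    ("symbol_digit", "processing_speed", +1),
    ("stroop_time", "processing_speed", -1),
    ("rey_copy", "visuoconstruction", +1),
    ("memory_scanning", "working_memory", +1),
    ("ravlt_immediate", "immediate_memory", +1),
    ("ravlt_delayed", "delayed_memory", +1),
    ("serial_attention", "attention", +1),
    ("verbal_fluency", "executive", +1),
)

COGNITIVE_DOMAINS = tuple(dict.fromkeys(d for _, d, _ in TEST_BATTERY))


def _attenuated_hemispheres(subject: SubjectRecord) -> tuple[str, ...]:
    """Hemisphere(s) whose hub edges are attenuated for this subject.

    The remote effect sits contralateral to the lesion; a bilateral
    lesion affects both hemispheres, and a stroke without a visible
    lesion has no modelled remote effect.
    """
    if subject.group == "control":
        return ()
    side = subject.lesion_side
    if side == "left":
        return ("right",)
    if side == "right":
        return ("left",)
    if side == "bilateral":
        return ("left", "right")
    return ()


def build_ground_truth_covariance(
    parcellation: Parcellation,
    subject: SubjectRecord,
    config: SimulationConfig,
    project: bool = True,
) -> np.ndarray:
    """Ground-truth correlation matrix for one subject.

    Block-modular base (within-module ``within_module_r``, between-module
    ``between_module_r``, unit diagonal) with a ``hub_gain`` bonus on
    every edge incident to a hub node — hubs are hubs precisely because
    their connections are strong — capped at ``max_r``.  Group
    attenuation multiplies the off-diagonal entries incident to
    *contralesional* hub nodes by ``(1 - attenuation)``; the result is
    projected to the nearest positive semi-definite matrix by eigenvalue
    clipping at zero and the unit diagonal is restored.
    """
    n = len(parcellation)
    modules = config.modules
    names = parcellation.names
    hemis = parcellation.hemispheres
    community = np.array([modules[name] for name in names])
    same = community[:, None] == community[None, :]
    cov = np.where(same, config.within_module_r, config.between_module_r).astype(float)
    is_hub = np.array([name in config.hub_regions for name in names])
    hub_incident = is_hub[:, None] | is_hub[None, :]
    if config.hub_gain > 0:
        cov = np.where(hub_incident, np.minimum(cov + config.hub_gain, config.max_r), cov)
    np.fill_diagonal(cov, 1.0)

    if (subject.group in ("stroke_pse", "stroke_nopse")
            and config.interhemispheric_attenuation > 0):
        # remote effect of the infarct shared by both stroke groups:
        # reduced interhemispheric coupling (the hub-specific epilepsy
        # effect is modelled separately below)
        left = np.array([h == "left" for h in hemis])
        cross = left[:, None] != left[None, :]
        cov = np.where(cross, cov * (1.0 - config.interhemispheric_attenuation), cov)

    if subject.group == "stroke_pse":
        attenuation = config.pse_attenuation
    elif subject.group == "stroke_nopse":
        attenuation = config.nopse_hub_fraction * config.pse_attenuation
    else:
        attenuation = 0.0
    target_hemis = _attenuated_hemispheres(subject)
    if attenuation > 0 and target_hemis:
        hub_mask = np.array(
            [name in config.hub_regions and hemi in target_hemis
             for name, hemi in zip(names, hemis)]
        )
        incident = hub_mask[:, None] | hub_mask[None, :]
        np.fill_diagonal(incident, False)
        cov = np.where(incident, cov * (1.0 - attenuation), cov)

    if not project:  # raw planted structure, for inspection and tests
        return cov

    # project to the PSD cone, then restore the unit diagonal
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    cov = (evecs * evals) @ evecs.T
    cov = (cov + cov.T) / 2.0
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise InternalError("degenerate diagonal after PSD projection")
    cov = cov / np.outer(d, d)
    np.fill_diagonal(cov, 1.0)
    if np.linalg.eigvalsh(cov).min() < -1e-10:
        raise InternalError("covariance not PSD after projection")
    return cov


def covariance_factor(cov: np.ndarray) -> np.ndarray:
    """A factor L with L L^T = cov, valid for singular PSD matrices.

    Precompute once per distinct covariance and pass to
    :func:`simulate_bold` when simulating many subjects.
    """
    evals, evecs = np.linalg.eigh(cov)
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_bold(
    subject: SubjectRecord,
    covariance: np.ndarray,
    config: SimulationConfig,
    parcellation: Parcellation,
    subject_index: int = 0,
    factor: np.ndarray | None = None,
) -> tuple[TimeSeriesMatrix, ConfoundMatrix]:
    """Simulate one subject's parcellated BOLD run plus confounds.

    Returns ``t_volumes + n_dummy_volumes`` rows (the extra leading rows
    emulate the pre-steady-state dummy volumes removed by the cleaning
    stage).  Per-node variance is 1 before white measurement noise of sd
    ``noise_sd`` is added.  The confound matrix has 8 base regressors:
    six rigid-body motion traces plus mean white-matter and mean CSF
    signals, all independent of the neural signal.
    """
    rng = child_rng(config.seed, STAGE_BOLD, subject_index)
    t_total = config.t_volumes + config.n_dummy_volumes
    n = covariance.shape[0]
    if factor is None:
        factor = covariance_factor(covariance)
    z = rng.standard_normal((t_total, n))
    if config.ar1_phi > 0:
        phi = config.ar1_phi
        innovations = z * np.sqrt(1.0 - phi**2)
        innovations[0] = z[0]  # stationary start
        out = np.empty_like(innovations)
        out[0] = innovations[0]
        for t in range(1, t_total):
            out[t] = phi * out[t - 1] + innovations[t]
        z = out
    x = z @ factor.T
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)

    # slow drifting motion traces plus noisier tissue means
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(t_total, 6)), axis=0)
    motion += rng.normal(0.0, 0.01, size=motion.shape)
    tissue = 0.5 * np.cumsum(rng.normal(0.0, 0.05, size=(t_total, 2)), axis=0)
    tissue += rng.normal(0.0, 0.2, size=tissue.shape)
    confounds = ConfoundMatrix(np.hstack([motion, tissue]), CONFOUND_LABELS)

    ts = TimeSeriesMatrix(x, config.tr_seconds, tuple(parcellation.labels))
    return ts, confounds


def generate_cognition(
    cohort: CohortTable,
    true_nodal_metric: Mapping[str, float],
    config: SimulationConfig,
) -> CohortTable:
    """Fill raw cognitive scores, coupling processing speed to a metric.

    The processing-speed ability of subject *i* is

        a_i = beta * z(metric_i) + age_slope * (age_i - age_mean) + eps_i

    with ``eps ~ N(0, cognition_noise_sd)`` and ``z`` the across-cohort
    standardization of the supplied nodal metric.  Each processing-speed
    test records ``a_i`` with its orientation sign; every other domain's
    test is an independent standard-normal draw.
    """
    missing = [s.subject_id for s in cohort if s.subject_id not in true_nodal_metric]
    if missing:
        raise DataAlignmentError(
            f"no nodal metric supplied for subjects {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    rng = child_rng(config.seed, STAGE_COGNITION)
    metric = np.array([float(true_nodal_metric[s.subject_id]) for s in cohort])
    sd = metric.std()
    z_metric = (metric - metric.mean()) / sd if sd > 0 else np.zeros_like(metric)

    new_subjects = []
    for z_m, subject in zip(z_metric, cohort):
        eps = rng.normal(0.0, config.cognition_noise_sd) if config.cognition_noise_sd > 0 else 0.0
        ability = (
            config.cognition_beta * z_m
            + config.cognition_age_slope * (subject.age_years - config.age_mean)
            + eps
        )
        scores: dict[str, float] = {}
        for test, domain, sign in TEST_BATTERY:
            if domain == "processing_speed":
                scores[test] = sign * ability
            else:
                scores[test] = sign * float(rng.normal(0.0, 1.0))
        new_subjects.append(replace(subject, raw_cognitive_scores=scores))
    return CohortTable(new_subjects)
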