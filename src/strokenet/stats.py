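"""Group-level inference: cognitive Z-scoring and impairment, ANCOVA on
global network metrics, contralesional regional mass-univariate models
with Benjamini-Hochberg FDR, chi-square impairment comparisons, and the
metric-to-cognition regression.

Coding conventions: sex enters models as a male indicator; the group
contrast is coded with the stroke-without-epilepsy group as reference so
the group coefficient is the PSE effect; cognitive impairment means a
domain Z-score more than 1.5 SD below the control mean after aligning
every test so that lower = worse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from .cohort import CohortTable, STROKE_GROUPS
from .exceptions import (
    DataAlignmentError,
    DegenerateInputError,
    DesignMatrixError,
)
from .parcellation import Parcellation
from .simulate import COGNITIVE_DOMAINS, TEST_BATTERY

log = logging.getLogger(__name__)

IMPAIRMENT_THRESHOLD = -1.5

DEFAULT_TEST_DOMAINS: dict[str, str] = {test: domain for test, domain, _ in TEST_BATTERY}
DEFAULT_TEST_SIGNS: dict[str, int] = {test: sign for test, _, sign in TEST_BATTERY}


@dataclass
class GroupTestResult:
    """One model term: estimate, uncertainty, test statistic, p-values."""

    term: str
    estimate: float
    se: float
    statistic: float
    p: float
    ci_low: float
    ci_high: float
    p_fdr: float | None = None
    n: int = 0
    warning: str | None = None


@dataclass(frozen=True)
class DomainZScores:
    """Per-subject, per-domain cognitive Z-scores and impairment flags."""

    z: pd.DataFrame = field(repr=False)  # subjects x domains
    impaired: pd.DataFrame = field(repr=False)  # same shape, boolean


def cognitive_z_scores(
    cohort: CohortTable,
    test_domains: Mapping[str, str] | None = None,
    test_signs: Mapping[str, int] | None = None,
    age_adjust: bool = False,
) -> DomainZScores:
    """Convert raw test scores to control-referenced domain Z-scores.

    Each test is standardized against the control group's mean and SD,
    multiplied by its orientation sign so that lower always means worse,
    and tests of the same domain are averaged (missing tests ignored,
    with a log of how many were missing).  With ``age_adjust`` the
    control mean and SD are taken within decade age bands.
    """
    test_domains = dict(test_domains or DEFAULT_TEST_DOMAINS)
    test_signs = dict(test_signs or DEFAULT_TEST_SIGNS)
    controls = [s for s in cohort if s.group == "control"]
    if len(controls) < 2:
        raise DegenerateInputError("need at least 2 controls to standardize scores")

    def age_band(age: float) -> int:
        return int(age // 10) if age_adjust else 0

    # control reference per (test, band)
    reference: dict[tuple[str, int], tuple[float, float]] = {}
    for test in test_domains:
        bands: dict[int, list[float]] = {}
        for s in controls:
            if test in s.raw_cognitive_scores:
                bands.setdefault(age_band(s.age_years), []).append(
                    s.raw_cognitive_scores[test]
                )
        for band, values in bands.items():
            if len(values) < 2:
                continue
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1))
            if sd == 0:
                raise DegenerateInputError(
                    f"control SD is zero for test {test!r}; cannot standardize"
                )
            reference[(test, band)] = (mean, sd)

    pooled: dict[str, tuple[float, float]] = {}
    for test in test_domains:
        values = [
            s.raw_cognitive_scores[test]
            for s in controls
            if test in s.raw_cognitive_scores
        ]
        if len(values) >= 2:
            sd = float(np.std(values, ddof=1))
            if sd == 0:
                raise DegenerateInputError(
                    f"control SD is zero for test {test!r}; cannot standardize"
                )
            pooled[test] = (float(np.mean(values)), sd)

    n_missing = 0
    rows = {}
    for s in cohort:
        domain_parts: dict[str, list[float]] = {d: [] for d in COGNITIVE_DOMAINS}
        for test, domain in test_domains.items():
            raw = s.raw_cognitive_scores.get(test)
            if raw is None:
                n_missing += 1
                continue
            ref = reference.get((test, age_band(s.age_years))) or pooled.get(test)
            if ref is None:
                continue
            mean, sd = ref
            z = test_signs.get(test, 1) * (raw - mean) / sd
            domain_parts.setdefault(domain, []).append(z)
        rows[s.subject_id] = {
            d: (float(np.mean(v)) if v else np.nan) for d, v in domain_parts.items()
        }
    if n_missing:
        log.info("%d missing test scores ignored during Z-scoring", n_missing)
    z = pd.DataFrame.from_dict(rows, orient="index")
    z.index.name = "subject_id"
    impaired = z < IMPAIRMENT_THRESHOLD
    impaired = impaired.where(z.notna(), other=False)
    return DomainZScores(z=z, impaired=impaired)


def impairment_table(dz: DomainZScores, cohort: CohortTable) -> pd.DataFrame:
    """Per (domain, group): impaired count, denominator, percentage.

    The denominator counts subjects with a non-missing domain score.
    """
    group_of = {s.subject_id: s.group for s in cohort}
    rows = []
    for domain in dz.z.columns:
        have = dz.z[domain].notna()
        for group in sorted({*group_of.values()}):
            ids = [sid for sid in dz.z.index if group_of.get(sid) == group]
            ids = [sid for sid in ids if have.loc[sid]]
            n_impaired = int(dz.impaired.loc[ids, domain].sum())
            rows.append(
                {
                    "domain": domain,
                    "group": group,
                    "impaired": n_impaired,
                    "total": len(ids),
                    "pct": 100.0 * n_impaired / len(ids) if ids else np.nan,
                }
            )
    return pd.DataFrame(rows)


def chi_square_2x2(counts, yates: bool = False) -> GroupTestResult:
    """Pearson chi-square on a 2x2 table (no continuity correction by
    default; ``yates`` applies it)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise DataAlignmentError("need a 2x2 table of non-negative counts")
    if table.sum() < 1:
        raise DegenerateInputError("empty table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateInputError("a zero marginal makes the chi-square undefined")
    n = table.sum()
    expected = np.outer(row, col) / n
    diff = np.abs(table - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sstats.chi2.sf(stat, df=1))
    return GroupTestResult(
        term="group",
        estimate=stat,
        se=np.nan,
        statistic=stat,
        p=p,
        ci_low=np.nan,
        ci_high=np.nan,
        n=int(n),
    )


def _ols_term(y: np.ndarray, design: pd.DataFrame, term: str, n_label: int | None = None) -> GroupTestResult:
    x = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy(float))
    if rank < x.shape[1]:
        raise DesignMatrixError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]})"
        )
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int().loc[term]
    return GroupTestResult(
        term=term,
        estimate=float(fit.params[term]),
        se=float(fit.bse[term]),
        statistic=float(fit.tvalues[term]),
        p=float(fit.pvalues[term]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        n=n_label if n_label is not None else int(fit.nobs),
    )


def _covariate_frame(subjects) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_years": [s.age_years for s in subjects],
            "sex_male": [1.0 if s.sex == "male" else 0.0 for s in subjects],
        },
        index=[s.subject_id for s in subjects],
    )


def ancova_global(
    metric_values: Mapping[str, float],
    cohort: CohortTable,
    contrast: tuple[str, str] = ("stroke_nopse", "stroke_pse"),
) -> GroupTestResult:
    """ANCOVA of one global metric: ``metric ~ group + age + sex``.

    ``contrast`` is (reference, comparison); the returned term is the
    comparison-group effect.
    """
    ref, comp = contrast
    subjects = [s for s in cohort if s.group in contrast]
    for g in contrast:
        if sum(s.group == g for s in subjects) < 3:
            raise DegenerateInputError(f"need at least 3 subjects in group {g!r}")
    missing = [s.subject_id for s in subjects if s.subject_id not in metric_values]
    if missing:
        raise DataAlignmentError(f"metric missing for subjects {missing[:5]}")
    design = _covariate_frame(subjects)
    design.insert(0, "group", [1.0 if s.group == comp else 0.0 for s in subjects])
    y = np.array([float(metric_values[s.subject_id]) for s in subjects])
    return _ols_term(y, design, "group")


def contralesional_nodes(parcellation: Parcellation, subject) -> list[int]:
    """Node ids of the hemisphere opposite the subject's lesion."""
    if subject.lesion_side == "left":
        return parcellation.hemisphere_nodes("right")
    if subject.lesion_side == "right":
        return parcellation.hemisphere_nodes("left")
    raise DegenerateInputError(
        f"subject {subject.subject_id}: lesion_side={subject.lesion_side!r} has no "
        "contralesional hemisphere (excluded from regional analysis)"
    )


def apply_regional_exclusions(cohort: CohortTable) -> tuple[CohortTable, dict]:
    """Drop stroke subjects with a bilateral lesion or no lesion.

    Returns the retained subset (stroke subjects with a unilateral
    lesion) and an exclusion log whose counts always reconcile with the
    input size.
    """
    stroke = [s for s in cohort if s.group in STROKE_GROUPS]
    retained = [s for s in stroke if s.lesion_side in ("left", "right")]
    excluded = [s for s in stroke if s.lesion_side not in ("left", "right")]
    exclusion_log = {
        "input": len(stroke),
        "retained": len(retained),
        "excluded_bilateral": sum(s.lesion_side == "bilateral" for s in excluded),
        "excluded_no_lesion": sum(s.lesion_side == "none" for s in excluded),
        "excluded_ids": [s.subject_id for s in excluded],
    }
    assert exclusion_log["retained"] + len(excluded) == exclusion_log["input"]
    return CohortTable(retained), exclusion_log


def contralesional_regional_table(
    nodal_auc: Mapping[str, pd.DataFrame],
    parcellation: Parcellation,
    cohort: CohortTable,
    metrics: Sequence[str] = ("clustering_coefficient", "local_efficiency", "nodal_efficiency"),
) -> pd.DataFrame:
    """Tidy per-subject regional table on the contralesional hemisphere.

    ``nodal_auc`` maps subject_id to a (node_label x metric) frame of
    AUC-integrated nodal metrics computed on the whole network.  Left and
    right homologues share a region name so subjects with opposite lesion
    sides enter one per-region model.
    """
    labels = parcellation.labels
    names = parcellation.names
    rows = []
    for s in cohort:
        if s.subject_id not in nodal_auc:
            raise DataAlignmentError(f"no nodal metrics for subject {s.subject_id}")
        node_ids = contralesional_nodes(parcellation, s)
        frame = nodal_auc[s.subject_id]
        for nid in node_ids:
            label = labels[nid]
            if label not in frame.index:
                raise DataAlignmentError(
                    f"node label {label!r} missing from metrics of {s.subject_id}"
                )
            for metric in metrics:
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "region": names[nid],
                        "metric": metric,
                        "value": float(frame.loc[label, metric]),
                    }
                )
    return pd.DataFrame(rows)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejections.

    Adjusted p_(i) = min_{j >= i} m * p_(j) / j (capped at 1); reject
    where the adjusted value is <= q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or np.any((p < 0) | (p > 1)):
        raise DataAlignmentError("p-values must be a 1-D array in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def regional_mass_univariate(
    regional_table: pd.DataFrame,
    cohort: CohortTable,
    model: int = 1,
    fdr_q: float = 0.05,
    contrast: tuple[str, str] = ("stroke_nopse", "stroke_pse"),
) -> pd.DataFrame:
    """Per-region, per-metric linear models with BH-FDR per metric family.

    Model 1 adjusts for age and sex; Model 2 additionally for lesion
    volume.  Returns a tidy frame (metric, region, estimate, se, t, p,
    p_fdr, reject) where p-values of all regions of one metric form one
    FDR family.
    """
    if model not in (1, 2):
        raise DataAlignmentError("model must be 1 or 2")
    ref, comp = contrast
    subjects = {s.subject_id: s for s in cohort if s.group in contrast}
    table = regional_table[regional_table["subject_id"].isin(subjects)]
    if table.empty:
        raise DataAlignmentError("regional table has no subjects in the contrast")
    results = []
    for metric, metric_frame in table.groupby("metric", sort=True):
        family: list[dict] = []
        for region, region_frame in metric_frame.groupby("region", sort=True):
            subs = [subjects[sid] for sid in region_frame["subject_id"]]
            n_comp = sum(s.group == comp for s in subs)
            n_ref = sum(s.group == ref for s in subs)
            if n_comp < 3 or n_ref < 3:
                log.warning(
                    "region %s/%s skipped: fewer than 3 subjects per group", region, metric
                )
                continue
            design = _covariate_frame(subs)
            design.insert(0, "group", [1.0 if s.group == comp else 0.0 for s in subs])
            if model == 2:
                design["lesion_volume_ml"] = [s.lesion_volume_ml for s in subs]
            y = region_frame["value"].to_numpy(float)
            res = _ols_term(y, design, "group")
            family.append(
                {
                    "metric": metric,
                    "region": region,
                    "model": model,
                    "estimate": res.estimate,
                    "se": res.se,
                    "statistic": res.statistic,
                    "p": res.p,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": res.n,
                }
            )
        if not family:
            continue
        adjusted, reject = bh_fdr([f["p"] for f in family], q=fdr_q)
        for f, p_adj, rej in zip(family, adjusted, reject):
            f["p_fdr"] = float(p_adj)
            f["reject_fdr"] = bool(rej)
        results.extend(family)
    return pd.DataFrame(results)


def predict_cognition(
    dz: DomainZScores,
    regional_table: pd.DataFrame,
    cohort: CohortTable,
    region: str,
    metric: str,
    domain: str = "processing_speed",
    groups: tuple[str, ...] = ("stroke_pse",),
) -> GroupTestResult:
    """Regress a cognitive domain Z-score on a regional network metric.

    Model: ``z_domain ~ metric_z + age + sex + AED`` on the requested
    group(s) (default: the epilepsy group).  The metric is standardized
    so the reported coefficient is a standardized beta.  Fewer than 5
    usable subjects triggers a warning flag on the result rather than an
    error.
    """
    subjects = [s for s in cohort if s.group in groups]
    values = regional_table[
        (regional_table["region"] == region) & (regional_table["metric"] == metric)
    ].set_index("subject_id")["value"]
    rows = []
    for s in subjects:
        if s.subject_id not in values.index or s.subject_id not in dz.z.index:
            continue
        z_val = dz.z.loc[s.subject_id, domain]
        if pd.isna(z_val):
            continue
        rows.append(
            {
                "subject_id": s.subject_id,
                "y": float(z_val),
                "metric": float(values.loc[s.subject_id]),
                "age_years": s.age_years,
                "sex_male": 1.0 if s.sex == "male" else 0.0,
                "aed": 1.0 if s.aed_use else 0.0,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame) < 3:
        raise DegenerateInputError(
            f"only {len(frame)} usable subjects for the cognition regression"
        )
    sd = frame["metric"].std(ddof=0)
    if sd == 0:
        raise DegenerateInputError(
            f"metric {metric!r} of region {region!r} has zero variance"
        )
    frame["metric"] = (frame["metric"] - frame["metric"].mean()) / sd
    design = frame[["metric", "age_years", "sex_male", "aed"]]
    # drop constant covariates (e.g. nobody on AED) instead of failing
    keep = [c for c in design.columns if design[c].nunique() > 1 or c == "metric"]
    result = _ols_term(frame["y"].to_numpy(), design[keep], "metric")
    if len(frame) < 5:
        result.warning = f"only {len(frame)} subjects; estimates unstable"
        log.warning(result.warning)
    return result
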