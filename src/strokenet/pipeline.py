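"""End-to-end orchestration: simulate -> clean -> connectome -> metrics
-> stats, driven by one config with a single root seed.

Every stage writes its outputs to disk so each stage can be re-run and
audited independently; a run manifest records the config snapshot,
per-stage subject counts and a checksum of every written file.  The root
seed fans out to per-subject, per-stage child seeds through a
SeedSequence entropy list (see :func:`strokenet.cohort.child_rng`), so a
subject's data do not depend on cohort size or ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cleaning import ConfoundMatrix, TimeSeriesMatrix, clean_timeseries
from .cohort import CohortTable, SimulationConfig, generate_cohort
from .connectome import ConnectivityMatrix, build_connectome, density_grid
from .exceptions import ConfigurationError, DegenerateInputError, StrokenetError
from .metrics import (
    compute_all_metrics,
    metrics_at_density,
    subject_modularity_seed,
)
from .parcellation import Parcellation, make_default_parcellation
from .simulate import (
    build_ground_truth_covariance,
    covariance_factor,
    generate_cognition,
    simulate_bold,
)
from .stats import (
    ancova_global,
    apply_regional_exclusions,
    cognitive_z_scores,
    contralesional_regional_table,
    impairment_table,
    predict_cognition,
    regional_mass_univariate,
)

log = logging.getLogger(__name__)


@dataclass
class CleaningParams:
    drop_volumes: int = 4
    low_hz: float = 0.01
    high_hz: float = 0.08
    order: int = 2
    add_global_signal: bool = False


@dataclass
class ConnectomeParams:
    d_min: float = 0.05
    d_max: float = 0.40
    step: float = 0.05


@dataclass
class MetricsParams:
    n_restarts: int = 10
    local_variant: str = "subgraph"
    cognition_region: str = "precuneus"
    cognition_metric: str = "clustering_coefficient"


@dataclass
class StatsParams:
    fdr_q: float = 0.05
    cognition_domain: str = "processing_speed"


def _from_dict(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{section}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    run_id: str = "demo"
    seed: int = 0
    output_dir: str = "strokenet_run"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    clean: CleaningParams = field(default_factory=CleaningParams)
    connectome: ConnectomeParams = field(default_factory=ConnectomeParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def __post_init__(self) -> None:
        # the pipeline's root seed is authoritative for every stage
        self.simulate = dataclasses.replace(self.simulate, seed=self.seed)

    def to_dict(self) -> dict:
        data = {
            "run_id": self.run_id,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "simulate": dataclasses.asdict(self.simulate),
            "clean": dataclasses.asdict(self.clean),
            "connectome": dataclasses.asdict(self.connectome),
            "metrics": dataclasses.asdict(self.metrics),
            "stats": dataclasses.asdict(self.stats),
        }
        data["simulate"].pop("seed")  # derived from the root seed
        for key in ("hub_regions", "lesion_side_probs", "age_range"):
            data["simulate"][key] = list(data["simulate"][key])
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        top_known = {"run_id", "seed", "output_dir", "simulate", "clean",
                     "connectome", "metrics", "stats"}
        unknown = set(data) - top_known
        if unknown:
            raise ConfigurationError(f"config: unknown keys {sorted(unknown)}")
        sim = dict(data.pop("simulate", {}))
        sim.pop("seed", None)
        for key in ("hub_regions", "lesion_side_probs", "age_range"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        if sim.get("module_assignment") is not None:
            sim["module_assignment"] = dict(sim["module_assignment"])
        return cls(
            run_id=data.pop("run_id", "demo"),
            seed=int(data.pop("seed", 0)),
            output_dir=str(data.pop("output_dir", "strokenet_run")),
            simulate=_from_dict(SimulationConfig, sim, "simulate"),
            clean=_from_dict(CleaningParams, dict(data.pop("clean", {})), "clean"),
            connectome=_from_dict(
                ConnectomeParams, dict(data.pop("connectome", {})), "connectome"
            ),
            metrics=_from_dict(MetricsParams, dict(data.pop("metrics", {})), "metrics"),
            stats=_from_dict(StatsParams, dict(data.pop("stats", {})), "stats"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def demo_config(output_dir: str = "strokenet_demo", seed: int = 0) -> PipelineConfig:
    """A small configuration that exercises every stage in seconds."""
    return PipelineConfig(
        run_id="demo",
        seed=seed,
        output_dir=output_dir,
        simulate=SimulationConfig(n_per_group=5, t_volumes=100),
    )


class PipelineError(StrokenetError):
    """A stage failed; the message names the stage (and subject)."""


def _stage(stage_name: str, subject_id: str | None = None):
    """Context manager decorating stage exceptions with their location."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                where = stage_name if subject_id is None else f"{stage_name}/{subject_id}"
                raise PipelineError(f"stage {where}: {exc}") from exc
            return False

    return _Ctx()


def _tr(config: PipelineConfig) -> float:
    return config.simulate.tr_seconds


def stage_simulate(config: PipelineConfig, out: Path) -> CohortTable:
    """Generate and write parcellation, cohort manifest and BOLD runs."""
    parc = make_default_parcellation()
    out.mkdir(parents=True, exist_ok=True)
    parc.to_csv(out / "parcellation.csv")
    with _stage("simulate"):
        cohort = generate_cohort(config.simulate)
        cohort.to_csv(out / "cohort.csv")
    bold_dir = out / "bold"
    bold_dir.mkdir(exist_ok=True)
    factors: dict[bytes, np.ndarray] = {}
    for index, subject in enumerate(cohort):
        with _stage("simulate", subject.subject_id):
            cov = build_ground_truth_covariance(parc, subject, config.simulate)
            key = hashlib.sha256(cov.tobytes()).digest()
            if key not in factors:
                factors[key] = covariance_factor(cov)
            ts, confounds = simulate_bold(
                subject, cov, config.simulate, parc, subject_index=index,
                factor=factors[key],
            )
            ts.to_tsv(bold_dir / f"{subject.subject_id}_bold.tsv")
            confounds.to_tsv(bold_dir / f"{subject.subject_id}_confounds.tsv")
    return cohort


def stage_clean(config: PipelineConfig, out: Path) -> None:
    cohort = CohortTable.from_csv(out / "cohort.csv")
    cleaned_dir = out / "cleaned"
    cleaned_dir.mkdir(exist_ok=True)
    for subject in cohort:
        with _stage("clean", subject.subject_id):
            ts = TimeSeriesMatrix.from_tsv(
                out / "bold" / f"{subject.subject_id}_bold.tsv", _tr(config)
            )
            confounds = ConfoundMatrix.from_tsv(
                out / "bold" / f"{subject.subject_id}_confounds.tsv"
            )
            cleaned = clean_timeseries(
                ts,
                confounds,
                drop_volumes=config.clean.drop_volumes,
                low_hz=config.clean.low_hz,
                high_hz=config.clean.high_hz,
                order=config.clean.order,
                add_global_signal=config.clean.add_global_signal,
            )
            cleaned.to_tsv(cleaned_dir / f"{subject.subject_id}_cleaned.tsv")


def stage_connectome(config: PipelineConfig, out: Path) -> None:
    cohort = CohortTable.from_csv(out / "cohort.csv")
    conn_dir = out / "connectome"
    conn_dir.mkdir(exist_ok=True)
    for subject in cohort:
        with _stage("connectome", subject.subject_id):
            ts = TimeSeriesMatrix.from_tsv(
                out / "cleaned" / f"{subject.subject_id}_cleaned.tsv", _tr(config)
            )
            fc, net_set = build_connectome(
                ts,
                d_min=config.connectome.d_min,
                d_max=config.connectome.d_max,
                step=config.connectome.step,
            )
            fc.to_tsv(conn_dir / f"{subject.subject_id}_fc.tsv")
            for density, adj in zip(net_set.densities, net_set.adjacencies):
                ConnectivityMatrix(adj, fc.node_labels).to_tsv(
                    conn_dir / f"{subject.subject_id}_density-{density:.2f}.tsv"
                )


def stage_metrics(config: PipelineConfig, out: Path) -> None:
    """Graph metrics per subject, then synthetic cognition coupled to the
    configured regional metric (contralesional where defined)."""
    from .connectome import ThresholdedNetworkSet

    cohort = CohortTable.from_csv(out / "cohort.csv")
    parc = Parcellation.from_csv(out / "parcellation.csv")
    metrics_dir = out / "metrics"
    nodal_dir = metrics_dir / "nodal"
    nodal_dir.mkdir(parents=True, exist_ok=True)
    densities = density_grid(
        config.connectome.d_min, config.connectome.d_max, config.connectome.step
    )
    tidy_frames = []
    global_rows = {}
    nodal_auc: dict[str, pd.DataFrame] = {}
    for subject in cohort:
        with _stage("metrics", subject.subject_id):
            adjacencies = tuple(
                ConnectivityMatrix.from_tsv(
                    out / "connectome" / f"{subject.subject_id}_density-{d:.2f}.tsv"
                ).weights
                for d in densities
            )
            net_set = ThresholdedNetworkSet(
                densities, adjacencies, tuple(parc.labels)
            )
            result = compute_all_metrics(
                net_set,
                modularity_seed=subject_modularity_seed(subject.subject_id),
                n_restarts=config.metrics.n_restarts,
                local_variant=config.metrics.local_variant,
            )
            tidy_frames.append(result.to_tidy(subject.subject_id))
            global_rows[subject.subject_id] = result.global_auc
            nodal_auc[subject.subject_id] = result.nodal_auc
            result.nodal_auc.to_csv(nodal_dir / f"{subject.subject_id}.csv")
    pd.concat(tidy_frames, ignore_index=True).to_csv(
        metrics_dir / "metrics.csv", index=False
    )
    pd.DataFrame(global_rows).T.rename_axis("subject_id").to_csv(
        metrics_dir / "global_auc.csv"
    )

    with _stage("metrics"):
        metric_per_subject = _cognition_target_metric(
            nodal_auc, parc, cohort,
            config.metrics.cognition_region, config.metrics.cognition_metric,
        )
        cohort = generate_cognition(cohort, metric_per_subject, config.simulate)
        cohort.to_csv(out / "cohort.csv")


def _cognition_target_metric(
    nodal_auc: dict[str, pd.DataFrame],
    parc: Parcellation,
    cohort: CohortTable,
    region: str,
    metric: str,
) -> dict[str, float]:
    """Per-subject value of a regional metric: the contralesional node
    where a unilateral lesion defines one, otherwise the bilateral mean."""
    labels = parc.labels
    values = {}
    for subject in cohort:
        frame = nodal_auc[subject.subject_id]
        if subject.lesion_side in ("left", "right"):
            opposite = "right" if subject.lesion_side == "left" else "left"
            node_ids = [parc.node_id(region, opposite)]
        else:
            node_ids = parc.nodes_named(region)
        values[subject.subject_id] = float(
            np.mean([frame.loc[labels[nid], metric] for nid in node_ids])
        )
    return values


def stage_stats(config: PipelineConfig, out: Path) -> dict:
    cohort = CohortTable.from_csv(out / "cohort.csv")
    parc = Parcellation.from_csv(out / "parcellation.csv")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    global_auc = pd.read_csv(out / "metrics" / "global_auc.csv", index_col="subject_id")
    nodal_auc = {
        s.subject_id: pd.read_csv(
            out / "metrics" / "nodal" / f"{s.subject_id}.csv", index_col="node_label"
        )
        for s in cohort
    }
    counts: dict = {"n_subjects": len(cohort)}

    with _stage("stats"):
        dz = cognitive_z_scores(cohort)
        imp = impairment_table(dz, cohort)
        imp.to_csv(stats_dir / "impairment.csv", index=False)

        ancova_rows = []
        for metric in global_auc.columns:
            values = global_auc[metric].to_dict()
            for contrast in (("stroke_nopse", "stroke_pse"), ("control", "stroke_nopse")):
                try:
                    res = ancova_global(values, cohort, contrast=contrast)
                except DegenerateInputError as exc:
                    log.warning("ANCOVA %s %s skipped: %s", metric, contrast, exc)
                    continue
                ancova_rows.append(
                    {
                        "metric": metric,
                        "contrast": f"{contrast[1]}_vs_{contrast[0]}",
                        "estimate": res.estimate,
                        "se": res.se,
                        "t": res.statistic,
                        "p": res.p,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n": res.n,
                    }
                )
        ancova = pd.DataFrame(ancova_rows)
        ancova.to_csv(stats_dir / "global_ancova.csv", index=False)

        regional_cohort, exclusion_log = apply_regional_exclusions(cohort)
        counts["regional_retained"] = exclusion_log["retained"]
        counts["regional_excluded_bilateral"] = exclusion_log["excluded_bilateral"]
        counts["regional_excluded_no_lesion"] = exclusion_log["excluded_no_lesion"]
        regional_results = {}
        if exclusion_log["retained"] >= 6:
            regional = contralesional_regional_table(nodal_auc, parc, regional_cohort)
            for model in (1, 2):
                try:
                    frame = regional_mass_univariate(
                        regional, regional_cohort, model=model, fdr_q=config.stats.fdr_q
                    )
                except DegenerateInputError as exc:
                    log.warning("regional model %d skipped: %s", model, exc)
                    continue
                frame.to_csv(stats_dir / f"regional_model{model}.csv", index=False)
                regional_results[model] = frame
            try:
                res = predict_cognition(
                    dz,
                    regional,
                    regional_cohort,
                    region=config.metrics.cognition_region,
                    metric=config.metrics.cognition_metric,
                    domain=config.stats.cognition_domain,
                )
                pd.DataFrame(
                    [
                        {
                            "region": config.metrics.cognition_region,
                            "metric": config.metrics.cognition_metric,
                            "domain": config.stats.cognition_domain,
                            "beta": res.estimate,
                            "se": res.se,
                            "t": res.statistic,
                            "p": res.p,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "n": res.n,
                            "warning": res.warning or "",
                        }
                    ]
                ).to_csv(stats_dir / "cognition_regression.csv", index=False)
            except DegenerateInputError as exc:
                log.warning("cognition regression skipped: %s", exc)
        else:
            log.warning("too few unilateral stroke subjects for regional analysis")

        _write_summary(stats_dir / "summary.md", cohort, imp, ancova, counts)
    return counts


def _write_summary(path: Path, cohort, impairment, ancova, counts) -> None:
    lines = ["# Run summary", "", f"Subjects: {len(cohort)}", ""]
    lines.append("## Global ANCOVA (AUC-integrated metrics)")
    if len(ancova):
        lines.append(ancova.to_string(index=False))
    lines.append("")
    lines.append("## Cognitive impairment by group")
    lines.append(impairment.to_string(index=False))
    lines.append("")
    lines.append(f"Regional analysis: {counts.get('regional_retained', 0)} retained, "
                 f"{counts.get('regional_excluded_bilateral', 0)} bilateral and "
                 f"{counts.get('regional_excluded_no_lesion', 0)} lesion-free excluded")
    path.write_text("\n".join(lines) + "\n")


def _checksums(out: Path) -> dict[str, str]:
    sums = {}
    for file in sorted(out.rglob("*")):
        if file.is_file() and file.name != "manifest.json":
            sums[str(file.relative_to(out))] = hashlib.sha256(
                file.read_bytes()
            ).hexdigest()
    return sums


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest (also written).

    Rerunning with the same config reproduces identical outputs: all
    stochastic stages are seeded from the root seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    log.info("run %s: seed=%d out=%s", config.run_id, config.seed, out)
    cohort = stage_simulate(config, out)
    stage_clean(config, out)
    stage_connectome(config, out)
    stage_metrics(config, out)
    counts = stage_stats(config, out)
    manifest = {
        "run_id": config.run_id,
        "version": __version__,
        "config": config.to_dict(),
        "counts": {"simulated": len(cohort), **counts},
        "checksums": _checksums(out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_fixtures(out_dir) -> dict:
    """Write small canonical graphs and a 3-subject mini cohort.

    The graph fixtures (complete K4, star K1,3, two triangles joined by a
    weak edge) come with their closed-form expected metric values for use
    in tests and documentation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k4 = np.ones((4, 4)) - np.eye(4)
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 1.0
    two_tri = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        two_tri[i, j] = two_tri[j, i] = 1.0
    two_tri[2, 3] = two_tri[3, 2] = 0.01
    graphs = {"k4": k4, "star": star, "two_triangles": two_tri}
    expected = {
        "k4": {
            "strength": [3.0] * 4,
            "clustering_coefficient": [1.0] * 4,
            "global_efficiency": 1.0,
            "local_efficiency": [1.0] * 4,
            "betweenness_centrality": [0.0] * 4,
        },
        "star": {
            "strength": [3.0, 1.0, 1.0, 1.0],
            "clustering_coefficient": [0.0] * 4,
            "betweenness_centrality": [3.0, 0.0, 0.0, 0.0],
            "nodal_efficiency": [1.0, 2.0 / 3.0, 2.0 / 3.0, 2.0 / 3.0],
        },
        "two_triangles": {"modularity_partition": [0, 0, 0, 1, 1, 1]},
    }
    for name, adj in graphs.items():
        labels = [f"n{i}" for i in range(adj.shape[0])]
        ConnectivityMatrix(adj, labels).to_tsv(out / f"{name}.tsv")
    (out / "expected_metrics.json").write_text(json.dumps(expected, indent=2))

    mini = PipelineConfig(
        run_id="mini",
        seed=7,
        output_dir=str(out / "mini_cohort"),
        simulate=SimulationConfig(n_per_group=1, t_volumes=60),
    )
    parc = make_default_parcellation()
    mini_out = Path(mini.output_dir)
    stage_simulate(mini, mini_out)
    stage_clean(mini, mini_out)
    return expected


# re-exported for convenience in interactive use
__all__ = [
    "CleaningParams",
    "ConnectomeParams",
    "MetricsParams",
    "StatsParams",
    "PipelineConfig",
    "PipelineError",
    "demo_config",
    "run_pipeline",
    "make_fixtures",
    "stage_simulate",
    "stage_clean",
    "stage_connectome",
    "stage_metrics",
    "stage_stats",
    "metrics_at_density",
]
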