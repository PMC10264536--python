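"""End-to-end orchestration: load or simulate a cohort, run the
univariate and connectivity stages, build and compare the toxicity
networks, and write a reproducible report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    grade_class_proportions,
    load_cohort,
    log_transform,
    save_cohort,
)
from .connectivity import (
    associations_to_frame,
    group_connectivity,
    toxicity_associations,
)
from .network import (
    DEFAULT_PERCENTILE,
    NetworkComparison,
    build_network,
    compare_networks,
    export_edge_lists,
    export_excel,
    export_graphml,
    percentile_threshold,
)
from .simulate import (
    SyntheticCohortConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    save_ground_truth,
)
from .stats import (
    ALPHA,
    differential_profile,
    normality_profile,
    write_differential_tsv,
)

logger = logging.getLogger("seronet")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    outdir: str | Path = "seronet_out"
    synthetic: SyntheticCohortConfig | None = None
    abundance_path: str | Path | None = None
    panel_path: str | Path | None = None
    toxicity_path: str | Path | None = None
    percentile: float = DEFAULT_PERCENTILE
    alpha: float = ALPHA
    threshold: float | None = None  # manual override of the percentile rule
    include_ido: bool = True
    sign_sensitive: bool = False
    make_figures: bool = False
    export_extras: bool = False  # GraphML + spreadsheet edge lists

    def __post_init__(self) -> None:
        has_files = self.abundance_path is not None
        if has_files == (self.synthetic is not None):
            raise PipelineConfigError(
                "exactly one input source required: file paths or a synthetic config"
            )
        if has_files and self.toxicity_path is None:
            raise PipelineConfigError("toxicity_path is required with abundance_path")

    def to_dict(self) -> dict[str, Any]:
        return dict(
            outdir=str(self.outdir),
            synthetic=config_to_dict(self.synthetic) if self.synthetic else None,
            abundance_path=str(self.abundance_path) if self.abundance_path else None,
            panel_path=str(self.panel_path) if self.panel_path else None,
            toxicity_path=str(self.toxicity_path) if self.toxicity_path else None,
            percentile=self.percentile,
            alpha=self.alpha,
            threshold=self.threshold,
            include_ido=self.include_ido,
            sign_sensitive=self.sign_sensitive,
            make_figures=self.make_figures,
            export_extras=self.export_extras,
        )


def config_from_file(path: str | Path) -> PipelineConfig:
    path = Path(path)
    data = (
        json.loads(path.read_text())
        if path.suffix.lower() == ".json"
        else yaml.safe_load(path.read_text())
    )
    synthetic = data.pop("synthetic", None)
    if synthetic is not None:
        synthetic = config_from_dict(synthetic)
    return PipelineConfig(synthetic=synthetic, **data)


@dataclass
class PipelineResult:
    cohort: CohortTable
    comparison: NetworkComparison
    threshold_used: float
    manifest: dict[str, Any]
    outdir: Path
    differential: list = field(default_factory=list)
    associations: list = field(default_factory=list)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute load -> log-transform -> univariate -> connectivity ->
    networks -> comparison -> exports; abort (removing partial outputs)
    on any stage failure."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(path: Path | dict) -> None:
        if isinstance(path, dict):
            written.extend(path.values())
        else:
            written.append(path)

    try:
        if config.synthetic is not None:
            cohort, truth = _stage("simulate")(generate_cohort)(config.synthetic)
            track(save_cohort(cohort, outdir, prefix="synthetic"))
            track(save_ground_truth(truth, config.synthetic, outdir / "ground_truth_edges.tsv"))
        else:
            cohort = _stage("load")(load_cohort)(
                config.abundance_path, config.panel_path, config.toxicity_path
            )
        if not config.include_ido and "IDO" in cohort.panel:
            cohort = cohort.drop_analytes(["IDO"])

        logged = _stage("log_transform")(log_transform)(cohort)

        differential = _stage("univariate")(differential_profile)(logged, alpha=config.alpha)
        diff_path = outdir / "differential.tsv"
        write_differential_tsv(differential, diff_path)
        track(diff_path)

        normality = _stage("normality")(normality_profile)(logged)
        norm_path = outdir / "normality.tsv"
        pd.DataFrame(
            [dict(analyte_id=r.analyte_id, w_statistic=r.w_statistic, p_raw=r.p_raw)
             for r in normality]
        ).to_csv(norm_path, sep="\t", index=False)
        track(norm_path)

        associations = _stage("toxicity_associations")(toxicity_associations)(
            logged, alpha=config.alpha
        )
        assoc_path = outdir / "toxicity_associations.tsv"
        associations_to_frame(associations).to_csv(assoc_path, sep="\t", index=False)
        track(assoc_path)

        mat0 = _stage("connectivity")(group_connectivity)(logged, 0)
        mat1 = _stage("connectivity")(group_connectivity)(logged, 1)
        for mat in (mat0, mat1):
            path = outdir / f"connectivity_{mat.group_label}.tsv"
            mat.write_tsv(path)
            track(path)

        if config.threshold is not None:
            threshold = float(config.threshold)
        else:
            threshold = _stage("threshold")(percentile_threshold)(
                [mat0, mat1], config.percentile
            )
        net0 = _stage("network")(build_network)(mat0, threshold, config.alpha, cohort.panel)
        net1 = _stage("network")(build_network)(mat1, threshold, config.alpha, cohort.panel)
        comparison = _stage("compare")(compare_networks)(
            net0, net1, sign_sensitive=config.sign_sensitive
        )
        track(export_edge_lists(comparison, outdir))

        if config.export_extras:
            track(export_excel(comparison, outdir / "edge_lists.xlsx"))
            track(export_graphml(net0, outdir / "network_toxicity0.graphml"))
            track(export_graphml(net1, outdir / "network_toxicity1.graphml"))

        if config.make_figures:
            from . import plots

            track(plots.boxplot_significant(logged, differential, outdir / "boxplots.png"))
            track(plots.association_heatmap(associations, outdir / "toxicity_heatmap.png"))
            track(plots.matrix_heatmap(mat0, outdir / "connectivity_toxicity0.png"))
            track(plots.matrix_heatmap(mat1, outdir / "connectivity_toxicity1.png"))
            track(plots.network_figure(net0, outdir / "network_toxicity0.png"))
            track(plots.network_figure(net1, outdir / "network_toxicity1.png"))

        counts = comparison.counts()
        n0, n1 = cohort.group_sizes()
        manifest = dict(
            seronet_version=__version__,
            config=config.to_dict(),
            n_patients=cohort.n_patients,
            group_sizes=dict(toxicity0=n0, toxicity1=n1),
            threshold_used=threshold,
            percentile=config.percentile,
            alpha=config.alpha,
            n_analytes=len(cohort.panel),
            analytes_tested=len(differential),
            significant_analytes=sorted(
                r.analyte_id for r in differential if r.p_adjusted <= config.alpha
            ),
            significant_associations=sorted(
                a.analyte_id for a in associations if a.significant
            ),
            edge_counts=counts,
            unusable_analytes=sorted(cohort.unusable_analytes | logged.unusable_analytes),
            outputs=sorted(str(p.name) for p in written),
        )
        if cohort.grade_class is not None:
            manifest["grade_class_pct"] = grade_class_proportions(cohort)
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        track(manifest_path)

        summary_path = outdir / "summary.txt"
        summary_path.write_text(_summary_text(manifest))
        track(summary_path)
    except Exception:
        for path in written:
            Path(path).unlink(missing_ok=True)
        raise

    return PipelineResult(
        cohort=cohort,
        comparison=comparison,
        threshold_used=threshold,
        manifest=manifest,
        outdir=outdir,
        differential=differential,
        associations=associations,
    )


def run_from_manifest(manifest_path: str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """Re-run a pipeline from a previously written manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    data = manifest["config"]
    synthetic = data.pop("synthetic", None)
    if synthetic is not None:
        synthetic = config_from_dict(synthetic)
    if outdir is not None:
        data["outdir"] = str(outdir)
    data = {k: v for k, v in data.items() if v is not None or k in ("threshold",)}
    return run_pipeline(PipelineConfig(synthetic=synthetic, **data))


def _summary_text(manifest: dict[str, Any]) -> str:
    counts = manifest["edge_counts"]
    lines = [
        f"seronet {manifest['seronet_version']} pipeline summary",
        f"patients: {manifest['n_patients']} "
        f"(toxicity 0: {manifest['group_sizes']['toxicity0']}, "
        f"toxicity 1: {manifest['group_sizes']['toxicity1']})",
        f"analytes: {manifest['n_analytes']} ({manifest['analytes_tested']} tested)",
        f"edge threshold |rho| > {manifest['threshold_used']:.4f} "
        f"(percentile {manifest['percentile']}, alpha {manifest['alpha']})",
        f"significant analytes (group test): "
        f"{', '.join(manifest['significant_analytes']) or 'none'}",
        f"significant toxicity associations: "
        f"{', '.join(manifest['significant_associations']) or 'none'}",
        f"network edges: {counts['edges_group0']} (no toxicity), "
        f"{counts['edges_group1']} (toxicity)",
        f"shared edges: {counts['shared']}; "
        f"specific to no-toxicity: {counts['specific_to_group0']}; "
        f"specific to toxicity: {counts['specific_to_group1']}",
    ]
    return "\n".join(lines) + "\n"
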