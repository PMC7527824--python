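"""End-to-end run: read -> compensate -> subtract -> gate -> resultant -> report."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import color_model, gating, plotting, preprocess, reporting
from .config import AnalysisConfig, parse_config, validate_against
from .fcs_io import RawEventTable, read_fcs
from .reporting import HueFilter

__all__ = ["PipelineResult", "RunResult", "analyze", "run"]


@dataclass
class PipelineResult:
    """All in-memory stages of one analysis."""

    table: RawEventTable
    cfg: AnalysisConfig
    processed: preprocess.ProcessedTable
    status: gating.GateStatus
    records: color_model.ResultantSet
    stats: reporting.StatsReport


@dataclass
class RunResult:
    exit_code: int
    artifacts: dict[str, Path] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


class ValidationFailure(RuntimeError):
    def __init__(self, findings: list[str]):
        super().__init__("; ".join(findings))
        self.findings = findings


def analyze(cfg: AnalysisConfig, table: RawEventTable) -> PipelineResult:
    """Run the deterministic analysis pipeline on parsed inputs."""
    findings = validate_against(cfg, table)
    if findings:
        raise ValidationFailure(findings)
    processed = preprocess.process(table, cfg)
    status = gating.apply_gate(processed, cfg)
    records = color_model.compute_resultants(processed, cfg, status.labels)
    stats = reporting.summarize(processed, status, cfg)
    return PipelineResult(
        table=table, cfg=cfg, processed=processed,
        status=status, records=records, stats=stats,
    )


def run(
    config_path: str | Path,
    out_dir: str | Path,
    *,
    hue_filter: HueFilter | None = None,
    plot_format: str = "png",
    plot: bool = True,
) -> RunResult:
    """Execute a full analysis and write artifacts into ``out_dir``.

    Exit code 2 signals validation findings (listed in the log), 1 signals
    I/O failure, 0 success.
    """
    result = RunResult(exit_code=0)
    out_dir = Path(out_dir)
    try:
        cfg = parse_config(config_path)
        fcs_path = Path(cfg.fcs_file)
        if not fcs_path.is_absolute():
            fcs_path = Path(config_path).parent / fcs_path
        if not fcs_path.exists():
            result.log.append(f"FCS file not found: {fcs_path}")
            result.exit_code = 2
            return result
        table = read_fcs(fcs_path)
    except (ValueError, OSError) as err:
        result.log.append(str(err))
        result.exit_code = 2 if isinstance(err, ValueError) else 1
        return result

    try:
        pipeline = analyze(cfg, table)
    except ValidationFailure as err:
        result.log.extend(err.findings)
        result.exit_code = 2
        return result

    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        stats_path = out_dir / "stats.csv"
        pipeline.stats.to_csv(stats_path)
        result.artifacts["stats"] = stats_path
        (out_dir / "stats.txt").write_text(pipeline.stats.pretty())
        result.artifacts["stats_text"] = out_dir / "stats.txt"

        events_path = out_dir / "events.csv"
        reporting.events_frame(pipeline.records).to_csv(events_path, index=False)
        result.artifacts["events"] = events_path

        if plot:
            spec = plotting.PlotSpec(output_format=plot_format)
            plot_path, manifest = plotting.resultant_plot(
                table, pipeline.records, cfg, spec,
                out_dir / f"resultant_plot.{plot_format}",
            )
            result.artifacts["plot"] = plot_path
            manifest.to_csv(out_dir / "plot_manifest.csv", index=False)
            result.artifacts["plot_manifest"] = out_dir / "plot_manifest.csv"

        if hue_filter is not None:
            fstats = reporting.summarize_filtered(
                pipeline.processed, pipeline.status, pipeline.records,
                hue_filter, cfg,
            )
            fstats_path = out_dir / "stats_filtered.csv"
            fstats.to_csv(fstats_path)
            result.artifacts["stats_filtered"] = fstats_path
            if plot:
                spec = plotting.PlotSpec(output_format=plot_format)
                fplot_path, fmanifest = plotting.filtered_plot(
                    table, pipeline.records, hue_filter, cfg, spec,
                    out_dir / f"filtered_plot.{plot_format}",
                )
                result.artifacts["filtered_plot"] = fplot_path
                fmanifest.to_csv(out_dir / "filtered_manifest.csv", index=False)
                result.artifacts["filtered_manifest"] = out_dir / "filtered_manifest.csv"
    except OSError as err:
        result.log.append(str(err))
        result.exit_code = 1
        return result

    counts = pipeline.status.counts()
    result.log.append(
        f"{table.n_events} events: {counts['COLORED']} colored, "
        f"{counts['EXCLUDED']} excluded, {counts['NON_GATED']} non-gated"
    )
    return result
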