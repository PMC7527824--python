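"""FSC x SSC dot plots with per-event resultant colors and a hue rule legend.

The testing surface is the color manifest returned alongside each figure, a
deterministic pure function of the resultant records and the plot spec —
pixel output is never asserted against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .color_model import LIGHTNESS, ResultantSet, Status, hsl_to_rgb
from .config import AnalysisConfig
from .fcs_io import RawEventTable
from .reporting import HueFilter, hue_filter_mask

__all__ = ["PlotSpec", "resultant_plot", "filtered_plot"]


@dataclass
class PlotSpec:
    x_param: str = "FSC-A"
    y_param: str = "SSC-A"
    point_size: float = 2.0
    excluded_color: tuple[int, int, int] = (0, 0, 0)
    non_gated_color: tuple[int, int, int] = (160, 160, 160)
    achromatic_color: tuple[int, int, int] = (210, 210, 210)
    output_format: str = "png"
    hue_rule: bool = True
    title: str = ""
    extra: dict = field(default_factory=dict)


def _axis_column(table: RawEventTable, cfg: AnalysisConfig, name: str) -> np.ndarray:
    if name in cfg.scatter_columns:
        return table.column(cfg.scatter_columns[name])
    if name in table.param_names:
        return table.values[:, table.param_names.index(name)]
    raise ValueError(f"parameter {name!r} not found in FCS file or scatter map")


def _manifest(records: ResultantSet, spec: PlotSpec) -> pd.DataFrame:
    n = len(records)
    rgb = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        st = records.status[i]
        if st is Status.COLORED:
            rgb[i] = records.rgb(i)
        elif st is Status.EXCLUDED:
            rgb[i] = spec.excluded_color
        elif st is Status.ACHROMATIC:
            rgb[i] = spec.achromatic_color
        else:
            rgb[i] = spec.non_gated_color
    return pd.DataFrame(
        {
            "event_index": np.arange(n),
            "status": [s.value for s in records.status],
            "r": rgb[:, 0],
            "g": rgb[:, 1],
            "b": rgb[:, 2],
        }
    )


def _draw_hue_rule(fig, cfg: AnalysisConfig) -> None:
    """Linear 0-360 degree hue bar with channel tick labels below the axes."""
    ax = fig.add_axes([0.13, 0.02, 0.74, 0.05])
    degrees = np.arange(0, 360)
    strip = np.array(
        [hsl_to_rgb(d, 1.0, LIGHTNESS) for d in degrees], dtype=np.float64
    ) / 255.0
    ax.imshow(strip[np.newaxis, :, :], aspect="auto", extent=(0, 360, 0, 1))
    ax.set_yticks([])
    ax.set_xticks([0, 90, 180, 270, 360])
    ax.tick_params(labelsize=6)
    for ch in cfg.channels:
        if ch.index in cfg.resultant and ch.hue_deg is not None:
            ax.annotate(
                ch.label,
                xy=(ch.hue_deg, 1.0),
                xytext=(ch.hue_deg, 1.7),
                ha="center",
                fontsize=6,
                arrowprops={"arrowstyle": "-", "lw": 0.5},
                annotation_clip=False,
            )


def _render(
    x: np.ndarray,
    y: np.ndarray,
    manifest: pd.DataFrame,
    order: list[Status],
    cfg: AnalysisConfig,
    spec: PlotSpec,
    out: str | Path,
) -> Path:
    out = Path(out)
    fig, ax = plt.subplots(figsize=(5.0, 5.4))
    status = manifest["status"].to_numpy()
    colors = manifest[["r", "g", "b"]].to_numpy() / 255.0
    for st in order:  # overplot order: colored events land on top
        sel = status == st.value
        if sel.any():
            ax.scatter(
                x[sel], y[sel], s=spec.point_size, c=colors[sel],
                marker=".", linewidths=0,
            )
    ax.set_xlabel(spec.x_param)
    ax.set_ylabel(spec.y_param)
    if spec.title:
        ax.set_title(spec.title, fontsize=9)
    if spec.hue_rule:
        fig.subplots_adjust(bottom=0.22)
        _draw_hue_rule(fig, cfg)
    try:
        fig.savefig(out, format=spec.output_format, dpi=150)
    except OSError as err:
        raise OSError(f"cannot write figure to {out}: {err}") from err
    finally:
        plt.close(fig)
    return out


def resultant_plot(
    table: RawEventTable,
    records: ResultantSet,
    cfg: AnalysisConfig,
    spec: PlotSpec,
    out: str | Path,
) -> tuple[Path, pd.DataFrame]:
    """Render every event on the scatter axes; COLORED events drawn on top.

    Returns the figure path and the manifest of per-event RGB assignments
    (length N, one row per event).
    """
    x = _axis_column(table, cfg, spec.x_param)
    y = _axis_column(table, cfg, spec.y_param)
    manifest = _manifest(records, spec)
    path = _render(
        x, y, manifest,
        [Status.NON_GATED, Status.EXCLUDED, Status.ACHROMATIC, Status.COLORED],
        cfg, spec, out,
    )
    return path, manifest


def filtered_plot(
    table: RawEventTable,
    records: ResultantSet,
    f: HueFilter,
    cfg: AnalysisConfig,
    spec: PlotSpec,
    out: str | Path,
) -> tuple[Path, pd.DataFrame]:
    """Render only events passing the hue filter; manifest length == selection size."""
    mask = hue_filter_mask(records, f)
    x = _axis_column(table, cfg, spec.x_param)[mask]
    y = _axis_column(table, cfg, spec.y_param)[mask]
    manifest = _manifest(records, spec).loc[mask].reset_index(drop=True)
    path = _render(x, y, manifest, [Status.COLORED], cfg, spec, out)
    return path, manifest
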