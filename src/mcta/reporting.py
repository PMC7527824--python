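"""Statistics block and hue-range ("resultant plot with filter") selections.

All statistics run on the processed data matrix (post compensation and
background subtraction) restricted to COLORED events.  Geometric mean and
geometric SD use strictly positive values only (log of zero is undefined);
the count actually used is reported alongside as ``n_positive``.  Medians
run over all COLORED values including zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color_model import ResultantSet, Status
from .config import AnalysisConfig
from .gating import GateStatus
from .preprocess import ProcessedTable

__all__ = [
    "ChannelStats",
    "StatsReport",
    "HueFilter",
    "summarize",
    "hue_filter_mask",
    "summarize_filtered",
]


@dataclass
class ChannelStats:
    """Summary statistics for one resultant channel over the gated events."""

    index: int
    label: str
    geometric_mean: float | None
    geometric_sd: float | None
    median: float | None
    n_positive: int


@dataclass
class StatsReport:
    total_events: int
    gated_events: int
    channels: list[ChannelStats] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "channel": c.index,
                    "label": c.label,
                    "geometric_mean": c.geometric_mean,
                    "geometric_sd": c.geometric_sd,
                    "median": c.median,
                    "n_positive": c.n_positive,
                }
                for c in self.channels
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def pretty(self) -> str:
        """Fixed-width text block (2-decimal display)."""
        lines = [
            f"Total events:          {self.total_events}",
            f"Events meeting gate:   {self.gated_events}",
            "",
            f"{'channel':>7}  {'label':<12} {'geo.mean':>10} {'geo.SD':>8} "
            f"{'median':>10} {'n>0':>7}",
        ]
        for c in self.channels:
            gm = f"{c.geometric_mean:.2f}" if c.geometric_mean is not None else "n/a"
            gs = f"{c.geometric_sd:.2f}" if c.geometric_sd is not None else "n/a"
            md = f"{c.median:.2f}" if c.median is not None else "n/a"
            lines.append(
                f"{c.index:>7}  {c.label:<12} {gm:>10} {gs:>8} {md:>10} "
                f"{c.n_positive:>7}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class HueFilter:
    """Inclusive hue range in degrees; ``lo > hi`` wraps through 0/360."""

    lo_deg: float
    hi_deg: float

    def __post_init__(self) -> None:
        for v in (self.lo_deg, self.hi_deg):
            if not 0.0 <= v < 360.0:
                raise ValueError(f"filter bound {v} outside [0, 360)")

    def contains(self, hue: np.ndarray) -> np.ndarray:
        hue = np.asarray(hue, dtype=np.float64)
        with np.errstate(invalid="ignore"):
            if self.lo_deg <= self.hi_deg:
                inside = (hue >= self.lo_deg) & (hue <= self.hi_deg)
            else:
                inside = (hue >= self.lo_deg) | (hue <= self.hi_deg)
        return inside & ~np.isnan(hue)


def _channel_stats(values: np.ndarray, index: int, label: str) -> ChannelStats:
    positive = values[values > 0]
    if positive.size:
        logs = np.log(positive)
        gm = float(math.exp(logs.mean()))
        gsd = float(math.exp(logs.std(ddof=1))) if positive.size > 1 else 1.0
    else:
        gm = gsd = None
    median = float(np.median(values)) if values.size else None
    return ChannelStats(
        index=index,
        label=label,
        geometric_mean=gm,
        geometric_sd=gsd,
        median=median,
        n_positive=int(positive.size),
    )


def _summarize_mask(
    processed: ProcessedTable, mask: np.ndarray, cfg: AnalysisConfig
) -> StatsReport:
    report = StatsReport(
        total_events=processed.n_events, gated_events=int(mask.sum())
    )
    for ch_index in sorted(cfg.resultant):
        ch = cfg.channel(ch_index)
        values = processed.intensities[mask, ch_index - 1]
        report.channels.append(_channel_stats(values, ch.index, ch.label))
    return report


def summarize(
    processed: ProcessedTable, status: GateStatus, cfg: AnalysisConfig
) -> StatsReport:
    """Statistics over COLORED events only, on processed intensities only.

    With zero COLORED events a report is still returned, with counts set and
    every statistic flagged not-available (None) — not an exception.
    """
    mask = status.labels == Status.COLORED
    return _summarize_mask(processed, mask, cfg)


def hue_filter_mask(records: ResultantSet, f: HueFilter) -> np.ndarray:
    """Boolean per event: COLORED, defined hue, inside the (wrapping) range."""
    colored = records.status == Status.COLORED
    return colored & f.contains(records.hue_deg)


def summarize_filtered(
    processed: ProcessedTable,
    status: GateStatus,
    records: ResultantSet,
    f: HueFilter,
    cfg: AnalysisConfig,
) -> StatsReport:
    """Like :func:`summarize` but restricted to the hue-filter selection."""
    mask = hue_filter_mask(records, f)
    return _summarize_mask(processed, mask, cfg)


def events_frame(records: ResultantSet) -> pd.DataFrame:
    """Per-event export: index, status, resultant coordinates and color."""
    n = len(records)
    rgb = np.full((n, 3), -1, dtype=np.int64)
    for i in range(n):
        color = records.rgb(i)
        if color is not None:
            rgb[i] = color
    return pd.DataFrame(
        {
            "event_index": np.arange(n),
            "status": [s.value for s in records.status],
            "rx": records.rx,
            "ry": records.ry,
            "magnitude": records.magnitude,
            "hue_deg": records.hue_deg,
            "saturation": records.saturation,
            "r": rgb[:, 0],
            "g": rgb[:, 1],
            "b": rgb[:, 2],
        }
    )
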