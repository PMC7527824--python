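"""Spillover compensation and background subtraction.

Order of operations: compensate first, then subtract per-channel backgrounds.
Negative compensated values are retained in the ``compensated`` matrix but
clamped to zero in ``intensities``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, ChannelDef, SpilloverTable
from .fcs_io import RawEventTable

__all__ = [
    "ProcessedTable",
    "CompensationError",
    "compensation_operator",
    "compensate",
    "subtract_background",
    "process",
]

#: refuse to invert spillover matrices with condition number above this
MAX_CONDITION = 1e6


class CompensationError(ValueError):
    """Raised when a spillover matrix is singular or too ill-conditioned."""


@dataclass
class ProcessedTable:
    """Per-event processed intensities (channel order matches the config).

    ``intensities`` is ``max(0, compensated - background)`` elementwise and
    carries the I_j values consumed by gating, colors and statistics.
    """

    intensities: np.ndarray
    compensated: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.compensated = np.asarray(self.compensated, dtype=np.float64)
        if self.intensities.shape != self.compensated.shape:
            raise ValueError("intensities and compensated shapes differ")
        if (self.intensities < 0).any():
            raise ValueError("processed intensities must be nonnegative")

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    @property
    def nc(self) -> int:
        return self.intensities.shape[1]


def compensation_operator(spill: SpilloverTable) -> np.ndarray:
    """Return the nc x nc compensation operator O = inv(S/100).

    With rows = source fluorochrome and columns = detector, forward mixing
    of row-vector events is ``observed = true @ (S/100)`` (entry (r, c) is
    the percent of fluorochrome r's primary signal seen in detector c), so
    true abundances are recovered by ``observed @ O``.  Identity spillover
    maps to the identity operator.
    """
    mixing = spill.matrix / 100.0
    cond = np.linalg.cond(mixing)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise CompensationError(
            f"spillover matrix is singular or ill-conditioned "
            f"(condition number {cond:.3g} > {MAX_CONDITION:.0e})"
        )
    return np.linalg.inv(mixing)


def compensate(raw_fluor: np.ndarray, operator: np.ndarray) -> np.ndarray:
    """Apply the compensation operator to each event row."""
    raw_fluor = np.asarray(raw_fluor, dtype=np.float64)
    if raw_fluor.ndim != 2 or raw_fluor.shape[1] != operator.shape[0]:
        raise ValueError(
            f"event matrix has {raw_fluor.shape[-1] if raw_fluor.ndim else 0} "
            f"columns, operator expects {operator.shape[0]}"
        )
    return raw_fluor @ operator


def subtract_background(
    compensated: np.ndarray, channels: list[ChannelDef]
) -> ProcessedTable:
    """Clamp-subtract per-channel backgrounds from the compensated matrix."""
    compensated = np.asarray(compensated, dtype=np.float64)
    if compensated.shape[1] != len(channels):
        raise ValueError(
            f"{compensated.shape[1]} columns vs {len(channels)} channel definitions"
        )
    bg = np.array([c.background for c in channels], dtype=np.float64)
    if (bg < 0).any():
        raise ValueError("background thresholds must be nonnegative")
    intensities = np.maximum(0.0, compensated - bg)
    return ProcessedTable(intensities=intensities, compensated=compensated)


def process(table: RawEventTable, cfg: AnalysisConfig) -> ProcessedTable:
    """Run compensation + background subtraction on the config's fluorescence columns."""
    raw = np.column_stack([table.column(ch.source_column) for ch in cfg.channels])
    operator = compensation_operator(cfg.spillover)
    return subtract_background(compensate(raw, operator), cfg.channels)
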