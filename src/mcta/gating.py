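"""Boolean marker gating: veto exclusion channels, conjunctive inclusion.

An event is EXCLUDED if positive for any exclusion channel (evaluated first),
COLORED if positive for every inclusion channel, otherwise NON_GATED.  With an
empty inclusion set every non-excluded event is COLORED.  Positivity means a
strictly positive processed intensity, i.e. compensated signal above the
channel background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color_model import Status
from .config import AnalysisConfig
from .preprocess import ProcessedTable

__all__ = ["GateStatus", "positivity", "apply_gate"]


@dataclass
class GateStatus:
    """Per-event gate labels plus label counts; labels partition all events."""

    labels: np.ndarray  # array of Status values, length N

    @property
    def n_events(self) -> int:
        return self.labels.shape[0]

    @property
    def n_colored(self) -> int:
        return int(np.sum(self.labels == Status.COLORED))

    @property
    def n_excluded(self) -> int:
        return int(np.sum(self.labels == Status.EXCLUDED))

    @property
    def n_non_gated(self) -> int:
        return int(np.sum(self.labels == Status.NON_GATED))

    def counts(self) -> dict[str, int]:
        return {
            "COLORED": self.n_colored,
            "EXCLUDED": self.n_excluded,
            "NON_GATED": self.n_non_gated,
        }


def positivity(processed: ProcessedTable, channel: int) -> np.ndarray:
    """Boolean per event: processed intensity strictly above zero for ``channel``."""
    if not 1 <= channel <= processed.nc:
        raise ValueError(f"channel {channel} outside 1..{processed.nc}")
    return processed.intensities[:, channel - 1] > 0.0


def apply_gate(processed: ProcessedTable, cfg: AnalysisConfig) -> GateStatus:
    """Classify every event as COLORED, EXCLUDED or NON_GATED."""
    n = processed.n_events
    excluded = np.zeros(n, dtype=bool)
    for ch in sorted(cfg.exclude):
        excluded |= positivity(processed, ch)
    included = np.ones(n, dtype=bool)
    for ch in sorted(cfg.include):
        included &= positivity(processed, ch)

    labels = np.full(n, Status.NON_GATED, dtype=object)
    labels[included] = Status.COLORED
    labels[excluded] = Status.EXCLUDED  # veto overrides inclusion
    return GateStatus(labels=labels)
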