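"""Hue assignment and per-event resultant vectors.

Channels are ranked by ascending maximal emission wavelength (ties broken by
channel index) and rank k receives hue ``k * 360/nc``, dividing the color
wheel into equal parts.  Each event's resultant vector is the intensity-
weighted sum of the channel unit vectors over the resultant channel set; its
angle is the event's hue, its length (normalized) the saturation.  Lightness
is fixed at 0.5.
"""

from __future__ import annotations

import colorsys
import enum
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, ChannelDef

__all__ = [
    "Status",
    "ResultantRecord",
    "ResultantSet",
    "LIGHTNESS",
    "assign_hues",
    "unit_vector",
    "resultant",
    "hue_of",
    "saturation_of",
    "hsl_to_rgb",
    "compute_resultants",
]

LIGHTNESS = 0.5

#: saturation normalization percentile over COLORED magnitudes
SATURATION_PERCENTILE = 99.5


class Status(enum.Enum):
    COLORED = "COLORED"
    EXCLUDED = "EXCLUDED"
    NON_GATED = "NON_GATED"
    ACHROMATIC = "ACHROMATIC"


@dataclass
class ResultantRecord:
    """Per-event resultant vector, color coordinates and gate status."""

    rx: float
    ry: float
    magnitude: float
    hue_deg: float | None  # None == UNDEFINED (degenerate resultant)
    saturation: float
    status: Status
    lightness: float = LIGHTNESS


def assign_hues(channels: list[ChannelDef]) -> list[ChannelDef]:
    """Fill ``hue_deg`` on every channel by equal division of 360 degrees.

    Channels carrying an explicit hue override keep it; the rest are ranked
    by ascending emission (ties: lower channel index first) and rank k gets
    ``k * 360/nc``.  Returns the same list, mutated, for chaining.
    """
    nc = len(channels)
    if nc < 1:
        raise ValueError("need at least one channel")
    step = 360.0 / nc
    order = sorted(channels, key=lambda c: (c.emission_nm, c.index))
    for rank, ch in enumerate(order):
        if ch.hue_deg is None:
            ch.hue_deg = rank * step
    return channels


def unit_vector(hue_deg: float) -> tuple[float, float]:
    """Unit vector at ``hue_deg`` on the color wheel: (cos h, sin h)."""
    h = np.deg2rad(hue_deg)
    return float(np.cos(h)), float(np.sin(h))


def resultant(
    intensities: np.ndarray,
    hues: np.ndarray,
    resultant_set: set[int] | frozenset[int],
) -> tuple[float, float, float]:
    """Resultant (rx, ry, magnitude) of one event.

    ``intensities`` and ``hues`` are length-nc arrays indexed by channel
    order; only channels whose 1-based index is in ``resultant_set``
    contribute.
    """
    intensities = np.asarray(intensities, dtype=np.float64)
    hues = np.asarray(hues, dtype=np.float64)
    if intensities.shape != hues.shape:
        raise ValueError("intensities and hues length mismatch")
    if not resultant_set:
        raise ValueError("resultant channel set must not be empty")
    idx = np.array(sorted(resultant_set)) - 1
    if idx.min() < 0 or idx.max() >= intensities.shape[0]:
        raise ValueError("resultant set references unknown channels")
    h = np.deg2rad(hues[idx])
    rx = float(np.sum(intensities[idx] * np.cos(h)))
    ry = float(np.sum(intensities[idx] * np.sin(h)))
    return rx, ry, float(np.hypot(rx, ry))


def hue_of(rx: float, ry: float, *, eps: float = 1e-12) -> float | None:
    """atan2 angle in [0, 360), or None when the magnitude is below ``eps``."""
    if np.hypot(rx, ry) <= eps:
        return None
    return float(np.rad2deg(np.arctan2(ry, rx)) % 360.0)


def saturation_of(magnitude: float, norm_constant: float) -> float:
    """Map a resultant magnitude to saturation in [0, 1] by clamped division."""
    if norm_constant <= 0:
        raise ValueError("norm_constant must be positive")
    return min(1.0, magnitude / norm_constant)


def hsl_to_rgb(hue_deg: float, saturation: float, lightness: float) -> tuple[int, int, int]:
    """Standard HSL -> 8-bit RGB conversion."""
    if not 0.0 <= saturation <= 1.0:
        raise ValueError(f"saturation {saturation} outside [0, 1]")
    if not 0.0 <= lightness <= 1.0:
        raise ValueError(f"lightness {lightness} outside [0, 1]")
    r, g, b = colorsys.hls_to_rgb((hue_deg % 360.0) / 360.0, lightness, saturation)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


@dataclass
class ResultantSet:
    """Vectorized per-event resultant results (structure of arrays).

    ``hue_deg`` is NaN where undefined; ``status`` holds :class:`Status`
    values, with COLORED events of degenerate magnitude downgraded to
    ACHROMATIC.  ``norm_constant`` is the magnitude that maps to full
    saturation.
    """

    rx: np.ndarray
    ry: np.ndarray
    magnitude: np.ndarray
    hue_deg: np.ndarray
    saturation: np.ndarray
    status: np.ndarray
    norm_constant: float
    eps: float

    def __len__(self) -> int:
        return self.rx.shape[0]

    def __getitem__(self, i: int) -> ResultantRecord:
        hue = self.hue_deg[i]
        return ResultantRecord(
            rx=float(self.rx[i]),
            ry=float(self.ry[i]),
            magnitude=float(self.magnitude[i]),
            hue_deg=None if np.isnan(hue) else float(hue),
            saturation=float(self.saturation[i]),
            status=self.status[i],
        )

    def rgb(self, i: int) -> tuple[int, int, int] | None:
        """8-bit color of a COLORED event; None for any other status."""
        if self.status[i] is not Status.COLORED:
            return None
        return hsl_to_rgb(float(self.hue_deg[i]), float(self.saturation[i]), LIGHTNESS)


def compute_resultants(
    processed,
    cfg: AnalysisConfig,
    status_labels: np.ndarray,
    *,
    norm_constant: float | None = None,
) -> ResultantSet:
    """Batch-compute resultant vectors, hues and saturations for all events.

    ``status_labels`` is the gating module's per-event array of
    :class:`Status` values (COLORED/EXCLUDED/NON_GATED); COLORED events whose
    resultant magnitude is degenerate become ACHROMATIC.  The undefined-hue
    threshold is ``1e-12 * max(processed intensity)`` so it is unit-free.
    """
    assign_hues(cfg.channels)
    hues = np.array([ch.hue_deg for ch in cfg.channels], dtype=np.float64)
    intens = processed.intensities
    idx = np.array(sorted(cfg.resultant)) - 1
    h = np.deg2rad(hues[idx])
    sub = intens[:, idx]
    rx = sub @ np.cos(h)
    ry = sub @ np.sin(h)
    magnitude = np.hypot(rx, ry)

    scale = float(intens.max()) if intens.size else 0.0
    eps = 1e-12 * scale if scale > 0 else 1e-12

    hue = np.degrees(np.arctan2(ry, rx)) % 360.0
    defined = magnitude > eps
    hue = np.where(defined, hue, np.nan)

    status = np.array(status_labels, dtype=object)
    colored = status == Status.COLORED
    status[colored & ~defined] = Status.ACHROMATIC
    colored = status == Status.COLORED

    if norm_constant is None:
        mags = magnitude[colored]
        norm_constant = (
            float(np.percentile(mags, SATURATION_PERCENTILE)) if mags.size else 1.0
        )
        if norm_constant <= 0:
            norm_constant = 1.0
    saturation = np.minimum(1.0, magnitude / norm_constant)

    return ResultantSet(
        rx=rx,
        ry=ry,
        magnitude=magnitude,
        hue_deg=hue,
        saturation=saturation,
        status=status,
        norm_constant=norm_constant,
        eps=eps,
    )
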