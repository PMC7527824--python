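"""Synthetic multi-channel cytometry events with known ground truth.

Populations carry lognormal per-channel true signals, a Gaussian scatter
cluster, and forward spillover mixing plus truncated-Gaussian
autofluorescence noise, so that every pipeline stage can be exercised
offline with exact expectations.  One integer seed governs everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AnalysisConfig, ChannelDef, SpilloverTable, write_config
from .fcs_io import RawEventTable, write_fcs

__all__ = [
    "PopulationSpec",
    "GroundTruth",
    "generate",
    "box1_spillover",
    "make_config",
    "emit_experiment",
    "BOX1_LABELS",
    "BOX1_EMISSIONS_NM",
]

#: the packaged five-fluorochrome spillover panel (percent units)
BOX1_LABELS = ["FITC", "PE", "PerCP", "APC", "APC Cy7"]

#: maximal emission wavelengths (nm) for the five packaged fluorochromes
BOX1_EMISSIONS_NM = {
    "FITC": 519.0,
    "PE": 578.0,
    "PerCP": 675.0,
    "APC": 660.0,
    "APC Cy7": 774.0,
}

_BOX1_MATRIX = [
    [100.00, 1.40, 0.00, 0.00, 0.00],
    [18.22, 100.00, 0.00, 0.00, 0.00],
    [2.80, 15.42, 100.00, 0.00, 0.00],
    [0.00, 0.41, 6.86, 100.00, 14.49],
    [0.00, 0.00, 0.00, 6.54, 100.00],
]


def box1_spillover() -> SpilloverTable:
    """The packaged 5x5 percent spillover matrix (FITC, PE, PerCP, APC, APC Cy7)."""
    return SpilloverTable(
        matrix=np.array(_BOX1_MATRIX, dtype=np.float64), labels=list(BOX1_LABELS)
    )


@dataclass
class PopulationSpec:
    """One synthetic subpopulation.

    ``signals`` maps 1-based channel index to ``(geometric_mean,
    geometric_sd)`` of the lognormal true signal; unlisted channels are
    unstained (zero true signal).  ``scatter`` gives (mean, sd) per scatter
    axis.  ``dominant_channel``, when set, must carry the strictly greatest
    geometric mean among the population's signal channels.
    """

    name: str
    n_events: int
    signals: dict[int, tuple[float, float]] = field(default_factory=dict)
    scatter: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"FSC-A": (50_000.0, 8_000.0), "SSC-A": (30_000.0, 6_000.0)}
    )
    dominant_channel: int | None = None

    def validate(self, nc: int) -> None:
        if self.n_events <= 0:
            raise ValueError(f"population {self.name}: n_events must be positive")
        for ch, (gm, gsd) in self.signals.items():
            if not 1 <= ch <= nc:
                raise ValueError(f"population {self.name}: channel {ch} outside 1..{nc}")
            if gm <= 0:
                raise ValueError(f"population {self.name}: geometric mean must be > 0")
            if gsd < 1.0:
                raise ValueError(f"population {self.name}: geometric SD must be >= 1")
        if self.dominant_channel is not None:
            if self.dominant_channel not in self.signals:
                raise ValueError(
                    f"population {self.name}: dominant channel has no signal"
                )
            dom_gm = self.signals[self.dominant_channel][0]
            others = [
                gm for ch, (gm, _) in self.signals.items()
                if ch != self.dominant_channel
            ]
            if others and dom_gm <= max(others):
                raise ValueError(
                    f"population {self.name}: dominant channel geometric mean "
                    "must be strictly greatest"
                )


@dataclass
class GroundTruth:
    """Per-event population labels and true (pre-spillover) intensities."""

    labels: np.ndarray  # array of population names, length N
    true_intensities: np.ndarray  # N x nc

    def counts(self) -> dict[str, int]:
        names, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))


def generate(
    populations: list[PopulationSpec],
    spill: SpilloverTable,
    backgrounds: np.ndarray | list[float],
    seed: int,
) -> tuple[RawEventTable, GroundTruth]:
    """Draw events, forward-mix through the spillover matrix, add noise.

    Observed fluorescence is ``true @ (S/100)`` plus truncated-Gaussian
    autofluorescence with per-channel scale ``background/3``.  Scatter
    columns come first in the output table (FSC-A, SSC-A by default),
    followed by one column per fluorescence channel.  Events are shuffled;
    everything is deterministic per seed.
    """
    nc = spill.nc
    backgrounds = np.asarray(backgrounds, dtype=np.float64)
    if backgrounds.shape != (nc,):
        raise ValueError(f"need {nc} backgrounds, got shape {backgrounds.shape}")
    if (backgrounds < 0).any():
        raise ValueError("backgrounds must be nonnegative")
    if not populations:
        raise ValueError("need at least one population")
    scatter_names = list(populations[0].scatter.keys())
    for pop in populations:
        pop.validate(nc)
        if list(pop.scatter.keys()) != scatter_names:
            raise ValueError("all populations must declare the same scatter axes")

    rng = np.random.default_rng(seed)
    true_blocks: list[np.ndarray] = []
    scatter_blocks: list[np.ndarray] = []
    label_blocks: list[np.ndarray] = []
    for pop in populations:
        block = np.zeros((pop.n_events, nc), dtype=np.float64)
        for ch, (gm, gsd) in sorted(pop.signals.items()):
            block[:, ch - 1] = rng.lognormal(
                mean=np.log(gm), sigma=np.log(gsd), size=pop.n_events
            )
        true_blocks.append(block)
        sc = np.column_stack(
            [
                np.clip(rng.normal(mu, sd, size=pop.n_events), 0.0, None)
                for mu, sd in pop.scatter.values()
            ]
        )
        scatter_blocks.append(sc)
        label_blocks.append(np.full(pop.n_events, pop.name, dtype=object))

    true = np.concatenate(true_blocks)
    scatter = np.concatenate(scatter_blocks)
    labels = np.concatenate(label_blocks)

    observed = true @ (spill.matrix / 100.0)
    noise_scale = backgrounds / 3.0
    noise = np.abs(rng.normal(0.0, 1.0, size=observed.shape)) * noise_scale
    observed = observed + noise

    perm = rng.permutation(true.shape[0])
    true, scatter, labels, observed = (
        true[perm], scatter[perm], labels[perm], observed[perm],
    )

    values = np.column_stack([scatter, observed])
    names = scatter_names + list(spill.labels)
    table = RawEventTable(
        values=values,
        param_names=names,
        param_long_names=[""] * len(scatter_names) + list(spill.labels),
    )
    return table, GroundTruth(labels=labels, true_intensities=true)


def make_config(
    fcs_file: str,
    spill: SpilloverTable,
    backgrounds: np.ndarray | list[float],
    *,
    emissions: dict[str, float] | None = None,
    include: set[int] | None = None,
    exclude: set[int] | None = None,
    resultant: set[int] | None = None,
    scatter_names: tuple[str, str] = ("FSC-A", "SSC-A"),
) -> AnalysisConfig:
    """Build the AnalysisConfig matching a :func:`generate` layout.

    Column layout: scatter axes first, then one column per spillover label.
    Emissions default to the packaged fluorochrome table for known labels,
    else to an ascending synthetic ladder.
    """
    nc = spill.nc
    backgrounds = np.asarray(backgrounds, dtype=np.float64)
    n_scatter = len(scatter_names)
    channels = []
    for j, label in enumerate(spill.labels):
        if emissions and label in emissions:
            em = emissions[label]
        elif label in BOX1_EMISSIONS_NM:
            em = BOX1_EMISSIONS_NM[label]
        else:
            em = 500.0 + 50.0 * j
        channels.append(
            ChannelDef(
                index=j + 1,
                source_column=n_scatter + j + 1,
                label=label,
                emission_nm=em,
                background=float(backgrounds[j]),
            )
        )
    cfg = AnalysisConfig(
        fcs_file=fcs_file,
        total_columns=n_scatter + nc,
        used_columns=list(range(1, n_scatter + nc + 1)),
        scatter_columns={name: i + 1 for i, name in enumerate(scatter_names)},
        channels=channels,
        spillover=spill,
        include=set(include or set()),
        exclude=set(exclude or set()),
        resultant=set(resultant if resultant is not None else range(1, nc + 1)),
    )
    cfg.validate()
    return cfg


def emit_experiment(
    out_dir: str | Path,
    populations: list[PopulationSpec],
    spill: SpilloverTable,
    backgrounds: np.ndarray | list[float],
    seed: int,
    *,
    include: set[int] | None = None,
    exclude: set[int] | None = None,
    resultant: set[int] | None = None,
) -> dict[str, Path]:
    """Write a ready-to-run experiment: FCS file, in.dat config, ground-truth CSV."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = generate(populations, spill, backgrounds, seed)
    fcs_path = out_dir / "sample.fcs"
    write_fcs(table, fcs_path)
    cfg = make_config(
        str(fcs_path), spill, backgrounds,
        include=include, exclude=exclude, resultant=resultant,
    )
    cfg_path = write_config(cfg, out_dir / "in.dat")
    truth_frame = pd.DataFrame(
        truth.true_intensities, columns=[f"true_{lbl}" for lbl in spill.labels]
    )
    truth_frame.insert(0, "population", truth.labels)
    truth_path = out_dir / "ground_truth.csv"
    truth_frame.to_csv(truth_path, index=False)
    return {"fcs": fcs_path, "config": cfg_path, "ground_truth": truth_path}
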