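import numpy as np
import pytest

from mcta.config import AnalysisConfig, ChannelDef, SpilloverTable
from mcta.synth import PopulationSpec, box1_spillover, generate, make_config


@pytest.fixture
def box1() -> SpilloverTable:
    return box1_spillover()


@pytest.fixture
def identity_spill() -> SpilloverTable:
    return SpilloverTable(matrix=np.eye(3) * 100.0, labels=["A", "B", "C"])


def build_config(
    nc: int = 3,
    *,
    backgrounds=None,
    include=frozenset(),
    exclude=frozenset(),
    resultant=None,
    emissions=None,
    total_columns=None,
) -> AnalysisConfig:
    """Small hand-rolled config: scatter in columns 1-2, channels from column 3."""
    backgrounds = list(backgrounds) if backgrounds is not None else [0.0] * nc
    emissions = list(emissions) if emissions is not None else [
        500.0 + 40.0 * j for j in range(nc)
    ]
    channels = [
        ChannelDef(
            index=j + 1,
            source_column=3 + j,
            label=f"M{j + 1}",
            emission_nm=emissions[j],
            background=backgrounds[j],
        )
        for j in range(nc)
    ]
    cfg = AnalysisConfig(
        fcs_file="sample.fcs",
        total_columns=total_columns or (nc + 2),
        used_columns=list(range(1, nc + 3)),
        scatter_columns={"FSC-A": 1, "SSC-A": 2},
        channels=channels,
        spillover=SpilloverTable(matrix=np.eye(nc) * 100.0),
        include=set(include),
        exclude=set(exclude),
        resultant=set(resultant) if resultant is not None else set(range(1, nc + 1)),
    )
    cfg.validate()
    return cfg


@pytest.fixture
def config_builder():
    return build_config


@pytest.fixture
def three_pop_experiment(box1):
    """Box 1 panel, three populations with distinct dominant channels."""
    backgrounds = np.array([30.0, 30.0, 30.0, 30.0, 30.0])
    populations = [
        PopulationSpec(
            name="popA", n_events=400,
            signals={1: (1800.0, 1.4), 2: (200.0, 1.4), 4: (200.0, 1.4)},
            dominant_channel=1,
        ),
        PopulationSpec(
            name="popB", n_events=400,
            signals={3: (1800.0, 1.4), 2: (200.0, 1.4), 5: (200.0, 1.4)},
            dominant_channel=3,
        ),
        PopulationSpec(
            name="popC", n_events=400,
            signals={5: (1800.0, 1.4), 1: (200.0, 1.4), 3: (200.0, 1.4)},
            dominant_channel=5,
        ),
    ]
    table, truth = generate(populations, box1, backgrounds, seed=20240917)
    cfg = make_config("sample.fcs", box1, backgrounds)
    return table, truth, cfg, populations
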