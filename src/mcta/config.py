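"""Analysis configuration: channel map, emissions, backgrounds, spillover, roles.

Two interchangeable on-disk forms are accepted: a line-oriented ``in.dat``
dialect (``key = value`` lines, a spillover block, and a signed-token role
line) and a JSON document with the same field names.  ``#`` comments and
blank lines are permitted in the text form.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ChannelDef",
    "SpilloverTable",
    "AnalysisConfig",
    "ConfigError",
    "parse_config",
    "parse_config_text",
    "serialize_config",
    "write_config",
    "validate_against",
]


class ConfigError(ValueError):
    """Raised when a configuration file violates the syntax or logical rules."""


@dataclass
class ChannelDef:
    """One renumbered fluorescence channel.

    ``index`` is the 1-based renumbered channel id used by roles and the
    spillover matrix; ``source_column`` is the original 1-based FCS column.
    ``hue_deg`` is filled by the color model (or by an explicit ``hue:``
    override in the config).
    """

    index: int
    source_column: int
    label: str
    emission_nm: float
    background: float
    hue_deg: float | None = None

    def __post_init__(self) -> None:
        if self.emission_nm <= 0:
            raise ConfigError(f"channel {self.index}: emission must be positive")
        if self.background < 0:
            raise ConfigError(f"channel {self.index}: background must be >= 0")


@dataclass
class SpilloverTable:
    """Percent spillover matrix, rows = source fluorochrome, columns = detector."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape != (n, n):
            raise ConfigError("spillover matrix must be square")
        if not np.allclose(np.diag(self.matrix), 100.0, atol=1e-9):
            raise ConfigError("spillover diagonal entries must equal 100.00")
        if (self.matrix < 0).any():
            raise ConfigError("spillover entries must be nonnegative")
        if not self.labels:
            self.labels = [f"ch{i + 1}" for i in range(n)]

    @property
    def nc(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AnalysisConfig:
    fcs_file: str
    total_columns: int
    used_columns: list[int]
    scatter_columns: dict[str, int]
    channels: list[ChannelDef]
    spillover: SpilloverTable
    include: set[int] = field(default_factory=set)
    exclude: set[int] = field(default_factory=set)
    resultant: set[int] = field(default_factory=set)

    @property
    def nc(self) -> int:
        return len(self.channels)

    @property
    def backgrounds(self) -> np.ndarray:
        return np.array([c.background for c in self.channels], dtype=np.float64)

    def channel(self, index: int) -> ChannelDef:
        for ch in self.channels:
            if ch.index == index:
                return ch
        raise KeyError(f"no channel with index {index}")

    def validate(self) -> None:
        nc = self.nc
        if nc == 0:
            raise ConfigError("at least one fluorescence channel is required")
        indices = [c.index for c in self.channels]
        if sorted(indices) != list(range(1, nc + 1)):
            raise ConfigError(f"channel indices must be exactly 1..{nc}, got {indices}")
        sources = [c.source_column for c in self.channels]
        if len(set(sources)) != len(sources):
            dupes = sorted({s for s in sources if sources.count(s) > 1})
            raise ConfigError(f"duplicate source columns: {dupes}")
        for c in self.channels:
            if not 1 <= c.source_column <= self.total_columns:
                raise ConfigError(
                    f"channel {c.index} source column {c.source_column} "
                    f"outside 1..{self.total_columns}"
                )
        for role_a, role_b in (
            ("include", "exclude"),
            ("include", "resultant"),
            ("exclude", "resultant"),
        ):
            overlap = getattr(self, role_a) & getattr(self, role_b)
            if overlap:
                raise ConfigError(
                    f"channels {sorted(overlap)} appear in both {role_a} and {role_b}"
                )
        for role in ("include", "exclude", "resultant"):
            bad = [k for k in getattr(self, role) if not 1 <= k <= nc]
            if bad:
                raise ConfigError(f"{role} references unknown channels {sorted(bad)}")
        if not self.resultant:
            raise ConfigError("resultant channel set must not be empty")
        if self.spillover.nc != nc:
            raise ConfigError(
                f"spillover is {self.spillover.nc}x{self.spillover.nc} "
                f"but there are {nc} channels"
            )


_CHANNEL_RE = re.compile(r"^channel\s+(\d+)$")


def _parse_channel_fields(index: int, value: str) -> ChannelDef:
    fields: dict[str, str] = {}
    for part in value.split(","):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ConfigError(f"channel {index}: malformed field {part!r}")
        key, _, val = part.partition(":")
        fields[key.strip().lower()] = val.strip()
    missing = {"column", "label", "emission", "background"} - fields.keys()
    if missing:
        raise ConfigError(f"channel {index}: missing fields {sorted(missing)}")
    hue = fields.get("hue")
    return ChannelDef(
        index=index,
        source_column=int(fields["column"]),
        label=fields["label"],
        emission_nm=float(fields["emission"]),
        background=float(fields["background"]),
        hue_deg=float(hue) if hue is not None else None,
    )


def _parse_roles(tokens: list[str]) -> tuple[set[int], set[int], set[int]]:
    include: set[int] = set()
    exclude: set[int] = set()
    resultant: set[int] = set()
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            continue
        if tok.startswith("0:"):
            resultant.add(int(tok[2:]))
        elif tok.startswith("-"):
            exclude.add(int(tok[1:]))
        else:
            include.add(int(tok.lstrip("+")))
    return include, exclude, resultant


def parse_config_text(text: str, *, origin: str = "<config>") -> AnalysisConfig:
    """Parse the ``in.dat`` text dialect into a validated :class:`AnalysisConfig`."""
    lines = text.splitlines()
    scalars: dict[str, str] = {}
    channels: list[ChannelDef] = []
    spill_rows: list[list[float]] = []
    roles_tokens: list[str] | None = None
    in_spill = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if in_spill:
            try:
                spill_rows.append([float(x) for x in line.split()])
                continue
            except ValueError:
                in_spill = False  # first non-numeric line ends the block
        if "=" not in line:
            raise ConfigError(f"{origin}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        m = _CHANNEL_RE.match(key)
        if m:
            channels.append(_parse_channel_fields(int(m.group(1)), value))
        elif key == "spillover":
            in_spill = True
            if value:
                spill_rows.append([float(x) for x in value.split()])
        elif key == "roles":
            roles_tokens = value.split()
        else:
            scalars[key] = value

    for required in ("file", "total_columns", "used_columns"):
        if required not in scalars:
            raise ConfigError(f"{origin}: missing required key {required!r}")
    if roles_tokens is None:
        raise ConfigError(f"{origin}: missing 'roles' line")
    if not spill_rows:
        raise ConfigError(f"{origin}: missing spillover block")
    widths = {len(r) for r in spill_rows}
    if widths != {len(spill_rows)}:
        raise ConfigError(f"{origin}: spillover block is not square")

    scatter: dict[str, int] = {}
    for part in scalars.get("scatter", "").split(","):
        part = part.strip()
        if not part:
            continue
        name, _, col = part.rpartition(":")
        scatter[name.strip()] = int(col)

    include, exclude, resultant = _parse_roles(roles_tokens)
    channels.sort(key=lambda c: c.index)
    cfg = AnalysisConfig(
        fcs_file=scalars["file"],
        total_columns=int(scalars["total_columns"]),
        used_columns=[int(x) for x in scalars["used_columns"].split(",") if x.strip()],
        scatter_columns=scatter,
        channels=channels,
        spillover=SpilloverTable(
            matrix=np.array(spill_rows), labels=[c.label for c in channels]
        ),
        include=include,
        exclude=exclude,
        resultant=resultant,
    )
    cfg.validate()
    return cfg


def _parse_config_json(text: str, *, origin: str) -> AnalysisConfig:
    doc = json.loads(text)
    channels = [
        ChannelDef(
            index=int(c["index"]),
            source_column=int(c["column"]),
            label=str(c["label"]),
            emission_nm=float(c["emission"]),
            background=float(c["background"]),
            hue_deg=float(c["hue"]) if c.get("hue") is not None else None,
        )
        for c in doc["channels"]
    ]
    channels.sort(key=lambda c: c.index)
    cfg = AnalysisConfig(
        fcs_file=str(doc["file"]),
        total_columns=int(doc["total_columns"]),
        used_columns=[int(x) for x in doc["used_columns"]],
        scatter_columns={str(k): int(v) for k, v in doc.get("scatter", {}).items()},
        channels=channels,
        spillover=SpilloverTable(
            matrix=np.array(doc["spillover"], dtype=np.float64),
            labels=[c.label for c in channels],
        ),
        include={int(x) for x in doc.get("include", [])},
        exclude={int(x) for x in doc.get("exclude", [])},
        resultant={int(x) for x in doc.get("resultant", [])},
    )
    cfg.validate()
    return cfg


def parse_config(path: str | Path) -> AnalysisConfig:
    """Parse a configuration file (text dialect or JSON, detected by content)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if path.suffix.lower() == ".json" or stripped.startswith("{"):
        return _parse_config_json(text, origin=str(path))
    return parse_config_text(text, origin=str(path))


def serialize_config(cfg: AnalysisConfig) -> str:
    """Render a config back to the text dialect; reparsing yields an equal config."""
    out: list[str] = [
        f"file = {cfg.fcs_file}",
        f"total_columns = {cfg.total_columns}",
        "used_columns = " + ",".join(str(c) for c in cfg.used_columns),
    ]
    if cfg.scatter_columns:
        out.append(
            "scatter = "
            + ", ".join(f"{k}:{v}" for k, v in sorted(cfg.scatter_columns.items()))
        )
    for ch in cfg.channels:
        parts = (
            f"column:{ch.source_column}, label:{ch.label}, "
            f"emission:{ch.emission_nm:g}, background:{ch.background:g}"
        )
        if ch.hue_deg is not None:
            parts += f", hue:{ch.hue_deg:g}"
        out.append(f"channel {ch.index} = {parts}")
    out.append("spillover =")
    for row in cfg.spillover.matrix:
        out.append("  " + " ".join(f"{x:.6g}" for x in row))
    tokens = (
        [str(k) for k in sorted(cfg.include)]
        + [f"-{k}" for k in sorted(cfg.exclude)]
        + [f"0:{k}" for k in sorted(cfg.resultant)]
    )
    out.append("roles = " + " ".join(tokens))
    return "\n".join(out) + "\n"


def write_config(cfg: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(serialize_config(cfg), encoding="utf-8")
    return path


def validate_against(cfg: AnalysisConfig, table) -> list[str]:
    """Cross-check a config against a parsed FCS table.

    Returns a list of human-readable findings; empty means consistent.
    Never raises: findings, not exceptions.
    """
    findings: list[str] = []
    if cfg.total_columns != table.n_params:
        findings.append(
            f"config declares {cfg.total_columns} columns "
            f"but FCS file has {table.n_params}"
        )
    for col in cfg.used_columns:
        if not 1 <= col <= table.n_params:
            findings.append(f"used column {col} does not exist in the FCS file")
    for role, col in cfg.scatter_columns.items():
        if not 1 <= col <= table.n_params:
            findings.append(f"scatter column {role}:{col} does not exist")
    for ch in cfg.channels:
        if not 1 <= ch.source_column <= table.n_params:
            findings.append(
                f"channel {ch.index} ({ch.label}) source column "
                f"{ch.source_column} does not exist"
            )
    return findings


def with_roles(
    cfg: AnalysisConfig,
    *,
    include: set[int] | None = None,
    exclude: set[int] | None = None,
    resultant: set[int] | None = None,
) -> AnalysisConfig:
    """Return a copy of ``cfg`` with replaced role sets (validated)."""
    new = replace(
        cfg,
        include=set(cfg.include if include is None else include),
        exclude=set(cfg.exclude if exclude is None else exclude),
        resultant=set(cfg.resultant if resultant is None else resultant),
    )
    new.validate()
    return new
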