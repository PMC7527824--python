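"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Only the features needed by this pipeline are implemented: single-dataset
files, ``$MODE=L``, datatypes ``F`` (float32), ``D`` (float64) and ``I``
(unsigned 16/32-bit integers), both byte orders.  Values are returned on the
stored linear scale; log-amplified parameters (``$PnE`` other than ``0,0``)
trigger a warning and are read raw.
"""

from __future__ import annotations

import math
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RawEventTable",
    "FcsFormatError",
    "FcsTruncationError",
    "FcsUnsupportedError",
    "read_fcs",
    "write_fcs",
]


class FcsFormatError(ValueError):
    """Raised when the file is not a parseable FCS file."""


class FcsTruncationError(FcsFormatError):
    """Raised when the DATA segment is shorter than $TOT x $PAR items."""


class FcsUnsupportedError(FcsFormatError):
    """Raised for valid FCS features outside the supported subset."""


@dataclass
class RawEventTable:
    """Event matrix plus parameter naming read from (or destined for) FCS.

    Attributes
    ----------
    values : numpy.ndarray
        ``(n_events, n_params)`` float64 matrix on the stored linear scale.
    param_names : list of str
        Short names (``$PnN``), unique after normalization.
    param_long_names : list of str
        Optional stain labels (``$PnS``); empty string when absent.
    metadata : dict
        TEXT-segment keywords (uppercased keys) as read from the file.
    """

    values: np.ndarray
    param_names: list[str]
    param_long_names: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x parameters matrix")
        if len(self.param_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.param_names)} names for {self.values.shape[1]} columns"
            )
        if not self.param_long_names:
            self.param_long_names = [""] * self.values.shape[1]

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def column(self, source_column: int) -> np.ndarray:
        """Return one column by 1-based FCS column number."""
        if not 1 <= source_column <= self.n_params:
            raise IndexError(f"column {source_column} outside 1..{self.n_params}")
        return self.values[:, source_column - 1]


_HEADER_LEN = 58


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # a trailing delimiter is required by the standard; tolerate its absence
    if body.endswith(delim):
        body = body[:-1]
    # escaped delimiters (doubled) are not disambiguated; rare in practice
    tokens = body.split(delim)
    if len(tokens) % 2 != 0:
        tokens = tokens[:-1]
    out: dict[str, str] = {}
    for i in range(0, len(tokens), 2):
        key = tokens[i].decode("utf-8", "replace").strip().upper()
        val = tokens[i + 1].decode("utf-8", "replace").strip()
        if key:
            out[key] = val
    return out


def _require(meta: dict[str, str], key: str) -> str:
    if key not in meta:
        raise FcsFormatError(f"required keyword {key} missing from TEXT segment")
    return meta[key]


def read_fcs(path: str | Path) -> RawEventTable:
    """Read the first dataset of an FCS 3.0/3.1 file into a :class:`RawEventTable`.

    Raises
    ------
    FcsFormatError
        Missing/invalid header or required keywords.
    FcsTruncationError
        DATA segment shorter than ``$TOT * $PAR`` items.
    FcsUnsupportedError
        Datatype, mode or bit width outside the supported subset.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FcsFormatError(f"{path}: file shorter than FCS header")
    version = blob[0:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise FcsFormatError(f"{path}: bad magic {version!r}, not an FCS file")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsUnsupportedError(f"{path}: unsupported FCS version {version!r}")

    def offset(lo: int, hi: int) -> int:
        txt = blob[lo:hi].decode("ascii", "replace").strip()
        return int(txt) if txt else 0

    text_beg, text_end = offset(10, 18), offset(18, 26)
    data_beg, data_end = offset(26, 34), offset(34, 42)
    if text_beg <= 0 or text_end < text_beg:
        raise FcsFormatError(f"{path}: invalid TEXT segment offsets")
    meta = _parse_text_segment(blob[text_beg : text_end + 1])

    # large files store DATA offsets in TEXT instead of the header
    if data_beg == 0:
        data_beg = int(_require(meta, "$BEGINDATA"))
    if data_end == 0:
        data_end = int(_require(meta, "$ENDDATA"))

    mode = meta.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsUnsupportedError(f"{path}: $MODE={mode}; only list mode is supported")
    datatype = _require(meta, "$DATATYPE").upper()
    n_par = int(_require(meta, "$PAR"))
    n_tot = int(_require(meta, "$TOT"))
    byteord = _require(meta, "$BYTEORD")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FcsUnsupportedError(f"{path}: unsupported $BYTEORD={byteord}")

    bits = [int(_require(meta, f"$P{i}B")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsUnsupportedError(f"{path}: $DATATYPE=F requires $PnB=32")
        dtypes = [np.dtype(endian + "f4")] * n_par
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FcsUnsupportedError(f"{path}: $DATATYPE=D requires $PnB=64")
        dtypes = [np.dtype(endian + "f8")] * n_par
    elif datatype == "I":
        dtypes = []
        for b in bits:
            if b == 16:
                dtypes.append(np.dtype(endian + "u2"))
            elif b == 32:
                dtypes.append(np.dtype(endian + "u4"))
            else:
                raise FcsUnsupportedError(
                    f"{path}: $DATATYPE=I with $PnB={b}; only 16/32 supported"
                )
    else:
        raise FcsUnsupportedError(f"{path}: unsupported $DATATYPE={datatype}")

    row_bytes = sum(b // 8 for b in bits)
    data = blob[data_beg : data_end + 1]
    if len(data) < n_tot * row_bytes:
        raise FcsTruncationError(
            f"{path}: DATA segment holds {len(data)} bytes, "
            f"need {n_tot * row_bytes} for $TOT={n_tot} x $PAR={n_par}"
        )
    data = data[: n_tot * row_bytes]

    if len(set(dtypes)) == 1:
        values = (
            np.frombuffer(data, dtype=dtypes[0])
            .reshape(n_tot, n_par)
            .astype(np.float64)
        )
    else:  # mixed integer widths: structured read
        struct_dt = np.dtype([(f"p{i}", dt) for i, dt in enumerate(dtypes)])
        rec = np.frombuffer(data, dtype=struct_dt)
        values = np.column_stack(
            [rec[f"p{i}"].astype(np.float64) for i in range(n_par)]
        )

    names: list[str] = []
    long_names: list[str] = []
    for i in range(1, n_par + 1):
        name = meta.get(f"$P{i}N", f"P{i}").strip() or f"P{i}"
        if name in names:  # dialect normalization: disambiguate duplicates
            name = f"{name}.{i}"
        names.append(name)
        long_names.append(meta.get(f"$P{i}S", "").strip())

        amp = meta.get(f"$P{i}E", "0,0").replace(" ", "")
        if amp not in ("0,0", "0.0,0.0", ""):
            warnings.warn(
                f"{path}: $P{i}E={amp} declares log amplification; reading raw values",
                stacklevel=2,
            )
        if datatype == "I":
            rng = meta.get(f"$P{i}R")
            if rng:
                r = int(float(rng))
                if r > 0:
                    mask = (1 << max(1, math.ceil(math.log2(r)))) - 1
                    values[:, i - 1] = (
                        values[:, i - 1].astype(np.uint64) & np.uint64(mask)
                    ).astype(np.float64)
        gain = meta.get(f"$P{i}G")
        if gain:
            g = float(gain)
            if g > 0 and g != 1.0:
                values[:, i - 1] = values[:, i - 1] / g

    if meta.get("$NEXTDATA", "0").strip() not in ("0", ""):
        warnings.warn(
            f"{path}: multi-dataset file ($NEXTDATA != 0); only the first dataset is read",
            stacklevel=2,
        )
    if np.isnan(values).any():
        raise FcsFormatError(f"{path}: DATA segment contains NaN values")

    return RawEventTable(
        values=values, param_names=names, param_long_names=long_names, metadata=meta
    )


def write_fcs(table: RawEventTable, path: str | Path) -> Path:
    """Write ``table`` as a minimal single-dataset FCS 3.1 file.

    The file is float32 little-endian list mode and round-trips through
    :func:`read_fcs` within float32 precision.  Output is deterministic:
    identical tables produce identical bytes.
    """
    if table.n_events == 0 or table.n_params == 0:
        raise ValueError("cannot write an empty event table")
    path = Path(path)

    n_tot, n_par = table.values.shape
    keywords: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i in range(n_par):
        keywords.append((f"$P{i + 1}N", table.param_names[i]))
        if table.param_long_names[i]:
            keywords.append((f"$P{i + 1}S", table.param_long_names[i]))
        keywords.append((f"$P{i + 1}B", "32"))
        keywords.append((f"$P{i + 1}E", "0,0"))
        col_max = float(np.max(table.values[:, i])) if n_tot else 0.0
        rng = max(1, int(math.ceil(col_max)) + 1)
        keywords.append((f"$P{i + 1}R", str(rng)))

    delim = "/"
    for key, val in keywords:
        if delim in key or delim in val:
            raise ValueError(f"keyword text may not contain {delim!r}: {key}={val}")

    data = np.ascontiguousarray(table.values, dtype="<f4").tobytes()

    def build_text(data_beg: int, data_end: int) -> bytes:
        pairs = [("$BEGINDATA", str(data_beg)), ("$ENDDATA", str(data_end))] + keywords
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs) + delim
        return body.encode("ascii")

    # TEXT length depends on DATA offsets; two passes reach a fixed point
    text = build_text(0, 0)
    for _ in range(4):
        text_beg = _HEADER_LEN
        text_end = text_beg + len(text) - 1
        data_beg = text_end + 1
        data_end = data_beg + len(data) - 1
        new_text = build_text(data_beg, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:  # pragma: no cover - offsets stabilize in <= 2 iterations
        raise RuntimeError("TEXT segment offsets failed to stabilize")

    header = struct.pack(
        "<6s4s8s8s8s8s8s8s",
        b"FCS3.1",
        b"    ",
        str(text_beg).rjust(8).encode(),
        str(text_end).rjust(8).encode(),
        str(data_beg).rjust(8).encode() if data_end <= 99_999_999 else b"       0",
        str(data_end).rjust(8).encode() if data_end <= 99_999_999 else b"       0",
        b"       0",
        b"       0",
    )
    path.write_bytes(header + text + data)
    return path
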