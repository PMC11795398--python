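"""Minimal FCS 3.0/3.1 list-mode reader and a fixture writer.

Supports uncompressed list-mode ($MODE=L) files with $DATATYPE F, D or I
and either byte order. The writer emits just enough of the standard
(float32, little-endian) to round-trip fixtures through the reader; it is
not an instrument-grade exporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FCSParseError, UnsupportedFormatError

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")

# $DATATYPE -> (numpy kind, fixed itemsize or None meaning use $PnB/8)
_DTYPE_KIND = {"F": "f", "D": "f", "I": "u"}


@dataclass
class FCSFile:
    """Parsed FCS content: keyword table plus the event matrix."""

    text: dict[str, str]
    events: np.ndarray          # (n_events, n_channels) float64
    channel_names: list[str]    # $PnS when present, else $PnN
    short_names: list[str] = field(default_factory=list)  # $PnN


def _read_offsets(header: bytes) -> tuple[str, int, int, int, int]:
    version = header[0:6].decode("ascii", errors="replace")
    if version not in _SUPPORTED_VERSIONS:
        raise UnsupportedFormatError(f"unsupported FCS version {version!r}")

    def off(a: int, b: int, what: str) -> int:
        raw = header[a:b].decode("ascii", errors="replace").strip()
        if raw == "":
            return 0
        try:
            return int(raw)
        except ValueError as exc:
            raise FCSParseError(f"non-numeric {what} offset {raw!r} in header") from exc

    return (version, off(10, 18, "TEXT begin"), off(18, 26, "TEXT end"),
            off(26, 34, "DATA begin"), off(34, 42, "DATA end"))


def _parse_text(segment: bytes) -> dict[str, str]:
    if len(segment) < 2:
        raise FCSParseError("TEXT segment too short")
    delim = segment[0:1]
    body = segment[1:]
    if body.endswith(delim):
        body = body[:-1]
    # doubled delimiters escape a literal delimiter inside a value
    sentinel = b"\x00\x01\x02"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2 != 0:
        raise FCSParseError("TEXT segment has an odd number of delimited tokens")
    out: dict[str, str] = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        out[key.decode("utf-8", errors="replace").strip().upper()] = (
            value.decode("utf-8", errors="replace")
        )
    return out


def _require(text: dict[str, str], key: str) -> str:
    if key not in text:
        raise FCSParseError(f"required keyword {key} missing from TEXT segment")
    return text[key]


def read_fcs_file(path: str) -> FCSFile:
    """Parse an FCS 3.0/3.1 file into keywords and an event matrix."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FCSParseError("file shorter than a valid FCS header")
    _, t0, t1, d0, d1 = _read_offsets(raw[:58])
    if t1 <= t0:
        raise FCSParseError("invalid TEXT segment offsets in header")
    text = _parse_text(raw[t0:t1 + 1])

    if d0 == 0 and d1 == 0:
        d0 = int(text.get("$BEGINDATA", "0"))
        d1 = int(text.get("$ENDDATA", "0"))

    mode = _require(text, "$MODE").strip().upper()
    if mode != "L":
        raise UnsupportedFormatError(f"only list mode supported, got $MODE={mode}")
    datatype = _require(text, "$DATATYPE").strip().upper()
    if datatype not in _DTYPE_KIND:
        raise UnsupportedFormatError(f"unsupported $DATATYPE={datatype}")
    n_par = int(_require(text, "$PAR"))
    n_tot = int(_require(text, "$TOT"))
    byteord = _require(text, "$BYTEORD").strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise UnsupportedFormatError(f"unsupported $BYTEORD={byteord}")

    bits = [int(_require(text, f"$P{i}B")) for i in range(1, n_par + 1)]
    if datatype == "F" and any(b != 32 for b in bits):
        raise UnsupportedFormatError("$DATATYPE=F requires 32-bit $PnB")
    if datatype == "D" and any(b != 64 for b in bits):
        raise UnsupportedFormatError("$DATATYPE=D requires 64-bit $PnB")
    if datatype == "I" and len(set(bits)) > 1:
        raise UnsupportedFormatError("mixed-width integer channels not supported")

    itemsize = bits[0] // 8 if bits else 4
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    else:
        if itemsize not in (1, 2, 4, 8):
            raise UnsupportedFormatError(f"unsupported integer width {bits[0]} bits")
        dtype = np.dtype(f"{endian}u{itemsize}")

    n_values = n_tot * n_par
    if n_values:
        expected = n_values * dtype.itemsize
        blob = raw[d0:d1 + 1]
        if len(blob) < expected:
            raise FCSParseError(
                f"DATA segment holds {len(blob)} bytes; $TOT/$PAR require {expected}"
            )
        events = np.frombuffer(blob[:expected], dtype=dtype).astype(np.float64)
        events = events.reshape(n_tot, n_par)
    else:
        events = np.empty((0, n_par), dtype=np.float64)

    short_names = [_require(text, f"$P{i}N") for i in range(1, n_par + 1)]
    channel_names = [text.get(f"$P{i}S", "").strip() or short_names[i - 1]
                     for i in range(1, n_par + 1)]
    return FCSFile(text=text, events=events,
                   channel_names=channel_names, short_names=short_names)


def write_fcs_file(path: str, events: np.ndarray, channel_names: list[str],
                   stain_names: list[str] | None = None) -> None:
    """Write a minimal FCS 3.1 file (float32 LE) for test fixtures."""
    events = np.asarray(events, dtype="<f4")
    if events.ndim != 2:
        raise ValueError("events must be 2-D (events x channels)")
    n_tot, n_par = events.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match event columns")

    kw: list[tuple[str, str]] = [
        ("$MODE", "L"), ("$DATATYPE", "F"), ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)), ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i, name in enumerate(channel_names, start=1):
        kw += [(f"$P{i}N", name), (f"$P{i}B", "32"),
               (f"$P{i}E", "0,0"), (f"$P{i}R", "4194304")]
        if stain_names is not None and stain_names[i - 1]:
            kw.append((f"$P{i}S", stain_names[i - 1]))

    data = events.tobytes()
    header_len = 58
    # iterate because BEGINDATA/ENDDATA lengths depend on the TEXT length
    d0 = d1 = 0
    for _ in range(8):
        full = kw + [("$BEGINDATA", str(d0)), ("$ENDDATA", str(d1))]
        text = "/" + "/".join(f"{k}/{v}" for k, v in full) + "/"
        t0 = header_len
        t1 = t0 + len(text.encode("ascii")) - 1
        nd0 = t1 + 1
        nd1 = nd0 + len(data) - 1 if data else nd0
        if (nd0, nd1) == (d0, d1):
            break
        d0, d1 = nd0, nd1
    header = (
        "FCS3.1    "
        + f"{t0:>8d}{t1:>8d}"
        + (f"{d0:>8d}{d1:>8d}" if d1 < 10 ** 8 else f"{0:>8d}{0:>8d}")
        + f"{0:>8d}{0:>8d}"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("ascii"))
        fh.write(data)
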