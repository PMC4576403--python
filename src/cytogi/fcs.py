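"""Minimal FCS 3.0/3.1 list-mode codec.

Reads and writes the subset of the FCS standard this package needs: list-mode
(``$MODE L``) data stored as float32/float64 (``$DATATYPE F``/``D``) or
unsigned integers (``$DATATYPE I`` with 8/16/32/64-bit parameters), little- or
big-endian per ``$BYTEORD``.  Anything else is rejected with a named error
rather than guessed at.  Linear gain (``$PnG``) is applied on read;
log-amplified integer parameters (``$PnE`` with a nonzero decade count) are
not supported.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .events import EventTable

__all__ = [
    "FCSError",
    "FCSParseError",
    "TruncatedFCSError",
    "UnsupportedFCSError",
    "read_fcs",
    "write_fcs",
]

_DELIM = "/"
_HEADER_LEN = 58  # 6-byte version + 4 spaces + 6 eight-byte offsets


class FCSError(Exception):
    """Base class for FCS I/O failures."""


class FCSParseError(FCSError):
    """Structurally invalid file (bad header, missing keyword, ...)."""


class TruncatedFCSError(FCSError):
    """File ends before the declared data segment does."""


class UnsupportedFCSError(FCSError):
    """Valid FCS, but a dialect this codec does not handle."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    if not text:
        raise FCSParseError("empty TEXT segment")
    delim = text[0]
    # Split on the delimiter; the standard escapes a literal delimiter by
    # doubling it, which shows up here as empty fields to be re-joined.
    parts = text[1:].split(delim)
    fields: list[str] = []
    buf = ""
    i = 0
    while i < len(parts):
        buf += parts[i]
        if i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            buf += delim
            i += 2
            continue
        fields.append(buf)
        buf = ""
        i += 1
    if fields and fields[-1] == "":
        fields.pop()
    if len(fields) % 2 != 0:
        raise FCSParseError("TEXT segment has an unpaired keyword")
    return {
        fields[j].strip().upper(): fields[j + 1]
        for j in range(0, len(fields), 2)
    }


def _require(keywords: dict[str, str], name: str) -> str:
    if name not in keywords:
        raise FCSParseError(f"required keyword {name} missing from TEXT segment")
    return keywords[name]


def read_fcs(path: str | Path) -> EventTable:
    """Parse an FCS 3.0/3.1 file into an :class:`EventTable`.

    Channel order and names come from ``$PnN``; the declared instrument range
    (``$PnR``) is preserved in the returned table.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN:
        raise TruncatedFCSError(f"{path}: shorter than an FCS header")
    version = blob[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedFCSError(f"{path}: unsupported version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        field = blob[lo:hi].decode("ascii", errors="replace").strip()
        try:
            return int(field) if field else 0
        except ValueError:
            raise FCSParseError(f"{path}: malformed header offset {field!r}")

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_end >= len(blob):
        raise TruncatedFCSError(f"{path}: TEXT segment extends past end of file")
    kw = _parse_text_segment(blob[text_begin : text_end + 1])

    # FCS 3.x allows the header data offsets to be zero with the real offsets
    # in $BEGINDATA/$ENDDATA.
    if data_begin == 0:
        data_begin = int(_require(kw, "$BEGINDATA"))
        data_end = int(_require(kw, "$ENDDATA"))

    datatype = _require(kw, "$DATATYPE").strip().upper()
    mode = _require(kw, "$MODE").strip().upper()
    if mode != "L":
        raise UnsupportedFCSError(f"{path}: only list mode supported, got $MODE {mode}")
    byteord = _require(kw, "$BYTEORD").strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise UnsupportedFCSError(f"{path}: unsupported $BYTEORD {byteord}")
    n_par = int(_require(kw, "$PAR"))
    n_tot = int(_require(kw, "$TOT"))

    names, bits, ranges, gains = [], [], [], []
    for i in range(1, n_par + 1):
        names.append(_require(kw, f"$P{i}N").strip())
        bits.append(int(_require(kw, f"$P{i}B")))
        ranges.append(float(kw.get(f"$P{i}R", "1024")))
        gains.append(float(kw.get(f"$P{i}G", "1")))
        amp = kw.get(f"$P{i}E", "0,0").split(",")
        if datatype == "I" and float(amp[0]) != 0.0:
            raise UnsupportedFCSError(
                f"{path}: log-amplified parameter $P{i}E={kw[f'$P{i}E']} not supported"
            )

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise UnsupportedFCSError(f"{path}: $DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise UnsupportedFCSError(f"{path}: $DATATYPE D requires 64-bit parameters")
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        width = set(bits)
        if len(width) != 1 or bits[0] not in (8, 16, 32, 64):
            raise UnsupportedFCSError(
                f"{path}: $DATATYPE I with mixed or non-byte-aligned widths {sorted(width)}"
            )
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise UnsupportedFCSError(f"{path}: unsupported $DATATYPE {datatype}")

    expected = n_tot * n_par * dtype.itemsize
    segment = blob[data_begin : data_end + 1]
    if len(segment) < expected:
        if len(blob) < data_begin + expected:
            raise TruncatedFCSError(
                f"{path}: data segment holds {len(segment)} bytes, "
                f"{expected} required for {n_tot} events x {n_par} channels"
            )
        segment = blob[data_begin : data_begin + expected]
    values = np.frombuffer(segment[:expected], dtype=dtype).reshape(n_tot, n_par)
    values = values.astype(float)
    for j, g in enumerate(gains):
        if g not in (0.0, 1.0):
            values[:, j] /= g

    return EventTable(
        values=values,
        channels=tuple(names),
        ranges=tuple(ranges),
        subject_id=kw.get("SUBJECT_ID") or None,
        visit=kw.get("VISIT") or None,
    )


def write_fcs(events: EventTable, path: str | Path) -> None:
    """Write an :class:`EventTable` as a little-endian float32 FCS 3.1 file.

    Round-trips through :func:`read_fcs` to the same values within float32
    precision.  Refuses to write an event-less table: an empty FCS file is
    almost always an upstream bug, not a valid artifact.
    """
    if events.n_events == 0:
        raise ValueError("refusing to write an FCS file with zero events")
    path = Path(path)
    data = np.ascontiguousarray(events.values, dtype="<f4").tobytes()

    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(events.n_channels)),
        ("$TOT", str(events.n_events)),
    ]
    for i, (name, rng) in enumerate(zip(events.channels, events.ranges), start=1):
        kw += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", f"{rng:g}"),
        ]
    if events.subject_id:
        kw.append(("SUBJECT_ID", events.subject_id))
    if events.visit:
        kw.append(("VISIT", events.visit))

    # Two-pass offset computation: data offsets appear inside TEXT, so build
    # TEXT with fixed-width placeholders first.
    def render(begin_data: int, end_data: int) -> bytes:
        pairs = [("$BEGINDATA", f"{begin_data:010d}"), ("$ENDDATA", f"{end_data:010d}")] + kw
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in pairs) + _DELIM
        return body.encode("ascii")

    text = render(0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text = render(data_begin, data_end)

    header = (
        b"FCS3.1    "
        + f"{text_begin:8d}".encode()
        + f"{text_end:8d}".encode()
        + (f"{data_begin:8d}".encode() if data_begin <= 99_999_999 else b"       0")
        + (f"{data_end:8d}".encode() if data_end <= 99_999_999 else b"       0")
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    path.write_bytes(header + text + data)
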