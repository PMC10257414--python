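"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer.

Writes list-mode float32 files with a single data segment ($DATATYPE/F,
$MODE/L, little-endian $BYTEORD/1,2,3,4), carrying the channel name in $PnN
and the marker name in $PnS. Reads both FCS 3.0 and 3.1 with float or double
data. Channel matching against a panel is by $PnS first, $PnN fallback,
case-insensitive; the returned matrix follows panel order, not file order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .events import EventMatrix
from .panel import MarkerPanel

_DELIM = "|"  # keyword values may legitimately contain "/" (e.g. pSmad1/5/9)


class FCSFormatError(ValueError):
    """Raised when a file does not parse as FCS 3.0/3.1."""


def write_fcs(events: EventMatrix, path: str | Path) -> Path:
    """Persist raw events as FCS 3.1 (float32 list mode)."""
    if events.transform != "raw":
        raise ValueError("only raw event matrices are persisted to FCS")
    path = Path(path)
    data = np.ascontiguousarray(events.values, dtype="<f4")
    n_cells, n_par = data.shape

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_cells)),
    ]
    for i, entry in enumerate(events.panel, start=1):
        keywords += [
            (f"$P{i}N", entry.channel),
            (f"$P{i}S", entry.marker),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1, np.ceil(data[:, i - 1].max() if n_cells else 1))))),
        ]
    sid = events.sample_id
    if isinstance(sid, str):
        keywords.append(("$SRC", sid))

    for key, value in keywords:
        if _DELIM in key or _DELIM in value:
            raise ValueError(f"keyword {key!r}={value!r} contains the TEXT delimiter")

    header_len = 58  # 6 version + 4 spaces + 6 fields x 8 chars
    # Two passes: placeholder offsets first, then rebuild with real numbers.
    begin_data = end_data = 0
    for _ in range(2):
        kw = keywords + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kw) + _DELIM
        text_start = header_len
        text_end = text_start + len(text) - 1
        begin_data = text_end + 1
        end_data = begin_data + data.nbytes - 1 if data.nbytes else 0
    if text_end > 99_999_999:
        raise ValueError("TEXT segment too large for this writer")

    def _field(n: int) -> bytes:
        return f"{n:>8d}".encode("ascii")

    header = b"FCS3.1    " \
        + _field(text_start) + _field(text_end) \
        + _field(begin_data if data.nbytes else 0) + _field(end_data) \
        + _field(0) + _field(0)
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(data.tobytes())
    return path


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise FCSFormatError("empty TEXT segment")
    delim = segment[:1].decode("latin-1")
    body = segment.decode("latin-1")
    # Double delimiters escape a literal delimiter; rare — handle via sentinel.
    sentinel = "\x00"
    body = body.replace(delim * 2, sentinel)
    parts = [p.replace(sentinel, delim) for p in body.split(delim)]
    parts = parts[1:]  # leading delimiter
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def _read_segments(path: Path) -> tuple[dict[str, str], bytes]:
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FCSFormatError(f"{path} too short to be an FCS file")
    version = raw[:6].decode("latin-1", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"unsupported FCS version {version!r}")

    def _offset(a: int, b: int) -> int:
        s = raw[a:b].decode("latin-1").strip()
        return int(s) if s else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if not (0 < text_start < text_end):
        raise FCSFormatError("invalid TEXT segment offsets")
    text = _parse_text(raw[text_start:text_end + 1])
    if data_start == 0 and "$BEGINDATA" in text:
        data_start = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    n_tot = int(text["$TOT"])
    data = raw[data_start:data_end + 1] if n_tot else b""
    return text, data


def read_fcs(path: str | Path, panel: MarkerPanel) -> EventMatrix:
    """Read an FCS file and return raw events in panel channel order.

    Every panel channel must be present in the file ($PnS marker name first,
    $PnN channel name fallback, case-insensitive); a missing channel raises
    ``KeyError`` naming it.
    """
    path = Path(path)
    try:
        text, data = _read_segments(path)
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text.get("$DATATYPE", "F").upper()
        byteord = text.get("$BYTEORD", "1,2,3,4")
    except FCSFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FCSFormatError(f"cannot parse {path}: {exc}") from exc

    if datatype not in ("F", "D"):
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r} (float data only)")
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(f"{endian}f{4 if datatype == 'F' else 8}")
    widths = {int(text.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
    if widths - {dtype.itemsize * 8}:
        raise FCSFormatError(f"unsupported $PnB widths {sorted(widths)} for type {datatype}")

    n_expected = n_tot * n_par * dtype.itemsize
    if len(data) < n_expected:
        raise FCSFormatError("DATA segment shorter than $TOT x $PAR")
    matrix = np.frombuffer(data[:n_expected], dtype=dtype).reshape(n_tot, n_par).astype(float)

    by_name: dict[str, int] = {}
    for i in range(1, n_par + 1):
        pnn = text.get(f"$P{i}N", "").strip().lower()
        pns = text.get(f"$P{i}S", "").strip().lower()
        if pnn and pnn not in by_name:
            by_name[pnn] = i - 1
    by_short = {}
    for i in range(1, n_par + 1):
        pns = text.get(f"$P{i}S", "").strip().lower()
        if pns and pns not in by_short:
            by_short[pns] = i - 1

    order = []
    for entry in panel:
        j = by_short.get(entry.marker.lower())
        if j is None:
            j = by_name.get(entry.channel.lower())
        if j is None:
            j = by_short.get(entry.channel.lower())
        if j is None:
            raise KeyError(
                f"channel {entry.channel!r} (marker {entry.marker!r}) not found in {path.name}"
            )
        order.append(j)
    sample_id = text.get("$SRC")
    return EventMatrix(matrix[:, order], panel, "raw", sample_id)
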