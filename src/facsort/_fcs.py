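"""Minimal FCS 3.0/3.1 codec.

Covers the subset of the standard this toolkit needs: a single dataset with
HEADER, TEXT and DATA segments, list-mode float data. Keyword preservation
beyond channel names, bit widths and amplification is a non-goal, as are
integer/ASCII data types and supplemental TEXT segments.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import FormatError

_HEADER_LEN = 58
_DELIM = "/"

#: $PnE "f1,f2" with f1 > 0 declares log amplification for channel n.


def _required(keywords: dict[str, str], key: str, segment: str) -> str:
    try:
        return keywords[key]
    except KeyError:
        raise FormatError(f"FCS {segment} segment: missing required keyword {key}") from None


def read(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read an FCS 3.0/3.1 file.

    Returns ``(channel_names, values, scale_tags)`` where ``values`` is an
    ``(n_events, n_channels)`` float64 array and ``scale_tags[i]`` is
    ``"log10"`` when channel *i* declares log amplification, else ``"linear"``.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FormatError("FCS HEADER segment: file shorter than 58-byte header")
    version = raw[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"FCS HEADER segment: unsupported version {version!r}")
    try:
        offsets = [int(raw[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    except ValueError:
        raise FormatError("FCS HEADER segment: non-numeric segment offsets") from None
    text_begin, text_end, data_begin, data_end = offsets

    if not (0 < text_begin < text_end < len(raw)):
        raise FormatError("FCS HEADER segment: TEXT offsets out of range")
    text = raw[text_begin : text_end + 1].decode("utf-8", errors="replace")
    delim = text[0]
    if text[-1] != delim:
        raise FormatError("FCS TEXT segment: does not end with its delimiter")
    fields = text[1:-1].split(delim)
    if len(fields) % 2:
        raise FormatError("FCS TEXT segment: odd number of delimited fields")
    keywords = {fields[i].strip().upper(): fields[i + 1] for i in range(0, len(fields), 2)}

    if data_begin == 0 or data_end == 0:  # large files push offsets into TEXT
        data_begin = int(_required(keywords, "$BEGINDATA", "TEXT"))
        data_end = int(_required(keywords, "$ENDDATA", "TEXT"))

    datatype = _required(keywords, "$DATATYPE", "TEXT").strip().upper()
    if datatype not in ("F", "D"):
        raise FormatError(f"FCS TEXT segment: unsupported $DATATYPE {datatype!r} (need F or D)")
    mode = _required(keywords, "$MODE", "TEXT").strip().upper()
    if mode != "L":
        raise FormatError(f"FCS TEXT segment: unsupported $MODE {mode!r} (need list mode)")
    byteord = _required(keywords, "$BYTEORD", "TEXT").strip()
    if byteord == "1,2,3,4":
        endian = "<"
    elif byteord == "4,3,2,1":
        endian = ">"
    else:
        raise FormatError(f"FCS TEXT segment: unsupported $BYTEORD {byteord!r}")

    n_par = int(_required(keywords, "$PAR", "TEXT"))
    n_tot = int(_required(keywords, "$TOT", "TEXT"))
    names, tags = [], []
    for i in range(1, n_par + 1):
        names.append(_required(keywords, f"$P{i}N", "TEXT"))
        amp = keywords.get(f"$P{i}E", "0,0").split(",")
        try:
            decades = float(amp[0])
        except (ValueError, IndexError):
            decades = 0.0
        tags.append("log10" if decades > 0 else "linear")

    itemsize = 4 if datatype == "F" else 8
    expected = n_tot * n_par * itemsize
    blob = raw[data_begin : data_end + 1]
    if len(blob) < expected:
        raise FormatError(
            f"FCS DATA segment: truncated ({len(blob)} bytes, expected {expected})"
        )
    dtype = np.dtype(f"{endian}f{itemsize}")
    values = np.frombuffer(blob[:expected], dtype=dtype).astype(np.float64)
    return names, values.reshape(n_tot, n_par), tags


def write(path: str | Path, channels: list[str], values: np.ndarray) -> None:
    """Write a minimal FCS 3.1 file (list mode, little-endian float32)."""
    values = np.asarray(values, dtype=np.float64)
    n_tot, n_par = values.shape
    if n_par != len(channels):
        raise ValueError("channel count does not match value columns")

    pairs = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "%010d",
        "$ENDDATA": "%010d",
        "$NEXTDATA": "0",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(channels, start=1):
        if _DELIM in name:
            raise ValueError(f"channel name {name!r} contains the TEXT delimiter")
        peak = float(np.max(values[:, i - 1], initial=0.0))
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = str(int(np.ceil(peak)) + 1)

    # Fixed-width data offsets break the TEXT-length / offset circularity.
    def render(data_begin: int, data_end: int) -> str:
        parts = []
        for key, val in pairs.items():
            if val == "%010d":
                val = "%010d" % (data_begin if key == "$BEGINDATA" else data_end)
            parts.append(f"{key}{_DELIM}{val}")
        return _DELIM + _DELIM.join(parts) + _DELIM

    text_begin = _HEADER_LEN
    text_len = len(render(0, 0))
    data_begin = text_begin + text_len
    data_end = data_begin + n_tot * n_par * 4 - 1
    text = render(data_begin, data_end)
    assert len(text) == text_len

    header = b"FCS3.1    " + b"".join(
        b"%8d" % off
        for off in (text_begin, text_begin + text_len - 1, data_begin, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    payload = values.astype("<f4").tobytes(order="C")
    assert struct.calcsize("<f") == 4
    Path(path).write_bytes(header + text.encode("utf-8") + payload)
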