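"""Minimal FCS 3.0/3.1 list-mode reader (plus a writer for test fixtures).

Scope is deliberately narrow: single data segment, $MODE L (list mode),
$DATATYPE F (float32) or I (unsigned integer, uniform bit width), little-
or big-endian per $BYTEORD.  Analysis segments, compensation matrices and
gating metadata are ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_HEADER_LEN = 58
_SUPPORTED_VERSIONS = (b"FCS3.0", b"FCS3.1")


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str | float]]:
    """Read a list-mode FCS file into (events DataFrame, metadata dict).

    The DataFrame has one column per parameter ($PnN short names) and one
    row per event.  Metadata keys include ``version`` and, per channel,
    ``range:<name>`` holding the $PnR full-scale value.
    """
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER_LEN:
        raise ValueError("file too short to hold an FCS header")
    version = blob[:6]
    if version not in _SUPPORTED_VERSIONS:
        raise ValueError(
            f"unsupported FCS magic {version!r}; expected FCS3.0 or FCS3.1"
        )

    def _offset(lo: int) -> int:
        fieldtext = blob[lo : lo + 8].decode("ascii").strip()
        return int(fieldtext) if fieldtext else 0

    text_start, text_end = _offset(10), _offset(18)
    data_start, data_end = _offset(26), _offset(34)

    text = blob[text_start : text_end + 1].decode("ascii")
    if not text:
        raise ValueError("empty TEXT segment")
    delim = text[0]
    parts = text[1:].split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise ValueError("TEXT segment holds an odd number of tokens")
    keywords = {
        parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)
    }

    if data_start == 0:
        data_start = int(keywords["$BEGINDATA"])
        data_end = int(keywords["$ENDDATA"])

    mode = keywords.get("$MODE", "").strip().upper()
    if mode != "L":
        raise ValueError(f"only list mode ($MODE L) is supported, got {mode!r}")
    datatype = keywords.get("$DATATYPE", "").strip().upper()
    if datatype not in ("F", "I"):
        raise ValueError(f"only $DATATYPE F or I supported, got {datatype!r}")
    byteord = keywords.get("$BYTEORD", "").strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise ValueError(f"unsupported $BYTEORD {byteord!r}")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    bits = [int(keywords[f"$P{i}B"]) for i in range(1, n_par + 1)]
    if len(set(bits)) != 1:
        raise ValueError("mixed parameter bit widths are not supported")
    nbytes = bits[0] // 8
    if datatype == "F":
        if bits[0] != 32:
            raise ValueError("$DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(f"{endian}f4")
    else:
        if bits[0] not in (16, 32):
            raise ValueError("$DATATYPE I requires 16- or 32-bit parameters")
        dtype = np.dtype(f"{endian}u{nbytes}")

    expected = n_tot * n_par * nbytes
    segment = blob[data_start : data_end + 1]
    if len(segment) != expected:
        raise ValueError(
            f"data segment holds {len(segment)} bytes but $TOT={n_tot}, "
            f"$PAR={n_par} at {bits[0]} bits imply {expected}"
        )
    values = np.frombuffer(segment, dtype=dtype).reshape(n_tot, n_par)
    frame = pd.DataFrame(values.astype(np.float64), columns=names)

    meta: dict[str, str | float] = {"version": version.decode("ascii")}
    for i, name in enumerate(names, start=1):
        if f"$P{i}R" in keywords:
            meta[f"range:{name}"] = float(keywords[f"$P{i}R"])
    return frame, meta


def write_fcs_fixture(
    path: str | Path,
    channels: dict[str, np.ndarray],
    datatype: str = "F",
    byteord: str = "1,2,3,4",
    ranges: dict[str, float] | None = None,
) -> None:
    """Write a small single-segment FCS 3.0 file for round-trip testing.

    Not an instrument-grade writer: fixed keyword set, float32 or uint32
    storage, no analysis segment.
    """
    names = list(channels)
    arrays = [np.asarray(channels[n]) for n in names]
    n_tot = len(arrays[0])
    if any(len(a) != n_tot for a in arrays):
        raise ValueError("all channels must have the same number of events")
    endian = "<" if byteord == "1,2,3,4" else ">"
    if datatype == "F":
        stacked = np.stack(arrays, axis=1).astype(f"{endian}f4")
    elif datatype == "I":
        stacked = np.stack(arrays, axis=1).astype(f"{endian}u4")
    else:
        raise ValueError("datatype must be 'F' or 'I'")
    data = stacked.tobytes()

    ranges = ranges or {}
    delim = "/"
    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "{begindata}"),
        ("$ENDDATA", "{enddata}"),
        ("$BYTEORD", byteord),
        ("$DATATYPE", datatype),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(len(names))),
        ("$TOT", str(n_tot)),
    ]
    for i, name in enumerate(names, start=1):
        pairs.append((f"$P{i}N", name))
        pairs.append((f"$P{i}B", "32"))
        pairs.append((f"$P{i}E", "0,0"))
        pairs.append((f"$P{i}R", f"{ranges.get(name, 262144)}"))

    # fixed-width offsets keep the TEXT length independent of their values
    template = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs) + delim
    text_start = _HEADER_LEN
    text_len = len(template.format(begindata="0" * 10, enddata="0" * 10))
    text_end = text_start + text_len - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1
    text = template.format(
        begindata=f"{data_start:010d}", enddata=f"{data_end:010d}"
    )
    assert len(text) == text_len

    header = b"FCS3.0    " + (
        f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text.encode("ascii") + data)
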