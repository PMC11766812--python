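"""Minimal FCS 3.0 reader/writer (list mode, float32, little-endian).

Only the subset needed to exchange event tables with cytometry software
is implemented: the HEADER offsets, the delimited TEXT segment, and an
uncompressed float DATA segment.  No ANALYSIS segment, no $PnE scaling.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd


class FCSFormatError(ValueError):
    """Raised when a file does not parse as FCS 3.0/3.1."""


def write_fcs(path, data: pd.DataFrame, delimiter: str = "/") -> None:
    """Write a DataFrame of float channels as an FCS 3.0 file."""
    names = list(data.columns)
    arr = np.ascontiguousarray(data.to_numpy(dtype="<f4"))
    n_events, n_par = arr.shape

    def build_text(data_begin: int, data_end: int) -> bytes:
        kv = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": str(data_begin), "$ENDDATA": str(data_end),
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
            "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
        }
        for i, name in enumerate(names, start=1):
            kv[f"$P{i}N"] = name
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            kv[f"$P{i}R"] = str(int(max(float(np.max(arr[:, i - 1], initial=0.0)), 1)) + 1)
        text = delimiter + delimiter.join(f"{k}{delimiter}{v}" for k, v in kv.items()) + delimiter
        return text.encode("ascii")

    header_len = 58
    text_begin = header_len
    # offsets appear inside TEXT, so iterate until stable
    data_begin = data_end = 0
    for _ in range(8):
        text = build_text(data_begin, data_end)
        new_begin = text_begin + len(text)
        new_end = new_begin + arr.nbytes - 1
        if (new_begin, new_end) == (data_begin, data_end):
            break
        data_begin, data_end = new_begin, new_end
    text = build_text(data_begin, data_end)
    header = (
        b"FCS3.0    "
        + f"{text_begin:8d}".encode()
        + f"{text_begin + len(text) - 1:8d}".encode()
        + f"{data_begin:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(arr.tobytes())


def read_fcs(path) -> tuple[dict, pd.DataFrame]:
    """Read an FCS 3.0/3.1 file; returns (keywords, events DataFrame)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FCSFormatError("not an FCS 3.0/3.1 file")
    try:
        text_begin = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FCSFormatError("malformed HEADER offsets") from exc
    text = raw[text_begin:text_end + 1].decode("ascii", errors="replace")
    if not text:
        raise FCSFormatError("empty TEXT segment")
    delim = text[0]
    tokens = text.strip(delim).split(delim)
    kw = {tokens[i]: tokens[i + 1] for i in range(0, len(tokens) - 1, 2)}

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        data_begin = int(kw.get("$BEGINDATA") or raw[26:34])
        data_end = int(kw.get("$ENDDATA") or raw[34:42])
    except (KeyError, ValueError) as exc:
        raise FCSFormatError(f"missing required keyword: {exc}") from exc
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise FCSFormatError("only list-mode float ($DATATYPE/F, $MODE/L) supported")
    dtype = "<f4" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">f4"
    blob = raw[data_begin:data_end + 1]
    expected = n_par * n_tot * 4
    if len(blob) < expected:
        raise FCSFormatError("DATA segment shorter than $PAR * $TOT events")
    arr = np.frombuffer(blob[:expected], dtype=dtype).reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return kw, pd.DataFrame(arr.astype(float), columns=names)
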