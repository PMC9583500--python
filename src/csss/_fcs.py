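"""Minimal read-only parser for FCS 3.0 / 3.1 flow-cytometry files.

Supports list-mode ($MODE L) data with $DATATYPE F (float32), D (float64)
or I (unsigned integer with byte-aligned $PnB), and $BYTEORD little/big
endian. Spillover compensation, gating and analysis segments are ignored.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_fcs"]


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty TEXT segment")
    delim = raw[0:1]
    # split on the delimiter; FCS escapes a literal delimiter by doubling it
    parts = raw[1:].split(delim)
    # re-join doubled delimiters (empty fields between two delimiters)
    fields: list[str] = []
    i = 0
    while i < len(parts):
        piece = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == b"" and i + 2 < len(parts):
            piece = piece + delim + parts[i + 2]
            i += 2
        fields.append(piece.decode("utf-8", errors="replace"))
        i += 1
    if fields and fields[-1] == "":
        fields.pop()
    kv: dict[str, str] = {}
    for key, val in zip(fields[::2], fields[1::2]):
        kv[key.strip().upper()] = val.strip()
    return kv


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS file.

    Returns ``(events, channel_names, text)`` where *events* is an
    ``(n_events, n_channels)`` float64 array, *channel_names* uses $PnS when
    present else $PnN, and *text* is the raw TEXT-segment dictionary.
    """
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise ValueError(f"{path}: too short to be an FCS file")
    version = data[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r} (need FCS 3.0/3.1)")

    def _offset(segment: bytes) -> int:
        s = segment.decode("ascii").strip()
        return int(s) if s else 0

    text_start, text_end = _offset(data[10:18]), _offset(data[18:26])
    data_start, data_end = _offset(data[26:34]), _offset(data[34:42])

    text = _parse_text_segment(data[text_start : text_end + 1])

    # data offsets may live only in TEXT for large files
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise ValueError(f"{path}: only list-mode ($MODE L) FCS is supported, got {mode}")
    dtype_code = text["$DATATYPE"].upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    endian = "<" if little else ">"

    bits = [int(text[f"$P{i}B"]) for i in range(1, n_par + 1)]
    raw = data[data_start : data_end + 1]

    if dtype_code == "F":
        if any(b != 32 for b in bits):
            raise ValueError("$DATATYPE F requires $PnB 32 for every channel")
        events = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=endian + "f4")
    elif dtype_code == "D":
        if any(b != 64 for b in bits):
            raise ValueError("$DATATYPE D requires $PnB 64 for every channel")
        events = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=endian + "f8")
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32, 64):
            raise ValueError(f"unsupported integer widths {sorted(set(bits))}; need uniform 8/16/32/64")
        nbytes = bits[0] // 8
        events = np.frombuffer(raw[: nbytes * n_par * n_tot], dtype=f"{endian}u{nbytes}")
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    if events.size < n_par * n_tot:
        raise ValueError(f"{path}: DATA segment truncated ({events.size} values for {n_tot}x{n_par})")
    events = np.asarray(events[: n_par * n_tot], dtype=np.float64).reshape(n_tot, n_par)

    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}S") or text.get(f"$P{i}N") or f"P{i}")
    return events, names, text


def write_fcs(path: str | Path, events: np.ndarray, channel_names: list[str]) -> None:
    """Write a minimal FCS 3.0 file (float32, little-endian).

    Intended for tests and synthetic round-trips, not instrument fidelity.
    """
    events = np.asarray(events, dtype="<f4")
    n_tot, n_par = events.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length must match event columns")
    d = "/"
    kv = {"$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
          "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0"}
    for i, name in enumerate(channel_names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(np.ceil(events[:, i - 1].max())) + 1 if n_tot else 1024)
    text = d + d.join(f"{k}{d}{v}" for k, v in kv.items()) + d
    text_bytes = text.encode("ascii")
    text_start = 58
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + events.nbytes - 1
    header = (
        b"FCS3.0    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == 58
    Path(path).write_bytes(header + text_bytes + struct.pack("<%df" % events.size, *events.ravel()))
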