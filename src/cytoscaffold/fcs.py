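"""Minimal read-only parser for list-mode FCS 3.0 / 3.1 files.

Supports the subset of the standard produced by mass and flow cytometers in
practice: list mode ($MODE/L), datatypes F (float32), D (float64) and I
(unsigned integers with $PnB a multiple of 8), and both byte orders.
Analysis segments and multi-dataset files are ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = ["read_fcs"]


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped (doubled) delimiters are not supported; plain split suffices
    # for machine-written keyword values.
    fields = [p.decode("utf-8", errors="replace") for p in body.split(delim)]
    if len(fields) % 2 != 0:
        fields = fields[:-1]
    return {fields[j].strip().upper(): fields[j + 1] for j in range(0, len(fields), 2)}


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file and return ``(events x parameters array, names)``.

    Parameter names are taken from $PnS when present, else $PnN.

    Raises
    ------
    FormatError
        If the file is not parseable FCS 3.x, or contains zero events.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = raw[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        txt = raw[lo:hi].decode("ascii", errors="replace").strip()
        return int(txt) if txt else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(raw[text_start : text_end + 1])

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:  # pragma: no cover - malformed files
        raise FormatError(f"{path}: missing required keyword {exc}") from exc

    if n_tot == 0:
        raise FormatError(f"{path}: FCS file contains 0 events")
    if data_start == 0 or data_end == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_start == 0 or data_end <= data_start:
        raise FormatError(f"{path}: no DATA segment")
    mode = kw.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise FormatError(f"{path}: only list-mode ($MODE/L) FCS is supported")

    little = byteord.startswith("1")
    order = "<" if little else ">"
    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}"
        names.append(name.strip())

    data = raw[data_start : data_end + 1]
    if datatype == "F":
        arr = np.frombuffer(data[: n_tot * n_par * 4], dtype=f"{order}f4")
    elif datatype == "D":
        arr = np.frombuffer(data[: n_tot * n_par * 8], dtype=f"{order}f8")
    elif datatype == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) % 8 != 0:
            raise FormatError(f"{path}: unsupported mixed/odd $PnB for integer data")
        nbytes = next(iter(bits)) // 8
        if nbytes not in (1, 2, 4, 8):
            raise FormatError(f"{path}: unsupported integer width {nbytes * 8} bits")
        arr = np.frombuffer(data[: n_tot * n_par * nbytes], dtype=f"{order}u{nbytes}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    if arr.size < n_tot * n_par:
        raise FormatError(
            f"{path}: DATA segment truncated ({arr.size} values, expected {n_tot * n_par})"
        )
    values = arr[: n_tot * n_par].astype(np.float64).reshape(n_tot, n_par)
    return values, names
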