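"""Shared fixtures: synthetic datasets and a byte-level FCS file builder."""

from __future__ import annotations

import numpy as np
import pytest

from cytoscaffold.synthetic import SyntheticSpec, generate_reference


def build_fcs_bytes(
    values: np.ndarray,
    names: list[str],
    datatype: str = "F",
    byteord: str = "1,2,3,4",
) -> bytes:
    """Construct a minimal valid FCS 3.0 file from scratch.

    Used to exercise the reader without binary fixtures on disk.
    """
    values = np.asarray(values)
    n_tot, n_par = values.shape if values.size else (0, len(names))
    dtype = {"F": "<f4", "D": "<f8"}[datatype]
    if byteord.startswith("4"):
        dtype = dtype.replace("<", ">")
    data = values.astype(dtype).tobytes()

    kw = {
        "$DATATYPE": datatype,
        "$MODE": "L",
        "$BYTEORD": byteord,
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    nbytes = 4 if datatype == "F" else 8
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = str(nbytes * 8)
        kw[f"$P{i}R"] = "262144"
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_start = 58
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + max(len(data) - 1, 0)
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}"
        .encode("ascii")
        + f"{0:8d}{0:8d}".encode("ascii")
    )
    assert len(header) == 58
    return header + text.encode("ascii") + data


@pytest.fixture(scope="session")
def small_reference():
    """A well-separated 4-type reference, small enough for fast tests."""
    spec = SyntheticSpec(
        n_cell_types=4,
        backbone_dim=8,
        signaling_dim=4,
        cells_per_type_reference=400,
        separation_cap=0.7,
        within_type_sd=0.2,
        seed=42,
    )
    return spec, generate_reference(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
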