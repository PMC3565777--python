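"""Minimal FCS 3.0 list-mode writer for round-trip fixtures (synthetic data).

Writes only what the reader needs: a HEADER with TEXT/DATA offsets, a TEXT
segment with the required keywords, and a float or integer list-mode DATA
segment.  Not a general-purpose FCS writer.
"""

from __future__ import annotations

import numpy as np


def write_fcs(path, channels: dict[str, np.ndarray], datatype: str = "F",
              version: str = "FCS3.0") -> None:
    names = list(channels)
    cols = [np.asarray(channels[n], dtype=float) for n in names]
    n_tot = len(cols[0])
    assert all(len(c) == n_tot for c in cols)
    events = np.stack(cols, axis=1)

    if datatype == "F":
        raw = events.astype("<f4").tobytes()
        bits = 32
    elif datatype == "D":
        raw = events.astype("<f8").tobytes()
        bits = 64
    elif datatype == "I":
        raw = events.astype("<u4").tobytes()
        bits = 32
    else:
        raise ValueError(datatype)

    kw = {
        "$MODE": "L", "$DATATYPE": datatype, "$BYTEORD": "1,2,3,4",
        "$PAR": str(len(names)), "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = str(bits)
        kw[f"$P{i}R"] = "262144"
        kw[f"$P{i}E"] = "0,0"

    header_len = 58
    # iterate because the TEXT segment length depends on the offsets it quotes
    for _ in range(3):
        delim = "/"
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        data_begin = text_end + 1
        data_end = data_begin + len(raw) - 1
        kw["$BEGINDATA"] = str(data_begin)
        kw["$ENDDATA"] = str(data_end)

    header = (
        f"{version}    "
        f"{text_begin:8d}{text_end:8d}{data_begin:8d}{data_end:8d}"
        f"{0:8d}{0:8d}"
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("latin-1"))
        fh.write(raw)
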