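"""Reading single-cell fluorescence events and decade gating.

Raw events are linear-scale fluorescence intensities, one value per cell, read
either from FCS 3.0/3.1 list-mode files or from CSV.  Modelling happens on the
log10 scale, where the instrument's calibrated range spans decades 0-3 and the
conventional gates are LN (low, decade 0-1), MN (middle, 1-2) and HN (high,
2-3).  Values outside the calibrated range are labelled "out" and excluded
from occupancy fractions.  Day-to-day bead calibration is assumed done
upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GateDefinition", "read_events", "to_log10", "gate_classify", "gate_report"]

logger = logging.getLogger(__name__)

GATE_LABELS = ("LN", "MN", "HN")


@dataclass(frozen=True)
class GateDefinition:
    """Half-open decade gates on the log10 scale; HN is closed on the right."""

    ln_range: tuple[float, float] = (0.0, 1.0)
    mn_range: tuple[float, float] = (1.0, 2.0)
    hn_range: tuple[float, float] = (2.0, 3.0)

    def __post_init__(self) -> None:
        ranges = (self.ln_range, self.mn_range, self.hn_range)
        for lo, hi in ranges:
            if not lo < hi:
                raise ValueError("each gate must be a non-empty interval")
        if not (self.ln_range[1] == self.mn_range[0] and self.mn_range[1] == self.hn_range[0]):
            raise ValueError("gates must be contiguous and ascending")


DEFAULT_GATES = GateDefinition()


class FCSFormatError(ValueError):
    """Raised for malformed FCS files; carries the byte offset of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


def _parse_fcs_text(raw: bytes, base_offset: int) -> dict[str, str]:
    if len(raw) < 2:
        raise FCSFormatError("TEXT segment too short", base_offset)
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # Escaped delimiters (doubled) are rare in practice; split then re-join empties.
    parts = body.split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of fields", base_offset)
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def _read_fcs(path: Path, channel: str) -> np.ndarray:
    data = path.read_bytes()
    if len(data) < 58:
        raise FCSFormatError("file shorter than an FCS header", 0)
    version = data[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"unsupported FCS version {version!r}", 0)

    def _offset(lo: int, hi: int) -> int:
        field = data[lo:hi].decode("latin-1").strip()
        try:
            return int(field) if field else 0
        except ValueError:
            raise FCSFormatError(f"non-numeric header offset {field!r}", lo) from None

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if not (0 < text_begin < text_end < len(data)):
        raise FCSFormatError("invalid TEXT segment offsets", 10)
    text = _parse_fcs_text(data[text_begin: text_end + 1], text_begin)

    if data_begin == 0:
        data_begin = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    if not (0 < data_begin <= data_end < len(data) + 1):
        raise FCSFormatError("invalid DATA segment offsets", 26)

    if text.get("$MODE", "L").upper() != "L":
        raise FCSFormatError("only list-mode ($MODE/L) data is supported", text_begin)
    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"].upper()
        byteord = text["$BYTEORD"]
    except KeyError as exc:
        raise FCSFormatError(f"missing required keyword {exc}", text_begin) from None

    names = [text.get(f"$P{i+1}N", f"P{i+1}") for i in range(n_par)]
    if channel not in names:
        raise ValueError(f"unknown channel {channel!r}; available channels: {names}")

    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {int(text.get(f"$P{i+1}B", "0")) for i in range(n_par)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise FCSFormatError("integer data requires one uniform $PnB of 8/16/32/64", text_begin)
        width = int(text[f"$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{width}")
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r}", text_begin)

    expected = n_par * n_tot * dtype.itemsize
    raw = data[data_begin: data_begin + expected]
    if len(raw) != expected:
        raise FCSFormatError(
            f"DATA segment truncated: expected {expected} bytes", data_begin + len(raw)
        )
    events = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)
    return events[:, names.index(channel)]


def read_events(path, source_format: str | None = None, channel: str | None = None) -> np.ndarray:
    """Read raw linear-scale event intensities for one channel.

    ``source_format`` is "fcs" or "csv" (inferred from the extension when
    omitted).  CSV may be a headerless single column, a single named column,
    or a multi-column table in which case ``channel`` names the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if source_format is None:
        source_format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if source_format == "fcs":
        if channel is None:
            raise ValueError("an FCS read requires a channel name")
        return _read_fcs(path, channel)
    if source_format != "csv":
        raise ValueError(f"unknown source format {source_format!r}")

    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if df.empty and len(df.columns) <= 1:
        # headerless single column: first line was data, re-read without header
        df = pd.read_csv(path, header=None)
    if len(df.columns) == 1:
        col = df.columns[0]
        # a lone header that parses as a number means there was no header
        try:
            float(col)
            df = pd.read_csv(path, header=None)
            col = df.columns[0]
        except (TypeError, ValueError):
            pass
        values = df[col]
    else:
        if channel is None or channel not in df.columns:
            raise ValueError(
                f"channel {channel!r} not found; available channels: {list(df.columns)}"
            )
        values = df[channel]
    arr = pd.to_numeric(values, errors="raise").to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError(f"no events in {path}")
    return arr


def to_log10(values, return_dropped: bool = False):
    """log10-transform positive intensities, dropping non-positive ones.

    The number of dropped values is logged; pass ``return_dropped=True`` to
    also get it back.  All-non-positive input is an error.
    """
    arr = np.asarray(values, dtype=float).ravel()
    mask = arr > 0.0
    n_dropped = int(arr.size - mask.sum())
    if mask.sum() == 0:
        raise ValueError("no positive values to transform")
    if n_dropped:
        logger.info("dropped %d non-positive values before log10", n_dropped)
    out = np.log10(arr[mask])
    return (out, n_dropped) if return_dropped else out


def gate_classify(values_log10, gates: GateDefinition = DEFAULT_GATES):
    """Label each log10 value LN/MN/HN/out and report in-gate occupancies.

    Gates are closed on the left and open on the right, except HN which is
    closed on both ends; anything outside the calibrated decades is "out" and
    excluded from the occupancy fractions.
    """
    arr = np.asarray(values_log10, dtype=float).ravel()
    labels = np.full(arr.shape, "out", dtype=object)
    labels[(arr >= gates.ln_range[0]) & (arr < gates.ln_range[1])] = "LN"
    labels[(arr >= gates.mn_range[0]) & (arr < gates.mn_range[1])] = "MN"
    labels[(arr >= gates.hn_range[0]) & (arr <= gates.hn_range[1])] = "HN"
    in_gate = labels != "out"
    n_in = int(in_gate.sum())
    occupancies = {
        lab: (float(np.sum(labels == lab)) / n_in if n_in else 0.0) for lab in GATE_LABELS
    }
    return labels, occupancies


def gate_report(values_log10, gates: GateDefinition = DEFAULT_GATES) -> dict:
    """JSON-ready gate counts: {LN, MN, HN, out, n_total}."""
    labels, _ = gate_classify(values_log10, gates)
    return {
        "LN": int(np.sum(labels == "LN")),
        "MN": int(np.sum(labels == "MN")),
        "HN": int(np.sum(labels == "HN")),
        "out": int(np.sum(labels == "out")),
        "n_total": int(labels.size),
    }
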