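"""Published three-component landscape estimates for mouse ES cell cultures.

These are the reported posterior-mean parameters of the Nanog-GFP landscape
model under four culture conditions (LIF+BMP4 self-renewal, the MEK inhibitor
PD03, the GSK3 inhibitor Chiron, and their combination 2i): occupancy
percentages, component means and variances on the log10 fluorescence scale,
and the noise intensity B.  They serve as ground truth for synthetic-data
recovery studies and as ready-made models for landscape plots and
cross-condition prediction scoring.
"""

from __future__ import annotations

from .mixture import MixtureParams, StochasticModel

__all__ = ["REFERENCE_CONDITIONS", "reference_model", "CONDITIONS"]

# (occupancy % LN/MN/HN, means, variances, noise B)
_ROWS: dict[str, tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...], float]] = {
    "LIF+BMP4": ((12.7, 43.1, 44.2), (0.807, 1.80, 2.22), (0.955, 0.673, 0.571), 0.230),
    "PD03":     ((43.9, 46.5, 10.6), (0.524, 1.71, 2.38), (0.187, 0.393, 0.199), 0.860),
    "Chiron":   ((10.3, 27.5, 62.2), (0.601, 1.65, 2.21), (0.831, 1.05, 0.246), 0.186),
    "2i":       ((2.68, 5.67, 91.6), (0.598, 1.80, 2.32), (0.195, 0.818, 0.382), 0.303),
}

CONDITIONS = tuple(_ROWS)


def reference_model(condition: str) -> StochasticModel:
    """The published landscape model for one culture condition."""
    try:
        alphas, means, variances, noise = _ROWS[condition]
    except KeyError:
        raise KeyError(f"unknown condition {condition!r}; have {CONDITIONS}") from None
    return StochasticModel(MixtureParams.from_percentages(alphas, means, variances), noise)


REFERENCE_CONDITIONS: dict[str, StochasticModel] = {c: reference_model(c) for c in CONDITIONS}
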