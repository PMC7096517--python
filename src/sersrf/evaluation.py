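"""Evaluation statistics for variable- and group-selection results.

Ground truth is the set of characteristic bands (the bands of single
spectra 1 and 2): sensitivity is measured against their variables, band
sensitivity against the bands themselves, and the false positive rate
against all variables not in any characteristic band.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "variable_sensitivity",
    "band_sensitivity",
    "false_positive_rate",
    "selection_frequency",
]


def variable_sensitivity(selected: np.ndarray, char_band_mask: np.ndarray) -> float:
    """Correctly identified variables over all characteristic-band variables.

    Returns NaN when there are no characteristic-band variables (the
    null scenario, where sensitivity is undefined).
    """
    selected = np.asarray(selected, dtype=bool)
    char = np.asarray(char_band_mask, dtype=bool)
    if selected.shape != char.shape:
        raise ValueError("mask length mismatch")
    n_char = char.sum()
    if n_char == 0:
        return float("nan")
    return float((selected & char).sum() / n_char)


def band_sensitivity(selected: np.ndarray, band_masks: Sequence[np.ndarray]) -> float:
    """Bands with at least one selected variable over all characteristic bands."""
    selected = np.asarray(selected, dtype=bool)
    band_masks = list(band_masks)
    if len(band_masks) == 0:
        return float("nan")
    hit = sum(1 for m in band_masks if (selected & np.asarray(m, dtype=bool)).any())
    return float(hit / len(band_masks))


def false_positive_rate(selected: np.ndarray, char_band_mask: np.ndarray) -> float:
    """Falsely selected variables over all non-characteristic variables.

    The denominator is every variable outside the characteristic bands,
    including background-band variables.
    """
    selected = np.asarray(selected, dtype=bool)
    char = np.asarray(char_band_mask, dtype=bool)
    if selected.shape != char.shape:
        raise ValueError("mask length mismatch")
    n_non = (~char).sum()
    if n_non == 0:
        raise ValueError("no non-characteristic variables")
    return float((selected & ~char).sum() / n_non)


def selection_frequency(selections: Sequence[np.ndarray]) -> np.ndarray:
    """Per-item fraction of replicates in which it was selected."""
    selections = [np.asarray(s, dtype=bool) for s in selections]
    if len(selections) == 0:
        raise ValueError("need at least one replicate")
    shape = selections[0].shape
    if any(s.shape != shape for s in selections):
        raise ValueError("inconsistent selection dimensions")
    return np.mean(np.stack(selections), axis=0)
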