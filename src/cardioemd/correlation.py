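"""Pearson correlation with the five-band rule-of-thumb interpretation.

Correlation strength is banded by ``|r|`` at 0.20 / 0.40 / 0.60 / 0.80 into
negligible, low, moderate, significant and high ("significant" here is a
magnitude band, not a hypothesis test); boundary values go to the higher
band.  The sign is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

_BAND_EDGES = (0.20, 0.40, 0.60, 0.80)
_BAND_NAMES = ("negligible", "low", "moderate", "significant", "high")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient.

    Pairs with a non-finite member in either sequence (e.g. beats whose Pb
    was undefined) are removed pairwise first.  Needs at least three valid
    pairs and two non-constant sequences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least three valid pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(x, y).statistic)


def interpret(r: float) -> tuple[str, str]:
    """(category, sign) of a correlation coefficient.

    Category from the five |r| bands with boundaries assigned upward;
    sign is ``"positive"``, ``"negative"`` or ``"zero"``.
    """
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise ValueError("|r| must be at most 1")
    mag = abs(r)
    category = _BAND_NAMES[int(np.searchsorted(_BAND_EDGES, mag, side="right"))]
    sign = "zero" if r == 0 else ("positive" if r > 0 else "negative")
    return category, sign


@dataclass(frozen=True)
class CorrelationReport:
    """One pairwise correlation with its interpretation."""

    label_a: str
    label_b: str
    r: float
    category: str
    sign: str


def correlation_table(series: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise correlations of beat-aligned series, strongest first.

    ``series`` maps labels to equal-length per-beat arrays (NaNs mark
    undefined beats and are dropped pairwise).  Rows are sorted by |r|
    descending.  Pairs where the correlation is undefined (constant or too
    few valid beats) are reported with ``r = NaN``.
    """
    if len(series) < 2:
        raise ValueError("need at least two series")
    rows = []
    for a, b in combinations(series, 2):
        try:
            r = pearson(series[a], series[b])
            category, sign = interpret(r)
        except ValueError:
            r, category, sign = np.nan, "undefined", "undefined"
        rows.append(CorrelationReport(a, b, r, category, sign))
    frame = pd.DataFrame([vars(row) for row in rows])
    order = frame["r"].abs().sort_values(ascending=False, na_position="last").index
    return frame.loc[order].reset_index(drop=True)
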