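"""Multivariate Environmental Similarity Surface (MESS) and the validity mask.

MESS scores how similar the conditions at a query location are to a set of
reference points (here: the localities a forest was trained on).  For one
variable, with f the percentage of reference values strictly below the query
value p, min/max the reference extremes, the similarity is

    f = 0        : 100 * (p - min) / (max - min)
    0 < f <= 50  : 2 * f
    50 < f < 100 : 2 * (100 - f)
    f = 100      : 100 * (max - p) / (max - min)

so similarity is 100 when p sits at the reference median, 0 at the reference
extremes, and negative beyond them.  The MESS value of a location is the
minimum similarity over variables; negative MESS flags locations where a
model projection would be extrapolation rather than prediction.

Projected-surface cells are kept only where MESS exceeds the median of the
strictly positive MESS values — a deliberately conservative rule that trims
even the lower half of the non-extrapolated area.  The milder conventional
alternative (keep all non-negative cells) is available as ``rule="nonnegative"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .grid import PREDICTORS, GridGeometry, PredictorStack, AnalysisTable


class DegenerateReferenceError(ValueError):
    """A reference variable is constant (max == min)."""


@dataclass
class MessResult:
    """Per-variable similarity scores and their minimum, in percent.

    ``per_variable`` maps each predictor to an array of scores shaped like
    the query (grid or vector); ``mess`` is the cell-wise minimum.  NaN marks
    query cells with no data.
    """

    per_variable: dict[str, np.ndarray]
    mess: np.ndarray
    reference_summary: pd.DataFrame  # index: variable; cols: min, max, n
    geometry: GridGeometry | None = None


@dataclass
class ValidityMask:
    """Boolean keep-grid from the median-of-positive-MESS rule."""

    keep: np.ndarray
    threshold: float
    rule: str = "median_positive"
    geometry: GridGeometry | None = None


def similarity_univariate(reference: np.ndarray, p: Union[float, np.ndarray]) -> np.ndarray:
    """Similarity (percent) of query value(s) ``p`` to one reference variable.

    Vectorised over ``p``; NaN queries yield NaN.  Raises
    DegenerateReferenceError if the reference variable is constant.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    if ref.size == 0 or np.isnan(ref).any():
        raise ValueError("reference must be non-empty and finite")
    lo, hi = ref[0], ref[-1]
    span = hi - lo
    if span <= 0:
        raise DegenerateReferenceError("degenerate reference variable (max == min)")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    finite = np.isfinite(p)
    f = np.full(p.shape, np.nan)
    # percentage of reference values strictly less than p
    f[finite] = 100.0 * np.searchsorted(ref, p[finite], side="left") / ref.size
    sim = np.full(p.shape, np.nan)
    m = finite & (f == 0)
    sim[m] = 100.0 * (p[m] - lo) / span
    m = finite & (f > 0) & (f <= 50)
    sim[m] = 2.0 * f[m]
    m = finite & (f > 50) & (f < 100)
    sim[m] = 2.0 * (100.0 - f[m])
    m = finite & (f == 100)
    sim[m] = 100.0 * (hi - p[m]) / span
    return sim[0] if scalar else sim


def compute_mess(
    reference: Union[AnalysisTable, pd.DataFrame],
    query: Union[PredictorStack, AnalysisTable, pd.DataFrame],
) -> MessResult:
    """MESS of every query cell (or row) against the reference predictor table.

    ``reference`` supplies one column per canonical predictor (an
    AnalysisTable's predictor block, or a bare DataFrame).  ``query`` may be
    a PredictorStack (per-cell surface) or another table (per-point scores).
    Nodata query cells stay NaN.
    """
    ref_df = reference.predictors if isinstance(reference, AnalysisTable) else reference
    missing = [n for n in PREDICTORS if n not in ref_df.columns]
    if missing:
        raise ValueError(f"reference lacks predictor columns: {missing}")

    geometry = None
    if isinstance(query, PredictorStack):
        geometry = query.geometry
        query_arrays = {n: query.layers[n].values for n in PREDICTORS}
    else:
        q_df = query.predictors if isinstance(query, AnalysisTable) else query
        missing = [n for n in PREDICTORS if n not in q_df.columns]
        if missing:
            raise ValueError(f"query lacks predictor columns: {missing}")
        query_arrays = {n: q_df[n].to_numpy(dtype=float) for n in PREDICTORS}

    per_variable = {}
    summary_rows = []
    for name in PREDICTORS:
        ref = ref_df[name].to_numpy(dtype=float)
        per_variable[name] = similarity_univariate(ref, query_arrays[name])
        summary_rows.append({"variable": name, "min": ref.min(), "max": ref.max(),
                             "n": ref.size})
    stacked = np.stack(list(per_variable.values()))
    any_nan = np.isnan(stacked).any(axis=0)
    mess = np.full(any_nan.shape, np.nan)
    ok = ~any_nan
    if np.ndim(mess) == 0:  # scalar query
        mess = stacked.min() if ok else np.nan
    else:
        mess[ok] = stacked[:, ok].min(axis=0)
    summary = pd.DataFrame(summary_rows).set_index("variable")
    return MessResult(per_variable=per_variable, mess=mess,
                      reference_summary=summary, geometry=geometry)


def validity_mask(result: MessResult, rule: str = "median_positive") -> ValidityMask:
    """Boolean mask of cells where a projection is considered trustworthy.

    ``median_positive`` (default): threshold = median of strictly positive
    MESS cells; keep cells with MESS strictly greater than the threshold
    (cells at the threshold are excluded).  ``nonnegative``: keep cells with
    MESS >= 0.  NaN cells are never kept.
    """
    mess = np.asarray(result.mess, dtype=float)
    if rule == "nonnegative":
        keep = np.where(np.isfinite(mess), mess >= 0, False)
        return ValidityMask(keep=keep, threshold=0.0, rule=rule,
                            geometry=result.geometry)
    if rule != "median_positive":
        raise ValueError(f"unknown mask rule {rule!r}")
    positives = mess[np.isfinite(mess) & (mess > 0)]
    if positives.size == 0:
        raise ValueError("mask undefined: all MESS non-positive")
    threshold = float(np.median(positives))
    keep = np.where(np.isfinite(mess), mess > threshold, False)
    return ValidityMask(keep=keep, threshold=threshold, rule=rule,
                        geometry=result.geometry)
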