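"""Classification-accuracy measures over Monte-Carlo replicates.

A provider is the unit of classification; *outlier* is the positive class and
the flagged direction is ignored (a provider flagged in the wrong direction
still counts as a true positive if it truly is an outlier).  Per-replicate
sensitivity, specificity, PPV and NPV are averaged over replicates where the
measure is defined (an empty denominator yields a missing value, never a
zero), with 5th/95th-percentile bounds.  Eagerness is the proportion of usable
replicates in which a method flags at least one provider, true outlier or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .outcome import NORMAL

MEASURES = ("sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    """Provider-level confusion counts; outlier = positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(truth_labels, observed_labels) -> ConfusionCounts:
    """Compare observed labels with true status, direction ignored."""
    t = np.asarray(truth_labels, dtype=object)
    o = np.asarray(observed_labels, dtype=object)
    if t.shape != o.shape:
        raise ValueError("truth and observed labels must have equal length")
    t_out = t != NORMAL
    o_out = o != NORMAL
    return ConfusionCounts(
        tp=int(np.sum(t_out & o_out)),
        fp=int(np.sum(~t_out & o_out)),
        tn=int(np.sum(~t_out & ~o_out)),
        fn=int(np.sum(t_out & ~o_out)),
    )


def performance(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV; ``None`` when the denominator is 0."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "ppv": ratio(counts.tp, counts.tp + counts.fp),
        "npv": ratio(counts.tn, counts.tn + counts.fn),
    }


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce per-replicate measures to a tidy per-method summary.

    Parameters
    ----------
    records:
        One row per (replicate, method) with columns ``method``, the four
        measures (NaN where undefined) and ``n_flagged``.

    Returns
    -------
    DataFrame with one row per (method, measure): mean over replicates where
    the measure is defined, 5th/95th-percentile bounds (linear-interpolation
    quantiles), the number of defined replicates, and an ``eagerness`` row per
    method (no interval).
    """
    if records.empty:
        raise ValueError("no usable replicates to summarize")
    rows = []
    for method, grp in records.groupby("method", sort=False):
        n_usable = len(grp)
        for measure in MEASURES:
            vals = grp[measure].dropna().to_numpy(dtype=float)
            rows.append({
                "method": method,
                "measure": measure,
                "mean": vals.mean() if vals.size else np.nan,
                "lo90": np.quantile(vals, 0.05) if vals.size else np.nan,
                "hi90": np.quantile(vals, 0.95) if vals.size else np.nan,
                "n_defined": int(vals.size),
                "n_usable": n_usable,
            })
        rows.append({
            "method": method,
            "measure": "eagerness",
            "mean": float((grp["n_flagged"] > 0).mean()),
            "lo90": np.nan,
            "hi90": np.nan,
            "n_defined": n_usable,
            "n_usable": n_usable,
        })
    return pd.DataFrame(rows)
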