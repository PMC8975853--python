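"""Pearson correlations among component weights and sleep variables.

The component weights of a population are not independent: rows of the
normalized weight matrix live on a simplex, and behaviourally antagonistic
components (evening vs. night activity) show strong negative correlations.
This module computes the pairwise weight correlation grid and the
components x sleep-variables association table (sleep time, mid-sleep time,
wake-up time, sleep duration), each cell a Pearson r with its two-sided
p-value from the t distribution with n - 2 degrees of freedom.

Hour-valued sleep variables are linearized on the noon-anchored axis
(12 -> 0, ..., 11 -> 23) before correlating, so "later in the night" is
monotone across midnight; naive clock hours would make 23:00 and 00:00
maximally distant.  No multiple-testing correction is applied: the p-values
are raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nmf import NormalizedWeights

SLEEP_VARIABLES = ("sleep_time", "mid_sleep_time", "wake_time", "sleep_duration")
_SUMMARY_COLS = {
    "sleep_time": "typical_sleep",
    "mid_sleep_time": "typical_mid_sleep",
    "wake_time": "typical_wake",
    "sleep_duration": "mean_duration",
}
_HOUR_VALUED = ("sleep_time", "mid_sleep_time", "wake_time")


@dataclass
class AssociationTable:
    """Aligned grids of Pearson r and p, rows = components, columns = variables."""

    r: pd.DataFrame
    p: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = [
            (comp, var, self.r.loc[comp, var], self.p.loc[comp, var])
            for comp in self.r.index
            for var in self.r.columns
        ]
        return pd.DataFrame(rows, columns=["component", "variable", "r", "p"])

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value.

    The p-value comes from t = r sqrt((n-2)/(1-r^2)) referred to a t
    distribution with n - 2 degrees of freedom.  Inputs must have equal
    length >= 3 and neither may be constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def linearize_hours(hours) -> np.ndarray:
    """Map clock hours to the continuous noon-anchored axis (12 -> 0 ... 11 -> 23)."""
    return (np.asarray(hours, dtype=float) - 12.0) % 24.0


def weight_correlation_matrix(weights: NormalizedWeights) -> AssociationTable:
    """Pairwise Pearson r and p for all component-weight pairs; unit diagonal."""
    W = weights.weights
    if W.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    labels = list(weights.component_order)
    k = len(labels)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = pearson_with_p(W[:, i], W[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return AssociationTable(
        pd.DataFrame(r, index=labels, columns=labels),
        pd.DataFrame(p, index=labels, columns=labels),
    )


def sleep_weight_associations(
    weights: NormalizedWeights, summaries: pd.DataFrame
) -> AssociationTable:
    """Components x sleep-variables grid of Pearson (r, p).

    ``summaries`` is the per-person sleep summary table (one row per
    participant).  Participants are matched by id; a mismatch raises and
    lists the unmatched ids.
    """
    if weights.row_ids is None:
        raise ValueError("weights carry no participant ids")
    wf = weights.to_frame().set_index("user")
    sf = summaries.set_index("user")
    unmatched = sorted(set(wf.index).symmetric_difference(sf.index))
    if unmatched:
        raise ValueError(f"participants not present in both tables: {unmatched}")
    if len(wf) < 3:
        raise ValueError("need at least 3 matched participants")
    sf = sf.loc[wf.index]

    labels = list(weights.component_order)
    r = pd.DataFrame(index=labels, columns=list(SLEEP_VARIABLES), dtype=float)
    p = r.copy()
    for var in SLEEP_VARIABLES:
        y = sf[_SUMMARY_COLS[var]].to_numpy(float)
        if var in _HOUR_VALUED:
            y = linearize_hours(y)
        for comp in labels:
            r.loc[comp, var], p.loc[comp, var] = pearson_with_p(
                wf[comp].to_numpy(float), y
            )
    return AssociationTable(r, p)
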