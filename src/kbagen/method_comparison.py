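"""Cross-metric comparison: IQR outlier removal and Kendall correlations.

Different metrics of the same areas are compared by Kendall's tau-b —
robust, rank-based, and well defined with the ties that small area sets
produce.  Before correlating, per-metric outliers can be removed with the
Tukey fence (values beyond ``k x IQR`` from the quartiles, k = 1.5 by
default, quartiles by linear interpolation / type-7).  Each metric pair is
computed on its own pairwise-complete area set, so sample sizes may differ
between pairs — expected when a metric (typically N_e) is unavailable for
some areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kba_criteria import MetricVector

__all__ = [
    "iqr_outlier_filter",
    "kendall_tau",
    "correlation_matrix",
    "CorrelationMatrix",
]

log = logging.getLogger(__name__)


def iqr_outlier_filter(
    values: pd.Series, k: float = 1.5
) -> tuple[pd.Series, pd.Series]:
    """Remove entries beyond the Tukey fences of their own distribution.

    Fences are ``Q1 - k*IQR`` and ``Q3 + k*IQR`` with type-7 (linear
    interpolation) quartiles over the non-missing values.  Returns the
    filtered series (outliers set to NaN) and the removed entries.  With
    fewer than 4 observations the series is returned unchanged.
    """
    vals = pd.Series(values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if len(finite) < 4:
        log.warning("fewer than 4 observations; IQR filter is identity")
        return vals.copy(), finite.iloc[0:0]
    q1, q3 = np.percentile(finite, [25, 75])  # numpy default = type-7
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out_mask = np.isfinite(vals) & ((vals < lo) | (vals > hi))
    removed = vals[out_mask]
    filtered = vals.copy()
    filtered[out_mask] = np.nan
    if len(removed):
        log.info("IQR filter removed %d value(s): %s", len(removed), list(removed.index))
    return filtered, removed


def kendall_tau(x, y, method: str = "auto") -> tuple[float, float]:
    """Kendall's tau-b with p-value.

    ``method="auto"`` uses the exact permutation null when n <= 10 and
    neither vector has ties, otherwise a normal approximation with
    continuity correction and the Kendall-Gibbons tie-adjusted variance of
    S = C - D.  All-tied input is an error (tau undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("tau undefined: a vector is constant (all tied)")
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be auto, exact or asymptotic")
    use_exact = method == "exact" or (method == "auto" and n <= 10 and no_ties)
    if use_exact:
        res = stats.kendalltau(x, y, variant="b", method="exact")
        return float(res.statistic), float(res.pvalue)

    tau = float(stats.kendalltau(x, y, variant="b", method="asymptotic").statistic)
    # S = C - D recovered from tau-b and the tie corrections
    n0 = n * (n - 1) / 2.0
    tx = np.unique(x, return_counts=True)[1]
    ty = np.unique(y, return_counts=True)[1]
    n1 = float(np.sum(tx * (tx - 1) / 2.0))
    n2 = float(np.sum(ty * (ty - 1) / 2.0))
    s = tau * np.sqrt((n0 - n1) * (n0 - n2))
    # Kendall & Gibbons variance of S under the null with ties
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - vt - vu) / 18.0
    var += float(np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1))) / (2.0 * n * (n - 1))
    var += (
        float(np.sum(tx * (tx - 1) * (tx - 2)) * np.sum(ty * (ty - 1) * (ty - 2)))
        / (9.0 * n * (n - 1) * (n - 2))
    )
    if var <= 0:
        return tau, 1.0
    z = (abs(s) - 1.0) / np.sqrt(var)  # continuity correction of one unit of S
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return tau, float(min(p, 1.0))


@dataclass
class CorrelationMatrix:
    """Symmetric tau / p / n tables over a metric set."""

    tau: pd.DataFrame
    p_value: pd.DataFrame
    n_used: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        metrics = list(self.tau.index)
        for i, m1 in enumerate(metrics):
            for m2 in metrics[i + 1:]:
                rows.append(
                    {
                        "metric_a": m1,
                        "metric_b": m2,
                        "tau": self.tau.loc[m1, m2],
                        "p_value": self.p_value.loc[m1, m2],
                        "n_used": self.n_used.loc[m1, m2],
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(
    vectors: list[MetricVector],
    outlier_k: float | None = None,
    outlier_metrics: set[str] | None = None,
    min_n: int = 3,
) -> CorrelationMatrix:
    """Pairwise Kendall correlations over a list of per-area metric vectors.

    ``outlier_k`` enables the IQR filter; ``outlier_metrics`` restricts it
    to named metrics (e.g. only AMOVA), otherwise every metric is filtered.
    Pairs with fewer than ``min_n`` complete areas are marked unavailable
    (NaN tau/p, n recorded).
    """
    if len(vectors) < 2:
        raise ValueError("need at least two metric vectors")
    names = [v.metric for v in vectors]
    if len(set(names)) != len(names):
        raise ValueError("duplicate metric names")
    cleaned: dict[str, pd.Series] = {}
    for v in vectors:
        vals = pd.Series(v.values, dtype=float)
        vals[~np.isfinite(vals)] = np.nan
        if outlier_k is not None and (outlier_metrics is None or v.metric in outlier_metrics):
            vals, _ = iqr_outlier_filter(vals, outlier_k)
        cleaned[v.metric] = vals

    frame = pd.DataFrame(cleaned)
    tau = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.full((len(names), len(names)), np.nan), index=names, columns=names)
    n_used = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, m1 in enumerate(names):
        n_used.loc[m1, m1] = int(frame[m1].notna().sum())
        for m2 in names[i + 1:]:
            sub = frame[[m1, m2]].dropna()
            n = len(sub)
            n_used.loc[m1, m2] = n_used.loc[m2, m1] = n
            if n < min_n:
                tau.loc[m1, m2] = tau.loc[m2, m1] = np.nan
                continue
            try:
                t, pv = kendall_tau(sub[m1].to_numpy(), sub[m2].to_numpy())
            except ValueError:
                t, pv = np.nan, np.nan
            tau.loc[m1, m2] = tau.loc[m2, m1] = t
            p.loc[m1, m2] = p.loc[m2, m1] = pv
    return CorrelationMatrix(tau, p, n_used)
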