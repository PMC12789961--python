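"""Key Biodiversity Area criterion assessment from a per-area metric vector.

The KBA standard scores a site by the *proportion* of a species' global
distinct genetic diversity it holds: each area's metric value divided by
the sum over all areas.  Criterion A1b flags areas holding > 1% of that
sum, criterion B1 areas holding > 10% (strict inequalities; a ``>=``
variant is available for users following other guidance).

Two adjustments make arbitrary metric vectors proportion-ready, in the
order the pipeline applies them:

1. ``fill_missing_with_median`` — areas lacking an estimate (e.g. infinite
   N_e) receive the median of the remaining areas, so criteria can be
   applied without inflating the proportions of the other sites.
2. ``shift_to_positive`` — when estimates can be negative (again N_e), the
   smallest natural number k making every value strictly positive is added.
   The shift distorts ratios, so k is recorded in the assessment's
   adjustment log for auditability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricVector",
    "KBAAssessment",
    "fill_missing_with_median",
    "shift_to_positive",
    "proportions",
    "apply_criteria",
    "assess",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {"A1b": 0.01, "B1": 0.10}


@dataclass
class MetricVector:
    """One named metric's value per area (may contain NaN / ±inf)."""

    metric: str
    values: pd.Series  # index = area ids
    adjustments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if len(self.values) < 1:
            raise ValueError("metric vector needs at least one area")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate area ids in metric vector")

    @classmethod
    def from_dict(cls, metric: str, data: dict[str, float]) -> "MetricVector":
        return cls(metric, pd.Series(data, dtype=float))

    def copy_with(self, values: pd.Series, note: str) -> "MetricVector":
        return MetricVector(self.metric, values, [*self.adjustments, note])


@dataclass
class KBAAssessment:
    """Per-area proportions and criterion flags for one metric."""

    metric: str
    proportions: pd.Series
    flags: pd.DataFrame  # columns A1b, B1 (bool)
    thresholds: dict[str, float]
    adjustments: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"proportion": self.proportions})
        for c in self.flags.columns:
            out[c] = self.flags[c]
        return out


def fill_missing_with_median(v: MetricVector, treat_inf_as_missing: bool = True) -> MetricVector:
    """Replace missing entries by the median of the non-missing areas.

    ``treat_inf_as_missing`` extends "missing" to ±infinite values (the
    default policy for infinite N_e estimates); set it False to keep
    infinities and handle them elsewhere.
    """
    vals = v.values.copy()
    bad = vals.isna()
    if treat_inf_as_missing:
        bad |= ~np.isfinite(vals)
    if not bad.any():
        return v.copy_with(vals, "median_fill: none needed")
    good = vals[~bad]
    if good.empty:
        raise ValueError(f"metric {v.metric!r}: every area is missing")
    med = float(good.median())
    vals[bad] = med
    return v.copy_with(
        vals, f"median_fill: {int(bad.sum())} area(s) set to median {med:.6g}"
    )


def shift_to_positive(v: MetricVector) -> MetricVector:
    """Add the smallest natural number making every value strictly positive."""
    vals = v.values
    if not np.isfinite(vals).all():
        raise ValueError(
            f"metric {v.metric!r} has non-finite values; apply "
            "fill_missing_with_median (or an infinity policy) first"
        )
    lo = float(vals.min())
    if lo > 0:
        return v.copy_with(vals.copy(), "shift: k=0 (already positive)")
    k = math.floor(-lo) + 1  # smallest natural number with lo + k > 0
    return v.copy_with(vals + k, f"shift: k={k} added to all areas")


def proportions(v: MetricVector) -> pd.Series:
    """Each area's share of the summed metric; requires positive finite input."""
    vals = v.values
    if vals.isna().any() or not np.isfinite(vals).all():
        raise ValueError(
            f"metric {v.metric!r}: non-finite values; run fill_missing_with_median first"
        )
    if (vals <= 0).any():
        raise ValueError(
            f"metric {v.metric!r}: non-positive values; run shift_to_positive first"
        )
    return vals / vals.sum()


def apply_criteria(
    props: pd.Series,
    thresholds: dict[str, float] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Boolean criterion flags per area (strict '>' by default)."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    flags = {}
    for name, thr in thresholds.items():
        flags[name] = (props > thr) if strict else (props >= thr)
    return pd.DataFrame(flags, index=props.index)


def assess(
    v: MetricVector,
    thresholds: dict[str, float] | None = None,
    strict: bool = True,
    cap_infinities: bool = False,
) -> KBAAssessment:
    """Full pipeline: median-fill, shift to positive, proportions, flags.

    ``cap_infinities`` replaces +inf by the largest finite value instead of
    treating it as missing (alternative policy for infinite N_e).
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    work = v
    if cap_infinities:
        vals = work.values.copy()
        inf = np.isinf(vals) & (vals > 0)
        if inf.any():
            finite = vals[np.isfinite(vals)]
            if finite.empty:
                raise ValueError(f"metric {v.metric!r}: no finite values to cap with")
            vals[inf] = float(finite.max())
            work = work.copy_with(vals, f"cap: {int(inf.sum())} +inf set to max finite")
    work = fill_missing_with_median(work)
    work = shift_to_positive(work)
    props = proportions(work)
    flags = apply_criteria(props, thresholds, strict)
    return KBAAssessment(v.metric, props, flags, dict(thresholds), list(work.adjustments))
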