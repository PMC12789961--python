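"""High-level orchestration: prepared dataset -> per-area metric table.

Ties the modules together the way the CLI and the benchmark studies use
them: apply the preparation pipeline once, compute the requested per-area
metrics, and return a wide table (one row per area, one column per metric).
The LD N_e estimator runs on the *filtered but unimputed* genotypes by
default, because fractional mean-imputed dosages attenuate the
disequilibrium signal; every frequency-based metric uses the imputed data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allele_stats, distinct_metrics, diversity_metrics
from .datamodel import GenotypeDataset
from .kba_criteria import MetricVector
from .preprocess import PrepConfig, filter_missing_individuals, filter_small_areas, impute_mean_dosage

__all__ = ["MetricOptions", "compute_metric_table", "metric_vectors"]

log = logging.getLogger(__name__)

ALL_METRICS = ("avtd", "overlap", "dest", "amova", "lambda", "ne", "richness")


@dataclass
class MetricOptions:
    """Tunables forwarded to the individual metrics."""

    weights: distinct_metrics.HierarchyWeights = field(
        default_factory=lambda: distinct_metrics.ALLELIC_WEIGHTS
    )
    presence_threshold: float = 0.0
    overlap_method: str = "czekanowski"
    dest_combine: str = "arithmetic"
    amova_statistic: str = "sigma2_a"
    pcrit: float = 0.02
    ne_use_imputed: bool = False
    richness_g: int | str = "auto"


def compute_metric_table(
    ds: GenotypeDataset,
    metrics: tuple[str, ...] = ALL_METRICS,
    prep: PrepConfig | None = None,
    options: MetricOptions | None = None,
) -> pd.DataFrame:
    """Prepare ``ds`` and compute the requested per-area metrics.

    Returns a DataFrame indexed by area.  Metrics that fail for an area
    (e.g. N_e with no eligible locus pairs) are recorded as NaN; infinite
    N_e estimates are kept as +inf for downstream policy handling.
    """
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; choose from {ALL_METRICS}")
    if not metrics:
        raise ValueError("no metrics requested")
    prep = prep or PrepConfig()
    options = options or MetricOptions()

    filtered = filter_small_areas(ds, prep.min_area_n)
    filtered = filter_missing_individuals(filtered, prep.max_individual_missing)
    if prep.strict_recheck:
        filtered = filter_small_areas(filtered, prep.min_area_n)
    imputed = impute_mean_dosage(filtered) if prep.impute else filtered

    counts = allele_stats.count_alleles(imputed)
    freqs = allele_stats.frequencies(counts)
    ne_input = imputed if options.ne_use_imputed else filtered
    areas = counts.areas
    table: dict[str, dict[str, float]] = {m: {} for m in metrics}

    for area in areas:
        for m in metrics:
            try:
                table[m][area] = _one_metric(
                    m, area, imputed, counts, freqs, ne_input, options
                )
            except (ValueError, KeyError) as exc:
                log.warning("metric %r failed for area %r: %s", m, area, exc)
                table[m][area] = float("nan")
    out = pd.DataFrame(table, index=pd.Index(areas, name="area"))
    return out[list(metrics)]


def _one_metric(m, area, imputed, counts, freqs, ne_input, opt: MetricOptions) -> float:
    if m == "avtd":
        return distinct_metrics.avtd(freqs, area, opt.weights, opt.presence_threshold)
    if m == "overlap":
        return distinct_metrics.overlap_per_area(freqs, area, opt.overlap_method)
    if m == "dest":
        return distinct_metrics.dest_per_area(counts, area, opt.dest_combine)
    if m == "amova":
        return distinct_metrics.amova_per_area(imputed, area, opt.amova_statistic)
    if m == "lambda":
        return diversity_metrics.simpson_lambda_cor(counts, area).mean_diversity
    if m == "ne":
        return diversity_metrics.ne_ld(ne_input, area, opt.pcrit).value
    if m == "richness":
        return allele_stats.allelic_richness(counts, area, opt.richness_g)
    raise AssertionError(m)


def metric_vectors(table: pd.DataFrame) -> list[MetricVector]:
    """Split a wide metric table into per-metric vectors."""
    return [MetricVector(str(col), table[col]) for col in table.columns]
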