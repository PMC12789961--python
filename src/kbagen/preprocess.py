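"""Uniform data-preparation pipeline: area-size filter, individual
missingness filter, global mean imputation.

The defaults mirror common practice for LD-based effective-size estimation:
areas with fewer than 30 individuals are dropped (small samples produce
negative and unrealistically low N_e values) and individuals with more than
20% missing loci are dropped (missingness inflates N_e).  Remaining missing
genotypes are replaced by the mean observed allele dosage at that locus,
pooled over ALL individuals in the dataset — not per area — which biases
area frequencies slightly toward the global mean; this pooling is the
documented convention of the pipeline.

Both thresholds are strict: exactly 30 individuals survive the area filter,
exactly 20% missingness survives the individual filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import GenotypeDataset

__all__ = [
    "PrepConfig",
    "filter_small_areas",
    "filter_missing_individuals",
    "impute_mean_dosage",
    "prepare",
]

log = logging.getLogger(__name__)


@dataclass
class PrepConfig:
    """Settings for :func:`prepare`.

    min_area_n
        Areas with fewer than this many individuals are removed (strict).
    max_individual_missing
        Individuals whose missing-locus fraction strictly exceeds this are
        removed.
    impute
        Replace remaining missing genotypes by pooled mean dosages.
    strict_recheck
        Re-apply the area-size filter after individual removal.
    """

    min_area_n: int = 30
    max_individual_missing: float = 0.20
    impute: bool = True
    strict_recheck: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_individual_missing <= 1:
            raise ValueError("max_individual_missing must be in [0, 1]")
        if self.min_area_n < 0:
            raise ValueError("min_area_n must be >= 0")


def filter_small_areas(ds: GenotypeDataset, min_area_n: int = 30) -> GenotypeDataset:
    """Drop every area with fewer than ``min_area_n`` individuals."""
    table = ds.area_table()
    keep: list[int] = []
    for area, ix in table.items():
        if len(ix) < min_area_n:
            log.info("removing area %r: %d < %d individuals", area, len(ix), min_area_n)
        else:
            keep.extend(ix.tolist())
    if not keep:
        raise ValueError(
            f"no areas remain: all {len(table)} areas have fewer than "
            f"{min_area_n} individuals"
        )
    keep.sort()
    return ds.subset_individuals(keep)


def filter_missing_individuals(ds: GenotypeDataset, max_missing: float = 0.20) -> GenotypeDataset:
    """Drop individuals whose missing fraction strictly exceeds ``max_missing``."""
    frac = ds.missing_fraction()
    keep = np.flatnonzero(frac <= max_missing)
    n_drop = ds.n_individuals - keep.size
    if n_drop:
        log.info("removing %d individuals with > %.0f%% missing data", n_drop, 100 * max_missing)
    return ds.subset_individuals(keep)


def impute_mean_dosage(ds: GenotypeDataset) -> GenotypeDataset:
    """Replace missing genotypes with the mean observed dosage per allele.

    Means are taken over all individuals observed at the locus, across the
    whole dataset.  Loci observed in zero individuals are dropped with a
    warning.  The diploid sum invariant is preserved exactly: allele-wise
    means of rows summing to 2 sum to 2.
    """
    if not ds.missing.any():
        return GenotypeDataset(
            ds.individual_ids, ds.areas, ds.loci, ds.dosage, ds.missing,
            imputed=ds.imputed, validate=False,
        )
    obs = ~ds.missing  # (n, L)
    n_obs = obs.sum(axis=0)  # per locus
    dead = np.flatnonzero(n_obs == 0)
    work = ds
    if dead.size:
        log.warning("dropping %d loci observed in zero individuals", dead.size)
        keep = np.flatnonzero(n_obs > 0)
        work = ds.subset_loci(keep)
        obs = ~work.missing
        n_obs = obs.sum(axis=0)

    dosage = work.dosage.copy()
    with np.errstate(invalid="ignore"):
        mean = (dosage * obs[:, :, None]).sum(axis=0) / n_obs[:, None]  # (L, A)
    for l in range(work.n_loci):
        rows = np.flatnonzero(work.missing[:, l])
        dosage[rows, l, :] = mean[l]
    missing = np.zeros_like(work.missing)
    return GenotypeDataset(
        work.individual_ids, work.areas, work.loci, dosage, missing, imputed=True
    )


def prepare(ds: GenotypeDataset, cfg: PrepConfig | None = None) -> GenotypeDataset:
    """Run the full pipeline: area filter, individual filter, imputation."""
    cfg = cfg or PrepConfig()
    out = filter_small_areas(ds, cfg.min_area_n)
    out = filter_missing_individuals(out, cfg.max_individual_missing)
    if cfg.strict_recheck:
        out = filter_small_areas(out, cfg.min_area_n)
    else:
        for area, ix in out.area_table().items():
            if len(ix) < cfg.min_area_n:
                log.warning(
                    "area %r fell to %d (< %d) individuals after the missingness "
                    "filter; retained (strict_recheck=False)",
                    area, len(ix), cfg.min_area_n,
                )
    if cfg.impute:
        out = impute_mean_dosage(out)
    return out
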