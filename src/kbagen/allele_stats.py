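"""Per-area allele count and frequency tables, and rarefied allelic richness.

The count table sums allele dosages per (area, locus, allele); the
gene-copy total per (area, locus) is twice the number of contributing
individuals.  Allelic richness is rarefied to a common number of gene
copies g by the hypergeometric expectation

    AR_l = sum_a [ 1 - C(n - n_a, g) / C(n, g) ],

the expected number of distinct alleles among g copies drawn without
replacement.  Fractional imputed counts are rounded to the nearest integer
only inside this combinatorial step; frequencies stay fractional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import GenotypeDataset, Locus

__all__ = [
    "AlleleCountTable",
    "AlleleFrequencyTable",
    "count_alleles",
    "frequencies",
    "allelic_richness",
]


@dataclass
class AlleleCountTable:
    """Summed allele dosages per area.

    ``counts`` has shape (n_areas, n_loci, max_alleles); ``n_copies``
    (n_areas, n_loci) holds gene-copy totals (2 x contributing individuals).
    """

    areas: list[str]
    loci: list[Locus]
    counts: np.ndarray
    n_copies: np.ndarray

    def area_index(self, area: str) -> int:
        try:
            return self.areas.index(area)
        except ValueError:
            raise KeyError(f"unknown area {area!r}") from None

    def n_individuals(self, area: str) -> np.ndarray:
        """Per-locus diploid individual counts for an area."""
        return self.n_copies[self.area_index(area)] / 2.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, area in enumerate(self.areas):
            for l, loc in enumerate(self.loci):
                n = self.n_copies[k, l]
                for a, al in enumerate(loc.alleles):
                    rows.append(
                        {
                            "area": area,
                            "locus": loc.name,
                            "allele": al,
                            "count": self.counts[k, l, a],
                            "n": n,
                            "freq": self.counts[k, l, a] / n if n > 0 else np.nan,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class AlleleFrequencyTable:
    """Normalized allele frequencies per area.

    ``freqs`` mirrors the count-table shape; (area, locus) cells with zero
    gene copies are flagged in ``absent`` and carry zero frequencies rather
    than NaN.
    """

    areas: list[str]
    loci: list[Locus]
    freqs: np.ndarray
    absent: np.ndarray  # (n_areas, n_loci) bool
    n_copies: np.ndarray = field(default=None)  # carried through for estimators

    def area_index(self, area: str) -> int:
        try:
            return self.areas.index(area)
        except ValueError:
            raise KeyError(f"unknown area {area!r}") from None


def count_alleles(ds: GenotypeDataset) -> AlleleCountTable:
    """Sum allele dosages per area; missing genotypes contribute nothing."""
    table = ds.area_table()
    areas = list(table)
    A = ds.max_alleles
    counts = np.zeros((len(areas), ds.n_loci, A))
    n_copies = np.zeros((len(areas), ds.n_loci))
    obs = ~ds.missing
    for k, area in enumerate(areas):
        ix = table[area]
        counts[k] = ds.dosage[ix].sum(axis=0)
        n_copies[k] = 2.0 * obs[ix].sum(axis=0)
    return AlleleCountTable(areas, list(ds.loci), counts, n_copies)


def frequencies(t: AlleleCountTable) -> AlleleFrequencyTable:
    """Normalize counts to frequencies; zero-copy cells flagged absent."""
    absent = t.n_copies <= 0
    denom = np.where(absent, 1.0, t.n_copies)
    freqs = t.counts / denom[:, :, None]
    freqs[absent] = 0.0
    return AlleleFrequencyTable(list(t.areas), list(t.loci), freqs, absent, t.n_copies.copy())


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(t: AlleleCountTable, area: str, g: int | str = "auto") -> float:
    """Mean rarefied allelic richness over loci for one area.

    ``g`` is the rarefaction depth in gene copies; ``"auto"`` uses the
    smallest per-(area, locus) gene-copy total across the whole table, the
    standard choice that makes all areas comparable.  Counts are rounded to
    nearest integers for the binomial coefficients.
    """
    if g == "auto":
        pos = t.n_copies[t.n_copies > 0]
        if pos.size == 0:
            raise ValueError("no gene copies anywhere: cannot rarefy")
        g = int(np.round(pos.min()))
    g = int(g)
    if g < 2:
        raise ValueError("rarefaction depth g must be >= 2")
    k = t.area_index(area)
    per_locus = []
    for l in range(len(t.loci)):
        n = int(np.round(t.n_copies[k, l]))
        if n == 0:
            continue
        if g > n:
            raise ValueError(
                f"rarefaction depth g={g} exceeds gene copies n={n} at "
                f"locus {t.loci[l].name!r} in area {area!r}"
            )
        na = np.round(t.counts[k, l, : t.loci[l].n_alleles]).astype(int)
        na = na[na > 0]
        # P(allele absent from g draws) = C(n - n_a, g) / C(n, g)
        with np.errstate(invalid="ignore"):
            p_absent = np.where(
                n - na >= g,
                np.exp(_log_comb((n - na).astype(float), g) - _log_comb(float(n), g)),
                0.0,
            )
        per_locus.append(float(np.sum(1.0 - p_absent)))
    if not per_locus:
        raise ValueError(f"area {area!r} has no observed loci")
    return float(np.mean(per_locus))
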