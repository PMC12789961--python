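"""Core in-memory containers for diploid multi-locus genotype data.

The canonical representation is an allele-dosage tensor of shape
``(n_individuals, n_loci, max_alleles)``: entry ``[i, l, a]`` holds how many
copies of allele ``a`` at locus ``l`` individual ``i`` carries.  For observed
genotypes the dosages over alleles sum to exactly 2 (diploid); after mean
imputation they may be fractional but still sum to 2.  Missing genotypes are
flagged in a boolean ``missing`` mask and carry all-zero dosage.

Dosages rather than two allele slots are used so that fractional
mean-imputed genotypes are representable, and because every downstream
metric (allele frequencies, differentiation, AMOVA distances, composite
linkage disequilibrium) is a function of dosages only.  Loci are unordered
labels; genomic coordinates play no role in any metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["Locus", "GenotypeDataset", "DIPLOID_TOL"]

#: tolerance on the diploid dosage-sum invariant after fractional imputation
DIPLOID_TOL = 1e-9

MARKER_TYPES = ("snp", "microsatellite")


@dataclass(frozen=True)
class Locus:
    """A named marker with an ordered allele label set.

    ``marker_type`` is ``"snp"`` (nucleotide or 0/1 codes) or
    ``"microsatellite"`` (repeat sizes as text).  Allele labels must be
    unique within the locus and at least one allele must be present.
    """

    name: str
    marker_type: str = "snp"
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.marker_type not in MARKER_TYPES:
            raise ValueError(f"unknown marker_type {self.marker_type!r}")
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate allele labels at locus {self.name!r}")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


class GenotypeDataset:
    """Diploid genotypes for a set of individuals assigned to areas.

    Parameters
    ----------
    individual_ids
        Ordered unique individual labels.
    areas
        One area id (opaque string) per individual.  Areas partition the
        individual set; they carry no geographic semantics.
    loci
        Ordered :class:`Locus` descriptors.  The third tensor axis is padded
        to the maximum allele count over loci; padding columns are zero.
    dosage
        ``(n_individuals, n_loci, max_alleles)`` float array of allele
        copy numbers.
    missing
        ``(n_individuals, n_loci)`` boolean mask; ``True`` marks an
        unobserved genotype (all-zero dosage row).
    imputed
        Whether missing genotypes have been replaced by fractional means.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        areas: Sequence[str],
        loci: Sequence[Locus],
        dosage: np.ndarray,
        missing: np.ndarray | None = None,
        imputed: bool = False,
        validate: bool = True,
    ) -> None:
        self.individual_ids = list(map(str, individual_ids))
        self.areas = np.asarray(areas, dtype=object)
        self.loci = list(loci)
        self.dosage = np.asarray(dosage, dtype=float)
        n, L = len(self.individual_ids), len(self.loci)
        if missing is None:
            missing = np.zeros((n, L), dtype=bool)
        self.missing = np.asarray(missing, dtype=bool)
        self.imputed = imputed
        if validate:
            self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        n, L = self.n_individuals, self.n_loci
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if self.areas.shape != (n,):
            raise ValueError("areas must have one entry per individual")
        A = max((loc.n_alleles for loc in self.loci), default=0)
        if self.dosage.shape != (n, L, max(A, 0)) and not (L == 0 and self.dosage.size == 0):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{n} individuals x {L} loci x {A} alleles"
            )
        if self.missing.shape != (n, L):
            raise ValueError("missing mask shape mismatch")
        if np.any(self.dosage < 0):
            raise ValueError("negative allele dosage")
        # padding columns beyond each locus's allele count must be zero
        for l, loc in enumerate(self.loci):
            if np.any(self.dosage[:, l, loc.n_alleles:] != 0):
                raise ValueError(f"nonzero dosage in padding at locus {loc.name!r}")
        sums = self.dosage.sum(axis=2)
        obs = ~self.missing
        if not np.allclose(sums[obs], 2.0, atol=DIPLOID_TOL, rtol=0):
            raise ValueError("non-missing genotype dosages must sum to 2 (diploid)")
        if np.any(sums[self.missing] != 0):
            raise ValueError("missing genotypes must carry all-zero dosage")

    # -- basic properties ----------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def max_alleles(self) -> int:
        return max((loc.n_alleles for loc in self.loci), default=0)

    def area_table(self) -> dict[str, np.ndarray]:
        """Area id -> array of individual indices (insertion-ordered)."""
        table: dict[str, list[int]] = {}
        for i, a in enumerate(self.areas):
            table.setdefault(a, []).append(i)
        return {a: np.asarray(ix, dtype=int) for a, ix in table.items()}

    def area_ids(self) -> list[str]:
        return list(self.area_table())

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing loci."""
        if self.n_loci == 0:
            return np.zeros(self.n_individuals)
        return self.missing.mean(axis=1)

    # -- subsetting ----------------------------------------------------------------

    def subset_individuals(self, indices: Iterable[int]) -> "GenotypeDataset":
        ix = np.asarray(list(indices), dtype=int)
        return GenotypeDataset(
            [self.individual_ids[i] for i in ix],
            self.areas[ix],
            self.loci,
            self.dosage[ix],
            self.missing[ix],
            imputed=self.imputed,
            validate=False,
        )

    def subset_loci(self, indices: Iterable[int]) -> "GenotypeDataset":
        ix = np.asarray(list(indices), dtype=int)
        loci = [self.loci[l] for l in ix]
        A = max((loc.n_alleles for loc in loci), default=0)
        return GenotypeDataset(
            self.individual_ids,
            self.areas,
            loci,
            self.dosage[:, ix, :A],
            self.missing[:, ix],
            imputed=self.imputed,
            validate=False,
        )

    def subset_area(self, area: str) -> "GenotypeDataset":
        table = self.area_table()
        if area not in table:
            raise KeyError(f"unknown area {area!r}")
        return self.subset_individuals(table[area])

    # -- equality (used by round-trip tests) ---------------------------------------

    def equals(self, other: "GenotypeDataset", atol: float = 0.0) -> bool:
        if self.individual_ids != other.individual_ids:
            return False
        if list(self.areas) != list(other.areas):
            return False
        if [(l.name, tuple(l.alleles)) for l in self.loci] != [
            (l.name, tuple(l.alleles)) for l in other.loci
        ]:
            return False
        if not np.array_equal(self.missing, other.missing):
            return False
        return np.allclose(self.dosage, other.dosage, atol=atol, rtol=0)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"<GenotypeDataset {self.n_individuals} individuals x {self.n_loci} loci, "
            f"{len(self.area_table())} areas, imputed={self.imputed}>"
        )


def from_genotype_pairs(
    individual_ids: Sequence[str],
    areas: Sequence[str],
    locus_names: Sequence[str],
    genotypes: Mapping[tuple[int, int], tuple[str, str] | None] | np.ndarray,
    marker_type: str = "snp",
) -> GenotypeDataset:
    """Build a dataset from two-allele-slot genotype calls.

    ``genotypes`` maps ``(individual_index, locus_index)`` to a pair of
    allele labels, or ``None`` for missing.  Allele label sets per locus are
    collected in order of first appearance (sorted for determinism).
    """
    n, L = len(individual_ids), len(locus_names)
    calls: dict[tuple[int, int], tuple[str, str] | None]
    if isinstance(genotypes, np.ndarray):
        calls = {
            (i, l): (
                None
                if genotypes[i, l] is None
                else (str(genotypes[i, l][0]), str(genotypes[i, l][1]))
            )
            for i in range(n)
            for l in range(L)
        }
    else:
        calls = dict(genotypes)

    allele_sets: list[set[str]] = [set() for _ in range(L)]
    for (i, l), g in calls.items():
        if g is not None:
            allele_sets[l].update(g)
    loci = []
    for l, name in enumerate(locus_names):
        labels = sorted(allele_sets[l], key=_allele_sort_key) or ["0"]
        loci.append(Locus(str(name), marker_type, tuple(labels)))

    A = max(loc.n_alleles for loc in loci)
    dosage = np.zeros((n, L, A))
    missing = np.ones((n, L), dtype=bool)
    index = [{al: a for a, al in enumerate(loc.alleles)} for loc in loci]
    for (i, l), g in calls.items():
        if g is None:
            continue
        missing[i, l] = False
        for al in g:
            dosage[i, l, index[l][al]] += 1.0
    return GenotypeDataset(individual_ids, areas, loci, dosage, missing)


def _allele_sort_key(label: str):
    """Numeric-aware sort so microsatellite repeat sizes order naturally."""
    try:
        return (0, float(label), label)
    except ValueError:
        return (1, 0.0, label)
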