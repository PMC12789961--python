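"""Shared fixtures: tiny hand-built genotype datasets with known structure."""

from __future__ import annotations

import numpy as np
import pytest

from kbagen.datamodel import GenotypeDataset, from_genotype_pairs


def dataset_from_calls(rows, locus_names, marker_type="microsatellite"):
    """Build a dataset from ``(individual, area, [(a1, a2) | None per locus])`` rows."""
    individual_ids = [r[0] for r in rows]
    areas = [r[1] for r in rows]
    calls = {}
    for i, r in enumerate(rows):
        for l, g in enumerate(r[2]):
            calls[(i, l)] = None if g is None else (str(g[0]), str(g[1]))
    return from_genotype_pairs(individual_ids, areas, locus_names, calls, marker_type)


@pytest.fixture
def two_area_fixed():
    """Two areas fixed for alternate alleles at every locus: maximal divergence."""
    rows = []
    for i in range(30):
        rows.append((f"a{i}", "north", [("1", "1"), ("1", "1")]))
    for i in range(30):
        rows.append((f"b{i}", "south", [("2", "2"), ("2", "2")]))
    return dataset_from_calls(rows, ["L1", "L2"])


@pytest.fixture
def two_area_identical():
    """Two areas with identical genotype multisets: zero differentiation."""
    rows = []
    for area in ("east", "west"):
        for i in range(15):
            g = ("1", "2") if i % 3 == 0 else ("1", "1") if i % 3 == 1 else ("2", "2")
            rows.append((f"{area}{i}", area, [g, ("1", "2")]))
    return dataset_from_calls(rows, ["L1", "L2"])


@pytest.fixture
def small_mixed():
    """3 areas x 4 individuals, 2 loci, some missing genotypes."""
    rows = [
        ("i1", "A", [("1", "1"), ("3", "3")]),
        ("i2", "A", [("1", "2"), ("3", "4")]),
        ("i3", "A", [("2", "2"), None]),
        ("i4", "A", [("1", "2"), ("3", "3")]),
        ("i5", "B", [("1", "1"), ("4", "4")]),
        ("i6", "B", [("1", "1"), ("3", "4")]),
        ("i7", "B", [None, ("4", "4")]),
        ("i8", "B", [("1", "2"), ("4", "4")]),
        ("i9", "C", [("2", "2"), ("3", "3")]),
        ("i10", "C", [("2", "2"), ("3", "3")]),
        ("i11", "C", [("1", "2"), ("3", "4")]),
        ("i12", "C", [("2", "2"), None]),
    ]
    return dataset_from_calls(rows, ["L1", "L2"])


def duplicate_individuals(ds: GenotypeDataset) -> GenotypeDataset:
    """Every individual appears twice (sample-size-dependence probes)."""
    ids = ds.individual_ids + [f"{i}__dup" for i in ds.individual_ids]
    areas = np.concatenate([ds.areas, ds.areas])
    return GenotypeDataset(
        ids, areas, ds.loci,
        np.concatenate([ds.dosage, ds.dosage]),
        np.concatenate([ds.missing, ds.missing]),
        imputed=ds.imputed,
    )
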