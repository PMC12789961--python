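"""Readers and writers for the standard population-genetic genotype formats.

Four dialects are supported and all load into the same
:class:`~kbagen.datamodel.GenotypeDataset`:

* Genepop (2- or 3-digit allele codes), one area per ``POP`` block;
* Structure two-row-per-individual tables with a population column;
* VCF 4.x plus a two-column individual-to-area population map;
* a long-format TSV (``individual  area  locus  allele_a  allele_b``) that
  round-trips any integer-dosage dataset.

Area identity is an opaque label taken from the POP block, population
column or popmap; no geographic meaning is attached.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np

from .datamodel import GenotypeDataset, Locus, from_genotype_pairs

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_structure",
    "read_vcf",
    "read_table",
    "write_table",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def read_genepop(path, allele_digits: int = 3, marker_type: str = "microsatellite") -> GenotypeDataset:
    """Read a Genepop file.

    Each genotype field is ``2 * allele_digits`` wide; an all-zero code marks
    a missing genotype.  Each ``POP`` block becomes one area, named by the
    label of its last individual (the Genepop convention), falling back to
    ``pop<k>`` when the label is empty.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError("empty Genepop file")

    # title line, then locus names until the first POP
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            # locus names may be comma-separated on one line
            locus_names.extend(s.strip() for s in part.split(",") if s.strip())
        i += 1
    if not locus_names:
        raise ParseError(f"line {i + 1}: no locus names before first POP")

    width = 2 * allele_digits
    missing_code = "0" * allele_digits
    blocks: list[list[tuple[str, list[str]]]] = []
    while i < len(lines):
        if lines[i].strip().lower() != "pop":
            raise ParseError(f"line {i + 1}: expected POP, got {lines[i]!r}")
        i += 1
        block: list[tuple[str, list[str]]] = []
        while i < len(lines) and lines[i].strip().lower() != "pop":
            line = lines[i].strip()
            if line:
                if "," not in line:
                    raise ParseError(f"line {i + 1}: missing ',' separator")
                label, geno = line.split(",", 1)
                fields = geno.split()
                if len(fields) != len(locus_names):
                    raise ParseError(
                        f"line {i + 1}: {len(fields)} genotype fields, "
                        f"expected {len(locus_names)}"
                    )
                for f in fields:
                    if len(f) != width or not f.isdigit():
                        raise ParseError(
                            f"line {i + 1}: genotype field {f!r} is not "
                            f"{width} digits wide"
                        )
                block.append((label.strip(), fields))
            i += 1
        if block:
            blocks.append(block)
    if not blocks:
        raise ParseError("no POP blocks found")

    individual_ids: list[str] = []
    areas: list[str] = []
    calls: dict[tuple[int, int], tuple[str, str] | None] = {}
    for b, block in enumerate(blocks):
        area = block[-1][0] or f"pop{b + 1}"
        for label, fields in block:
            idx = len(individual_ids)
            individual_ids.append(label or f"ind{idx + 1}")
            areas.append(area)
            for l, f in enumerate(fields):
                a1, a2 = f[:allele_digits], f[allele_digits:]
                if a1 == missing_code and a2 == missing_code:
                    calls[(idx, l)] = None
                elif a1 == missing_code or a2 == missing_code:
                    calls[(idx, l)] = None  # half-missing treated as missing
                else:
                    calls[(idx, l)] = (a1, a2)
    # duplicate labels across blocks are disambiguated
    individual_ids = _dedupe(individual_ids)
    return from_genotype_pairs(individual_ids, areas, locus_names, calls, marker_type)


def write_genepop(
    ds: GenotypeDataset,
    path,
    allele_digits: int = 3,
    title: str = "kbagen export",
    label_style: str = "area",
) -> None:
    """Write integer-dosage genotypes as a Genepop file.

    With ``label_style="area"`` (default) every row of a POP block carries
    the area id as its label — the common locality-label layout, under
    which :func:`read_genepop` recovers the area names exactly (individual
    ids are not representable in Genepop and are regenerated on read).
    ``label_style="individual"`` writes the individual ids instead.
    """
    _require_integer_dosage(ds, "write_genepop")
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    code = {}
    for l, loc in enumerate(ds.loci):
        for a, al in enumerate(loc.alleles):
            if not al.isdigit() or len(al) > allele_digits:
                raise ValueError(
                    f"allele label {al!r} at locus {loc.name!r} is not encodable "
                    f"with {allele_digits} digits"
                )
            code[(l, a)] = al.zfill(allele_digits)
    missing_code = "0" * allele_digits

    out = [title]
    out.extend(loc.name for loc in ds.loci)
    if label_style not in ("area", "individual"):
        raise ValueError("label_style must be 'area' or 'individual'")
    for area, ix in ds.area_table().items():
        out.append("POP")
        for i in ix:
            fields = []
            for l in range(ds.n_loci):
                if ds.missing[i, l]:
                    fields.append(missing_code * 2)
                    continue
                pair = _dosage_to_pair(ds.dosage[i, l], ds.loci[l].n_alleles)
                fields.append(code[(l, pair[0])] + code[(l, pair[1])])
            label = area if label_style == "area" else ds.individual_ids[i]
            out.append(f"{label} ,  " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Structure two-row format
# ---------------------------------------------------------------------------

def read_structure(path, n_loci: int, missing_code: int = -9, marker_type: str = "microsatellite") -> GenotypeDataset:
    """Read a Structure two-row-per-individual file.

    Each individual occupies two whitespace-delimited rows of
    ``label  population  allele_1 ... allele_n_loci``; the population column
    defines the area.  ``missing_code`` in either row marks that locus
    missing for the individual.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.strip():
            parts = line.split()
            if len(parts) != n_loci + 2:
                raise ParseError(
                    f"line {lineno}: {len(parts)} columns, expected {n_loci + 2} "
                    "(label, population, loci)"
                )
            rows.append((lineno, parts))
    if len(rows) % 2 != 0:
        raise ParseError("odd number of data rows: individuals need two rows each")

    individual_ids: list[str] = []
    areas: list[str] = []
    calls: dict[tuple[int, int], tuple[str, str] | None] = {}
    miss = str(missing_code)
    for k in range(0, len(rows), 2):
        (ln1, r1), (ln2, r2) = rows[k], rows[k + 1]
        if r1[0] != r2[0]:
            raise ParseError(
                f"lines {ln1}/{ln2}: row pair labels differ ({r1[0]!r} vs {r2[0]!r})"
            )
        if r1[1] != r2[1]:
            raise ParseError(f"lines {ln1}/{ln2}: population differs within individual")
        idx = len(individual_ids)
        individual_ids.append(r1[0])
        areas.append(r1[1])
        for l in range(n_loci):
            a1, a2 = r1[2 + l], r2[2 + l]
            calls[(idx, l)] = None if miss in (a1, a2) else (a1, a2)
    individual_ids = _dedupe(individual_ids)
    locus_names = [f"locus{l + 1}" for l in range(n_loci)]
    return from_genotype_pairs(individual_ids, areas, locus_names, calls, marker_type)


# ---------------------------------------------------------------------------
# VCF + popmap
# ---------------------------------------------------------------------------

def read_vcf(path, popmap) -> GenotypeDataset:
    """Read diploid GT calls from a VCF plus a two-column popmap.

    Biallelic records become two-allele SNP loci; multi-allelic records keep
    all ALT alleles as one locus (metrics are per-locus over allele sets).
    ``./.`` marks missing.  Samples absent from the popmap are dropped with
    a warning; popmap entries absent from the VCF raise.
    """
    from cyvcf2 import VCF

    area_of: dict[str, str] = {}
    for lineno, line in enumerate(Path(popmap).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"popmap line {lineno}: need 'individual area'")
        area_of[parts[0]] = parts[1]

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = set(area_of) - set(samples)
    if unknown:
        raise ValueError(f"popmap references samples absent from VCF: {sorted(unknown)}")
    keep = [s for s in samples if s in area_of]
    dropped = [s for s in samples if s not in area_of]
    if dropped:
        log.warning("dropping %d VCF samples absent from popmap: %s", len(dropped), dropped)
    keep_ix = [samples.index(s) for s in keep]

    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    missing_cols: list[np.ndarray] = []
    for var in vcf:
        alleles = (var.REF, *var.ALT)
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        gts = var.genotype.array()  # (n_samples, ploidy+1); last col = phase
        gts = np.asarray(gts)[keep_ix]
        if gts.shape[1] - 1 != 2:
            raise ValueError(f"non-diploid GT at {name}")
        alle = gts[:, :2]
        miss = np.any(alle < 0, axis=1)
        dos = np.zeros((len(keep), len(alleles)))
        for a in range(len(alleles)):
            dos[:, a] = (alle == a).sum(axis=1)
        dos[miss] = 0.0
        loci.append(Locus(str(name), "snp", tuple(map(str, alleles))))
        columns.append(dos)
        missing_cols.append(miss)
    vcf.close()

    L = len(loci)
    A = max((loc.n_alleles for loc in loci), default=0)
    dosage = np.zeros((len(keep), L, A))
    missing = np.zeros((len(keep), L), dtype=bool)
    for l in range(L):
        dosage[:, l, : loci[l].n_alleles] = columns[l]
        missing[:, l] = missing_cols[l]
    areas = [area_of[s] for s in keep]
    return GenotypeDataset(keep, areas, loci, dosage, missing)


# ---------------------------------------------------------------------------
# Long-format table
# ---------------------------------------------------------------------------

_TABLE_HEADER = "individual\tarea\tlocus\tallele_a\tallele_b"


def write_table(ds: GenotypeDataset, path, marker_type_comment: bool = True) -> None:
    """Write the long-format TSV (one row per individual x locus).

    Only integer-dosage (pre-imputation) data can be exported; fractional
    imputed dosages have no two-allele representation.
    """
    _require_integer_dosage(ds, "write_table")
    out = []
    if marker_type_comment and ds.n_loci:
        out.append(f"# marker_type={ds.loci[0].marker_type}")
    out.append(_TABLE_HEADER)
    for i, ind in enumerate(ds.individual_ids):
        for l, loc in enumerate(ds.loci):
            if ds.missing[i, l]:
                a1 = a2 = "NA"
            else:
                pa = _dosage_to_pair(ds.dosage[i, l], loc.n_alleles)
                a1, a2 = loc.alleles[pa[0]], loc.alleles[pa[1]]
            out.append(f"{ind}\t{ds.areas[i]}\t{loc.name}\t{a1}\t{a2}")
    Path(path).write_text("\n".join(out) + "\n")


def read_table(path, marker_type: str | None = None) -> GenotypeDataset:
    """Read the long-format TSV written by :func:`write_table`."""
    lines = Path(path).read_text().splitlines()
    mt = marker_type
    body = []
    for line in lines:
        if line.startswith("#"):
            m = re.match(r"#\s*marker_type=(\w+)", line)
            if m and marker_type is None:
                mt = m.group(1)
            continue
        if line.strip():
            body.append(line)
    if not body or body[0].split("\t")[:5] != _TABLE_HEADER.split("\t"):
        raise ParseError("missing long-format header line")
    mt = mt or "snp"

    individual_ids: list[str] = []
    ind_index: dict[str, int] = {}
    areas: list[str] = []
    locus_names: list[str] = []
    loc_index: dict[str, int] = {}
    calls: dict[tuple[int, int], tuple[str, str] | None] = {}
    for lineno, line in enumerate(body[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"line {lineno}: expected 5 tab-separated columns")
        ind, area, locus, a1, a2 = parts
        if ind not in ind_index:
            ind_index[ind] = len(individual_ids)
            individual_ids.append(ind)
            areas.append(area)
        elif areas[ind_index[ind]] != area:
            raise ParseError(f"line {lineno}: individual {ind!r} in two areas")
        if locus not in loc_index:
            loc_index[locus] = len(locus_names)
            locus_names.append(locus)
        key = (ind_index[ind], loc_index[locus])
        calls[key] = None if "NA" in (a1, a2) else (a1, a2)
    return from_genotype_pairs(individual_ids, areas, locus_names, calls, mt)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require_integer_dosage(ds: GenotypeDataset, op: str) -> None:
    if ds.imputed or not np.allclose(ds.dosage, np.round(ds.dosage), atol=0):
        raise ValueError(
            f"{op} requires integer allele dosages; export the dataset before "
            "mean imputation (fractional dosages have no two-allele form)"
        )


def _dosage_to_pair(row: np.ndarray, n_alleles: int) -> tuple[int, int]:
    pair = []
    for a in range(n_alleles):
        pair.extend([a] * int(round(row[a])))
    if len(pair) != 2:
        raise ValueError("genotype dosage does not describe two allele copies")
    return pair[0], pair[1]


def _dedupe(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for s in ids:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out
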