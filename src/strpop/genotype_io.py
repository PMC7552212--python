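"""Canonical data model and I/O for codominant STR genotype tables.

The in-memory container is :class:`GenotypeTable`: individuals x loci with two
integer allele calls per genotype (0 = missing).  Two text dialects are
supported:

* a GenAlEx-style codominant CSV (three header rows declaring counts, a title
  row, and column names; two allele columns per locus), and
* a canonical long-format CSV with one row per individual x locus
  (``individual,population,locus,allele1,allele2``).

Half-missing genotypes (one allele 0, the other not) are invalid.  Males at an
X-linked locus are hemizygous: they carry a single physical allele which is
stored as a doubled code together with a hemizygous flag, so heterozygosity
statistics naturally see them as homozygotes while allele-frequency code can
optionally count a single gene copy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = 0

AUTOSOMAL = "autosomal"
X_LINKED = "x_linked"


class GenotypeFileError(ValueError):
    """Raised when a genotype file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one STR locus."""

    name: str
    chromosome_mode: str = AUTOSOMAL

    def __post_init__(self) -> None:
        if self.chromosome_mode not in (AUTOSOMAL, X_LINKED):
            raise ValueError(f"unknown chromosome_mode {self.chromosome_mode!r}")

    @property
    def x_linked(self) -> bool:
        return self.chromosome_mode == X_LINKED


@dataclass
class GenotypeTable:
    """Diploid codominant genotype calls for a set of individuals.

    Parameters
    ----------
    individuals:
        Individual identifiers, one per row.
    populations:
        Population label per individual (same length as ``individuals``).
    loci:
        Ordered locus metadata.
    calls:
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele codes are
        positive integers, 0 encodes a missing allele.  A genotype must be
        fully missing (0, 0) or fully called.
    hemizygous:
        Optional boolean array ``(n_individuals, n_loci)`` marking genotypes
        that are a doubled single-copy call (males at an X-linked locus).
    """

    individuals: list[str]
    populations: list[str]
    loci: list[LocusMeta]
    calls: np.ndarray
    hemizygous: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(self.populations) != len(self.individuals):
            raise ValueError("populations and individuals differ in length")
        if self.hemizygous is None:
            self.hemizygous = np.zeros(self.calls.shape[:2], dtype=bool)
        else:
            self.hemizygous = np.asarray(self.hemizygous, dtype=bool)
            if self.hemizygous.shape != self.calls.shape[:2]:
                raise ValueError("hemizygous flag array has wrong shape")

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [m.name for m in self.loci]

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {p: 0 for p in self.population_labels()}
        for p in self.populations:
            sizes[p] += 1
        return sizes

    def population_mask(self, label: str) -> np.ndarray:
        return np.asarray([p == label for p in self.populations], dtype=bool)

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown locus {name!r}") from None

    def subset(self, individual_mask: Sequence[bool]) -> "GenotypeTable":
        mask = np.asarray(individual_mask, dtype=bool)
        return GenotypeTable(
            individuals=[i for i, m in zip(self.individuals, mask) if m],
            populations=[p for p, m in zip(self.populations, mask) if m],
            loci=list(self.loci),
            calls=self.calls[mask].copy(),
            hemizygous=self.hemizygous[mask].copy(),
        )

    def equals(self, other: "GenotypeTable") -> bool:
        """Structural equality on IDs, labels, loci and calls."""
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# validation

def validate(table: GenotypeTable) -> list[str]:
    """Check all container invariants; return human-readable violations.

    Reports rather than raises: an empty list means the table is valid.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for ind in table.individuals:
        if ind in seen:
            violations.append(f"duplicated individual ID {ind!r}")
        seen.add(ind)
    if not table.loci:
        violations.append("table has no loci")
    names = table.locus_names
    if len(set(names)) != len(names):
        violations.append("duplicated locus names")
    if (table.calls < 0).any():
        violations.append("negative allele codes present")
    a1 = table.calls[:, :, 0]
    a2 = table.calls[:, :, 1]
    half = (a1 == MISSING) ^ (a2 == MISSING)
    for i, l in zip(*np.nonzero(half)):
        violations.append(
            f"half-missing genotype for individual {table.individuals[i]!r} "
            f"at locus {names[l]!r}"
        )
    hemi_bad = table.hemizygous & (a1 != a2)
    for i, l in zip(*np.nonzero(hemi_bad)):
        violations.append(
            f"hemizygous genotype with two distinct alleles for individual "
            f"{table.individuals[i]!r} at locus {names[l]!r}"
        )
    return violations


# ---------------------------------------------------------------------------
# GenAlEx-dialect CSV

def _parse_int(token: str, where: str) -> int:
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        raise GenotypeFileError(f"expected an integer at {where}, got {token!r}") from None


def read_genalex(
    path: str | Path,
    x_linked_loci: Iterable[str] = ("LEX3",),
    strict: bool = False,
) -> GenotypeTable:
    """Read a GenAlEx-style codominant CSV.

    Layout: row 1 declares ``n_loci, n_samples, n_pops, size_1, ..., size_k``;
    row 2 is a free title row (population names may sit above their size
    columns); row 3 names the columns (``Ind, Pop, Locus1, , Locus2, , ...``);
    data rows follow with two allele columns per locus.

    In lenient mode (default) blank trailing cells are ignored; ``strict=True``
    rejects them.  Loci whose names appear in ``x_linked_loci`` are flagged
    X-linked.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeFileError(f"no such file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) < 4:
        raise GenotypeFileError("file too short: need 3 header rows plus data (row 1)")

    header = rows[0]
    if len(header) < 3:
        raise GenotypeFileError("malformed header: row 1 needs at least 3 count fields")
    n_loci = _parse_int(header[0], "row 1, column 1 (locus count)")
    n_samples = _parse_int(header[1], "row 1, column 2 (sample count)")
    n_pops = _parse_int(header[2], "row 1, column 3 (population count)")
    if len([c for c in header[3:] if c.strip()]) < n_pops:
        raise GenotypeFileError(
            f"malformed header: row 1 declares {n_pops} populations but lists "
            f"fewer size fields"
        )
    declared_sizes = [
        _parse_int(c, f"row 1, column {i + 4} (population size)")
        for i, c in enumerate(header[3 : 3 + n_pops])
    ]

    colnames = rows[2]
    locus_cols = colnames[2:]
    if strict:
        allele_cols = len(locus_cols)
    else:
        while locus_cols and not locus_cols[-1].strip():
            # GenAlEx sheets often carry one trailing blank column
            if len(locus_cols) <= 2 * n_loci:
                break
            locus_cols = locus_cols[:-1]
        allele_cols = len(locus_cols)
    if allele_cols != 2 * n_loci:
        if allele_cols % 2 == 1:
            raise GenotypeFileError(
                f"odd number of allele columns ({allele_cols}) in row 3"
            )
        raise GenotypeFileError(
            f"row 3 has {allele_cols // 2} locus column pairs but row 1 "
            f"declares {n_loci} loci"
        )
    locus_names = [locus_cols[2 * i].strip() for i in range(n_loci)]
    if any(not n for n in locus_names):
        raise GenotypeFileError("row 3: empty locus name")
    xset = set(x_linked_loci)
    loci = [
        LocusMeta(n, X_LINKED if n in xset else AUTOSOMAL) for n in locus_names
    ]

    data = rows[3:]
    if len(data) != n_samples:
        raise GenotypeFileError(
            f"count mismatch: declared {n_samples} samples, found {len(data)} data rows"
        )
    individuals: list[str] = []
    populations: list[str] = []
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    for r, row in enumerate(data):
        rowno = r + 4
        cells = row if strict else [c for c in row]
        if len(cells) < 2 + 2 * n_loci:
            raise GenotypeFileError(
                f"row {rowno}: expected {2 + 2 * n_loci} cells, found {len(cells)}"
            )
        extra = cells[2 + 2 * n_loci :]
        if strict and any(c.strip() for c in extra):
            raise GenotypeFileError(f"row {rowno}: unexpected trailing cells")
        individuals.append(cells[0].strip())
        populations.append(cells[1].strip())
        for l in range(n_loci):
            for a in range(2):
                tok = cells[2 + 2 * l + a].strip()
                calls[r, l, a] = _parse_int(tok, f"row {rowno}, locus {locus_names[l]}") if tok else MISSING

    table = GenotypeTable(individuals, populations, loci, calls)
    found_sizes = table.population_sizes()
    if len(found_sizes) != n_pops:
        raise GenotypeFileError(
            f"count mismatch: declared {n_pops} populations, found "
            f"{len(found_sizes)} ({sorted(found_sizes)})"
        )
    if declared_sizes != list(found_sizes.values()):
        raise GenotypeFileError(
            f"count mismatch: declared population sizes {declared_sizes}, "
            f"found {list(found_sizes.values())}"
        )
    problems = validate(table)
    if problems:
        raise GenotypeFileError("; ".join(problems))
    return table


def write_genalex(table: GenotypeTable, path: str | Path, title: str = "strpop export") -> None:
    """Write ``table`` in the GenAlEx codominant CSV dialect (round-trips)."""
    if not table.loci:
        raise GenotypeFileError("cannot write a table with no loci")
    problems = validate(table)
    if problems:
        raise GenotypeFileError("refusing to write invalid table: " + "; ".join(problems))
    labels = table.population_labels()
    sizes = table.population_sizes()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [table.n_loci, table.n_individuals, len(labels)] + [sizes[p] for p in labels]
        )
        w.writerow([title, "", ""] + labels)
        header = ["Ind", "Pop"]
        for m in table.loci:
            header += [m.name, ""]
        w.writerow(header)
        for i, (ind, pop) in enumerate(zip(table.individuals, table.populations)):
            row: list[object] = [ind, pop]
            for l in range(table.n_loci):
                row += [int(table.calls[i, l, 0]), int(table.calls[i, l, 1])]
            w.writerow(row)


# ---------------------------------------------------------------------------
# canonical long CSV

LONG_COLUMNS = ("individual", "population", "locus", "allele1", "allele2")


def read_long(path: str | Path, x_linked_loci: Iterable[str] = ("LEX3",)) -> GenotypeTable:
    """Read the canonical long-format CSV (one row per individual x locus)."""
    path = Path(path)
    if not path.exists():
        raise GenotypeFileError(f"no such file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames[:5]) != LONG_COLUMNS:
            raise GenotypeFileError(
                f"long CSV must start with columns {','.join(LONG_COLUMNS)}"
            )
        records = list(reader)
    individuals: list[str] = []
    populations: dict[str, str] = {}
    locus_names: list[str] = []
    cells: dict[tuple[str, str], tuple[int, int]] = {}
    for rec in records:
        ind = rec["individual"].strip()
        if ind not in populations:
            individuals.append(ind)
            populations[ind] = rec["population"].strip()
        elif populations[ind] != rec["population"].strip():
            raise GenotypeFileError(
                f"individual {ind!r} appears with two population labels"
            )
        loc = rec["locus"].strip()
        if loc not in locus_names:
            locus_names.append(loc)
        key = (ind, loc)
        if key in cells:
            raise GenotypeFileError(f"duplicate row for {ind!r} at {loc!r}")
        cells[key] = (
            _parse_int(rec["allele1"], f"{ind}/{loc} allele1"),
            _parse_int(rec["allele2"], f"{ind}/{loc} allele2"),
        )
    xset = set(x_linked_loci)
    loci = [LocusMeta(n, X_LINKED if n in xset else AUTOSOMAL) for n in locus_names]
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    for (ind, loc), (a1, a2) in cells.items():
        calls[individuals.index(ind), locus_names.index(loc)] = (a1, a2)
    table = GenotypeTable(individuals, [populations[i] for i in individuals], loci, calls)
    problems = validate(table)
    if problems:
        raise GenotypeFileError("; ".join(problems))
    return table


def write_long(table: GenotypeTable, path: str | Path) -> None:
    """Write ``table`` as the canonical long-format CSV."""
    if not table.loci:
        raise GenotypeFileError("cannot write a table with no loci")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LONG_COLUMNS)
        for i, (ind, pop) in enumerate(zip(table.individuals, table.populations)):
            for l, meta in enumerate(table.loci):
                w.writerow(
                    [ind, pop, meta.name, int(table.calls[i, l, 0]), int(table.calls[i, l, 1])]
                )
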