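"""Data model and I/O for mixed-ploidy multilocus SSR genotypes.

An SSR (microsatellite) genotype is recorded per accession and locus as the
*set* of distinct allele fragment sizes observed (in base pairs).  Dosage is
unknown: a diploid scored with a single size is taken to be homozygous, and a
polyploid may show up to four distinct sizes.  Missing data is an empty set.

Three formats are supported:

* a tidy genotype CSV (one row per accession x locus, semicolon-separated
  allele sizes) — the package's native dialect;
* a STRUCTURE-style whitespace table (one row per allele-copy slot,
  ``-9`` for missing) for interoperability with external admixture tools;
* a 0/1 presence/absence matrix over all (locus, allele) columns, the input
  to distance-based analyses that must handle diploids and polyploids
  together.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCall",
    "AccessionRecord",
    "GenotypeTable",
    "BinaryMatrix",
    "read_genotypes",
    "write_genotypes",
    "encode_binary",
    "write_structure_format",
    "load_collection_metadata",
    "STUDY_LOCI",
]

#: The 19-locus SSR panel used for the apple collection layout, with the
#: apple linkage group each marker maps to.
STUDY_LOCI: dict[str, int] = {
    "CH05c06": 16, "CH-Vf1": 1, "Hi07h02": 17, "CH03d12": 6, "CH05e03": 2,
    "Hi04e04": 16, "CH02b03b": 10, "CH01f03b": 9, "CH02c09": 15,
    "Hi22f12": 5, "CH01g12": 12, "AU223657": 3, "CH01h02": 9, "CH01h01": 17,
    "CH04a12": 11, "Hi03a10": 7, "CH04c07": 14, "CH01c06": 8, "CH02g01": 13,
}

VALID_STATUS = ("LV", "CV", "UA")
MAX_ALLELES_PER_CALL = 4


class GenotypeError(ValueError):
    """Raised for malformed or invariant-violating genotype data."""


@dataclass(frozen=True)
class AlleleCall:
    """Distinct allele sizes observed at one locus for one accession.

    ``sizes`` is an unordered set of 0–4 distinct positive integers;
    the empty set means the call is missing.
    """

    locus_id: str
    sizes: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.sizes) > MAX_ALLELES_PER_CALL:
            raise GenotypeError(
                f"{self.locus_id}: {len(self.sizes)} alleles in one call "
                f"(max {MAX_ALLELES_PER_CALL})"
            )
        for s in self.sizes:
            if not isinstance(s, (int, np.integer)) or s <= 0:
                raise GenotypeError(
                    f"{self.locus_id}: allele sizes must be positive "
                    f"integers, got {s!r}"
                )

    @property
    def is_missing(self) -> bool:
        return len(self.sizes) == 0

    def sorted_sizes(self) -> tuple[int, ...]:
        return tuple(sorted(self.sizes))


@dataclass(frozen=True)
class AccessionRecord:
    """Identity and curation metadata for one accession."""

    accession_id: str
    name: str = ""
    collection_code: str = ""
    status: str = "UA"
    declared_ploidy: str | None = None  # "D", "P" or unknown

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUS:
            raise GenotypeError(
                f"accession {self.accession_id}: status {self.status!r} "
                f"not one of {VALID_STATUS}"
            )
        if self.declared_ploidy not in (None, "D", "P"):
            raise GenotypeError(
                f"accession {self.accession_id}: ploidy "
                f"{self.declared_ploidy!r} not D/P"
            )


class GenotypeTable:
    """Accession x locus matrix of unordered distinct-allele-size sets."""

    def __init__(
        self,
        accessions: Iterable[AccessionRecord],
        loci: Iterable[str],
        calls: Mapping[tuple[str, str], AlleleCall],
    ) -> None:
        self.accessions: list[AccessionRecord] = list(accessions)
        self.loci: list[str] = list(loci)
        ids = [a.accession_id for a in self.accessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeError(f"duplicate accession ids: {dupes}")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeError("duplicate locus ids")
        self._by_id = {a.accession_id: a for a in self.accessions}
        self.calls: dict[tuple[str, str], AlleleCall] = {}
        for acc in ids:
            for locus in self.loci:
                call = calls.get((acc, locus))
                if call is None:
                    call = AlleleCall(locus)
                self.calls[(acc, locus)] = call
        extra = set(calls) - set(self.calls)
        if extra:
            raise GenotypeError(f"calls reference unknown accession/locus: "
                                f"{sorted(extra)[:3]}")

    # -- basic accessors ---------------------------------------------------
    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def record(self, accession_id: str) -> AccessionRecord:
        return self._by_id[accession_id]

    def call(self, accession_id: str, locus: str) -> AlleleCall:
        return self.calls[(accession_id, locus)]

    def profile(self, accession_id: str) -> tuple[tuple[int, ...], ...]:
        """Full multilocus profile as sorted tuples in locus order."""
        return tuple(
            self.calls[(accession_id, l)].sorted_sizes() for l in self.loci
        )

    def alleles_at(self, locus: str) -> list[int]:
        """Sorted distinct allele sizes observed anywhere at ``locus``."""
        seen: set[int] = set()
        for acc in self.accession_ids:
            seen |= self.calls[(acc, locus)].sizes
        return sorted(seen)

    def subset(self, accession_ids: Iterable[str]) -> "GenotypeTable":
        keep = set(accession_ids)
        accs = [a for a in self.accessions if a.accession_id in keep]
        calls = {
            (a.accession_id, l): self.calls[(a.accession_id, l)]
            for a in accs for l in self.loci
        }
        return GenotypeTable(accs, self.loci, calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and self.loci == other.loci
            and self.calls == other.calls
        )


@dataclass
class BinaryMatrix:
    """0/1 presence/absence encoding of a genotype table.

    Columns are (locus, allele size) pairs in locus order then ascending
    size.  ``missing_mask[i, j]`` is True where row i's accession had a
    missing call at the locus column j belongs to.
    """

    rows: list[str]
    columns: list[tuple[str, int]]
    values: np.ndarray
    missing_mask: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{l}_{a}" for l, a in self.columns]
        return pd.DataFrame(self.values, index=self.rows, columns=cols)


# ---------------------------------------------------------------------------
# tidy CSV dialect

CSV_HEADER = ["accession_id", "name", "collection", "status", "locus",
              "alleles"]


def _parse_alleles(text: str, locus: str, line_no: int) -> AlleleCall:
    text = text.strip()
    if not text:
        return AlleleCall(locus)
    sizes = []
    for tok in text.split(";"):
        tok = tok.strip()
        try:
            sizes.append(int(tok))
        except ValueError:
            raise GenotypeError(
                f"line {line_no}: allele {tok!r} is not an integer"
            ) from None
    if len(set(sizes)) != len(sizes):
        raise GenotypeError(
            f"line {line_no}: non-distinct allele sizes {sizes} at {locus}"
        )
    return AlleleCall(locus, frozenset(sizes))


def read_genotypes(path, dialect: str = "tidy_csv") -> GenotypeTable:
    """Read a genotype table from the tidy CSV dialect.

    Header: ``accession_id,name,collection,status,locus,alleles``; alleles
    semicolon-separated; empty alleles field = missing; '#' comment lines
    skipped.  Duplicate (accession, locus) rows are rejected.
    """
    if dialect != "tidy_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    records: dict[str, AccessionRecord] = {}
    loci: list[str] = []
    calls: dict[tuple[str, str], AlleleCall] = {}
    ploidy: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        header = None
        for line_no, raw in enumerate(fh, start=1):
            if raw.startswith("#!ploidy"):
                # structured comment: "#!ploidy acc=P acc2=D ..."
                for tok in raw.split()[1:]:
                    acc, _, pl = tok.partition("=")
                    ploidy[acc] = pl
                continue
            if raw.lstrip().startswith("#") or not raw.strip():
                continue
            row = next(csv.reader([raw]))
            if header is None:
                if [c.strip() for c in row] != CSV_HEADER:
                    raise GenotypeError(
                        f"line {line_no}: bad header {row}; expected "
                        f"{CSV_HEADER}"
                    )
                header = row
                continue
            if len(row) != len(CSV_HEADER):
                raise GenotypeError(
                    f"line {line_no}: expected {len(CSV_HEADER)} fields, "
                    f"got {len(row)}"
                )
            acc_id, name, coll, status, locus, alleles = (
                c.strip() for c in row
            )
            rec = AccessionRecord(acc_id, name, coll, status,
                                  ploidy.get(acc_id))
            prev = records.get(acc_id)
            if prev is not None and prev != rec:
                raise GenotypeError(
                    f"line {line_no}: inconsistent metadata for accession "
                    f"{acc_id}"
                )
            records.setdefault(acc_id, rec)
            if locus not in loci:
                loci.append(locus)
            key = (acc_id, locus)
            if key in calls:
                raise GenotypeError(
                    f"line {line_no}: duplicate row for {key}"
                )
            calls[key] = _parse_alleles(alleles, locus, line_no)
    if not records:
        raise GenotypeError(f"{path}: no data rows")
    return GenotypeTable(records.values(), loci, calls)


def write_genotypes(table: GenotypeTable, path) -> None:
    """Write ``table`` in the tidy CSV dialect (inverse of read_genotypes)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        declared = [
            f"{a.accession_id}={a.declared_ploidy}"
            for a in table.accessions if a.declared_ploidy
        ]
        if declared:
            # declared ploidy travels in a structured comment so the file
            # stays within the 6-column dialect
            fh.write("#!ploidy " + " ".join(declared) + "\n")
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for acc in table.accessions:
            for locus in table.loci:
                call = table.calls[(acc.accession_id, locus)]
                w.writerow([
                    acc.accession_id, acc.name, acc.collection_code,
                    acc.status, locus,
                    ";".join(str(s) for s in call.sorted_sizes()),
                ])


# ---------------------------------------------------------------------------
# binary presence/absence encoding

def encode_binary(table: GenotypeTable) -> BinaryMatrix:
    """Convert allele presence to a 0/1 matrix over (locus, allele) columns."""
    if table.n_accessions == 0 or table.n_loci == 0:
        raise GenotypeError("cannot encode an empty table")
    columns: list[tuple[str, int]] = []
    for locus in table.loci:
        columns.extend((locus, a) for a in table.alleles_at(locus))
    col_index = {c: j for j, c in enumerate(columns)}
    n, m = table.n_accessions, len(columns)
    values = np.zeros((n, m), dtype=np.int8)
    missing = np.zeros((n, m), dtype=bool)
    for i, acc in enumerate(table.accession_ids):
        for locus in table.loci:
            call = table.calls[(acc, locus)]
            if call.is_missing:
                for a in table.alleles_at(locus):
                    missing[i, col_index[(locus, a)]] = True
            else:
                for a in call.sizes:
                    values[i, col_index[(locus, a)]] = 1
    return BinaryMatrix(list(table.accession_ids), columns, values, missing)


# ---------------------------------------------------------------------------
# STRUCTURE-format export

def write_structure_format(table: GenotypeTable, path,
                           ploidy: Mapping[str, int] | None = None) -> None:
    """Write a STRUCTURE-style file: one row per allele-copy slot.

    Diploids get 2 rows; an accession with ploidy k (from ``ploidy`` or a
    declared 'P' -> 3) gets k rows.  Within a locus, observed sizes fill
    slots in ascending order; a diploid singleton is written twice
    (homozygote); leftover slots beyond the observed distinct alleles repeat
    the smallest observed size; missing calls are ``-9`` in every slot.
    """
    ploidy = dict(ploidy or {})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(table.loci) + "\n")
        for acc in table.accessions:
            k = ploidy.get(
                acc.accession_id, 3 if acc.declared_ploidy == "P" else 2
            )
            slots: list[list[int]] = [[] for _ in range(k)]
            for locus in table.loci:
                sizes = table.calls[(acc.accession_id, locus)].sorted_sizes()
                for slot in range(k):
                    if not sizes:
                        slots[slot].append(-9)
                    elif slot < len(sizes):
                        slots[slot].append(sizes[slot])
                    elif len(sizes) == 1 or k == 2:
                        slots[slot].append(sizes[0])
                    else:
                        slots[slot].append(sizes[0])
            for slot in range(k):
                fh.write(
                    acc.accession_id + "\t"
                    + "\t".join(str(v) for v in slots[slot]) + "\n"
                )


# ---------------------------------------------------------------------------
# packaged study metadata

def load_collection_metadata() -> pd.DataFrame:
    """Load the packaged 175-accession apple collection metadata table.

    Columns: accession_id, name, collection, status (LV local variety /
    CV commercial variety / UA unknown accession), ploidy (D/P).
    """
    ref = resources.files("ssrkit.data") / "apple_collection_metadata.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, dtype={"accession_id": str})
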