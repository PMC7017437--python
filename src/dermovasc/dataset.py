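"""Specimen tables for the dermal-armour porosity datasets.

Two datasets are packaged with the library, one plate (cross-section) per
row: 31 testudinatan shell sections and 32 pseudosuchian osteoderm
sections. The measured trait is the porosity of the section — the
fraction of the sectional area occupied by vascular cavities — and each
plate carries a lifestyle category: ``terrestrial`` / ``freshwater`` /
``marine`` for the turtle total group, ``terrestrial`` / ``semi-aquatic``
for the crocodylian-line archosaurs (freshwater and coastal ambush
predators are pooled). *Yarasuchus deccanensis* sits in the pseudosuchian
table as a near-outgroup (clade ``Avemetatarsalia-outgroup``) and can be
excluded with :meth:`SpecimenTable.drop_outgroup`.

Tables are plain CSV with a fixed header; plates of the same species get
suffixed ``specimen_id`` values and are bound to a shared tree tip through
:func:`conspecific_groups`.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable

import pandas as pd

__all__ = [
    "SpecimenRecord",
    "SpecimenTable",
    "load_specimen_table",
    "load_testudinata",
    "load_pseudosuchia",
    "subset_by_lifestyle",
    "conspecific_groups",
    "taxon_slug",
    "LIFESTYLES",
    "COLUMNS",
]

COLUMNS = [
    "specimen_id",
    "taxon",
    "clade",
    "porosity",
    "lifestyle",
    "region",
    "ornamented",
    "age",
    "collection_number",
]

#: Lifestyle vocabulary per dataset label.
LIFESTYLES = {
    "testudinata": ("terrestrial", "freshwater", "marine"),
    "pseudosuchia": ("terrestrial", "semi-aquatic"),
}

CLADES = {"Testudinata", "Pseudosuchia", "Avemetatarsalia-outgroup"}

_BOOL = {"yes": True, "no": False, "true": True, "false": False}


class DatasetError(ValueError):
    """Malformed or invalid specimen-table input."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One dermal-plate cross-section."""

    specimen_id: str
    taxon: str
    clade: str
    porosity: float
    lifestyle: str
    region: str
    ornamented: bool
    age: str
    collection_number: str


@dataclass(frozen=True)
class SpecimenTable:
    records: tuple[SpecimenRecord, ...]
    dataset_label: str

    def __post_init__(self) -> None:
        if self.dataset_label not in LIFESTYLES:
            raise DatasetError(f"unknown dataset label {self.dataset_label!r}")
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate specimen_ids: {dupes}")
        vocab = LIFESTYLES[self.dataset_label]
        for r in self.records:
            if r.lifestyle not in vocab:
                raise DatasetError(
                    f"record {r.specimen_id!r}: lifestyle {r.lifestyle!r} not in "
                    f"{self.dataset_label} vocabulary {vocab}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lifestyles(self) -> tuple[str, ...]:
        return LIFESTYLES[self.dataset_label]

    def porosities(self) -> list[float]:
        return [r.porosity for r in self.records]

    def drop_outgroup(self) -> "SpecimenTable":
        """Exclude near-outgroup plates (clade ``Avemetatarsalia-outgroup``)."""
        kept = tuple(r for r in self.records if r.clade != "Avemetatarsalia-outgroup")
        return SpecimenTable(kept, self.dataset_label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=COLUMNS)

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        df["ornamented"] = df["ornamented"].map({True: "yes", False: "no"})
        df.to_csv(path, index=False)


def _parse_record(row: dict, rownum: int, vocab: tuple[str, ...]) -> SpecimenRecord:
    try:
        porosity = float(row["porosity"])
    except ValueError as exc:
        raise DatasetError(f"row {rownum}: unparseable porosity {row['porosity']!r}") from exc
    if not 0.0 <= porosity <= 1.0:
        raise DatasetError(f"row {rownum}: porosity {porosity} outside [0, 1]")
    lifestyle = row["lifestyle"].strip()
    if lifestyle not in vocab:
        raise DatasetError(f"row {rownum}: unknown lifestyle {lifestyle!r} (allowed: {vocab})")
    clade = row["clade"].strip()
    if clade not in CLADES:
        raise DatasetError(f"row {rownum}: unknown clade {clade!r}")
    orn = row["ornamented"].strip().lower()
    if orn not in _BOOL:
        raise DatasetError(f"row {rownum}: ornamented must be yes/no, got {row['ornamented']!r}")
    return SpecimenRecord(
        specimen_id=row["specimen_id"].strip(),
        taxon=row["taxon"].strip(),
        clade=clade,
        porosity=porosity,
        lifestyle=lifestyle,
        region=row["region"].strip(),
        ornamented=_BOOL[orn],
        age=row["age"].strip(),
        collection_number=row["collection_number"].strip(),
    )


def _load_from_text(text: str, dataset_label: str) -> SpecimenTable:
    if dataset_label not in LIFESTYLES:
        raise DatasetError(f"unknown dataset label {dataset_label!r}")
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != COLUMNS:
        raise DatasetError(
            f"header mismatch: expected {COLUMNS}, got {reader.fieldnames}"
        )
    vocab = LIFESTYLES[dataset_label]
    records = []
    for rownum, row in enumerate(reader, start=2):  # 1-based, after header
        if any(v is None for v in row.values()) or None in row:
            raise DatasetError(f"row {rownum}: wrong number of fields")
        records.append(_parse_record(row, rownum, vocab))
    return SpecimenTable(tuple(records), dataset_label)


def load_specimen_table(path, dataset_label: str) -> SpecimenTable:
    """Load and validate a specimen table from a CSV file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _load_from_text(fh.read(), dataset_label)


def _packaged(name: str) -> str:
    return resources.files("dermovasc.data").joinpath(name).read_text(encoding="utf-8")


def load_testudinata() -> SpecimenTable:
    """The packaged 31-section turtle-shell dataset."""
    return _load_from_text(_packaged("table1a.csv"), "testudinata")


def load_pseudosuchia() -> SpecimenTable:
    """The packaged 32-section pseudosuchian osteoderm dataset."""
    return _load_from_text(_packaged("table1b.csv"), "pseudosuchia")


def subset_by_lifestyle(table: SpecimenTable, lifestyle: str) -> SpecimenTable:
    """Records with the given lifestyle label, in table order."""
    if lifestyle not in table.lifestyles:
        raise DatasetError(
            f"unknown lifestyle {lifestyle!r} for dataset {table.dataset_label!r}"
        )
    kept = tuple(r for r in table.records if r.lifestyle == lifestyle)
    return SpecimenTable(kept, table.dataset_label)


def taxon_slug(taxon: str) -> str:
    """Canonical tree-tip label for a taxon name."""
    s = taxon.lower().replace("'", "")
    s = re.sub(r"[^a-z0-9]+", "_", s)
    return s.strip("_")


def conspecific_groups(table: SpecimenTable | Iterable[SpecimenRecord]) -> dict[str, list[str]]:
    """Map each taxon's tree-tip slug to its specimen ids (table order).

    Multi-member groups are the conspecific plates that the 1-Myr split
    rule attaches below a hypothetical common ancestor.
    """
    groups: dict[str, list[str]] = {}
    for r in table:
        groups.setdefault(taxon_slug(r.taxon), []).append(r.specimen_id)
    return groups
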