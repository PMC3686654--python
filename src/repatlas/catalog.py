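"""The packaged REP class catalog.

Ships the 35 cross-strain REP consensus classes of the two studied bacterial
groups — PF1..PF22 for the Pseudomonas fluorescens species complex and
SM1..SM13 for stenotrophomonads — with their orthogroup assignment and the
accession of the cognate RAYT where one survives ("n.a." classes have no
associated RAYT gene anywhere in the respective strain set).

Catalog files are TSV with columns: label, orthogroup, rayt_accession,
rayt_strain, iupac.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .rep_discovery import (
    NotARepError,
    RepConsensus,
    classify_architecture,
    find_rep_structure,
)

_CATALOG_RESOURCE = "rep_catalog.tsv"


@dataclass
class CatalogEntry:
    consensus: RepConsensus
    rayt_accession: str | None
    rayt_strain: str | None

    @property
    def label(self) -> str:
        return self.consensus.label

    @property
    def orthogroup(self) -> str:
        return self.consensus.orthogroup


@dataclass
class Catalog:
    entries: list[CatalogEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def get(self, label: str) -> CatalogEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def consensi(self) -> list[RepConsensus]:
        return [e.consensus for e in self.entries]

    def group(self, prefix: str) -> list[CatalogEntry]:
        """Entries of one host group, e.g. prefix 'PF' or 'SM'."""
        return [e for e in self.entries if e.label.startswith(prefix)]

    def orthogroups(self, prefix: str) -> dict[str, list[str]]:
        """Orthogroup -> class labels for one host group; the ungrouped
        'NO' pool is excluded."""
        out: dict[str, list[str]] = {}
        for e in self.group(prefix):
            if e.orthogroup != "NO":
                out.setdefault(e.orthogroup, []).append(e.label)
        return out


def _build_entry(row: pd.Series) -> CatalogEntry:
    iupac = str(row["iupac"]).strip().upper()
    try:
        structure = find_rep_structure(iupac)
        architecture = classify_architecture(structure)
    except NotARepError:
        # e.g. PF20 carries no qualifying degenerate-complementary stem
        structure = None
        architecture = "other"
    accession = str(row["rayt_accession"]).strip()
    accession = None if accession in ("", "n.a.", "nan") else accession
    strain = str(row.get("rayt_strain", "") or "").strip() or None
    if strain == "nan":
        strain = None
    consensus = RepConsensus(
        label=str(row["label"]),
        iupac=iupac,
        structure=structure,
        architecture=architecture,
        orthogroup=str(row["orthogroup"]),
        cognate_rayt=accession,
    )
    return CatalogEntry(consensus=consensus, rayt_accession=accession, rayt_strain=strain)


def read_catalog(path: str | Path) -> Catalog:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"label", "orthogroup", "rayt_accession", "iupac"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return Catalog([_build_entry(row) for _, row in df.iterrows()])


def load_packaged_catalog() -> Catalog:
    ref = resources.files("repatlas").joinpath("data", _CATALOG_RESOURCE)
    with resources.as_file(ref) as p:
        return read_catalog(p)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    rows = [
        {
            "label": e.label,
            "orthogroup": e.orthogroup,
            "rayt_accession": e.rayt_accession or "n.a.",
            "rayt_strain": e.rayt_strain or "",
            "iupac": e.consensus.iupac,
            "architecture": e.consensus.architecture,
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
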