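"""Sequence and metadata I/O plus the packaged primer/population fixtures.

The central container is :class:`BarcodeLibrary`: an ordered collection of
ITS2-like sequences, each labelled with the species, geographical population
and country it was sampled from.  Metadata travels in a TSV sidecar keyed by
record id; as a fallback, FASTA descriptions of the form
``<species>_<population>-<country>`` (the style used for psocid strain names,
e.g. ``L. entomophila_BJ-China``) are parsed directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

IUPAC_DNA = "ACGTRYSWKMBDHVN"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)

_HEADER_PATTERN = re.compile(r"^(?P<species>.+?)_(?P<population>[^_]+?)-(?P<country>[^-]+)$")


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


def _validate_seq(seq: str, record_id: str) -> str:
    """Uppercase, map U->T and reject anything outside the IUPAC DNA alphabet."""
    seq = seq.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_DNA:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {ch!r} at position {pos}"
            )
    return seq


@dataclass
class SequenceRecord:
    """One ITS2-like sequence with its provenance labels."""

    id: str
    seq: str
    species: str = "unknown"
    population: str = ""
    country: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = _validate_seq(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class BarcodeLibrary:
    """Ordered collection of records with a species index."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    @property
    def species_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for rec in self.records:
            index.setdefault(rec.species, []).append(rec.id)
        return index

    @property
    def species(self) -> list[str]:
        return list(self.species_index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def records_of(self, species: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.species == species]

    def subset(self, record_ids: Iterable[str]) -> "BarcodeLibrary":
        wanted = set(record_ids)
        return BarcodeLibrary([r for r in self.records if r.id in wanted])


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    seq = seq.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_DNA + "-":
            raise ValueError(f"non-IUPAC character {ch!r} at position {pos}")
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_fasta_text(text: str, path: str) -> list[tuple[str, str, str]]:
    """Parse FASTA into (id, description, seq) triples with line-aware errors."""
    entries: list[tuple[str, str, list[str]]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            desc = line[1:].strip()
            rec_id = desc.split()[0] if desc else ""
            if not rec_id:
                raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
            entries.append((rec_id, desc, []))
        else:
            if not entries:
                raise FastaParseError(
                    f"{path}: sequence data before first '>' header at line {lineno}"
                )
            entries[-1][2].append(line)
    return [(rid, desc, "".join(chunks)) for rid, desc, chunks in entries]


def read_fasta(path: str | Path, metadata_path: str | Path | None = None) -> BarcodeLibrary:
    """Read a FASTA file (and optional metadata TSV) into a BarcodeLibrary.

    The metadata TSV must have columns ``id, species, population, country``.
    Records without metadata fall back to parsing the FASTA description as
    ``<species>_<population>-<country>``; otherwise species is "unknown".
    """
    path = Path(path)
    text = path.read_text()
    meta: dict[str, dict[str, str]] = {}
    if metadata_path is not None:
        table = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        required = {"id", "species", "population", "country"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"metadata file missing columns: {sorted(missing)}")
        meta = {row["id"]: row for row in table.to_dict("records")}

    records = []
    for rec_id, desc, seq in _parse_fasta_text(text, str(path)):
        if rec_id in meta:
            m = meta[rec_id]
            rec = SequenceRecord(rec_id, seq, m["species"] or "unknown",
                                 m["population"], m["country"])
        else:
            match = _HEADER_PATTERN.match(desc)
            if match:
                rec = SequenceRecord(rec_id, seq, match["species"],
                                     match["population"], match["country"])
            else:
                rec = SequenceRecord(rec_id, seq)
        records.append(rec)
    return BarcodeLibrary(records)


def write_fasta(lib: BarcodeLibrary | Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as canonical 60-column wrapped FASTA."""
    records = lib.records if isinstance(lib, BarcodeLibrary) else list(lib)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_metadata(lib: BarcodeLibrary, path: str | Path) -> None:
    pd.DataFrame(
        [{"id": r.id, "species": r.species, "population": r.population,
          "country": r.country} for r in lib]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures: the published primer panel and population survey.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerFixtureRow:
    species: str
    primer_name: str
    role: str              # "F" or "R"
    seq: str
    printed_length: int
    printed_tm: float | None   # None where the published value is truncated
    target_fragment: int
    note: str = ""


@dataclass(frozen=True)
class PopulationFixtureRow:
    species: str
    population_code: str
    location: str
    country: str


def _data_path(name: str):
    return resources.files("psocid_id.data").joinpath(name)


def load_table1_fixture() -> list[PrimerFixtureRow]:
    """The published panel of 10 species-specific primer pairs (20 oligos)."""
    with resources.as_file(_data_path("table1_primers.tsv")) as p:
        table = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    rows = []
    for r in table.to_dict("records"):
        rows.append(PrimerFixtureRow(
            species=r["species"],
            primer_name=r["primer_name"],
            role=r["role"],
            seq=r["seq"],
            printed_length=int(r["printed_length"]),
            printed_tm=float(r["printed_tm"]) if r["printed_tm"] else None,
            target_fragment=int(r["target_fragment"]),
            note=r.get("note", ""),
        ))
    return rows


def load_table2_fixture() -> list[PopulationFixtureRow]:
    """The 35 geographical populations (10 species, 5 countries)."""
    with resources.as_file(_data_path("table2_populations.tsv")) as p:
        table = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    return [PopulationFixtureRow(r["species"], r["population_code"],
                                 r["location"], r["country"])
            for r in table.to_dict("records")]


def table1_pairs() -> dict[str, tuple[PrimerFixtureRow, PrimerFixtureRow]]:
    """Published primers grouped as species -> (forward, reverse)."""
    rows = load_table1_fixture()
    pairs: dict[str, dict[str, PrimerFixtureRow]] = {}
    for row in rows:
        pairs.setdefault(row.species, {})[row.role] = row
    return {sp: (d["F"], d["R"]) for sp, d in pairs.items()}
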