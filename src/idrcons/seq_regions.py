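"""Protein sequences and region annotations.

Canoe/Afadin orthologs are handled as plain amino-acid records plus a table of
named regions (folded domains such as RA1/RA2, FHA, DIL, PDZ; the C-terminal
intrinsically disordered region, IDR; and the F-actin-binding tail, FAB).
Coordinates are 1-based and inclusive on both ends throughout, matching the
way residues are numbered in the literature (e.g. "aas 1500-1665").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard residues plus X for unknown.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")


class RegionClass(str, enum.Enum):
    """Structural class of an annotated region."""

    DOMAIN = "domain"
    IDR = "idr"
    FAB = "fab"


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with an optional species tag."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"illegal residue {ch!r} at position {pos} in {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named interval on a protein, classified domain/idr/fab.

    ``start`` and ``end`` are 1-based inclusive residue indices.
    """

    name: str
    start: int
    end: int
    klass: RegionClass

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"region {self.name!r}: need 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """Ordered, non-overlapping regions on one protein."""

    protein_id: str
    regions: list[RegionAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: r.start)
        names = [r.name for r in self.regions]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate region name {dup!r} on {self.protein_id!r}")
        for prev, cur in zip(self.regions, self.regions[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"regions {prev.name!r} and {cur.name!r} overlap on "
                    f"{self.protein_id!r}"
                )

    def get(self, name: str) -> RegionAnnotation | None:
        for r in self.regions:
            if r.name == name:
                return r
        return None

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA into validated records.

    Whitespace inside sequence lines is stripped and letters uppercased.
    Raises on an empty file, a duplicate id, or an illegal residue character.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(id=rec.id, sequence=seq,
                                     species=rec.description[len(rec.id):].strip()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records to FASTA; round-trips through :func:`read_fasta`."""
    out = []
    for r in records:
        desc = r.species if r.species else ""
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


REGION_TABLE_COLUMNS = ["protein_id", "name", "start", "end", "class"]


def load_region_table(path: str | Path) -> dict[str, RegionSet]:
    """Load a TSV of region annotations keyed by protein id.

    Expected header: ``protein_id  name  start  end  class`` with class in
    {domain, idr, fab}. Overlapping or inverted intervals are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REGION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region table missing column(s) {missing}")
    out: dict[str, RegionSet] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        regions = [
            RegionAnnotation(
                name=row["name"],
                start=int(row["start"]),
                end=int(row["end"]),
                klass=RegionClass(row["class"]),
            )
            for _, row in grp.iterrows()
        ]
        out[pid] = RegionSet(protein_id=pid, regions=regions)
    return out


def write_region_table(region_sets: dict[str, RegionSet], path: str | Path) -> None:
    rows = [
        {"protein_id": rs.protein_id, "name": r.name, "start": r.start,
         "end": r.end, "class": r.klass.value}
        for rs in region_sets.values()
        for r in rs
    ]
    pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False)


def extract_region(record: ProteinRecord, region: RegionAnnotation) -> ProteinRecord:
    """Slice out a region subsequence; id is suffixed with the region name."""
    if region.end > len(record.sequence):
        raise ValueError(
            f"region {region.name!r} ({region.start}-{region.end}) exceeds "
            f"length {len(record.sequence)} of {record.id!r}"
        )
    sub = record.sequence[region.start - 1 : region.end]
    return ProteinRecord(id=f"{record.id}|{region.name}", sequence=sub,
                         species=record.species)
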