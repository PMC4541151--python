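"""Local reference gene database: parsing, validation, group labels.

The search stages run against a small, manually curated nucleotide database
of genes of interest (the motivating case is *copA*, the core determinant of
microbial copper resistance).  Records follow the ``gi_<number>_<Species_name>``
header convention; headers that do not match the convention are kept verbatim
as record ids with an empty ``gi`` field.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Group(str, Enum):
    """Functional family of a reference gene.

    Sequences annotated under one name in public databases can belong to two
    unrelated protein families: transmembrane P-type ATPase Cu(I) pumps and
    laccase-like multicopper oxidases.  Group labels drive downstream motif
    screening.
    """

    ATPASE = "ATPASE"
    MCO = "MCO"
    UNKNOWN = "UNKNOWN"


_HEADER_RE = re.compile(r"^gi_(\d+)_(.+)$")
_VALID_NT = frozenset("ACGTN")

#: minimum plausible gene length enforced when parsing a database file
MIN_REFERENCE_LEN = 60


@dataclass(frozen=True)
class ReferenceGene:
    record_id: str
    gi: str
    species: str
    sequence: str
    group: Group = Group.UNKNOWN

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def protein(self) -> str:
        """Translate the gene (bacterial code, first codon forced to M)."""
        nt = self.sequence[: len(self.sequence) - len(self.sequence) % 3]
        aa = str(Seq(nt).translate(table=11))
        if aa.endswith("*"):
            aa = aa[:-1]
        return ("M" + aa[1:]) if aa else aa


@dataclass
class ReferenceDB:
    genes: list[ReferenceGene]
    name: str = "refdb"
    source_path: str = ""
    _by_id: dict[str, ReferenceGene] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {g.record_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate record_ids in database")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, record_id: str) -> ReferenceGene:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    @property
    def total_length(self) -> int:
        """Sum of reference lengths; the E-value search-space ``n``."""
        return sum(len(g) for g in self.genes)


def _parse_header(record_id: str) -> tuple[str, str]:
    m = _HEADER_RE.match(record_id)
    if m:
        return m.group(1), m.group(2)
    return "", ""


def parse_reference_fasta(
    path: str | Path,
    default_group: Group = Group.UNKNOWN,
    min_len: int = MIN_REFERENCE_LEN,
) -> ReferenceDB:
    """Parse a nucleotide reference database from FASTA.

    Headers matching ``gi_<digits>_<rest>`` contribute a ``gi`` number and an
    underscore-joined species name; any other header is kept as the record id
    with ``gi`` and ``species`` empty.  Sequences are upper-cased and must be
    over {A, C, G, T, N}.
    """
    path = Path(path)
    genes: list[ReferenceGene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate header: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in _VALID_NT:
                raise ValueError(
                    f"non-IUPAC nucleotide character {ch!r} in record "
                    f"{rec.id} at position {pos + 1}"
                )
        if len(seq) < min_len:
            raise ValueError(
                f"record {rec.id} shorter than minimum reference length {min_len}"
            )
        gi, species = _parse_header(rec.id)
        genes.append(
            ReferenceGene(
                record_id=rec.id,
                gi=gi,
                species=species,
                sequence=seq,
                group=default_group,
            )
        )
    if not genes:
        raise ValueError("empty database")
    return ReferenceDB(genes=genes, name=path.stem, source_path=str(path))


def write_reference_fasta(db: ReferenceDB, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.record_id, description="") for g in db
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def assign_groups(db: ReferenceDB, labels: dict[str, Group]) -> ReferenceDB:
    """Return a copy of *db* with group labels applied.

    Every key of *labels* must name an existing record; unlabeled genes keep
    their current group.
    """
    for key in labels:
        if key not in db:
            raise KeyError(f"unknown record_id: {key}")
    genes = [
        replace(g, group=labels[g.record_id]) if g.record_id in labels else g
        for g in db
    ]
    return ReferenceDB(genes=genes, name=db.name, source_path=db.source_path)


def load_group_labels(path: str | Path) -> dict[str, Group]:
    """Read a two-column TSV (record_id, group) of group labels."""
    labels: dict[str, Group] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            record_id, group = row[0], row[1]
            labels[record_id] = Group(group.upper())
    return labels
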