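"""Alignment and species-map input/output.

The central container is :class:`Alignment`, a rectangular character matrix
over ``{A,C,G,T, IUPAC ambiguity, -, N}`` with ordered, unique taxon labels.
Column coordinates are 1-based inclusive in every user-facing report (the way
marker regions are cited in the plastome literature) and 0-based half-open
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    CoordinateError,
    FormatError,
    LabelError,
    TaxaMismatchError,
)

__all__ = [
    "Alignment",
    "Partition",
    "read_alignment",
    "write_alignment",
    "read_species_map",
    "write_species_map",
    "validate_species_map",
    "subset_by_taxa",
    "concatenate",
]

_NORMALIZE = str.maketrans({"u": "T", "U": "T"})


@dataclass(frozen=True)
class Partition:
    """A named 1-based inclusive column range within an alignment."""

    name: str
    start: int
    end: int


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: equal-length rows with unique labels."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    partitions: tuple[Partition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentShapeError("taxa and sequences differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise LabelError(f"duplicate taxon labels: {', '.join(dup)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        L = self.length
        for p in self.partitions:
            if not (1 <= p.start <= p.end <= L):
                raise CoordinateError(
                    f"partition {p.name!r} range ({p.start},{p.end}) outside [1,{L}]"
                )

    @property
    def length(self) -> int:
        """Number of columns L."""
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise LabelError(f"unknown taxon: {taxon!r}") from None

    def columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment of 1-based inclusive columns [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(
                f"columns ({start},{end}) outside [1,{self.length}]"
            )
        return Alignment(
            self.taxa, tuple(s[start - 1 : end] for s in self.sequences)
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment.

    Sequences are uppercased and U mapped to T; the description after the
    first whitespace is ignored for taxon identity.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) < 2:
        raise FormatError(f"alignment needs >=2 records, got {len(records)}")
    taxa = tuple(r.id for r in records)
    seqs = tuple(_normalize(str(r.seq)) for r in records)
    return Alignment(taxa, seqs)


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 80) -> None:
    """Write FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a TSV ``accession<TAB>species`` table (header required)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"empty species map: {path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            acc, species = parts
            if acc in mapping:
                raise LabelError(f"duplicate accession in species map: {acc!r}")
            mapping[acc] = species
    return mapping


def write_species_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tspecies\n")
        for acc, species in mapping.items():
            fh.write(f"{acc}\t{species}\n")


def validate_species_map(aln: Alignment, mapping: Mapping[str, str]) -> None:
    """Check every alignment taxon is mapped to a species exactly once."""
    missing = [t for t in aln.taxa if t not in mapping]
    if missing:
        raise LabelError(f"taxa missing from species map: {', '.join(missing)}")


def subset_by_taxa(aln: Alignment, keep: Iterable[str]) -> Alignment:
    """Row subset preserving row order and all columns.

    Invariant (constant) columns are retained: coordinates stay comparable
    with the full matrix.
    """
    keep_set = set(keep)
    unknown = keep_set - set(aln.taxa)
    if unknown:
        raise LabelError(f"unknown taxa: {', '.join(sorted(unknown))}")
    idx = [i for i, t in enumerate(aln.taxa) if t in keep_set]
    return Alignment(
        tuple(aln.taxa[i] for i in idx),
        tuple(aln.sequences[i] for i in idx),
        aln.partitions,
    )


def concatenate(
    alns: Sequence[Alignment], names: Sequence[str] | None = None
) -> Alignment:
    """Column-wise concatenation of alignments over identical taxon sets.

    Rows of later alignments are reordered to the first alignment's taxon
    order; partitions record each source's column range, 1-based inclusive.
    """
    if not alns:
        raise FormatError("concatenate needs >=1 alignment")
    first = alns[0]
    ref = set(first.taxa)
    for a in alns[1:]:
        if set(a.taxa) != ref:
            raise TaxaMismatchError(
                "taxon sets differ: "
                f"{sorted(ref ^ set(a.taxa))} not shared by all inputs"
            )
    if names is None:
        names = [f"part{i + 1}" for i in range(len(alns))]
    seqs = ["" for _ in first.taxa]
    partitions = []
    offset = 0
    for a, name in zip(alns, names):
        for row, taxon in enumerate(first.taxa):
            seqs[row] += a.sequence(taxon)
        partitions.append(Partition(name, offset + 1, offset + a.length))
        offset += a.length
    return Alignment(first.taxa, tuple(seqs), tuple(partitions))


def read_partitions(path: str | Path) -> tuple[Partition, ...]:
    """Read a TSV partition table ``name<TAB>start<TAB>end`` (header required)."""
    out = []
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            out.append(Partition(parts[0], int(parts[1]), int(parts[2])))
    return tuple(out)


def write_partitions(partitions: Iterable[Partition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for p in partitions:
            fh.write(f"{p.name}\t{p.start}\t{p.end}\n")
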