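"""Alignment IO and the complete-deletion trimming rule.

Alignments are consumed, not built: the input is aligned amino-acid FASTA
whose headers encode species, gene tag and (optionally) chromosome as
``species|gene|chrN``.  Before distance computation every column containing
a gap or missing datum ('X' or any non-standard letter) is removed —
complete deletion in the MEGA sense.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"


class AlignmentError(ValueError):
    pass


class EmptyAlignmentError(AlignmentError):
    """All columns were removed by trimming."""


@dataclass(frozen=True)
class AlignmentRecord:
    sequence_id: str
    species_id: str
    gene_tag: str
    chromosome: Optional[str]
    seq: str


@dataclass
class Alignment:
    records: list

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        ok = set(AMINO_ACIDS + GAP + MISSING)
        for r in self.records:
            bad = set(r.seq) - ok
            if bad:
                raise AlignmentError(f"{r.sequence_id}: invalid characters {sorted(bad)}")

    def __len__(self):
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def ids(self) -> list:
        return [r.sequence_id for r in self.records]

    def matrix(self) -> np.ndarray:
        """Rows as a (n, length) array of single-byte strings."""
        return np.array([list(r.seq) for r in self.records], dtype="U1")

    def take_columns(self, cols) -> "Alignment":
        m = self.matrix()[:, cols]
        recs = [
            AlignmentRecord(r.sequence_id, r.species_id, r.gene_tag, r.chromosome, "".join(row))
            for r, row in zip(self.records, m)
        ]
        return Alignment(recs)


def parse_header(header: str) -> tuple:
    """Split ``species|gene|chrN`` (chromosome part optional)."""
    parts = header.strip().split("|")
    if len(parts) < 2 or not parts[0] or not parts[1]:
        raise AlignmentError(f"unparseable header {header!r}; expected species|gene[|chrN]")
    chrom = None
    if len(parts) >= 3 and parts[2]:
        chrom = parts[2]
        if chrom.lower().startswith("chr"):
            chrom = chrom[3:]
    return parts[0], parts[1], chrom


def read_alignment(source, species: Optional[Iterable[str]] = None) -> Alignment:
    """Read an aligned FASTA into a validated :class:`Alignment`.

    ``source`` is FASTA text or a path.  When ``species`` is given, headers
    naming a species outside it are an error.
    """
    text = str(source)
    if not text.lstrip().startswith(">"):
        text = Path(source).read_text()
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        sp, gene, chrom = parse_header(rec.id)
        records.append(AlignmentRecord(rec.id, sp, gene, chrom, str(rec.seq).upper()))
    if species is not None:
        known = set(species)
        unknown = {r.species_id for r in records} - known
        if unknown:
            raise AlignmentError(f"unknown species in headers: {sorted(unknown)}")
    return Alignment(records)


def write_fasta(aln: Alignment, path=None, width: int = 70) -> str:
    chunks = []
    for r in aln.records:
        chunks.append(f">{r.sequence_id}")
        chunks.extend(r.seq[i : i + width] for i in range(0, len(r.seq), width))
    text = "\n".join(chunks) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def trim_complete_deletion(aln: Alignment) -> Alignment:
    """Keep exactly the columns where no row has a gap or missing datum.

    Idempotent; raises :class:`EmptyAlignmentError` if nothing survives.
    """
    m = aln.matrix()
    allowed = np.isin(m, list(AMINO_ACIDS))
    keep = allowed.all(axis=0)
    if not keep.any():
        raise EmptyAlignmentError("complete deletion removed every column")
    return aln.take_columns(np.nonzero(keep)[0])
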