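"""Sequence and alignment I/O with a codon-aware data model.

Reads and writes FASTA (via Biopython) and Newick (via :mod:`cladediv.phylo`),
and enforces the two alignment contracts the downstream analyses rely on:

* :class:`ProteinAlignment` — equal-length amino-acid rows, gap ``-``.
* :class:`CodonAlignment` — in-frame nucleotide rows whose codon triplets are
  either fully gapped (``---``) or fully ungapped, with no internal stop
  codons (the codon substitution model is defined on sense codons only).

Coordinates are 0-based, half-open throughout; for codon alignments region
boundaries must fall on codon multiples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._codons import STOP_CODONS

__all__ = [
    "SeqFormatError",
    "SequenceRecord",
    "ProteinAlignment",
    "CodonAlignment",
    "Region",
    "RegionMap",
    "read_fasta",
    "read_phylip",
    "write_fasta",
    "read_region_map",
    "translate",
    "extract_region",
    "excise_region",
    "read_newick",
    "write_newick",
]

AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY" "X*-")
NT_CHARS = frozenset("ACGT" "RYSWKMBDHVN" "-")
_NT_AMBIG = frozenset("RYSWKMBDHVN")


class SeqFormatError(ValueError):
    """Raised for malformed sequence files or alignment-contract violations."""


@dataclass
class SequenceRecord:
    """A named residue string (amino-acid or nucleotide, with ``-`` gaps)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("sequence record with empty identifier")
        if not self.seq:
            raise SeqFormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "nucleotide":
        seq = seq.replace("U", "T")
    return seq


def _check_alphabet(rec: SequenceRecord, alphabet: str) -> None:
    allowed = AA_CHARS if alphabet == "protein" else NT_CHARS
    for col, ch in enumerate(rec.seq):
        if ch not in allowed:
            raise SeqFormatError(
                f"record {rec.id!r}: character {ch!r} at column {col} is not "
                f"in the {alphabet} alphabet"
            )


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SeqFormatError(f"duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)


class _Alignment:
    """Shared behaviour of the two alignment flavours."""

    alphabet: str = ""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            raise SeqFormatError("alignment with no records")
        _check_unique_ids(self.records)
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise SeqFormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        for rec in self.records:
            _check_alphabet(rec, self.alphabet)

    @property
    def taxa(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __getitem__(self, taxon: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == taxon:
                return rec
        raise KeyError(taxon)

    def to_matrix(self) -> np.ndarray:
        """Rows x columns character matrix (dtype ``<U1``)."""
        return np.array([list(r.seq) for r in self.records])

    def reorder(self, taxa: Sequence[str]):
        if sorted(taxa) != sorted(self.taxa):
            raise SeqFormatError("reorder: taxon set does not match alignment")
        by_id = {r.id: r for r in self.records}
        return type(self)([by_id[t] for t in taxa])

    def __eq__(self, other) -> bool:
        return (
            type(self) is type(other)
            and [(r.id, r.seq) for r in self.records]
            == [(r.id, r.seq) for r in other.records]
        )


class ProteinAlignment(_Alignment):
    """Aligned amino-acid sequences."""

    alphabet = "protein"


class CodonAlignment(_Alignment):
    """In-frame aligned coding sequences.

    Parameters
    ----------
    records
        Nucleotide records; length must be a multiple of 3.
    permissive
        If True, internal stop codons are tolerated (translated as ``*``)
        instead of raising.
    """

    alphabet = "nucleotide"

    def __init__(self, records: Iterable[SequenceRecord], permissive: bool = False):
        super().__init__(records)
        self.permissive = permissive
        if self.length % 3:
            raise SeqFormatError(
                f"codon alignment length {self.length} is not a multiple of 3"
            )
        for rec in self.records:
            for k in range(self.n_codons):
                codon = rec.seq[3 * k : 3 * k + 3]
                n_gap = codon.count("-")
                if n_gap not in (0, 3):
                    raise SeqFormatError(
                        f"record {rec.id!r}: partially gapped codon {codon!r} "
                        f"at codon {k} — codons must be fully gapped or fully "
                        "ungapped"
                    )
                if (
                    not permissive
                    and codon in STOP_CODONS
                    and k != self.n_codons - 1
                ):
                    raise SeqFormatError(
                        f"record {rec.id!r}: internal stop codon {codon!r} at "
                        f"codon {k}"
                    )

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, taxon: str, k: int) -> str:
        return self[taxon].seq[3 * k : 3 * k + 3]


@dataclass(frozen=True)
class Region:
    """Named half-open column interval ``[start, end)`` in alignment coords."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise SeqFormatError(
                f"region {self.name!r}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionMap:
    """Ordered, non-overlapping regions of an alignment."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise SeqFormatError(f"regions {a.name!r} and {b.name!r} overlap")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise SeqFormatError("duplicate region names")

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]


def read_phylip(path, alphabet: str) -> list[SequenceRecord]:
    """Read a PHYLIP alignment (strict or relaxed names) into records,
    normalised the same way as :func:`read_fasta`."""
    from Bio import AlignIO

    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    try:
        msa = AlignIO.read(str(path), "phylip-relaxed")
    except ValueError:
        try:
            msa = AlignIO.read(str(path), "phylip")
        except ValueError as exc:
            raise SeqFormatError(f"cannot parse PHYLIP file {path}: {exc}") from exc
    records = [
        SequenceRecord(rec.id, _normalize(str(rec.seq), alphabet)) for rec in msa
    ]
    if not records:
        raise SeqFormatError(f"no records in {path}")
    _check_unique_ids(records)
    for rec in records:
        _check_alphabet(rec, alphabet)
    return records


def read_fasta(path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Identifiers are the first whitespace-delimited token of each header.
    Sequences are uppercased; for ``alphabet='nucleotide'``, ``U`` becomes
    ``T``. Duplicate identifiers, empty files, and characters outside the
    declared alphabet raise :class:`SeqFormatError`.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = [
        SequenceRecord(rec.id, _normalize(str(rec.seq), alphabet))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SeqFormatError(f"no FASTA records in {path}")
    _check_unique_ids(records)
    for rec in records:
        _check_alphabet(rec, alphabet)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    recs = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_region_map(path) -> RegionMap:
    """Read a TSV of ``name<TAB>start<TAB>end`` rows (0-based, half-open)."""
    regions = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, start, end = row[0], int(row[1]), int(row[2])
            regions.append(Region(name, start, end))
    return RegionMap(regions)


def _translate_codon(codon: str, taxon: str, k: int, permissive: bool) -> str:
    if codon == "---":
        return "-"
    if any(b not in "ACGT" for b in codon):
        return "X"
    if codon in STOP_CODONS:
        if permissive:
            return "*"
        raise SeqFormatError(
            f"record {taxon!r}: stop codon {codon!r} at codon {k}"
        )
    return str(Seq(codon).translate())


def translate(alignment: CodonAlignment, permissive: bool | None = None) -> ProteinAlignment:
    """Translate a codon alignment with the standard genetic code.

    ``---`` codons become ``-``; codons containing ambiguity characters
    become ``X``. A terminal stop codon is emitted as ``*``; a non-terminal
    stop raises unless ``permissive`` (defaulting to the alignment's own
    flag) is set.
    """
    if permissive is None:
        permissive = alignment.permissive
    out = []
    last = alignment.n_codons - 1
    for rec in alignment.records:
        aas = [
            _translate_codon(
                rec.seq[3 * k : 3 * k + 3],
                rec.id,
                k,
                permissive or k == last,
            )
            for k in range(alignment.n_codons)
        ]
        out.append(SequenceRecord(rec.id, "".join(aas)))
    return ProteinAlignment(out)


def _region_bounds(alignment: _Alignment, region) -> tuple[int, int]:
    if isinstance(region, Region):
        start, end = region.start, region.end
    else:
        start, end = region
    if start < 0 or end > alignment.length or end <= start:
        raise SeqFormatError(
            f"region [{start}, {end}) out of bounds for alignment of "
            f"length {alignment.length}"
        )
    if isinstance(alignment, CodonAlignment) and (start % 3 or end % 3):
        raise SeqFormatError(
            f"region [{start}, {end}) does not fall on codon boundaries"
        )
    return start, end


def extract_region(alignment, region):
    """Columns ``[start, end)`` of the alignment, as the same alignment type."""
    start, end = _region_bounds(alignment, region)
    recs = [SequenceRecord(r.id, r.seq[start:end]) for r in alignment.records]
    if isinstance(alignment, CodonAlignment):
        return CodonAlignment(recs, permissive=True)
    return type(alignment)(recs)


def excise_region(alignment, region):
    """The complement of :func:`extract_region`, column order preserved."""
    start, end = _region_bounds(alignment, region)
    recs = [
        SequenceRecord(r.id, r.seq[:start] + r.seq[end:])
        for r in alignment.records
    ]
    if isinstance(alignment, CodonAlignment):
        return CodonAlignment(recs, permissive=True)
    return type(alignment)(recs)


def read_newick(path):
    """Parse a Newick file (with optional ``$k`` clade tags) into a tree."""
    from .phylo import LabeledTree

    return LabeledTree.from_newick(Path(path).read_text())


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
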