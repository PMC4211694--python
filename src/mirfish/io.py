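"""Readers and writers for the external formats the pipeline touches.

Small-RNA reads arrive as FASTA or FASTQ (Sanger Phred+33, optionally
gzipped); the mature-miRNA reference uses the miRBase mature-FASTA dialect,
whose headers start with a species-prefixed name such as ``dre-miR-122``;
every tabular artefact is a TSV with a header row and a documented sort key
so that repeated runs are byte-comparable.

Sequences are stored as read (RNA references keep their ``U``); all
comparison elsewhere in the package happens on a T-normalized copy so that
sequenced cDNA reads (``T``) match reference entries (``U``).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "ReferenceMiRNA",
    "LibraryMeta",
    "MirnaId",
    "read_reads",
    "read_mirbase_fasta",
    "parse_mirna_id",
    "normalize_t",
    "write_table",
    "read_table",
    "read_samplesheet",
]

_RNA_TO_DNA = str.maketrans("Uu", "Tt")

TISSUES = ("brain", "liver", "gonad")
SEXES = ("female", "male")


def normalize_t(sequence: str) -> str:
    """Uppercase and map U -> T so reads and RNA references compare equal."""
    return sequence.upper().translate(_RNA_TO_DNA)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; ``quality`` is per-base Phred, absent for FASTA."""

    id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MirnaId:
    """Decomposition of a miRBase-style identifier.

    ``family`` is a purely lexical normalization: strip the arm (-5p/-3p),
    then a trailing ``-N`` gene-copy number, then trailing paralog letters
    (miR-138-1 -> miR-138; miR-27a -> miR-27; let-7a-2-3p -> let-7).
    A trailing ``*`` (old star nomenclature) sets ``star`` without claiming
    an arm.  ``parsed`` is False when no 3-letter species prefix was found.
    """

    species: str
    name: str
    family: str
    arm: str | None  # "5p" | "3p" | None
    star: bool = False
    parsed: bool = True


_SPECIES_RE = re.compile(r"^[a-z]{3}$")
_LETTER_SUFFIX_RE = re.compile(r"^(.*?\d)([a-z]+)$")


def _family_of(name: str) -> str:
    tokens = name.split("-")
    if tokens and tokens[-1] in ("5p", "3p"):
        tokens = tokens[:-1]
    # trailing "-N" copy number, only when a core remains (miR-138-1, let-7a-2)
    if len(tokens) > 2 and tokens[-1].isdigit():
        tokens = tokens[:-1]
    # trailing paralog letters on the numeric core: 27a -> 27, 7a -> 7
    if tokens:
        m = _LETTER_SUFFIX_RE.match(tokens[-1])
        if m:
            tokens[-1] = m.group(1)
    return "-".join(tokens)


def parse_mirna_id(header_id: str) -> MirnaId:
    """Split ``dre-miR-202-5p`` into species, name, family and arm.

    Never raises: identifiers without a species prefix come back with
    ``species == ""`` and ``parsed == False`` but are otherwise normalized.
    """
    if not header_id:
        raise ValueError("empty miRNA identifier")
    star = header_id.endswith("*")
    raw = header_id.rstrip("*")
    tokens = raw.split("-")
    # a species prefix is followed by the miRNA symbol (miR/let/lin/...),
    # never directly by the number: "let-7a" carries no species code
    if (
        len(tokens) >= 2
        and _SPECIES_RE.match(tokens[0])
        and tokens[1][:1].isalpha()
    ):
        species, name, parsed = tokens[0], "-".join(tokens[1:]), True
    else:
        species, name, parsed = "", raw, False
    arm: str | None = None
    if name.endswith("-5p"):
        arm = "5p"
    elif name.endswith("-3p"):
        arm = "3p"
    return MirnaId(
        species=species,
        name=name,
        family=_family_of(name),
        arm=arm,
        star=star,
        parsed=parsed,
    )


@dataclass(frozen=True)
class ReferenceMiRNA:
    """A mature miRNA reference record (miRBase mature-FASTA dialect)."""

    header_id: str
    species: str
    name: str
    family: str
    arm: str | None
    sequence: str  # as stored in the reference (RNA alphabet)
    seq_t: str = field(repr=False, default="")  # T-normalized for alignment

    @staticmethod
    def from_header(header_id: str, sequence: str) -> "ReferenceMiRNA":
        ident = parse_mirna_id(header_id)
        if not ident.parsed:
            raise ValueError(
                f"reference header {header_id!r} lacks a 3-letter species "
                "prefix followed by '-'"
            )
        seq = sequence.strip().upper()
        if not 15 <= len(seq) <= 35:
            raise ValueError(
                f"reference {header_id!r}: length {len(seq)} outside [15, 35]"
            )
        if set(seq) - set("ACGUTN"):
            raise ValueError(f"reference {header_id!r}: non-nucleotide characters")
        return ReferenceMiRNA(
            header_id=header_id,
            species=ident.species,
            name=ident.name,
            family=ident.family,
            arm=ident.arm,
            sequence=seq,
            seq_t=normalize_t(seq),
        )


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for one small-RNA library (one tissue of one sex)."""

    library_id: str
    tissue: str
    sex: str
    condition: str = "none"
    total_usable_reads: int = 0
    path: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.condition not in ("normoxia", "hypoxia", "none"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.total_usable_reads < 0:
            raise ValueError("total_usable_reads must be >= 0")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fastq", ".fq")):
        return "fastq"
    if name.endswith((".fasta", ".fa", ".fna")):
        return "fasta"
    raise ValueError(f"cannot infer read format from file name {name!r}")


def read_reads(path: str | Path, format: str | None = None) -> Iterator[ReadRecord]:
    """Yield reads from a FASTA/FASTQ file in file order.

    Malformed records (quality/sequence length mismatch, truncated file)
    raise a ValueError naming the 1-based record index.
    """
    fmt = (format or _sniff_format(path)).lower()
    if fmt not in ("fastq", "fasta"):
        raise ValueError(f"unsupported read format {fmt!r}")
    index = 0
    with _open_text(path) as handle:
        try:
            if fmt == "fastq":
                # FastqGeneralIterator raises on seq/quality length mismatch
                for title, seq, qual in FastqGeneralIterator(handle):
                    index += 1
                    yield ReadRecord(
                        id=title.split()[0],
                        sequence=seq.upper(),
                        quality=tuple(ord(c) - 33 for c in qual),
                    )
            else:
                for title, seq in SimpleFastaParser(handle):
                    index += 1
                    if not seq:
                        raise ValueError("empty sequence")
                    yield ReadRecord(id=title.split()[0], sequence=seq.upper())
        except ValueError as exc:
            raise ValueError(f"malformed record {index + 1} in {path}: {exc}") from exc


def read_mirbase_fasta(path: str | Path) -> list[ReferenceMiRNA]:
    """Parse a mature-miRNA FASTA; duplicate header ids are rejected."""
    records: list[ReferenceMiRNA] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            header_id = title.split()[0]
            if header_id in seen:
                raise ValueError(f"duplicate reference id {header_id!r}")
            seen.add(header_id)
            records.append(ReferenceMiRNA.from_header(header_id, seq))
    return records


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write a TSV with header row and deterministic row order.

    ``sort_by`` names the sort-key columns; by default all columns, left to
    right, so shuffled inputs produce byte-identical files.
    """
    out = df.copy()
    keys = list(sort_by) if sort_by else list(out.columns)
    if keys and len(out):
        out = out.sort_values(keys, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_samplesheet(path: str | Path) -> list[LibraryMeta]:
    """Samplesheet TSV: library_id, tissue, sex[, condition][, path]."""
    df = read_table(path)
    required = {"library_id", "tissue", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"samplesheet missing columns: {sorted(missing)}")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            LibraryMeta(
                library_id=str(row.library_id),
                tissue=str(row.tissue),
                sex=str(row.sex),
                condition=str(getattr(row, "condition", "none")),
                path=str(row.path) if hasattr(row, "path") else None,
            )
        )
    ids = [m.library_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_id in samplesheet")
    return metas
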