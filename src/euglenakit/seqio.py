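"""Sequence records and plain-text format I/O (FASTA, FASTQ, GFF3, TSV).

All internal coordinates are 0-based half-open; emitted files use each
format's native convention (GFF3 is 1-based inclusive).  Parsing of FASTA
and FASTQ is delegated to Bio.SeqIO; this module adds the strict validation
the rest of the package relies on (alphabet checks, unique ids, mate
inference) and reports offending line numbers where it reasonably can.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import unquote

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_KINDS = frozenset(
    {
        "SL_match",
        "CDS",
        "signal_peptide",
        "transit_peptide",
        "anchor_TMD",
        "repeat_unit",
        "fusion_segment",
    }
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised on malformed input; carries the file path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line else "") + "]"
        super().__init__(message + where)


@dataclass
class NucSequence:
    """An assembled contig / transcript model (DNA)."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteinSequence:
    """A protein record (20 amino acids + X; terminal stop stripped)."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SeqRead:
    """A raw sequencing read with Phred qualities."""

    id: str
    residues: str
    quality: list[int]
    mate: int = 1

    def __post_init__(self):
        if len(self.quality) != len(self.residues):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.residues)}"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"read {self.id}: mate must be 1 or 2")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """A located annotation on a nucleotide or protein sequence.

    start/end are 0-based half-open.  strand is '+'/'-' for nucleotide
    features and None for residue-space features.
    """

    seq_id: str
    kind: str
    start: int
    end: int
    strand: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature on {self.seq_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"feature on {self.seq_id}: bad strand {self.strand!r}")


def _header_lines(path) -> list[int]:
    """1-based line numbers of FASTA headers, for error reporting."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                out.append(i)
    return out


def _find_bad_line(path, header_line: int, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if i <= header_line:
                continue
            if line.startswith(">"):
                break
            if any(c in bad for c in line.strip().upper()):
                return i
    return header_line


def read_fasta(path, alphabet: str = "dna"):
    """Read a FASTA file into NucSequence or ProteinSequence records.

    ``alphabet`` is ``"dna"`` (A/C/G/T/N) or ``"protein"`` (20 aa + X; a
    single terminal ``*`` is accepted and stripped).  Residues are
    upper-cased.  Duplicate ids or illegal residues raise ParseError.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    cls = NucSequence if alphabet == "dna" else ProteinSequence
    headers = _header_lines(path)
    records = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        hline = headers[idx] if idx < len(headers) else None
        if not rec.id:
            raise ParseError("FASTA record with empty id", path, hline)
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r}", path, hline)
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if alphabet == "protein" and residues.endswith("*"):
            residues = residues[:-1]
        illegal = set(residues) - allowed
        if illegal:
            line = _find_bad_line(path, hline or 0, illegal)
            raise ParseError(
                f"illegal {alphabet} residue(s) {sorted(illegal)} in record {rec.id!r}",
                path,
                line,
            )
        records.append(cls(id=rec.id, residues=residues, description=rec.description))
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records (anything with .id/.residues/.description) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = rec.id
            if desc and desc != rec.id and not desc.startswith(rec.id + " "):
                header = f"{rec.id} {desc}"
            elif desc.startswith(rec.id + " "):
                header = desc
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _infer_mate(rec_id: str, description: str) -> tuple[str, int]:
    if rec_id.endswith("/1"):
        return rec_id, 1
    if rec_id.endswith("/2"):
        return rec_id, 2
    parts = description.split()
    if len(parts) >= 2 and parts[0] == rec_id and parts[1][:1] in ("1", "2"):
        return rec_id, int(parts[1][0])
    return rec_id, 1


def read_fastq(path) -> list[SeqRead]:
    """Read Phred+33 FASTQ; mate inferred from '/1','/2' or ' 1',' 2'."""
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            rid, mate = _infer_mate(rec.id, rec.description)
            residues = str(rec.seq).upper()
            illegal = set(residues) - DNA_ALPHABET
            if illegal:
                raise ParseError(
                    f"illegal residue(s) {sorted(illegal)} in read {rid!r}", path
                )
            reads.append(
                SeqRead(
                    id=rid,
                    residues=residues,
                    quality=list(rec.letter_annotations["phred_quality"]),
                    mate=mate,
                )
            )
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"malformed FASTQ: {exc}", path) from exc
    return reads


def write_fastq(reads: Iterable[SeqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(min(q, 60) + 33) for q in r.quality)
            fh.write(f"@{r.id}\n{r.residues}\n+\n{qual}\n")


# GFF3 reserves ; = & , and % in attribute values.
_GFF3_ESCAPES = [("%", "%25"), (";", "%3B"), ("=", "%3D"), ("&", "%26"), (",", "%2C"), ("\t", "%09"), ("\n", "%0A")]


def _gff3_escape(value: str) -> str:
    for raw, esc in _GFF3_ESCAPES:
        value = value.replace(raw, esc)
    return value


def write_gff3(features: Sequence[Feature], path, source: str = "euglenakit") -> None:
    """Write features as GFF3 (coordinates converted to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(
                f"{_gff3_escape(str(k))}={_gff3_escape(str(v))}"
                for k, v in f.attributes.items()
            )
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        source,
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand or ".",
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Feature]:
    """Read the GFF3 files this package writes back into Features."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError("GFF3 line does not have 9 columns", path, lineno)
            attributes = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    if not pair:
                        continue
                    key, _, value = pair.partition("=")
                    attributes[unquote(key)] = unquote(value)
            features.append(
                Feature(
                    seq_id=cols[0],
                    kind=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=None if cols[6] == "." else cols[6],
                    attributes=attributes,
                )
            )
    return features
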