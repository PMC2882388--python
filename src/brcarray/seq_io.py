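"""Sequence and alignment IO.

Containers (:class:`BioSequence`, :class:`Msa`) plus FASTA reading/writing and
CDS translation. Everything downstream of this module works on these two types.

Conventions
-----------
* Coordinates are 0-based and intervals half-open; conversion to 1-based
  inclusive happens only at report boundaries.
* Gap characters (``-``) are legal only inside an :class:`Msa` row; an
  unaligned :class:`BioSequence` rejects them.
* Inputs are pre-spliced CDS or protein sequences; exon stitching is out of
  scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NUC_RESIDUES = frozenset("ACGTN")
_PROT_RESIDUES = frozenset(_AMINO_ACIDS + "X*")

_STANDARD_TABLE = unambiguous_dna_by_id[1]


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


class AlignmentError(ValueError):
    """Rows of unequal length, or an otherwise invalid alignment."""


def _legal_residues(alphabet: str, aligned: bool) -> frozenset[str]:
    base = _NUC_RESIDUES if alphabet == NUCLEOTIDE else _PROT_RESIDUES
    return base | {"-"} if aligned else base


@dataclass(frozen=True)
class BioSequence:
    """A single named sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier token (unique within a file).
    residues : str
        Upper-case residue string over the declared alphabet.
    alphabet : str
        ``"nucleotide"`` or ``"protein"``.
    description : str
        Free text following the id on the FASTA header line.
    aligned : bool
        Whether gap characters are permitted (Msa rows only).
    """

    id: str
    residues: str
    alphabet: str = PROTEIN
    description: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        legal = _legal_residues(self.alphabet, self.aligned)
        bad = set(self.residues) - legal
        if bad:
            raise ValueError(
                f"illegal {self.alphabet} residue(s) {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: equal-length rows, 0-based columns."""

    rows: tuple[BioSequence, ...]

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if rows:
            n = len(rows[0].residues)
            for r in rows:
                if len(r.residues) != n:
                    raise AlignmentError(
                        f"row {r.id!r} has length {len(r.residues)}, expected {n}"
                    )
            ids = [r.id for r in rows]
            if len(set(ids)) != len(ids):
                raise AlignmentError("duplicate row ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def row(self, seq_id: str) -> BioSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


def read_fasta(path, alphabet: str, aligned: bool = False) -> list[BioSequence]:
    """Read a FASTA file into a list of :class:`BioSequence`, order preserved.

    Residues are upper-cased. Malformed headers and illegal residues raise
    :class:`FastaParseError` naming the line number.
    """
    records: list[BioSequence] = []
    seen: set[str] = set()
    header: tuple[str, str, int] | None = None  # id, description, line number
    chunks: list[str] = []
    legal = _legal_residues(alphabet, aligned)

    def _flush() -> None:
        if header is None:
            return
        seq_id, desc, lineno = header
        rec = BioSequence(
            id=seq_id,
            residues="".join(chunks),
            alphabet=alphabet,
            description=desc,
            aligned=aligned,
        )
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                chunks = []
                body = line[1:].strip()
                if not body:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                parts = body.split(None, 1)
                seq_id = parts[0]
                if seq_id in seen:
                    raise FastaParseError(f"line {lineno}: duplicate id {seq_id!r}")
                seen.add(seq_id)
                header = (seq_id, parts[1] if len(parts) > 1 else "", lineno)
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                up = line.upper()
                bad = set(up) - legal
                if bad:
                    raise FastaParseError(
                        f"line {lineno}: illegal {alphabet} residue(s) {sorted(bad)}"
                    )
                chunks.append(up)
    _flush()
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write records as FASTA (wrapped at `width`); round-trips with read_fasta."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_msa(path, alphabet: str) -> Msa:
    """Read an aligned FASTA file; unequal row lengths raise AlignmentError."""
    return Msa(tuple(read_fasta(path, alphabet, aligned=True)))


def write_msa(msa: Msa, path) -> None:
    if msa.n_rows == 0:
        raise AlignmentError("refusing to write an empty alignment")
    write_fasta(msa.rows, path)


@dataclass(frozen=True)
class TranslationResult:
    protein: BioSequence
    internal_stop: bool
    partial_codon_dropped: bool


def translate(cds: BioSequence, frame: int = 0) -> TranslationResult:
    """Translate a coding sequence with the standard genetic code.

    A single trailing stop is dropped; internal stops are rendered ``*`` and
    flagged. Codons containing ``N`` translate to ``X``. A trailing partial
    codon is dropped with a warning.
    """
    if cds.alphabet != NUCLEOTIDE:
        raise ValueError("translate requires a nucleotide sequence")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    body = cds.residues[frame:]
    if len(body) < 3:
        raise ValueError("fewer than one codon after applying frame offset")
    partial = len(body) % 3 != 0
    if partial:
        warnings.warn(
            f"{cds.id}: trailing partial codon of {len(body) % 3} nt dropped",
            stacklevel=2,
        )
        body = body[: len(body) - len(body) % 3]
    aas = []
    for i in range(0, len(body), 3):
        codon = body[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _STANDARD_TABLE.stop_codons:
            aas.append("*")
        else:
            aas.append(_STANDARD_TABLE.forward_table[codon])
    if aas and aas[-1] == "*":
        aas.pop()
    protein_str = "".join(aas)
    internal_stop = "*" in protein_str
    prot = BioSequence(
        id=cds.id,
        residues=protein_str,
        alphabet=PROTEIN,
        description=cds.description,
    )
    return TranslationResult(prot, internal_stop, partial)
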