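"""Sequence primitives: alphabet handling, reverse complement, IUPAC
pattern matching, codon queries, edit application and FASTA I/O.

Conventions
-----------
All coordinates are 0-based, half-open.  Loci are concrete DNA over
``{A,C,G,T}`` (uppercase-normalized on input; ambiguity codes rejected),
while PAM patterns may use the full IUPAC nucleotide alphabet.
Paper-style 1-based labels such as ``A200C`` are converted at the
interface layer only (see :func:`parse_edit_spec`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    EditConflictError,
    ParameterError,
    ReferenceMismatchError,
)

DNA_BASES = frozenset("ACGT")

#: IUPAC nucleotide codes and the concrete bases each one matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _validate_alphabet(seq: str, *, allow_iupac: bool = False, what: str = "sequence") -> str:
    seq = seq.upper()
    allowed = IUPAC_CODES.keys() if allow_iupac else DNA_BASES
    bad = set(seq) - set(allowed)
    if bad:
        raise AlphabetError(
            f"{what} contains non-nucleotide character(s): {sorted(bad)!r}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement, 5'->3'.

    IUPAC ambiguity codes are complemented to their mirror codes so the
    function also serves PAM patterns.  Raises :class:`AlphabetError` on
    any non-nucleotide character.  ``reverse_complement("") == ""``.
    """
    seq = _validate_alphabet(seq, allow_iupac=True)
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(pattern: str, window: str) -> bool:
    """True if ``window`` (concrete DNA) matches the IUPAC ``pattern``."""
    if len(pattern) != len(window):
        return False
    return all(w in IUPAC_CODES[p] for p, w in zip(pattern, window))


def iupac_find(pattern: str, seq: str) -> list[int]:
    """All (possibly overlapping) start positions of an IUPAC ``pattern``
    in a concrete DNA ``seq``, ascending, on the given strand only.

    ``V`` expands to {A,C,G}, ``N`` to {A,C,G,T}, etc.  An empty result is
    not an error.
    """
    if not pattern:
        raise ParameterError("pattern must be non-empty")
    pattern = _validate_alphabet(pattern, allow_iupac=True, what="pattern")
    seq = _validate_alphabet(seq)
    k = len(pattern)
    sets = [IUPAC_CODES[p] for p in pattern]
    hits: list[int] = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in sets[j] for j in range(k)):
            hits.append(i)
    return hits


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter, ``*`` for stop) for a codon, standard code."""
    codon = _validate_alphabet(codon, what="codon")
    if len(codon) != 3:
        raise ParameterError(f"codon must be 3 nt, got {len(codon)}")
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def synonymous_single_substitutions(codon: str) -> list[tuple[int, str]]:
    """Every single-base change of ``codon`` that preserves the encoded
    amino acid, as ``(offset, alt_base)`` pairs (standard genetic code).

    Stop codons are handled: synonymous stop->stop changes are returned.
    ``ATG`` (Met) and ``TGG`` (Trp) admit no synonymous single change.
    """
    aa = translate_codon(codon)
    out: list[tuple[int, str]] = []
    for off in range(3):
        for base in "ACGT":
            if base == codon[off]:
                continue
            variant = codon[:off] + base + codon[off + 1 :]
            if translate_codon(variant) == aa:
                out.append((off, base))
    return out


@dataclass(frozen=True)
class Edit:
    """A substitution edit: ``ref`` -> ``alt`` starting at a 0-based
    locus ``position``.  Substitutions only: equal, non-zero lengths."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", _validate_alphabet(self.ref, what="ref"))
        object.__setattr__(self, "alt", _validate_alphabet(self.alt, what="alt"))
        if self.position < 0:
            raise ParameterError(f"edit position must be >= 0, got {self.position}")
        if len(self.ref) != len(self.alt) or len(self.ref) < 1:
            raise ParameterError(
                "ref and alt must be equal-length and non-empty "
                f"(got {self.ref!r} -> {self.alt!r})"
            )
        if self.ref == self.alt:
            raise ParameterError(f"edit {self.ref!r} -> {self.alt!r} changes nothing")

    @property
    def interval(self) -> tuple[int, int]:
        """Half-open interval of affected positions."""
        return (self.position, self.position + len(self.ref))

    def mirrored(self, locus_len: int) -> "Edit":
        """The same edit expressed on the reverse-complement strand."""
        start = locus_len - self.position - len(self.ref)
        return Edit(start, reverse_complement(self.ref), reverse_complement(self.alt))


@dataclass(frozen=True)
class CdsAnnotation:
    """A coding interval on a locus: 0-based half-open ``[start, end)``,
    ``strand`` in {'+','-'}, ``frame`` offset 0-2 (bases to skip at the
    coding 5' end before the first full codon)."""

    start: int
    end: int
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.frame <= 2:
            raise ParameterError(f"frame must be 0-2, got {self.frame}")
        if self.start < 0 or self.end <= self.start:
            raise ParameterError(f"bad CDS interval [{self.start}, {self.end})")
        if (self.end - self.start - self.frame) % 3 != 0:
            raise ParameterError(
                "CDS length minus frame offset must be a multiple of 3 "
                f"(interval [{self.start}, {self.end}), frame {self.frame})"
            )


@dataclass(frozen=True)
class Locus:
    """A named reference sequence, optionally with a CDS annotation.

    The coordinate frame for every design.  ``seq`` is validated to be
    non-empty concrete DNA; ambiguity codes are rejected because designs
    must be concrete molecules.
    """

    name: str
    seq: str
    cds: CdsAnnotation | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate_alphabet(self.seq, what=f"locus {self.name!r}"))
        if not self.seq:
            raise AlphabetError(f"locus {self.name!r} has an empty sequence")
        if self.cds is not None and self.cds.end > len(self.seq):
            raise ParameterError(
                f"CDS [{self.cds.start}, {self.cds.end}) exceeds locus length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def mirrored(self) -> "Locus":
        """Reverse-complement view of the locus (CDS mirrored too)."""
        cds = None
        if self.cds is not None:
            n = len(self.seq)
            cds = CdsAnnotation(
                n - self.cds.end,
                n - self.cds.start,
                "-" if self.cds.strand == "+" else "+",
                self.cds.frame,
            )
        return Locus(self.name, reverse_complement(self.seq), cds)


def apply_edits(locus: Locus | str, edits: Sequence[Edit]) -> str:
    """Return the edited top-strand sequence; the locus is unmodified.

    Edits must be non-overlapping and each ``ref`` must match the locus,
    otherwise :class:`EditConflictError` / :class:`ReferenceMismatchError`.
    """
    seq = locus.seq if isinstance(locus, Locus) else _validate_alphabet(locus)
    ordered = sorted(edits, key=lambda e: e.position)
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.interval[1] > nxt.position:
            raise EditConflictError(
                f"edits at {prev.position} and {nxt.position} overlap"
            )
    out = list(seq)
    for e in ordered:
        lo, hi = e.interval
        if hi > len(seq):
            raise ReferenceMismatchError(
                f"edit at {e.position} runs past the end of the sequence"
            )
        found = seq[lo:hi]
        if found != e.ref:
            raise ReferenceMismatchError(
                f"expected {e.ref!r} at position {e.position}, found {found!r}"
            )
        out[lo:hi] = e.alt
    return "".join(out)


def parse_edit_spec(spec: str) -> Edit:
    """Parse a CLI-style edit ``POS:REF>ALT`` with POS 1-based (to match
    paper-style labels like A200C) into an internal 0-based :class:`Edit`."""
    try:
        pos_s, change = spec.split(":", 1)
        ref, alt = change.split(">", 1)
        pos = int(pos_s)
    except ValueError as exc:
        raise ParameterError(f"cannot parse edit spec {spec!r}; expected POS:REF>ALT") from exc
    if pos < 1:
        raise ParameterError(f"edit position is 1-based on the CLI, got {pos}")
    return Edit(pos - 1, ref, alt)


# --------------------------------------------------------------------------
# FASTA I/O (multi-record, wrapped or unwrapped lines) via Biopython.

def read_fasta(path: str | Path, *, cds: CdsAnnotation | None = None) -> list[Locus]:
    """Read all records of a FASTA file as :class:`Locus` objects."""
    loci = []
    for rec in SeqIO.parse(str(path), "fasta"):
        loci.append(Locus(rec.id, str(rec.seq), cds))
    if not loci:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return loci


class EmptyFastaError(AlphabetError):
    """A FASTA file contained no records."""


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs to a FASTA file."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
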