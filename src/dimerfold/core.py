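"""Sequence and secondary-structure data model.

Residues are 1-based, 5'->3'. The only structure serialization is
dot-bracket; pairs are stored as a frozenset of (i, j) tuples with i < j.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

ALPHABET = frozenset("ACGU")

#: Canonical Watson-Crick plus G.U wobble pairs (unordered base combinations).
PAIRABLE = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
                      ("G", "U"), ("U", "G")})


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ/dot-bracket input."""


def _clean_residues(raw: str, *, line: int | None = None) -> str:
    s = raw.upper().replace("T", "U")
    for ch in s:
        if ch not in ALPHABET:
            where = f" (line {line})" if line is not None else ""
            raise ParseError(f"non-nucleotide character {ch!r}{where}")
    return s


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence: identifier plus residues over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ParseError(f"empty sequence {self.id!r}")
        object.__setattr__(self, "residues", _clean_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """1-based residue access."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside 1..{len(self.residues)}")
        return self.residues[i - 1]


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) set of base pairs on 1..length.

    Invariants enforced at construction: each position in at most one
    pair, pairs non-crossing, hairpin loops of at least three residues.
    """

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    MIN_HAIRPIN = 3

    def __post_init__(self):
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen: set[int] = set()
        for i, j in pairs:
            if not (1 <= i < j <= self.length):
                raise ParseError(f"pair ({i},{j}) outside 1..{self.length}")
            if j - i - 1 < self.MIN_HAIRPIN:
                raise ParseError(
                    f"pair ({i},{j}) closes a hairpin loop shorter than "
                    f"{self.MIN_HAIRPIN}")
            for p in (i, j):
                if p in seen:
                    raise ParseError(f"position {p} paired twice")
                seen.add(p)
        ordered = sorted(pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise ParseError(
                        f"crossing pairs ({i},{j}) and ({k},{l})")

    @property
    def dot_bracket(self) -> str:
        out = ["."] * self.length
        for i, j in self.pairs:
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)

    def partner(self) -> dict:
        """Map position -> paired position (both directions)."""
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def hairpin_loops(self) -> list:
        """Return [(i, j), ...] closing pairs of hairpin loops (no pair inside)."""
        partner = self.partner()
        out = []
        for i, j in sorted(self.pairs):
            if all(p not in partner for p in range(i + 1, j)):
                out.append((i, j))
        return out


def parse_dot_bracket(s: str, *, length: int | None = None) -> SecondaryStructure:
    """Parse a dot-bracket string into a SecondaryStructure.

    Only '.', '(' and ')' are accepted; brackets must balance.
    """
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ParseError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    n = len(s) if length is None else length
    return SecondaryStructure(length=n, pairs=frozenset(pairs))


def _line_of(path: Path, fragment: str) -> int | None:
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if fragment and fragment in line.upper().replace("T", "U"):
            return lineno
    return None


def read_fasta(path) -> list:
    """Read a FASTA file into a list of RnaSequence (T transliterated to U)."""
    path = Path(path)
    records = []
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            try:
                records.append(RnaSequence(id=rec.id, residues=str(rec.seq)))
            except ParseError as exc:
                raw = str(rec.seq).upper().replace("T", "U")
                bad = next((ch for ch in raw if ch not in ALPHABET), "")
                lineno = _line_of(path, raw[:max(raw.find(bad), 1)] + bad)
                where = f" at line {lineno}" if lineno else ""
                raise ParseError(f"record {rec.id!r}{where}: {exc}") from exc
    return records


def write_fasta(seqs: Iterable[RnaSequence], path) -> None:
    with Path(path).open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def read_fastq(path) -> list:
    """Read FASTQ; qualities are discarded after parsing."""
    records = []
    with Path(path).open() as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            records.append(RnaSequence(id=rec.id, residues=str(rec.seq)))
    return records


def read_structure_text(text: str) -> tuple:
    """Parse the two-line 'sequence\\nstructure' text format."""
    lines = [ln.strip() for ln in io.StringIO(text) if ln.strip()]
    if len(lines) != 2:
        raise ParseError("expected exactly two non-empty lines")
    seq = RnaSequence(id="seq", residues=lines[0])
    ss = parse_dot_bracket(lines[1])
    if ss.length != len(seq):
        raise ParseError("sequence/structure length mismatch")
    return seq, ss


# The five oligonucleotides of the study system: computationally designed
# hairpin-forming variants (RNA I, IA, IB), the duplex-forming design
# (RNA II) and the native 19-mer fragment of the Mom translation
# initiation region.
STUDY_SEQUENCES = {
    "RNA_I": RnaSequence("RNA_I", "CGAGAACCAGAGAGUUCCGG"),
    "RNA_IA": RnaSequence("RNA_IA", "CUGCAACCAGAGAGUUGCGG"),
    "RNA_IB": RnaSequence("RNA_IB", "CGCGUACAAGUGAGUACCGG"),
    "RNA_II": RnaSequence("RNA_II", "AGAGAACCCGGAGUUCCCU"),
    "MOM_19": RnaSequence("MOM_19", "GAAUGCCUGCGAGCAUCCC"),
}
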