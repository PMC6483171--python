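"""Sequence-level annotation of self-complementary antiparallel duplexes.

Two copies of the same strand are opposed antiparallel; in the blunt
register position i of strand 1 faces position n+1-i of strand 2.  Each
opposed base combination is labelled canonical Watson-Crick (WC),
wobble (G.U), A.C, G.G, or other; shifted registers leave unpaired
overhangs at the ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .core import RnaSequence

LABELS = ("WC", "wobble", "AC", "GG", "other", "overhang")

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_label(b1: str, b2: str) -> str:
    pair = (b1, b2)
    if pair in _WC:
        return "WC"
    if pair in _WOBBLE:
        return "wobble"
    if {b1, b2} == {"A", "C"}:
        return "AC"
    if b1 == b2 == "G":
        return "GG"
    return "other"


@dataclass(frozen=True)
class DuplexPair:
    pos1: int | None  # strand 1 position, 1-based 5'->3'; None if overhang on strand 2
    pos2: int | None  # opposed strand 2 position; None for a strand-1 overhang
    base1: str | None
    base2: str | None
    label: str


@dataclass(frozen=True)
class DuplexAlignment:
    """Antiparallel register of a homodimer duplex with per-pair labels."""

    sequence: RnaSequence
    register_offset: int
    pairs: tuple  # DuplexPair, ordered along strand 1 (overhangs included)

    def census(self) -> dict:
        """Counts by label; overhang counts residues, not opposings."""
        counts = {lab: 0 for lab in LABELS}
        for p in self.pairs:
            counts[p.label] += 1
        return counts

    def paired_count(self) -> int:
        return sum(1 for p in self.pairs if p.label != "overhang")

    def to_table(self) -> str:
        lines = ["pos1\tpos2\tbase1\tbase2\tlabel"]
        for p in self.pairs:
            lines.append("\t".join(str(x) if x is not None else "-"
                                   for x in (p.pos1, p.pos2, p.base1,
                                             p.base2, p.label)))
        return "\n".join(lines) + "\n"

    def census_json(self) -> str:
        return json.dumps({"register_offset": self.register_offset,
                           **self.census()}, indent=1)


def _build(seq: RnaSequence, offset: int) -> DuplexAlignment:
    """Oppose strand1 position i with strand2 position n+1-i+offset."""
    n = len(seq)
    pairs = []
    used2 = set()
    for i in range(1, n + 1):
        j = n + 1 - i + offset
        if 1 <= j <= n:
            b1, b2 = seq[i], seq[j]
            pairs.append(DuplexPair(i, j, b1, b2, pair_label(b1, b2)))
            used2.add(j)
        else:
            pairs.append(DuplexPair(i, None, seq[i], None, "overhang"))
    for j in range(1, n + 1):
        if j not in used2:
            pairs.append(DuplexPair(None, j, None, seq[j], "overhang"))
    return DuplexAlignment(sequence=seq, register_offset=offset,
                           pairs=tuple(pairs))


def align_self_duplex(seq: RnaSequence,
                      register: int | str = "blunt") -> DuplexAlignment:
    """Antiparallel self-alignment of ``seq`` against an identical strand.

    register: "blunt" (offset 0), an integer offset, or "auto", which
    scans offsets -3..+3 and keeps the one maximizing the WC + wobble
    count (ties to the smallest \\|offset\\|, then to the negative one).
    """
    if len(seq) < 2:
        raise ValueError("duplex alignment requires length >= 2")
    if register == "blunt":
        return _build(seq, 0)
    if register == "auto":
        best = None
        for offset in sorted(range(-3, 4), key=lambda o: (abs(o), o)):
            aln = _build(seq, offset)
            counts = aln.census()
            score = counts["WC"] + counts["wobble"]
            if best is None or score > best[0]:
                best = (score, aln)
        return best[1]
    return _build(seq, int(register))


def census(alignment: DuplexAlignment) -> dict:
    return alignment.census()
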