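"""Deterministic scanning for SELEX-derived sequence motifs.

Motifs are IUPAC strings with one optional bounded gap written as
``(N){lo,hi}`` -- e.g. the bipartite Com-binding motif
``GAGNNCC(N){2,3}GAGNNCC``.  Scanning is exact pattern expansion, not
probabilistic motif discovery: every occurrence (overlaps included) is
reported.  A synthetic pool generator with motif planting supports
soundness and background-rate checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .core import RnaSequence
from .fold import fold_mfe
from .params import EnergyParameters

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC", "B": "CGU", "D": "AGU",
    "H": "ACU", "V": "ACG", "N": "ACGU",
}

_GAP_RE = re.compile(r"\(N\)\{(\d+),(\d+)\}")


class MotifError(ValueError):
    """Raised for malformed motif patterns."""


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC motif, 5'->3', with at most one bounded (N){lo,hi} gap."""

    pattern: str

    def __post_init__(self):
        self.parse()

    def parse(self):
        """Return (left, gap_lo, gap_hi, right); gap bounds None if no gap."""
        m = _GAP_RE.search(self.pattern)
        if m is None:
            left, right, lo, hi = self.pattern, "", None, None
        else:
            if _GAP_RE.search(self.pattern, m.end()):
                raise MotifError("at most one gap is supported")
            left, right = self.pattern[:m.start()], self.pattern[m.end():]
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise MotifError(f"gap bounds {lo} > {hi}")
        for part in (left, right):
            for ch in part.upper():
                if ch not in IUPAC:
                    raise MotifError(f"invalid IUPAC code {ch!r}")
        if not left:
            raise MotifError("empty motif")
        return left.upper(), lo, hi, right.upper()

    def span_range(self) -> tuple:
        left, lo, hi, right = self.parse()
        fixed = len(left) + len(right)
        if lo is None:
            return fixed, fixed
        return fixed + lo, fixed + hi

    def _regex(self) -> re.Pattern:
        def expand(part):
            return "".join(ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]"
                           for ch in part)
        left, lo, hi, right = self.parse()
        body = expand(left)
        if lo is not None:
            body += f"[ACGU]{{{lo},{hi}}}" + expand(right)
        # lookahead with a capture so overlapping matches are all found
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    matched: str


@dataclass(frozen=True)
class ScanReport:
    """Per-sequence hit lists plus pool-level summary counts."""

    hits: dict  # sequence id -> tuple of MotifHit
    n_scanned: int

    @property
    def n_with_hit(self) -> int:
        return sum(1 for h in self.hits.values() if h)

    @property
    def n_hits(self) -> int:
        return sum(len(h) for h in self.hits.values())

    def summary(self) -> dict:
        return {"sequences_scanned": self.n_scanned,
                "sequences_with_hit": self.n_with_hit,
                "total_hits": self.n_hits}


def scan(pool, motif: MotifSpec) -> ScanReport:
    """Report every motif occurrence in every sequence (overlaps allowed).

    Note: the bounded gap is greedy within a start position; distinct
    start positions are all enumerated, and a hit is recorded once per
    start (the regex engine reports one gap width per start).
    """
    rx = motif._regex()
    hits = {}
    for seq in pool:
        found = []
        for m in rx.finditer(seq.residues):
            text = m.group(1)
            found.append(MotifHit(start=m.start() + 1,
                                  end=m.start() + len(text), matched=text))
        hits[seq.id] = tuple(found)
    return ScanReport(hits=hits, n_scanned=len(pool))


def scan_in_loop(pool, motif: MotifSpec,
                 params: EnergyParameters) -> ScanReport:
    """Like :func:`scan`, keeping only hits that touch a hairpin loop.

    Each sequence is folded to its MFE structure; a hit is retained iff
    at least one matched residue lies unpaired inside a hairpin loop.
    Sequences whose MFE structure has no pairs have no hairpin loop and
    therefore retain no hits.
    """
    base = scan(pool, motif)
    hits = {}
    for seq in pool:
        found = base.hits[seq.id]
        if not found:
            hits[seq.id] = ()
            continue
        ss = fold_mfe(seq, params).mfe_structure
        loop_positions = set()
        for (i, j) in ss.hairpin_loops():
            loop_positions.update(range(i + 1, j))
        kept = tuple(h for h in found
                     if any(p in loop_positions
                            for p in range(h.start, h.end + 1)))
        hits[seq.id] = kept
    return ScanReport(hits=hits, n_scanned=len(pool))


def plant_motif(rng: np.random.Generator, length: int,
                motif: MotifSpec) -> str:
    """One uniform-random sequence of ``length`` with one planted instance."""
    left, lo, hi, right = motif.parse()
    bases = "ACGU"
    gap = 0 if lo is None else int(rng.integers(lo, hi + 1))
    span = len(left) + gap + len(right)
    if length < span:
        raise MotifError(f"length {length} < motif span {span}")
    instance = "".join(
        [IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in left]
        + [bases[rng.integers(4)] for _ in range(gap)]
        + [IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in right])
    offset = int(rng.integers(0, length - span + 1))
    seq = [bases[k] for k in rng.integers(4, size=length)]
    seq[offset:offset + span] = instance
    return "".join(seq)


def simulate_pool(n: int, length: int, plant=None,
                  seed: int = 0) -> list:
    """Uniform random pool; optionally plant a motif in a fraction of it.

    plant: optional (MotifSpec, fraction) -- floor(fraction*n) sequences
    receive one planted instance at a random feasible offset.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGU"
    planted = 0
    if plant is not None:
        motif, fraction = plant
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction {fraction} outside [0, 1]")
        lo_span, _ = motif.span_range()
        if length < lo_span:
            raise MotifError(f"length {length} < motif span {lo_span}")
        planted = int(fraction * n)
    pool = []
    for idx in range(n):
        if idx < planted:
            residues = plant_motif(rng, length, plant[0])
        else:
            residues = "".join(bases[k] for k in rng.integers(4, size=length))
        pool.append(RnaSequence(id=f"pool_{idx}", residues=residues))
    return pool


def background_match_probability(motif: MotifSpec, length: int) -> float:
    """Analytic P(>=1 match) for one uniform random sequence.

    Per-offset match probability is the product of per-position class
    probabilities, summed over gap widths; offsets are treated as
    independent (accurate to first order for rare motifs).
    """
    import math

    left, lo, hi, right = motif.parse()
    expected = 0.0
    widths = [0] if lo is None else range(lo, hi + 1)
    p_site = 1.0
    for ch in left + right:
        p_site *= len(IUPAC[ch]) / 4.0
    for gap in widths:
        span = len(left) + gap + len(right)
        expected += max(0, length - span + 1) * p_site
    # Poisson approximation for rare, nearly independent match events
    return 1.0 - math.exp(-expected)
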