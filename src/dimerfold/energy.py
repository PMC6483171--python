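"""Free energy of a given secondary structure by loop decomposition.

The decomposition is the standard nearest-neighbor one: stacks,
hairpin/bulge/internal loop initiations by size, an affine multiloop
term and terminal penalties for helix ends closed by A-U or G-U.

A two-strand complex is represented as the concatenation of the strands
with a nick after position ``nick``: a loop whose cycle crosses the
nick is scored like an exterior loop (terminal penalties only), and no
stack may bridge the nick.  This function is also the scoring oracle
for the folding recursions: enumeration plus this function defines the
reference ensemble the dynamic programs must reproduce.
"""

from __future__ import annotations

from .core import PAIRABLE, RnaSequence, SecondaryStructure
from .params import EnergyParameters


class StructureEnergyError(ValueError):
    """Raised when a structure pairs bases the model cannot pair."""


def terminal_penalty(s: str, i: int, j: int, params: EnergyParameters) -> float:
    return params.terminal_penalty(s[i - 1], s[j - 1])


def stack_energy(s: str, i: int, j: int, params: EnergyParameters) -> float:
    """Energy of the helix step with outer pair (i,j) and inner (i+1,j-1)."""
    outer = s[i - 1] + s[j - 1]
    inner = s[i] + s[j - 2]
    return params.stack[(outer, inner)]


def interior_energy(s: str, i: int, j: int, k: int, l: int,
                    params: EnergyParameters) -> float:
    """Loop between outer pair (i,j) and inner pair (k,l), no nick inside."""
    l1, l2 = k - i - 1, j - l - 1
    if l1 == 0 and l2 == 0:
        return stack_energy(s, i, j, params)
    both_ends = (terminal_penalty(s, i, j, params)
                 + terminal_penalty(s, k, l, params))
    if l1 == 0 or l2 == 0:
        return params.bulge(l1 + l2) + both_ends
    return params.internal(l1 + l2) + both_ends


def hairpin_energy(s: str, i: int, j: int, params: EnergyParameters) -> float:
    return params.hairpin(j - i - 1) + terminal_penalty(s, i, j, params)


def _check_pairs(s: str, pairs) -> list:
    ordered = sorted(pairs)
    for i, j in ordered:
        if (s[i - 1], s[j - 1]) not in PAIRABLE:
            raise StructureEnergyError(
                f"bases {s[i-1]}{i} and {s[j-1]}{j} cannot pair")
    return ordered


def _children(ordered_pairs):
    """Direct enclosure tree: {parent_pair_or_None: [child pairs 5'->3']}."""
    tree: dict = {None: []}
    stack: list = []
    for p in ordered_pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        tree.setdefault(parent, []).append(p)
        tree.setdefault(p, [])
        stack.append(p)
    return tree


def _nick_exposed(left_bounds, nick):
    """True if the junction nick|nick+1 lies in a free gap of a loop.

    left_bounds are the (a, b) position ranges of the free (unpaired)
    walks of the loop; the junction is exposed iff some walk steps from
    a position <= nick to one > nick.
    """
    if nick is None:
        return False
    return any(a <= nick < b for a, b in left_bounds)


def pair_set_energy(s: str, pairs, params: EnergyParameters,
                    nick: int | None = None) -> float:
    """Energy of a raw pair set on sequence string ``s`` (1-based pairs)."""
    n = len(s)
    ordered = _check_pairs(s, pairs)
    tree = _children(ordered)
    total = 0.0
    # exterior loop: terminal penalties for the outermost branches
    for (i, j) in tree[None]:
        total += terminal_penalty(s, i, j, params)
    for (i, j) in ordered:
        kids = tree[(i, j)]
        bounds = []
        prev = i
        for (k, l) in kids:
            bounds.append((prev, k))
            prev = l
        bounds.append((prev, j))
        if _nick_exposed(bounds, nick):
            # loop crosses the strand break: exterior-type scoring
            total += terminal_penalty(s, i, j, params)
            for (k, l) in kids:
                total += terminal_penalty(s, k, l, params)
        elif not kids:
            total += hairpin_energy(s, i, j, params)
        elif len(kids) == 1:
            (k, l) = kids[0]
            total += interior_energy(s, i, j, k, l, params)
        else:
            unpaired = sum(b - a - 1 for a, b in bounds)
            total += (params.multiloop_closing
                      + params.multiloop_branch * (1 + len(kids))
                      + params.multiloop_unpaired * unpaired
                      + terminal_penalty(s, i, j, params)
                      + sum(terminal_penalty(s, k, l, params)
                            for k, l in kids))
    del n
    return total


def energy_of_structure(seq: RnaSequence, ss: SecondaryStructure,
                        params: EnergyParameters) -> float:
    """Free energy (kcal/mol) of ``ss`` on ``seq``; empty structure -> 0."""
    if ss.length != len(seq):
        raise StructureEnergyError(
            f"structure length {ss.length} != sequence length {len(seq)}")
    return pair_set_energy(seq.residues, ss.pairs, params)
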