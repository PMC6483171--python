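"""Exhaustive-enumeration reference implementations.

These enumerate every nested secondary structure of a (short) sequence
and score it with dimerfold's loop-decomposition energy function,
providing an independent reference for the MFE and partition-function
dynamic programs.  Usable up to n ~ 16-18 residues.
"""

import math
from functools import lru_cache

from dimerfold.core import PAIRABLE
from dimerfold.energy import pair_set_energy

MIN_HAIRPIN = 3


def enumerate_structures(s: str, nick: int | None = None):
    """All nested pair sets on s (1-based positions), as tuples of pairs.

    A pair spanning the nick is exempt from the minimum-hairpin rule.
    """
    n = len(s)

    def can(i, j):
        if (s[i - 1], s[j - 1]) not in PAIRABLE:
            return False
        if j - i - 1 >= MIN_HAIRPIN:
            return True
        return nick is not None and i <= nick < j

    @lru_cache(maxsize=None)
    def region(i, j):
        if i >= j:
            return (() ,)
        out = list(region(i + 1, j))
        for k in range(i + 1, j + 1):
            if can(i, k):
                for inner in region(i + 1, k - 1):
                    head = ((i, k),) + inner
                    for rest in region(k + 1, j):
                        out.append(head + rest)
        return tuple(out)

    result = region(1, n)
    region.cache_clear()
    return result


def oracle_fold(s: str, params, nick=None, pseudo=None,
                require_spanning=False):
    """(mfe, Z, pair_weights) by brute force.

    pseudo: optional 1-based list of per-paired-residue penalties.
    require_spanning: keep only structures with >= 1 pair across nick.
    """
    rt = params.rt
    mfe = 0.0
    z = 0.0
    weights = {}
    best = ()
    any_kept = False
    for pairs in enumerate_structures(s, nick=nick):
        if require_spanning and not any(i <= nick < j for i, j in pairs):
            continue
        e = pair_set_energy(s, pairs, params, nick=nick)
        if pseudo is not None:
            e += sum(pseudo[i - 1] + pseudo[j - 1] for i, j in pairs)
        if not any_kept or e < mfe - 1e-12:
            mfe, best = e, pairs
        any_kept = True
        w = math.exp(-e / rt)
        z += w
        for p in pairs:
            weights[p] = weights.get(p, 0.0) + w
    if not any_kept:
        return None, 0.0, {}
    probs = {p: w / z for p, w in weights.items()}
    return mfe, z, probs
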