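"""Single-strand secondary-structure prediction.

``fold_mfe`` is a Zuker-style minimum-free-energy dynamic program and
``partition_function`` the McCaskill inside/outside algorithm, both over
the identical structure space: nested structures of Watson-Crick and
G.U pairs with hairpin loops of at least three residues.  Both score
structures exactly as :func:`dimerfold.energy.pair_set_energy`, which is
what makes the exhaustive-enumeration equivalence tests possible.

Partition-function arithmetic is carried out in linear space, which is
ample for the oligonucleotide scale this package targets (up to roughly
a hundred residues before Boltzmann weights would overflow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PAIRABLE, RnaSequence, SecondaryStructure
from .energy import hairpin_energy, interior_energy, terminal_penalty
from .params import EnergyParameters

INF = float("inf")
#: maximum number of unpaired residues enumerated in an interior loop
MAXLOOP = 30
MIN_HAIRPIN = SecondaryStructure.MIN_HAIRPIN
_EPS = 1e-7


class ConstraintError(ValueError):
    """Raised when a constraint or reactivity vector mismatches the sequence."""


@dataclass
class FoldResult:
    """Folding output: MFE structure/energy and optional ensemble values."""

    sequence: RnaSequence
    mfe_structure: SecondaryStructure
    mfe: float
    ensemble_free_energy: float | None = None
    pair_probability: np.ndarray | None = None  # (n+1, n+1), 1-based

    def __post_init__(self):
        if self.ensemble_free_energy is not None:
            assert self.ensemble_free_energy <= self.mfe + 1e-9


def _prepare(seq, constraints, pseudo):
    n = len(seq)
    if constraints is not None and len(constraints) != n:
        raise ConstraintError(
            f"constraint mask length {len(constraints)} != sequence length {n}")
    if pseudo is not None and len(pseudo) != n:
        raise ConstraintError(
            f"pseudo-energy vector length {len(pseudo)} != sequence length {n}")
    mask = [True] + ([bool(x) for x in constraints] if constraints is not None
                     else [True] * n)
    pse = [0.0] + ([float(x) for x in pseudo] if pseudo is not None
                   else [0.0] * n)
    return seq.residues, n, mask, pse


def _pairable(s, mask, i, j):
    return (mask[i] and mask[j] and j - i - 1 >= MIN_HAIRPIN
            and (s[i - 1], s[j - 1]) in PAIRABLE)


def fold_mfe(seq: RnaSequence, params: EnergyParameters,
             constraints=None, pseudo=None) -> FoldResult:
    """Minimum-free-energy structure.

    constraints: optional per-residue mask; False forces the residue
    unpaired.  pseudo: optional per-residue energy added whenever the
    residue is paired (SHAPE pseudo-free-energy term).  Ties are broken
    deterministically, preferring structures reachable through unpaired
    extensions (fewer pairs) and smaller pair indices.
    """
    s, n, mask, pse = _prepare(seq, constraints, pseudo)
    ta = lambda i, j: terminal_penalty(s, i, j, params)
    a, b, c = (params.multiloop_closing, params.multiloop_branch,
               params.multiloop_unpaired)

    V = [[INF] * (n + 2) for _ in range(n + 2)]
    WM = [[INF] * (n + 2) for _ in range(n + 2)]
    WM1 = [[INF] * (n + 2) for _ in range(n + 2)]

    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            if _pairable(s, mask, i, j):
                best = hairpin_energy(s, i, j, params)
                kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 2)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
                    for l in range(lmin, j):
                        if V[k][l] < INF:
                            e = interior_energy(s, i, j, k, l, params) + V[k][l]
                            if e < best:
                                best = e
                # multiloop: split the interior into a >=1-branch prefix
                # and a single trailing branch
                base = a + b + ta(i, j)
                for m in range(i + 2, j - 1):
                    if WM[i + 1][m - 1] < INF and WM1[m][j - 1] < INF:
                        e = base + WM[i + 1][m - 1] + WM1[m][j - 1]
                        if e < best:
                            best = e
                V[i][j] = best + pse[i] + pse[j]
            # WM1: exactly one branch starting at i
            w1 = WM1[i][j - 1] + c
            if V[i][j] < INF:
                w1 = min(w1, V[i][j] + b + ta(i, j))
            WM1[i][j] = w1
            # WM: at least one branch
            w = min(WM[i + 1][j] + c, WM1[i][j])
            for l in range(i + MIN_HAIRPIN + 1, j):
                if V[i][l] < INF and WM[l + 1][j] < INF:
                    e = V[i][l] + b + ta(i, l) + WM[l + 1][j]
                    if e < w:
                        w = e
            WM[i][j] = w

    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        w = W[j - 1]
        for k in range(1, j):
            if V[k][j] < INF:
                e = W[k - 1] + V[k][j] + ta(k, j)
                if e < w:
                    w = e
        W[j] = w

    pairs = _traceback(s, n, params, mask, pse, V, WM, WM1, W)
    ss = SecondaryStructure(length=n, pairs=frozenset(pairs))
    return FoldResult(sequence=seq, mfe_structure=ss, mfe=W[n])


def _traceback(s, n, params, mask, pse, V, WM, WM1, W):
    ta = lambda i, j: terminal_penalty(s, i, j, params)
    a, b, c = (params.multiloop_closing, params.multiloop_branch,
               params.multiloop_unpaired)
    pairs = []
    tasks = [("W", 1, n)]
    while tasks:
        kind, i, j = tasks.pop()
        if j <= i:
            continue
        if kind == "W":
            target = W[j]
            if j == 0 or abs(W[j - 1] - target) <= _EPS:
                tasks.append(("W", i, j - 1))
                continue
            for k in range(1, j):
                if V[k][j] < INF and \
                        abs(W[k - 1] + V[k][j] + ta(k, j) - target) <= _EPS:
                    pairs.append((k, j))
                    tasks.append(("W", 1, k - 1))
                    tasks.append(("V", k, j))
                    break
            else:  # pragma: no cover - DP/traceback mismatch
                raise AssertionError("exterior traceback failed")
        elif kind == "V":
            target = V[i][j] - pse[i] - pse[j]
            if abs(hairpin_energy(s, i, j, params) - target) <= _EPS:
                continue
            done = False
            kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 2)
            for k in range(i + 1, kmax + 1):
                l1 = k - i - 1
                lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
                for l in range(lmin, j):
                    if V[k][l] < INF and abs(
                            interior_energy(s, i, j, k, l, params)
                            + V[k][l] - target) <= _EPS:
                        pairs.append((k, l))
                        tasks.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            base = a + b + ta(i, j)
            for m in range(i + 2, j - 1):
                if WM[i + 1][m - 1] < INF and WM1[m][j - 1] < INF and abs(
                        base + WM[i + 1][m - 1] + WM1[m][j - 1]
                        - target) <= _EPS:
                    tasks.append(("WM", i + 1, m - 1))
                    tasks.append(("WM1", m, j - 1))
                    done = True
                    break
            if not done:  # pragma: no cover
                raise AssertionError(f"V traceback failed at ({i},{j})")
        elif kind == "WM1":
            target = WM1[i][j]
            if WM1[i][j - 1] < INF and abs(WM1[i][j - 1] + c - target) <= _EPS:
                tasks.append(("WM1", i, j - 1))
            elif V[i][j] < INF and abs(
                    V[i][j] + b + ta(i, j) - target) <= _EPS:
                pairs.append((i, j))
                tasks.append(("V", i, j))
            else:  # pragma: no cover
                raise AssertionError("WM1 traceback failed")
        else:  # WM
            target = WM[i][j]
            if WM[i + 1][j] < INF and abs(WM[i + 1][j] + c - target) <= _EPS:
                tasks.append(("WM", i + 1, j))
                continue
            if abs(WM1[i][j] - target) <= _EPS:
                tasks.append(("WM1", i, j))
                continue
            for l in range(i + MIN_HAIRPIN + 1, j):
                if V[i][l] < INF and WM[l + 1][j] < INF and abs(
                        V[i][l] + b + ta(i, l) + WM[l + 1][j]
                        - target) <= _EPS:
                    pairs.append((i, l))
                    tasks.append(("V", i, l))
                    tasks.append(("WM", l + 1, j))
                    break
            else:  # pragma: no cover
                raise AssertionError("WM traceback failed")
    return pairs


def partition_function(seq: RnaSequence, params: EnergyParameters,
                       constraints=None, pseudo=None) -> FoldResult:
    """McCaskill partition function with base-pair probabilities.

    Returns a FoldResult whose ensemble_free_energy is -RT ln Z and
    whose pair_probability[i, j] (1-based) is the Boltzmann probability
    that residues i and j pair.
    """
    s, n, mask, pse = _prepare(seq, constraints, pseudo)
    rt = params.rt
    eb = lambda x: math.exp(-x / rt)
    ta = lambda i, j: terminal_penalty(s, i, j, params)
    a, b, c = (params.multiloop_closing, params.multiloop_branch,
               params.multiloop_unpaired)

    Qb = [[0.0] * (n + 2) for _ in range(n + 2)]
    ZM = [[0.0] * (n + 2) for _ in range(n + 2)]
    ZM1 = [[0.0] * (n + 2) for _ in range(n + 2)]

    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            if _pairable(s, mask, i, j):
                q = eb(hairpin_energy(s, i, j, params))
                kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 2)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
                    for l in range(lmin, j):
                        if Qb[k][l] > 0.0:
                            q += eb(interior_energy(s, i, j, k, l, params)) \
                                * Qb[k][l]
                qm = 0.0
                for m in range(i + 2, j - 1):
                    qm += ZM[i + 1][m - 1] * ZM1[m][j - 1]
                q += eb(a + b + ta(i, j)) * qm
                Qb[i][j] = eb(pse[i] + pse[j]) * q
            ZM1[i][j] = ZM1[i][j - 1] * eb(c) + Qb[i][j] * eb(b + ta(i, j))
            zm = ZM[i + 1][j] * eb(c)
            for l in range(i + MIN_HAIRPIN + 1, j + 1):
                if Qb[i][l] > 0.0:
                    zm += Qb[i][l] * eb(b + ta(i, l)) \
                        * (eb(c * (j - l)) + ZM[l + 1][j])
            ZM[i][j] = zm

    ZL = [1.0] * (n + 2)
    for j in range(1, n + 1):
        z = ZL[j - 1]
        for k in range(1, j):
            if Qb[k][j] > 0.0:
                z += ZL[k - 1] * Qb[k][j] * eb(ta(k, j))
        ZL[j] = z
    ZR = [1.0] * (n + 3)
    for i in range(n, 0, -1):
        z = ZR[i + 1]
        for j in range(i + 1, n + 1):
            if Qb[i][j] > 0.0:
                z += Qb[i][j] * eb(ta(i, j)) * ZR[j + 1]
        ZR[i] = z
    Z = ZL[n]
    if not math.isfinite(Z):  # pragma: no cover - defensive
        raise OverflowError("partition function overflow; sequence too long "
                            "for linear-space arithmetic")

    # outside recursion
    O = [[0.0] * (n + 2) for _ in range(n + 2)]
    u = lambda x, y: eb(c * (y - x + 1)) if y >= x else 1.0
    zm_of = lambda x, y: ZM[x][y] if y >= x else 0.0
    for d in range(n - 1, MIN_HAIRPIN, -1):
        for i in range(1, n - d + 1):
            j = i + d
            if Qb[i][j] == 0.0:
                continue
            o = ZL[i - 1] * eb(ta(i, j)) * ZR[j + 1]
            pmin = max(1, i - MAXLOOP - 1)
            for p in range(pmin, i):
                l1 = i - p - 1
                qmax = min(n, j + 1 + (MAXLOOP - l1))
                for q in range(j + 1, qmax + 1):
                    if O[p][q] > 0.0:
                        o += O[p][q] * eb(pse[p] + pse[q]) \
                            * eb(interior_energy(s, p, q, i, j, params))
            fac_ij = eb(b + ta(i, j))
            for p in range(1, i):
                for q in range(j + 1, n + 1):
                    if O[p][q] > 0.0 and _pairable(s, mask, p, q):
                        left = zm_of(p + 1, i - 1)
                        right = zm_of(j + 1, q - 1)
                        combos = (left * (u(j + 1, q - 1) + right)
                                  + u(p + 1, i - 1) * right)
                        if combos > 0.0:
                            o += O[p][q] * eb(pse[p] + pse[q]) \
                                * eb(a + b + ta(p, q)) * fac_ij * combos
            O[i][j] = o

    P = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if Qb[i][j] > 0.0:
                P[i, j] = Qb[i][j] * O[i][j] / Z

    mfe_res = fold_mfe(seq, params, constraints, pseudo)
    return FoldResult(sequence=seq, mfe_structure=mfe_res.mfe_structure,
                      mfe=mfe_res.mfe, ensemble_free_energy=-rt * math.log(Z),
                      pair_probability=P)
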