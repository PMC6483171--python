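"""Two-strand homodimer thermodynamics.

The dimer ensemble is computed on the concatenation seq||seq with a
strand nick between positions n and n+1.  The nick rules follow the
standard treatment of cofolded complexes:

* a pair may span the nick with no minimum-loop restriction;
* no hairpin loop, stack or other closed loop may have the nick in one
  of its free (unpaired) walks -- such a loop is scored like an
  exterior loop (terminal penalties only);
* the ensemble is restricted to structures with at least one
  inter-strand pair; the intermolecular initiation penalty is added
  once, and optionally the +RT ln 2 symmetry correction for two
  indistinguishable strands.

Every structure in this ensemble contains a unique outermost
inter-strand pair, which is what the final summation decomposes over;
this avoids the catastrophic cancellation of the naive
Z_total - Z_mono^2 difference for weak dimers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import PAIRABLE, RnaSequence
from .energy import hairpin_energy, interior_energy, terminal_penalty
from .fold import MAXLOOP, MIN_HAIRPIN
from .params import EnergyParameters

INF = float("inf")


@dataclass(frozen=True)
class DimerEquilibrium:
    """Monomer/homodimer ensemble free energies and the dimerization gap.

    gap = dimer_f - 2*monomer_f; k_dimer = exp(-gap/RT).  A sequence
    that cannot form a single inter-strand pair is non-dimerizing:
    gap = +inf and k_dimer = 0.
    """

    monomer_f: float
    dimer_f: float
    gap: float
    k_dimer: float

    @property
    def dimerizing(self) -> bool:
        return math.isfinite(self.gap)


def _monomer_hairpin_z(s: str, params: EnergyParameters) -> float:
    """Partition function restricted to single stem-loop structures.

    Structures with exactly one hairpin loop and no multiloop: a stack
    of helices connected by bulge/internal loops, with free unpaired
    flanks.  The empty structure is excluded.
    """
    n = len(s)
    rt = params.rt
    eb = lambda x: math.exp(-x / rt)
    Qh = [[0.0] * (n + 2) for _ in range(n + 2)]
    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            if (s[i - 1], s[j - 1]) not in PAIRABLE:
                continue
            q = eb(hairpin_energy(s, i, j, params))
            kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 2)
            for k in range(i + 1, kmax + 1):
                l1 = k - i - 1
                lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
                for l in range(lmin, j):
                    if Qh[k][l] > 0.0:
                        q += eb(interior_energy(s, i, j, k, l, params)) \
                            * Qh[k][l]
            Qh[i][j] = q
    z = 0.0
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if Qh[i][j] > 0.0:
                z += Qh[i][j] * eb(terminal_penalty(s, i, j, params))
    return z


def dimer_partition_function(seq: RnaSequence, params: EnergyParameters):
    """Return (z_mono, z_inter) for the homodimer of ``seq``.

    z_inter sums Boltzmann weights of all structures on seq||seq with
    >=1 inter-strand pair (initiation/symmetry terms NOT included).
    """
    s1 = seq.residues
    n = len(s1)
    s = s1 + s1
    N = 2 * n
    t = n  # nick between t and t+1
    rt = params.rt
    eb = lambda x: math.exp(-x / rt)
    ta = lambda i, j: terminal_penalty(s, i, j, params)
    a, b, c = (params.multiloop_closing, params.multiloop_branch,
               params.multiloop_unpaired)

    def can(i, j):
        return (s[i - 1], s[j - 1]) in PAIRABLE

    def intra(i, j):
        return j <= t or i > t

    Qb = [[0.0] * (N + 2) for _ in range(N + 2)]
    ZM = [[0.0] * (N + 2) for _ in range(N + 2)]

    # intra-strand tables (plain single-molecule recursions on each block)
    for d in range(MIN_HAIRPIN + 1, n):
        for i0 in range(1, n - d + 1):
            for off in (0, n):
                i, j = i0 + off, i0 + d + off
                if can(i, j):
                    q = eb(hairpin_energy(s, i, j, params))
                    kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 2)
                    for k in range(i + 1, kmax + 1):
                        l1 = k - i - 1
                        lmin = max(k + MIN_HAIRPIN + 1,
                                   j - 1 - (MAXLOOP - l1))
                        for l in range(lmin, j):
                            if Qb[k][l] > 0.0:
                                q += eb(interior_energy(s, i, j, k, l,
                                                        params)) * Qb[k][l]
                    qm = 0.0
                    for m in range(i + 2, j - 1):
                        if ZM[i + 1][m - 1] > 0.0:
                            zz = 0.0
                            for l in range(j - 1, m - 1, -1):
                                if Qb[m][l] > 0.0:
                                    zz += Qb[m][l] * eb(b + ta(m, l)) \
                                        * eb(c * (j - 1 - l))
                            qm += ZM[i + 1][m - 1] * zz
                    q += eb(a + b + ta(i, j)) * qm
                    Qb[i][j] = q
                zm = ZM[i + 1][j] * eb(c)
                for l in range(i + MIN_HAIRPIN + 1, j + 1):
                    if Qb[i][l] > 0.0:
                        zm += Qb[i][l] * eb(b + ta(i, l)) \
                            * (eb(c * (j - l)) + ZM[l + 1][j])
                ZM[i][j] = zm

    # exterior partition functions on each strand:
    # EL[x]: region [x..t] of strand 1; ER[y]: region [t+1..y] of strand 2
    # ZL1[x]: prefix [1..x] of strand 1; ZR2[y]: suffix [y..2n] of strand 2
    EL = [1.0] * (N + 3)
    for x in range(t, 0, -1):
        z = EL[x + 1]
        for l in range(x + 1, t + 1):
            if Qb[x][l] > 0.0:
                z += Qb[x][l] * eb(ta(x, l)) * EL[l + 1]
        EL[x] = z
    ER = [1.0] * (N + 3)
    for y in range(t + 1, N + 1):
        z = ER[y - 1]
        for k in range(t + 1, y):
            if Qb[k][y] > 0.0:
                z += ER[k - 1] * Qb[k][y] * eb(ta(k, y))
        ER[y] = z
    ZL1 = [1.0] * (N + 2)
    for j in range(1, t + 1):
        z = ZL1[j - 1]
        for k in range(1, j):
            if Qb[k][j] > 0.0:
                z += ZL1[k - 1] * Qb[k][j] * eb(ta(k, j))
        ZL1[j] = z
    ZR2 = [1.0] * (N + 3)
    for i in range(N, t, -1):
        z = ZR2[i + 1]
        for j in range(i + 1, N + 1):
            if Qb[i][j] > 0.0:
                z += Qb[i][j] * eb(ta(i, j)) * ZR2[j + 1]
        ZR2[i] = z
    z_mono = ZL1[n]

    # inter-strand pairs, ascending span
    spanning = [(i, j) for d in range(1, N)
                for i in range(max(1, t + 1 - d), t + 1)
                if (j := i + d) > t and j <= N and can(i, j)]
    spanning.sort(key=lambda p: p[1] - p[0])
    uml = lambda x, y: eb(c * (y - x + 1)) if y >= x else 1.0
    zm_of = lambda x, y: ZM[x][y] if y >= x else 0.0
    for (i, j) in spanning:
        # nick in the loop: exterior-type interior
        q = eb(ta(i, j)) * EL[i + 1] * ER[j - 1]
        # nick buried inside a spanning inner pair: normal interior loop
        kmax = min(i + MAXLOOP + 1, t)
        for k in range(i + 1, kmax + 1):
            l1 = k - i - 1
            lmin = max(t + 1, j - 1 - (MAXLOOP - l1))
            for l in range(lmin, j):
                if Qb[k][l] > 0.0:
                    q += eb(interior_energy(s, i, j, k, l, params)) * Qb[k][l]
        # multiloop with one spanning branch and >=1 intra-strand branch;
        # the closing pair's b is here, the spanning branch's b below
        base = eb(a + b + ta(i, j))
        for k in range(i + 1, t + 1):
            for l in range(t + 1, j):
                if Qb[k][l] > 0.0:
                    left = zm_of(i + 1, k - 1)
                    right = zm_of(l + 1, j - 1)
                    combos = (left * (uml(l + 1, j - 1) + right)
                              + uml(i + 1, k - 1) * right)
                    if combos > 0.0:
                        q += base * Qb[k][l] * eb(b + ta(k, l)) * combos
        Qb[i][j] = q

    z_inter = 0.0
    for (i, j) in spanning:
        if Qb[i][j] > 0.0:
            z_inter += ZL1[i - 1] * Qb[i][j] * eb(ta(i, j)) * ZR2[j + 1]
    if not (math.isfinite(z_inter) and math.isfinite(z_mono)):
        raise OverflowError("cofold partition function overflow")  # pragma: no cover
    return z_mono, z_inter


def cofold_homodimer(seq: RnaSequence, params: EnergyParameters,
                     monomer_ensemble: str = "all") -> DimerEquilibrium:
    """Monomer/homodimer equilibrium of a single self-interacting strand.

    monomer_ensemble: "all" uses the unconstrained single-strand
    ensemble for monomer_f; "hairpin" restricts it to single stem-loop
    structures (no multiloops, exactly one hairpin loop).
    """
    if len(seq) < 2:
        raise ValueError("cofold requires a sequence of length >= 2")
    if monomer_ensemble not in ("all", "hairpin"):
        raise ValueError(f"unknown monomer ensemble {monomer_ensemble!r}")
    rt = params.rt
    z_mono, z_inter = dimer_partition_function(seq, params)
    if monomer_ensemble == "hairpin":
        z_mono = _monomer_hairpin_z(seq.residues, params)
    monomer_f = -rt * math.log(z_mono) if z_mono > 0.0 else INF
    if z_inter > 0.0:
        dimer_f = (-rt * math.log(z_inter) + params.duplex_init
                   + params.symmetry_correction)
    else:
        dimer_f = INF
    if math.isinf(dimer_f):
        gap, k_dimer = INF, 0.0
    elif math.isinf(monomer_f):
        gap, k_dimer = -INF, INF
    else:
        gap = dimer_f - 2.0 * monomer_f
        k_dimer = math.exp(-gap / rt)
    return DimerEquilibrium(monomer_f=monomer_f, dimer_f=dimer_f,
                            gap=gap, k_dimer=k_dimer)
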