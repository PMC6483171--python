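"""Motif-constrained inverse design of monomer- or dimer-forming RNAs.

The objective is the dimerization gap dG = F_dimer - 2*F_monomer of the
ensemble free energies (see :mod:`dimerfold.cofold`): minimizing the gap
yields sequences with a strong propensity to homodimerize, maximizing
it yields sequences locked in the monomeric (hairpin) form.  The search
is simulated annealing over single-nucleotide substitutions at the
unconstrained positions, with Metropolis acceptance and geometric
cooling; the motif is expressed as per-position IUPAC classes so both
halves of a bipartite motif can be pinned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cofold import DimerEquilibrium, cofold_homodimer
from .core import RnaSequence
from .motifs import IUPAC
from .params import EnergyParameters

#: finite stand-in for the non-dimerizing +inf gap inside the annealer
_INF_SCORE = 1.0e6


class DesignError(ValueError):
    """Raised for infeasible design specifications."""


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule (temperatures in kcal/mol units)."""

    t_init: float = 1.0
    cooling: float = 0.999
    steps: int = 5000


@dataclass(frozen=True)
class DesignSpec:
    """Target length, pinned IUPAC classes, optimization mode and seed."""

    length: int
    fixed_positions: dict = field(default_factory=dict)  # 1-based -> IUPAC
    mode: str = "dimer"  # or "monomer"
    seed: int = 0
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    monomer_ensemble: str = "all"

    def __post_init__(self):
        if self.mode not in ("monomer", "dimer"):
            raise DesignError(f"unknown mode {self.mode!r}")
        if self.length < 2:
            raise DesignError("design length must be >= 2")
        allowed = {}
        for pos, code in self.fixed_positions.items():
            pos = int(pos)
            if not 1 <= pos <= self.length:
                raise DesignError(f"fixed position {pos} outside 1..{self.length}")
            code = str(code).upper().replace("T", "U")
            if code not in IUPAC:
                raise DesignError(f"invalid IUPAC code {code!r} at {pos}")
            allowed[pos] = IUPAC[code]
        object.__setattr__(self, "fixed_positions",
                           {p: c for p, c in sorted(self.fixed_positions.items())})
        mutable = [p for p in range(1, self.length + 1)
                   if len(allowed.get(p, "ACGU")) > 1]
        if not mutable:
            raise DesignError("no free position: every residue is fully pinned")

    def allowed_bases(self, pos: int) -> str:
        code = self.fixed_positions.get(pos, "N")
        return IUPAC[str(code).upper()]

    def satisfied_by(self, seq: RnaSequence) -> bool:
        return len(seq) == self.length and all(
            seq[p] in self.allowed_bases(p) for p in range(1, self.length + 1))


@dataclass(frozen=True)
class DesignResult:
    sequence: RnaSequence
    equilibrium: DimerEquilibrium
    trajectory: tuple  # per-step objective (gap, kcal/mol; +inf sentinel kept)
    accepted_steps: int


def objective(seq: RnaSequence, mode: str,
              params: EnergyParameters,
              monomer_ensemble: str = "all") -> float:
    """The dimerization gap (kcal/mol); +inf for a non-dimerizing sequence.

    The optimizer minimizes the gap in dimer mode and maximizes it in
    monomer mode; the value returned here is always the raw gap.
    """
    eq = cofold_homodimer(seq, params, monomer_ensemble=monomer_ensemble)
    return eq.gap


def _score(gap: float, mode: str) -> float:
    g = max(min(gap, _INF_SCORE), -_INF_SCORE)
    return g if mode == "dimer" else -g


def design_sequence(spec: DesignSpec,
                    params: EnergyParameters) -> DesignResult:
    """Simulated-annealing search; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    allowed = [spec.allowed_bases(p) for p in range(1, n + 1)]
    mutable = [p for p in range(n) if len(allowed[p]) > 1]

    state = [al[rng.integers(len(al))] for al in allowed]
    cache: dict = {}

    def gap_of(letters) -> float:
        key = "".join(letters)
        if key not in cache:
            cache[key] = objective(RnaSequence("candidate", key), spec.mode,
                                   params, spec.monomer_ensemble)
        return cache[key]

    cur_gap = gap_of(state)
    best_state, best_gap = list(state), cur_gap
    best_score = _score(best_gap, spec.mode)
    trajectory = [cur_gap]
    accepted = 0
    temp = spec.schedule.t_init
    for _ in range(spec.schedule.steps):
        p = mutable[rng.integers(len(mutable))]
        choices = [bs for bs in allowed[p] if bs != state[p]]
        nb = choices[rng.integers(len(choices))]
        old = state[p]
        state[p] = nb
        new_gap = gap_of(state)
        delta = _score(new_gap, spec.mode) - _score(cur_gap, spec.mode)
        if delta <= 0.0 or (temp > 0.0
                            and rng.random() < math.exp(-delta / temp)):
            cur_gap = new_gap
            accepted += 1
            score = _score(cur_gap, spec.mode)
            if score < best_score:
                best_score, best_gap = score, cur_gap
                best_state = list(state)
        else:
            state[p] = old
        trajectory.append(cur_gap)
        temp *= spec.schedule.cooling

    seq = RnaSequence("design", "".join(best_state))
    eq = cofold_homodimer(seq, params, monomer_ensemble=spec.monomer_ensemble)
    return DesignResult(sequence=seq, equilibrium=eq,
                        trajectory=tuple(trajectory),
                        accepted_steps=accepted)


def read_design_spec(path) -> DesignSpec:
    """Read a key=value design spec file.

    Keys: length, mode, seed, motif (an IUPAC string anchored at
    position given by motif_start, default 1), t_init, cooling, steps.
    """
    from pathlib import Path

    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DesignError(f"malformed spec line {line!r}")
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    if "length" not in kv:
        raise DesignError("design spec must give length=")
    length = int(kv["length"])
    fixed = {}
    if "motif" in kv:
        start = int(kv.get("motif_start", 1))
        for off, ch in enumerate(kv["motif"].upper().replace("T", "U")):
            if ch != "N":
                fixed[start + off] = ch
    schedule = AnnealSchedule(
        t_init=float(kv.get("t_init", AnnealSchedule.t_init)),
        cooling=float(kv.get("cooling", AnnealSchedule.cooling)),
        steps=int(kv.get("steps", AnnealSchedule.steps)))
    return DesignSpec(length=length, fixed_positions=fixed,
                      mode=kv.get("mode", "dimer"),
                      seed=int(kv.get("seed", 0)), schedule=schedule,
                      monomer_ensemble=kv.get("monomer_ensemble", "all"))
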