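"""SHAPE reactivity handling and reactivity-constrained folding.

Reactivities report per-residue backbone flexibility: a highly
reactive residue is almost certainly unpaired.  Residues are classed
high (reactivity >= 0.85), moderate (>= 0.4, < 0.85) or weak (< 0.4),
with both lower bounds inclusive; missing values are unconstrained.

Two folding modes are offered: ``hard`` forces high-reactivity
residues unpaired; ``pseudo`` adds the Deigan-style pseudo-free-energy
m*ln(reactivity + 1) + b to every paired residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .core import RnaSequence
from .fold import ConstraintError, FoldResult, fold_mfe
from .params import EnergyParameters

HIGH_THRESHOLD = 0.85
MODERATE_THRESHOLD = 0.4

#: default slope/intercept (kcal/mol) of the pseudo-free-energy term
DEFAULT_M = 2.6
DEFAULT_B = -0.8


@dataclass(frozen=True)
class ShapeProfile:
    """Per-residue reactivities (None = missing) with class labels."""

    reactivity: tuple  # floats >= 0 or None

    def __post_init__(self):
        vals = []
        for i, r in enumerate(self.reactivity, start=1):
            if r is None or (isinstance(r, float) and math.isnan(r)):
                vals.append(None)
            else:
                r = float(r)
                if r < 0:
                    raise ConstraintError(
                        f"negative reactivity {r} at position {i}")
                vals.append(r)
        object.__setattr__(self, "reactivity", tuple(vals))

    def __len__(self):
        return len(self.reactivity)

    @property
    def classes(self) -> tuple:
        out = []
        for r in self.reactivity:
            if r is None:
                out.append("missing")
            elif r >= HIGH_THRESHOLD:
                out.append("high")
            elif r >= MODERATE_THRESHOLD:
                out.append("moderate")
            else:
                out.append("weak")
        return tuple(out)


def classify_shape(reactivities) -> ShapeProfile:
    """Build a ShapeProfile from an iterable of reactivities/None."""
    return ShapeProfile(reactivity=tuple(reactivities))


def read_shape_file(path) -> ShapeProfile:
    """Two-column text: position, reactivity ('NA' or negative = missing).

    Positions must be 1..n in order; a -999-style sentinel or 'NA'
    marks a missing value.
    """
    values = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ConstraintError(f"malformed reactivity line {lineno}")
        pos = int(fields[0])
        raw = fields[1]
        if raw.upper() in ("NA", "NAN") or float(raw) < 0:
            values[pos] = None
        else:
            values[pos] = float(raw)
    n = max(values) if values else 0
    return ShapeProfile(reactivity=tuple(values.get(i) for i in range(1, n + 1)))


def fold_with_shape(seq: RnaSequence, profile: ShapeProfile,
                    params: EnergyParameters, mode: str = "pseudo",
                    m: float = DEFAULT_M, b: float = DEFAULT_B) -> FoldResult:
    """Fold under SHAPE constraints.

    hard: residues classed high are forced unpaired.  pseudo: penalty
    m*ln(r+1)+b per paired residue with measured reactivity r.
    """
    if len(profile) != len(seq):
        raise ConstraintError(
            f"profile length {len(profile)} != sequence length {len(seq)}")
    if mode == "hard":
        mask = [cls != "high" for cls in profile.classes]
        return fold_mfe(seq, params, constraints=mask)
    if mode == "pseudo":
        pseudo = [0.0 if r is None else m * math.log(r + 1.0) + b
                  for r in profile.reactivity]
        return fold_mfe(seq, params, pseudo=pseudo)
    raise ConstraintError(f"unknown SHAPE mode {mode!r}")
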