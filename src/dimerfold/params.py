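"""Nearest-neighbor energy parameter tables.

Parameters are bundled as a versioned plain-text TSV resource and loaded
deterministically; a missing entry is a load-time error, never a silent
zero. Free energies are kcal/mol at the table's reference temperature
(37 C for the bundled Turner 2004 set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

GAS_CONSTANT = 1.98717e-3  # kcal/(mol*K)

_PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")


class ParameterError(ValueError):
    """Raised for unknown or incomplete parameter sets."""


@dataclass(frozen=True)
class EnergyParameters:
    """A complete reduced nearest-neighbor parameter set.

    stack maps ("XY", "ZW") -> kcal/mol for the helix step with outer
    pair X-Y and inner pair Z-W (5'-XZ-3' / 3'-YW-5').  Loop initiation
    maps are keyed by loop size and extended logarithmically beyond the
    largest tabulated size (Jacobson-Stockmayer, coefficient 1.75*RT).
    """

    name: str
    temperature: float  # kelvin
    stack: dict
    hairpin_init: dict
    bulge_init: dict
    internal_init: dict
    multiloop_closing: float  # a
    multiloop_branch: float   # b, applied per branch incl. the closing one
    multiloop_unpaired: float  # c, per unpaired residue in a multiloop
    terminal_au: float
    duplex_init: float
    #: +RT ln 2 correction for indistinguishable strands in a homodimer;
    #: switchable at the cofold call site.
    symmetry_correction: float = field(default=0.0)

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature

    def _loop_init(self, table: dict, size: int) -> float:
        if size in table:
            return table[size]
        lmax = max(table)
        if size < min(table):
            raise ParameterError(f"loop size {size} below tabulated range")
        return table[lmax] + 1.75 * self.rt * math.log(size / lmax)

    def hairpin(self, size: int) -> float:
        return self._loop_init(self.hairpin_init, size)

    def bulge(self, size: int) -> float:
        return self._loop_init(self.bulge_init, size)

    def internal(self, size: int) -> float:
        return self._loop_init(self.internal_init, size)

    def terminal_penalty(self, b1: str, b2: str) -> float:
        """Terminal penalty for a helix end closed by A-U or G-U."""
        return self.terminal_au if {b1, b2} in ({"A", "U"}, {"G", "U"}) else 0.0


def _validate(name, stack, hairpin, bulge, internal, ml, misc):
    missing = []
    for ab in _PAIR_TYPES:
        for cd in _PAIR_TYPES:
            if (ab, cd) not in stack:
                missing.append(f"stack {ab}:{cd}")
    for tname, table, lo in (("hairpin", hairpin, 3), ("bulge", bulge, 1),
                             ("internal", internal, 2)):
        for size in range(lo, 31):
            if size not in table:
                missing.append(f"{tname} {size}")
        if any(v < 0 for v in table.values()):
            raise ParameterError(f"{name}: negative {tname} initiation term")
    for key in ("closing", "branch", "unpaired"):
        if key not in ml:
            missing.append(f"multiloop {key}")
    for key in ("terminal_au", "duplex_init"):
        if key not in misc:
            missing.append(f"misc {key}")
    if missing:
        raise ParameterError(
            f"parameter set {name!r} incomplete; missing: " + ", ".join(missing))


def load_parameters(resource: str = "turner2004-reduced",
                    temperature: float = 310.15,
                    symmetry_correction: bool = True) -> EnergyParameters:
    """Load a named bundled parameter set.

    temperature only sets RT for ensemble computations; the tabulated
    free energies themselves are at the table's reference temperature.
    """
    fname = f"{resource}.tsv"
    root = resources.files("dimerfold.data")
    if not (root / fname).is_file():
        raise ParameterError(f"unknown parameter set {resource!r}")
    stack, hairpin, bulge, internal = {}, {}, {}, {}
    ml, misc = {}, {}
    for line in (root / fname).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "stack":
            stack[(fields[1], fields[2])] = float(fields[3])
        elif kind in ("hairpin", "bulge", "internal"):
            {"hairpin": hairpin, "bulge": bulge,
             "internal": internal}[kind][int(fields[1])] = float(fields[2])
        elif kind == "multiloop":
            ml[fields[1]] = float(fields[2])
        elif kind == "misc":
            misc[fields[1]] = float(fields[2])
        else:
            raise ParameterError(f"unrecognized record {kind!r}")
    _validate(resource, stack, hairpin, bulge, internal, ml, misc)
    rt = GAS_CONSTANT * temperature
    return EnergyParameters(
        name=resource,
        temperature=temperature,
        stack=stack,
        hairpin_init=hairpin,
        bulge_init=bulge,
        internal_init=internal,
        multiloop_closing=ml["closing"],
        multiloop_branch=ml["branch"],
        multiloop_unpaired=ml["unpaired"],
        terminal_au=misc["terminal_au"],
        duplex_init=misc["duplex_init"],
        symmetry_correction=rt * math.log(2.0) if symmetry_correction else 0.0,
    )
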