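"""3D analysis of RNA duplex coordinates.

Reads PDB/mmCIF models (via gemmi), detects base pairs with a
distance-plus-planarity hydrogen-bond heuristic, measures C1'-C1'
distances and lambda angles, fits a global straight helix axis (first
principal direction of the C1'-C1' midpoints) and reports per-step
rise and twist against it, and performs Kabsch least-squares
superposition.  A deterministic ideal A-form fixture generator
supports parameter-recovery tests.

The straight-axis choice is a deliberate simplification relative to
per-step local axes (3DNA-style): for nearly straight oligomer
duplexes the global axis reproduces rise to ~0.1 A and twist to ~1 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .core import RnaSequence
from .duplex import pair_label

RNA_BASES = {"A", "C", "G", "U"}
PURINES = {"A", "G"}
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}
#: base nitrogen/oxygen atoms that can donate/accept hydrogen bonds
POLAR_BASE_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}
#: ring (plus exocyclic) atoms used for base-plane fitting
PLANE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

HBOND_MAX = 3.5          # A, donor-acceptor cutoff
PLANE_MAX_ANGLE = 30.0   # deg, max angle between base planes
STACK_MAX_RISE = 1.5     # A, max out-of-plane offset of a contact vector
#                          (discriminates in-plane hydrogen bonds from
#                          stacking contacts, which run along the normal)

A_FORM_RISE = 2.81
A_FORM_TWIST = 32.7


class StructureError(ValueError):
    """Raised for unreadable or unusable coordinate input."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    chain: str
    number: int
    base: str
    atoms: dict             # atom name -> Atom (post altloc policy)
    alt_atoms: dict = field(default_factory=dict)  # (name, altloc) -> Atom

    def coord(self, name: str) -> np.ndarray:
        if name not in self.atoms:
            raise KeyError(f"{self.chain}{self.number}{self.base}: no {name}")
        return self.atoms[name].coord

    def has(self, *names) -> bool:
        return all(n in self.atoms for n in names)

    @property
    def glyc_n(self) -> str:
        return GLYCOSIDIC_N[self.base]

    def altloc_labels(self) -> tuple:
        labels = sorted({al for (_, al) in self.alt_atoms if al})
        return tuple(labels) if labels else ("",)

    def coord_alt(self, name: str, altloc: str) -> np.ndarray:
        """Coordinate of ``name`` preferring the given altloc label."""
        for key in ((name, altloc), (name, "")):
            if key in self.alt_atoms:
                return self.alt_atoms[key].coord
        return self.coord(name)


@dataclass
class Structure3D:
    """Polymer RNA residues by chain, with waters/ions listed separately."""

    name: str
    chains: dict            # chain id -> list of Residue (by number)
    hetero: list = field(default_factory=list)  # (chain, number, name)

    def residues(self) -> list:
        return [r for cid in sorted(self.chains) for r in self.chains[cid]]


def _apply_altloc(groups: dict, policy: str) -> dict:
    """groups: name -> list of Atom variants; returns name -> Atom."""
    chosen = {}
    for name, variants in groups.items():
        if len(variants) == 1:
            chosen[name] = variants[0]
        elif policy == "highest_occupancy":
            chosen[name] = max(variants,
                               key=lambda a: (a.occupancy, -ord(a.altloc or "~")))
        elif policy.startswith("label:"):
            want = policy.split(":", 1)[1]
            match = [a for a in variants if a.altloc in ("", want)]
            chosen[name] = match[0] if match else variants[0]
        else:
            raise StructureError(f"unknown altloc policy {policy!r}")
    return chosen


def read_structure(path, fmt: str | None = None,
                   altloc_policy: str = "highest_occupancy") -> Structure3D:
    """Read PDB or mmCIF coordinates into a Structure3D.

    Polymer RNA residues (A/C/G/U) are retained for analysis; waters,
    ions and other heterogens are listed in ``hetero``.  Residues
    lacking a C1' atom are excluded from the chains with a warning.
    """
    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise StructureError(f"cannot read structure file {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unreadable structure file {path}: {exc}")
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    chains: dict = {}
    hetero = []
    for chain in model:
        for res in chain:
            rname = res.name.strip()
            if rname in RNA_BASES:
                groups: dict = {}
                for atom in res:
                    al = atom.altloc
                    if al in ("\x00", " "):
                        al = ""
                    a = Atom(name=atom.name, element=atom.element.name,
                             xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                             occupancy=atom.occ, altloc=al)
                    groups.setdefault(atom.name, []).append(a)
                alt = {(a.name, a.altloc): a
                       for v in groups.values() for a in v}
                residue = Residue(chain=chain.name, number=res.seqid.num,
                                  base=rname,
                                  atoms=_apply_altloc(groups, altloc_policy),
                                  alt_atoms=alt)
                if "C1'" not in residue.atoms:
                    import warnings
                    warnings.warn(f"residue {chain.name}{res.seqid.num} "
                                  f"lacks C1'; excluded from geometry")
                    continue
                chains.setdefault(chain.name, []).append(residue)
            else:
                hetero.append((chain.name, res.seqid.num, rname))
    for cid in chains:
        chains[cid].sort(key=lambda r: r.number)
    return Structure3D(name=st.name or path.stem, chains=chains,
                       hetero=hetero)


def _base_plane(res: Residue):
    """(centroid, unit normal) of the base plane by SVD."""
    coords = np.array([res.coord(a) for a in PLANE_ATOMS[res.base]
                       if a in res.atoms])
    if coords.shape[0] < 3:
        return None
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _hbond_contacts(r1: Residue, r2: Residue, normal: np.ndarray) -> list:
    out = []
    for a1 in POLAR_BASE_ATOMS[r1.base]:
        if a1 not in r1.atoms:
            continue
        c1 = r1.coord(a1)
        for a2 in POLAR_BASE_ATOMS[r2.base]:
            if a2 not in r2.atoms:
                continue
            v = r2.coord(a2) - c1
            d = float(np.linalg.norm(v))
            if d <= HBOND_MAX and abs(float(v @ normal)) <= STACK_MAX_RISE:
                out.append((a1, a2, d))
    return out


@dataclass(frozen=True)
class BasePairGeometry:
    """Measured geometry of one detected (or asserted) base pair."""

    res1: Residue
    res2: Residue
    c1_c1: float
    lambda1: float  # deg, at res1's C1'
    lambda2: float
    hbond_count: int
    label: str
    altloc: tuple = ("", "")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.res1.coord("C1'") + self.res2.coord("C1'"))

    @property
    def c1_vector(self) -> np.ndarray:
        return self.res2.coord("C1'") - self.res1.coord("C1'")


def _angle(v1: np.ndarray, v2: np.ndarray) -> float:
    cosv = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def pair_geometry(r1: Residue, r2: Residue,
                  hbond_count: int | None = None,
                  altloc: tuple = ("", "")) -> BasePairGeometry:
    """C1'-C1' distance and lambda angles for an opposed residue pair.

    altloc selects alternate-location coordinates per residue for
    statically disordered pairs; the default uses the policy-selected
    coordinates.
    """
    for r in (r1, r2):
        if not r.has("C1'", r.glyc_n):
            raise StructureError(
                f"residue {r.chain}{r.number} lacks C1'/{r.glyc_n}")
    a1, a2 = altloc
    c1 = r1.coord_alt("C1'", a1)
    c2 = r2.coord_alt("C1'", a2)
    n1 = r1.coord_alt(r1.glyc_n, a1)
    n2 = r2.coord_alt(r2.glyc_n, a2)
    vec = c2 - c1
    lam1 = _angle(n1 - c1, vec)
    lam2 = _angle(n2 - c2, -vec)
    if hbond_count is None:
        plane = _base_plane(r1)
        normal = plane[1] if plane else np.array([0.0, 0.0, 1.0])
        hbond_count = len(_hbond_contacts(r1, r2, normal))
    return BasePairGeometry(res1=r1, res2=r2,
                            c1_c1=float(np.linalg.norm(vec)),
                            lambda1=lam1, lambda2=lam2,
                            hbond_count=hbond_count,
                            label=pair_label(r1.base, r2.base),
                            altloc=altloc)


def pair_geometry_altlocs(r1: Residue, r2: Residue) -> dict:
    """Per-altloc-combination geometry for a disordered pair."""
    out = {}
    for a1 in r1.altloc_labels():
        for a2 in r2.altloc_labels():
            out[(a1, a2)] = pair_geometry(r1, r2, altloc=(a1, a2))
    return out


def detect_pairs(structure: Structure3D) -> list:
    """Detect base pairs by hydrogen-bond geometry.

    Residues pair when they share >= 2 donor-acceptor contacts within
    3.5 A whose vectors lie within the base planes, and the two base
    planes are within 30 degrees of parallel.  Each residue joins at
    most one pair (greedy by contact count, ties by distance); pairs
    are returned ordered along the first chain 5'->3'.
    """
    residues = structure.residues()
    planes = {id(r): _base_plane(r) for r in residues}
    candidates = []
    for i, r1 in enumerate(residues):
        for r2 in residues[i + 1:]:
            if r1.chain == r2.chain and abs(r1.number - r2.number) <= 1:
                continue
            p1, p2 = planes[id(r1)], planes[id(r2)]
            if p1 is None or p2 is None:
                continue
            ang = _angle(p1[1], p2[1])
            if min(ang, 180.0 - ang) > PLANE_MAX_ANGLE:
                continue
            normal = p1[1]
            contacts = _hbond_contacts(r1, r2, normal)
            if len(contacts) < 2:
                continue
            dmin = min(c[2] for c in contacts)
            candidates.append((len(contacts), -dmin, r1, r2))
    candidates.sort(key=lambda c: (-c[0], -c[1],
                                   c[2].chain, c[2].number))
    used = set()
    pairs = []
    for nb, _, r1, r2 in candidates:
        if id(r1) in used or id(r2) in used:
            continue
        used.update((id(r1), id(r2)))
        pairs.append(pair_geometry(r1, r2, hbond_count=nb))
    pairs.sort(key=lambda p: (p.res1.chain, p.res1.number))
    return pairs


@dataclass(frozen=True)
class HelixFrame:
    """Global straight helix axis with per-step rise and twist."""

    axis: tuple     # unit vector
    point: tuple    # a point on the axis (midpoint centroid)
    rise_per_step: tuple
    twist_per_step: tuple

    @property
    def mean_rise(self) -> float:
        return float(np.mean(self.rise_per_step))

    @property
    def mean_twist(self) -> float:
        return float(np.mean(self.twist_per_step))


def fit_helix(pairs) -> HelixFrame:
    """Fit a straight axis through the C1'-C1' midpoints of ``pairs``.

    The axis is the first principal direction of the midpoints,
    oriented 5'->3' along the pair order.  rise_i projects consecutive
    midpoint steps onto the axis; twist_i is the signed angle about
    the axis between consecutive C1'->C1' vectors projected onto the
    plane normal to it.
    """
    if len(pairs) < 2:
        raise StructureError("helix fit requires >= 2 base pairs")
    mids = np.array([p.midpoint for p in pairs])
    centroid = mids.mean(axis=0)
    _, _, vt = np.linalg.svd(mids - centroid)
    axis = vt[0]
    if axis @ (mids[-1] - mids[0]) < 0:
        axis = -axis
    rises = [float((mids[k + 1] - mids[k]) @ axis)
             for k in range(len(pairs) - 1)]
    twists = []
    for k in range(len(pairs) - 1):
        v1 = pairs[k].c1_vector
        v2 = pairs[k + 1].c1_vector
        p1 = v1 - (v1 @ axis) * axis
        p2 = v2 - (v2 @ axis) * axis
        sin = float(np.cross(p1, p2) @ axis)
        cos = float(p1 @ p2)
        twists.append(math.degrees(math.atan2(sin, cos)))
    return HelixFrame(axis=tuple(axis), point=tuple(centroid),
                      rise_per_step=tuple(rises),
                      twist_per_step=tuple(twists))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(float(m1 @ n2), float(n1 @ n2)))


def glycosidic_conformation(res: Residue) -> str:
    """'syn' or 'anti' from the chi torsion O4'-C1'-N9-C4 (purines) or
    O4'-C1'-N1-C2 (pyrimidines); syn iff chi in (-90, +90]."""
    if res.base in PURINES:
        names = ("O4'", "C1'", "N9", "C4")
    else:
        names = ("O4'", "C1'", "N1", "C2")
    if not res.has(*names):
        raise StructureError(
            f"residue {res.chain}{res.number} lacks chi atoms {names}")
    chi = dihedral(*(res.coord(n) for n in names))
    return "syn" if -90.0 < chi <= 90.0 else "anti"


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition of P onto Q (rows are atoms).

    Returns (rmsd, rotation, translation) with a proper rotation
    (determinant +1); no scaling.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError("superposition needs equal-size (n,3) selections")
    if P.shape[0] < 3:
        raise StructureError("superposition needs >= 3 atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return rmsd, R, t


def kabsch_rmsd(a, b, mapping=None) -> float:
    """RMSD after optimal rigid superposition.

    a/b: (n,3) arrays, or Structure3D objects with ``mapping`` a list
    of ((chain, resnum, atom), (chain, resnum, atom)) correspondences.
    """
    if isinstance(a, Structure3D):
        if mapping is None:
            raise StructureError("Structure3D input requires a mapping")
        index_a = {(r.chain, r.number): r for r in a.residues()}
        index_b = {(r.chain, r.number): r for r in b.residues()}
        P = np.array([index_a[(c, n)].coord(at) for (c, n, at), _ in mapping])
        Q = np.array([index_b[(c, n)].coord(at) for _, (c, n, at) in mapping])
    else:
        P, Q = a, b
    return kabsch_superpose(P, Q)[0]


# ---------------------------------------------------------------------------
# ideal A-form fixture generation

_GLYC_LEN = 1.48
_LAMBDA = 54.0  # deg
_C1_HALF = 5.25  # A; C1'-C1' distance 10.5

#: Watson-Crick-edge atoms presented toward the partner, by base:
#: (outer-level atom at y=2.9, inner-level atom at y=0.35)
_EDGE_ATOMS = {"A": ("N6", "N1"), "G": ("O6", "N1"),
               "C": ("N4", "N3"), "U": ("O4", "N3")}
#: in-plane filler atoms completing the base plane
_FILLER = {"A": (("C4", -3.5, 1.3), ("C5", -2.8, 1.9), ("C8", -4.6, 2.4)),
           "G": (("C4", -3.5, 1.3), ("C5", -2.8, 1.9), ("C8", -4.6, 2.4)),
           "C": (("C2", -3.8, 0.6), ("C4", -2.7, 1.9), ("C6", -4.4, 2.3)),
           "U": (("C2", -3.8, 0.6), ("C4", -2.7, 1.9), ("C6", -4.4, 2.3))}

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _template(base: str, side: int) -> dict:
    """In-plane atom template; side 1 is the -x strand, side 2 mirrored."""
    lam = math.radians(_LAMBDA)
    c1 = np.array([-_C1_HALF, 0.0, 0.0])
    ng = c1 + _GLYC_LEN * np.array([math.cos(lam), math.sin(lam), 0.0])
    outer, inner = _EDGE_ATOMS[base]
    atoms = {
        "C1'": c1,
        GLYCOSIDIC_N[base]: ng,
        outer: np.array([-1.45, 2.9, 0.0]),
        inner: np.array([-1.41, 0.35, 0.0]),
        "P": np.array([-8.0, -1.5, 1.2]),
    }
    for name, x, y in _FILLER[base]:
        atoms.setdefault(name, np.array([x, y, 0.0]))
    if side == 2:
        atoms = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in atoms.items()}
    return atoms


def make_ideal_aform(seq: RnaSequence, rise: float = A_FORM_RISE,
                     twist: float = A_FORM_TWIST,
                     partner: str = "revcomp") -> Structure3D:
    """Deterministic idealized duplex on a straight vertical axis.

    partner="revcomp" opposes each base with its Watson-Crick
    complement; partner="self" opposes the sequence with a second copy
    of itself in the blunt antiparallel register (as in a
    self-complementary homodimer), whatever mismatches that implies.
    Pair planes are stacked ``rise`` apart and rotated ``twist``
    degrees per step; chain A runs 5'->3' up the axis, chain B
    antiparallel.
    """
    n = len(seq)
    chains = {"A": [], "B": []}
    for t in range(n):
        b1 = seq[t + 1]
        b2 = (WC_COMPLEMENT[b1] if partner == "revcomp"
              else seq[n - t])
        ang = math.radians(twist * t)
        rot = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                        [math.sin(ang), math.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        shift = np.array([0.0, 0.0, rise * t])
        for side, base, chain_id, number in ((1, b1, "A", t + 1),
                                             (2, b2, "B", n - t)):
            atoms = {}
            for name, xyz in _template(base, side).items():
                pos = rot @ xyz + shift
                atoms[name] = Atom(name=name, element=name[0],
                                   xyz=tuple(round(float(v), 3)
                                             for v in pos))
            chains[chain_id].append(Residue(
                chain=chain_id, number=number, base=base, atoms=atoms,
                alt_atoms={(a.name, ""): a for a in atoms.values()}))
    chains["B"].sort(key=lambda r: r.number)
    return Structure3D(name=f"ideal_aform_{seq.id}", chains=chains)


def write_pdb(structure: Structure3D, path) -> None:
    """Write a Structure3D as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.name
    model = gemmi.Model("1")
    for cid in sorted(structure.chains):
        chain = gemmi.Chain(cid)
        for res in structure.chains[cid]:
            g = gemmi.Residue()
            g.name = res.base
            g.seqid = gemmi.SeqId(res.number, " ")
            for (name, altloc), atom in sorted(res.alt_atoms.items()):
                ga = gemmi.Atom()
                ga.name = name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                ga.occ = atom.occupancy
                if altloc:
                    ga.altloc = altloc
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
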