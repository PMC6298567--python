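"""Coordinate-level k-turn classification.

Given atomic coordinates and a mapping of residues onto the k-turn
nomenclature, this module detects hydrogen bonds, classifies base-pair
geometry (cis/trans, interacting edges), assigns the N1/N3 core class
from the acceptor of the -1n O2' donor on A2b, and measures the
interhelical kink angle.  A tightly kinked k-turn kinks the helical
axes by about 50 degrees (``REFERENCE_KINK_ANGLE``).

Geometric conventions (documented and test-pinned):

* H-bond: donor-acceptor distance <= 3.5 A; when the donor's covalent
  antecedent is present, the antecedent-donor-acceptor angle must be
  >= 120 deg (crystal structures lack hydrogens, so the angle test is
  skipped when no antecedent geometry exists).
* cis/trans: sign of the dot product of the two glycosidic-bond
  vectors' components perpendicular to the C1'-C1' pair axis
  (Leontis-Westhof sense): same side = cis, opposite = trans.
* Kink angle: one principal axis fitted per helix through backbone P
  atoms (fallback C1'), both oriented 5'->3' along the strand order, so
  two coaxial stacked helices read 0 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "HBond",
    "PairGeometryClass",
    "KTurnStructureClass",
    "StructureAnnotation",
    "DONOR_ACCEPTOR_TABLE",
    "REFERENCE_KINK_ANGLE",
    "detect_hbonds",
    "classify_pair_geometry",
    "assign_n_class",
    "kink_angle",
    "load_structure",
    "read_label_map",
]

REFERENCE_KINK_ANGLE = 50.0  # degrees, canonical tightly kinked value

HBOND_DISTANCE_MAX = 3.5  # Angstrom, donor-acceptor
HBOND_ANGLE_MIN = 120.0   # degrees at the donor, when computable

ResidueKey = tuple[str, int]          # (chain, residue number)
AtomKey = tuple[str, int, str]        # (chain, residue number, atom name)


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    xyz: tuple[float, float, float]

    @property
    def key(self) -> AtomKey:
        return (self.chain, self.resnum, self.name)

    @property
    def residue(self) -> ResidueKey:
        return (self.chain, self.resnum)


@dataclass
class StructureModel:
    """A flat atom list with unique (chain, residue, atom) keys."""

    atoms: list[Atom]
    _index: dict[AtomKey, Atom] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.xyz):
                raise ValueError(f"non-finite coordinates for {a.key}")
            if a.key in self._index:
                raise ValueError(f"duplicate atom key {a.key}")
            self._index[a.key] = a

    def get(self, chain: str, resnum: int, name: str) -> Atom | None:
        return self._index.get((chain, resnum, name))

    def residue_atoms(self, residue: ResidueKey) -> list[Atom]:
        return [a for a in self.atoms if a.residue == residue]

    def residue_name(self, residue: ResidueKey) -> str | None:
        for a in self.atoms:
            if a.residue == residue:
                return a.resname
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Rigid-body copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return StructureModel([
            Atom(a.chain, a.resnum, a.resname, a.name,
                 tuple((R @ np.array(a.xyz) + t).tolist()))
            for a in self.atoms
        ])


@dataclass(frozen=True)
class HBond:
    donor: AtomKey
    acceptor: AtomKey
    distance: float
    donor_angle: float | None  # degrees; None when no antecedent geometry

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError("H-bond distance must be positive")


@dataclass
class PairGeometryClass:
    residues: tuple[ResidueKey, ResidueKey]
    label: str  # trans-sugar-Hoogsteen | cis single-H-bond |
                # trans single-H-bond | cis-Watson-Crick | unclassified
    hbonds: list[HBond]
    reason: str = ""

    _LABELS = {"trans-sugar-Hoogsteen", "cis single-H-bond",
               "trans single-H-bond", "cis-Watson-Crick", "unclassified"}

    def __post_init__(self) -> None:
        if self.label not in self._LABELS:
            raise ValueError(f"invalid pair-geometry label {self.label!r}")
        if self.label != "unclassified" and not self.hbonds:
            raise ValueError("classified pair must carry supporting H-bonds")


@dataclass
class KTurnStructureClass:
    n_class: str  # N1 | N3 | unclassified
    l1_o2p_to_a1n_n1: bool
    m1n_o2p_acceptor: str | None  # atom name on the 2b residue, if bonded
    kink_angle_degrees: float | None
    reference_kinked_angle: float = REFERENCE_KINK_ANGLE
    hbonds: list[HBond] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Chemistry table: H-bond donors (with covalent antecedent) and acceptors
# ---------------------------------------------------------------------------

#: per residue type: donors as (atom, antecedent), acceptors as atom names.
#: O2' appears for every ribonucleotide (donor and acceptor).
DONOR_ACCEPTOR_TABLE: Mapping[str, dict[str, list]] = {
    "A": {"donors": [("N6", "C6"), ("O2'", "C2'")],
          "acceptors": ["N1", "N3", "N7", "O2'"]},
    "G": {"donors": [("N1", "C2"), ("N2", "C2"), ("O2'", "C2'")],
          "acceptors": ["N3", "N7", "O6", "O2'"]},
    "C": {"donors": [("N4", "C4"), ("O2'", "C2'")],
          "acceptors": ["N3", "O2", "O2'"]},
    "U": {"donors": [("N3", "C2"), ("O2'", "C2'")],
          "acceptors": ["O2", "O4", "O2'"]},
}

#: Leontis-Westhof interacting-edge membership per base
WC_EDGE = {"A": {"N1", "N6"}, "G": {"N1", "N2", "O6"},
           "C": {"N3", "N4", "O2"}, "U": {"N3", "O2", "O4"}}
HOOGSTEEN_EDGE = {"A": {"N6", "N7"}, "G": {"O6", "N7"},
                  "C": {"N4"}, "U": {"O4"}}
SUGAR_EDGE = {"A": {"N3", "O2'"}, "G": {"N2", "N3", "O2'"},
              "C": {"O2", "O2'"}, "U": {"O2", "O2'"}}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of the a-b-c triple."""
    u, v = a - b, c - b
    cosv = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def detect_hbonds(structure: StructureModel,
                  donor_acceptor_table: Mapping = DONOR_ACCEPTOR_TABLE,
                  max_distance: float = HBOND_DISTANCE_MAX,
                  min_angle: float = HBOND_ANGLE_MIN,
                  same_residue: bool = False) -> list[HBond]:
    """All donor-acceptor contacts meeting the geometric criteria.

    Distance <= ``max_distance``; when the donor antecedent atom exists,
    antecedent-donor-acceptor angle >= ``min_angle``.  Residue types
    absent from the table are skipped with a warning.  The result is
    sorted by distance and independent of atom enumeration order.
    """
    import warnings as _w

    donors: list[tuple[Atom, Atom | None]] = []
    acceptors: list[Atom] = []
    unknown: set[str] = set()
    for atom in structure.atoms:
        entry = donor_acceptor_table.get(atom.resname)
        if entry is None:
            unknown.add(atom.resname)
            continue
        for dname, antecedent in entry["donors"]:
            if atom.name == dname:
                donors.append(
                    (atom, structure.get(atom.chain, atom.resnum, antecedent)))
        if atom.name in entry["acceptors"]:
            acceptors.append(atom)
    if unknown:
        _w.warn(f"unknown residue types skipped in H-bond search: {sorted(unknown)}")

    out: list[HBond] = []
    for donor, antecedent in donors:
        d = np.array(donor.xyz)
        for acc in acceptors:
            if acc.key == donor.key:
                continue
            if not same_residue and acc.residue == donor.residue:
                continue
            dist = float(np.linalg.norm(d - np.array(acc.xyz)))
            if dist > max_distance:
                continue
            angle = None
            if antecedent is not None:
                angle = _angle_deg(np.array(antecedent.xyz), d, np.array(acc.xyz))
                if angle < min_angle:
                    continue
            out.append(HBond(donor.key, acc.key, dist, angle))
    out.sort(key=lambda h: (h.distance, h.donor, h.acceptor))
    return out


def _hbonds_between(structure: StructureModel, r1: ResidueKey, r2: ResidueKey,
                    **kw) -> list[HBond]:
    bonds = detect_hbonds(structure, **kw)
    keep = []
    for h in bonds:
        res = {h.donor[:2], h.acceptor[:2]}
        if res == {r1, r2}:
            keep.append(h)
    return keep


def _cis_or_trans(structure: StructureModel, r1: ResidueKey, r2: ResidueKey
                  ) -> str | None:
    """LW orientation from glycosidic-bond vectors vs the C1'-C1' axis."""
    def glyc(r: ResidueKey):
        name = structure.residue_name(r)
        n = structure.get(r[0], r[1], GLYCOSIDIC_N.get(name, ""))
        c1 = structure.get(r[0], r[1], "C1'")
        if n is None or c1 is None:
            return None
        return np.array(n.xyz), np.array(c1.xyz)

    g1, g2 = glyc(r1), glyc(r2)
    if g1 is None or g2 is None:
        return None
    axis = g2[1] - g1[1]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return None
    axis /= norm
    v1 = g1[1] - g1[0]  # N -> C1'
    v2 = g2[1] - g2[0]
    p1 = v1 - np.dot(v1, axis) * axis
    p2 = v2 - np.dot(v2, axis) * axis
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
        return None
    return "cis" if float(np.dot(p1, p2)) > 0 else "trans"


def classify_pair_geometry(structure: StructureModel,
                           r1: ResidueKey, r2: ResidueKey,
                           **hbond_kw) -> PairGeometryClass:
    """Classify one base pair: orientation, edges and H-bond count.

    The tandem G:A core pairs of a k-turn are trans-sugar-Hoogsteen
    (sugar edge of G, Hoogsteen edge of A); the flanking pairs of this
    motif include a cis C:A pair and a trans A:U pair each held by a
    single hydrogen bond, and ordinary cis-Watson-Crick pairs.
    """
    name1 = structure.residue_name(r1)
    name2 = structure.residue_name(r2)
    if name1 is None or name2 is None:
        return PairGeometryClass((r1, r2), "unclassified", [],
                                 reason="residue missing from structure")
    bonds = _hbonds_between(structure, r1, r2, **hbond_kw)
    if not bonds:
        return PairGeometryClass((r1, r2), "unclassified", [],
                                 reason="no qualifying hydrogen bonds")
    orientation = _cis_or_trans(structure, r1, r2)
    if orientation is None:
        return PairGeometryClass((r1, r2), "unclassified", bonds,
                                 reason="glycosidic-edge atoms missing")

    def atoms_on(r: ResidueKey, edge: Mapping[str, set]) -> set[str]:
        name = structure.residue_name(r)
        table = edge.get(name, set())
        involved = set()
        for h in bonds:
            for key in (h.donor, h.acceptor):
                if key[:2] == r and key[2] in table:
                    involved.add(key[2])
        return involved

    # trans-sugar-Hoogsteen G:A: sugar edge of G against Hoogsteen edge of A
    names = {name1: r1, name2: r2}
    if orientation == "trans" and set(names) == {"G", "A"}:
        g, a = names["G"], names["A"]
        if atoms_on(g, SUGAR_EDGE) and atoms_on(a, HOOGSTEEN_EDGE):
            return PairGeometryClass((r1, r2), "trans-sugar-Hoogsteen", bonds)
    if len(bonds) == 1:
        return PairGeometryClass((r1, r2), f"{orientation} single-H-bond", bonds)
    if orientation == "cis":
        wc1, wc2 = atoms_on(r1, WC_EDGE), atoms_on(r2, WC_EDGE)
        involved = {k[2] for h in bonds for k in (h.donor, h.acceptor)}
        if wc1 and wc2 and involved <= (WC_EDGE.get(name1, set())
                                        | WC_EDGE.get(name2, set())):
            return PairGeometryClass((r1, r2), "cis-Watson-Crick", bonds)
    return PairGeometryClass((r1, r2), "unclassified", bonds,
                             reason="edge pattern matches no known class")


# ---------------------------------------------------------------------------
# N-class assignment
# ---------------------------------------------------------------------------

@dataclass
class StructureAnnotation:
    """Residue mapping of k-turn labels onto chains/residue numbers.

    ``label_map`` must cover at least L1, 1n, 2b and -1n; helix residue
    lists (5'->3' order on the bulged strand) enable the kink angle.
    """

    label_map: Mapping[str, ResidueKey]
    c_helix_residues: Sequence[ResidueKey] = ()
    nc_helix_residues: Sequence[ResidueKey] = ()


def assign_n_class(structure: StructureModel,
                   annotation: StructureAnnotation,
                   **hbond_kw) -> KTurnStructureClass:
    """Assign N1/N3 from the hydrogen-bond census of the k-turn core.

    The class is read off the acceptor of the -1n O2' donor on the 2b
    adenine: N3 acceptor -> N3 class, N1 acceptor -> N1 class, neither
    within criteria -> unclassified.  The checklist independently
    records the L1 O2' -> A1n N1 cross-strand bond.
    """
    required = {"L1", "1n", "2b", "-1n"}
    missing = required - set(annotation.label_map)
    if missing:
        raise KeyError(f"annotation mapping incomplete: missing {sorted(missing)}")
    lm = annotation.label_map
    bonds = detect_hbonds(structure, **hbond_kw)

    def bond_from_to(donor_res, donor_atom, acc_res, acc_atom=None):
        for h in bonds:
            if h.donor[:2] == donor_res and h.donor[2] == donor_atom \
                    and h.acceptor[:2] == acc_res \
                    and (acc_atom is None or h.acceptor[2] == acc_atom):
                yield h

    l1_bond = any(bond_from_to(lm["L1"], "O2'", lm["1n"], "N1"))
    acc_atoms = sorted({h.acceptor[2]
                        for h in bond_from_to(lm["-1n"], "O2'", lm["2b"])})
    notes = []
    if len(acc_atoms) > 1:
        notes.append(f"-1n O2' contacts multiple 2b acceptors: {acc_atoms}")
    acceptor = acc_atoms[0] if acc_atoms else None
    n_class = {"N3": "N3", "N1": "N1"}.get(acceptor, "unclassified")
    if not l1_bond:
        notes.append("L1 O2' -> A1n N1 bond not found")

    angle = None
    if annotation.c_helix_residues and annotation.nc_helix_residues:
        angle = kink_angle(structure, annotation.c_helix_residues,
                           annotation.nc_helix_residues)
    return KTurnStructureClass(
        n_class=n_class, l1_o2p_to_a1n_n1=l1_bond, m1n_o2p_acceptor=acceptor,
        kink_angle_degrees=angle, hbonds=bonds, notes=notes,
    )


# ---------------------------------------------------------------------------
# Kink angle
# ---------------------------------------------------------------------------

def _axis_through(points: np.ndarray) -> np.ndarray:
    """Principal direction of a point cloud (unit vector)."""
    centred = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < 1e-9 or (len(s) > 1 and s[0] - s[1] < 1e-12):
        raise ValueError("degenerate helix geometry: no unique principal axis")
    return vt[0]


def kink_angle(structure: StructureModel,
               c_helix_residues: Sequence[ResidueKey],
               nc_helix_residues: Sequence[ResidueKey]) -> float:
    """Included angle (degrees) between the two helix axes.

    Each axis is the principal direction of the backbone P atoms
    (fallback C1') of the residues given in 5'->3' order; axis signs are
    chosen so each points 5'->3', making two coaxial stacked helices
    read 0 deg and the canonical tight k-turn read near
    ``REFERENCE_KINK_ANGLE``.  Result is in [0, 180].
    """
    def helix_axis(residues: Sequence[ResidueKey]) -> np.ndarray:
        pts = []
        for r in residues:
            atom = structure.get(r[0], r[1], "P") or structure.get(r[0], r[1], "C1'")
            if atom is not None:
                pts.append(atom.xyz)
        if len(pts) < 3:
            raise ValueError("need >= 3 residues with P or C1' atoms per helix")
        pts = np.asarray(pts, dtype=float)
        axis = _axis_through(pts)
        if np.dot(axis, pts[-1] - pts[0]) < 0:  # orient 5' -> 3'
            axis = -axis
        return axis

    u = helix_axis(c_helix_residues)
    v = helix_axis(nc_helix_residues)
    cosv = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(cosv))


# ---------------------------------------------------------------------------
# I/O: mmCIF / PDB via gemmi; label maps as TSV
# ---------------------------------------------------------------------------

def load_structure(path, model_index: int = 0) -> StructureModel:
    """Load coordinates from mmCIF (primary) or legacy PDB."""
    import gemmi

    st = gemmi.read_structure(str(path))
    model = st[model_index]
    atoms = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                atoms.append(Atom(chain.name, residue.seqid.num,
                                  residue.name.strip(), atom.name,
                                  (atom.pos.x, atom.pos.y, atom.pos.z)))
    return StructureModel(atoms)


def read_label_map(path) -> dict[str, ResidueKey]:
    """Read a 'label<TAB>chain<TAB>resnum' mapping file."""
    out: dict[str, ResidueKey] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("label\t"):
                continue
            label, chain, resnum = line.split("\t")[:3]
            out[label] = (chain, int(resnum))
    return out
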