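"""Synthetic-data generators with controlled ground truths.

Every generator is deterministic under a fixed seed and returns its
ground truth alongside the data, so downstream recovery tests consume
only the data and compare against the truth.  Random streams are
isolated per generator kind: adding a generator never perturbs the
fixtures of another.

The "paper-like" titration preset encodes the experimental levels of
the L7Ae/Mg2+ FRET study of this UTR k-turn as calibration inputs (20
nM labelled RNA, a baseline E_FRET of 0.18 and a protein-bound plateau
of 0.6); they are defaults of the simulation, not results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import (Bulge, HairpinModel, KTurnAnnotation, RNAStrand,
                       annotate_positions)
from .fret import SpectrumSet, TitrationCurve, efret_closed_form
from .probing import ReactivityLevels, ReactivityProfile, StateModel, predict_reactivity
from .structure import Atom, StructureAnnotation, StructureModel

__all__ = [
    "GeneratorSpec",
    "SyntheticTitration",
    "SyntheticUTR",
    "SyntheticStructure",
    "gen_titration",
    "gen_toy_utr",
    "gen_structure_fixture",
    "gen_spectra",
    "gen_probing_profiles",
    "utr_probing_states",
    "PAPER_LIKE_TITRATION",
]

_KIND_CODE = {"titration": 1, "utr": 2, "structure_fixture": 3,
              "spectra": 4, "probing": 5}


def _rng(kind: str, seed: int) -> np.random.Generator:
    """Per-kind isolated random stream."""
    return np.random.default_rng([int(seed) % (2 ** 31), _KIND_CODE[kind]])


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset."""

    kind: str
    parameters: dict
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODE:
            raise ValueError(f"unknown generator kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Titration curves
# ---------------------------------------------------------------------------

#: experimental levels of the steady-state FRET study (calibration inputs)
PAPER_LIKE_TITRATION = {"RT": 2e-8, "E0": 0.18, "dE": 0.42, "KA": 1e8}


@dataclass
class SyntheticTitration:
    curve: TitrationCurve
    truth: dict
    seed: int


def default_pt_grid(RT: float = 2e-8, n: int = 12) -> np.ndarray:
    """Log-spaced ligand grid bracketing the stoichiometric point."""
    return np.geomspace(RT / 20, RT * 50, n)


def gen_titration(truth: tuple[float, float, float] | None = None,
                  RT: float = PAPER_LIKE_TITRATION["RT"],
                  PT_grid: Sequence[float] | None = None,
                  sigma: float = 0.0,
                  seed: int = 0,
                  ligand_kind: str = "L7Ae") -> SyntheticTitration:
    """Simulate a tight-binding FRET titration with Gaussian noise.

    ``truth`` is (E0, dE, KA); the default is the paper-like preset
    (baseline 0.18, plateau 0.6, 20 nM RNA).
    """
    if truth is None:
        truth = (PAPER_LIKE_TITRATION["E0"], PAPER_LIKE_TITRATION["dE"],
                 PAPER_LIKE_TITRATION["KA"])
    E0, dE, KA = truth
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    pt = np.asarray(PT_grid if PT_grid is not None else default_pt_grid(RT),
                    dtype=float)
    if np.any(np.diff(pt) <= 0):
        raise ValueError("PT grid must be strictly increasing")
    e = efret_closed_form(pt, E0, dE, KA, RT)
    if sigma > 0:
        e = e + _rng("titration", seed).normal(0.0, sigma, size=pt.shape)
    curve = TitrationCurve(pt, e, rna_total=RT, ligand_kind=ligand_kind)
    return SyntheticTitration(curve=curve,
                              truth={"E0": E0, "dE": dE, "KA": KA,
                                     "RT": RT, "sigma": sigma},
                              seed=seed)


# ---------------------------------------------------------------------------
# Toy UTR hairpins with embedded k-turn cores
# ---------------------------------------------------------------------------

_WC = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_SD = "AGGAGG"


@dataclass
class SyntheticUTR:
    strand: RNAStrand
    model: HairpinModel          # ground-truth pairing
    annotation: KTurnAnnotation  # ground-truth nomenclature
    sd_interval: tuple[int, int] | None
    truth: dict
    seed: int


def gen_toy_utr(rule_signature: tuple[tuple[str, str], tuple[str, str]] = (("C", "A"), ("A", "U")),
                helix_lengths: tuple[int, int] = (8, 6),
                sd_placement: str = "in_stem",
                loop_side: str = "NC",
                bulge_seq: str = "GAU",
                loop_seq: str = "GAAA",
                seed: int = 0) -> SyntheticUTR:
    """Emit a hairpin UTR embedding a k-turn of a chosen rule signature.

    ``rule_signature`` is ((-1b, -1n), (3b, 3n)); ``helix_lengths`` are
    (C, NC) pair counts including the -1 closing pair and the G:A core
    respectively; the Shine-Dalgarno hexamer is written into the C-helix
    partner strand ("in_stem") or a single-stranded 3' tail
    ("downstream").  Returns the strand plus ground-truth pairing and
    annotation.
    """
    (m1b, m1n), (p3b, p3n) = rule_signature
    c_len, nc_len = helix_lengths
    if c_len < 2 or nc_len < 3:
        raise ValueError("need c_len >= 2 and nc_len >= 3 to place the signature")
    if sd_placement == "in_stem" and c_len < len(_SD) + 2:
        raise ValueError("constraint error: SD longer than available C-helix")
    for b in (m1b, m1n, p3b, p3n, *bulge_seq, *loop_seq):
        if b not in "ACGU":
            raise ValueError(f"invalid base {b!r}")
    rng = _rng("utr", seed)

    # bulged-strand helices, innermost pair first
    c_pairs = [(m1b, m1n)]  # -1b:-1n
    for _ in range(c_len - 1):
        c_pairs.append(_WC[rng.integers(len(_WC))])
    nc_pairs = [("G", "A"), ("A", "G"), (p3b, p3n)]  # 1,2,3
    for _ in range(nc_len - 3):
        nc_pairs.append(_WC[rng.integers(len(_WC))])

    if sd_placement == "in_stem":
        # write AGGAGG onto the partner strand of the C helix (-3n..-8n),
        # the region the folded stem occludes
        for k, base in enumerate(_SD):
            idx = 2 + k  # c_pairs index: -3 .. -8
            comp = {"A": "U", "G": "C", "C": "G", "U": "A"}[base]
            c_pairs[idx] = (comp, base)

    b_arm = ("".join(b for b, _ in reversed(c_pairs))  # -c_len b .. -1b
             + bulge_seq
             + "".join(b for b, _ in nc_pairs))        # 1b .. nc_len b
    n_arm = ("".join(n for _, n in reversed(nc_pairs))  # nc_len n .. 1n
             + "".join(n for _, n in c_pairs))          # -1n .. -c_len n

    tail = ""
    if sd_placement == "downstream":
        tail = "AC" + _SD + "AU"
    if loop_side == "NC":
        seq = b_arm + loop_seq + n_arm + tail
        loop = (len(b_arm), len(b_arm) + len(loop_seq))
        b_index = lambda i: i                        # noqa: E731
        n_index = lambda j: loop[1] + j              # noqa: E731
    elif loop_side == "C":
        seq = n_arm + loop_seq + b_arm + tail
        loop = (len(n_arm), len(n_arm) + len(loop_seq))
        b_index = lambda i: loop[1] + i              # noqa: E731
        n_index = lambda j: j                        # noqa: E731
    else:
        raise ValueError("loop_side must be 'NC' or 'C'")

    # ground-truth pairing: b_arm position i pairs n_arm position (L-1-i)
    pairs = []
    n_len = len(n_arm)
    for i in range(len(b_arm)):
        if c_len + len(bulge_seq) > i >= c_len:
            continue  # bulge
        shift = len(bulge_seq) if i >= c_len else 0
        j = n_len - 1 - (i - shift)
        p, q = b_index(i), n_index(j)
        pairs.append((min(p, q), max(p, q)))
    pairs.sort()

    strand = RNAStrand(id=f"toyUTR-{seed}", sequence=seq)
    model = HairpinModel(strand=strand, pairs=pairs, terminal_loop=loop,
                         bulges=[Bulge("hairpin", b_index(c_len),
                                       b_index(c_len + len(bulge_seq)))],
                         score=0)
    annotation = annotate_positions(
        (model, model.bulges[0]))

    sd_interval = None
    if sd_placement == "in_stem":
        sd_pos = sorted(n_index(len(nc_pairs) + 2 + k) for k in range(len(_SD)))
        sd_interval = (sd_pos[0], sd_pos[-1] + 1)
    elif sd_placement == "downstream":
        start = len(seq) - len(tail) + 2
        sd_interval = (start, start + len(_SD))

    return SyntheticUTR(
        strand=strand, model=model, annotation=annotation,
        sd_interval=sd_interval,
        truth={"rule_signature": rule_signature, "helix_lengths": helix_lengths,
               "bulge": bulge_seq, "loop_side": loop_side,
               "sd_placement": sd_placement},
        seed=seed,
    )


def gen_two_core_duplex():
    """A twofold-symmetric duplex with two embedded k-turn cores.

    Mimics the crystallization-style design: two identical strands,
    each carrying a GAU bulge + G:A/A:G core, pair so the duplex holds
    two k-turns related by twofold rotational symmetry (one bulge per
    strand, which a single-bulge hybridization cannot represent, so the
    pairing is constructed explicitly).
    """
    from .annotate import DuplexModel

    half_b = "GCGC" + "GAU" + "GA" + "AUC"   # C helix, bulge, core, NC extra
    half_p = "GAUGA" + "ACGC"                # partners of AUC+GA then GCGC
    seq = half_b + half_p
    x = RNAStrand("sym1", seq)
    y = RNAStrand("sym2", seq)
    pairs = []
    nb, np_ = len(half_b), len(half_p)
    for i in range(nb):
        if 4 <= i < 7:
            continue  # bulge on strand 1
        off = 3 if i >= 7 else 0
        pairs.append((i, 2 * nb + np_ - 1 - (i - off) - nb))  # into strand 2 tail
    for k in range(np_):
        j = nb - 1 - k if k < 5 else nb - 1 - k - 3  # skip strand 2 bulge
        pairs.append((nb + k, j))
    pairs.sort()
    return DuplexModel(bulged_strand=x, partner_strand=y, pairs=pairs,
                       bulges=[Bulge("bulged", 4, 7), Bulge("partner", 4, 7)])


# ---------------------------------------------------------------------------
# Coordinate fixtures: two helices at a chosen kink angle + core pseudo-atoms
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStructure:
    structure: StructureModel
    annotation: StructureAnnotation
    truth: dict
    seed: int


def _helix_points(origin: np.ndarray, axis: np.ndarray, v: np.ndarray,
                  w: np.ndarray, n_res: int, rise: float = 2.81,
                  radius: float = 9.4, twist_deg: float = 30.0
                  ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backbone P positions of both strands of an idealized duplex helix.

    The two strands sit at phases 180 deg apart at each axial level, so
    their radial displacements cancel pairwise and the principal axis
    of the combined point cloud equals ``axis`` exactly.
    """
    fwd, rev = [], []
    for i in range(n_res):
        phase = math.radians(twist_deg * i)
        level = origin + axis * (rise * i)
        fwd.append(level + radius * (v * math.cos(phase) + w * math.sin(phase)))
        rev.append(level - radius * (v * math.cos(phase) + w * math.sin(phase)))
    return fwd, rev


def gen_structure_fixture(kink_angle: float = 50.0,
                          n_class_truth: str = "N3",
                          n_res: int = 12,
                          seed: int = 0) -> SyntheticStructure:
    """Two idealized helices subtending ``kink_angle`` plus core atoms.

    The C helix runs 5'->3' into the junction along +x; the NC helix
    leaves the junction along an axis rotated by ``kink_angle`` in the
    xy-plane, so the measured 5'->3' interhelical angle equals the
    request (0 = coaxial).  O2'/N1/N3 pseudo-atoms of the core are
    placed so the N-class detector returns ``n_class_truth`` ("N1",
    "N3" or "none").
    """
    if not (0.0 <= kink_angle <= 180.0):
        raise ValueError("kink angle must be in [0, 180] degrees")
    if n_class_truth not in {"N1", "N3", "none"}:
        raise ValueError("n_class_truth must be 'N1', 'N3' or 'none'")
    theta = math.radians(kink_angle)
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([math.cos(theta), math.sin(theta), 0.0])
    z = np.array([0.0, 0.0, 1.0])

    def frame(u):
        v = np.cross(z, u)
        if np.linalg.norm(v) < 1e-9:
            v = np.array([0.0, 1.0, 0.0])
        v = v / np.linalg.norm(v)
        return v, np.cross(u, v)

    rise = 2.81
    v1, w1 = frame(u1)
    v2, w2 = frame(u2)
    o1 = -u1 * (rise * (n_res - 1) + 6.0)  # C helix ends 6 A before origin
    o2 = u2 * 6.0                           # NC helix starts 6 A after it
    atoms: list[Atom] = []
    c_res, nc_res = [], []
    fwd, rev = _helix_points(o1, u1, v1, w1, n_res)
    for i, (p, q) in enumerate(zip(fwd, rev)):
        atoms.append(Atom("A", i + 1, "G", "P", tuple(p)))
        atoms.append(Atom("B", 101 + i, "C", "P", tuple(q)))
        c_res.append(("A", i + 1))
    c_res += [("B", 101 + i) for i in range(n_res)]
    fwd, rev = _helix_points(o2, u2, v2, w2, n_res)
    for i, (p, q) in enumerate(zip(fwd, rev)):
        atoms.append(Atom("A", n_res + 1 + i, "C", "P", tuple(p)))
        atoms.append(Atom("B", 121 + i, "G", "P", tuple(q)))
        nc_res.append(("A", n_res + 1 + i))
    nc_res += [("B", 121 + i) for i in range(n_res)]

    # core cluster near the junction (positions independent of the angle):
    # A2b ring nitrogens, the -1n ribose donor, L1 ribose donor, A1n N1.
    core = {
        ("A", 31, "A", "N3"): (1.0, 2.0, 1.0),
        ("A", 31, "A", "N1"): (1.0, 4.2, 1.5),
        ("B", 40, "A", "N1"): (-2.0, 3.0, 0.5),   # A1n
        ("A", 30, "G", "O2'"): (-4.9, 3.0, 0.5),  # L1 ribose
        ("A", 30, "G", "C2'"): (-6.3, 3.0, 0.5),
    }
    if n_class_truth == "N3":
        o2p = (3.8, 2.0, 1.0)
    elif n_class_truth == "N1":
        o2p = (3.8, 4.2, 1.5)
    else:
        o2p = (8.5, 2.0, 1.0)
    core[("B", 41, "A", "O2'")] = o2p
    core[("B", 41, "A", "C2'")] = (o2p[0] + 1.4, o2p[1], o2p[2])
    for (chain, num, resname, name), xyz in core.items():
        atoms.append(Atom(chain, num, resname, name, xyz))

    structure = StructureModel(atoms)
    annotation = StructureAnnotation(
        label_map={"L1": ("A", 30), "2b": ("A", 31),
                   "1n": ("B", 40), "-1n": ("B", 41)},
        c_helix_residues=c_res, nc_helix_residues=nc_res,
    )
    return SyntheticStructure(
        structure=structure, annotation=annotation,
        truth={"kink_angle": kink_angle, "n_class": n_class_truth},
        seed=seed,
    )


#: hand-built planar coordinates for idealized base-pair geometries.
#: Each entry: residue 1 on chain A/resnum 1, residue 2 on chain B/resnum 2.
_PAIR_FIXTURES: dict[str, tuple[str, str, dict, dict]] = {
    # sheared G:A: G N2 -> A N7 and A N6 -> G N3 (sugar edge of G against
    # Hoogsteen edge of A, glycosidic bonds trans)
    "trans_sugar_hoogsteen_GA": ("G", "A", {
        "N3": (0.0, 0.0, 0.0), "N2": (0.76, 2.0, 0.0), "C2": (0.0, 1.35, 0.0),
        "N9": (-1.9, -0.8, 0.0), "C1'": (-3.2, -0.1, 0.0),
    }, {
        "N6": (2.9, 0.2, 0.0), "C6": (3.6, 1.35, 0.0), "N7": (3.4, 3.2, 0.0),
        "N9": (5.3, 2.9, 0.0), "C1'": (6.3, 1.8, 0.0),
    }),
    # the 3b:3n pair of this k-turn: trans A:U with a single A N6 -> U O2 bond
    "trans_AU": ("A", "U", {
        "N6": (2.9, 0.2, 0.0), "C6": (3.6, 1.35, 0.0),
        "N9": (5.3, 2.9, 0.0), "C1'": (6.3, 1.8, 0.0),
    }, {
        "O2": (0.0, 0.0, 0.0), "N1": (-1.2, -1.3, 0.0), "C1'": (-2.3, -0.4, 0.0),
    }),
    # the -1 pair of this k-turn: cis C:A with a single A N6 -> C N3 bond
    "cis_CA": ("C", "A", {
        "N3": (0.0, 0.0, 0.0), "N1": (-1.3, -1.4, 0.0), "C1'": (-2.4, -0.5, 0.0),
    }, {
        "N6": (2.9, 0.2, 0.0), "C6": (3.6, 1.35, 0.0),
        "N9": (5.3, 2.9, 0.0), "C1'": (5.9, 4.25, 0.0),
    }),
    # canonical cis-Watson-Crick G:C (three H-bonds)
    "cis_watson_crick_GC": ("G", "C", {
        "O6": (-0.1, 2.2, 0.0), "N1": (0.0, 0.0, 0.0), "C2": (-1.2, -0.6, 0.0),
        "N2": (0.9, -2.2, 0.0),
        "N9": (-0.9, -3.3, 0.0), "C1'": (-2.2, -4.0, 0.0),
    }, {
        "N3": (2.9, 0.0, 0.0), "N4": (2.7, 2.25, 0.0), "C4": (3.9, 2.2, 0.0),
        "O2": (3.7, -2.4, 0.0),
        "N1": (4.3, -3.3, 0.0), "C1'": (5.05, -4.5, 0.0),
    }),
}


def gen_pair_fixture(kind: str) -> tuple[StructureModel, tuple, tuple]:
    """An idealized two-residue base-pair fixture for geometry tests.

    Returns (structure, residue1, residue2) where the residues are
    (chain, resnum) keys.  Kinds: trans_sugar_hoogsteen_GA, trans_AU,
    cis_CA, cis_watson_crick_GC.
    """
    name1, name2, atoms1, atoms2 = _PAIR_FIXTURES[kind]
    atoms = [Atom("A", 1, name1, n, xyz) for n, xyz in atoms1.items()]
    atoms += [Atom("B", 2, name2, n, xyz) for n, xyz in atoms2.items()]
    return StructureModel(atoms), ("A", 1), ("B", 2)


def random_rigid_motion(seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    rng = _rng("structure_fixture", seed)
    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    t = rng.normal(0.0, 20.0, size=3)
    return R, t


# ---------------------------------------------------------------------------
# Emission spectra for acceptor normalization
# ---------------------------------------------------------------------------

def gen_spectra(E: float,
                eps_donor_at_donor_ex: float = 8.0e4,
                eps_acceptor_at_donor_ex: float = 6.0e3,
                eps_acceptor_at_acceptor_ex: float = 1.5e5,
                scale: float = 1.0,
                seed: int = 0) -> SpectrumSet:
    """Forward-simulate donor/acceptor emission channels for a chosen E.

    Donor and acceptor emission bands are Gaussian shapes (fluorescein-
    and Cy3-like peaks at 520 / 565 nm).  Under donor excitation the
    spectrum holds quenched donor emission, sensitized acceptor
    emission proportional to E*eps_D(lam_D), and directly excited
    acceptor emission proportional to eps_A(lam_D); under acceptor
    excitation only direct acceptor emission appears.
    """
    if not (0.0 <= E <= 1.0):
        raise ValueError("transfer efficiency must be in [0, 1]")
    lam = np.arange(450.0, 701.0, 1.0)
    donor_shape = np.exp(-0.5 * ((lam - 520.0) / 25.0) ** 2)
    acceptor_shape = np.exp(-0.5 * ((lam - 565.0) / 25.0) ** 2)
    donor_excited = scale * (
        eps_donor_at_donor_ex * (1.0 - E) * donor_shape
        + (eps_donor_at_donor_ex * E + eps_acceptor_at_donor_ex) * acceptor_shape)
    acceptor_excited = scale * eps_acceptor_at_acceptor_ex * acceptor_shape
    donor_only = 0.7 * donor_shape  # reference shape, arbitrary scale
    return SpectrumSet(
        wavelengths=lam,
        donor_excited=donor_excited,
        acceptor_excited=acceptor_excited,
        donor_only=donor_only,
        eps_donor_at_donor_ex=eps_donor_at_donor_ex,
        eps_acceptor_at_donor_ex=eps_acceptor_at_donor_ex,
        eps_acceptor_at_acceptor_ex=eps_acceptor_at_acceptor_ex,
    )


# ---------------------------------------------------------------------------
# In-line probing profiles
# ---------------------------------------------------------------------------

def utr_probing_states(utr: SyntheticUTR | None = None,
                       mutant: bool = False,
                       footprint_pad: int = 2,
                       seed: int = 0) -> tuple[StateModel, StateModel]:
    """(apo, bound) states for a toy UTR, natural or core-mutant.

    Apo: the UTR is predominantly single-stranded (uniform
    reactivity).  Bound, natural sequence: the stem-loop forms,
    stabilized by the protein clamped over the k-turn core (footprint =
    bulge +/- ``footprint_pad`` positions on both strands).  Bound,
    mutant (1b/2b exchanged for C/G so the k-turn cannot form): no
    stem-loop; the protein footprint is absent and the RNA stays
    single-stranded.
    """
    if utr is None:
        utr = gen_toy_utr(seed=seed)
    seq = utr.strand.sequence
    n = len(seq)
    if mutant:
        pos1b = utr.annotation.positions["1b"].index
        pos2b = utr.annotation.positions["2b"].index
        seq = "".join({pos1b: "C", pos2b: "G"}.get(i, c) for i, c in enumerate(seq))
        apo = StateModel(seq, [False] * n, name="mutant-apo")
        bound = StateModel(seq, [False] * n, protein_bound=True,
                           name="mutant-bound")
        return apo, bound
    apo = StateModel(seq, [False] * n, name="natural-apo")
    paired = [False] * n
    for i, j in utr.model.pairs:
        paired[i] = paired[j] = True
    core_idx = sorted(p.index for lab, p in utr.annotation.positions.items()
                      if lab in {"L1", "L2", "L3", "1b", "2b",
                                 "1n", "2n", "-1b", "-1n"})
    # the protein clamps the core on both strands: one footprint per
    # contiguous run of core positions (the two arms are separate runs)
    footprints = []
    run_start = core_idx[0]
    prev = core_idx[0]
    for idx in core_idx[1:] + [None]:
        if idx is None or idx > prev + 1:
            footprints.append((max(0, run_start - footprint_pad),
                               min(n, prev + 1 + footprint_pad)))
            run_start = idx
        prev = idx if idx is not None else prev
    # padding must not bleed into the terminal loop
    loop_lo, loop_hi = utr.model.terminal_loop
    clipped = []
    for lo, hi in footprints:
        if hi <= loop_lo or lo >= loop_hi:
            clipped.append((lo, hi))
        elif lo < loop_lo:
            clipped.append((lo, loop_lo))
        else:
            clipped.append((loop_hi, hi))
    bound = StateModel(seq, paired, footprints=clipped,
                       loop=utr.model.terminal_loop, protein_bound=True,
                       name="natural-bound")
    return apo, bound


def gen_probing_profiles(apo_state: StateModel, bound_state: StateModel,
                         sigma: float = 0.0, seed: int = 0,
                         levels: ReactivityLevels = ReactivityLevels()
                         ) -> tuple[ReactivityProfile, ReactivityProfile]:
    """Simulated apo/bound profiles: predicted levels + Gaussian noise.

    Noise is seeded and floored at zero (band intensities cannot be
    negative).
    """
    if apo_state.sequence != bound_state.sequence:
        raise ValueError("apo and bound states must share a sequence")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = _rng("probing", seed)
    out = []
    for state in (apo_state, bound_state):
        prof = predict_reactivity(state, levels)
        vals = prof.reactivities
        if sigma > 0:
            vals = np.clip(vals + rng.normal(0.0, sigma, size=vals.shape),
                           0.0, None)
        out.append(ReactivityProfile(vals, condition=prof.condition))
    return out[0], out[1]
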