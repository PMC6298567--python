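"""Duplex hybridization, hairpin folding and k-turn motif annotation.

The k-turn is a duplex RNA motif: a short bulge (usually 3 nt) followed
on its 3' side by tandem G:A and A:G base pairs.  The helix 5' of the
bulge is the canonical (C) helix; the helix containing the G:A pairs is
the non-canonical (NC) helix.  Positions are labelled by the standard
nomenclature: bulge nucleotides L1..Lk, then 1b, 2b, ... running into
the NC helix and -1b, -2b, ... into the C helix on the bulged strand,
with n-suffixed labels for the opposed positions on the other strand.

Coordinates are 0-based with half-open intervals throughout; rendered
reports additionally print 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RNAStrand",
    "Bulge",
    "DuplexModel",
    "HairpinModel",
    "Position",
    "KTurnAnnotation",
    "SDOverlapReport",
    "NoDuplexError",
    "AnnotationError",
    "hybridize_strands",
    "fold_hairpin",
    "scan_kturns",
    "annotate_positions",
    "sd_overlap",
    "scan_sd_consensus",
    "read_fasta_strand",
    "dot_bracket",
    "annotation_table",
]

RNA_ALPHABET = frozenset("ACGU")
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})

#: accepted bulge lengths for the k-turn scan (the canonical motif has 3)
BULGE_RANGE = (1, 5)


class NoDuplexError(ValueError):
    """Raised when two strands cannot form a duplex of at least ``min_pairs``."""


class AnnotationError(ValueError):
    """Raised when a candidate site cannot be annotated as a k-turn."""


def is_wc(x: str, y: str, count_wobble: bool = False) -> bool:
    """True if x:y is a Watson-Crick pair (optionally counting G:U wobble)."""
    if (x, y) in WC_PAIRS:
        return True
    return count_wobble and (x, y) in WOBBLE_PAIRS


@dataclass(frozen=True)
class RNAStrand:
    """A single RNA strand, sequence written 5'->3' over {A, C, G, U}."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace(" ", "")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"strand {self.id!r}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            if "T" in bad:
                raise ValueError(
                    f"strand {self.id!r}: contains T; RNA input must use U"
                )
            raise ValueError(f"strand {self.id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def __getitem__(self, i: int) -> str:
        return self.sequence[i]


@dataclass(frozen=True)
class Bulge:
    """A contiguous unpaired internal run, attributed to one strand."""

    strand: str  # 'bulged' | 'partner' | 'hairpin'
    start: int   # 0-based, half-open
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class DuplexModel:
    """Antiparallel two-strand duplex with at most one internal bulge.

    ``pairs`` lists opposed (i, j) ladder positions, i on the bulged
    strand ascending 5'->3', j on the partner strand descending; every
    opposed position in the aligned overlap is listed, whether or not it
    is Watson-Crick (the crystal structure of this motif shows the
    flanking C:A and A:U "pairs" are genuine, if non-canonical, pairs).
    """

    bulged_strand: RNAStrand
    partner_strand: RNAStrand
    pairs: list[tuple[int, int]]
    bulges: list[Bulge] = field(default_factory=list)
    score: int = 0
    ambiguous: bool = False

    def partner_map(self) -> dict[tuple[str, int], tuple[str, int]]:
        m: dict[tuple[str, int], tuple[str, int]] = {}
        for i, j in self.pairs:
            m[("b", i)] = ("n", j)
            m[("n", j)] = ("b", i)
        return m

    def base(self, pos: tuple[str, int]) -> str:
        strand = self.bulged_strand if pos[0] == "b" else self.partner_strand
        return strand[pos[1]]


@dataclass
class HairpinModel:
    """A single strand folded back on itself around a terminal loop."""

    strand: RNAStrand
    pairs: list[tuple[int, int]]  # (i, j) with i < j
    terminal_loop: tuple[int, int]  # half-open interval
    bulges: list[Bulge] = field(default_factory=list)
    score: int = 0
    ambiguous: bool = False

    def __post_init__(self) -> None:
        l, r = self.terminal_loop
        if r - l < 3:
            raise ValueError("terminal loop must be >= 3 nt")

    def partner_map(self) -> dict[tuple[str, int], tuple[str, int]]:
        m: dict[tuple[str, int], tuple[str, int]] = {}
        for i, j in self.pairs:
            m[("h", i)] = ("h", j)
            m[("h", j)] = ("h", i)
        return m

    def base(self, pos: tuple[str, int]) -> str:
        return self.strand[pos[1]]


@dataclass(frozen=True)
class Position:
    """One labelled k-turn position: strand id, 0-based index, base."""

    strand_id: str
    index: int
    base: str


@dataclass
class KTurnAnnotation:
    """Standard position nomenclature for one k-turn site.

    ``c_helix_length`` counts the -1b:-1n closing pair plus contiguous
    Watson-Crick steps extending 5' on the bulged strand;
    ``nc_helix_length`` counts the two tandem G:A core pairs plus the
    contiguous Watson-Crick steps from 3b:3n outward.  For the motif's
    printed duplex this yields C = 12 bp and NC = 13 bp, and the two
    lengths sum to the full partner-strand pairing (25 nt).
    """

    model: DuplexModel | HairpinModel
    positions: dict[str, Position]
    c_helix_length: int
    nc_helix_length: int
    bulge_sequence: str
    loop_polarity: str  # 'C-side' | 'NC-side' | 'duplex'
    bulge: Bulge | None = None
    ambiguous: bool = False

    def pair(self, number: int) -> tuple[str, str]:
        """Bases at (Nb, Nn) for a signed position number, e.g. pair(-1) = ('C','A')."""
        b = self.positions.get(f"{number}b")
        n = self.positions.get(f"{number}n")
        if b is None or n is None:
            raise AnnotationError(f"annotation lacks position pair {number}b:{number}n")
        return (b.base, n.base)

    @property
    def labels(self) -> set[str]:
        return set(self.positions)


@dataclass
class SDOverlapReport:
    """Shine-Dalgarno interval vs k-turn annotation overlap."""

    sd_interval: tuple[int, int]
    overlapping_labels: set[str]
    occluded_in_stem: bool


# ---------------------------------------------------------------------------
# Hybridization: ladder alignment with at most one internal bulge
# ---------------------------------------------------------------------------

def _core_bonus(bseq: str, pseq: str, rungs: list[tuple[int, int]],
                bulge_end: int | None) -> int:
    """Score bonus for tandem G:A / A:G immediately 3' of the bulge.

    These opposed positions are non-complementary yet genuinely paired
    (trans-sugar-Hoogsteen pairs), so the aligner credits them when they
    sit directly after a bulge in the motif arrangement.
    """
    if bulge_end is None:
        return 0
    after = [(i, j) for i, j in rungs if i >= bulge_end]
    if len(after) < 2:
        return 0
    (i1, j1), (i2, j2) = after[0], after[1]
    if i1 != bulge_end or i2 != bulge_end + 1:
        return 0
    if bseq[i1] == "G" and pseq[j1] == "A" and bseq[i2] == "A" and pseq[j2] == "G":
        return 2
    return 0


def _enumerate_ladders(m: int, n: int, max_bulge: int):
    """Yield (rungs, bulge_run) for every one-bulge antiparallel ladder.

    A ladder is parameterized by the offset of the two antiparallel
    strands and an optional internal skipped run of length g on the
    bulged strand.  ``rungs`` are opposed (i, j) with i ascending on the
    bulged strand and j descending on the partner.
    """
    for off in range(-(n - 1), m):
        # ungapped ladder: i pairs t = i - off in reversed-partner space
        base = [(i, i - off) for i in range(max(0, off), min(m, n + off))]
        if base:
            yield [(i, n - 1 - t) for i, t in base], None
        for g in range(1, max_bulge + 1):
            for k in range(1, m):  # bulge occupies bulged-strand [k, k+g)
                if k + g >= m:
                    continue
                left = [(i, i - off) for i in range(max(0, off), k)
                        if 0 <= i - off < n]
                right = [(i, i - off - g) for i in range(k + g, m)
                         if 0 <= i - off - g < n]
                # internal bulge requires pairing flanks on both sides
                if not left or not right:
                    continue
                if left[-1][0] != k - 1 or right[0][0] != k + g:
                    continue
                rungs = [(i, n - 1 - t) for i, t in left + right]
                yield rungs, (k, k + g)


def hybridize_strands(
    bulged: RNAStrand,
    partner: RNAStrand,
    max_bulge: int = 3,
    min_pairs: int = 4,
    count_wobble: bool = False,
) -> DuplexModel:
    """Anneal two antiparallel strands into a one-bulge duplex model.

    Returns the maximum-scoring non-crossing ladder alignment allowing
    at most one internal bulge of <= ``max_bulge`` nt on the bulged
    strand.  Watson-Crick pairs score 1 each; the tandem G:A/A:G core
    positions directly 3' of a bulge are special-cased as paired.

    Ties are broken toward the 5'-most, shortest bulge and flagged via
    ``ambiguous`` when distinct co-optimal pairings exist.
    """
    if max_bulge < 0:
        raise ValueError("max_bulge must be >= 0")
    bseq, pseq = bulged.sequence, partner.sequence
    m, n = len(bseq), len(pseq)

    best: list[tuple[tuple, list, tuple | None, int]] = []
    best_score = -1
    for rungs, bulge_run in _enumerate_ladders(m, n, max_bulge):
        wc = sum(1 for i, j in rungs if is_wc(bseq[i], pseq[j], count_wobble))
        score = wc + _core_bonus(bseq, pseq, rungs,
                                 bulge_run[1] if bulge_run else None)
        key = (bulge_run[0] if bulge_run else m,
               (bulge_run[1] - bulge_run[0]) if bulge_run else 0,
               rungs[0][0], -rungs[0][1])
        if score > best_score:
            best_score = score
            best = [(key, rungs, bulge_run, score)]
        elif score == best_score:
            best.append((key, rungs, bulge_run, score))

    if best_score < min_pairs:
        raise NoDuplexError(
            f"no duplex: best alignment scores {max(best_score, 0)} < {min_pairs} pairs"
        )
    best.sort(key=lambda t: t[0])
    distinct = {tuple(r) for _, r, _, _ in best}
    _, rungs, bulge_run, score = best[0]
    bulges = []
    if bulge_run is not None:
        bulges.append(Bulge("bulged", bulge_run[0], bulge_run[1]))
    return DuplexModel(
        bulged_strand=bulged,
        partner_strand=partner,
        pairs=rungs,
        bulges=bulges,
        score=score,
        ambiguous=len(distinct) > 1,
    )


def fold_hairpin(
    strand: RNAStrand,
    max_bulge: int = 3,
    min_loop: int = 3,
    max_loop: int = 12,
    min_pairs: int = 4,
    count_wobble: bool = False,
) -> HairpinModel:
    """Fold one strand into a stem-loop, allowing one internal stem bulge.

    The stem closes at the terminal loop (the pair flanking the loop is
    always formed); dangling single-stranded tails are allowed at the
    outer 5'/3' ends.  Scoring as in :func:`hybridize_strands`, with the
    bulge permitted on either arm.  This is combinatorial base-pair
    maximization over ladder stems, not free-energy folding.
    """
    s = strand.sequence
    L = len(s)
    best = None
    best_key = None
    n_opt = 0
    for loop_len in range(min_loop, max_loop + 1):
        for l in range(1, L - loop_len):
            r = l + loop_len
            arm1, arm2 = s[:l], s[r:]
            for pairs_local, bulge in _ladder_stem(arm1, arm2, max_bulge,
                                                   count_wobble):
                pairs = [(i, r + j) for i, j in pairs_local]
                wc = sum(1 for i, j in pairs if is_wc(s[i], s[j], count_wobble))
                bonus = 0
                if bulge is not None:
                    side, b0, b1 = bulge
                    bonus = _hairpin_core_bonus(s, dict(pairs), side, b1, r)
                score = wc + bonus
                key = (-score, loop_len, l,
                       bulge[1] if bulge else L)
                if best_key is None or key < best_key:
                    best_key, best = key, (pairs, bulge, (l, r), score)
                    n_opt = 1
                elif key is not None and best_key is not None and -key[0] == -best_key[0]:
                    n_opt += 1
    if best is None or best[3] < min_pairs:
        raise NoDuplexError("no hairpin stem with enough pairs")
    pairs, bulge, loop, score = best
    bulges = []
    if bulge is not None:
        side, b0, b1 = bulge
        if side == 2:
            b0, b1 = loop[1] + b0, loop[1] + b1
        bulges.append(Bulge("hairpin", b0, b1))
    return HairpinModel(strand=strand, pairs=pairs, terminal_loop=loop,
                        bulges=bulges, score=score, ambiguous=n_opt > 1)


def _hairpin_core_bonus(s: str, pair_map: dict[int, int], side: int,
                        bulge_end_local: int, r: int) -> int:
    """Tandem G:A/A:G bonus for a hairpin stem bulge (either arm)."""
    pm = dict(pair_map)
    pm.update({j: i for i, j in pair_map.items()})
    b_end = bulge_end_local if side == 1 else r + bulge_end_local
    p1, p2 = b_end, b_end + 1
    if p1 not in pm or p2 not in pm:
        return 0
    if pm[p2] != pm[p1] - 1:
        return 0
    if s[p1] == "G" and s[pm[p1]] == "A" and s[p2] == "A" and s[pm[p2]] == "G":
        return 2
    return 0


def _ladder_stem(arm1: str, arm2: str, max_bulge: int, count_wobble: bool):
    """Enumerate stem ladders pinned at the loop-closing pair.

    arm1 is the 5' arm (its last base closes the loop with arm2's first
    base).  Yields (pairs [(i1, j2_local)], bulge) where bulge is
    (arm, start, end) in arm-local coordinates, or None.
    """
    a, b = len(arm1), len(arm2)
    # no bulge: ladder from the closing pair outward
    k = min(a, b)
    yield [(a - 1 - t, t) for t in range(k)], None
    for g in range(1, max_bulge + 1):
        # bulge on arm1 after d closing pairs (counted from the loop)
        for d in range(1, min(a, b)):
            inner = [(a - 1 - t, t) for t in range(d)]
            k2 = min(a - d - g, b - d)
            if k2 < 1:
                continue
            outer = [(a - 1 - d - g - t, d + t) for t in range(k2)]
            yield inner + outer, (1, a - d - g, a - d)
        # bulge on arm2 after d closing pairs
        for d in range(1, min(a, b)):
            inner = [(a - 1 - t, t) for t in range(d)]
            k2 = min(a - d, b - d - g)
            if k2 < 1:
                continue
            outer = [(a - 1 - d - t, d + g + t) for t in range(k2)]
            yield inner + outer, (2, d, d + g)


# ---------------------------------------------------------------------------
# k-turn scanning and position nomenclature
# ---------------------------------------------------------------------------

def _tracks(model: DuplexModel | HairpinModel):
    """(key, length, seq) per strand track of the model."""
    if isinstance(model, DuplexModel):
        return [("b", len(model.bulged_strand), model.bulged_strand.sequence),
                ("n", len(model.partner_strand), model.partner_strand.sequence)]
    return [("h", len(model.strand), model.strand.sequence)]


def _candidate_runs(model: DuplexModel | HairpinModel):
    """Maximal internal unpaired runs, per track, outside terminal loops."""
    pm = model.partner_map()
    loop = model.terminal_loop if isinstance(model, HairpinModel) else None
    for key, length, _seq in _tracks(model):
        paired = [i for i in range(length) if (key, i) in pm]
        if not paired:
            continue
        lo, hi = paired[0], paired[-1]
        i = lo
        while i <= hi:
            if (key, i) in pm:
                i += 1
                continue
            j = i
            while j <= hi and (key, j) not in pm:
                j += 1
            if loop is None or not (i < loop[1] and j > loop[0]):
                yield (key, i, j)
            i = j


def scan_kturns(model: DuplexModel | HairpinModel,
                bulge_range: tuple[int, int] = BULGE_RANGE,
                count_wobble: bool = False) -> list[KTurnAnnotation]:
    """Locate k-turn motifs: a short internal bulge followed 3' (on the
    bulged strand) by opposed base identities G:A then A:G.

    Both strands of a duplex are scanned, so the motif is found whether
    or not the bulge lies on the strand designated "bulged" at
    hybridization time.  Returns annotations sorted by bulge position;
    an empty list is a valid result.
    """
    pm = model.partner_map()
    out = []
    lo, hi = bulge_range
    for key, start, end in _candidate_runs(model):
        if not (lo <= end - start <= hi):
            continue
        p1, p2 = (key, end), (key, end + 1)
        q5 = (key, start - 1)
        if p1 not in pm or p2 not in pm or q5 not in pm:
            continue
        if pm[p2][1] != pm[p1][1] - 1:  # core pairs must be ladder-contiguous
            continue
        if (model.base(p1), model.base(pm[p1])) != ("G", "A"):
            continue
        if (model.base(p2), model.base(pm[p2])) != ("A", "G"):
            continue
        out.append(annotate_positions((model, Bulge(key, start, end)),
                                      count_wobble=count_wobble))
    out.sort(key=lambda a: a.bulge.start)
    return out


def annotate_positions(site, count_wobble: bool = False) -> KTurnAnnotation:
    """Assign the standard nomenclature to a scanned k-turn site.

    ``site`` is (model, bulge) as produced by :func:`scan_kturns`.
    Bulge nucleotides are labelled L1..Lk 5'->3'; numbering increases
    (1b, 2b, ...) into the NC helix and decreases (-1b, -2b, ...) into
    the C helix, with n-labels on the opposed strand.  Helix lengths
    count contiguous ladder pairs: the C helix from the (possibly
    non-canonical) -1b:-1n closing pair through contiguous Watson-Crick
    steps, the NC helix from the two G:A core pairs through contiguous
    Watson-Crick steps beyond 2b:2n; counting stops at the first
    non-Watson-Crick step (G:U wobble excluded unless ``count_wobble``).
    """
    model, bulge = site
    pm = model.partner_map()
    key, start, end = bulge.strand, bulge.start, bulge.end
    key = {"bulged": "b", "partner": "n", "hairpin": "h"}.get(key, key)
    seq_of = model.base

    if (key, start - 1) not in pm or (key, end) not in pm:
        raise AnnotationError("core not helically closed: bulge lacks a paired flank")

    def strand_id(pos):
        if isinstance(model, HairpinModel):
            return model.strand.id
        return (model.bulged_strand.id if pos[0] == "b"
                else model.partner_strand.id)

    positions: dict[str, Position] = {}

    def put(label: str, pos: tuple[str, int]) -> None:
        positions[label] = Position(strand_id(pos), pos[1], seq_of(pos))

    for k, i in enumerate(range(start, end)):
        put(f"L{k + 1}", (key, i))

    def walk(first_b: int, step: int):
        """Ladder-contiguous opposed pairs walking from first_b by step."""
        out = []
        b = (key, first_b)
        if b not in pm:
            return out
        n = pm[b]
        out.append((b, n))
        while True:
            nb = (key, b[1] + step)
            if nb not in pm or pm[nb][1] != n[1] - step:
                break
            b, n = nb, pm[nb]
            out.append((b, n))
        return out

    # partner index decreases as bulged index increases in every ladder here
    nc_pairs = walk(end, +1)
    c_pairs = walk(start - 1, -1)
    for k, (b, n) in enumerate(nc_pairs, start=1):
        put(f"{k}b", b)
        put(f"{k}n", n)
    for k, (b, n) in enumerate(c_pairs, start=1):
        put(f"-{k}b", b)
        put(f"-{k}n", n)

    def helix_len(pairs, skip: int) -> int:
        """skip pairs counted unconditionally, then contiguous WC steps."""
        count = min(skip, len(pairs))
        for b, n in pairs[skip:]:
            if not is_wc(seq_of(b), seq_of(n), count_wobble):
                break
            count += 1
        return count

    c_len = helix_len(c_pairs, 1)
    nc_len = helix_len(nc_pairs, 2)
    if c_len < 1 or nc_len < 1:
        raise AnnotationError("core not helically closed")

    if isinstance(model, HairpinModel):
        polarity = "NC-side" if start < model.terminal_loop[0] else "C-side"
    else:
        polarity = "duplex"

    return KTurnAnnotation(
        model=model,
        positions=positions,
        c_helix_length=c_len,
        nc_helix_length=nc_len,
        bulge_sequence="".join(seq_of((key, i)) for i in range(start, end)),
        loop_polarity=polarity,
        bulge=Bulge(key, start, end),
        ambiguous=getattr(model, "ambiguous", False),
    )


# ---------------------------------------------------------------------------
# Shine-Dalgarno overlap
# ---------------------------------------------------------------------------

def sd_overlap(utr: RNAStrand, annotation: KTurnAnnotation,
               sd_interval: tuple[int, int]) -> SDOverlapReport:
    """Report which k-turn positions a Shine-Dalgarno interval covers and
    whether any SD position is paired (occluded) in the stem-loop model."""
    lo, hi = sd_interval
    if not (0 <= lo < hi <= len(utr)):
        raise IndexError(f"SD interval {sd_interval} out of range for UTR "
                         f"of length {len(utr)}")
    labels = {
        lab for lab, p in annotation.positions.items()
        if p.strand_id == utr.id and lo <= p.index < hi
    }
    pm = annotation.model.partner_map()
    track = "h" if isinstance(annotation.model, HairpinModel) else None
    occluded = False
    for i in range(lo, hi):
        keys = [("h", i)] if track else [("b", i), ("n", i)]
        for k in keys:
            if k in pm and _pos_on_strand(annotation.model, k, utr):
                occluded = True
    return SDOverlapReport(sd_interval=sd_interval, overlapping_labels=labels,
                           occluded_in_stem=occluded)


def _pos_on_strand(model, pos, strand: RNAStrand) -> bool:
    if isinstance(model, HairpinModel):
        return model.strand.id == strand.id
    s = model.bulged_strand if pos[0] == "b" else model.partner_strand
    return s.id == strand.id


SD_CONSENSUS = "AGGAGG"


def scan_sd_consensus(utr: RNAStrand, min_matches: int = 4) -> tuple[int, int] | None:
    """Optional consensus scan: the window best matching AGGAGG.

    Returns the half-open interval of the best-scoring window with at
    least ``min_matches`` identities, or None.  Never applied silently;
    the SD interval used in reports is always user-supplied.
    """
    w = len(SD_CONSENSUS)
    best, best_i = 0, None
    for i in range(len(utr) - w + 1):
        score = sum(a == b for a, b in zip(utr.sequence[i:i + w], SD_CONSENSUS))
        if score > best:
            best, best_i = score, i
    if best_i is None or best < min_matches:
        return None
    return (best_i, best_i + w)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_fasta_strand(path, label: str | None = None) -> RNAStrand:
    """Read the first record of a FASTA file as an RNAStrand."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return RNAStrand(id=rec.id, sequence=str(rec.seq).upper().replace("T", "U"),
                     label=label)


def dot_bracket(model: DuplexModel | HairpinModel) -> str:
    """Dot-bracket rendering; duplex strands joined by '&'."""
    if isinstance(model, HairpinModel):
        chars = ["."] * len(model.strand)
        for i, j in model.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)
    b = ["."] * len(model.bulged_strand)
    n = ["."] * len(model.partner_strand)
    for i, j in model.pairs:
        b[i], n[j] = "(", ")"
    return "".join(b) + "&" + "".join(n)


def annotation_table(ann: KTurnAnnotation) -> str:
    """TSV of (label, strand, 0-based index, 1-based position, base)."""
    lines = ["label\tstrand\tindex0\tposition1\tbase"]

    def sort_key(item):
        lab = item[0]
        if lab.startswith("L"):
            return (1, int(lab[1:]), 0)
        sign = -1 if lab.startswith("-") else 1
        num = int(lab.rstrip("bn").lstrip("-"))
        return (0 if sign < 0 else 2, sign * num, 0 if lab.endswith("b") else 1)

    for lab, p in sorted(ann.positions.items(), key=sort_key):
        lines.append(f"{lab}\t{p.strand_id}\t{p.index}\t{p.index + 1}\t{p.base}")
    return "\n".join(lines) + "\n"
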