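# Methods

This note records the models, conventions and numerical choices behind
`kturn`, in the spirit of a package manual: what is computed, under
which assumptions, and what the synthetic tests do and do not show.

## The k-turn model and position nomenclature

A k-turn is modelled at sequence level as a ladder duplex: a short
internal bulge (1–5 nt accepted, canonically 3) on one strand,
immediately followed on its 3′ side by opposed base identities G:A and
then A:G — the sequence-level proxy for the tandem
*trans*-sugar-Hoogsteen pairs that define the motif. Positions are
labelled L1..Lk across the bulge, 1b, 2b, … into the non-canonical
(NC) helix and −1b, −2b, … into the canonical (C) helix, with
n-suffixed labels for the opposed strand. Coordinates are 0-based,
intervals half-open; rendered tables also print 1-based positions.

Helix lengths follow the counting that reproduces the motif's
published duplex dimensions: the C helix counts the −1b:−1n closing
pair unconditionally (it is a genuine pair even when non-canonical,
e.g. C:A) plus contiguous Watson–Crick steps 5′ of it; the NC helix
counts the two G:A core pairs plus contiguous Watson–Crick steps
beyond 2b:2n. Counting stops at the first non-WC step (strict); G:U
wobble is excluded by default and can be enabled via `count_wobble`.
For a one-bulge duplex the two lengths sum to the partner-strand
length (12 + 13 = 25 for the FRET construct; adding the 3-nt bulge
gives the 28-nt bulged strand).

### Hybridization and hairpin folding

`hybridize_strands` enumerates every antiparallel ladder alignment
with at most one internal bulge (≤ `max_bulge` nt) on the bulged
strand, scoring +1 per Watson–Crick pair and +2 when a bulge is
directly followed by the G:A/A:G core identities (these two opposed
positions are treated as paired although non-complementary). The
maximum-scoring ladder wins; all opposed positions in its overlap are
recorded as pairs, mismatched ones included — the crystal structure of
this motif shows that the flanking C:A and A:U "mismatches" are real,
if non-canonical, pairs. Ties prefer the 5′-most, shortest bulge and
set an `ambiguous` flag. Alignments scoring fewer than `min_pairs`
(default 4) raise `NoDuplexError`.

`fold_hairpin` applies the same machinery to a single strand: the stem
is pinned at the loop-closing pair, the bulge may sit on either arm,
terminal loops of 3–12 nt are searched, and dangling tails are allowed
at the outer ends. This is combinatorial base-pair maximization, not
free-energy folding: co-optimal stems exist for pathological
sequences, and no attempt is made to rank them thermodynamically.
Consequently the generator round-trip guarantee is stated against the
generated pairing model; refolding from raw sequence is unambiguous
only when the stem retains enough Watson–Crick content (it is, for the
canonical C:A / A:U signature).

### Shine–Dalgarno handling

The SD interval is always user-supplied. `scan_sd_consensus` offers a
best-window match to AGGAGG (≥ 4 identities) but is never applied
silently, because the source data mark SD sites without giving a
detection rule.

## Folding rules

The rule engine is table-driven (YAML, versioned, user-extensible):

* 3b:3n — Watson–Crick pairs prevent ion-induced folding; 3b = C or
  3n = G confers it. When both clauses apply (C:G) the conferring
  clause wins by default; the precedence is configurable because the
  complete sequence-behaviour table is only partially published.
* −1b:−1n — C:G confers, G:C prevents, C:A prevents; all other pairs
  are undetermined (no systematic study exists).
* Combination — any "prevents" dominates; otherwise any "confers"
  yields "folds", with a reduced-confidence note when the other rule
  is undetermined; otherwise undetermined. The trace always carries
  both rule outcomes so callers can inspect hedged cases.
* Protein-induced folding is the constant "folds": every k-turn
  analyzed to date folds on L7Ae binding regardless of these
  sequences.
* N-class prediction is a 3b:3n lookup shipping with the single
  experimentally confirmed row A:U → N3.

## Tight-binding FRET isotherm

With RNA at concentrations comparable to the dissociation constant,
ligand depletion matters and the fitted model is

E(P_T) = E0 + ΔE · [(1 + K_A P_T + K_A R_T) − √((1 + K_A P_T + K_A R_T)² − 4 K_A² R_T P_T)] / (2 K_A R_T)

the bracketed term being the bound fraction (smaller root of the
mass-balance quadratic, clamped to [0, 1]; the radicand is clipped at
zero against round-off, with a hard error if it goes negative beyond
1e-8 relative). Units: concentrations molar, K_A in M⁻¹, E
dimensionless.

Fitting choices: homoscedastic least squares (no per-point errors are
available for this kind of data); ln K_A is the optimized variable to
enforce positivity across decades; initialization E0 ← min E,
ΔE ← max E − min E, K_A ← 1/(P_T at half amplitude); trust-region
reflective with tolerances 1e-14 so fits are reproducible to machine
precision. Standard errors come from the Jacobian curvature at the
optimum; 95 % intervals use a t quantile with n−3 degrees of freedom.
Degenerate (flat) curves are flagged: se(ln K_A) > 2 — an e²-fold
uncertainty either way — marks K_A unidentifiable; boundary hits and
non-convergence are reported as warnings, never silently.

E_FRET itself is computed by acceptor normalization: the donor-excited
spectrum is decomposed by linear least squares into a scaled
donor-only reference plus a scaled copy of the directly excited
acceptor spectrum; the acceptor coefficient is (ratio)A and
E = ((ratio)A − ε_A(λ_D)/ε_A(λ_A)) · ε_A(λ_A)/ε_D(λ_D). Extinction
ratios are inputs, not constants, because normalization dialects
differ between instruments; the implemented formula is pinned by
round-trip tests against the forward simulator.

Response classification: a titration whose E_FRET never reaches 0.18
is "non_folding" (the ion signature of this UTR); a converged fit with
ΔE > 3 SE and plateau E0 + ΔE above the threshold is a
"folding_transition" (the protein signature); anything else returns
"undetermined" with diagnostics. The 0.18 threshold is a configurable
default taken from the observed ion-titration ceiling.

## Structural classification

Hydrogen bonds: donor–acceptor distance ≤ 3.5 Å; when the donor's
covalent antecedent atom is present, the antecedent–donor–acceptor
angle must be ≥ 120° (crystal structures lack hydrogens, so the angle
test is skipped when no antecedent geometry exists). The
donor/acceptor chemistry table covers A, C, G, U base edges plus the
2′-OH; unknown residue types are skipped with a warning. The detector
is pinned against an independent all-pairs brute-force oracle.

cis/trans orientation follows the Leontis–Westhof sense
operationalized as the sign of the dot product of the two
glycosidic-bond vectors' components perpendicular to the C1′–C1′ pair
axis. Edge assignment is by which atoms carry the hydrogen bonds
(WC/Hoogsteen/sugar edge membership tables). The classifier
distinguishes trans-sugar-Hoogsteen G:A, single-H-bond cis/trans
pairs, and cis-Watson–Crick; everything else is unclassified with a
reason.

N1/N3 class is read off the acceptor of the −1n O2′ donor on the 2b
adenine (N3 → N3 class, N1 → N1); the checklist independently records
the L1 O2′ → A1n N1 cross-strand bond. Because the source material is
internally inconsistent about the −1 pair's acceptor atom, the
classifier reports whatever acceptor satisfies the criteria instead of
hard-coding one.

Kink angle: one principal axis per helix through backbone P atoms
(fallback C1′), each oriented 5′→3′ along the given residue order, so
coaxial stacked helices read 0° and the canonical tightly kinked
geometry reads ≈ 50° (`REFERENCE_KINK_ANGLE`). Under this orientation
convention the kinked fixture necessarily measures a *larger* axis
deviation than the extended (coaxial) one, and that is the ordering
the tests assert. Collinear or under-determined point sets raise a
geometry error rather than returning noise.

## In-line probing model

Reactivity is a three-level deterministic map of the structural state:
baseline 1.0 for flexible single strand, 0.2 for paired or
protein-footprinted positions, 2.5 for terminal-loop positions in the
bound state (arbitrary band-intensity units, configurable, with the
invariant protected < baseline < enhanced). Contradictory assignments
resolve to the lower level with a note. Protection calls between
conditions use conventional two-fold thresholds (bound/apo ≤ 0.5
protected, ≥ 2.0 enhanced, configurable); zero-apo positions have
undefined fold change and are called unchanged with a flag. The SD
occlusion score is the protected fraction of the SD interval. The
probing readout here is a model of the qualitative published pattern
(uniform apo cleavage; stem protection and loop enhancement on protein
binding; no stem protection for the core mutant); no per-band
intensities exist to fit quantitatively.

## Synthetic data

Generators are seeded (`numpy` `default_rng` keyed by seed and a
per-generator stream id, so adding a generator never perturbs another)
and always return their ground truth beside the data.

* Titrations: closed-form isotherm plus Gaussian noise on a 12-point
  log grid bracketing the stoichiometric point. The paper-like preset
  (R_T = 20 nM, E0 = 0.18, plateau 0.6, K_A = 1e8 M⁻¹ giving K_d
  comparable to R_T) encodes the experimental levels as calibration
  inputs; σ = 0.02 is a realistic steady-state E_FRET noise.
* Toy UTRs: hairpins embedding a GAU bulge and G:A/A:G core with any
  requested −1b:−1n and 3b:3n identities, C/NC helix lengths
  (defaults 8/6 — short, as in the natural 5′-UTR stems), terminal
  loop on either side, and the SD hexamer written into the C-helix
  partner strand or a single-stranded tail.
* Structure fixtures: two idealized duplex helices (rise 2.81 Å,
  radius 9.4 Å, twist 30° — 12 residues per strand cover exactly one
  turn, so the principal axis of each point cloud equals the
  construction axis and angle recovery is exact) subtending the
  requested angle, plus core pseudo-atoms placed to make the N-class
  detector return N1, N3 or unclassified by construction. Idealized
  planar base-pair fixtures cover the four pair-geometry classes.
* Probing profiles: predicted levels plus Gaussian noise floored at
  zero; apo/bound state pairs for natural and core-mutant (1b→C,
  2b→G) sequences.

What the generators do **not** emulate: thermodynamic ensembles and
partial occupancy, instrument corrections (lamp, polarization),
heteroscedastic or correlated noise, gel-lane geometry and band
overlap, crystallographic disorder. Passing tests therefore
demonstrate correctness of the algorithms under the stated study
conditions, not robustness to every artifact of real data.

## Problem sizes and determinism

The test suite and acceptance checks run at the sizes the analyses
were designed for: the 28/25-nt FRET duplex; 10⁴ random parameter
points for the isotherm-vs-quadratic cross-check (agreement ≤ 1e-10);
500 replicate 12-point titrations for parameter recovery (median
relative K_A error and t-interval coverage); 100 random 30-atom
structures for the H-bond oracle; 100 random rigid motions for
invariance; 50 noise seeds for probing call accuracy. Everything is
seeded; the whole suite completes in well under a minute on one CPU.

## Known limitations

* The scanner requires exact G:A then A:G identities; k-loop variants
  and multi-bulge cores are out of scope.
* Only one internal bulge per duplex alignment: twofold two-k-turn
  constructs must be built as explicit pairings (the synthetic module
  provides one) rather than aligned from sequence.
* The rule tables are deliberately partial, mirroring what is
  experimentally established; unlisted pairs return
  undetermined/unknown rather than a guess.
* Helix-axis fitting assumes roughly straight helical segments; long
  curved helices would need piecewise fitting.
* The probing model is qualitative by design.
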