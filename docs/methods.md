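# Methods

## Energy model

`dimerfold` scores nested (pseudoknot-free) secondary structures with a
reduced nearest-neighbor model over Watson–Crick (A-U, G-C) and wobble
(G·U) pairs:

* **Stacks.** All 36 ordered combinations of the six pair types, Turner
  2004 values, bundled in `src/dimerfold/data/turner2004-reduced.tsv`
  (free energies at 37 °C, kcal/mol). The table records the step
  `stack XY ZW` as outer pair X–Y over inner pair Z–W
  (5′-XZ-3′/3′-YW-5′); strand symmetry `S[XY][ZW] = S[WZ][YX]` is tested.
* **Loops.** Hairpin (≥ 3 unpaired), bulge and internal-loop initiations
  tabulated by size up to 30, extended by the Jacobson–Stockmayer form
  `E(l) = E(30) + 1.75·RT·ln(l/30)`.
* **Multiloops.** Affine: closing `a = 9.3`, per-branch `b = −0.9`
  (closing branch included), per-unpaired `c = 0.0` kcal/mol.
* **Helix ends.** `+0.5` kcal/mol per helix end closed by A-U or G-U,
  applied in every non-stack loop context (hairpin, bulge, internal,
  multiloop, exterior). An isolated pair therefore pays it twice.
* **Dimer terms.** `+4.1` kcal/mol intermolecular initiation per complex,
  and `+RT ln 2` homodimer symmetry correction for indistinguishable
  strands (switchable via `load_parameters(symmetry_correction=False)`).

Deliberate omissions, chosen so that the whole model is exactly
reproducible by exhaustive enumeration at test time: no sequence-specific
tetraloop bonuses, no dangling ends, no coaxial stacking, no Ninio
asymmetry term for internal loops, and no stack retention through 1-nt
bulges (all bulges are scored as initiation plus two helix-end
penalties). For the 19–20-mers this package targets, stem and
hairpin-loop terms dominate and these refinements shift all candidate
sequences nearly uniformly.

Temperature (default 310.15 K) only sets RT for Boltzmann sums; the
tabulated free energies themselves are 37 °C values.

## Folding algorithms

`fold_mfe` is a Zuker-style dynamic program (`V`/`WM`/`WM1` plus exterior
`W`), interior loops capped at 30 unpaired residues, with a
deterministic traceback that prefers unpaired extensions (fewer pairs)
and smaller pair indices among energy ties (tie tolerance 1e−7
kcal/mol). `partition_function` is the McCaskill inside/outside
algorithm over the identical structure space and energy terms; pair
probabilities come from the outside recursion
`P(i,j) = Q^b_{ij}·O_{ij}/Z`. Arithmetic is linear-space (no rescaling),
which is exact and overflow-safe for the oligonucleotide regime
(roughly n ≤ 100); longer inputs raise rather than silently overflow.

Constraints enter in two forms: a per-residue mask forcing residues
unpaired (hard SHAPE constraints), and per-paired-residue pseudo-free
energies (see SHAPE below). Both are honored identically by the MFE and
partition-function engines and by the enumeration oracle used in tests.

**Correctness strategy.** The loop-decomposition scorer
(`energy.pair_set_energy`) is the single source of truth. The test suite
enumerates every nested structure of hundreds of seeded random
sequences (n ≤ 13; ≥ 200 sequences in the acceptance check), scores them
with that function, and requires the DP MFE, Z and all pair
probabilities to match brute force to 1e−6 relative. This catches any
divergence between recursion and energy model, at the price of
restricting the model to terms a loop decomposition can express — which
is exactly why the omissions above were chosen.

## Homodimer ensemble

`cofold_homodimer` computes the two-strand ensemble on the concatenation
`seq‖seq` with a nick between positions n and n+1:

* a pair may span the nick with no minimum-loop restriction (a blunt
  1-bp "duplex" is a valid, if weak, structure);
* any loop whose free (unpaired) walk crosses the nick — including what
  would otherwise be a hairpin or a stack bridging the two strands — is
  scored like an exterior loop: terminal penalties only;
* the dimer ensemble keeps only structures with ≥ 1 inter-strand pair.

The final sum decomposes over the unique *outermost* inter-strand pair,
so `Z_inter` is built directly rather than as the difference
`Z_total − Z_mono²`, avoiding catastrophic cancellation for weakly
dimerizing sequences. Then
`ΔG_dimer = −RT ln Z_inter + ΔG_init + RT ln 2`,
`gap = ΔG_dimer − 2·ΔG_monomer`, `K = exp(−gap/RT)`. A sequence with no
possible inter-strand pair (e.g. poly-A) is reported as non-dimerizing:
`gap = +∞`, `K = 0`.

The monomer reference is the unconstrained single-strand ensemble by
default. A `monomer_ensemble="hairpin"` flag restricts it to single
stem-loop structures (one hairpin loop, bulges/internal loops allowed,
no multiloops, empty structure excluded); the default was chosen because
the unconstrained ensemble is the natural partition-function object and
the restriction is a modeling hypothesis best left explicit.

## Sequence design

`design_sequence` runs simulated annealing over single-nucleotide
substitutions at unconstrained positions. Constraints are per-position
IUPAC classes, so a bipartite motif can pin both strands' copies.
Defaults: initial temperature 1.0 (kcal/mol units), geometric cooling
0.999/step, 5000 steps — ample for 20-mers, whose feasible space a few
thousand evaluations covers densely; tests and quick runs use far fewer
steps. Metropolis acceptance uses the gap (dimer mode) or its negative
(monomer mode); the non-dimerizing `+∞` sentinel is clamped to ±1e6
kcal/mol inside the acceptance rule so monomer-mode searches can move
toward it and dimer-mode searches away from it. Objective values are
cached per sequence; the best-seen sequence is returned, and the
trajectory invariant (best trajectory value = returned objective) is
tested. With the temperature set to 0 the algorithm reduces to greedy
hill-climbing, which is also tested.

The search strategy itself (annealing, move set, schedule) is this
package's own choice; only the objective — the ensemble dimerization
gap — is fixed by the problem.

## SHAPE handling

Reactivity classes follow the usual reporting thresholds: high ≥ 0.85,
moderate ≥ 0.4, weak < 0.4, missing = unconstrained (both lower bounds
inclusive). `fold_with_shape` offers `hard` mode (high-reactivity
residues forced unpaired) and `pseudo` mode with the Deigan-style term
`ΔG(i) = m·ln(r_i + 1) + b` per paired residue, defaults m = 2.6,
b = −0.8 kcal/mol — configuration values, not constants of the method.
Reactivity files are two-column text (`position reactivity`, `NA` or a
negative sentinel for missing).

## Duplex annotation

`align_self_duplex` opposes position i of one strand with position
n+1−i+offset of an identical antiparallel strand. Labels:
WC (A-U/U-A/C-G/G-C), wobble (G·U), AC, GG, and `other` for every
remaining opposition, so the census is total; `overhang` marks residues
with no opposed partner in shifted registers. `auto` register scans
offsets −3..+3 and keeps the (WC + wobble)-maximal one, ties to the
smallest |offset| — wobble counts as favorable because it is
helix-compatible. For the study's 19-mer RNA II the blunt register gives
14 WC + 4 A·C + 1 G·G (the central position 10 opposes itself).

## Motif scanning

Motifs are IUPAC strings with at most one bounded gap `(N){lo,hi}`.
Scanning compiles to a regex inside a lookahead so overlapping start
positions are all reported; at one start position the gap width is
resolved greedily (one hit per start). Per-sequence presence (≥ 1 hit)
is the headline statistic. `scan_in_loop` refolds each sequence and
keeps hits only if a matched residue lies inside a hairpin loop of the
MFE structure. The pool simulator plants one motif instance (random gap
width and N-fills, random feasible offset) in a chosen fraction of
uniform random sequences — by construction the scanner must then report
at least the planted count, which is the soundness test. The analytic
background model is Poissonian: P(≥1 match) = 1 − exp(−E[matches]),
accurate for rare motifs; the observed background rate is required to
match within three binomial standard errors.

The simulator emulates a sequenced SELEX pool only in the sense of
motif placement statistics; it has no selection rounds, no sequencing
error, and no nucleotide composition bias, so passing tests say nothing
about enrichment dynamics in real pools. Probabilistic motif-discovery
counts (MEME/GLAM2-style) are a different algorithm class and are not
comparable to this deterministic scanner's counts.

## 3D geometry

Structures are read via gemmi (PDB or mmCIF); polymer RNA residues
(A/C/G/U with a C1′ atom) enter the analysis, everything else is listed
as heterogens. Alternate locations are resolved by policy:
`highest_occupancy` (default), `label:X`, or explicit per-combination
enumeration for disordered pairs (`pair_geometry_altlocs`).

Base pairs are detected geometrically: ≥ 2 contacts ≤ 3.5 Å between base
N/O atoms, base planes (SVD fits) within 30° of parallel, and the
contact vector's projection onto the plane normal ≤ 1.5 Å — the last
criterion separates in-plane hydrogen bonds from stacking contacts,
which run along the normal. Assignment is greedy by contact count, then
closest contact; each residue joins at most one pair. Labels are by base
composition (WC/wobble/AC/GG/other).

Per-pair measurements: C1′–C1′ distance and the two λ angles (glycosidic
bond vs the C1′→C1′ vector). Helix parameters use a single global
straight axis — the first principal direction of the C1′–C1′ midpoints,
oriented 5′→3′: rise is the projection of consecutive midpoint steps on
the axis, twist the signed angle between consecutive C1′→C1′ vectors
projected perpendicular to it. This is simpler than per-step local axes
(3DNA-style); for nearly straight oligomer duplexes it reproduces rise
to ~0.1 Å and twist to ~1°, which is the tolerance used for crystal
comparisons. Strongly bent helices would need local axes and are out of
scope. Syn/anti glycosidic conformations are classified by the χ
torsion (syn iff χ ∈ (−90°, +90°]).

`kabsch_superpose` implements the SVD superposition with the proper-
rotation determinant correction; tests cross-check it against
`scipy.spatial.transform.Rotation.align_vectors` and verify the metric
properties.

The ideal A-form generator places per-pair atom templates (C1′,
glycosidic N, the two Watson–Crick-edge polar atoms, ring fillers, P) on
a straight vertical axis with configurable rise and twist (defaults
2.81 Å, 32.7° ≈ 11 bp/turn). It is a *synthetic* fixture generator: its
templates have idealized in-plane bases and exact helical symmetry, so
parameter-recovery tests on it validate the measurement code, not any
claim about real crystals. With `partner="self"` it builds the blunt
homodimer of a given sequence including its mismatched oppositions
(A·C, G·G), which exercises the detection/labeling path on
non-canonical pairs.

## Numerical choices and edge cases

* Boltzmann sums in linear space; overflow raises (`OverflowError`)
  rather than degrading — adequate below ~100 nt.
* MFE tie-breaking: fixed traceback order (hairpin before interior
  before multiloop; unpaired extension first), tolerance 1e−7.
* Interior loops capped at 30 unpaired residues (standard MAXLOOP).
* Pair probability matrices are (n+1)×(n+1) with 1-based indexing;
  row sums ≤ 1 is a tested invariant.
* Degenerate inputs: length-1 sequences fold to the empty structure with
  Z = 1; `cofold` requires n ≥ 2; helix fitting requires ≥ 2 pairs;
  superposition requires ≥ 3 atoms and equal selections.
* All randomized components (pool simulation, annealing) take explicit
  integer seeds and are bit-reproducible.

## Test-scale choices

Enumeration-oracle checks use sequences of length ≤ 13 (hundreds of
structures each), 200+ sequences per run; cofold oracle checks use
strands of length ≤ 8 (16-nt concatenations). Design tests use 12-mers
with 60–150 annealing steps against 100-sample random baselines. These
sizes give exhaustive coverage of the recursion cases while keeping the
whole suite in a few seconds.

## Known limitations

* The reduced energy model is not bit-compatible with full Turner 2004
  implementations (no dangles/tetraloops/coaxial terms); absolute free
  energies differ from ViennaRNA's by roughly the magnitude of those
  terms, while rankings of closely related oligomers are largely
  preserved.
* No pseudoknots, no heterodimers, no concentration-dependent
  monomer/dimer solver (the gap and K are per-complex quantities).
* The global-axis helix parameters are only meaningful for short,
  nearly straight duplexes.
* Hydrogen-bond detection is a geometric heuristic, not a trained
  classifier; protonation-dependent pairs (A⁺·C) are labeled by
  composition, not chemistry.
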