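# dimerfold

Short self-complementary RNAs sit on a knife edge between two folds: each
strand can close on itself into a hairpin, or two strands can anneal into an
antiparallel duplex. Which form dominates matters biologically — the
zinc-finger protein Com of bacteriophage Mu, for example, recognizes its
`GAG(N)2CC` target motif only when it is presented in a hairpin loop, and
binds the same motif weakly inside a duplex. `dimerfold` is a toolkit for
designing and analyzing oligonucleotides on that monomer/homodimer boundary.

It is aimed at structural and synthetic RNA biologists who want to:

* compute nearest-neighbor folding thermodynamics for short RNAs — minimum
  free energy (MFE) structures, McCaskill partition functions `Z`, base-pair
  probabilities;
* quantify the homodimerization equilibrium of a single sequence via the
  **gap** `ΔG_gap = ΔG_dimer − 2·ΔG_monomer`, related to the dimerization
  constant by `K = exp(−ΔG_gap/RT)`;
* inverse-design sequences that pin a conserved motif while minimizing
  (dimer-forming) or maximizing (hairpin-forming) that gap, by simulated
  annealing;
* fold under SHAPE reactivity constraints (hard or pseudo-free-energy);
* annotate self-complementary duplex registers and census canonical vs
  non-canonical oppositions;
* scan sequence pools for gapped IUPAC motifs (SELEX-style), with an
  optional hairpin-loop context filter;
* measure 3D duplex geometry from PDB/mmCIF coordinates: base-pair
  detection, C1′–C1′ distances, λ angles, helix-axis rise and twist, and
  Kabsch superposition.

## The model

Folding free energies use a reduced Turner 2004 nearest-neighbor model:
Watson–Crick and G·U stacks, length-dependent hairpin/bulge/internal-loop
initiations (Jacobson–Stockmayer extension beyond 30 nt), an affine
multiloop term, terminal A-U/G-U penalties, and an intermolecular
initiation penalty plus `+RT ln 2` symmetry correction for homodimers. The
two-strand ensemble is computed on the concatenation `seq‖seq` with a
strand nick: loops crossing the nick are scored like exterior loops, and
the dimer ensemble is restricted to structures with at least one
inter-strand pair. Ensemble (not MFE) free energies feed the design
objective. Full details, assumptions and limitations are in
[docs/methods.md](docs/methods.md).

Every dynamic program is validated against exhaustive structure
enumeration: on hundreds of random short sequences, MFE, `Z`, and all pair
probabilities agree with brute force to 1e−6 relative or better.

## Worked example

Fold the hairpin-designed 20-mer RNA I and cofold the duplex-designed
19-mer RNA II:

```text
$ dimerfold fold CGAGAACCAGAGAGUUCCGG
# params=turner2004-reduced T=310.15K
CGAGAACCAGAGAGUUCCGG
...((((......))))...
mfe_kcal_mol    -0.10
ensemble_free_energy_kcal_mol   -0.68
```

RNA I folds into a 4-bp stem closed hairpin whose terminal loop holds
exactly six residues (positions 8–13) — the loop that presents the
`CC(N)2-3GAG` motif. The ensemble free energy (−0.68) lies below the MFE
because `Z` sums every structure's Boltzmann weight.

```text
$ dimerfold cofold AGAGAACCCGGAGUUCCCU
# params=turner2004-reduced T=310.15K
monomer_f_kcal_mol      -0.849
dimer_f_kcal_mol        -10.833
gap_kcal_mol    -9.136
k_dimer 2.738e+06
```

RNA II's dimerization gap of −9.1 kcal/mol (dimerization constant ~3e6)
says the duplex form dominates — the design intent. The same command on
RNA I gives a gap of only −4.2 kcal/mol, and the designer
(`dimerfold design`) will push either quantity further in either
direction under motif constraints.

```text
$ dimerfold annotate-duplex AGAGAACCCGGAGUUCCCU
{
 "register_offset": 0,
 "WC": 14, "wobble": 0, "AC": 4, "GG": 1, "other": 0, "overhang": 0
}
```

The blunt antiparallel self-alignment of RNA II opposes 14 canonical
Watson–Crick combinations and 5 non-canonical ones (four A·C and the
central G·G at position 10) — exactly the pairing census observed in the
crystal structure of this duplex (PDB 6IA2).

3D analysis of a structure file:

```sh
dimerfold make-fixture GGACUUCG --rise 2.81 --twist 32.7 --out duplex.pdb
dimerfold geometry duplex.pdb
```

reports per-pair C1′–C1′ distances and λ angles, and per-step rise/twist
against a global helix axis.

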