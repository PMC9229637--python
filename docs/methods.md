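# Methods

This note records the models implemented, the defaults and why, what the
synthetic generators do and do not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Reactivity descriptors

The descriptor set is the standard finite-difference (operational) form of
conceptual DFT.  Within Koopmans' approximation the frontier eigenvalues
stand in for vertical ionization energy and electron affinity
(IE = −ε_HOMO, EA = −ε_LUMO), from which hardness η = (IE − EA)/2, softness
S = 1/(IE − EA), chemical potential µ = (ε_HOMO + ε_LUMO)/2 (χ = −µ),
electrophilicity ω = µ²/2η and gap E_g = ε_LUMO − ε_HOMO follow.  The exact
derivative definitions (∂E/∂N at fixed external potential) are conceptual
background only and are never evaluated; only the operational forms are
implemented.

Choices:

* **Units** are eV throughout.  Hartree inputs must be pre-converted with
  the documented constant 27.211386 eV/hartree.  This matches how these
  descriptors are conventionally tabulated for drug-like molecules.
* **Signs** follow the Koopmans identification even when it yields a
  negative EA (unbound LUMO above zero): the descriptor table is a linear
  transform of the orbital energies and should not silently clamp.
* A **degenerate or inverted gap** (ε_LUMO ≤ ε_HOMO) is rejected rather
  than propagated, because softness diverges and the closed-shell
  assumption is violated.
* Text output rounds to two decimals (the convention of published
  descriptor tables); full precision is kept in memory, and tests of the
  algebraic identities run at 1e-10.
* Orbital energies enter via a TSV contract (`compound_id`, `homo_ev`,
  `lumo_ev`), not by parsing quantum-chemistry log files: log dialects are
  a moving target and out of scope, and a table is what an appendix or SI
  actually provides.

## Structure I/O

PDB reading is a small fixed-column parser because the downstream contracts
are unusually specific: element inference when columns 77–78 are absent
(two-letter symbols such as Cl/Br recognized only when left-justified at
column 13, so ` CA ` in an amino acid is carbon, not calcium), altloc
filtering (keep blank or 'A'), water removal (HOH/WAT), first-MODEL-only
semantics, and line-numbered errors for malformed coordinates.  The writer
emits the same fixed-column layout; a test verifies that gemmi parses the
writer's output to identical atoms, so the implementation is cross-checked
against an independent PDB stack.

Ligand chemistry is derived geometrically: bonds by a covalent-radius
criterion (sum of radii × 1.3 for heavy pairs; hydrogen attaches within
1.2 Å), rings by enumerating simple cycles of length 5–6 over the
C/N/O/S subgraph and accepting those whose members deviate at most 0.15 Å
from the best-fit plane.  Both tolerances are configurable; the defaults
are conventional values that accept aromatic rings and reject chair
conformers (±0.25 Å puckering).  CONECT records are deliberately not
trusted: docked-pose files routinely lack or corrupt them.

## Interaction profiling

Three detector families, all exact all-pairs scans (no spatial index, so a
brute-force oracle reproduces them bit-for-bit):

* **Halogen contacts** use the operational survey criterion: receptor
  hydrogen strictly closer than 4 Å to a ligand F/Cl/Br/I.  This is a
  deliberate design choice of fidelity to the docking-survey definition
  rather than the crystallographic σ-hole definition; an optional
  `sigma-hole` mode adds a C–X···H angle ≥ 140° requirement for
  comparison and is off by default.  The boundary is strict: a pair at
  exactly 4.0 Å is not a contact.  A receptor without any explicit
  hydrogen cannot satisfy the criterion, so that case raises a warning
  that is embedded in the report rather than returning a silently empty
  list.
* **Hydrogen bonds**: donor/acceptor heavy atoms are N, O, S; a pair
  qualifies at heavy-atom distance ≤ 3.5 Å, and when explicit hydrogens
  are present on either heavy atom the best D–H···A angle must reach
  120°.  Pairs with no explicit hydrogen pass on distance alone, because
  polar hydrogens are commonly absent from X-ray-derived receptors.  The
  3.5 Å / 120° defaults are typical visualization-software settings; the
  exact values used are embedded in every report so results are
  self-describing.  Weak C–H···O bonds are excluded.
* **π interactions**: ring–ring contacts at centroid distance ≤ 5.5 Å
  with interplanar angle ≤ 30° (parallel) or within [60°, 90°]
  (T-shaped); ring–alkyl contacts when an sp3 carbon (an aliphatic
  side-chain carbon of Ala/Val/Leu/Ile/Pro/Met, or a ligand carbon
  bearing ≥ 3 hydrogens) lies within 5.5 Å of a ring centroid.  Receptor
  rings come from canonical side-chain atom names of Phe/Tyr/Trp/His.
  Finer π subtypes (π–σ, amide–π, π–cation) are not distinguished.

Contacts are sorted by (kind, distance, resseq, serial), making reports
byte-stable; within a kind each unordered atom pair appears once.  Reports
expose both the unique-contact total and the (kind, residue) pair total,
since published aggregate counts can follow either convention.

## Docking metrics

Ki = exp(ΔG/RT) with R = 1.98720425864×10⁻³ kcal mol⁻¹ K⁻¹ and T
defaulting to 298.15 K (recorded in every output).  Ranking is ascending
in signed ΔG with a lexicographic tie-break.  The halogen-trend test
compares class means of signed ΔG and is undefined (reported as such, not
guessed) when a class is absent.  Printed-value comparisons in tests use
1% relative tolerance because published ΔG values are rounded to two
decimals before the exponential.

## Superposition and trajectory metrics

Kabsch superposition via SVD of the weighted covariance matrix, with the
reflection case handled by sign-flipping the smallest singular direction so
the rotation determinant is always +1.  The unit test checks the result
against an independent oracle: a rotation-angle grid scan refined by
Nelder–Mead on the no-fit RMSD objective.

Trajectory RMSD fits each frame onto a reference frame (default: frame 0)
over a selection (default: Cα atoms; ligand analyses use all ligand heavy
atoms — published MD summaries rarely state their selection, so it is a
parameter, not a guess).  RMSF fits all frames to the first, then takes
each atom's RMS distance from its trajectory-mean position, averaged per
residue.  For isotropic Gaussian jitter of amplitude σ per axis the
expected RMSF is σ√3; fitting to a noisy reference and removing six
rigid-body degrees of freedom biases this down by roughly
√(1 − 6/(3N_atoms)), about 2.5% at 40 atoms, which is inside the 5%
recovery tolerance used.

Multi-model PDB is the only trajectory format: it is text, diff-able and
sufficient for desk-scale validation; binary MD formats are out of scope.
Published context values for this workflow (a 1.03 Å redocking RMSD, RMSD
ranges of roughly 1.3–3.6 Å over 100 ns runs) require the original docking
and MD engines and are context only — nothing in this package claims to
reproduce them.

## Structure–property correlation

Pearson r via scipy, with zero-variance input rejected explicitly
(returning 0 would silently fabricate independence).  Correlations use
signed ΔG; a `negate_score` switch covers the |score| convention, which
flips every sign — published correlation signs are ambiguous on this point,
so the convention is documented rather than assumed silently.  Rows with
missing values are dropped and counted, never imputed.  No p-values by
default (screen-scale n makes them more misleading than helpful); a
t-based two-sided p is available behind a flag.

## Synthetic generators

The generators emulate the *trend structure* of the study conditions, not
the physics:

* **Orbital tables**: reference compound at ε_HOMO = −5.74, ε_LUMO = −1.50
  (hardness 2.12 eV, the typical parent-scaffold value); halogen series
  F/Cl/Br/I in patterns R1/R2/R3 (one substitution) and R4 (three), with
  the LUMO lowered by 0.29 eV × halogen rank × substitution count plus
  ±0.05 eV uniform jitter.  One iodine substitution then lowers the LUMO
  by 1.16 eV, giving a 3.08 eV gap — the mono-iodo anchor value.  The
  jitter bound is strictly below half the smallest trend step, so the
  hardness ordering along F→Cl→Br→I is deterministic for every seed.
* **Pocket complexes**: a benzene-like ligand ring (heavy atoms only) with
  up to three halogen substituents and one hydroxyl-type oxygen; receptor
  fragments (Val/Leu-style C–H probes, Ser O–H donors, Phe/Tyr rings,
  Pro/Ala alkyl carbons, with familiar active-site residue numbers) are
  placed along pre-analyzed directions so each planted contact is realized
  at its exact requested distance while staying outside every other
  criterion (angular sectors ≥ 60° apart; cross-distances verified in the
  design).  Decoy atoms sit just outside each cutoff.  A collision check
  (non-bonded atoms ≥ 0.8 Å apart) rejects unsatisfiable plants.
  Supported plant counts: ≤ 6 halogen, ≤ 2 each for hydrogen bonds, π–π
  and π–alkyl.
* **Trajectories**: Cα-only helical backbone (default 80 residues numbered
  from 130), per-frame isotropic Gaussian displacement with σ = 0.25 Å in
  the binding-region residue ranges 140–160 and 180–200 and 0.80 Å
  elsewhere — emulating the observation that binding-site residues
  fluctuate least — plus an optional per-frame rigid drift to exercise
  the superposition fit.
* **Property tables**: (µ, ΔG) from a bivariate normal with the requested
  correlation, centered at µ = −4 eV, ΔG = −11 kcal/mol; the remaining
  descriptor columns follow exactly from an independently drawn hardness,
  so the algebraic identities hold in generated data by construction.
* **Docking records**: class means deepening by 0.45 kcal/mol per halogen
  rank from a −10.4 kcal/mol fluorine baseline with ±0.1 kcal/mol jitter,
  so the F < Cl < Br < I ordering holds for every seed.

Passing tests on these fixtures demonstrates that the *detectors and
estimators are correct against known ground truth*; it does not
demonstrate anything about real docked poses, whose geometry is not
ring-plus-fragments, whose hydrogens may be missing, and whose contact
counts depend on pose quality.  That caveat is the price of testability
without the original engines.

## Problem sizes

The default test and acceptance runs use: 10⁴ random orbital pairs for the
identity suite; 100 generated complexes (tens of atoms each) for detector
recovery; 10⁴ frames × 40 residues × 3 seeds for RMSF recovery; n = 1000 ×
20 seeds for correlation recovery.  These sizes make sampling error small
relative to the stated tolerances while keeping a full run in the seconds
range.

## Known limitations

* Element inference from atom names is heuristic; exotic hetero-elements
  outside the documented set fall back to first-letter inference.
* The hydrogen-bond detector does not check donor/acceptor chemistry
  beyond element type (no hybridization or protonation inference).
* Ring perception is geometric, not electronic: any planar 5/6-cycle of
  C/N/O/S counts as aromatic-like.
* The halogen-contact criterion is the operational H···X distance rule;
  counts under it are not comparable to σ-hole halogen-bond statistics.
* Trajectory I/O is multi-model PDB only, which is impractical beyond
  ~10⁵ frame-atoms; the metrics themselves are format-agnostic and accept
  arrays directly.
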