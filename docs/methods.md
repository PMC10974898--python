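# Methods

## Model and assumptions

An RNA chain is represented at two resolutions. The all-atom resolution
keeps every heavy atom of the four standard ribonucleotides (hydrogens are
always dropped; modified nucleotides are excluded). The coarse-grained
resolution keeps three beads per nucleotide, placed exactly on the P, C4′,
and glycosidic-nitrogen atoms (N9 for A/G, N1 for U/C). Backmapping assumes
that each nucleotide can be reconstructed independently by rigidly posing a
template conformation onto its three beads; inter-nucleotide chemistry is
restored afterwards by local repair rather than by simulation. This is the
method's central trade: per-nucleotide fitting is exact, fast, and
deterministic, but concerted multi-residue geometry (helical grooves,
base-pair coplanarity) is only as good as the bead positions imply.

Three beads determine a rigid pose fully (up to the degenerate collinear
case, which is flagged and resolved by the SVD convention), so template
choice is the only discrete decision per nucleotide: every same-base
template is Kabsch-fitted from its own (P, C4′, N) atoms onto the beads and
the smallest fit RMSD wins, ties going to the lower template index.

## Standard fragments and the helix frame

The index-0 template of every base type is an idealized A-form nucleotide
constructed at first use (deterministically, cached):

1. A C3′-endo ribose (pseudorotation phase 18°, amplitude 38°) is solved by
   least squares against standard ring bond lengths, bond angles, and the
   five pseudorotation torsions. Exocyclic substituents (C5′, O3′, O2′ and
   the glycosidic nitrogen) are attached with standard bond lengths/angles,
   taking the stereochemical face from the chemical component dictionary so
   the D-ribose/β-glycoside configuration is preserved. The 5′ arm uses the
   A-form torsions γ = 54° and β = 178°.
2. The base ring is taken rigidly from the CCD ideal geometry (bundled with
   biotite; accurate for in-plane bond lengths and angles) and docked onto
   anchors generated from the anti glycosidic torsion χ = −158°. The CCD
   ideal *conformation* itself is not usable — its ribose is flat — which
   is why the sugar and backbone are built from internal coordinates.
3. The finished nucleotide is posed in a helix frame: a rigid placement is
   solved (least squares, seeded analytically from the nucleotide's own
   screw propagation) such that applying the helix operator — twist 32.7°,
   rise 2.81 Å about z — produces the canonical inter-residue geometry:
   O3′–P bond of 1.60 Å, C3′–O3′–P ≈ 119.7°, O3′–P–O5′ ≈ 104°, and the
   ε/ζ/α torsions near −153°/−71°/−68°, with a hinge penalty keeping all
   non-bonded neighbour contacts outside hard-sphere overlap. All four
   bases share one backbone construction and one placement, so a
   mixed-sequence strand propagated with the helix operator is covalently
   continuous (achieved bond 1.611 Å) and clash-free under the package's
   own radii.

The `next_P` of a standard fragment is its own P mapped one helix step
forward. It contributes to fragment-diversity RMSDs but is never emplaced;
the 3′-neighbour's template provides that phosphate.

## Template library

Fragments segmented from all-atom structures must carry the complete
expected heavy-atom set for their base type (5′-phosphate included, OP3
excluded); incomplete nucleotides are skipped and counted. The diversity
score of a fragment is the post-superposition RMSD to its standard over all
shared named heavy atoms, `next_P` included when both carry it — the paper
behind this design does not name the atom set, and using all atoms captures
backbone and base deviation together. Selection for a k-template library is
stratified-percentile: the non-standard pool is ranked by that score and
the fragment nearest each of the k−1 evenly spaced percentile midpoints is
taken, ties broken by pool order. This guarantees determinism and spread;
it does not attempt the (unpublished) exact selection used to build any
particular released library. Redundancy removal of source structures is
the user's responsibility; a naive greedy sequence-identity filter is
provided as a convenience only.

## Refinement

Parameters (all configurable via `RefineParams`): bond window [1.4, 1.8] Å
with repair target 1.6 Å; C4′–C4′ pair prefilter 20 Å; rotation step π/20;
step cap 100 per clashing pair; Bondi-type van der Waals radii C 1.70,
N 1.55, O 1.52, P 1.80 Å (the clash criterion is distance < radius sum; the
radii themselves are this package's choice).

Bond repair translates the 5′-phosphate group (P, OP1, OP2, O5′) of the
downstream residue rigidly along the O3′→P direction to the target length —
the simplest local move that preserves the group's internal geometry. If
the translation leaves O5′–C5′ outside [1.2, 1.7] Å, O5′ alone is scaled
back to the nearest bound. Numbering gaps greater than one are treated as
declared chain breaks and never "repaired".

Clash elimination considers only base-involving pairs (phosphate–base,
sugar–base, base–base): backbone–backbone contacts are rare in assembled
structures and skipping them is a deliberate speed choice inherited from
the method. For each clashing pair (i, j), j > i, in ascending order, the
base of residue j rotates about its C4′→N axis; the glycosidic nitrogen is
the fixed pivot, so bead positions are untouched. The rotation sign is
re-chosen each step as the direction that moves the base centroid away from
the deepest colliding atom — a deterministic proxy for "away along the
collision vector". Two safeguards extend the bare loop: the step cap stops
irresolvable geometries, and if processing a pair leaves the structure with
more total clashes than before, the base is restored, making the global
clash count provably non-increasing on every input. Bond check runs before
clash elimination, once; clash rotations cannot break bonds (they move base
atoms only), so no second bond pass is needed.

## Synthetic fixtures: what they do and do not emulate

`make_ideal_strand` propagates the standard nucleotide with the helix
operator — it is *library-native* geometry, which makes exact round trips
(reconstruction error < 1e−6 Å) a meaningful self-test rather than luck.
Gaussian bead jitter emulates CG-model imprecision.

`make_fragment_pool` emulates conformational diversity with two concerted
rigid-group modes, both visible to the beads: the 5′-phosphate arm swings
about a fixed axis through C5′ (moving the P bead) and the base tilts about
a fixed axis through C1′ (moving the N bead with the base). Fixed axes make
the pool a low-dimensional family, mimicking how real conformations vary
along correlated torsions; this is what lets a better bead fit imply a
better conformation, the mechanism behind accuracy growing with template
count. What the fixtures do **not** emulate: base rotations about the
glycosidic C4′→N axis itself (invisible to the beads — exactly the loop
base-flip errors that remain hard for the method on real data), sugar
pucker repuckering, sequence-dependent helical irregularity, and tertiary
contacts. Passing tests therefore demonstrate the pipeline's contracts and
trends, not field accuracy on experimental structures — that requires
reconstructing real PDB chains with a library built from a PDB snapshot.

Default study conditions for the desk-scale experiments: 20 strands of the
12-nt mixed sequence GACGUAUGCAGG, bead noise σ = 0.3 Å, nested template
sets k = 1, 3, 6 drawn from one 40-conformer pool per base; refinement
contracts are checked on 50 strands at σ = 0.35 Å. In the acceptance
script's reconstruction-accuracy experiment, ground-truth structures are
assembled from a *separate*, richer 12-template pool (different seed), so
the reconstruction library never contains the exact truth conformers and
the k-dependence is not a trivial round trip.

## Numerical choices

* Kabsch: reflection corrected by sign-flipping the smallest singular
  direction; rotations orthogonal to 1e−9; rank < 2 moving sets flagged
  `degenerate` (fit still returned). Oracle agreement in tests: 1e−6,
  against a quaternion-eigendecomposition implementation.
* Exact-identity guarantees are honored literally: zero-angle base
  rotation, σ = 0 jitter, and refinement of a clean structure return
  bitwise-identical coordinates.
* PDB I/O: altloc blank/'A' kept; first model only; coordinates beyond the
  ±9999.999 fixed-width field raise rather than silently truncate; writing
  round-trips coordinates to the format's 1e−3 Å.
* Tie-breaks: template choice by lowest index; stratified selection by
  stable sort and pool order.

## Known limitations

No duplex generator (the "A-helix" and "strand" fixture forms both produce
a single helical strand). No multi-nucleotide fragments, so CG models with
fewer than three beads per nucleotide are out of scope. No energy model:
refinement guarantees bond windows and non-increasing clash counts, not
clash-free structures (deep interlocks terminate at the step cap and are
reported unresolved). Base-pair interaction fidelity (INF) and
MolProbity-style clash scores are external validators and are not
computed; the internal clash count uses this package's radii and criterion.
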