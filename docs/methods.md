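# Methods

## Scope and model

`trifibril` analyzes amyloid-β (Aβ40) fibrils with three-fold (C3)
symmetry: three protofilaments of in-register, parallel-stacked peptide
chains wound about a common axis, with the C-terminal β-strands lining a
central water pore.  The package covers the *modelling arithmetic* and
the *trajectory observables* of such systems; it runs no molecular
dynamics and assigns no force field.  Simulated trajectories are an
external input (multi-model PDB); for testing they are replaced by a
rigid-body synthetic generator (below).

Chains are indexed by a topology map `chain → (filament f ∈ 1..F, layer
l ∈ 1..L)`.  Because depositions do not document which chain belongs to
which filament/layer, the map is a convention (`layer_major` by default:
chains in deposition order fill layer 1 filaments 1..F first) and can be
overridden by an explicit mapping.  Every analysis indexes structures
only through this map, which keeps per-layer and per-filament statistics
auditable.

## Model building

**Layer replication.** The mean displacement vector between adjacent
layers is the average, over filaments, adjacent layer pairs and atoms
matched by (residue number, atom name), of the upper-minus-lower
coordinate difference.  Stacking k layers places layer k at
`(k−1)·v` — exactly in register, no twist, matching the experimentally
reported absence of twist in this polymorph.  `mean_layer_displacement ∘
replicate_layers` is the identity on `v` to machine precision.

**Truncation and capping.** N-terminal truncation removes residues
below the first kept residue (default 9, i.e. Aβ9–40) from every chain
and places an acetyl cap: six atoms (CH3, C, O, three methyl hydrogens)
with ideal internal geometry (C–N 1.335 Å, C=O 1.229 Å, C–CH3 1.510 Å),
oriented along the former backbone direction.  No energy is ever
computed from these coordinates, so chemical sanity — not rotamer
realism — is the placement criterion.  The operation is idempotent.

**Composition accounting.** Atom counts per chain are derived from the
one-letter sequence with hydrogens included under standard protonation
at neutral pH: Asp/Glu deprotonated, Lys/Arg protonated, His neutral, a
charged N-terminus adding two protons, a charged C-terminus one
carboxylate oxygen, an acetyl N-terminus adding its six atoms and no
terminal proton.  This convention gives 598 atoms and net charge −3 for
Aβ1–40 (charged termini) and 481 atoms / −2 for acetyl-Aβ9–40, and is
the only protonation choice that closes the solvated totals of all eight
reference systems exactly with three-site waters and Na+ counter ions
(`total = chains·atoms_per_chain + ions + 3·waters`,
`ions = |chains·charge|`).  Solvation itself is out of scope: water
counts are inputs.

**Infinite fibril box.** For a periodic (infinite) fibril the stack is
aligned with z and the cuboid box's z dimension is shrunk so that the
distance between the top layer and the periodic image of the bottom
layer equals the template layer spacing exactly.  The measurement uses
Cα centroids of the terminal layers (the reference atoms are exposed
because the original protocol does not specify them).  Waters with
oxygen z outside the half-open `[0, z_new)` slab are deleted; the
half-open interval avoids double-counting molecules on the periodic
face.  The adjustment is idempotent.

## Trajectory observables

**Inter-filament angle φ.** Each filament's axis is the vector between
the Phe19 Cα atoms of its two outermost layers (for a periodic cell: the
first and last layers of the primary cell).  φ is the arc-cosine of the
normalized dot product, averaged over the three unordered filament
pairs, with the dot product clamped to [−1, 1].  An aligned, untwisted
stack gives φ ≈ 0.

**Pore dimension.** The mean intra-layer Met35–Met35 side-chain
distance over the three chain pairs of a layer.  The reference atom
defaults to the side-chain sulfur (SD) and may be set to CE or the
side-chain centroid; on the experimental template the SD choice
reproduces the ~23 Å initial pore.

**RMSD / RMSF.** Backbone (N, Cα, C, O) over residues 9–40 by default,
excluding the flexible N-terminal arm.  RMSD uses optimal rigid-body
superposition (Kabsch, via scipy's `Rotation.align_vectors`); RMSF is
the per-atom RMS deviation about the time-average structure after
superposing every frame onto the reference (first frame unless given).
Whether "mean RMSF" averages over atoms or over per-residue values is
ambiguous in common usage, so both reductions are exposed.

**Radius of gyration.** Mass-weighted; either of the whole assembly or
as the mean over per-layer values (three chains per layer), since
a layer-averaged Rg is the natural per-slice size measure for a fibril.

**Contacts.** An atom-pair contact is a distance strictly below the
cutoff (4 Å default); boundary equality counts as no contact so that
repeated runs are bit-identical.  Counting uses a k-d tree with an exact
distance re-check; tests pin it to an O(n²) brute force.  The
N-terminus × turn map reports, for rows 1–8 and columns 21–30, the
percentage of frames in which the row residue of a chain has at least
one atom pair within cutoff to the column residue of its cyclic
intra-layer successor (1→2, 2→3, 3→1), averaged over layers and, when
several trajectories are given, over runs with equal weight.
Hydrogens are included by default (all-atom counting) with a heavy-atom
option.  Inter-filament series count atom pairs between whole filaments
per frame, divided by the layer count under `per_layer` normalization —
the reading that makes magnitudes comparable across stack sizes.

**Topology classification.** From the three per-layer interface counts,
applied in order: TWO_PLUS_ONE if exactly one interface ≥ `t_high` and
the other two < `2·t_low`; DISSOCIATED if at least two interfaces <
`t_low`; TRIPLE if all ≥ `t_low` and max/min < 3; OTHER else.  The 2+1
rule precedes dissociation because a reinforced pair with two broken
interfaces satisfies both.  Defaults `t_low = 10`, `t_high = 40`
contacts/layer separate the characteristic magnitudes (intact
interfaces at tens of contacts per layer; a reinforced pair far above
`t_high`; broken interfaces near zero); the taxonomy itself is
qualitative, so the thresholds are explicit free parameters and every
label echoes the configuration used.  Trajectories are smoothed with a
centered moving average (default window 10 frames, shrinking at the
edges) before labelling; the end state is the modal label of the final
window, ties resolved toward the most recent label.

## Synthetic fibril generator

The generator emulates the geometry and phenomenology a real fibril
trajectory would show, with none of the physics:

* **Chains are coarse**: one Cα per residue along an idealized
  strand–loop–strand trace, plus named side-chain reference atoms for
  exactly the residues the metrics address.  Every operation in the
  package consumes named atoms, so full-atom rotamer realism would add
  nothing the tests could detect.
* **C3 symmetry is exact** (filaments by 120° rotation about z, layers
  in register at 4.8 Å), so designed values are recovered analytically:
  the Met35 SD atoms sit at `pore_radius` from the axis and the pore
  dimension is `√3·pore_radius` exactly (19.9 Å at the default radius
  11.5 Å, the ~20 Å pore of a relaxed fibril; 13.28 Å reproduces the
  23 Å of the experimental template).
* **The C-terminal interface is engineered**: residues 31–40 carry one
  donor and one acceptor pseudo-atom each (interface circle radius 8 Å,
  ±47°, z-staggered by 0.48 Å per residue), giving ≈80 atom-pair
  contacts per interface per layer in the intact fibril and ≈180 on the
  reinforced interface when two filaments close their 3.6 Å
  donor–acceptor gap — the tens-vs-hundred scale of an all-atom
  interface.
* **The N-terminal arm is engineered** to place exactly the
  experimentally observed polar pairs Arg5–Glu22, Arg5–Val24,
  Asp7–Ser26 and Ser8–Ser26 within the 4 Å cutoff of the successor
  chain's turn, and no other (row 1–8) × (column 21–30) pair.  Relative
  depths and z-offsets of the remaining turn side chains (Asp23, Asn27
  pointing away) enforce this by construction.

Trajectory modes apply per-filament rigid transforms plus i.i.d.
Gaussian jitter (default σ 0.1 Å) from a seeded generator (bit-exact
reproducibility): `stable` (jitter only), `twist` (each filament tilts
about its own radial axis at a linear rate; for equal tilts α about
radials 120° apart every pairwise angle obeys
`cos φ = 1 − 1.5 sin²α`, which `twist_rate_from_angles` inverts exactly
before a least-squares slope fit), `dissociate` (all three filaments
drift apart radially, 1 Å/frame default — separating every stack is the
only motion the default thresholds can distinguish from a 2+1 state,
since a single detached filament leaves an intact ~80-contact interface
that would classify as a reinforced pair), and `two_plus_one` (filament
1 detaches to 30 Å — far enough to clear the long N-terminal arms of
its neighbors — while filaments 2 and 3 each close half the
donor–acceptor gap on a delayed ramp, so the total contact count dips
and then partially recovers).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: internal chain flexibility, correlated
thermal motion, secondary-structure change, solvent, relaxation of the
initial pore (23 → 20 Å is an MD phenomenon), and any energetics or
kinetics of the rearrangements.  Recovery tests demonstrate that the
analysis stack measures what the generator put in, not that real fibril
trajectories behave this way.

## Numerical choices

* Distance comparisons are strict (`<` cutoff); dot products clamped
  before `acos`; acos is ill-conditioned near 0°, so angle invariance is
  asserted at 1e-5 degrees while linear quantities use 1e-9 Å.
* RMSD/RMSF reference defaults to the first frame when none is given.
* Classifier smoothing uses a centered window shrinking at the edges;
  end-state ties break toward the most recent label.
* Water pruning is half-open in z; chain ids are single characters
  (PDB field width), capping replication at 36 chains.
* Problem sizes in the test and acceptance runs (six-layer fibrils,
  40–100-frame trajectories, 20 seeds per mode) were chosen as the
  smallest sizes at which every recovery statistic is stable to well
  within its tolerance.

## Known limitations

* Composition accounting assumes the twenty standard residues and
  Na+-only neutralization; positively charged systems are rejected.
* The periodic z adjustment assumes the fibril axis is already aligned
  with z; it does not perform the alignment.
* The contact stack is exact but not optimized for very large systems
  (no cell lists across frames, no parallelism).
* `read_structure` parses coordinates via biotite and keeps the
  single-character chain-id limit of the PDB format; mmCIF is not
  supported.
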