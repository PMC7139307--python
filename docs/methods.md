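# Methods

This note documents the models, conventions and numerical choices behind
`fibrilkit`, the assumptions of the synthetic generator, and the known
limitations. Units are nm, ns, nm² and kcal/mol throughout; PDB I/O
converts Å↔nm at the boundary.

## Structures and trajectories

A structure is an ordered atom list grouped into chains and residues; a
trajectory is a frame stack over one topology with a fixed time-per-frame.
The interchange format is multi-model PDB: no computation here depends on a
binary trajectory container, and a text format keeps every pipeline stage
inspectable. Chain stacking order defaults to file order and can be
overridden in the configuration. Alternate-location records keep the first
conformer (with a warning); insertion codes are rejected — stacked fibril
models do not use them. Window arithmetic resolves "the last W ns" to the
trailing `round(W / time_per_frame)` frames; the default analysis window is
25 ns and the clustering window 50 ns.

## Secondary structure (β only)

β content uses the Kabsch–Sander hydrogen-bond model. Amide hydrogens are
placed at `N + 0.10 nm · unit(C_prev − O_prev)`; chain-first residues and
prolines get none. The bond energy, with distances in Å, is

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol,

clamped to −9.9 when any of the four distances is under 0.5 Å; a bond
exists iff `E < −0.5`. `Hbond(i, j)` denotes the carbonyl of residue *i*
accepting from the amide of residue *j*. Donors keep at most their two
best-energy acceptors. Bridges follow the standard rules — parallel at
(i, j) iff `[Hbond(i−1, j) and Hbond(j, i+1)]` or
`[Hbond(j−1, i) and Hbond(i, j+1)]`; antiparallel iff
`[Hbond(i, j) and Hbond(j, i)]` or `[Hbond(i−1, j+1) and Hbond(j−1, i+1)]`
— and chain into ladders along (i+1, j+1) (parallel) or (i+1, j−1)
(antiparallel). Ladder members are E, isolated bridges B, everything else
C; β-bulge joining of ladders is not implemented, which can only make the
assignment slightly conservative. The β fraction counts E and B by default
(configurable to E-only). Sequence-adjacent bonds (|Δres| < 2 within a
chain) are excluded, and same-chain bridges require a separation of at
least 3 residues. The implementation is cross-checked in the test suite
against an independent DSSP implementation on the synthetic pentamer.

## Order parameter

For chain *c* and residue *n*, the connecting vector runs from the chain's
centre to the residue's Cα and is normalized to unit length;
`ordP(t)` is the mean over all (c, n) of the dot product between the
reference-frame vector and the frame-t vector, then averaged over the
window. Choices made where the definition is genuinely open:

- **Normalization.** The dot product of raw connecting vectors is
  dimensionful; "values close to 1 mean preserved alignment" is only
  meaningful for unit vectors, so vectors are normalized.
- **Centre definition.** Default (`com_mode="chain"`): the chain's Cα
  centroid, giving a fan of chain-orientation vectors. Alternative
  (`com_mode="residue"`): each residue's own atom centroid. The chain mode
  is the default because it measures exactly the loss of chain-frame
  orientation that distinguishes an ordered stack from a distorted one.
  Using the Cα centroid (rather than a mass-weighted all-atom centre)
  makes the statistic depend only on the Cα selection and keeps the
  identity tests exact.
- **Fitting.** Frames are least-squares fitted (Kabsch, all selected Cα)
  onto the reference by default; otherwise rigid tumbling of the whole
  fibril would read as disorder in every system. The unfitted mode is a
  flag for trajectories already aligned to the fibril axis.

Exact identities hold by construction: ordP = 1 on the reference frame, 1
under arbitrary global rigid transforms with fitting on, 0 when every
chain is turned 90° about an axis through its centre with fitting off, and
a mean of 0 over uniformly random chain orientations (verified as a
Monte-Carlo null at 1000 frames).

## Surface areas

SASA is Shrake–Rupley with a deterministic Fibonacci-sphere quadrature
(default 960 points/atom, probe 0.14 nm, radii C 0.17, N 0.155, O 0.152,
S 0.18, H 0.12 nm; all configurable). The inner occlusion loop is a
numba-compiled kernel with a KD-tree neighbour list (nearest neighbours
first, early exit); a pure-numpy fallback gives identical results.
Quadrature error on a single atom is under 1% at 960 points and halving
behaviour is verified (< 0.5% change on doubling).

"Contact surface between adjacent chains with a distance cutoff" admits
two readings, so both are computed per consecutive chain pair in stacking
order: the primary metric, buried SASA `½·[S(A) + S(B) − S(A∪B)]` (clamped
at zero against quadrature noise), and a companion count of cross-chain
heavy-atom pairs within the 0.35 nm cutoff. Neither is asserted to be the
other's equal; both appear in the per-pair CSV.

## Ligand contacts

A residue identity (residue number + name, chains pooled — the stack is a
repetition of identical chains, so only the residue type is informative)
is in contact in a frame iff any chain's copy has a heavy atom strictly
within 0.35 nm of any ligand heavy atom. Probability = contact frames /
considered frames. For ligands that can leave the site, frames are first
masked to those where the ligand–receptor minimum distance is under the
same cutoff (strict inequality at the boundary, so a pair at exactly the
cutoff is unbound). Hydrogens are excluded by default because explicit-H
models inflate contact counts.

## Clustering

Frames of the trailing 50 ns are clustered by single linkage: two frames
share a cluster iff connected by a path of pairs with fitted Cα RMSD
strictly below the 0.1 nm cutoff (the semantics of the classic GROMACS
linkage clustering; the strict comparison and the Cα fit group are
configurable assumptions, not reported facts). Clusters are numbered by
decreasing size with ties broken by lowest member frame index. The
centroid is the member with minimum mean RMSD to the rest (ties to the
lowest frame index) and is emitted as a single-model PDB — the receptor
hand-off for ensemble docking. Correctness is guaranteed by exhaustive
brute-force equivalence tests on randomized instances up to 50 frames.

## Synthetic generator

The generator emulates the *statistical* structure of an S-shaped Aβ42
fibril fragment — order, contacts, hydrogen-bond registry — not its
physics. Defaults: 5 chains × 32 residues (Aβ42 numbering 11–42 and the
matching sequence), a planar three-strand meander (11/10/11 residues,
0.35 nm Cα steps, 0.55 nm between strands), chains stacked in register at
the 0.48 nm cross-β rise. Backbone N/Cα/C are placed along the local
strand direction (±0.12 nm from Cα) and carbonyl oxygens alternate along
±z by residue parity; together with the standard amide-H placement this
reproduces the alternating peptide-plane orientation of an extended
strand, so stacked chains form Kabsch–Sander bonds and the default build
assigns > 50% E (calibrated; the calibration is itself a test). Spacings
above 0.6 nm warn that the registry will not bond.

A pseudo-ligand is a seeded 20-atom carbon blob (radius 0.12 nm) planted
at one of three sites: the pocket (the concave face between the first two
meander strands of the middle chain), between the two middle chains'
centres, or outside the terminal chain. Chemistry is irrelevant to the
geometric metrics under test.

Distortion regimes (seeded, bit-reproducible; defaults are the package's
study conditions):

- **stable** — i.i.d. Gaussian jitter, sd 0.01 nm, on every atom.
- **melt** — jitter ramping linearly from 0 to 0.2 nm across the run.
- **detach** — the terminal chain translated rigidly along +x, ramping
  from mid-run to 8 nm, plus baseline jitter. The chain is extended along
  x, so the displacement must exceed its own ~4 nm in-plane extent for the
  interface to vanish; 8 nm makes the final quarter of the run genuinely
  detached.
- **pocket_distort** — the pocket-lining first strand of every chain
  displaced in-plane toward −y (open space, so the strand cannot collide
  with the rest of its own meander), ramping from a quarter of the run to
  0.6 nm. Adjacent chains get alternating displacement magnitudes plus a
  seeded direction jitter: a coherent displacement of all chains would
  preserve the stacking registry and distort nothing, while alternation
  guarantees neighbouring copies of the pocket shear apart.

What the generator does **not** reproduce: side chains, realistic bond
geometry at the meander turns, solvent, force-field energetics, gradual
unbinding kinetics, and the absolute β percentages of real fibril
simulations (the idealized registry is more ordered than a thermalized
fibril, so its baseline β content is higher than experimentally derived
structures show). Passing tests therefore demonstrate that the *metrics*
respond correctly to planted, labelled distortions — not that the
generator predicts real fibril behaviour.

## Numerical and reproducibility choices

- One analysis window feeds all report metrics, so the β, ordP and area
  summaries are computed on identical frame sets.
- Strict `<` at every distance cutoff; documented tie rules everywhere a
  tie is possible (cluster ordering, centroid, argmin).
- `min_distance` is an exact dense scan (squared distances, one square
  root at the end); no grid approximation is used at these problem sizes,
  and brute-force equality is asserted in the tests.
- Kabsch superposition enforces a proper rotation (det +1) and rejects
  collinear references; weights default to uniform.
- All random draws go through `numpy.random.default_rng(seed)`; pipeline
  outputs are byte-identical across reruns, and every CSV carries its
  configuration in a header comment.
- Test and demonstration problem sizes (200-frame runs, 0.25 ns/frame,
  240–960 quadrature points, 5 seeds per regime) were chosen as the
  smallest sizes at which the regime fingerprints are unambiguous;
  `scripts/acceptance.py` states its sizes alongside every reported value.

## Known limitations

- No β-bulge handling and no helix/turn assignment (β is the only class
  reported).
- Analysis assumes whole-molecule, unwrapped coordinates; there is no
  periodic-boundary imaging.
- The interaction-area metric is quadrature-based; an analytic
  (Lee–Richards) SASA is out of scope.
- Under pure positional jitter the buried-area metric can *rise* (noise
  inflates per-chain surface area faster than the shared interface
  shrinks), so melt runs separate from the baseline in area without
  decreasing monotonically; β content and ordP are the monotone
  indicators for that regime.
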