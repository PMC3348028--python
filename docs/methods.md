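# Methods

## The model

A *motif binding geometry* (MBG) is the relative rigid-body placement of
two structural components as observed in a known complex.  The package
treats complex modeling as three sub-problems: (i) deciding that a target
domain shares the scaffold of a template domain (motif matching), (ii)
transferring the template's MBG to the targets (superposition and frame
algebra), and (iii) rejecting assemblies that are physically impossible
(steric clash, unbridgeable linkers) or implausible (unusual buried
interface area).  The underlying assumption — domains that fold alike bind
alike — is a heuristic: it proposes a small set of candidate geometries; it
does not score binding energetics, and refinement of stereochemistry is
out of scope.

## Secondary-structure reduction

SSE detection is purely geometric, from Cα coordinates: residue windows
with d(Cαᵢ, Cαᵢ₊₃) ∈ [4.5, 6.0] Å and virtual torsion ∈ [35°, 75°] seed
helices (minimum 5 residues); windows with d(Cαᵢ, Cαᵢ₊₂) ∈ [6.3, 7.3] Å
outside helices seed strands (minimum 3).  These windows bracket ideal
α-helix (d₁₃ ≈ 5.05 Å, torsion ≈ +50°) and pleated β-strand
(d₀₂ ≈ 6.5–7.0 Å) geometry; a perfectly straight chain with 3.8 Å spacing
has d₀₂ = 7.6 Å and is deliberately *not* a strand — real strands pleat.
Hydrogen-bond based assignments from an external tool can be imported
instead (per-residue H/E/C tables) when working with experimental
structures.

Each SSE becomes an oriented segment: direction = first principal
component of its Cα set, signed N→C; origin = projection of the first Cα
onto the axis; length = span of the projections.  A finite helix's
principal axis tilts slightly off the true helical axis (the xy phase
couples with rise; ≈ 0.04 rad at 12 residues, vanishing with length).
This bias is identical for homologous motifs fitted the same way, so it
cancels in matching; tests therefore assert convergence with length
rather than exact axis recovery.  Inter-vector angles are
orientation-insensitive by default (range [0, π/2]), because strand
directions may reverse between homologs; a signed mode is available.
Distances are between *finite* segments, not infinite lines, to avoid
rewarding far-field crossings.

## Monte Carlo alignment

The match score is `Σᵢ w_θ·θᵢ² + w_d·dᵢ²` with defaults w_θ = 1 rad⁻²,
w_d = 0.1 Å⁻², making 10° of angular error roughly equivalent to 0.55 Å
of displacement.  Minimization over SE(3) uses Metropolis Monte Carlo:

- proposals: rotation about a random axis, angle uniform in
  [0, 5°·s(T)], through either the moving motif's centroid or a pivot
  displaced by up to the fixed motif's extent (pivot diversity keeps
  rotations about distant axes reachable); half of the proposals add a
  translation uniform in a 0.5·s(T) Å ball;
- temperature: geometric decay T: 1.0 → 10⁻⁴ over n_steps (default
  10,000); acceptance min(1, exp(−Δ/T));
- step annealing: s(T) = clip(√(T/T₀), 0.02, 1) — the proposal size tracks
  the width of a quadratic basin equilibrated at T.  A colder finish than
  a naive schedule is needed because the walk equilibrates at score ≈ T,
  so recovering scores below 10⁻³ requires T_f ≪ 10⁻³;
- restarts: n_starts chains (default 8; start 0 from the identity, the
  rest from random placements), all seeded deterministically from one
  master seed via `numpy.random.SeedSequence.spawn`;
- quench: each chain ends with 25% extra greedy (T = 0) steps restarted
  from its best-so-far state, because annealed chains often visit a good
  basin early and then wander off before freezing.

Identical seeds give bit-identical results.  On a three-SSE motif with a
planted 25° / 4 Å displacement, 20/20 seeded runs recover the transform to
better than 0.01° and 0.002 Å (the recovery test requires 1° / 0.2 Å in
≥ 95% of runs).  Two-segment toy problems have genuine local minima under
the orientation-insensitive angle; restarts are the defense, and the
planar (z-rotation + xy-translation) mode is validated against an
exhaustive 1° × 0.1 Å grid.

## Frames and transfer

A component's local frame is built from rotation-equivariant anchors
(centroid, first and last reference atom — Cα, or C1′ for DNA), not from
PCA axes, whose sign ambiguity breaks equivariance.  A binding geometry
stores F_A⁻¹∘F_B — the B frame expressed in A's frame — and is therefore
invariant under any global motion of the template.  Transfer superposes
each target onto its template component with proper-rotation Kabsch
(reflections forbidden: the smallest singular direction is flipped when
the cross-covariance determinant is negative, preserving chirality) and
records the superposition RMSDs on the candidate.  Target↔template atom
pairing is by explicit mapping, or by reference-atom order when the counts
agree.

## DNA scaffolds

B-DNA is generated at pseudo-atom resolution (P, C1′, glycosidic N per
nucleotide) on ideal helical frames: base pair *i* at z = i·rise, rotated
i·twist, defaults rise 3.38 Å and twist 36°/bp, phosphates at 9.4 Å from
the axis; strand two is the reverse complement, antiparallel.  Everything
downstream (anchoring, clash checks, splicing) needs only this backbone
geometry; full-atom nucleotides are out of scope.  Splicing superposes the
downstream segment's overlap base pairs onto the upstream segment's
(≥ 2 bp), rejects overlaps with post-fit RMSD above 1.0 Å, drops the
duplicated nucleotides and renumbers continuously.  Splitting one duplex
and re-splicing reconstructs it to < 10⁻⁶ Å.

## Screening

- **Clashes**: inter-component heavy-atom pairs closer than 2.5 Å
  (severe van-der-Waals overlap) in hard mode, or closer than
  0.8 × (r_vdw,i + r_vdw,j) with Chothia-style radii (C 1.87, N 1.65,
  O 1.40, S 1.85, P 1.90 Å) in soft mode.  Neighbor search uses a KD
  tree but is exactly equal to all-pairs enumeration (property-tested).
- **Linker feasibility**: an n-residue loop can bridge its anchor atoms
  (C of the upstream residue, N of the downstream one, configurable) iff
  their distance ≤ n × 3.5 Å, boundary inclusive — 14 Å for the 4-residue
  receiver–effector linker, approximately a fully extended chain.
- **Interface plausibility**: buried areas inside 639–3,228 Å² (the range
  typical of heterocomplexes) are flagged plausible; this is annotation
  only, never a hard filter.
- **Ranking**: candidates with feasible linkers and zero clashes first,
  then by descending total buried area, ties by id.

## Surface areas

Areas use numeric sphere sampling: each heavy atom's probe-expanded
sphere (probe 1.4 Å) is covered by a deterministic Fibonacci spiral
lattice (default 960 points — no random numbers, so results are
bit-reproducible), and unoccluded fraction × sphere area is summed.
Buried interface area is two-sided: area(A) + area(B) − area(A∪B), with
all groups evaluated in their complex placements.  A single sphere is
exact by construction; two-sphere unions agree with the closed-form lens
formula to < 1%.  Published interfacial areas for comparable complexes do
not always state their convention (one- vs two-sided, probe, radii set),
so comparisons against literature values should allow ±10%.  Hydrogens,
waters and hetero-atoms are excluded by default.

## Synthetic data

The fixture generators produce what the pipeline needs with known ground
truth: ideal helices (rise 1.5 Å, twist 100°/res, radius 2.3 Å — Cα–Cα
3.83 Å), pleated strands (axial step 3.45 Å, pleat ±0.80 Å — Cα–Cα 3.8 Å,
d₀₂ = 6.9 Å), a compact helix–strand–helix domain, two-domain chains
with planted inter-domain transforms and a 4-residue connecting loop, and
pose-decoy sets with disjoint planted categories (linker-feasible+clean /
clashing+infeasible / clean+infeasible) in exact requested fractions.
Backbone N, C, O atoms are placed by fixed internal geometry along the
chain direction so C(i)–N(i+1) continuity holds, and an optional CB-like
pseudo side-chain atom gives the structures volume for clash and surface
work.  Loops are jittered Cartesian interpolations, redrawn until no
detection window touching a loop residue satisfies the helix or strand
criteria — this keeps fixture ground truth exact, at the cost of loops
that are not stereochemically realistic.  What passing tests show is that
the geometry, transfer and screening machinery is correct; they do not
show that idealized SSE criteria or pseudo-backbone fixtures capture the
irregularity of experimental structures, where imported secondary-structure
assignments and full-atom coordinates should be preferred.

## Numerical choices and degenerate inputs

Kabsch requires ≥ 3 non-collinear points and raises on rank-deficient
sets.  Local frames raise on collinear reference atoms.  Segment-segment
distances use the clamped closest-point parametrization with guards for
near-parallel segments (verified against brute-force sampling and an
independent critical-point formulation).  Alternate conformers collapse to
the highest-occupancy atom (ties by altLoc order); only model 1 of
multi-model files is kept; residue numbering is author numbering, ranges
inclusive.  PDB output is fixed-column with TER/END; write–read–write is
byte-stable, and coordinates survive round trips to the format's 3
decimals.

## Problem sizes

The test suite and the reproduction script run on small synthetic systems
chosen to exercise every code path at full fidelity: three-vector motifs
for Monte Carlo recovery (20 seeded runs of 20,000 + 5,000 steps each),
100-pose planted decoy screens plus a 2,000-pose random-contact survey,
30-bp duplexes for splicing, and dimers of ~100 atoms for surface work.

## Known limitations

No energetics anywhere: candidates that pass all filters are geometric
hypotheses, not predicted affinities.  Loop feasibility is a distance
bound, not a loop builder.  The Cα-only SSE detector misses π/3₁₀ helices
and irregular strands.  DNA is straight unless a template supplies bent
coordinates; intrinsic curvature is not modeled.  The matcher treats
motifs as rigid — hinged domains must be split and matched separately.
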