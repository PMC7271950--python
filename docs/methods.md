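# Methods

`embuild` builds protein main-chain models into cryo-EM density maps with
likelihood density targets, docks known sequences onto the traced chains,
and iterates build cycles, reporting the cycle whose model best explains
the map. This note describes the model, the algorithmic choices, the
synthetic data the package tests itself on, and the known limitations.

## Density maps and map preparation

A map is a real-valued grid on an orthogonal box (`DensityMap`), read from
and written to MRC/CCP4 2014 volumes (axis permutations honoured on read;
the origin uses the ORIGIN record when nonzero, else `nstart x spacing`).
Maps interconvert with a P1 structure-factor store by plain DFT; the
convention is fixed so that the amplitude of the (0,0,0) term equals the
mean density times the number of voxels. Map preparation truncates the
transform at the stated resolution d (all Miller indices with 1/d(h,k,l) <=
1/d retained) and optionally applies a global B-factor: amplitudes are
scaled by exp(-B s^2/4), s = 1/d; negative B sharpens. Density values are
interpolated trilinearly everywhere.

## Likelihood targets

The search target is the classic fragment-likelihood construction: sample
the reference map at a fixed sub-grid of offsets d_i (|d_i| <= radius,
lexicographically ordered; step = max(map spacing, resolution/4)) in a
canonical residue frame for every occurrence in the reference, and keep the
per-offset mean mu_i and population variance sigma_i^2. A placement (x, R)
scores

    llk(x, R) = - sum_i ( rho(x + R d_i) - mu_i )^2 / (2 sigma_i^2),

a log-likelihood up to a placement-independent constant. The residue frame
puts the origin on CA (or the ideal CB constructed from N/CA/C with
standard tetrahedral geometry — also used for glycine), the x axis along
the orthogonalised C-N direction and z along the N-CA-C plane normal.

Two target families are built from one reference: a 4 Å CA-centred target
for locating and extending main chain, and twenty 5.5 Å CB-centred targets
(one per residue type) for side-chain classification. Variances are floored
(1e-6 of the squared dynamic range by default); for target families built
from near-homogeneous references the pipeline adds an error-model floor of
(0.08 x dynamic range)^2 so interpolation-level mismatches are not
over-penalised.

Because helical and extended CA environments differ systematically, a
single blended CA target has its optimum displaced from the true CA by a
few tenths of an Ångström. The pipeline therefore accumulates two
conformation-conditioned CA targets (compact vs extended, classified by the
CA(i)–CA(i+3) distance in the reference, threshold 7 Å) and scores
candidates with the better of the two; the blended target is kept for the
Fourier seed search, which needs a single template.

The reference may be any map/model pair; by default the package simulates
one from a bundled synthetic model (a serpentine fold alternating helix and
strand rows, 220 residues, every residue type at least 11 times) at the
working resolution, so nothing needs to be downloaded.

## Scoring modes

`correlation` mode re-fits the map's scale and offset per placement by
weighted least squares (weights 1/sigma_i^2) before evaluating the
quadratic form, making the score invariant under any affine intensity
transform of the map with positive scale — cryo-EM maps are not on an
absolute density scale, so this is the default. `llk` mode evaluates the
raw quadratic form and assumes the map is on the reference scale.

## Seed search

Fast mode places two built-in 4-residue CA mini-motifs (ideal helix: rise
1.5 Å, twist 100°; ideal strand: rise 3.3 Å, twist 180°), rendered at the
working resolution, at density-ranked candidate nodes over a deterministic
quasi-uniform rotation set (super-Fibonacci, 288 orientations; a 72-
orientation first pass prunes the nodes). The score is the Pearson
correlation between sampled density and motif density — intrinsically
scale- and offset-free, as is the density ranking of candidate nodes.
Reported seeds sit on an interior CA of the motif with that residue's
frame.

The exhaustive Fourier search evaluates the llk target at every grid node
for every orientation. Because trilinear interpolation is linear in the
grid values, the quadratic term decomposes exactly into cross-correlations
of lagged product maps rho(x)·rho(x+delta) (27 small lags, folded to 14 by
symmetry) with per-orientation kernels, each evaluated by FFT; node scores
equal direct scoring to numerical precision. This search is not
scale-invariant, which is why fast mode is preferred on EM maps.

Both searches apply greedy non-maximum suppression (radius 2 Å) and report
the top N placements; accepted placements are refined by a deterministic
coarse-to-fine local hill-climb in position and orientation.

## Chain growing and fragment processing

Growth proposes candidate next-CA positions at 3.8 Å from the current tip
over a deterministic cone (pseudo-bond angle 75–145°, 4 angles x 8
torsions), scores them with the CA target, and extends by beam search
(width 4), in both directions from the seed. Each candidate's residue frame
needs the unknown outgoing tangent: once three or more residues exist the
tangent is extrapolated from the chain's local screw motion (exact for
ideal helix and strand); earlier steps marginalise over a small hypothesis
cone. Accepted tips are refined by a constrained hill-climb (CA–CA distance
held in a trans-like window 3.55–4.10 Å). Growth stops when the best
candidate falls below the score floor, set at 0.8 of the map's background
(null) score median — the median score of quasi-random placements — which
makes the floor scale-free.

Completed traces are smoothed by red-black coordinate sweeps under the CA
target (neighbour distances and the CA(i)–CA(i±2) >= 4.2 Å no-knot bound
enforced), split where per-residue scores fall below 0.8 of the null
median, end-trimmed at 0.65 of it, residue-level de-duplicated against
better fragments (2.4 Å), merged where termini abut with legal local
geometry, pruned by a greedy keep-best rule (a fragment is dropped when
more than half its CAs lie within 2.8 Å of a kept fragment), and filtered
(fragments shorter than 6 residues, or with most CAs outside the mask, are
discarded). Each fragment's reading direction is chosen by scoring the
residue frames of both readings — the target's carbonyl/CB asymmetry makes
the true direction score better.

## Sequence docking

Each traced residue is scored against the twenty CB targets at its
constructed CB frame, giving an L x 20 matrix. The matrix rows are
z-scored (so no residue dominates) and column-centred (removing per-type
bias), then slid along every input sequence at every ungapped offset
(forward direction only; up to 4 residues may overhang each end). The best
placement is accepted only when its total beats the runner-up by a margin
(default 1.5 z-units, calibrated so decoy placements are rejected);
otherwise the whole fragment stays unsequenced. When a whole fragment fails
to dock, its halves are docked independently (register defects in a trace
otherwise veto the entire fragment). Assigned residues take the sequence
letters; everything else is UNK.

## Cycles, refinement stand-in, and cycle selection

One cycle is: seeds → grow → smooth → split/trim/merge/prune/filter →
orient → dock → per-residue rigid real-space fit. The fit translates each
residue's constellation (N/CA/C/O plus its side chain at standard geometry
once typed, or CB + a stub otherwise) by up to 1.5 Å in coarse-to-fine axis
steps to maximise mean interpolated density, keeping neighbour distances
legal. It is a light tidy-up, not a reciprocal-space refinement. The
previous cycle's model enters the next cycle as fragments whose termini are
extended (at a stricter floor, 0.6 of null, so converged fragments are not
churned); preserved atoms from `known-structure` selections or
`nonprotein-radius` are copied verbatim into every output and shield an
exclusion radius against new main chain.

The best cycle is the argmax of FSC_average — the reflection-count-weighted
mean over 20 equal-width shells in 1/d (DC excluded) of the Fourier shell
correlation between the prepared map and a density rendering of the model.
Empty models score 0.

## Synthetic data

The fixture generator builds ideal-geometry backbones (helix rise 1.5
Å/twist 100°, strand rise 3.3 Å/twist 180°, mixed folds, two-chain and
serpentine layouts) with a known sequence. N and C atoms are placed from
the CA trace with both bonds tilted a fixed amount toward the local
curvature centre, so each residue's own backbone constellation is the same
in every conformation — as in real backbones, helix and strand then differ
through their neighbours. Side chains are emulated by short stems of
pseudo-atoms from CB (count = the residue type's heavy-atom count) with a
type-specific axis tilt and spacing and a compact tip cluster, so the 5.5 Å
CB sphere discriminates types the way real side-chain density does at ~3 Å.
Maps are sums of unit-mass isotropic Gaussians whose width combines an
atomic B with a resolution-dependent blur chosen so less than 1% of the
spectral power lies beyond the stated resolution; optional white noise
(stated as a fraction of signal RMS) and an affine intensity transform
a·rho + b emulate noisy, arbitrarily scaled reconstructions. Everything is
deterministic per seed.

What the generator does not emulate: real stereochemistry and rotamers,
element-dependent scattering, the negative features of electrostatic
potential maps (only reachable via the offset control), CTF/reconstruction
artefacts, and local resolution variation. Passing tests on these fixtures
demonstrate the machinery is self-consistent under controlled conditions;
they do not certify performance on experimental maps.

## Problem sizes used by the shipped experiments

The flagship build runs 5 cycles on a noise-free 60-residue
helix-turn-strand fixture at 3 Å (1 Å voxels). The mode-comparison
experiment runs one cycle in three mode settings on twenty 24-residue
fixtures (1.3 Å voxels) with random affine intensity perturbations (scale
log-uniform in [0.3, 3], offset up to half the signal RMS). The
fragment-length benchmark chops a 120-residue fixture (10% and 20% noise
variants) into windows of 8–30 residues. These sizes were chosen so every
experiment runs on a single desktop core in minutes.

## Known limitations

* Helix register: on ideal helices the trace can slip by one residue per
  ~10 grown (the target optimum sits slightly inside the CA ring, and a
  3.8 Å step on an inner spiral advances more than one residue of twist).
  Trace coverage is good but within-1-Å recovery saturates around half of
  the residues on mixed folds, and register defects veto or corrupt
  sequence docking of the affected fragment. This is the dominant error
  mode; a reciprocal-space refinement step (out of scope here) is what
  normally repairs it.
* Iterating cycles does not reliably improve the model: extensions add
  material but re-processing can also degrade converged fragments, so the
  FSC-based best-cycle selection frequently picks an early cycle.
* The scale/offset-corrected score refits the transform per placement,
  which costs some discrimination relative to plain llk on a correctly
  scaled map.
* Only orthogonal cells and P1 symmetry are supported; anisotropic or
  local sharpening is not.
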