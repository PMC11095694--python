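# Methods

This note records the models, parameter choices and numerical decisions
behind `lcpscan`, and what the synthetic-fixture tests do and do not
demonstrate about real data.

## Structures and input handling

Structures are plain atom lists with fixed-column PDB input/output;
coordinates are Å throughout and residue numbering follows the input file.
Multi-model PDB files (`MODEL`/`ENDMDL`) are the trajectory format; XYZ
blocks can be read against a known topology. Altloc duplicates resolve to
the highest-occupancy conformer, ties broken by label order; atoms without
an altloc label are never merged. Chain filtering (e.g. retaining chain A
of a crystallographic dimer) and residue-name stripping (waters, imidazole,
diol cryoprotectants) are explicit operations so a preparation pipeline is
reproducible from the run record.

Geometry operations run on heavy atoms by default using a bundled
united-atom radius table (carbon 1.85 Å, nitrogen 1.65 Å, oxygen 1.60 Å,
sulfur 1.90 Å), which absorbs the hydrogens that hydrogen-free inputs
lack; a Bondi all-atom table is bundled for structures with explicit
hydrogens, and both are swappable for any two-column text table. Atoms are
treated as exact spheres of their vdW radius — no multi-sphere
approximation — because the exact geometry is both more accurate and
directly testable against brute-force distance oracles.

## Tunnel search

The void space is discretized on a regular grid (default spacing 0.4 Å)
carrying the *free radius*: the distance from each voxel center to the
nearest atom surface, computed exactly per distinct radius value with a
k-d tree and negative inside atoms. Bulk solvent is the region a probe of
`shell_radius` (3 Å) reaches from the grid boundary; a surface layer of
`shell_depth` (4 Å) extends inward from it. Tunnels are Dijkstra
minimum-cost paths over 26-connected void voxels *deeper* than this
layer, terminating at first contact with it — excluding the surface layer
from the search space is what prevents paths from crawling around the
outside of the structure to reach a second mouth cheaply. Distinct exits
are connected components of the contact voxels; exits closer than
`shell_radius` merge, keeping the cheaper path. The start point snaps to
the most open voxel within 3 Å, so a start placed on the heme iron moves
into the adjacent void.

The per-step cost is `ds / max(r, 0.05 Å)²` and a path's throughput is
`exp(-cost · 1 Å² / d)` with `d` the straight start-to-exit distance.
For a straight cylinder of radius r this is `exp(-1/r²)`, independent of
length; constrictions and detours only lower it. This reproduces the
qualitative ordering of tunnel-ranking tools (wider, shorter, straighter
is better) but the absolute values are this package's own scale and are
never compared numerically with CAVER's. Curvature is defined as path
length over straight start-to-exit distance (always ≥ 1). Paths whose
bottleneck falls below the minimum probe radius (0.9 Å) are pruned.

Tunnel families across snapshots are built by average-linkage
hierarchical clustering (the Murtagh reciprocal-nearest-neighbor scheme,
as implemented in `scipy.cluster.hierarchy`) on the mean Euclidean
distance between equal-arclength-resampled centerlines, cut at 3.5.
Cluster priority divides the summed member throughput by the total
snapshot count, so snapshots where the pathway is absent drag it down;
the occurrence fraction (snapshots in which the pathway appears at all)
is reported alongside, since both conventions are in circulation and
they differ whenever a pathway appears intermittently.

Discretization caveat: voxel centers do not lie exactly on a channel
axis, so a reported bottleneck can sit up to roughly one grid spacing
below the true clearance; the tests assert recovery at exactly that
tolerance, and halving the spacing must move the answer by less than the
coarser spacing.

## Pockets

Alpha spheres are computed as Delaunay-tetrahedron circumcenters of heavy
atom centers — mathematically the Voronoi vertices, with the four
defining atoms read off the tetrahedron. Radii are measured to atom
*centers*, matching the convention implied by the 3.4–6.2 Å default
bounds; spheres outside the bounds or centered outside the convex hull
are discarded, and every retained sphere is asserted equidistant from its
four atoms to 1e-6 Å. Pockets are single-linkage components of sphere
centers at a 1.8 Å cutoff (the linkage method is standard; the cutoff is
this package's default and configurable) with at least 15 spheres, ranked
by sphere count — external tools rank by multi-descriptor scores that are
not reproducible from their outputs, so pocket *numbering* is not
comparable across tools.

Monte-Carlo volumes sample the sphere union's bounding box uniformly; a
hit lies inside at least one alpha sphere and outside every atom sphere,
so the reported number is a solvent-accessible void volume with a
binomial standard error. Fixed seeds give bit-identical results.
Hydrophobicity is the apolar (C, S) fraction of lining atoms within 2 Å
of any sphere surface — a proxy score on this package's own scale.
Published pocket volumes from other tools (e.g. 173.52 or 77.21 Å³ for
the two heme-proximal pockets of LcpK30) are context, not oracles: they
depend on tool-internal sphere filtering that their text output does not
specify.

## Trajectory metrics

Superposition uses the Kabsch SVD construction with a proper-rotation
determinant correction; collinear point sets are rejected. RMSF and PCA
superpose all frames onto the ensemble mean, iterated twice — the
standard essential-dynamics choice; RMSD series superpose each frame onto
the reference structure over a fit selection before measuring over a
calculation selection. RMSF aggregates per residue as the Cα value when
a Cα is selected, else the mean over the residue's selected atoms; noisy
termini are omitted by restricting the selection (e.g.
`"name CA and not resnum 29-49"`).

PCA pools frames from all supplied trajectories into one covariance
(frame tags record the source so bound/unbound or open/closed ensembles
can be projected apart), eigen-decomposes via SVD, and fixes each mode's
sign so its largest-magnitude component is positive; projections onto a
pooled covariance of tagged ensembles is one of the two conventions in
use (the other projects one ensemble onto the other's modes) and is
flagged in the result rather than silently assumed. Porcupine vectors
are `scale · sqrt(eigenvalue) · mode` per atom, zeroed below 2 Å. A
rank-deficiency warning fires when frames < 3 × atoms.

The RDF uses minimum-image distances when the trajectory carries an
orthorhombic box (periodic k-d tree pair search) and normalizes by exact
shell volumes and the mean-box bulk density; without a box a bulk-density
override is required rather than guessed, and edge effects are then the
caller's responsibility. Smoothing is a centered moving average with the
window shrinking at the ends; the interior attenuation of a sinusoid
follows the analytic Dirichlet factor `sin(Mω/2)/(M sin(ω/2))`, which the
tests assert to 1e-6.

## Polymer model

The repeat unit is `-CH2-C(CH3)=CH-CH2-`; hydrogen-capped termini give
C₅ₙH₈ₙ₊₂ (C50H82 at n = 10). Bonds are idealized (C–C 1.54 Å, C=C
1.34 Å, C–H 1.09 Å; sp² 120°, sp³ 109.47°) and placed by natural-
extension (NeRF) internal-coordinate construction. Every double bond is
cis (torsion 0°, asserted within 15°). The backbone single-bond torsions
default to a skew pattern (±120°, ±60°, ±120°) with handedness
alternating unit to unit: an all-trans pattern would curl a cis chain
back onto itself, while the alternating-skew pattern extends it
(~4.7 Å/unit) and keeps all non-bonded atoms > 1.8 Å apart. Per-torsion
overrides allow folded test poses; the cis geometry itself is not
overridable.

Double bonds are numbered from the dimethyl terminus — the end whose
first unit presents R-C=C-(CH₃)₂, i.e. the branch methyl plus the capped
terminal methyl. Chain width is the maximum pairwise distance among heavy
atoms projected perpendicular to the principal axis, plus a 1.1 Å
hydrogen allowance; a single-atom model degenerates to its own diameter.
The cleavage rule `(k-1, n-k)` assigns the cleaved bond's own unit no
intact C=C; it reproduces the central-bond products (4- and 5-unit
oligomers for bond 5 of a 10-mer), and whether terminal partial units
should ever be counted differently is undecidable from product-size
statements alone, so the rule is fixed and symmetric
(`products(n,k) = reversed(products(n, n+1-k))`).

## Binding analyses

A residue contacts the ligand in a frame when the minimum heavy-atom
distance is ≤ 5 Å; fractions below 4.5 % are suppressed from reports but
kept internally. When averaging over a class of similar poses, the
report threshold applies *after* averaging. NAC counting uses the strict
`< 4 Å` criterion on the minimum of the two carbon–oxygen distances; the
midpoint convention and the threshold are configurable for sensitivity
analysis, since the per-carbon convention used for published histograms
is not stated anywhere authoritative. Each NAC event contributes one
count to both fragment sizes `k-1` and `n-k`, so the unnormalized
spectrum weight is exactly twice the event count.

Conformation labels follow the field's qualitative definitions made
operational: a terminus is "in the pocket" within 2.5 Å of an
alpha-sphere center, "at the surface" when its burial depth below the
protein heavy-atom convex hull is ≤ 3 Å; extended = exactly one terminus
in the pocket with the other at the surface, folded = both termini at
the surface with the ligand centroid within 12 Å of the heme, anything
else extended-like. The three thresholds are calibration constants
exposed in the API, not measured quantities.

LIE sums all ligand–environment pairs with the 12-6 form
`ε[(Rmin/r)¹² − 2(Rmin/r)⁶]` (geometric-mean ε, summed Rmin/2) and
vacuum Coulomb `332.0636 q₁q₂/r` kcal/mol, with no cutoff and no
periodic images: this makes every value reproducible by a naive
double-loop oracle to 1e-9 relative, at the price of not reproducing any
engine-specific cutoff/PME scheme. The vdW/electrostatic percentage
split is computed from absolute mean term magnitudes and that base is
stated in the output metadata, because percentage conventions differ.
MM/GBSA-style binding free energies are deliberately out of scope; the
report format leaves room for externally supplied per-frame energies.

## Synthetic fixtures and what the tests show

Generators plant ground truth and record it in a JSON manifest; analysis
tests read only the manifest. Channels are wall-atom tubes whose axial
clearance is the construction parameter (leaky wall spacings are
refused); cavities are jittered Fibonacci-sphere shells whose interior
Voronoi vertices have radii near the shell radius; binding trajectories
realize contact schedules by moving per-residue probe atoms between
"just inside" and "well outside" the cutoff on deterministic
evenly-spread frame schedules (exact fractions), and NAC schedules by
moving the distal O₂ to exactly the dip distance from the scheduled
bond's carbon in contiguous disjoint frame blocks (conflicting demands
raise, naming the pair); two-state ensembles draw frames from two rigid
states, with the displacement projected off the six rigid-body modes
since superposition would remove those anyway; the uniform gas is the
ideal-gas RDF reference.

Default study conditions in the tests: 1000–2000 frames for exact
schedule recovery and RMSF (per-axis σ 0.5 Å recovered within 5 %), 500
frames for two-state PCA (zero assignment errors, mode within 5° of the
planted direction), a 2000-point / 100-frame / 40 Å box gas for the RDF
(unity within 0.05 mid-range), 10⁶ Monte-Carlo samples for the 4 Å
sphere volume (within 3 standard errors of 268.08 Å³), and 0.4 Å grids
on ~12 Å channel fixtures. These sizes were chosen so each oracle's
statistical tolerance is comfortably resolved.

Passing these tests demonstrates that the implementations compute their
definitions correctly and deterministically. It does not demonstrate
force-field realism: the fixtures have no physical dynamics, no solvent
structure beyond uniform density, and ligand/protein geometries far
simpler than a real enzyme, so conclusions about a real system still
depend on the quality of the input structures and trajectories.

## Known limitations

- The tunnel backend is grid-based, not an exact Voronoi search; results
  converge with the grid but carry O(spacing) discretization error, and
  throughput values are on a package-specific scale.
- Pocket ranking is by sphere count; volumes exclude atom interiors, so
  they are smaller than alpha-sphere-union volumes reported by tools
  that do not subtract atoms.
- The PDB writer enforces fixed-column limits (residue numbers ≤ 9999,
  |coordinate| < 10⁴ Å) and rejects rather than silently wrapping.
- No mmCIF or binary trajectory formats; no protonation assignment; no
  docking score recomputation.
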