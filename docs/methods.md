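# Methods

This note documents the models and procedures implemented in `ppiface`,
the parameters that matter, the numerical choices, and what the synthetic
test fixtures do and do not establish about real structures.

## Structural model and conventions

Coordinates are in Å, right-handed, exactly as read from PDB/mmCIF (gemmi
backend); the package never re-orients or renumbers anything — author
residue numbering with insertion codes is the identity used everywhere.
Waters and non-polypeptide HETATM ligands are dropped on reading; polymer
members with nonstandard names are kept with one-letter code `X`.
Hydrogens are retained but flagged, and all distance-based operations use
heavy atoms only (hydrogens are usually absent from crystal structures).
Altloc conformers: highest occupancy wins, ties break to the
alphabetically first altloc.  Only the first model of a multi-model (NMR)
file is used.

One van der Waals radius table serves both SASA and the concavity grids:
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, default 1.70 Å.

## Solvent accessibility

SASA is a Shrake–Rupley numerical integration: for each heavy atom,
`sasa_points` (default 960) points on the probe-inflated sphere
(probe 1.4 Å) are tested against neighbouring inflated spheres.  The point
set is a deterministic golden spiral — no RNG — and is oriented in a
canonical molecular frame (principal axes of the atom cloud with a
positive-third-moment sign convention), which makes the value exactly
invariant under rigid-body motion of the input; without this, a fixed
global point set changes the result by ~0.1 % under rotation.  The
isolated-atom value is exact to machine precision and two-sphere overlaps
agree with the analytic spherical-cap formula to well under 1 % at 10 000
points.

Relative solvent accessibility (RSA) normalizes per-residue SASA by the
Tien et al. (2013) theoretical maxima (generic 200 Å² for `X`).  This
normalization differs slightly from older per-program tables; since every
classification threshold is applied to the same normalization, the
difference only shifts thresholds, which are config keys anyway:
interface core < 25 % RSA in the complex (ties to periphery), solvent
inaccessible < 7 %, exposure classes buried/intermediate/exposed at
7 / 25 %.  These cut-offs follow common core/rim practice; they are
deliberate defaults, not derived constants.

## Interface detection and segmentation

A residue is an interface residue iff any heavy atom lies within 5.0 Å
(inclusive) of a partner heavy atom.  The *smaller* side contributes fewer
residues; ties break to the lexicographically smaller chain id.

Segments are maximal runs of interface positions in author numbering with
gaps of at most `gap_threshold` (default 4) non-interacting positions.
Gaps are counted as numeric spans, so a crystallographic chain break of
12 missing residues breaks a segment; distinct insertion codes at one
seq_num are adjacent.  An interface is *single* (continuous) iff the
smaller side has exactly one segment.  The greedy left-to-right grouping
is checked against an independent run-expansion oracle over random masks
and thresholds 0–8; segment count is non-increasing in the threshold.

## Planarity

RMSD of interface Cα atoms (both sides) from the total-least-squares
plane, computed as the smallest principal component of the centered
coordinates.  Fewer than 3 Cα or collinear Cα raise a degenerate-geometry
error.  Checked against a spherical-grid plane search to 1e-3 Å.

## Concavity: the inaccessible probe radius

Binding-site depth is measured per grid voxel as the smallest probe radius
in a multiscale ladder for which the voxel is *enclosed* — no probe of
that radius can be placed without overlapping the partner chain while
still covering the voxel.  This equals membership in the morphological
closing of the molecular volume by a ball of that radius; smaller values
mean deeper, more confined pockets, and voxels no probe can be excluded
from stay at ∞ (flat/convex surroundings).

Implementation: the exact signed Euclidean distance field d_mol to the vdW
union is evaluated at voxel centres (k-nearest atom centres, k = 24, valid
because radii span < 0.3 Å).  For each ladder radius ρ ascending, legal
probe-centre voxels satisfy d_mol ≥ ρ − spacing/2 — the half-voxel slack
is required because d_mol is 1-Lipschitz, so a legal *continuous* centre
inside a voxel guarantees the voxel centre passes the slackened test;
without it, exact-fit probes (a 3.0 Å probe in a 3.0 Å pocket, a single
legal point) are unrepresentable on any finite grid.  A voxel is
accessible at ρ when a legal voxel lies within ρ (Euclidean distance
transform); R_inaccess is the first ρ at which a non-molecular voxel is
not accessible.  Assigning at the first radius only makes the enclosed
sets nested by construction.  For Euclidean balls this distance-field
formulation is mathematically the dilation/erosion pair; it is exact
sub-voxel on the dilation side and much faster than explicit
structuring-element morphology.

Defaults: ladder 0.5–10 Å in 0.5 Å steps (a Ghecom-like multiscale set;
the "groove magnitude" band is 0.5–2 Å), spacing 0.8 Å, padding
max-probe + 2 Å.  Spacing must not exceed the smallest probe *diameter*
or the smallest ladder radii could never be resolved.  Analytic anchor: a
hemispherical pocket of radius 3.0 Å encloses its bottom exactly at the
first ladder value above 3.0 (3.5 Å), and halving the grid spacing or
rigidly moving the complex moves the value by at most one ladder step.

Aggregation: per residue, the deepest-bound atom's value (each heavy atom
reads its nearest voxel, half-way ties to the lower index; an atom hugging
the partner surface whose voxel rasterized as occupied reads the nearest
free voxel within three voxels).  Per interface, the arithmetic mean of
per-residue deepest values over the smaller side against the larger
side's grid, with ∞ capped at the ladder maximum for averaging; the
interlocking summary is the pair of deepest values, each side against the
other's grid.

Validation is dual-route: an independent brute-force oracle enumerates
probe centres on a 0.2 Å candidate grid with strict legality
(no atom within r_atom + ρ).  Because both routes are discretizations of
the same continuous quantity, the oracle is run twice — strict, and with
half-candidate-cell slack — bracketing the continuous answer; the
morphology result must match one bracket within ±1 ladder step, allowing
±1 voxel boundary discrepancy, at every surface-adjacent voxel outside
the sub-voxel rasterization skin.  On random 12–25-atom clusters this
holds with zero exceptions.

## Enclosed residues and sub-pockets

An interface residue is *enclosed* (an anchor candidate) iff it is solvent
inaccessible (complex RSA < 7 %) and its deepest-atom R_inaccess is
≤ 4.0 Å (inclusive, "4 Å or less").  Enclosed residues are clustered on
heavy-atom centroids with DBSCAN (eps 8.0 Å, min_samples 3 — residue-scale
adjacency defaults; both configurable); clusters proxy orthosteric
sub-pockets, and an interface "has a sub-pocket" iff at least one cluster
exists.  The scikit-learn clustering is cross-checked against a
first-principles density-reachability expansion.

## Secondary structure

A Kabsch–Sander-style three-state assignment: the amide H is built
geometrically (N displaced 1.01 Å along the previous residue's O→C
direction; prolines donate nothing), the H-bond energy is
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with bonds
below −0.5; helix = residues covered by two consecutive i→i+4 turns,
sheet = residues in parallel/antiparallel bridge patterns (|i−j| ≥ 3),
everything else loop.  Chains shorter than 5 residues and residues with
incomplete backbones are loop.  An ideal α-helix (φ = −57°, ψ = −47°)
assigns helix throughout its core; an isolated extended strand has no
ladder partner and is all loop.

## Contacts

Inter-chain heavy-atom contacts are typed by documented geometric rules
(distance cut-offs per type; ring templates for His/Phe/Tyr/Trp; amide
groups from the backbone C,O,N(+1) triad and Asn/Gln side chains).  Each
atom pair collects every type it satisfies except `proximal`, which is
reserved for ≤ 5 Å pairs matching nothing else.  The rule table is
exported as JSON (`contact_rules()`) and results carry
`method_tag="simplified-geometric"`: these are this package's rules, with
no atom-type perception or aromaticity detection beyond the templates,
and their absolute counts are not interchangeable with other programs'.
Counts are normalized per 100 Å² of whole-interface BSA (the per-side
alternative was rejected to keep one normalizer per interface).

## Shape indices (NSc / NIP)

Both indices are openly documented adaptations, tagged `lc-sc-adapted`;
analyses should use them for orderings, not absolute comparisons with
other implementations.  Surface samples are exposed vdW-surface points
(golden spiral per atom, ~2 points/Å²) with radial normals; the contact
patch is the water-excluded zone — samples within one probe radius
(1.4 Å) of the partner surface.  NSc is the median over both directions
of (n_x · n_y′)·exp(−w·d²) against the nearest partner sample (w =
0.5 Å⁻²; the partner normal negated), which scores 1 for a perfectly
self-complementary patch.  NIP is 1 − V_gap/(BSA/2 · w_shell): V_gap is
the voxelized empty volume lying within 5 Å of both chains, so
well-packed interfaces approach 1 and loosely packed ones fall toward or
below 0.  Interfaces with fewer than 10 contact-patch samples raise an
insufficient-surface error.

## Dataset assembly

Filters run in a fixed order, each interface counted once under its first
failing rule, so the report's counts always sum to the input count:
(a) any interface residue missing backbone N/CA/C/O; (b) overlap — two
pairs sharing at least one interface residue on the same chain instance
(same source structure and chain); (c) interface residue product
n_A × n_B < 25; (d) BSA < 100 Å².

Redundancy clustering is greedy in descending structure quality (X-ray
preferred, then −resolution, then backbone completeness; ties by id, so
the outcome is independent of input order).  A pair joins a cluster when
both chains reach 95 % global-alignment identity to the seed under the
best chain pairing (match +1, mismatch 0, gap −0.5 open/extend; identity =
matches/alignment length) *and* both interface-sequence strings reach a
75 % Ratcliff/Obershelp ratio (stdlib `difflib.SequenceMatcher`; two empty
strings count as identical).  The seed is the representative.

Typing assigns exactly one of five labels: peptidic when the shorter
chain is ≤ 30 residues (enzyme-flagged partner → enzyme–peptide, else
protein–peptide, with a warning when the annotation is absent);
otherwise ≥ 95 % identity makes the pair identical, split into symmetric
vs non-symmetric at a Jaccard overlap of 0.7 between the two sides'
interface positions mapped through the chain alignment; everything else
is a heteropair.  The 30-residue peptide cut-off and 0.7 symmetry cut-off
are deliberate defaults (config keys), chosen where the underlying
convention is not standardized.

## Statistics

One-way ANOVA (scipy), Tukey HSD with studentized-range p-values
(Tukey–Kramer standard error for unbalanced groups; q = |Δmean| /
√(MSW/2·(1/nᵢ+1/nⱼ))), Pearson's r, and 2D Gaussian-KDE grids (Scott
bandwidth) for density summaries.  Reject flags use α = 0.05
(configurable); no multiple-testing handling beyond Tukey is applied.
F, q and r are verified against direct sum-of-squares and covariance
formulas to 1e-9, and Tukey against an independent reference
implementation; with k = 2 the q statistic reduces to t·√2.

## Synthetic archetypes: what they emulate, and limits

The generator produces deterministic backbone-only toy complexes
(4-atom glycine-like residues; ideal-geometry peptides via internal-
coordinate chain extension).  Archetypes: `peptide_in_groove` (12-residue
ideal helix moulded into a slab with 0.3 Å clearance — single segment,
deep concavity, well packed), `flat_homodimer` (two identical two-row
sheets with a displaced middle run — three segments, Cα planarity
0.4 Å, loosely packed, symmetric interface), `heteropair_discontinuous`,
`slab_with_pocket` (hemispherical cavity of exact radius lined by a
smooth atom shell, plus a one-atom probe ligand), `coplanar_interface`
(planarity exactly 0) and `subthreshold_pair` (residue product 20, or a
sparse oxygen-contact design burying ~77 Å² < 100 Å²).

These fixtures have analytically known geometry, which is exactly why
they validate the measurement machinery: segment counts, filter fates,
pocket radii and orderings (groove mean R_inaccess 6.9 Å < flat ceiling
10 Å; groove NIP > homodimer NIP) are constructions, not discoveries.
They do not emulate side-chain packing, interdigitation at sub-atomic
clearances, B-factor/occupancy noise, missing density or physically
realistic energetics — so passing tests demonstrate correctness of the
descriptors, not field ranges for real PDB interfaces.  In particular a
smooth backbone-only groove cannot produce the sub-2 Å "groove magnitude"
values real side-chain pockets give; the hemisphere fixture covers the
deep-pocket regime instead.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
slabs of 2 600–4 900 pseudo-atoms, 0.4 Å analysis grids for the analytic
pocket checks, 25-atom clusters for the probe-placement oracle, 1 000
random masks for segmentation, 40-point sets over 20 seeds for DBSCAN,
and a 12-complex filter batch — sizes chosen so each check runs in
seconds to a couple of minutes while still exercising every code path.
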