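# Methods

## Scope and model

`qpeakfit` treats guest identification as a purely geometric problem: the
observable is a list of residual-map maxima (Q-peaks) with fractional
coordinates and relative heights, and the hypothesis space is a set of
candidate molecules with known heavy-atom connectivity and 3D geometry. The
package deliberately does not model the physics that produces the peaks
(scattering, Fourier truncation, thermal motion); peak heights are treated
as ordinal only — no absolute calibration of residual-map units is
attempted, and heights enter the algorithm solely through the noise filter.

Hydrogens are excluded throughout: residual maps in this regime resolve
heavy atoms only, and hydrogen placement belongs to the downstream
refinement step. Matching is performed on heavy-atom skeletons, and
hydrogen-bond detection uses donor–acceptor heavy-atom distances.

## Crystallographic geometry

Fractional → Cartesian conversion uses the standard orthogonalization
convention (**a** along *x*, **b** in the *xy* plane). Cartesian values are
convention-dependent; all distances are not. Symmetry operations are stored
as integer rotation matrices plus translations modulo 1 and are always
supplied explicitly — from a CIF symmetry loop, SHELX LATT/SYMM cards, or a
config list — never inferred from a space-group symbol, which keeps the
package free of a space-group database. The packaged sponge-host fixture
ships the full I2/a operator list (order 8).

Minimum-image distances use an adaptive search: the wrapped difference
vector gives an upper bound `d₀`, and the number of lattice shells examined
along each axis is `ceil(d₀ / wᵢ)` where `wᵢ` is the cell's perpendicular
width along axis `i`. This is exact for arbitrarily skewed cells; a fixed
5³-block brute force is retained as an independent reference implementation
for testing.

Parsing of xyz-triplet operators and CIF files is delegated to `gemmi`;
SHELX res/ins records (CELL/LATT/SYMM headers, atom lines with
scattering-factor indices and the 10+occ fixed-parameter convention,
trailing Q-peak lines) are parsed in-package.

## Candidate generation

Candidates come from SMILES via RDKit's ETKDG distance-geometry embedding
(seeded, hence bit-reproducible per platform) followed by MMFF cleanup and
hydrogen removal, or from user coordinate templates validated against a
1.1–1.8 Å heavy-atom bond-length window. Flexibility is handled by a small
conformer ensemble: 5 conformers for molecules with ≥1 rotatable bond, 1
otherwise; the matcher takes the best-scoring conformer. This is the
package's largest modelling simplification — matching is rigid per
conformer, so a guest frozen in a pore conformation far from any ensemble
member will score poorly. The ensemble size is a config knob.

The built-in screening library is ten common guests (DMF, DEF, pyridine,
cyclohexane, urea, 2-methylimidazole, benzoic acid, ethyl acetate,
benzaldehyde, isovaleraldehyde) spanning sizes (4–9 heavy atoms),
polarities, and binding motifs.

## Clustering

Peaks below `height_min` (default 0.15) × the tallest height are discarded.
Remaining peaks are expanded over all symmetry operators plus one shell of
lattice translations, and connected components are taken under the
bond-length adjacency window (1.1–1.8 Å). This reassembles molecules that
straddle a cell face or a symmetry element. One symmetry-unique
representative per cluster orbit is returned (identified by the multiset of
contributing peaks); clusters are reported largest first and matched
independently, which assumes one symmetry-unique guest per pore — disorder
with multiple overlapping orientations is out of scope.

## Matching and scoring

The association graph has a vertex for every (peak, atom) assignment and an
edge where peak–peak and atom–atom distances agree within `pair_tol`
(default 0.25 Å, roughly 3.5σ of pairwise jitter at the σ = 0.05 Å noise
level the recovery guarantee targets). Admissible correspondences of a
candidate are the cliques with at least `min_coverage` (default 0.6) of its
heavy atoms; the matcher enumerates maximal cliques (`networkx`) plus their
admissible subsets — every admissible correspondence is a subset of some
maximal clique, so this search is exhaustive over the admissible space, and
an independent DFS enumeration oracle confirms score equality on small
cases to 1e-9 Å.

Each correspondence is scored after a proper-rotation Kabsch superposition
(SVD with determinant correction, so mirror images are never matched by a
reflection):

    score = RMSD + λ·(1 − n_matched / max(n_atoms, n_cluster_points))

λ (default 2.0 Å per unmatched fraction) was designed around the fragment
problem: a candidate that is a substructure of the true guest covers its own
atoms perfectly, and under raw RMSD it wins whenever its per-point residual
is marginally lower. Counting unexplained cluster points in the denominator
makes the larger, complete explanation win. λ = 0 (`rmsd_only`) restores
pure-RMSD ranking for comparison with workflows that rank that way — there
small fragments and near-identical-geometry alternatives do outrank larger
true guests, which is the documented failure mode of RMSD-only screening.

Scores within `tie_tol` = 0.01 Å are reported as a shared rank, ordered
alphabetically for output stability. Rejected candidates (no admissible
correspondence) trail the ranking with infinite score. All tie-breaks
(conformer index, correspondence order, alphabetical names) are
deterministic, and reports are byte-identical across runs.

## Model building

Matched peaks are placed as carbon atoms at the realized cluster positions
(occupancy 1.0, U_iso 0.05 Å²); unmatched candidate atoms are completed at
the transformed template positions and flagged `added`. The molecule is
wrapped rigidly — by its centroid, never atom-by-atom — so guests near a
cell face stay contiguous. Element reassignments implied by the candidate
(C→N, C→O, …) are emitted as suggestions, never applied silently; the
pipeline applies them only for the chemistry-dependent interaction analysis.
Unexplained peaks are reported, never deleted: removal of spurious atoms is
a chemical judgement left to the user, mirrored by the emitted polish
checklist (reassignments, anisotropic refinement, hydrogens, restraints,
extinction) that documents where external refinement takes over.

## Interactions and occupancy cap

Contacts are classified in priority order with minimum-image,
symmetry-aware distances:

- **coordination**: metal (default Bi, configurable) to guest O within
  2.4–2.86 Å, the accepted Bi–O coordination range;
- **hydrogen bond**: guest N/O to host N/O within 2.5–3.1 Å
  (donor–acceptor distance; hydrogens are not yet placed);
- **π-stacking**: guest aromatic-ring centroid to nearest framework atom
  within 3.7 Å. The centroid-to-atom convention is used (covering reported
  centroid–H offset-stacking distances of 3.0–3.6 Å with margin); the
  common alternative, centroid–centroid with an interplanar-angle test, is
  deliberately not implemented because framework rings are not perceived
  from a host atom list;
- **van der Waals**: residual class — a guest with none of the above gets
  one vdW label citing its nearest framework contact, so every guest
  receives at least one label and pair kinds are mutually exclusive.

The occupancy cap generates all symmetry images of the placed guest over
one lattice shell (rigid centroid wrapping), builds the graph of mutual
steric clashes (any heavy-atom pair < 2.2 Å, a distance well below any
plausible nonbonded contact), and returns 1/k for the largest mutually
clashing clique containing the reference copy. Images coinciding with the
reference (guest on a special position) are not clashes. A refined
occupancy exceeding the cap is flagged as inconsistent.

## Synthetic data

The generator poses a candidate's first conformer with a uniform random
rotation and a translation keeping all atoms inside one cell, then applies
isotropic Gaussian jitter (σ), random or exact-count peak deletion, and
spurious peaks placed ≥2.5 Å from every true peak (so ground-truth labels
stay unambiguous; a smaller separation can be configured for harder tests).
Heights are drawn from Gaussians in which true peaks stochastically
dominate spurious ones (means 4.0 vs 1.5, spread 0.5, arbitrary units).
Everything is driven by one `numpy` Generator seed and is exactly
reproducible.

What passing tests on this generator shows: the clustering, correspondence
search, scoring, and ranking machinery recover a known guest under
controlled positional noise and corruption. What it does not show:
performance on real residual maps, whose peak positions are correlated with
resolution and thermal motion, whose heights carry element information the
package deliberately ignores, and which can contain systematic artifacts
(series-termination ripples, dynamical-scattering residuals) unlike
uniform random spurious peaks.

## Default study conditions and problem sizes

The statistical guarantees are evaluated at: 100 seeded simulations with
the guest drawn uniformly from the ten-guest library; recovery at
σ = 0.05 Å with no corruption (true guest rank 1 or tied-1 in ≥95/100);
robustness at σ = 0.10 Å with one spurious and one deleted peak (true guest
in the top 3 in ≥80/100). Oracle equivalence uses 50 seeded cases of up to
7 peaks/atoms, the cap at which exhaustive enumeration stays trivial.
Simulation cells default to a monoclinic I-centered cell of ~3650 Å³
(a sponge-framework scale); simulations default to P1 so that each case
contains a single symmetry-unique guest, with symmetry exercised separately
by the clustering and occupancy tests.

## Known limitations

- Rigid-per-conformer matching; no on-the-fly torsion fitting.
- Peak heights are never used to infer elements or weight superpositions.
- One guest species per cluster; no compositional disorder.
- The association-graph search is exponential in the worst case; practical
  for guests up to ~12 heavy atoms and clusters of similar size, which
  covers sponge-sized guests comfortably.
- Refinement (least squares, ADPs, hydrogens, restraints) is out of scope;
  the package writes refinement-ready input and a checklist instead.
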