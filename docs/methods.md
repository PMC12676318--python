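# Methods

This note documents the models, conventions and design choices behind
`hitfunnel`, in the order the funnel runs.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The triage funnel

The pipeline mirrors a standard structure-based virtual-screening
campaign: pharmacophore search → drug-likeness gate → docking →
toxicity-aware ranking → pharmacokinetic annotation → MD validation of the
top hits.  `hitfunnel` implements the analysis side of each stage; it does
not run docking, homology modeling or MD themselves, and it never
recomputes quantities (docking affinity, predicted LD50, P-gp substrate
flags) that arrive as annotations in the input table.

Stage order in `run_funnel`: deduplicate → qualitative gate (only when
structures are available for the records) → quadrant filter → ideal point
→ Euclidean ranking → region/P-gp annotation.  Every threshold used is
echoed into the run report, and per-stage counts are non-increasing.

## Drug-likeness gate (`chem_filters`)

* **Lipinski rule of five**, inclusive bounds: HBD ≤ 5, HBA ≤ 10,
  MW ≤ 500 g/mol, logP ≤ 5.  A descriptor exactly at a bound is
  compliant.
* **HBD** counts donor *atoms* — any N or O bearing at least one hydrogen
  (water: 1).  **HBA** is the classic Lipinski convention: all N + O
  atoms.  Both are deliberately the rule's original coarse definitions,
  not perception-based donor/acceptor models; the perception-based view
  lives in the pharmacophore module where geometry matters.
* **logP** is Wildman–Crippen ("WLogP") and **TPSA** is the fragment-based
  topological polar surface area *including* the sulfur/phosphorus
  contributions by default, because the BOILED-Egg ellipses (below) are
  parameterized on that convention; `tpsa_include_s_p=False` restores the
  O/N-only scheme.  Both come from RDKit.
* **PAINS and Brenk** catalogs are RDKit's built-in FilterCatalog sets
  (480 and 105 patterns), which encode the original publications' SMARTS.
  Custom catalogs can be supplied as `(id, SMARTS, description)` entries;
  malformed patterns fail at load time.  The catalog name and size are
  logged with every run as a version stamp.
* **The combined gate** passes a molecule only with zero Lipinski
  violations AND zero PAINS AND zero Brenk matches.  Some screening
  services allow one Lipinski violation; `max_violations` exposes that,
  default 0 (strict).
* **Deduplication** keeps first occurrences, keyed by id or by canonical
  SMILES (`by_structure=True`) for hits harvested from multiple vendor
  libraries under different ids.

## Pharmacophore model and matching (`pharmacophore`)

The reference model carries eight typed feature spheres derived from a 3D
rosiglitazone pose: (1) acceptor on the thiazolidinedione amide oxygen,
(2) donor on the amide nitrogen, (3) hydrophobic on the ring sulfur —
typed hydrophobic rather than a thioether-specific class — (4)+(5)
aromatic and hydrophobic on the disubstituted-benzene centroid, (6)+(7)
hydrophobic and aromatic on the pyridine centroid, (8) hydrophobic on the
tertiary-amine methyl.  The bundled pose (`data/rgz_synthetic.sdf`) is an
ETKDG-embedded, MMFF-minimized conformer generated with RDKit and labelled
synthetic: the model's absolute geometry is fixture-defined, and any
crystallographic pose can be substituted through `build_reference_model`.

Feature perception is deliberately permissive (matching prunes): donors =
N/O with ≥ 1 H; acceptors = O plus N with an available lone pair
(pyrrole-type aromatic NH and quaternary N excluded); aromatic = aromatic
ring centroids; hydrophobic = ring centroids, neutral sulfur, and sp3
carbons with ≥ 2 hydrogens, skipping atoms adjacent to formal charges.

Matching is alignment-free pairwise-distance consistency: an injective,
kind-respecting assignment σ with |d_model(i,j) − d_mol(σi,σj)| ≤ tol for
every pair — a clique in the correspondence graph, found by backtracking
with incremental pruning, minimizing the maximum deviation.  Default
tolerance 1.0 Å per feature pair; `use_radii=True` switches to
per-pair max(radius_i, radius_j).  Ties between equally good assignments
break lexicographically, so results are platform-independent.  Because
only internal distances are compared, matching is exactly invariant under
rigid motion and atom relabeling; no superposition is ever fitted.

## Enrichment (`enrichment`)

Scores are docking affinities, *lower is better*; the sweep internally
negates them so the standard "higher = more active" ROC machinery applies,
and the convention is an explicit field of `ScoredSet` to prevent silent
inversion.  Equal scores collapse into a single threshold step, which
makes the trapezoidal AUC equal the Mann–Whitney probability with ties
counted ½ — the property the test suite verifies against a brute-force
pairwise oracle.  The decoy generator is a stand-in for property-matched
decoy services: it emits records whose MW and logP lie within ±10% of the
active's with distinct structure keys, deterministic under seed; it makes
no claim of chemical realism.

## Pose RMSD (`pose_compare`)

`symmetry_rmsd` minimizes the RMSD over all element- and
bond-order-preserving atom permutations (graph automorphisms) of the
ligand, heavy atoms only.  Default mode is **in-place** (no superposition),
the docking-community convention for redocking validation, because both
poses already live in the receptor frame; `superpose=True` Kabsch-aligns
each candidate mapping first and measures conformational rather than
positional deviation.  Both modes are exposed because published redocking
numbers do not always state which was used.

Automorphisms are enumerated by backtracking over vertices ordered
rarest-(element, degree)-class first, checking adjacency *and*
non-adjacency against all previously assigned vertices; the search is
capped at 10,000 mappings with an explicit error, since pathological
symmetry (e.g. disconnected identical fragments) grows factorially.
Kabsch superposition uses the SVD construction with the determinant
correction, guaranteeing a proper rotation.

## Ranking core (`triage_ranking`)

* **Quadrant filter**: keep candidates with affinity ≤ reference and
  LD50 ≥ reference, both inclusive.  Inclusivity matters: a candidate that
  exactly ties the reference affinity must pass.  The reference itself is
  excluded from the candidate list.
* **Ideal point**: componentwise best values — most negative affinity,
  largest LD50.  When the ideal is defined over a larger pool than the
  ranked subset (the usual case: the pool extremes need not survive the
  quadrant), pass it explicitly; `from_set` mode scans the given records.
* **Distance**: `sqrt((affinity_i − affinity_min)² + (ld50_i − ld50_max)²)`
  computed verbatim in mixed units (kcal/mol and mol/kg).  This is the
  published convention and the default.  Because affinities span ~kcal/mol
  units while LD50 spans ~0.1 mol/kg, the affinity axis dominates; a
  z-score `normalize=True` mode is provided as unit hygiene but is OFF by
  default — reproduce first, improve second.  Ranking ties break by id.
* **BOILED-Egg**: two ellipses in (TPSA, WLogP) space, bundled in
  `data/boiled_egg.json` with the published two-ellipse parameters: inside
  the yolk → BBB, else inside the white → HIA, else Out; the yolk wins
  overlaps.  Region labels already present on input records are treated as
  annotations and never silently recomputed.

## Structure QC (`structure_qc`)

* **Alignment**: Biopython `PairwiseAligner`, global mode with free end
  gaps, BLOSUM62, gap open 10 / extend 0.5.  Free end gaps are essential:
  a template covering only an interior stretch of the target must not pay
  terminal-gap penalties, or coverage would distort the alignment.
  **Identity** = matches / aligned non-gap columns × 100, two decimals
  (for an equal-length pair with k substitutions this equals
  (L−k)/L × 100); **coverage** = aligned target residues / target length.
  Mismatches are listed in 1-based target numbering.
* **Dihedrals**: φ = C(i−1)–N–CA–C, ψ = N–CA–C–N(i+1), IUPAC sign
  convention, degrees in (−180, 180].  A CA–CA distance > 4.5 Å is a
  chain break and suppresses angles across it; terminal residues are
  flagged.  Verified against an independent plane-normal formulation to
  1e-9 degrees.
* **Ramachandran classification** uses a bundled *coarse* polygonal map
  (α, β and left-handed-α basins with allowed halos) — a transparent
  stand-in, not any validation server's criterion, so its percentages are
  not comparable to published server scores.  Points on a polygon edge
  take the more favorable class.

## MD metrics (`md_analysis`)

* **RMSD**: per frame, Kabsch-superpose the selection (typically backbone
  atom names) onto the reference frame, then RMSD over the same selection.
* **RMSF**: per-atom `sqrt(mean_f |x_f − <x>|²)` about the time-mean
  position, averaged within residues; computed on the backbone and
  reported per residue by default.  Optional pre-alignment to the mean
  structure removes global rigid-body drift.  For isotropic Gaussian noise
  of width σ per coordinate the expected RMSF is σ√3, which is the planted
  truth the generators record.
* **Hydrogen bonds**: a donor–acceptor pair counts when its distance is
  ≤ 3.5 Å.  The criterion is distance-only by default because that is the
  stated analysis setting being mirrored; an optional D–H···A angle cutoff
  (150° when enabled) is available for stricter geometry and requires a
  donor→hydrogen map.
* **Energies**: `energy_summary` is the mean over frames of
  (Coul-SR + LJ-SR); both terms are the *short-range* GROMACS-style
  components, read from plain two-column text files (`#`/`@` headers
  ignored).  `energy_ratio` is |E_system| / |E_reference| rounded half-even
  to 4 decimals, with a same-sign requirement so the ratio compares
  like-for-like attraction.

## Synthetic data (`synthetic_data`)

Each generator draws from its own counter-based Philox stream keyed by
(seed, generator-name): adding or reordering generators never perturbs
another's output, and identical specs give byte-identical data.  Defaults
emulate the study regimes the pipeline is built for:

* compound tables: affinity ~ U(−11.5, −6.5) kcal/mol, LD50 ~ U(2.3, 3.0)
  mol/kg, with an exact planted number of quadrant passers vs the
  rosiglitazone reference (−8.5, 2.713), e.g. 199 compounds with 12
  passers; optional planted duplicates (274 → 250 after deduplication);
* score sets: actives N(μ−δ, σ), decoys N(μ, σ) around μ = −7.2 kcal/mol,
  expected AUC = Φ(δ/σ√2) recorded as truth (5 actives × 50 decoys each →
  250 pooled decoys is the emulated validation design);
* toy conformers: idealized benzene (12 automorphisms),
  para-difluorobenzene (4), and the bundled rosiglitazone pose, under
  controlled rigid motions with known symmetry-RMSD truth;
* trajectories: static base + per-residue isotropic Gaussian noise, truth
  RMSF = σ√3;
* sequence pairs: 272-residue target with 3 planted substitutions →
  98.90% identity, optional window truncation for partial coverage
  (e.g. 272/500 → 54.4%).

What the generators do **not** emulate: real chemical-space structure
(decoys and table rows carry matched bulk properties, not molecules),
conformational flexibility, correlated protein motions, force-field
physics, or alignment-gap scenarios beyond terminal truncation.  Passing
tests therefore demonstrate correctness of the *analysis operators* under
known ground truth, not predictive validity on experimental data.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by choice: ranking
on the 13-row bundled table; AUC oracles at ≤ 200×200 pairs with the
closed-form check averaged over 25 replicates of 20 actives × 1000 decoys;
automorphism oracles on ≤ 8-atom fixtures; RMSF recovery at 10⁴ frames ×
12 atoms; alignments at ≤ 500 residues.  Tolerances: exact (1e-12/1e-9)
for algebraic identities and oracles, 3% for the 10⁴-frame RMSF recovery,
3 standard errors for Monte-Carlo means.

Floating-point ties in the pharmacophore and ranking searches are broken
lexicographically; automorphism minimization uses a 1e-15 improvement
margin so platform-dependent last-bit noise cannot flip mappings.  Numbers
copied from typeset tables parse with unicode minus/en-dash tolerance.

## Known limitations

* The verbatim mixed-unit distance makes the affinity axis dominate the
  ranking; the z-score mode exists but changes the published ordering and
  is therefore opt-in.
* The BOILED-Egg ellipses are bundled constants; compounds outside the
  parameterized property range are simply "Out".
* The Ramachandran map is coarse by design (see above).
* The automorphism enumerator targets drug-sized ligands; highly symmetric
  or disconnected inputs hit the cap deliberately.
* Trajectory I/O is multi-model PDB / multi-frame XYZ text only; engine
  binary formats are out of scope, as are docking, MD and homology-model
  construction themselves.
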