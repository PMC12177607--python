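# Methods

This note documents the models, conventions and numerical choices behind
odorkit, what the synthetic generators do and do not emulate, and the
limitations a user should know before trusting a number.

## Structure model and PDB I/O

Coordinates are read from fixed-column PDB v3.x only (mmCIF and binary
trajectory formats are out of scope).  One `StructureModel` is built per
MODEL block; an `Ensemble` enforces an identical atom-key sequence
(chain, resseq, icode, name) across models, since every ensemble observable
assumes frame-to-frame atom correspondence.  Alternate locations are
collapsed before anything else sees the atoms: the highest-occupancy
conformer wins, ties resolve to the lexicographically smallest altloc
(blank/'A' first).  Occupancies outside [0, 1] are clamped with a warning
rather than rejected, because such files occur in the wild.  Protein
selections (`CA`, `backbone`, `heavy`) take all ATOM records plus HETATM
records whose residue is a standard amino acid (covering modified residues
such as MSE) — so docking ligands and ions never leak into RMSD fits.
Writing is round-trip safe to the PDB's 3-decimal coordinate precision;
coordinates that cannot fit the 8.3 field are an error, not a silent
truncation.

## Superposition and pruned RMSD

The rigid fit is the standard Kabsch SVD solution with the determinant
sign correction that excludes reflections; optional per-atom weights are
normalized internally.  Collinear point sets produce a warning, not an
error, because the fit is still defined (up to a spin about the line).

Residue pairing for two-structure comparison uses CA atoms only.
`numbering` mode pairs identical residue keys; `alignment` mode derives
one-letter sequences and pairs the non-gap columns of a global
Needleman–Wunsch alignment (BLOSUM62, gap open 10, extend 0.5, penalty
convention positive — conventional protein defaults, recorded in the
result).  Secondary-structure-weighted alignment of the kind interactive
viewers perform is deliberately not reproduced.

Pruning iterates: fit the retained pairs, find the set E of pairs whose
fitted CA–CA distance exceeds the cutoff (default 2.0 Å), remove the
r = max(1, min(⌊0.10·N⌋, ⌊0.50·|E|⌋)) farthest pairs — N the *current*
pair count, ties broken toward the lower residue index for determinism —
then refit, stopping when E is empty or when removal would leave fewer
than 3 pairs (flagged non-converged).  The max(1, ·) floor guarantees
progress, so the loop terminates in at most N rounds.  Percentages are
taken of the current count, not the original; this is the one place the
procedure's published description is ambiguous, and the choice is recorded
here.  Both the first-iteration all-pair RMSD and the final pruned RMSD
are reported, with the retained-pair list.

RMSF uses a two-pass mean-structure reference: fit every model to model 1,
average, refit every model to that mean, average again, and measure
fluctuations about the second mean.  The reference-structure convention
matters at the ~1/n level (n = atom count) and mean-structure RMSF is the
standard choice.  Radius of gyration supports uniform and mass weighting;
masses come from a small element table with carbon as the fallback.

## Geometry quality control

φ is C(i−1)–N(i)–CA(i)–C(i), ψ is N(i)–CA(i)–C(i)–N(i+1), both by the
standard atan2 torsion in [−180, 180).  A peptide C–N distance above
2.5 Å is treated as a chain break, so the flanking residues become
effective termini with undefined φ or ψ.  Residue classes: Gly and Pro by
residue name, pre-Pro for a non-Gly/Pro residue whose successor is Pro,
else General.

Ramachandran regions are coarse Favored/Allowed polygons per class,
shipped as versioned package data (`data/rama_regions.json`) and tested
for torus periodicity.  They follow the familiar high-resolution contour
conventions qualitatively — α and β favored basins, a left-handed-α
allowed region, mirrored regions for Gly, a restricted φ band for Pro —
but are *not* a published contour set; absolute favored/outlier
percentages from finer contour tables will differ, and the data file is
designed to be swappable.  A full MolProbity score is intentionally not
computed (its calibration is specific to its implementation); the report
exposes the ingredients instead.

Bond/angle QC evaluates the backbone subset only (N–CA, CA–C, C–O,
peptide C–N; the N–CA–C, CA–C–N, C–N–CA, CA–C–O, O–C–N angles) against
Engh–Huber-style restraint targets in `data/ideal_backbone.json`, flagging
|observed − mean| > 4σ.  A backbone subset suffices to exercise the
mechanism; whole-structure fractions from full-dictionary validators will
differ.

Clashscore counts unordered heavy-atom pairs with van der Waals overlap
(r_i + r_j − d) ≥ 0.4 Å, per 1000 heavy atoms, excluding pairs within
3 bonds of each other.  Connectivity comes from chemistry templates for
the 20 standard residues plus backbone/peptide bonds; unknown residues
fall back to distance bonding (< 1.9 Å).  The neighbor search is a spatial
hash with cell size 2·r_max, verified exactly against the all-pairs loop.

SASA is Shrake–Rupley with a deterministic Fibonacci sphere (default 960
points per atom, < 32 rejected as too coarse), probe 1.4 Å, heavy atoms
only.  Single-sphere accuracy at 960 points is well inside 1% of
4π(r + probe)²; the two-sphere case matches the analytic spherical-cap
solution within 2%.

## Chemical-space clustering

The descriptor pipeline assumes a molecules × descriptors CSV; descriptor
*computation* from SMILES is outside the core (an external engine's job).
Cleaning drops non-finite and zero-variance columns.  The correlation
filter walks columns in order and drops any column with |Pearson r| above
the threshold (default 0.95) against an already-kept column — keep-first
is arbitrary but deterministic and recorded.

PCA operates on z-scored columns (so it is a correlation-structure
decomposition) via scikit-learn's exact SVD solver, with a deterministic
sign convention (largest-magnitude loading positive).  The default
retained dimension is m = 2 — chemical-space plots and the centroid
distances live in this plane — configurable by count or cumulative
variance target.

K-means is Lloyd's algorithm with k-means++ seeding, best of 10 restarts
by WCSS, convergence at centroid shift < 1e-8, and empty-cluster repair by
reseeding at the farthest point.  It is implemented here rather than
delegated because the objective (WCSS) is the quantity every criterion
below consumes, and the test suite cross-checks it against both exhaustive
partition enumeration (n ≤ 10, k = 2) and scikit-learn.

For the criteria, the likelihood is that of spherical Gaussians at the
centroids with one shared variance; the MLE σ̂² = WCSS/(n·m) gives
ln L̂ = −(n·m/2)(ln(2π σ̂²) + 1), an *absolute* log-likelihood so AIC and
BIC are absolute too (only differences matter for selection).  The
parameter count is p = k·m + 1 (k centroids of dimension m plus the shared
variance), making BIC − AIC = p(ln n − 2) an exact identity the tests
assert.  Both σ̂² policy and p are isolated behind one function so
alternative conventions are one-line swaps.  Silhouette, Davies–Bouldin
(σ_i = mean member–centroid distance) and Calinski–Harabasz follow their
defining formulas; a singleton cluster's silhouette is defined as 0 and
flagged.  The chosen k is the mode of the five per-criterion winners with
ties resolved toward the BIC winner; when silhouette stays below 0.3 at
every k the result carries a weak-structure flag, since a featureless
cloud will still produce an argmin.  Note that on well-separated mixtures
AIC/BIC under this spherical model keep improving past the true k — the
consensus is robust to that because the three geometry-based indices peak
sharply at the right k.

Representatives are, per cluster, the m molecules with smallest Euclidean
distance to their centroid in PCA space (default 4; 4 × 5 clusters = 20
selections), in increasing-distance order with input order breaking ties;
clusters smaller than m return all members and are flagged.

## Docking-score statistics

Tables are keyed (receptor, ligand, engine) with engines vina /
gnina_affinity / gnina_cnnscore; duplicate keys and non-finite values are
rejected at load.  Responsiveness labels must arrive pre-binarized — the
thresholding of experimental response data is a judgment call that belongs
to the caller.

Kruskal–Wallis H and its χ² p-value come from scipy with the tie
correction; the all-values-identical degenerate case is reported as H = 0,
p = 1 by convention.  Dunn's post hoc computes pairwise z from pooled-rank
means with the tie-corrected variance term, two-sided normal p-values,
Bonferroni-adjusted and capped at 1.00 by default (the capping is why
honest post hoc tables contain many exact 1.00 entries).  With two groups
and no adjustment, Dunn's z² equals H and the p-value equals the
Mann–Whitney normal approximation — both are asserted numerically.

AUC uses midranks, so tied scores contribute half credit, and the emitted
ROC curve steps through tied scores jointly; its trapezoidal area equals
the rank AUC to 1e-9 by construction.  Orientation defaults to
lower-is-active because binding energies are negative-better; CNN pose
scores flip it.

## Synthetic generators

All generators are pure functions of (spec, seed) using NumPy's
`default_rng`, so fixtures are bitwise reproducible.

- `build_helix` places N/CA/C/O sequentially by the natural-extension
  reference frame from the same ideal bond/angle table the QC uses, so an
  unperturbed build passes bond/angle checks with zero flags and returns
  exactly the φ/ψ it was given (the carbonyl O sits at torsion ψ − 180°,
  which fixes O–C–N at 123.0° by construction).  Per-residue torsion lists
  allow injecting single Ramachandran outliers.
- `perturb_structure` composes a rigid motion, seeded isotropic Gaussian
  noise, and a fixed displacement of a chosen residue subset — a
  core + outlier pair where the pair the pruning should remove is known.
- `gen_mixture` draws 5 spherical Gaussian components in 2-D, unit σ,
  centers ≥ 10σ apart, 30 points each by default.  This makes
  cluster-number recovery a sharp test: the correct answer is unambiguous,
  and failure indicates a mechanical bug, not statistical bad luck.  A
  hard mode (~2σ separation) exists for diagnostic behavior.  Optional
  nuisance columns (exact copies, r ≈ 0.96 near-copies) exercise the
  correlation filter.
- `gen_scores` draws per-receptor energies N(base + shift, sd²) with an
  active fraction shifted by −Δ; with Δ = 1 and sd = 1 the population AUC
  is Φ(Δ/√2) ≈ 0.7602, which the empirical AUC matches within ±0.02 at
  2000 per class.

What these fixtures do *not* emulate: real descriptor distributions are
heavy-tailed, discrete and massively collinear rather than Gaussian;
real docking-score distributions are skewed and receptor-correlated; real
structures have side chains, heterogeneous B-factors and missing density.
Passing tests therefore demonstrate that the *mechanisms* (pruning,
criteria, rank statistics, quadrature) are correct, not that any
particular biological conclusion transfers.

## Problem sizes and defaults

Defaults follow the conventions of the workflow the package supports:
pruning cutoff 2.0 Å, correlation threshold 0.95, PCA dimension 2,
k range 2–10, 4 representatives per cluster, SASA probe 1.4 Å with 960
points, clash overlap 0.4 Å, bond/angle z-threshold 4.  The acceptance
script uses 15-structure benchmark aggregation, a 150-molecule mixture
with a 20-seed recovery experiment, 10 grid-search oracle instances,
1000 null replicates for the Kruskal–Wallis calibration and 2000 per class
for the Gaussian AUC law — sizes chosen so every quantity is statistically
stable while the whole script runs in seconds.

## Known limitations

- Ramachandran percentages depend on the coarse shipped polygons; they are
  for mechanism testing and relative comparison, not for publication-grade
  validation against finer contour sets.
- Bond/angle QC covers the backbone subset only; rotamers, Cβ deviations
  and CaBLAM are out of scope.
- The pruning procedure's percentage base (current vs original pair count)
  is a documented convention, as is the AIC/BIC parameter count.
- `numbering` pairing requires consistent residue numbering; renumbered or
  heavily gapped structures should use `alignment` mode.
- No trajectory formats: ensembles must arrive as multi-MODEL PDB.
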