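# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `oligoqs`, module by module, in the order a comparison runs.

## Structure model

Assemblies are parsed with gemmi (PDB and mmCIF; a stored biological
assembly can be expanded by its operators).  Filters match standard
quaternary-structure surveys: chains under 20 residues (peptides) and
Cα-trace chains are dropped; an input in which nothing survives is an
error.  Altloc handling keeps the highest-occupancy conformer per atom
name.  Modified residues map to their parent one-letter code via gemmi's
tabulated chemistry (MSE → M); anything unmapped becomes X and is treated
as alanine for alignment scoring only.

Every residue carries a representative coordinate: Cβ, or Cα for glycine.
A non-glycine residue lacking Cβ falls back to Cα with a logged warning —
this keeps incomplete crystal structures usable at the cost of ~0.5–1.5 Å
positional bias for those residues.

*Chemical equivalence.*  Chains share an entity when a global alignment
(Needleman–Wunsch, BLOSUM62, gap −11/−1 — used for every alignment in the
package) shows ≥ 95% identity over ≥ 90% mutual coverage; the partition is
the transitive closure, so His-tagged or truncated variants of one protein
group together.  The 95% figure matches the redundancy level commonly used
for target–template separation.  Stoichiometry strings (`A2B2`) order
entities by descending multiplicity, ties by representative sequence.

## Solvent accessibility and residue classes

SASA uses the Shrake–Rupley algorithm with a 1.4 Å probe and 960
deterministic golden-spiral points per atom; per-element van der Waals
radii (C 1.70, N 1.55, O 1.52, S 1.80 Å).  An isolated atom reproduces the
analytic sphere area exactly; quadrature error on buried atoms is well
under the 2% the tests allow.  Relative accessibilities divide by the
Tien et al. (2013) theoretical maximum ASA per residue type.  Because other
tools (e.g. Naccess-based workflows) use slightly different reference
values, classifications of residues sitting near the 25% boundaries can
flip between implementations; this is inherent to the rule, not resolved
here.

Classification: interface if rBSA > 25% **and** assembly rASA < 25%;
otherwise surface if monomer rASA > 25%; otherwise core.  A residue can
satisfy both the interface and surface definitions; interface takes
precedence.  Per-interaction buried surface (half the pairwise ASA loss)
is exposed as a utility, e.g. to filter crystal-packing contacts
(< 250 Å²).

## Contacts

Interface contacts are inter-chain residue pairs with representative-atom
distance strictly below 12 Å (a k-d tree implementation, tested against
brute force).  The strict inequality is a convention choice; boundary
pairs are measure-zero in practice.

## Chain mapping

Rigid superposition is Kabsch (SVD with reflection guard), cross-checked
in tests against an independent implementation.  Mapping search:

1. entities matched across assemblies greedily by alignment identity, with
   a 20% identity homology floor;
2. if the number of entity-consistent bijections is ≤ 10,080 (covers
   single-entity complexes to 7 chains), exhaustive enumeration: each
   candidate's aligned representative coordinates are superposed globally
   and the lowest RMSD wins (ties broken by lexicographically smallest
   pair list);
3. otherwise, symmetry-guided search.  Symmetry detection superposes
   entity-equivalent chain pairs to propose rigid operations (deduplicated
   at < 15° rotation difference), validates each against the whole
   assembly (every chain must land on a distinct same-entity chain within
   3 Å RMSD), and requires the induced permutation to have uniform cycle
   length.  The chains are then partitioned into asymmetric-unit groups —
   e.g. a C2 dimer gives two singleton groups related by one transform; an
   α2β2 tetramer gives two αβ pairs.  Search seeds comprise every
   entity-consistent injection between group pairs **plus** every single
   chain pair: the two assemblies may admit incompatible group
   decompositions (both are valid symmetries), and single-chain seeds keep
   the search exact in that case.  Each seed fixes a transform; remaining
   chains are assigned per entity by a Hungarian assignment of
   RMSD-under-transform, and the completed mapping is rescored by global
   superposition.

On all test fixtures with ≤ 5 chains the symmetry-guided optimum equals
the exhaustive minimum to 1e-6 Å.  A seed budget of 100,000 guards
against pathological cases (mirroring the small fraction of complexes a
survey must set aside as intractable); such pairs raise a dedicated error
and are excluded from clustering, not silently mis-mapped.

Residue correspondence comes from the per-chain-pair global alignments.
The superposition RMSD is computed over representative (Cβ/Cα) atoms for
consistency with the contact definition.

## QS-score

Implemented exactly as stated in the README formula.  Conventions:

* "mapped" requires presence in the residue mapping only — residue
  identity may differ, which is what makes heterologous comparisons work;
* an A-contact whose mapped pair exceeds the cutoff in B is non-shared
  (and vice versa);
* two assemblies that both lack inter-chain contacts entirely (monomers)
  score 1.0 — identical, empty, interfaces; the 0/0 of the formula is
  resolved in favour of the self-identity property.

The score is symmetric in its arguments given inverse mappings, bounded in
[0, 1], equals 1 exactly on self-comparison, and decreases monotonically
(in median) under growing coordinate noise — all property-tested.

## PPI fingerprint

Column conservation is relative entropy against the alignment-wide non-gap
background, RE_c = Σ_a p_a log2(p_a / p_ab), normalised by log2 20 and
clamped to [0, 1].  Region averages use the complementary normalised
**entropy** h_c = 1 − RE_c/log2 20 (0 = fully conserved), weighted by
monomer rASA; this makes the interface–surface log-ratio
IS = ln((1+⟨S⟩ᵢ)/(1+⟨S⟩ₛ)) negative for conserved interfaces, the sign
convention under which all downstream interpretation (and the fingerprint
figures of the field) operate.

Null model: an adjacency graph over surface residues (minimum atom–atom
distance ≤ N Å, N grown from 4.5 Å in 0.5 Å steps until connected);
patches grow from a random surface residue by adding random neighbours
until they match the interface size; each patch is scored against the
remaining surface with the original interface excluded throughout.  The
iteration count defaults to max(100, 2 × surface size) — proportional to
surface size, scaled for desk runtime.  The P-value is the smaller flank
integral of a Gaussian KDE (Silverman bandwidth) over the null, clamped to
[0, 1]; IS outside the null range gives P = 0; a zero-variance null
degenerates to P = 1 iff IS equals the constant.  C_score = IS (1 − P).

The curve spans thresholds 0.00–0.95 in 0.05 steps (20 points).  Identity
to the query counts matches over mutually non-gapped columns.  Thresholds
retaining fewer than 5 sequences are undefined and excluded from the four
summary features (minimum; absolute maximum with sign; full-MSA value;
trapezoid area over defined points).  When a protein has several
interfaces, scores are computed per interface and averaged.

*Interface designation.*  The burial-based 25% classification is the
primary interface definition.  The fingerprint and feature-extraction
entry points also accept an explicit interface residue set: the idealised
test oligomers (few atoms per residue) are intrinsically more exposed
relative to the reference ASA than real proteins, so their designed
interfaces are passed explicitly (or derived from the contact map, the
same definition the QS-score uses).  The pipeline falls back to the
contact-based interface automatically when burial classification finds
none, and logs that it did.

## Assembly clustering

Three nested levels: state (mono/homo/hetero), stoichiometry string, and
QS-score geometry.  Distances are 1 − QS.  The threshold convention
follows the heterogeneity-survey axis: threshold t merges assemblies with
QS ≥ t (cut distance 1 − t), so t = 0 collapses each stoichiometry group
to one cluster; a literal distance interpretation is available via
`threshold_kind="distance"`.  Complete linkage (scipy) serves PDB-style
surveys; greedy agglomeration (merge the closest pair below the cut,
lowest-index tie-break) serves template consensus.  Pairs whose mapping is
intractable are recorded and the offending assemblies set aside greedily.
Sequence-level grouping reimplements CD-HIT-style greedy clustering at 90%
identity (longest-first, join-first-matching-representative), adequate at
fixture scale; an assembly's sequence-cluster key is the frozen set of its
chains' cluster ids, so heteromers with chains in different clusters are
keyed correctly.

## Template features and ranking

Per target–template pair, 29 features in four classes (sequence, MSA, QS
consensus, composition), each property multiplied by target coverage
(aligned fraction of the target sequence).  Choices where the scheme was
open:

* similarity = fraction of aligned pairs with positive BLOSUM62 score;
* secondary structure: template 3-state H/E/C from backbone φ/ψ ranges
  (coil when backbone atoms are missing); the target string is an input,
  as SS prediction is upstream of this package;
* accessibility agreement: 2-state buried/exposed at rASA 25%;
* composition sets: hydrophobic {A,V,L,I,M,F,W,C}, hydrophilic
  {R,N,D,Q,E,H,K,S,T,Y}; B-factor feature = mean(interface)/mean(surface),
  1.0 when the denominator vanishes;
* template e-value and profile entropy are read from upstream search
  output when supplied; the fixture generator fabricates them.

Heteromeric targets: features are computed per target sequence against its
best-matching template chain and averaged.

Quality bins on QS: [0, 0.1) incorrect, [0.1, 0.3) low, [0.3, 0.7] medium,
(0.7, 1] high (0.7 itself is medium, resolving an ambiguity between two
equally citable conventions).

Co-evolution agreement: predicted inter-chain contacts are truncated to
the top 1.5 × target length by score; the feature is the fraction realized
in the model at < 7 Å between representative atoms.

The ranker is an RBF-kernel support-vector regressor behind a
standardise → select → fit pipeline.  Grid search covers
C ∈ {1, 10, 100}, γ ∈ {scale, 0.1, 0.01}, ε ∈ {0.01, 0.1}; 10-fold
cross-validation with folds grouped by target (a target never spans train
and test); fold count drops to the group count with a warning when
needed.  Univariate feature selection keeps the top 25 features ranked by
absolute Pearson correlation with the label — numerically equivalent in
ordering to the univariate F-test but finite for a perfectly correlated
feature, where the F-statistic diverges and would otherwise silently drop
the best feature.  Ranking is by descending predicted QS, ties broken by
template id.

## Pipeline

Template admissibility requires (i) a homologous chain (≥ 20% identity)
for every target sequence, (ii) no two target sequences mapped to
overlapping fragments of one template chain (aligned-range overlap test),
(iii) topological connectivity of heteromers (contact graph over chains
connected).  Survivors are clustered; consensus fractions are the
template's cluster size over the homolog count at each level.  With a
trained predictor the report ranks by predicted QS, otherwise by sequence
identity.  The JSON report nests state → stoichiometry → QS cluster with
per-template rank, predicted QS, identity and coverage, and lists rejected
templates with reasons.  Reports are byte-deterministic for a fixed
seed/config.

## Synthetic fixtures

Oligomers: chains are circular arcs of idealised residues (Cα spacing
3.8 Å, five atoms N/CA/C/O/Cβ, Cβ radially outward, gentle z-undulation),
sized so consecutive chains leave a 5 Å gap — guaranteeing inter-chain
contacts at the arc junctions.  Symmetry operators are applied exactly
(C2/C3/C4 rotations about z; D2 as the four-element rotation group;
heteromers stack a second entity 5.5 Å below the first).  Generated
assemblies satisfy their symmetry to well under 0.1 Å and round-trip
through the PDB reader.  Perturbations: Gaussian jitter, interface
swapping (chains re-stacked on the first chain — an alternative binding
mode with disjoint contacts), and subcomplex extraction.

MSAs: a random query plus rows on a ladder of target identities.
Substitution counts per row are exact (positions random, uniform over the
19 alternatives), with interface/surface rates renormalised so each row
realises its requested identity; a rate schedule lets conservation switch
on only above a chosen identity (two-regime families).  When a region's
rate is zero it is never mutated, even if that makes a very low requested
identity unreachable.

What the fixtures do **not** emulate: real side-chain packing and
stereochemistry, realistic ASA magnitudes (hence the explicit interface
designation above), gapped alignments, phylogenetic correlation between
MSA rows, and BLOSUM-structured substitution preferences.  Tests passing
on these fixtures validate the algorithms and their invariants, not
absolute performance on crystallographic data.

## Problem sizes and numerical conventions

Test and acceptance runs use chains of 24–30 residues, assemblies of 2–4
chains, MSAs of 25–40 rows, 20-group clustering sets, patch nulls of
60–100 iterations, and ranking datasets of ~200–300 rows — sizes chosen so
the full suite runs in well under a minute while every code path (including
the exhaustive mapping oracle) is exercised.  RMSD ties in the mapping
search are broken within 1e-6 Å toward the lexicographically smallest
pairing; all randomness flows through seeded `numpy` generators, and every
stochastic operation logs its seed.
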