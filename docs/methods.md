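# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `morphoseq`. It is written for a reader who wants to
judge what the package's computations — and its synthetic-data tests —
do and do not establish.

## Morphometric arm

### Generalized Procrustes analysis

Configurations are centered, scaled to unit centroid size, and iteratively
rotated onto the running consensus; the consensus is the mean of the
superimposed configurations, renormalized to unit size and re-aligned to
the previous consensus so the coordinate frame is stable across
iterations. Convergence is declared when the root-mean-square change of
the consensus falls below `tol = 1e-10` (default), with `max_iter = 100`;
non-convergence raises an error that carries the last fit. Only proper
rotations (determinant +1) are allowed: wing data come from one side of
the body, so reflections would be a digitization error, not biology.

After superimposition the coordinates are orthogonally projected onto the
tangent space at the consensus (the component along the unit consensus
vector is removed) before any multivariate analysis. This is standard
practice for small shape variation; an option (`tangent=False`) analyses
raw Procrustes coordinates instead. At the shape variation magnitudes the
generator produces (deformations ≤ ~7% of centroid size) the two choices
are numerically almost indistinguishable.

### Canonical variate analysis

Procrustes shape coordinates for k landmarks in 2 dimensions are rank
deficient: superimposition removes 2 translations, 1 rotation and 1 scale,
leaving at most 2k − 4 dimensions. The coordinates are therefore reduced
to the principal components with eigenvalue > 1e-10 × the largest, capped
at min(n − g, 2k − 4) axes, before forming between-group (**B**) and
pooled within-group (**W**) sums of squares and cross products. The
generalized eigenproblem **B**v = λ**W**v is solved with a symmetric
dense solver; c = min(g − 1, p) axes are retained and scaled so the
pooled within-group covariance of the canonical scores is the identity
(Euclidean distance in score space is then a Mahalanobis distance).
Wilks' Λ = Π(1 + λᵢ)⁻¹; the F approximation is Rao's, with
df₁ = pq, df₂ = ms − pq/2 + 1, m = n − 1 − (p + q + 1)/2,
s = √((p²q² − 4)/(p² + q² − 5)), q = g − 1. For a design with p = 31
retained dimensions, 6 groups and n = 239 this gives df (155, 1009) — the
dimensionality a real wing study of that size reports.

### Squared Mahalanobis distances, phenogram, classification

D²(g₁,g₂) is computed in the reduced PC space with the pooled within-group
covariance (Cholesky solve; the matrix is symmetric positive definite
after rank reduction). The g × g SMD matrix is clustered by UPGMA (see
below) into the phenogram. Classification assigns each specimen to the
group with the nearest mean in the same metric; `resubstitution`
(default) uses statistics fitted on all data and reproduces the
conventional, optimistic confusion matrix, while `leave_one_out`
recomputes the left-out specimen's group mean and the pooled covariance
without it — the honest error estimate. Reported percents are rounded to
one decimal, half-up, matching how such tables are conventionally printed.

### Centroid size comparison

Kruskal–Wallis H (tie-corrected, via scipy) followed by Dunn's pairwise z
tests on mean ranks, z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − T)(1/nᵢ + 1/nⱼ)) with
tie term T = Σ(t³ − t)/(12(N − 1)), Bonferroni-corrected over all
g(g−1)/2 pairs and capped at 1. Significance groups at α = 0.05 are
summarized by an insert-and-absorb compact letter display.

## Genetic arm

### Trimming, collapse, canonical mapping

Flank trimming locates the 18S 3′-end and 5.8S 5′-end reference fragments
by a minimum-Hamming scan (budget `max_mismatch = 2` by default) on both
strands and returns the intervening core. Per-sample collapse clusters
sequences by single linkage at ≥ 99% pairwise identity (identity =
matching residues over aligned ungapped column pairs of a global
alignment) and returns the most frequent exact sequence of the largest
cluster; frequency ties go to the first sequence in input order and are
flagged. "Predominant" is implemented as *most frequent clone*, not as a
consensus — with 1–2 substitutions among a handful of clones a consensus
would usually coincide, but the modal clone is reproducible and auditable.

Canonical mapping aligns the query (match +1, mismatch −1, gap open −4,
gap extend −1) against each exemplar's ungapped sequence, picks the
exemplar with the highest identity, and projects the query through that
exemplar's gap pattern into columns 1..669. Query insertions relative to
the exemplar have no canonical column and are dropped; identity below 70%
is rejected as non-ITS1. The bundled exemplar set is synthetic (one
noise-free sequence per type on the package's own canonical frame); users
with a curated reference alignment supply it as aligned FASTA.

### Diagnostic typing

The rule table (`data/af_its1_rules.txt`) encodes each type's markers on
the canonical frame. Matching semantics: *insertion* — motif occurs in
the ungapped content of the stated range ± 1 column of slack (published
coordinates are routinely off by one); *substitution* — stated residue at
the stated column, no slack; *reduction* — the ungapped content of the
exact stated range equals the reduced motif; *repeat* — the maximum run
of consecutive unit copies in the window falls within the stated count
range. Columns 1–109 (the 5′ interrupted poly(A) region) are excluded
from all matching: the region is too variable to align.

Variants inherit their parent's required markers except where one of
their own markers overlaps a parent marker's stated range — the variant
then *shadows* the parental marker. This is forced by the data: one
variant's expansion occupies part of its parent's diagnostic motif range,
so both cannot be present literally. Classification is therefore
family-wise: a sequence belongs to a base family if the base *or any of
its variants* matches in full; the deepest full match wins; matching two
distinct families sets an ambiguity flag. Markers described in the
literature without explicit positions or motifs ("several other SNPs")
are deliberately not encoded; the SNP residues at stated positions are
placeholders consistent with the synthetic exemplars, since published
descriptions give positions but not residues. The rule table is data, not
ground truth, and is meant to be edited when a curated frame exists.

### Distances, UPGMA, bootstrap

Distances are computed after complete deletion (only columns where every
sequence is unambiguous A/C/G/T; IUPAC ambiguity codes are normalized to
N and removed). Models: p-distance; JC, d = −¾ln(1 − 4p/3); JC+Γ,
d = (3a/4)[(1 − 4p/3)^(−1/a) − 1]; TN93 and TN93+Γ from the
transition/transversion and base composition of each pair (verified
against R `ape::dist.dna` to 1e-9). Saturated pairs raise an error rather
than returning infinity. Gamma shape defaults to a = 1, the value such
ITS1 studies report using. MEGA-style "maximum composite likelihood"
pairwise distances have no closed form outside that program; TN93(+Γ) is
the closest closed-form model and the model is a switch everywhere.

UPGMA merges the closest pair at height d/2 and sets the new cluster's
distance to the others to the size-weighted mean of its parts; ties break
toward the lexicographically smallest taxon pair, making the tree
deterministic. The result is ultrametric by construction. Bootstrap
support resamples the surviving columns with replacement, rebuilds
distances and the tree, and reports for each original clade the
percentage of replicates containing the same unrooted leaf bipartition;
one master seed drives all replicates.

## Congruence

Both trees are pruned to their shared leaves after optional leaf-name
harmonization (morphometric sample codes and sequence codes usually
differ; the mapping is explicit data). Robinson–Foulds distance counts
unrooted nontrivial bipartitions present in exactly one tree, normalized
by 2(n − 3); cophenetic correlation is the Pearson correlation of
tip-to-tip path-length vectors; per group label, the report flags whether
the group's leaves form a clade in each tree. These metrics are added
instrumentation for what is otherwise an eyeball comparison of
side-by-side dendrograms; the package deliberately does not attach
p-values to them (no SH/AU-style topology tests).

## Synthetic data: what it emulates, and what passing tests show

### Landmark generator

Specimen i of group j is
sizescaleⱼ · sᵢ · R(θᵢ) · (base + deformationⱼ + noise) + tᵢ,
with θᵢ ~ U(0, 2π), tᵢ ~ U(−20, 20)² image units, log-normal size jitter
(sd 0.03) and isotropic Gaussian landmark noise. Defaults, chosen once as
the study conditions the pipeline assumes: 6 groups × 40 specimens (a
~240-specimen, six-morphotype design), deformation scale δ = 0.05 and
landmark noise σ = 0.0025 in units of the unit-centroid-size template,
i.e. δ/σ = 20 — the "deformation well above noise" regime in which
morphotypes are distinguishable at all.

Three structural choices matter and are worth stating explicitly:

* **Deformations live in shape space.** Group deformation fields are drawn
  orthogonal to the four similarity directions (x/y translation,
  infinitesimal rotation, scaling) at the base shape. A random
  36-dimensional vector has a sizeable random component along those
  directions, which superimposition silently absorbs — group separations
  would then be distorted by up to ~30% in unpredictable directions.
* **Spread magnitudes.** In the flat (non-hierarchical) mode, group
  deformation magnitudes are spread over 0.6–1.5 × δ along mutually
  orthogonal directions. Equal magnitudes would make all pairwise
  deformation distances coincide, so "does the recovered SMD matrix rank
  groups correctly" would be a question about ties, not about recovery.
* **Tree mode.** Given a group tree, each branch receives an orthogonal
  offset of squared norm proportional to its length, so squared
  deformation distances between groups are exactly proportional to
  cophenetic tree distances — the concordant-evolution scenario in which
  the phenogram should reproduce the genetic dendrogram.

Estimated squared Mahalanobis distances carry an additive small-sample
bias of order p(1/nᵢ + 1/nⱼ) and multiplicative noise of order
√(2/(n − g − p)); with p ≈ 32 retained dimensions this is why the
defaults use 40 specimens per group and δ/σ = 20. At weaker separation or
smaller samples the SMD matrix is dominated by estimation error and *no*
method reproduces the generating structure — a property of the statistic,
not of this implementation.

### Sequence generator

Sequences are built on a fixed 669-column canonical frame: a deterministic
AT-rich template (~75% AT; the 5′ poly(A) region is ~70% A) with reserved
gap columns for every type's insertions, forced residues at diagnostic
SNP columns, and guard residues that keep short diagnostic motifs from
arising by chance next to their windows. A type's sequence is the
template plus its effective markers plus a fixed set of type-private
substitutions at neutral columns — the counterpart of the unlisted "other
SNPs" that accompany every published type description. Private
substitutions nest (variants carry their parent's background plus a few
of their own) and are AT-preserving (complementary changes). Their counts
are spaced so that between-family distances are tie-free with UPGMA merge
heights separated by ~2× (tied heights would make dendrogram topology a
coin flip), and so that family-level mean intragroup distances reproduce
the qualitative published pattern: a tight single-type group (~0.002), a
mildly divergent family (~0.006), a variant-rich family (~0.03–0.04).
Background substitution noise (default 0 in unit tests, 0.001 in
end-to-end runs) only hits columns outside every marker window, so truth
labels stay valid; an `adversarial` flag lifts that protection to probe
classifier robustness. Optional homopolymer slippage perturbs tract
lengths in the output records only; optional flank wrapping produces
~870 nt amplicons for trim testing.

Generated core lengths fall in 532–562 nt for the bundled types, inside
the 530–583 nt range such amplicons span in practice.

### What passing tests do *not* show

The generators emulate the *statistical structure* the analyses assume,
not real biology: no landmark covariance (real wing landmarks covary
along veins), no allometry, no digitization error model, no indel
evolution or alignment uncertainty (the canonical frame is exact by
construction), no intra-individual ITS1 paralog variation, and
concordance between morphology and genetics is imposed, not evolved.
Passing the recovery and congruence suites therefore shows the pipeline
is correct and well-conditioned under its own assumptions — it does not
show that real wing shape and real ITS1 types must agree.

## Numerical choices and degenerate inputs

* GPA: tol 1e-10 on consensus RMS change, ≤ 100 iterations; degenerate
  (all-coincident) configurations are rejected.
* CVA rank reduction: eigenvalue > 1e-10 × largest, ≤ min(n − g, 2k − 4).
* UPGMA ties: lexicographically smallest taxon pair; NaN and asymmetric
  matrices are rejected; saturation raises instead of producing Inf.
* Marker slack: 1 column for insertions/repeats, none for substitutions
  and reductions.
* Identity threshold for canonical mapping: 70%; collapse threshold: 99%.
* Rounding of reported percents: one decimal, half-up.
* All stochastic components take explicit seeds; fixed seeds give
  bit-identical outputs.

## Limitations

* The Table-4-style classification matrix defaults to resubstitution
  (what such studies print); leave-one-out is the honest option and both
  are exposed.
* TN93+Γ stands in for MEGA's maximum composite likelihood distances;
  with a distance-model switch the difference is documented rather than
  hidden.
* The rule table's SNP residues and two marker coordinates (shifted off
  colliding columns) are synthetic placeholders pending a curated
  reference alignment.
* Recomputing published intragroup distances from archived accessions
  requires network access to sequence databases; offline, the package
  demonstrates the computation on synthetic type groups with the same
  structure instead.
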