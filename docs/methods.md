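# Methods

`chronomorph` implements a comparative-morphometrics stack for clades mixing
extant and fossil members: size-adjusted trait spaces built from linear
measurements, group-separation statistics, fossil-calibrated time trees,
phylogenetic-signal estimation, and the chronophylomorphospace — a phylogeny
embedded in (trait, trait, geological age) coordinates.  This note records
the models, the parameter choices that matter, and the numerical decisions
taken where the design was genuinely open.

## Shape variables and morphospace

Linear measurements confound isometric size with shape.  Each specimen's
measurements are divided by their geometric mean, `GM = (Πaᵢ)^(1/k)`,
computed in log space for stability.  The resulting Mosimann shape ratios are
dimensionless, multiply to exactly 1 within a specimen, and are invariant to
rescaling a specimen's row by any positive constant — both properties are
enforced by tests.  The morphospace is a PCA of these ratios with every
variable scaled to unit variance (a correlation-matrix PCA), computed by SVD
of the standardized data rather than by forming the covariance matrix.  Axis
signs are fixed by making the largest-magnitude loading on each axis
positive, so scores are reproducible across BLAS implementations.  A helper
returns the smallest number of leading axes reaching a cumulative-variance
cutoff (default 90%); downstream analyses operate on exactly the axes the
caller selects.  Species centroids (arithmetic mean scores per species) are
the tip data for all phylogenetic analyses.

## Classification and group separation

LDA uses the shared-covariance Gaussian model (scikit-learn's SVD solver
underneath, which tolerates near-singular pooled covariances without an
explicit ridge).  Priors default to group proportions and can be switched to
uniform; the choice is exposed because published analyses rarely state it.
Validation is a leave-one-out jackknife that refits the full model for every
fold — no rank-one shortcut — retaining per-specimen posterior probabilities.
Folds that would empty a group are predicted among the remaining groups and
flagged.

NPMANOVA computes the pseudo-F from sums of squared Euclidean inter-point
distances, `SS_total = Σ_{i<j} d²ᵢⱼ / n` partitioned into within- and
among-group components, with significance from random relabelings.  The
permutation p value uses the +1 convention (the observed statistic counts as
one permutation), so the smallest attainable value with 9999 permutations is
10⁻⁴; a reported p of 0.0001 means "no permutation exceeded the observed F".
Specimens, not centroids, are the test units.  Pairwise comparisons re-permute
within each pair (each pair gets an independent child seed) and are adjusted
by sequential Bonferroni (Holm).  With two groups in one dimension the
pseudo-F reduces algebraically to the classical ANOVA F; a test asserts this
to 10⁻¹⁰, and the one-way statistic is cross-checked against scikit-bio's
independent PERMANOVA implementation.

## Time-scaling

Ages are stored as Ma before present; branch durations are always derived as
`age(parent) − age(child)`, never stored separately.  Three calibration modes
are provided.  In the main mode, fossil tips sit at the arithmetic midpoint of
their stratigraphic range, extant tips constrain their parent nodes by first
occurrence and are extended to the present; internal nodes take
`max(molecular date, oldest descendant constraint)` in a single post-order
pass, which guarantees parent ≥ child everywhere.  The range mode dates nodes
by first occurrences and extends terminal branches to last occurrences; the
midpoint mode uses midpoints throughout, treating the present as the upper
margin for extant ranges.  Molecular dates attach to internal nodes by the
MRCA of a stated tip pair (`mrca_of` column), since node identity cannot be
carried in a flat CSV any other way.  A molecular date younger than the
fossil constraint is overridden by the fossil (max rule) and logged with a
warning; nothing propagates from such a node to deeper unconstrained nodes
beyond the parent ≥ child pass itself.

Zero-length branches — unavoidable when a node's age is set by its own oldest
descendant — are resolved by one of two policies.  `share` (default) finds,
for each zero chain, the nearest ancestral branch with positive duration and
spaces the chain's nodes evenly along it; the age at the bottom of the chain
is unchanged, so root-to-tip ages of all tips are preserved.  Chains are
collected deepest-first so a multi-edge chain is treated as one unit.
`epsilon` pushes each zero-duration child a fixed ε (default 0.1 Myr)
younger than its parent; it perturbs tip dates but never raises nodes, which
makes it the right tool when node ages themselves are under scrutiny.  A zero
chain reaching the root is a hard error under `share`: there is no duration
to redistribute, and silently inventing a root age would corrupt every
downstream rate estimate.

Pruning to the morphometric sample preserves node ages exactly (collapsed
unary nodes simply disappear), so patristic distances among retained tips are
unchanged — tested against a path-sum oracle.  Grafting replaces a
supraspecific placeholder tip with a resolved donor subtree and clears all
ages, because a composite tree is only meaningful after re-dating.

## Parsimony scoring

Character matrices hold state *sets* per cell: singletons, polymorphic sets
(`[0 1]`), or — for `?` — the full set of states observed in that character.
Tree length is the minimum number of unordered state changes.  On binary
trees this is Fitch's intersection/union recursion; the implementation uses
the equivalent unit-cost dynamic program (per-state minimum cost vectors),
which stays exact on polytomies and with set-valued tips, and is verified
against exhaustive enumeration over all internal-state assignments on random
instances.  Ensemble indices use per-character minimum steps
`m = (#observed states − 1)` and star-tree maximum steps `g`, the latter
computed directly as the minimum over central states of the number of tips
whose set excludes that state (polymorphic tips thereby contribute their
cheapest state).  Published rescaled-consistency values are ambiguous about
which CI variant they multiply by RI, and the two conventions differ whenever
uninformative characters are present, so both CIs are always reported and the
RC convention is an explicit switch (`ci_all` by default).

The supraspecific-OTU rule collapses five exemplar species' binary scores by
vote: sums 0–1 give state 0, 4–5 give state 1, 2–3 give the polymorphic set
{0,1}.  Non-binary characters are accepted only when at least four of the
five exemplars agree, mirroring the documented exception for a ternary
character; anything else is an error rather than a guess.

## Phylogenetic signal

PCO axes are the eigenvectors of the Gower-centered squared patristic
distance matrix, scaled by the square roots of their eigenvalues; variance
fractions are taken over positive eigenvalues only and the smallest prefix
reaching the cutoff (default 95%) is retained.  "Distances built from branch
lengths" is read as plain patristic distances; because a tree metric is not
exactly Euclidean, a `sqrt_patristic` option provides the square-root
transform, which is (trees being of negative type) exactly embeddable and
yields the full n−1 positive axes — the saturation identity (regression on
all n−1 axes reproduces any response exactly) is tested in that metric.

PVR is OLS of one response on the retained axes plus an intercept, with the
usual F test; a constant response is defined to have R² = 0.  MPVR shares the
predictors across response columns; its pooled variance fraction is
trace-based, `Σ SSRⱼ / Σ SSTⱼ`, appropriate when the responses are PC scores
and hence already variance-weighted (the determinant-based alternative would
weight axes equally regardless of their variance).  Overall MPVR significance
is Wilks' Λ with Rao's F approximation.

Felsenstein's contrasts follow the pruning recursion; because branch-length
updates do not depend on the data, the full contrast vector is a fixed linear
operator of the tip values, which makes permutation tests a single matrix
product.  Blomberg's K is the ratio of the observed `MSE₀/MSE` (ordinary vs
V⁻¹-metric mean squared error about the GLS mean) to its Brownian
expectation `(tr V − n/(1ᵀV⁻¹1))/(n−1)`.  The permutation test shuffles tip
values and counts permutations whose phylogenetically corrected error is at
most the observed one; since the sum of squared standardized contrasts equals
the GLS residual quadratic form exactly (the contrasts are an orthonormal
transform of the whitened residuals — asserted by a test), this is the same
statistic as the conventional contrast-variance criterion but remains defined
on polytomous trees, including the star tree where K = 1 identically.
The point estimate is verified against R's picante implementation on a
fixture.  `pic` itself rejects polytomies explicitly rather than resolving
them silently.

## Ancestral states and the chronophylomorphospace

Ancestral estimates minimize `Σ_edges (Δx)²/duration` with tips fixed — the
weighted squared-change objective whose minimizer is also the Brownian-motion
ML estimate.  The first-order conditions form a sparse SPD linear system over
internal nodes, solved by sparse LU; an independent check confirms agreement
with direct numerical minimization to 10⁻⁶, and the root estimate equals the
GLS phylogenetic mean algebraically.  Traits are estimated independently per
axis (correlated multi-trait BM is out of scope).  The BM rate σ² is
estimated by REML on contrasts (mean squared standardized contrast; an ML
variant dividing by n is available — figure-level results are insensitive to
the choice, which is why both are exposed and neither asserted).  Per-node
estimation variances are the diagonal of the system inverse scaled by σ̂²;
95% intervals use the normal 1.96 multiplier.  Simulations show root-CI
coverage within 2% of nominal at 50 tips; at much smaller n the normal
multiplier undercovers slightly (a t quantile would widen it), a known
limitation.

The 2-D phylomorphospace places tips at observed scores and internal nodes at
their estimates, with one graph edge per tree edge.  The CPMS adds the node
age as a z coordinate taken directly from the time tree, so dropping z
reproduces the 2-D embedding bit-for-bit and parent age ≥ child age holds on
every edge by construction.  The 1-D variant carries CI bars per internal
node.  Graphs export to JSON, CSV pairs, or static matplotlib figures;
orientation (past at back/bottom) is a rendering option, not data.

## Synthetic study systems

The generator emulates the structure of a clade-wide skull-shape study:
52 species on a 30-Ma pure-birth tree (dendropy's simulator; terminal
branches extended by the waiting time to the next speciation so no zero-length
cherry remains), 35% of tips converted to fossils by truncating their
terminal branch uniformly within (10%, 90%) of its span, with a symmetric
stratigraphic range (default total width 1.5 Myr, shrunk near branch ends)
whose midpoint recovers the true tip age; extant tips get a first occurrence
inside their terminal branch.  Molecular dates (true node ages) are attached
to the root and to 30% of internal nodes — without at least a root date,
tip-driven calibration cannot date the basal splits, which mirrors why
published studies anchor deep nodes on molecular trees.  Traits evolve as
independent Brownian motions (σ² = 0.01 per Myr on the log scale, root state
0) with a Pagel-λ dial that shrinks the off-diagonal of the tip covariance
(λ = 1 pure BM, λ = 0 star-equivalent).  Specimen tables exponentiate
species means plus per-variable baseline offsets (log-uniform on (2, 5), i.e.
measurements spanning roughly 7–150 length units), then apply lognormal
within-species noise (sd 0.05, a typical intraspecific CV for cranial
measurements) and a single lognormal size factor per specimen (log-sd 0.3)
that the Mosimann transform must cancel exactly.  Lineages are true clades:
the tree is cut below its n−1 oldest internal nodes, giving 11 groups.
About 6.4 specimens per species (Poisson, minimum 2) yields ~330–350
specimens.

What passing tests on these data do and do not show: the generator's
between-lineage separation is strong relative to within-species noise, so
classification accuracies near 100% and very large pseudo-F values are
expected and say nothing about real clades, where lineages overlap; the
calibration properties (K ≈ 1 under BM, permutation tests holding their
level, CI coverage) are the transferable results.  The generator makes no
attempt to mimic realistic trait covariance structure, unequal rates, or
selection (no OU), and its fossil ages are unbiased by construction, unlike
real stratigraphic ranges.

## Problem sizes and tolerances

Statistical acceptance checks run at: 200 random 6-tip instances for the
parsimony oracle; 500 Brownian replicates on 50-tip trees for the K/PIC
calibration (199 permutations per null test); 50 random 20-tip instances plus
1000 replicates at 50 tips for the ancestral-state oracle and CI coverage;
500 replicates × 999 permutations for the NPMANOVA level.  Exact identities
(star-tree K, saturation R², Mosimann products, ANOVA equivalence, projection
identity) are asserted at 10⁻⁸–10⁻¹⁰; stochastic calibrations use binomial
95% intervals or the stated relative tolerances.  Permutation defaults are
9999 where a single analysis is run and 199–999 inside replicated
simulations.
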