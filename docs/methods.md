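# Methods

`laternet` implements an imaging-genetics analysis for hemispheric
asymmetry of weighted white-matter structural networks and its relation
to polygenic risk, together with a synthetic-data generator that lets
every stage — and the pipeline end to end — be validated against known
ground truth.

## Network model and metrics

A connectome is an undirected weighted graph on an atlas of regions,
each region annotated with a hemisphere (L/R) and a homologous-pair id
linking left and right counterparts.  Weights are nonnegative
connection strengths (e.g. streamline counts); input matrices that are
asymmetric only by numerical noise (max |A − Aᵀ| ≤ 1e-8) are
symmetrised as (A + Aᵀ)/2, anything worse is rejected, and the diagonal
must be zero.  An optional construction threshold can drop edges below
a minimum weight (default 0: keep everything), since tractography
pipelines differ in how aggressively they prune spurious streamlines.

Edge travel length is 1/w (the standard convention for efficiency
analysis); a zero weight is a non-edge.  On this length structure the
package computes:

* **D_nodal** — number of incident edges (default), or incident weight
  sum in `strength` mode.  Both are offered because field usage varies;
  the mode is recorded in the output.
* **E_nodal(i)** = (1/(N−1)) Σ_{j≠i} 1/d_ij with 1/∞ := 0 —
  unreachable pairs contribute zero rather than being dropped, so
  disconnected graphs are handled without special-casing.
* **E_glob** = mean over nodes of E_nodal (equivalently the mean
  inverse shortest-path length over ordered pairs).
* **E_loc** = (1/N) Σ_i E_glob(G_i), where G_i is the subgraph induced
  on the neighbours of i (i excluded), keeping the original weights; a
  neighbour set with fewer than two nodes contributes 0.

Two independent computational routes exist.  The per-graph route uses
`scipy.sparse.csgraph.shortest_path` (Dijkstra).  The batch route runs
a vectorised Floyd–Warshall over a stack of graphs — for local
efficiency every neighbour subgraph is padded to full size with
unreachable rows so one sweep covers all batch × N subgraphs — and is
what makes 500-replicate simulation studies affordable.  The
test-suite holds the two routes equal to 1e-12 and both equal to
naive triple-loop oracles to 1e-10.

## Asymmetry index

For a metric X computed separately on the hemisphere-extracted L and R
subnetworks (all inter-hemispheric edges discarded),

    AI(X) = 100 · (X(L) − X(R)) / (X(L) + X(R))   [percent]

per homologous pair for the nodal metrics and as a scalar for
E_glob/E_loc.  AI is antisymmetric, scale-invariant and bounded in
[−100, 100], saturating only when one side is exactly zero.  When both
sides are zero the index is undefined and propagated as missing (NaN);
downstream tests drop missing values listwise and log the exclusion.
Nodal AI is computed from the hemisphere-extracted subnetworks (not
whole-brain nodal values): laterality of a hemisphere's internal
organisation is the quantity of interest, and the extraction makes the
left and right values structurally comparable.

## Polygenic scores (clumping + thresholding)

Discovery summary statistics (SNP, CHR, BP, A1, A2, BETA-or-OR, P; OR
is log-transformed on load) are harmonised to the target dosage panel:
strand-ambiguous A/T and C/G records are excluded outright; records
whose alleles match after swapping A1/A2 are realigned by negating the
effect size (equivalent to complementing the dosage, up to an additive
per-participant constant that cancels in correlations and group
contrasts); records absent from the panel or with irreconcilable
alleles are dropped.  All removals are counted and reported.

Clumping is greedy and p-value-informed: the most significant
remaining variant becomes an index and removes every remaining variant
on the same chromosome within ±250 kb whose in-sample dosage r² with
the index is ≥ 0.1.  Ties on p are broken by (CHR, BP, SNP), making
the result independent of input row order.  LD is the squared Pearson
correlation of dosage vectors with pairwise-complete missing handling;
a zero-variance vector yields r² = 0 (logged).

Scores at each threshold t of the twelve-point grid 0.0001, 0.001,
0.01, 0.02, 0.03, 0.04, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5 are
Σ_{p_v ≤ t} dosage·β (sums by default; a `mean` mode divides by the
variant count).  Missing dosages are mean-imputed per variant.  The
retained-variant ledger is emitted per threshold; the sets nest by
construction.

## Association statistics

* **ANCOVA**: OLS of the outcome on group dummies plus covariates
  (age, gender as a single 0/1 column, main effects only); the group
  effect is the partial F between the full and covariates-only models.
  With no covariates this is exactly one-way ANOVA.  An exact-fit
  guard returns F = 0 when the covariates already explain the outcome
  to machine precision, where the F ratio would otherwise be rounding
  noise.  Rank-deficient designs are rejected with the collinear
  columns named.
* **LSD post hoc**: pairwise t-tests on differences of adjusted group
  means using the full-model residual variance and df; deliberately
  unadjusted per Fisher's LSD — family-level control is the Bonferroni
  gate on the omnibus tests.
* **Bonferroni**: min(1, p·m) with an explicit family size m that may
  exceed the number of p-values supplied.  The default family for the
  nodal asymmetry tests is 90 (2 nodal metrics × 45 pairs on the
  90-node atlas); the exact family composition is configurable because
  reasonable reconstructions differ.
* **Partial correlation**: residualise x and y on the covariates plus
  intercept, correlate the residuals, and test with
  t = r·√((n−2−k)/(1−r²)) on n−2−k df (two-tailed).  Reduces exactly
  to Pearson with no covariates.
* **Chi-square**: Pearson test of independence without continuity
  correction; zero marginals rejected.

## Gene-set enrichment

Variants retained in the score at a chosen threshold are mapped to
genes by coordinate containment in a local interval table (1-based
inclusive, optional flank; a variant inside several overlapping genes
maps to all).  Each gene set is tested with the upper-tail
hypergeometric p = P(X ≥ k) for overlap k, query size n, set size K
and universe N; the background universe defaults to every gene in the
annotation table and can be overridden.  Bonferroni runs over the
number of tested terms with the significance gate at adjusted p < 0.01
emitted as a flag, never as a row filter.  The plain hypergeometric
tail is used (not the EASE-style k−1 variant some web tools apply).

## Synthetic-data generator

The generator emulates a three-group case/high-risk/control study:

* **Cohort**: 97 SZ / 79 GHR / 192 HC; ages truncated-normal(30, 8) on
  [18, 54]; gender Bernoulli(0.5); a genotyped subsample of the first
  26 SZ and 48 GHR participants.
* **Connectomes**: a shared mirror-symmetric base graph (identical L/R
  intra-hemisphere blocks, symmetric inter-hemisphere block with
  always-present stronger homotopic edges; edge density 0.4, lognormal
  weights with log-mean 3.0 and log-sd 0.8 giving streamline-count-like
  magnitudes).  Per-participant multiplicative lognormal edge noise
  (log-sd 0.25) breaks mirror symmetry and supplies within-group
  variance.  Group effects are multiplicative: intra-L weights ×
  exp(+a/2) and intra-R × exp(−a/2) (a = 0.07 SZ, 0.06 GHR, 0 HC, plus
  small age/gender terms so covariate adjustment is non-vacuous, plus
  an extra focal shift of 0.12/0.10 on the edges of one designated
  homologous pair), and a uniform whole-brain weight attenuation of
  0.88 in SZ only.  Because hemispheric efficiencies scale exactly with
  uniform intra-hemisphere weight scaling, the noiseless AI equals
  100·tanh(a/2), and uniform attenuation shifts whole-brain efficiency
  proportionally without touching AI (which is scale-invariant) — the
  closed form the generator uses to translate AI-percent effects into
  weight shifts.  Effect sizes were fixed by simulation during
  development to give high (≳0.9) detection power at the study's group
  sizes and are not re-tuned.
* **Genetics**: 1200 variants in 20-variant LD blocks (one-factor
  latent Gaussian per haplotype, within-block latent correlation 0.8,
  thresholded at allele frequencies drawn U(0.05, 0.5)); 10% of
  variants causal with N(0, 0.05) effects; discovery summary
  statistics are the true effects plus estimation noise at a
  discovery sample of 65,967 with Wald p-values; 5% of records are
  strand-ambiguous, 10% allele-swapped and 3% absent from the panel so
  harmonisation is exercised; 1% of dosages are missing.
* **Score–asymmetry coupling**: the generator computes the pipeline's
  own C+T score at the 0.05 threshold, residualises it on age/gender
  and standardises it, and adds λ·s to each genotyped participant's
  asymmetry exponent.  If σ is the residual spread of AI-E_loc around
  the covariate fit, λ = ρ·σ/√(1−ρ²) yields a population partial
  correlation of ρ (default 0.4) between score and AI-E_loc.  σ is
  estimated by simulating score-free copies of the genotyped subsample
  under the same base graph; each replicated study calibrates its own
  λ because σ depends on the realised base anatomy.

What the generator does **not** emulate: realistic tractography
(edge weights are i.i.d.-noise perturbations of a random base graph,
with none of the spatial or distance structure of real connectomes),
human LD maps (blocks are homogeneous and independent), genotyping
batch effects, medication or symptom covariates, and site effects.
Passing recovery tests therefore demonstrates the statistical
machinery is correct and calibrated under the assumed generating
model, not that the effects would be detectable in any given real
sample.

## Problem sizes in the replicated studies

Single runs use the full scale (368 participants, 90-node atlas, 1200
variants).  The replicated recovery study uses the full cohort
structure with a 20-node atlas and a 300-variant panel, which keeps
500 independent studies at interactive speed; edge density is raised
to 0.6 there because a 10-node hemisphere at density 0.4 has a
non-negligible chance of containing no triangle, making E_loc
identically zero and its AI undefined — a degenerate regime the
full-size atlas never enters.  Undefined AI values are dropped
listwise and logged wherever they occur.

## Numerical choices

* Weight→length conversion is fixed at 1/w.
* Unreachable pairs contribute zero efficiency; neighbour subgraphs
  with < 2 nodes contribute zero local efficiency.
* Connectome matrices are written with full `repr` precision and read
  with round-trip float parsing, so load → write → load is
  bit-identical.
* Clumping ties broken lexicographically by (CHR, BP, SNP).
* All randomness flows through `numpy.random.SeedSequence([seed,
  stage])` streams, one per generator stage, so results are
  reproducible and stages are independently perturbable.
* The AI division is grouped as 100·((L−R)/(L+R)) so the saturating
  cases (one side zero) are exact.

## Known limitations

* LD is computed in-sample only; there is no reference-panel option.
* The hypergeometric test ignores gene length and SNP-density
  confounding (as does the plain over-representation model it
  implements).
* The ANCOVA assumes homoscedastic normal errors; no robust or
  permutation variants are provided.
* The 90-test Bonferroni family is a documented reconstruction; users
  whose family differs should set it explicitly.
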