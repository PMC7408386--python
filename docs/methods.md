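# Methods

## Model and rationale

Glycan abundances are treated as approximately log-normal; on the log
scale the samples are modeled as multivariate normal. Under that model the
conditional dependence structure is the support of the precision matrix,
and partial correlations — the standardized negative inverse of the
correlation matrix — vanish exactly for conditionally independent pairs.
Because glycans are synthesized by incremental addition of single
monosaccharides, pairs one enzymatic step apart share substrate/product
flux and are expected to remain partially correlated after conditioning on
all other glycans, while multi-step correlations are explained away. The
overlap between the FDR-selected partial-correlation network and the
composition-level synthesis pathway is therefore a biologically grounded
score for how much real covariance structure a normalization preserved
(and how little artifactual structure it introduced).

## Normalization menu

Seven base methods (raw, per-glycan quantile, per-glycan rank, total area,
median centering, probabilistic quotient, total area followed by
quotient), their natural-log variants (six: centring can produce
non-positive values, so it has no log variant), and per-IgG-subclass
application of the five subclass-eligible methods and their logs on
subclass-resolved data — 13 strategies on ordinary platforms, 23 on
subclass-resolved ones. Composition order is fixed: base method, then log,
the whole chain per block when applied per subclass. The quotient
reference is the per-glycan median of the dataset being normalized and is
recomputed inside every bootstrap replicate, since it is a sample-set
statistic.

Median centering is ambiguous in common usage; the package defaults to
subtracting each *sample's* median (constant per-sample offset
assumption) and also ships the per-glycan mode. Natural log is used
throughout; correlation-based scores are invariant to the base.

## GGM estimation

* **Shrinkage**: R* = λI + (1−λ)R with
  λ = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij², Var̂ computed from the empirical
  variance of the standardized data products (n/(n−1)³ · Σ_k (w_kij − w̄)²).
  λ is clipped to [0,1] and set to 1 when the denominator vanishes. Any
  λ > 0 makes R* positive definite; the inverse is taken via Cholesky.
* **Empirical null**: under the null a partial correlation follows
  f₀(r;κ) = (1−r²)^((κ−3)/2) / B(½, (κ−1)/2), i.e. r² ~ Beta(½, (κ−1)/2).
  κ is fitted by maximum likelihood *truncated at the 75th percentile of
  |r|*: real networks contain a minority of true edges whose large |r|
  would grossly widen a whole-sample fit (a 10% contamination at |r| = 0.5
  biases a naive MLE from κ = 50 to ≈ 21), while the truncated fit stays
  within a few percent. The truncation mass P(|R| ≤ c; κ) enters the
  likelihood, so the estimator remains consistent on pure-null data. An
  all-zero (degenerate) input drives κ to its upper bound (10⁶) and is
  flagged. A Fisher-z alternative (z = atanh(r)·√(κ−3)) is selectable.
* **Selection**: two-sided tail-area p-values, Benjamini–Hochberg step-up
  once per dataset over all C(p,2) pairs, default q = 0.01.

## Overlap score and bootstrap

All unordered glycan pairs are cross-classified by GGM/pathway edge
membership; the score is the one-sided hypergeometric tail
P(X ≥ tp | M, K, n) — one-sided because "lower p = higher overlap" is an
enrichment statement; the two-sided Fisher test is available by flag.
Bootstrap replicates resample samples with replacement and re-run the full
normalize→infer→score chain (a normalize-once mode exists for comparison).
Replicates that fail (a glycan constant after resampling) are skipped with
a warning; more than 5% skips aborts the strategy. Summary: median p and
the 2.5/97.5 percentile interval; strategies are ranked by median p with
alphabetical tie-break.

Seeding: one global seed expands into per-strategy substreams keyed by
`SeedSequence([seed, crc32(label)])`, so editing the strategy list never
changes another strategy's replicates; outputs contain a config hash and
no timestamps, making runs byte-reproducible.

## Reference pathways

Pathways are built at the composition level: nodes carry (hexose, HexNAc,
fucose, NeuAc) counts, and an edge joins two nodes iff the counts differ
by exactly one unit in exactly one class. Subclass-resolved panels get an
independent pathway copy per subclass (cross-subclass edges between
identical compositions are off by default — the platform measures
subclasses as separate peptide backbones — and available by flag). For
mass-only platforms, structures of equal residue-sum mass are merged into
one node (union of incident edges, self-loops dropped), nodes whose mass
matches no measured mass (±0.5 Da, configurable) are removed, and an
optional bridging flag reconnects neighbours of removed nodes
(transitively through runs of removed nodes; off by default, reading
"removed" literally). Constant offsets (reducing-end water, peptide mass)
cancel in mass-equality comparisons and are excluded. A user-supplied
two-column edge list always overrides the rule-based construction.

The bundled 50-glycoform IgG panel (20 IgG1 / 20 IgG2/3 / 10 IgG4) is a
curated synthetic stand-in with the canonical biantennary glycoforms; it
fixes benchmark shapes and is not a transcription of any published panel.

## Synthetic data generator

The generator draws log-scale multivariate normal data whose precision
matrix has support exactly on the pathway edges: unit diagonal, −ρ·s_ij at
edges with random seeded signs, diagonal loading to a minimum eigenvalue
of 0.05 followed by rescaling to unit diagonal (so for sparse pathways the
implied partial correlation at an edge is ≈ ρ). Defaults are the study
conditions used throughout: ρ = 0.3, per-glycan log-sd σ = 0.2 (≈ 20%
biological CV), per-glycan baseline means uniform on log[10², 10⁴], ages
uniform on [18, 88] with optional log-scale slopes. Technical artifacts
are layered on the clean abundances: multiplicative dilution
f_i ~ LogNormal(0, σ_d) (benchmarks use σ_d = 0.5, roughly a four-fold
amount range) and additive offsets o_i ~ Normal(0, σ_o), clipped to keep
values positive (clipping > 1% of cells warns). Closure is deliberately
*not* a generator step — TA is a strategy under test.

What the generator does **not** emulate: peak-picking noise, isotope and
charge-state interference, chromatographic co-elution (UHPLC peaks as
structure mixtures), batch structure, or missingness mechanisms. Passing
benchmarks therefore demonstrate correctness of the statistical machinery
and the expected qualitative ordering under dilution/offset artifacts, not
platform-specific performance on real spectra.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately compact sizes chosen
as sufficient for their statistical purpose: oracle equivalence on 100
random instances (p ≤ 8, tol 1e-8), closure artifact on 500 random
matrices, dilution recovery at n = 200 (Spearman ≥ 0.99), κ recovery on
5000 null draws, benchmark ranking at n = 300 with B = 100 on the
20-glycoform single-subclass panel, FDR control over 500 null datasets
(n = 50, p = 10), and edge recovery at n = 1000. Ties in ranks and
quantile positions use averages; degenerate inputs (constant columns, zero
row sums, non-positive quotient references) raise errors naming the
offending sample/glycan rather than propagating NaNs. Abundance tables are
written with `%.17g` (lossless for float64); ranking tables with 12
significant digits.

## Known limitations

* The exact significance variant of the cited shrinkage-GGM software is
  not fully specified in the literature it accompanies; this package
  implements tail-area empirical-null p-values + BH, with Fisher-z as the
  alternative. Local-fdr style selection is out of scope.
* Batch correction and missing-value imputation are out of scope
  (missing data are handled only by complete-case filtering).
* The composition-level pathway cannot resolve isomers or branch
  positions; UHPLC peaks are approximated by one predominant structure.
* Figure-level p-values from published cohort analyses are not
  reproducible from synthetic data and are not targeted; the benchmark
  reproduces the qualitative ranking (quotient-based strategies beat TA
  under dilution contamination).
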