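# Methods

## The statistical model

### Audic–Claverie test

With one library per condition there is no replication, so differential
expression is judged per gene from two counts alone.  Assume reads for a
gene arrive as Poisson processes with per-read rates proportional to
expression.  Conditioning on the count `x` observed in library 1 (depth
`N₁`) and placing a flat prior on the rate, the posterior predictive
distribution of the count `y` in library 2 (depth `N₂`) is

    p(y|x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) ),

a negative binomial in `y` with `x+1` successes and success probability
`N₁/(N₁+N₂)`.  The two-sided p-value doubles the smaller tail of this
distribution: `2S` where `S = Σ_{i=0..y} p(i|x)` when `S ≤ 0.5`, else
`2(1−S)`.  The boundary `S = 0.5` falls in the `2S` branch, so two zero
counts give exactly p = 1.  The statistic needs integer counts (the
factorials), so the test runs on raw counts; RPKM is used only for the fold
change.  Genes with zero counts in both libraries are excluded from testing
entirely.

Numerics: point probabilities are evaluated as log-gamma expressions; the
lower tail is a log-sum-exp over `i = 0..y`, and when `S > 0.5` the upper
tail `Σ_{i>y} p(i|x)` is summed directly in chunks until a geometric bound
on the remainder drops below 10⁻¹⁷ of the accumulated mass.  Summing the
smaller tail directly (instead of computing `1−S`) preserves relative
precision for p-values down to ~10⁻³⁰⁰, which deeply sequenced genes
actually reach; results are clamped into (0, 1], with 5×10⁻³²⁴ (the
smallest positive double) as the floor for values that underflow even in
log space.  The test suite cross-checks this path against two independent
routes: an arbitrary-precision term-by-term sum (mpmath, 60 digits) and
`scipy.stats.nbinom` via the negative-binomial identity.

### Multiple testing and DEG calling

Benjamini–Hochberg step-up with an explicit total test count `m_total`:
`q_(i) = min_{j≥i} p_(j)·m_total/j`, capped at 1, returned in input order.
`m_total` may exceed the number of p-values supplied — the convention
behind Q-values recomputed from a shortlist of significant pathways out of
a larger tested set (here 242).  Genome-wide, BH runs over all tested genes.
A gene is called up (higher in the pregnant library) when `FDR ≤ 0.001` and
`log₂ ratio ≥ 1`, down symmetrically; both thresholds inclusive.

### RPKM and the zero floor

`RPKM = 10⁹·C/(N·L)`.  The library total `N` defaults to the column sum of
the count table, which equals the uniquely-mapped total whenever the table
covers all genes; `#lib_total_a=`/`#lib_total_b=` metadata lines override
it.  For genes with zero counts in one library the log ratio is undefined;
both RPKM values are floored at the RPKM a single read would yield in the
smaller library for that gene's length (per-gene floor; a scalar override
is available), and the flooring is flagged in the output.  This keeps
one-library genes in the DEG list with large finite ratios rather than
infinities.

### Specific genes

A gene is library-specific when it has at least `min_count` reads (default
1) in one library and zero in the other.  The threshold is a parameter
because "expressed" has no universal minimum count; at the default, any
detected one-library gene counts as specific.

### Hypergeometric enrichment

For a term with `M` annotated genes in a universe of `N`, hit by `m` of
the `n` annotated DEGs, `p = P(X ≥ m)` computed via the survival function
(`scipy.stats.hypergeom.sf`), which sums the smaller tail and therefore
reproduces values like 2×10⁻¹⁵ at full printed precision.  `N` and `n` are
always recomputed from the supplied annotation set; terms with `m = 0` are
not tested and do not inflate the Bonferroni factor, while the BH total for
pathway Q-values counts every pathway hit by at least one DEG, including
unreported ones.  GO categories (BP/CC/MF) are tested jointly by default;
filter the annotation set per category for a per-category mode.  No GO
ancestor propagation is performed — annotations enter as flat gene→term
tables, as the formula assumes.

### 2^−ΔΔCT quantification

Per replicate, ΔCt = Ct(target) − Ct(reference) pairs wells of the same
run, so run-to-run shifts cancel; ΔΔCt is the difference of condition mean
ΔCt (pregnant − nonpregnant), and the relative ratio is 2^−ΔΔCt.
Significance comes from a two-sample t-test on the replicate ΔCt values —
Student's (equal-variance) by default, Welch by flag.  Noise-free panels
with zero variance in both conditions are degenerate for the t statistic;
they return p = 1 when ΔΔCt = 0 and p = 0 otherwise.  No amplification-
efficiency correction is applied (the method assumes doubling per cycle).

## The synthetic-data generator

The generator emulates the pooled two-library design, not read-level
sequencing: no FASTQ, no alignment, no positional bias.  Defaults are the
study-scale conditions — 20,651 genes, library depths 13,549,560
(nonpregnant, A) and 13,676,394 (pregnant, B), 8.3% truly DE genes with
|log₂ FC| ~ |N(2, 0.5)| (60% up in pregnancy), and 7.1% / 9.7% of genes
detected only in A / B.

- **Abundance**: log-normal means (σ_log = 1.5), the usual heavy right tail
  of RNA-seq; read rate is abundance × gene length, normalised per library
  so expected column totals equal the configured depths.  Gene lengths are
  uniform on 200–10,000 bp; RPKM correctness is tested independently of
  this choice.
- **Counts**: gamma-Poisson (negative binomial) with one dispersion knob
  (default 0.05) standing in for the biological variance of pooling three
  animals per library; dispersion 0 gives pure Poisson, the regime the AC
  test models.  Calibration and power checks therefore run at dispersion 0:
  with overdispersed counts the unreplicated exact test is anticonservative
  by construction, a property of the method, not of this implementation.
- **True DE** is split symmetrically (±lfc/2) between the libraries so
  null genes are comparable across conditions.  Specific genes get expected
  expression zero in the other library; if sampling leaves zero reads in
  their own library the count is raised to 1 so the ground-truth label
  always matches the zero pattern in the table.
- **Annotations**: planted terms draw members from true-DE genes with a
  configurable probability (1.0 = purely DE term); the rest draw uniformly.
  Term ids are shuffled so planted terms are not identifiable by name; the
  planted ids are returned alongside the set.
- **qPCR panels**: the pregnant-condition target Ct is shifted by
  −log₂(ratio) around a base of 26 cycles (reference 18), with i.i.d.
  Gaussian noise per well, so the noise-free 2^−ΔΔCt equals the requested
  ratio exactly.

What passing tests on these simulations do *not* show: robustness to
mapping artefacts, positional/GC bias, annotation incompleteness, or
biological replicate variance beyond the single dispersion knob.  The
published headline counts of the motivating study (1,724 DEGs, etc.)
depend on undeposited sequencing data and are deliberately not targets;
the in-paper pathway table, which is fully determined by printed counts,
is reproduced instead.

## Problem sizes and determinism

The test suite and the acceptance script use 10,000-gene nulls at
study-scale depth, ten 5,000-gene planted runs at 10⁷ reads, ten 2,000-gene
enrichment runs and 50–200-seed qPCR Monte-Carlo panels — large enough for
the 3-binomial-SE calibration bands and stable Monte-Carlo means, and small
enough to run in seconds.  All randomness flows from a single
`numpy.random.default_rng` seed per generator call; identical seeds give
bitwise-identical tables, and the pipeline writes byte-identical outputs
under a fixed config.

## Known limitations

- No replicate-aware inference (no NB GLM, no dispersion shrinkage): the
  implemented test is exactly the two-library exact test, which treats all
  variation as sampling noise and overstates significance when biological
  replicates exist.
- The BH total for pathway Q-values (all pathways with ≥ 1 DEG vs only
  tested ones) is a convention; both are reachable via `m_total`.
- Bonferroni for GO is verifiable only property-wise (no numeric GO
  p-values are bundled).
- qPCR validation is property-based: direction and Monte-Carlo recovery,
  not published bar heights.
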