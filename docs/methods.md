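# Methods

## Head-to-head pair detection

A gene model is reduced to (chromosome, strand, representative TSS), with
coordinates 1-based inclusive as in GTF.  The representative TSS is the
5′-most transcript start across the gene's isoforms — the minimum start on
`+`, the maximum end on `−` — the most inclusive deterministic choice for
promoter-proximity questions.  A head-to-head (divergent) pair is a
minus-strand gene and a plus-strand gene on the same chromosome with
`0 ≤ TSS₊ − TSS₋ ≤ d_max` (default 1000 bp).  Pairs whose 5′ ends overlap
(`TSS₊ < TSS₋`) are excluded: from TSS coordinates alone they cannot be
distinguished from small convergent arrangements.  Each gene joins at most
one pair; candidates are accepted greedily by ascending TSS distance with
lexicographic gene-id tie-breaks, which makes the catalog unique,
order-independent and exactly reproducible — the test suite checks it
against an O(n²) brute-force enumeration.  Records with a stated biotype
outside the filter (default `protein_coding`) are dropped; records with no
biotype attribute are kept.

## Dropout model and imputation

Counts are normalized per cell to 10,000 (CP10K) and transformed with
log(1+x).  For each gene, values across cells are modeled as

    λ · Gamma(x; α, β) + (1 − λ) · Normal(x; μ, σ)

The gamma component absorbs dropout-depressed values near zero, the normal
component the expressed mode.  EM initialization splits the gene at its
median: λ₀ is the fraction of entries below it, gamma moments come from
the lower half, normal moments from the upper half.  The M-step uses the
weighted gamma maximum-likelihood update (Minka's closed-form start plus
Newton steps on the shape), a floor of 1e-3 on σ, and a shape cap of 200.
Gamma densities are evaluated at max(x, 1e-6): exact zeros form a point
mass a continuous gamma cannot represent, and under this clamp the fitted
gamma for zero-inflated genes contracts onto the zero spike, sending the
dropout probability of zeros to ≈1 — the intended behavior.  Convergence
is declared when a gene's log-likelihood gain falls below `tol` (1e-6) or
after `max_iter` (100) iterations; non-converged genes keep their last
iterate with a warning.  Two degenerate rules: constant genes are flagged
with dropout probability 0, and fits whose gamma mean α/β is not below μ
are collapsed to λ = 0 (with one positive mode the mixture is
unidentifiable and there is no evidence of dropout).

The dropout probability of an entry is the posterior weight of the gamma
component at its value.  Entries above threshold `t` (default 0.5, the
convention of the mixture-based imputation literature) are replaced by a
similarity-weighted mean of the same gene over the cell's `k` (default 20)
most similar cells.  Cell-cell similarity is the Pearson correlation over
genes confident (probability ≤ t) in both cells, computed exactly for all
cell pairs via masked matrix products; neighbor weights are max(r, 0),
and neighbor entries that are themselves dropouts do not contribute.
Entries with no usable neighbor stay unchanged, confident entries are
never touched (bit-identical before/after), and imputed values are clamped
to 1.5× the gene's largest confident value to prevent outlier blow-up.
This neighbor-averaging step deliberately replaces the per-cluster
non-negative regression of the original scImpute-style method: it is
simpler, deterministic, and sufficient for rank-percentile analyses;
users comparing against the original tool should expect small
entry-level differences.  With the cell counts this package targets
(≤10,000) the computation is exact and seed-independent.

Correlations on the headline path are computed on the count scale: the
imputed log-scale matrix is mapped back through expm1 and the original
per-cell totals.  Log-scale correlation is available via
`correlation.scale: log` in the pipeline config.

## Correlation ranking and companion statistics

Pearson r is computed across all cells for every catalogued pair whose
two genes are present and non-constant; others are flagged
(`missing_gene`, `zero_variance`) and excluded from the distribution.
The rank percentile of a query pair is `100 × #{r ≥ r_query} / n_pairs`,
ties counting toward the numerator — conservative for "top X%" claims.
Signed r is the default ranking scale; ranking by |r| is a flag.

The linear-trend post-test uses equally spaced centered scores
`cᵢ = i − (k+1)/2` over the stated group order, slope `L = Σ cᵢ·x̄ᵢ`,
`SE = sqrt(MSE · Σ cᵢ²/nᵢ)` with the pooled within-group mean square,
`t = L/SE` on `N − k` degrees of freedom, two-sided p — the convention of
GraphPad Prism's post-test, and algebraically identical to the pooled
two-sample t-test at k = 2 (asserted to 1e-10 in the tests).  When every
group is constant and L = 0 the test returns p = 1.

Amplicon clustering computes the gene-gene Pearson matrix across samples
and applies average linkage to `1 − r`; genes are processed in
lexicographic order so leaf order and top-partner tables are independent
of input ordering, with ties resolved by gene id.

Expression ratios are per-sample `a/b`, excluding (and counting) samples
with zero denominator.  Marker normalization is implemented as `(a/b)/n`;
note that dividing both genes by the same marker before taking their
ratio would cancel algebraically, so the normalizer enters once.  The
alternative reading — normalizing each gene separately before averaging
across samples — is not implemented.

## Synthetic data: what it emulates and what it does not

The generator mirrors the scale of the motivating study: ~2,000
head-to-head pairs (≈4,400 genes) across ~1,500 cells per cell line.
Per-gene base means are lognormal(0, 1) counts/cell; per cell, gene g's
latent abundance is `mean_g · exp(σ_lat·z − σ_lat²/2)` with z standard
normal and σ_lat = 1.0, a biological coefficient of variation typical of
dynamically expressed genes and large enough that co-regulation survives
counting noise.  The two members of a planted pair share bivariate-normal
latents with correlation ρ (Gaussian copula), so ρ has a clean meaning
independent of negative-binomial noise; all other genes are independent.
Counts are NB with dispersion φ = 0.3 (var = μ + φμ²).  Technical dropout
then zeroes each entry with gene-level probability
`1/(1 + exp(a·(log mean − b)))`, a = 1.0, b = 1.0: a gentle logistic that
still leaves ~30–40% technical dropout at moderately expressed genes —
the regime the imputation stage exists for — while keeping the rate
monotone decreasing in expression.  Masked entries (nonzero counts zeroed
by dropout) are recorded as ground truth.

Planted pairs stand in for the query pair, which in real data is
detectably expressed; their base means are drawn from
lognormal(1.6, 0.25) (~5 counts/cell) rather than the genome-wide
lottery, so recovery runs exercise the imputation and ranking machinery
rather than the accident of whether the pair was expressed at all.

What the generator does **not** emulate: shared cell states (cell cycle,
size factors) that correlate genes globally, batch effects, doublets,
cell-type mixtures, and UMI saturation.  Two consequences matter for
interpreting green tests.  First, because cells share no global
structure, neighbor-based imputation has less signal to borrow than in
real data — the measured imputation benefit here is conservative.
Second, null pairs are exactly independent, so the null correlation
distribution is narrower than in real data, where co-expression ranks
must compete against pervasive background correlation; the rank
percentile achieved on synthetic data should not be read as a forecast
for any particular real pair.

## Problem sizes and numerics

The validation suite runs the planted-signal recovery at the full desk
scale (2,000 pairs × 1,500 cells × 20 seeds) and the imputation-benefit
and mixture-recovery checks at 400 pairs × 800 cells × 10 seeds and
n = 2,000 × 20 seeds respectively — sizes chosen so the whole suite
completes in minutes on one CPU while keeping Monte-Carlo error well
below the tested margins.  Matrix IO keeps 12 significant digits, enough
for lossless round trips at working precision.  All randomness flows
through `numpy.random.default_rng` seeded from the configuration; EM and
imputation are deterministic given their inputs.

## Known limitations

- The catalog depends on the annotation snapshot and the 5′-most-TSS
  rule; annotations with divergent 5′-overlapping pairs will undercount
  relative to searches that permit overlap.
- Dropout probability is a function of a gene's value distribution only;
  per-gene, all zeros receive the same probability, so biological zeros
  of dropout-prone genes are imputed along with technical ones.
- The back-transform to counts uses observed library sizes, which are
  themselves depressed by dropout; count-scale imputed values are
  therefore slightly conservative.
- The trend test assumes homoscedastic groups (pooled MSE); for strongly
  heteroscedastic data a robust contrast would be preferable.
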