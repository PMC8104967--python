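# bdgcoex

Tools for studying **bidirectional genes (BDG)** — head-to-head gene pairs on
opposite DNA strands whose transcription start sites (TSS) diverge within a
short distance and often share a bidirectional promoter — and for asking
whether a particular pair (for example *FOXM1*/*RHNO1* in ovarian cancer) is
unusually co-expressed at single-cell resolution.

The package is aimed at computational biologists who have a gene annotation
and single-cell (or bulk) expression matrices and want to:

1. **Catalog** every head-to-head pair genome-wide: two genes on the same
   chromosome with `strand(g₁) = −`, `strand(g₂) = +` and
   `0 ≤ TSS(g₂) − TSS(g₁) ≤ d_max` (default `d_max = 1000` bp).
2. **Impute** dropout zeros in single-cell counts.  On the log-CP10K scale
   each gene's values across cells are modeled as a two-component mixture

   `f(x) = λ·Gamma(x; α, β) + (1 − λ)·Normal(x; μ, σ)`

   fitted by EM; the posterior weight of the gamma component at an entry is
   its dropout probability, and entries above a threshold *t* are replaced
   by a similarity-weighted mean of the same gene in the cell's *k* most
   similar cells (Pearson similarity over jointly confident genes).
3. **Correlate and rank**: Pearson's *r* for every catalogued pair across
   cells, and the query pair's **rank percentile from the top**,
   `100 × #{pairs with r ≥ r_query} / n_pairs` — "top 1%" means almost no
   other head-to-head pair is as tightly co-expressed.
4. Companion analyses used alongside the ranking: hierarchical clustering
   of amplicon-gene correlation matrices (average linkage on `1 − r`),
   Spearman correlation, the one-way **ANOVA post-test for linear trend**
   across ordered copy-number classes (equally spaced centered contrast
   scores, pooled within-group variance), and per-sample expression ratios
   optionally normalized to a proliferation marker such as *MKI67*.

A fully seeded synthetic-data generator (`bdgcoex.simulate`) produces toy
annotations and negative-binomial count matrices with planted latent pair
correlations and a recorded dropout mask, so the whole pipeline is testable
with exact ground truth and no downloads.

## Worked example

`examples/03_rank_query_pair.py` simulates 400 head-to-head pairs across
500 cells, plants one pair with latent correlation ρ = 0.9, then imputes,
correlates and ranks:

```
scored 394 pairs; query pair r = 0.456
rank percentile = 0.25% (100 x pairs with r >= query / total; small = near the top)
the planted pair IS in the top 1%
```

The planted pair's observed *r* (0.456) is attenuated from ρ = 0.9 by
counting noise and dropout, yet it still outranks every one of the ~400
null pairs — percentile 0.25% means it is the single most correlated pair.
The other examples cover catalog construction, dropout imputation
(masked-entry RMSE drops from 7.07 to 6.42 against the known truth),
the copy-number trend test, marker-normalized ratios, and amplicon
clustering; each prints a short interpretation of its numbers.

For shell use the same stages are exposed as a thin CLI:

```bash
bdgcoex simulate --seed 1 --out sim/
bdgcoex catalog --annotation sim/toy_annotation.gtf --out catalog.tsv
bdgcoex run --config pipeline.yaml     # catalog -> impute -> correlate -> rank
```

`bdgcoex run` writes every stage output plus a manifest (config snapshot,
input checksums, seed, per-stage dimensions) into the configured output
directory.  Exit codes: 0 ok, 2 config error, 3 data error, 1 internal.

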