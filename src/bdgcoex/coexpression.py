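"""Pairwise co-expression statistics and downstream analyses.

Covers the correlation stages of the bidirectional-gene analysis: Pearson
correlation of every catalogued head-to-head pair across single cells,
rank-percentile scoring of a query pair against the genome-wide
distribution, hierarchical clustering of amplicon-gene correlations,
the ANOVA post-test for linear trend across ordered copy-number classes,
and proliferation-normalized expression ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .annotation import BDGPair
from .exprio import ExpressionMatrix


@dataclass
class PairCorrelation:
    """Pearson correlation of one gene pair across cells.

    ``status`` is ``ok`` (r defined), ``missing_gene`` (a member absent
    from the matrix) or ``zero_variance`` (a member constant across cells).
    """

    minus_gene: str
    plus_gene: str
    r: float | None
    n: int
    status: str = "ok"


@dataclass
class CorrelationDistribution:
    """All scored pair correlations plus an optional query pair's rank.

    ``query_percentile`` is the rank from the top: 100 x (number of pairs
    with r >= the query's, the query included) / number of pairs.
    """

    values: np.ndarray
    n_pairs: int
    query: str | None = None
    query_r: float | None = None
    query_percentile: float | None = None


@dataclass
class TrendTestResult:
    """ANOVA post-test for linear trend across ordered groups."""

    groups: list
    coefficients: np.ndarray
    slope: float
    se: float
    t: float
    df: int
    p: float


@dataclass
class RatioResult:
    """Per-sample expression ratios a/b, optionally normalized by a marker."""

    ratios: pd.Series
    group: pd.Series | None
    normalized: bool
    normalizer: str | None
    n_excluded: int
    summary: pd.DataFrame = field(default=None)


# ---------------------------------------------------------------------------
# pair correlations and rank percentile
# ---------------------------------------------------------------------------

def pair_correlations(
    m: ExpressionMatrix, pairs: list[BDGPair] | pd.DataFrame
) -> list[PairCorrelation]:
    """Pearson correlation across cells for every catalogued pair.

    ``pairs`` is a list of :class:`~bdgcoex.annotation.BDGPair` or a
    catalog frame with ``minus_gene``/``plus_gene`` columns.  Pairs with a
    missing or constant gene are flagged and carry no r.
    """
    if isinstance(pairs, pd.DataFrame):
        ids = list(zip(pairs["minus_gene"], pairs["plus_gene"]))
    else:
        ids = [(p.minus_gene.gene_id, p.plus_gene.gene_id) for p in pairs]
    if not ids:
        raise ValueError("empty pair list")
    if m.n_cells < 3:
        raise ValueError("need at least 3 cells for pair correlations")

    index = {g: i for i, g in enumerate(m.gene_ids)}
    V = m.values
    sd = V.std(axis=1)
    out: list[PairCorrelation] = []
    centered = V - V.mean(axis=1, keepdims=True)
    for a, b in ids:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            out.append(PairCorrelation(a, b, None, 0, "missing_gene"))
            continue
        if sd[ia] == 0.0 or sd[ib] == 0.0:
            out.append(PairCorrelation(a, b, None, m.n_cells, "zero_variance"))
            continue
        r = float(centered[ia] @ centered[ib] / (m.n_cells * sd[ia] * sd[ib]))
        out.append(PairCorrelation(a, b, r, m.n_cells, "ok"))
    return out


def rank_percentile(values: np.ndarray, query_r: float) -> float:
    """Rank from the top as a percentage: 100 x #(values >= query_r) / n.

    Ties count toward the numerator, which is conservative for "top X%"
    statements.  The result lies in (0, 100] whenever the query value is
    itself among ``values``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty correlation distribution")
    return 100.0 * float(np.count_nonzero(values >= query_r)) / values.size


def correlation_distribution(
    correlations: list[PairCorrelation],
    query: tuple[str, str] | None = None,
    absolute: bool = False,
) -> CorrelationDistribution:
    """Collect scored pair correlations and rank an optional query pair.

    With ``absolute=True`` ranking uses |r| instead of signed r.
    """
    ok = [c for c in correlations if c.status == "ok"]
    values = np.array([c.r for c in ok], dtype=np.float64)
    if absolute:
        values = np.abs(values)
    dist = CorrelationDistribution(values=values, n_pairs=values.size)
    if query is not None:
        qa, qb = query
        match = [c for c in correlations if {c.minus_gene, c.plus_gene} == {qa, qb}]
        if not match:
            raise ValueError(f"query pair {qa}/{qb} not found in the catalog correlations")
        if match[0].status != "ok":
            raise ValueError(f"query pair {qa}/{qb} unscored: status={match[0].status}")
        qr = abs(match[0].r) if absolute else match[0].r
        dist.query = f"{qa}/{qb}"
        dist.query_r = qr
        dist.query_percentile = rank_percentile(values, qr)
    return dist


def correlation_frame(correlations: list[PairCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "minus_gene": [c.minus_gene for c in correlations],
            "plus_gene": [c.plus_gene for c in correlations],
            "r": [c.r if c.r is not None else np.nan for c in correlations],
            "n": [c.n for c in correlations],
            "status": [c.status for c in correlations],
        }
    )


# ---------------------------------------------------------------------------
# other statistics
# ---------------------------------------------------------------------------

def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def coexpression_dendrogram(
    m: ExpressionMatrix, gene_list: list[str]
) -> tuple[pd.DataFrame, np.ndarray, list[str], pd.DataFrame]:
    """Hierarchical clustering of gene-gene expression correlations.

    Computes the pairwise Pearson matrix of the listed genes across
    samples, clusters with average linkage on distance 1 - r, and reports
    each gene's top partner (the gene with which it is most correlated).
    Genes are processed in lexicographic order so the output does not
    depend on the input ordering (ties resolve by gene id).

    Returns ``(correlation matrix, linkage, leaf order, top-partner table)``.
    """
    missing = [g for g in gene_list if g not in m.gene_ids]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    genes = sorted(set(gene_list))
    if len(genes) < 3:
        raise ValueError("need at least 3 distinct genes")
    sub = np.vstack([m.gene_vector(g) for g in genes])
    if np.any(sub.std(axis=1) == 0):
        flat = [g for g, s in zip(genes, sub.std(axis=1)) if s == 0]
        raise ValueError(f"constant gene(s) cannot be correlated: {flat}")
    corr = np.corrcoef(sub)
    corr_df = pd.DataFrame(corr, index=genes, columns=genes)

    dist = 1.0 - corr
    condensed = dist[np.triu_indices(len(genes), k=1)]
    condensed = np.maximum(condensed, 0.0)  # guard tiny negative round-off
    Z = sch.average(condensed)
    leaf_order = [genes[i] for i in sch.leaves_list(Z)]

    np.fill_diagonal(corr, -np.inf)
    top_idx = np.argmax(corr, axis=1)  # first (lexicographically smallest) on ties
    top = pd.DataFrame(
        {
            "gene": genes,
            "top_partner": [genes[i] for i in top_idx],
            "r": corr[np.arange(len(genes)), top_idx],
        }
    )
    np.fill_diagonal(corr, 1.0)
    return corr_df, Z, leaf_order, top


def linear_trend_test(values, group, group_order: list | None = None) -> TrendTestResult:
    """One-way ANOVA post-test for linear trend across ordered groups.

    Contrast coefficients are equally spaced centered scores
    ``c_i = i - (k + 1)/2`` for group index ``i = 1..k`` in the stated
    order (the convention of GraphPad Prism's post-test).  The slope
    ``L = sum c_i * mean_i`` is tested with the pooled within-group mean
    square: ``SE = sqrt(MSE * sum c_i^2 / n_i)``, ``t = L / SE`` on
    ``N - k`` degrees of freedom, two-sided p.  At k = 2 this reduces to
    the pooled two-sample t-test.
    """
    values = np.asarray(values, dtype=np.float64)
    group = np.asarray(group)
    if values.shape != group.shape:
        raise ValueError("values and group must align")
    if group_order is None:
        group_order = sorted(pd.unique(group).tolist())
    k = len(group_order)
    if k < 2:
        raise ValueError("need at least 2 groups for a trend test")

    means = np.empty(k)
    ns = np.empty(k)
    ss_within = 0.0
    for i, g in enumerate(group_order):
        v = values[group == g]
        if v.size == 0:
            raise ValueError(f"group {g!r} has no samples")
        means[i] = v.mean()
        ns[i] = v.size
        ss_within += ((v - v.mean()) ** 2).sum()
    N = int(ns.sum())
    df = N - k
    if df <= 0:
        raise ValueError("need total N > number of groups")

    c = np.arange(1, k + 1) - (k + 1) / 2.0
    L = float(c @ means)
    mse = ss_within / df
    se = float(np.sqrt(mse * np.sum(c**2 / ns)))
    if se == 0.0:
        t = 0.0 if L == 0.0 else np.inf * np.sign(L)
        p = 1.0 if L == 0.0 else 0.0
    else:
        t = L / se
        p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return TrendTestResult(
        groups=list(group_order), coefficients=c, slope=L, se=se, t=float(t), df=df, p=float(p)
    )


def expression_ratio(
    m: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    normalizer: str | None = None,
    group=None,
) -> RatioResult:
    """Per-sample expression ratio gene_a/gene_b, optionally divided by a
    proliferation marker (e.g. MKI67) to factor out proliferation rate.

    Samples where the denominator (or the normalizer) is zero are excluded
    and counted.  Per-group medians and IQRs are reported when group
    labels are given.
    """
    a = m.gene_vector(gene_a)
    b = m.gene_vector(gene_b)
    keep = b > 0
    ratio = np.full(m.n_cells, np.nan)
    ratio[keep] = a[keep] / b[keep]
    if normalizer is not None:
        nvec = m.gene_vector(normalizer)
        keep = keep & (nvec > 0)
        ratio[:] = np.nan
        ratio[keep] = (a[keep] / b[keep]) / nvec[keep]
    n_excluded = int((~keep).sum())

    ratios = pd.Series(ratio, index=m.cell_ids, name=f"{gene_a}/{gene_b}")[keep]
    gseries = None
    summary = None
    if group is not None:
        gseries = pd.Series(np.asarray(group), index=m.cell_ids)[keep]
        grouped = ratios.groupby(gseries)
        summary = pd.DataFrame(
            {
                "n": grouped.size(),
                "median": grouped.median(),
                "iqr": grouped.quantile(0.75) - grouped.quantile(0.25),
            }
        )
    return RatioResult(
        ratios=ratios,
        group=gseries,
        normalized=normalizer is not None,
        normalizer=normalizer,
        n_excluded=n_excluded,
        summary=summary,
    )
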