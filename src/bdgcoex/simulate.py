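"""Synthetic annotations and single-cell count matrices with known truth.

The generator emulates the scale of the study this pipeline targets: on
the order of 2,000 head-to-head gene pairs assayed across ~1,500 cells per
cell line.  Counts are negative-binomial with lognormal gene means;
gene-pair co-expression is planted through a Gaussian copula on per-cell
latent abundances, so a pair's latent correlation rho has a clean meaning
independent of counting noise; technical dropout zeroes entries with a
mean-dependent logistic probability and is recorded in a mask, giving
every downstream stage (catalog detection, imputation, correlation
ranking) an exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the target study's scale.

    ``planted_pairs`` lists ``(pair_index, rho)`` with |rho| < 1: the
    latent correlation imposed on that head-to-head pair (all other pairs
    are independent, rho = 0).  ``dropout_a``/``dropout_b`` set the
    logistic dropout curve ``p = 1 / (1 + exp(a * (log mean - b)))`` — a
    is the steepness, b the log-mean at which half the entries drop out.
    """

    n_genes: int = 4400
    n_cells: int = 1500
    n_bdg_pairs: int = 2000
    planted_pairs: list[tuple[int, float]] = field(default_factory=list)
    mean_log: float = 0.0        # lognormal meanlog of per-gene base means (counts)
    sd_log: float = 1.0          # lognormal sdlog of per-gene base means
    planted_meanlog: float = 1.6  # planted pairs emulate a moderately expressed query pair
    planted_sdlog: float = 0.25
    dispersion: float = 0.3      # NB dispersion phi: var = mu + phi mu^2
    latent_sd: float = 1.0       # per-cell lognormal variability around the gene mean
    dropout_a: float = 1.0
    dropout_b: float = 1.0       # 50% technical dropout at ~2.7 counts/cell
    chrom_length: int = 100_000_000
    tss_dist_meanlog: float = math.log(150.0)  # pair TSS distances, truncated at 1 kb
    tss_dist_sdlog: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.n_bdg_pairs > self.n_genes:
            raise ValueError("need n_genes >= 2 * n_bdg_pairs")
        for idx, rho in self.planted_pairs:
            if not 0 <= idx < self.n_bdg_pairs:
                raise ValueError(f"planted pair index {idx} out of range")
            if not abs(rho) < 1:
                raise ValueError(f"|rho| must be < 1, got {rho}")
        if self.dispersion <= 0 or self.latent_sd < 0 or self.dropout_a <= 0:
            raise ValueError("invalid distribution parameters")
        if self.sd_log < 0:
            raise ValueError("sd_log must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_counts: np.ndarray          # pre-dropout counts
    dropout_mask: np.ndarray         # True where dropout zeroed a nonzero count
    pair_rho: np.ndarray             # latent rho per head-to-head pair
    pair_genes: list[tuple[str, str]]
    gene_means: np.ndarray
    dispersion: float


def _gene_ids(cfg: SimulationConfig) -> tuple[list[str], list[tuple[str, str]]]:
    ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    for i in range(cfg.n_bdg_pairs):
        mg, pg = f"BDG{i:04d}M", f"BDG{i:04d}P"
        ids += [mg, pg]
        pairs.append((mg, pg))
    for i in range(cfg.n_genes - 2 * cfg.n_bdg_pairs):
        ids.append(f"SGL{i:04d}")
    return ids, pairs


def make_toy_annotation(cfg: SimulationConfig) -> tuple[str, pd.DataFrame]:
    """Build a toy GTF with the configured head-to-head pairs planted.

    Pairs sit on one toy chromosome with TSS distances drawn from a
    lognormal truncated at 1,000 bp; the remaining genes are isolated
    (>10 kb from anything) so no spurious pair can arise.  Returns the GTF
    text and the planted catalog (minus_gene, plus_gene, tss_distance),
    which a detection round-trip must reproduce exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    ids, pair_ids = _gene_ids(cfg)
    gene_len = 2000
    unit_gap = 20_000

    lines: list[str] = []
    rows = []

    def emit(gid: str, start: int, end: int, strand: str) -> None:
        attrs = f'gene_id "{gid}"; gene_name "{gid}"; gene_biotype "protein_coding";'
        for feature in ("gene", "transcript"):
            lines.append(
                f"toychr1\ttoysim\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
            )

    pos = 50_000
    for i, (mg, pg) in enumerate(pair_ids):
        d = int(np.clip(np.round(rng.lognormal(cfg.tss_dist_meanlog, cfg.tss_dist_sdlog)), 1, 1000))
        # minus gene: TSS at `pos` (its span end); plus gene TSS at pos + d
        emit(mg, pos - gene_len + 1, pos, "-")
        emit(pg, pos + d, pos + d + gene_len - 1, "+")
        rows.append({"minus_gene": mg, "plus_gene": pg, "minus_tss": pos,
                     "plus_tss": pos + d, "tss_distance": d})
        pos += d + gene_len + unit_gap
    for j, gid in enumerate(ids[2 * cfg.n_bdg_pairs:]):
        strand = "+" if j % 2 == 0 else "-"
        start, end = pos, pos + gene_len - 1
        emit(gid, start, end, strand)
        pos += gene_len + unit_gap
    if pos > cfg.chrom_length:
        raise ValueError(
            f"genes need {pos} bp but chrom_length is {cfg.chrom_length}; "
            "reduce n_genes or enlarge the chromosome"
        )
    return "\n".join(lines) + "\n", pd.DataFrame(rows)


def simulate_counts(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a genes x cells count matrix with planted pair correlations.

    Per cell, each gene's latent abundance is its lognormal base mean
    modulated by a standard-normal latent z through
    ``mu = mean * exp(latent_sd * z - latent_sd^2 / 2)``; the two members
    of a planted pair share bivariate-normal latents with correlation rho,
    everything else is independent.  Counts are NB(mu, dispersion); a
    dropout event then zeroes each entry with the gene's mean-dependent
    logistic probability.  The mask records only zeros the dropout step
    introduced (entries that were already zero are not masked).
    Fully reproducible from (cfg, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    ids, pair_ids = _gene_ids(cfg)
    G, C = cfg.n_genes, cfg.n_cells

    means = rng.lognormal(cfg.mean_log, cfg.sd_log, size=G)
    # Planted pairs stand in for the query pair, which is detectably
    # expressed; their base means come from a narrower lognormal at a
    # stated moderate level instead of the genome-wide lottery.
    for idx, _ in cfg.planted_pairs:
        means[2 * idx] = rng.lognormal(cfg.planted_meanlog, cfg.planted_sdlog)
        means[2 * idx + 1] = rng.lognormal(cfg.planted_meanlog, cfg.planted_sdlog)

    Z = rng.standard_normal((G, C))
    rho = np.zeros(cfg.n_bdg_pairs)
    for idx, r in cfg.planted_pairs:
        rho[idx] = r
    for i in np.flatnonzero(rho != 0.0):
        r = rho[i]
        gm, gp = 2 * i, 2 * i + 1
        Z[gp] = r * Z[gm] + math.sqrt(1.0 - r * r) * Z[gp]

    mu = means[:, None] * np.exp(cfg.latent_sd * Z - 0.5 * cfg.latent_sd**2)
    size = 1.0 / cfg.dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p).astype(np.float64)

    p_drop = 1.0 / (1.0 + np.exp(cfg.dropout_a * (np.log(means) - cfg.dropout_b)))
    drop_event = rng.random((G, C)) < p_drop[:, None]
    mask = drop_event & (counts > 0)
    observed = np.where(drop_event, 0.0, counts)

    cells = [f"cell{j:05d}" for j in range(C)]
    m = ExpressionMatrix(values=observed, gene_ids=ids, cell_ids=cells, layer_tag="counts")
    truth = GroundTruth(
        true_counts=counts,
        dropout_mask=mask,
        pair_rho=rho,
        pair_genes=pair_ids,
        gene_means=means,
        dispersion=cfg.dispersion,
    )
    return m, truth


def dropout_probability(cfg: SimulationConfig, gene_means: np.ndarray) -> np.ndarray:
    """The generator's logistic dropout curve, exposed for diagnostics."""
    return 1.0 / (1.0 + np.exp(cfg.dropout_a * (np.log(gene_means) - cfg.dropout_b)))
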