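"""Gene annotation parsing and bidirectional (head-to-head) gene-pair detection.

Bidirectional genes (BDG) are pairs of genes on opposite DNA strands whose
transcription start sites (TSS) diverge and lie close together, typically
sharing a bidirectional promoter in the short intergenic span between the
two 5' ends.  This module builds a genome-wide catalog of such pairs from a
GTF annotation (or a plain gene table) using a TSS-distance threshold,
1000 bp by default.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: biotypes retained by default when reading an annotation
DEFAULT_BIOTYPES = frozenset({"protein_coding"})

#: maximum TSS-to-TSS distance for a head-to-head pair, in bp
DEFAULT_MAX_DISTANCE = 1000


@dataclass(frozen=True)
class GeneModel:
    """One gene with a representative TSS.

    Coordinates are 1-based inclusive (GTF convention).  The representative
    TSS is the 5'-most start across the gene's transcripts: the minimum
    start for ``+`` genes and the maximum end for ``-`` genes.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    span_start: int
    span_end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.span_start > self.span_end:
            raise ValueError(
                f"{self.gene_id}: span_start {self.span_start} > span_end {self.span_end}"
            )
        expected = self.span_start if self.strand == "+" else self.span_end
        if self.tss != expected:
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} inconsistent with strand/span"
            )


@dataclass(frozen=True)
class BDGPair:
    """An ordered head-to-head gene pair: minus-strand TSS at or left of the
    plus-strand TSS, both on the same chromosome."""

    minus_gene: GeneModel
    plus_gene: GeneModel
    tss_distance: int
    orientation: str = field(default="divergent")

    def __post_init__(self) -> None:
        if self.minus_gene.strand != "-" or self.plus_gene.strand != "+":
            raise ValueError("pair must be (minus-strand gene, plus-strand gene)")
        if self.minus_gene.chrom != self.plus_gene.chrom:
            raise ValueError("pair genes must share a chromosome")
        if self.tss_distance != self.plus_gene.tss - self.minus_gene.tss:
            raise ValueError("tss_distance inconsistent with gene TSSs")
        if self.tss_distance < 0:
            raise ValueError("head-to-head pair requires tss(minus) <= tss(plus)")


def intergenic_span(pair: BDGPair) -> int:
    """Distance in bp between the two 5' ends (the putative bidirectional
    promoter span).  For FOXM1/RHNO1 this is roughly 150 bp."""
    return pair.tss_distance


# ---------------------------------------------------------------------------
# annotation reading
# ---------------------------------------------------------------------------

_GENE_TABLE_COLUMNS = ("gene_id", "symbol", "chrom", "strand", "txStart", "txEnd", "biotype")


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            data = data.decode()
        return io.StringIO(data)
    path = str(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for chunk in attr.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


_NORMALIZE_STRAND = {"+": "+", "-": "-", "−": "-"}  # accept unicode minus


def read_gene_models(
    source,
    biotype_filter: Iterable[str] | None = DEFAULT_BIOTYPES,
    fmt: str | None = None,
) -> list[GeneModel]:
    """Read gene models from a GTF stream/path or a tab-delimited gene table.

    Parameters
    ----------
    source
        Path (``.gz`` allowed) or open text/binary stream.
    biotype_filter
        Biotypes to retain; ``None`` keeps everything.  Records without a
        stated biotype are kept.
    fmt
        ``"gtf"``, ``"gene_table"`` or ``None`` to sniff from the first
        data line.

    Returns one :class:`GeneModel` per gene id.  The representative TSS is
    the 5'-most transcript start for the gene's strand, and the span covers
    all of its transcripts.  Records with a strand other than ``+``/``-``
    are skipped with a warning; malformed lines raise ``ValueError`` naming
    the line number.
    """
    fh = _open_text(source)
    lines = fh.read().splitlines()
    data_lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not data_lines:
        return []

    if fmt is None:
        first = data_lines[0][1].split("\t")
        fmt = "gtf" if len(first) >= 9 else "gene_table"

    if fmt == "gene_table":
        return _read_gene_table(data_lines, biotype_filter)
    if fmt != "gtf":
        raise ValueError(f"unknown annotation format {fmt!r}")

    # per gene: chrom, strand, min start, max end, symbol, biotype
    acc: dict[str, dict] = {}
    for lineno, line in data_lines:
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
        chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
        if feature not in ("gene", "transcript"):
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from None
        strand = _NORMALIZE_STRAND.get(strand)
        if strand is None:
            logger.warning("line %d: strand %r not in {+,-}; record skipped", lineno, fields[6])
            continue
        a = _parse_gtf_attributes(attrs)
        gid = a.get("gene_id")
        if not gid:
            raise ValueError(f"malformed GTF line {lineno}: missing gene_id attribute")
        rec = acc.get(gid)
        if rec is None:
            acc[gid] = {
                "chrom": chrom,
                "strand": strand,
                "start": start,
                "end": end,
                "symbol": a.get("gene_name", gid),
                "biotype": a.get("gene_biotype", a.get("gene_type")),
                # gene-feature lines alone define a span too; transcript
                # lines refine it
            }
        else:
            if rec["chrom"] != chrom or rec["strand"] != strand:
                logger.warning("line %d: gene %s spans chrom/strand conflict; keeping first", lineno, gid)
                continue
            rec["start"] = min(rec["start"], start)
            rec["end"] = max(rec["end"], end)
            if rec["biotype"] is None:
                rec["biotype"] = a.get("gene_biotype", a.get("gene_type"))

    allowed = None if biotype_filter is None else set(biotype_filter)
    genes = []
    for gid, rec in acc.items():
        biotype = rec["biotype"]
        if allowed is not None and biotype is not None and biotype not in allowed:
            continue
        tss = rec["start"] if rec["strand"] == "+" else rec["end"]
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=rec["symbol"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                tss=tss,
                span_start=rec["start"],
                span_end=rec["end"],
                biotype=biotype if biotype is not None else "unknown",
            )
        )
    return genes


def _read_gene_table(data_lines, biotype_filter) -> list[GeneModel]:
    header = data_lines[0][1].split("\t")
    has_header = header[0] == "gene_id"
    rows = data_lines[1:] if has_header else data_lines
    cols = header if has_header else list(_GENE_TABLE_COLUMNS[: len(data_lines[0][1].split("\t"))])
    idx = {c: i for i, c in enumerate(cols)}
    for required in ("gene_id", "chrom", "strand", "txStart", "txEnd"):
        if required not in idx:
            raise ValueError(f"gene table missing column {required!r}")

    allowed = None if biotype_filter is None else set(biotype_filter)
    acc: dict[str, dict] = {}
    for lineno, line in rows:
        f = line.split("\t")
        if len(f) < len(idx):
            raise ValueError(f"malformed gene-table line {lineno}: expected {len(idx)} fields")
        strand = _NORMALIZE_STRAND.get(f[idx["strand"]])
        if strand is None:
            logger.warning("line %d: strand %r not in {+,-}; record skipped", lineno, f[idx["strand"]])
            continue
        try:
            start, end = int(f[idx["txStart"]]), int(f[idx["txEnd"]])
        except ValueError:
            raise ValueError(f"malformed gene-table line {lineno}: non-integer coordinates") from None
        gid = f[idx["gene_id"]]
        rec = acc.get(gid)
        if rec is None:
            acc[gid] = {
                "chrom": f[idx["chrom"]],
                "strand": strand,
                "start": start,
                "end": end,
                "symbol": f[idx["symbol"]] if "symbol" in idx else gid,
                "biotype": f[idx["biotype"]] if "biotype" in idx else None,
            }
        else:
            rec["start"] = min(rec["start"], start)
            rec["end"] = max(rec["end"], end)

    genes = []
    for gid, rec in acc.items():
        if allowed is not None and rec["biotype"] is not None and rec["biotype"] not in allowed:
            continue
        tss = rec["start"] if rec["strand"] == "+" else rec["end"]
        genes.append(
            GeneModel(gid, rec["symbol"], rec["chrom"], rec["strand"], tss,
                      rec["start"], rec["end"], rec["biotype"] or "unknown")
        )
    return genes


# ---------------------------------------------------------------------------
# pair detection
# ---------------------------------------------------------------------------

def detect_bdg_pairs(
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[BDGPair]:
    """Detect head-to-head bidirectional gene pairs.

    A candidate pair is a minus-strand gene and a plus-strand gene on the
    same chromosome with ``0 <= tss(plus) - tss(minus) <= max_distance``
    (strict divergent arrangement: transcription proceeds away from the
    shared intergenic span on both strands).  Each gene joins at most one
    pair: candidates are accepted greedily by ascending TSS distance, ties
    broken by lexicographic (minus, plus) gene ids, so the catalog is unique
    and reproducible.  Output is sorted by chromosome then minus-gene TSS.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    candidates: list[tuple[int, str, str, GeneModel, GeneModel]] = []
    by_chrom_plus: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.strand == "+":
            by_chrom_plus.setdefault(g.chrom, []).append(g)
    for plist in by_chrom_plus.values():
        plist.sort(key=lambda g: g.tss)

    import bisect

    for g in genes:
        if g.strand != "-":
            continue
        plist = by_chrom_plus.get(g.chrom, [])
        keys = [p.tss for p in plist]
        lo = bisect.bisect_left(keys, g.tss)
        hi = bisect.bisect_right(keys, g.tss + max_distance)
        for p in plist[lo:hi]:
            candidates.append((p.tss - g.tss, g.gene_id, p.gene_id, g, p))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used: set[str] = set()
    pairs: list[BDGPair] = []
    for dist, mid, pid, mg, pg in candidates:
        if mid in used or pid in used:
            continue
        used.add(mid)
        used.add(pid)
        pairs.append(BDGPair(minus_gene=mg, plus_gene=pg, tss_distance=dist))
    pairs.sort(key=lambda p: (p.minus_gene.chrom, p.minus_gene.tss, p.minus_gene.gene_id))
    return pairs


def catalog_frame(pairs: Sequence[BDGPair]) -> pd.DataFrame:
    """BDG catalog as a DataFrame (the TSV export layout)."""
    return pd.DataFrame(
        {
            "minus_gene": [p.minus_gene.gene_id for p in pairs],
            "plus_gene": [p.plus_gene.gene_id for p in pairs],
            "chrom": [p.minus_gene.chrom for p in pairs],
            "minus_tss": [p.minus_gene.tss for p in pairs],
            "plus_tss": [p.plus_gene.tss for p in pairs],
            "tss_distance": [p.tss_distance for p in pairs],
        }
    )


def write_catalog(pairs: Sequence[BDGPair], path) -> None:
    catalog_frame(pairs).to_csv(path, sep="\t", index=False)
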