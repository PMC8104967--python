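"""End-to-end pipeline: catalog -> ingest -> impute -> correlate -> rank.

Driven by a YAML/dict config; writes every stage output plus a run
manifest (tool version, config snapshot, input checksums, seed, per-stage
dimensions, timestamps) so any figure-adjacent output can be regenerated
from the manifest and inputs alone.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os

import numpy as np
import yaml

from . import __version__
from .annotation import detect_bdg_pairs, read_gene_models, write_catalog
from .coexpression import (
    correlation_distribution,
    correlation_frame,
    pair_correlations,
)
from .exprio import (
    filter_matrix,
    inverse_cp10k_log,
    normalize_cp10k_log,
    read_matrix,
    write_matrix,
)
from .impute import fit_dropout_model, impute_matrix

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input data violates a pipeline precondition (CLI exit code 3)."""


_REQUIRED = ("annotation", "matrix", "query", "outdir")

_DEFAULTS = {
    "max_distance": 1000,
    "matrix_format": None,
    "seed": 0,
    "filter": {"min_cells_per_gene": 3, "min_genes_per_cell": 1},
    "impute": {"enabled": True, "threshold": 0.5, "k_neighbors": 20,
               "max_iter": 100, "tol": 1e-6},
    "correlation": {"scale": "counts", "absolute": False},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _merge_defaults(cfg: dict) -> dict:
    missing = [k for k in _REQUIRED if k not in cfg]
    if missing:
        raise ConfigError(f"config missing required field(s): {missing}")
    out = dict(cfg)
    for key, val in _DEFAULTS.items():
        if isinstance(val, dict):
            block = dict(val)
            block.update(cfg.get(key) or {})
            out[key] = block
        else:
            out.setdefault(key, val)
    query = out["query"]
    if isinstance(query, str):
        query = [q.strip() for q in query.split(",")]
    if not (isinstance(query, (list, tuple)) and len(query) == 2):
        raise ConfigError("query must name exactly two genes, e.g. 'FOXM1,RHNO1'")
    out["query"] = list(query)
    if out["correlation"]["scale"] not in ("counts", "log"):
        raise ConfigError("correlation.scale must be 'counts' or 'log'")
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    if os.path.isdir(path):
        for name in sorted(os.listdir(path)):
            with open(os.path.join(path, name), "rb") as fh:
                h.update(fh.read())
    else:
        with open(path, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_pipeline(config: dict | str) -> dict:
    """Execute all stages; returns the manifest dict.

    Stage outputs land in ``outdir``: the BDG catalog TSV, the imputed
    matrix, the pair-correlation TSV, a correlation histogram (TSV + PNG)
    and the query pair's rank-percentile report JSON.  A partial failure
    leaves completed-stage outputs plus a ``failure.json`` record.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merge_defaults(config)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)

    manifest = {
        "tool": "bdgcoex",
        "version": __version__,
        "config": cfg,
        "seed": cfg["seed"],
        "inputs": {},
        "stages": {},
        "started": _now(),
    }
    try:
        for key in ("annotation", "matrix"):
            if not os.path.exists(str(cfg[key])):
                raise DataError(f"{key} path not found: {cfg[key]}")
            manifest["inputs"][key] = {"path": str(cfg[key]), "sha256": _sha256(str(cfg[key]))}

        # --- catalog -------------------------------------------------------
        genes = read_gene_models(cfg["annotation"])
        pairs = detect_bdg_pairs(genes, max_distance=cfg["max_distance"])
        write_catalog(pairs, os.path.join(outdir, "bdg_catalog.tsv"))
        manifest["stages"]["catalog"] = {
            "n_genes": len(genes), "n_pairs": len(pairs), "at": _now(),
        }
        qa, qb = cfg["query"]
        in_catalog = any(
            {p.minus_gene.gene_id, p.plus_gene.gene_id} == {qa, qb} for p in pairs
        )
        if not in_catalog:
            raise DataError(f"query pair {qa}/{qb} is not in the detected BDG catalog")

        # --- ingest --------------------------------------------------------
        counts = read_matrix(cfg["matrix"], fmt=cfg["matrix_format"])
        counts = filter_matrix(counts, **cfg["filter"])
        manifest["stages"]["ingest"] = {
            "n_genes": counts.n_genes, "n_cells": counts.n_cells, "at": _now(),
        }

        # --- impute --------------------------------------------------------
        working = normalize_cp10k_log(counts)
        if cfg["impute"]["enabled"]:
            model = fit_dropout_model(
                working, max_iter=cfg["impute"]["max_iter"],
                tol=cfg["impute"]["tol"], seed=cfg["seed"],
            )
            model.to_frame().to_csv(
                os.path.join(outdir, "dropout_model.tsv"), sep="\t", index=False
            )
            imputed = impute_matrix(
                working, model, threshold=cfg["impute"]["threshold"],
                k_neighbors=cfg["impute"]["k_neighbors"],
            )
        else:
            imputed = working
        if cfg["correlation"]["scale"] == "counts":
            final = inverse_cp10k_log(imputed, counts.values.sum(axis=0))
        else:
            final = imputed
        write_matrix(final, os.path.join(outdir, "imputed_matrix.tsv"))
        manifest["stages"]["impute"] = {
            "enabled": bool(cfg["impute"]["enabled"]),
            "scale": cfg["correlation"]["scale"], "at": _now(),
        }

        # --- correlate -----------------------------------------------------
        correlations = pair_correlations(final, pairs)
        correlation_frame(correlations).to_csv(
            os.path.join(outdir, "pair_correlations.tsv"), sep="\t", index=False
        )
        dist = correlation_distribution(
            correlations, query=(qa, qb), absolute=cfg["correlation"]["absolute"]
        )
        _write_histogram(dist.values, outdir)
        manifest["stages"]["correlate"] = {
            "n_scored": int(dist.n_pairs),
            "n_flagged": len(correlations) - int(dist.n_pairs),
            "at": _now(),
        }

        # --- rank ----------------------------------------------------------
        report = {
            "query": dist.query,
            "r": dist.query_r,
            "rank_percentile": dist.query_percentile,
            "n_pairs": int(dist.n_pairs),
        }
        with open(os.path.join(outdir, "percentile_report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        manifest["stages"]["rank"] = {"percentile": dist.query_percentile, "at": _now()}
    except Exception as exc:
        manifest["failed"] = {"error": str(exc), "type": type(exc).__name__, "at": _now()}
        with open(os.path.join(outdir, "failure.json"), "w") as fh:
            json.dump(manifest["failed"], fh, indent=2)
        _write_manifest(manifest, outdir)
        raise
    manifest["finished"] = _now()
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _write_histogram(values: np.ndarray, outdir: str, bins: int = 40) -> None:
    counts, edges = np.histogram(values, bins=bins, range=(-1.0, 1.0))
    import pandas as pd

    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}).to_csv(
        os.path.join(outdir, "correlation_histogram.tsv"), sep="\t", index=False
    )
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="#4878a8")
        ax.set_xlabel("Pearson's coefficient")
        ax.set_ylabel("frequency of pairs")
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "correlation_histogram.png"), dpi=120)
        plt.close(fig)
    except Exception:  # plotting is best-effort; the TSV is authoritative
        logger.warning("could not render histogram PNG", exc_info=True)
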