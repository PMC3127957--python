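"""Per-cluster overrepresentation of transcription-factor motif targets.

A gene is a *target* of a matrix iff at least one binding-site hit falls
in its promoter region, regardless of how many.  For each matrix the
number of targets in a cluster is tested against the number of targets in
the whole promoter universe (one-sided Fisher's exact test, BH-adjusted
across matrices within the cluster), and matrices significant in exactly
one cluster are reported as exclusively overrepresented there.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .pwm import MotifHit, PwmModel

__all__ = [
    "count_targets",
    "motif_enrichment",
    "enrich_all_clusters",
    "exclusive_overrepresentation",
    "export_pfm_text",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


def count_targets(hits: Iterable[MotifHit] | pd.DataFrame,
                  known_genes: Iterable | None = None) -> dict[str, set]:
    """Collapse hits to matrix -> set of target genes (>= 1 hit counts once).

    Hits for genes outside ``known_genes`` (when given) are skipped with a
    warning — they cannot enter any 2x2 table.
    """
    if isinstance(hits, pd.DataFrame):
        pairs = hits[["matrix_id", "seq_id"]].itertuples(index=False)
    else:
        pairs = ((h.matrix_id, h.seq_id) for h in hits)
    known = set(known_genes) if known_genes is not None else None
    targets: dict[str, set] = {}
    skipped = 0
    for matrix_id, gene in pairs:
        if known is not None and gene not in known:
            skipped += 1
            continue
        targets.setdefault(matrix_id, set()).add(gene)
    if skipped:
        logger.warning("count_targets: skipped %d hits on unknown genes", skipped)
    return targets


def motif_enrichment(targets: Mapping[str, set], cluster_genes: Iterable,
                     background_genes: Iterable, set_id: str = "cluster",
                     matrices: Iterable[str] | None = None) -> pd.DataFrame:
    """One-sided (greater) Fisher test of target overrepresentation.

    The 2x2 table per matrix is (cluster targets, cluster non-targets)
    vs (rest-of-background targets, rest non-targets); BH adjustment runs
    across all tested matrices of the cluster.  Matrices without any
    target gene are skipped.
    """
    cluster = set(cluster_genes)
    bg = set(background_genes)
    if not cluster <= bg:
        raise ValueError("cluster genes must be contained in the background")
    matrix_ids = sorted(matrices) if matrices is not None else sorted(targets)
    rows = []
    for mid in matrix_ids:
        tg = targets.get(mid, set()) & bg
        if not tg:
            continue
        k = len(tg & cluster)
        K = len(tg)
        n_set, n_bg = len(cluster), len(bg)
        table = [[k, n_set - k], [K - k, (n_bg - n_set) - (K - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append((set_id, mid, k, n_set, K, n_bg, odds, p))
    result = pd.DataFrame(rows, columns=[
        "set_id", "feature_id", "in_set_annotated", "in_set_total",
        "background_annotated", "background_total", "odds_ratio", "pvalue"])
    result["adj_pvalue"] = bh_adjust(result["pvalue"].to_numpy()) if len(result) else []
    return result.sort_values("adj_pvalue", kind="stable").reset_index(drop=True)


def enrich_all_clusters(targets: Mapping[str, set],
                        clusters: Mapping[str, Iterable],
                        background_genes: Iterable,
                        matrices: Iterable[str] | None = None) -> dict[str, pd.DataFrame]:
    """Run :func:`motif_enrichment` for every cluster on a shared universe."""
    return {cid: motif_enrichment(targets, genes, background_genes, set_id=str(cid),
                                  matrices=matrices)
            for cid, genes in clusters.items()}


def exclusive_overrepresentation(results: Mapping[str, pd.DataFrame],
                                 alpha: float = ALPHA) -> pd.DataFrame:
    """Matrices significant (adjusted p < alpha) in exactly one cluster.

    A matrix overrepresented in two clusters, or in none, is excluded.
    Returns columns ``feature_id, cluster, adj_pvalue``.
    """
    sig: dict[str, list[tuple[str, float]]] = {}
    for cid, df in results.items():
        for row in df.itertuples(index=False):
            if row.adj_pvalue < alpha:
                sig.setdefault(row.feature_id, []).append((str(cid), row.adj_pvalue))
    rows = [(mid, hits[0][0], hits[0][1])
            for mid, hits in sorted(sig.items()) if len(hits) == 1]
    return pd.DataFrame(rows, columns=["feature_id", "cluster", "adj_pvalue"])


def export_pfm_text(models: Iterable[PwmModel], path) -> None:
    """Plain-text frequency-matrix export (sequence-logo ready, JASPAR-like)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.matrix_id} {m.name}".rstrip() + "\n")
            for b, row in zip("ACGT", m.counts):
                fh.write(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")
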