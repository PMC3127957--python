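"""Overrepresentation analysis: Fisher's exact test with BH adjustment.

Used for GO-term enrichment per expression cluster (two-sided by default)
and reused by the motif-enrichment stage (one-sided).  The 2x2 table for a
feature is::

                    annotated   not annotated
    in set              k          n_set - k
    background (rest)   K - k      (N - n_set) - (K - k)

where the background contains the gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "fisher_ora", "bh_adjust", "annotation_to_term_sets"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One feature's 2x2 test within one gene set."""

    set_id: str
    feature_id: str
    in_set_annotated: int
    in_set_total: int
    background_annotated: int
    background_total: int
    odds_ratio: float
    pvalue: float
    adj_pvalue: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotation_to_term_sets(annotation: pd.DataFrame,
                            gene_col: str = "gene",
                            term_col: str = "term") -> dict[str, set]:
    """Collapse a two-column (gene, term) table into term -> gene set."""
    return {t: set(g) for t, g in annotation.groupby(term_col)[gene_col]}


def fisher_ora(gene_set: Iterable, background: Iterable,
               annotation: pd.DataFrame | Mapping[str, set],
               set_id: str = "set",
               alternative: str = "two-sided") -> pd.DataFrame:
    """Per-term Fisher's exact overrepresentation test with BH adjustment.

    Only terms annotating at least one gene of the set are tested (a term
    with no in-set gene cannot be overrepresented and would only dilute
    the FDR correction).  Results are sorted by adjusted p.

    Parameters
    ----------
    gene_set, background
        The cluster genes and the annotated universe; the set must be
        contained in the background.
    annotation
        Either a (gene, term) DataFrame or a term -> gene-set mapping.
    alternative
        'two-sided' (default) or 'greater' for a pure enrichment test.
    """
    genes = set(gene_set)
    bg = set(background)
    if not genes <= bg:
        missing = sorted(genes - bg)[:5]
        raise ValueError(f"gene set not contained in background (e.g. {missing})")
    if isinstance(annotation, pd.DataFrame):
        term_sets = annotation_to_term_sets(annotation)
    else:
        term_sets = {t: set(g) for t, g in annotation.items()}

    n_set, n_bg = len(genes), len(bg)
    rows = []
    for term, annotated in sorted(term_sets.items()):
        annotated = annotated & bg
        k = len(annotated & genes)
        if k == 0 or not annotated:
            continue
        K = len(annotated)
        table = [[k, n_set - k], [K - k, (n_bg - n_set) - (K - k)]]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append((set_id, term, k, n_set, K, n_bg, odds, p))
    result = pd.DataFrame(rows, columns=[
        "set_id", "feature_id", "in_set_annotated", "in_set_total",
        "background_annotated", "background_total", "odds_ratio", "pvalue"])
    result["adj_pvalue"] = bh_adjust(result["pvalue"].to_numpy()) if len(result) else []
    return result.sort_values("adj_pvalue", kind="stable").reset_index(drop=True)
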