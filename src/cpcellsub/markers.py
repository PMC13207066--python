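"""Derivation of subpopulation-specific gene sets from labelled single cells.

The workflow is the standard one-vs-rest marker screen: log-normalize
counts, test each gene with a two-sided Wilcoxon rank-sum test of the
target subpopulation against all other cells, adjust with
Benjamini-Hochberg, and keep genes passing adjusted p < 0.05 and
log2 fold-change > 1 (both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import CellAnnotation, ExpressionMatrix, GeneSetCollection, Layer
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["MarkerTable", "log_normalize", "rank_markers", "derive_gene_sets"]

_EPS = 1e-9  # pseudocount for fold-change on the expm1 scale


@dataclass
class MarkerTable:
    """One-vs-rest differential expression results for one subpopulation."""

    subpopulation: str
    table: pd.DataFrame  # index = gene; columns log2fc, p_value, adj_p, pct_in, pct_out


def log_normalize(
    counts: ExpressionMatrix, scale_factor: float = 10_000.0
) -> ExpressionMatrix:
    """Depth-normalize and log-transform counts.

    value(g, u) = ln(1 + counts(g, u) * scale_factor / total(u)), the
    standard library-size normalization. Units with zero total count are an
    error (they should be filtered upstream by QC).
    """
    if counts.layer != Layer.counts:
        raise ValueError("log_normalize expects a counts-layer matrix")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"units with zero total count: {list(zero.index)}")
    norm = np.log1p(counts.values / totals * scale_factor)
    return ExpressionMatrix(norm, layer=Layer.lognorm)


def _vectorized_ranksum(
    in_mat: np.ndarray, out_mat: np.ndarray
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (rows), normal approximation
    with tie correction, vectorized across genes."""
    n1 = in_mat.shape[1]
    n2 = out_mat.shape[1]
    pooled = np.concatenate([in_mat, out_mat], axis=1)
    ranks = scipy.stats.rankdata(pooled, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per gene
    sorted_rows = np.sort(pooled, axis=1)
    # count run lengths of equal values
    tie_sum = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(sorted_rows[i], return_counts=True)
        tie_sum[i] = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu) / sigma
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p[~np.isfinite(z)] = 1.0  # constant gene across all cells
    return np.minimum(p, 1.0)


def rank_markers(
    lognorm: ExpressionMatrix,
    annotation: CellAnnotation,
    target: str,
    *,
    min_cells: int = 10,
    min_pct: float = 0.01,
) -> MarkerTable:
    """One-vs-rest marker test for one subpopulation.

    Per gene: two-sided Wilcoxon rank-sum p of target cells vs all other
    cells on log-normalized values; log2fc on the expm1 (depth-normalized)
    scale with a 1e-9 pseudocount; BH adjustment across tested genes. Genes
    detected in fewer than ``min_pct`` of cells of both groups are skipped
    (reported with NaN p-values).
    """
    if lognorm.layer != Layer.lognorm:
        raise ValueError("rank_markers expects a lognorm-layer matrix")
    if target not in set(annotation.table["subpopulation"]):
        raise ValueError(f"subpopulation {target!r} not present in annotation")
    in_cells = [c for c in annotation.cells_of(target) if c in set(lognorm.unit_ids)]
    all_cells = [c for c in lognorm.unit_ids if c in set(annotation.unit_ids)]
    out_cells = [c for c in all_cells if c not in set(in_cells)]
    if len(in_cells) < min_cells:
        raise ValueError(
            f"subpopulation {target!r} has {len(in_cells)} cells; "
            f"need at least {min_cells}"
        )
    if not out_cells:
        raise ValueError("no background cells outside the target subpopulation")

    in_mat = lognorm.values[in_cells].to_numpy()
    out_mat = lognorm.values[out_cells].to_numpy()

    pct_in = (in_mat > 0).mean(axis=1)
    pct_out = (out_mat > 0).mean(axis=1)
    tested = (pct_in >= min_pct) | (pct_out >= min_pct)
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("skipping %d gene(s) detected in < %g%% of cells of both groups",
                    n_skipped, 100 * min_pct)

    mean_in = np.expm1(in_mat).mean(axis=1)
    mean_out = np.expm1(out_mat).mean(axis=1)
    log2fc = np.log2((mean_in + _EPS) / (mean_out + _EPS))

    p = np.full(lognorm.shape[0], np.nan)
    if tested.any():
        p[tested] = _vectorized_ranksum(in_mat[tested], out_mat[tested])
    adj = np.full_like(p, np.nan)
    if tested.any():
        adj[tested] = bh_adjust(p[tested])

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
            "pct_in": pct_in,
            "pct_out": pct_out,
        },
        index=lognorm.gene_ids,
    )
    return MarkerTable(subpopulation=target, table=table)


def derive_gene_sets(
    tables: list[MarkerTable],
    adj_p_max: float = 0.05,
    log2fc_min: float = 1.0,
) -> GeneSetCollection:
    """Threshold marker tables into subpopulation-specific gene sets.

    A gene enters its subpopulation's set iff adj_p < ``adj_p_max`` and
    log2fc > ``log2fc_min`` (strict inequalities). Subpopulations with no
    passing gene are excluded with a warning.
    """
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    for mt in tables:
        t = mt.table
        mask = (t["adj_p"] < adj_p_max) & (t["log2fc"] > log2fc_min)
        genes = list(t.index[mask.fillna(False)])
        if not genes:
            logger.warning(
                "subpopulation %r yields no markers at adj_p<%g, log2fc>%g; excluded",
                mt.subpopulation, adj_p_max, log2fc_min,
            )
            continue
        sets[mt.subpopulation] = genes
        provenance[mt.subpopulation] = (
            f"one-vs-rest markers, adj_p<{adj_p_max}, log2fc>{log2fc_min}"
        )
    return GeneSetCollection(sets, provenance)
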