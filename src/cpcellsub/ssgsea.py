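"""Single-sample gene-set enrichment (ssGSEA) scoring.

Projects subpopulation-specific gene sets onto bulk samples (or spatial
spots) as per-sample abundance scores. The statistic is the rank-weighted
cumulative-difference enrichment score of Barbie et al.'s single-sample
variant: within each sample, genes are ranked by expression, and the score
is the summed gap between the weighted in-set rank ECDF and the uniform
out-of-set ECDF, with exponent ``alpha`` (default 0.25) on the rank
weights. Scoring is purely rank-based, so any strictly increasing
transform of one sample's expression leaves its scores unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["ScoreMatrix", "ssgsea_score"]


class ScoreMatrix:
    """Gene-set x unit enrichment scores."""

    def __init__(self, scores: pd.DataFrame, normalized: bool = False) -> None:
        if not np.all(np.isfinite(scores.to_numpy())):
            raise ValueError("non-finite enrichment score")
        self.scores = scores
        self.normalized = normalized

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.scores.columns)

    def row(self, set_name: str) -> pd.Series:
        return self.scores.loc[set_name]

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="gene_set")


def _enrichment_scores_one_unit(
    expr: np.ndarray,
    set_masks: np.ndarray,
    set_sizes: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """ES for every set in one unit.

    ``set_masks`` is sets x genes boolean. Genes are walked in descending
    expression order; ties receive average bottom-ranks in the weight.
    """
    n_genes = expr.shape[0]
    order = np.argsort(-expr, kind="stable")
    # average rank-from-bottom (ties averaged), then raised to alpha
    rank_from_bottom = scipy.stats.rankdata(expr)
    weights = np.abs(rank_from_bottom) ** alpha

    w_ordered = weights[order]                      # genes in walk order
    masks_ordered = set_masks[:, order]             # sets x genes, walk order

    in_w = np.where(masks_ordered, w_ordered[None, :], 0.0)
    denom_in = in_w.sum(axis=1, keepdims=True)      # sum of in-set weights
    p_in = np.cumsum(in_w, axis=1) / denom_in

    out_step = 1.0 / (n_genes - set_sizes)[:, None]
    p_out = np.cumsum(np.where(masks_ordered, 0.0, out_step), axis=1)

    return (p_in - p_out).sum(axis=1)


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
    *,
    min_overlap: int = 5,
) -> ScoreMatrix:
    """Score every gene set in every unit of ``expr``.

    Set genes absent from ``expr`` are ignored (intersection); sets sharing
    fewer than ``min_overlap`` genes with the matrix are dropped with a
    warning. If ``normalize``, all scores are divided by (max - min) over
    the whole matrix — the convention of the reference implementation.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    n_genes = len(gene_index)

    kept_names: list[str] = []
    masks: list[np.ndarray] = []
    for name in sets.names:
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        if len(idx) < min_overlap:
            logger.warning(
                "gene set %r overlaps %d gene(s) with the matrix "
                "(min_overlap=%d); dropped", name, len(idx), min_overlap,
            )
            continue
        if len(idx) >= n_genes:
            logger.warning("gene set %r covers every gene in the matrix; dropped", name)
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        kept_names.append(name)
        masks.append(mask)
    if not kept_names:
        raise ValueError("no gene set passes the overlap filter")

    set_masks = np.vstack(masks)
    set_sizes = set_masks.sum(axis=1)

    mat = expr.values.to_numpy()
    out = np.empty((len(kept_names), mat.shape[1]))
    for j in range(mat.shape[1]):
        out[:, j] = _enrichment_scores_one_unit(mat[:, j], set_masks, set_sizes, alpha)

    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    scores = pd.DataFrame(out, index=kept_names, columns=expr.unit_ids)
    return ScoreMatrix(scores, normalized=normalize)
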