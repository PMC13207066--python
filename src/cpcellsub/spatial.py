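"""Spatial co-localization of cell-subpopulation signatures.

Each tissue section's spots are scored per subpopulation signature (mean
z-score of set genes by default, or ssGSEA), pairs of signatures are
classified per section by Spearman correlation across spots — positive
co-localization when r > 0.2 with p < 0.05, negative when r < -0.2 with
p < 0.05, otherwise non-significant — and classifications are summarized
as proportions across sections. Differential expression inside
co-localization regions (spots where both signatures exceed their
per-section upper quantile) identifies recurrent region genes across
sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import GeneSetCollection, SpatialSection
from .markers import log_normalize
from .ssgsea import ScoreMatrix, ssgsea_score
from .stats import bh_adjust, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "SectionColocResult",
    "score_spots",
    "correlate_pair",
    "summarize_sections",
    "coloc_region_de",
    "recurrent_genes",
]


@dataclass
class SectionColocResult:
    """Pairwise co-localization call for one tissue section."""

    section_id: str
    pair: tuple[str, str]
    spearman_r: float
    p: float
    classification: str  # positive | negative | ns
    n_spots: int
    degenerate: bool = False


def score_spots(
    section: SpatialSection,
    sets: GeneSetCollection,
    method: str = "mean_z",
    *,
    ssgsea_alpha: float = 0.25,
    min_overlap: int = 1,
) -> ScoreMatrix:
    """Per-spot signature scores for every gene set.

    ``mean_z``: log-normalize the spot counts, z-score each gene across
    spots (zero-variance genes contribute 0), and average over set genes.
    ``ssgsea`` delegates to the enrichment module per spot. Sets with no
    genes in the section are dropped with a warning.
    """
    lognorm = log_normalize(section.spots)
    if method == "ssgsea":
        return ssgsea_score(
            lognorm, sets, alpha=ssgsea_alpha, normalize=True,
            min_overlap=min_overlap,
        )
    if method != "mean_z":
        raise ValueError(f"unknown scoring method {method!r}")

    mat = lognorm.values
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    # genes with (numerically) zero variance contribute 0, not amplified
    # float residue
    sd = sd.where(sd > 1e-12 * (1.0 + mu.abs()), np.nan)
    z = mat.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)

    rows = {}
    for name in sets.names:
        genes = [g for g in sets[name] if g in z.index]
        if len(genes) < min_overlap:
            logger.warning("set %r shares no genes with section %s; dropped",
                           name, section.section_id)
            continue
        rows[name] = z.loc[genes].mean(axis=0)
    if not rows:
        raise ValueError("no gene set overlaps the section's genes")
    return ScoreMatrix(pd.DataFrame(rows).T, normalized=False)


def correlate_pair(
    scores: ScoreMatrix,
    pair: tuple[str, str],
    *,
    section_id: str = "",
    r_threshold: float = 0.2,
    alpha: float = 0.05,
    min_spots: int = 10,
) -> SectionColocResult:
    """Classify a signature pair's co-localization in one section.

    Spearman correlation of the two score vectors over spots; positive iff
    r > ``r_threshold`` and p < ``alpha`` (strict), negative for the
    mirrored rule, ns otherwise. Constant score vectors yield ns with a
    degenerate flag.
    """
    a, b = pair
    x = scores.row(a).to_numpy(dtype=float)
    y = scores.row(b).to_numpy(dtype=float)
    n = len(x)
    if n < min_spots:
        raise ValueError(f"only {n} spots; need at least {min_spots}")
    r, p = spearman(x, y)
    if not np.isfinite(r):
        return SectionColocResult(section_id, pair, float("nan"), float("nan"),
                                  "ns", n, degenerate=True)
    if r > r_threshold and p < alpha:
        cls = "positive"
    elif r < -r_threshold and p < alpha:
        cls = "negative"
    else:
        cls = "ns"
    return SectionColocResult(section_id, pair, r, p, cls, n)


def summarize_sections(results: list[SectionColocResult]) -> pd.DataFrame:
    """Per-pair proportions of positive/negative/ns calls across sections."""
    if not results:
        raise ValueError("no section results to summarize")
    rows = []
    by_pair: dict[tuple[str, str], list[SectionColocResult]] = {}
    for res in results:
        by_pair.setdefault(res.pair, []).append(res)
    for pair, group in sorted(by_pair.items()):
        n = len(group)
        counts = {
            cls: sum(1 for g in group if g.classification == cls)
            for cls in ("positive", "negative", "ns")
        }
        rows.append(
            {
                "set_a": pair[0],
                "set_b": pair[1],
                "n_sections": n,
                **{f"n_{c}": v for c, v in counts.items()},
                **{f"prop_{c}": v / n for c, v in counts.items()},
            }
        )
    return pd.DataFrame(rows)


def coloc_region_de(
    section: SpatialSection,
    scores: ScoreMatrix,
    pair: tuple[str, str],
    *,
    high_quantile: float = 0.75,
    min_region_spots: int = 10,
) -> pd.DataFrame | None:
    """Differential expression of the pair's co-localization region vs rest.

    The region is the set of spots where BOTH signatures exceed their
    per-section ``high_quantile``; sections whose region holds fewer than
    ``min_region_spots`` spots are skipped (returns None). Per gene: two-
    sided Wilcoxon rank-sum of region vs rest on log-normalized values,
    log2 fold-change on the expm1 scale, BH adjustment.
    """
    a, b = pair
    sa = scores.row(a)
    sb = scores.row(b)
    region_mask = (sa > sa.quantile(high_quantile)) & (sb > sb.quantile(high_quantile))
    region = list(sa.index[region_mask])
    rest = list(sa.index[~region_mask])
    if len(region) < min_region_spots:
        logger.warning("section %s: co-localization region has %d spot(s); skipped",
                       section.section_id, len(region))
        return None

    from .markers import _vectorized_ranksum

    lognorm = log_normalize(section.spots)
    in_mat = lognorm.values[region].to_numpy()
    out_mat = lognorm.values[rest].to_numpy()
    p = _vectorized_ranksum(in_mat, out_mat)
    eps = 1e-9
    log2fc = np.log2(
        (np.expm1(in_mat).mean(axis=1) + eps) / (np.expm1(out_mat).mean(axis=1) + eps)
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "adj_p": bh_adjust(p)},
        index=lognorm.gene_ids,
    )


def recurrent_genes(
    tables: list[pd.DataFrame],
    min_sections: int = 2,
    *,
    alpha: float = 0.05,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Rank genes recurrently up-regulated in co-localization regions.

    A gene counts as significant in a section when adj_p < ``alpha`` and
    log2fc > 0. Genes significant in >= ``min_sections`` sections are
    ranked by (sections significant desc, mean log2fc desc, gene id); the
    top ``top_fraction`` of ranked genes is flagged in the ``selected``
    column.
    """
    tables = [t for t in tables if t is not None]
    if not tables:
        raise ValueError("no differential-expression tables supplied")
    genes = tables[0].index
    n_sig = pd.Series(0, index=genes)
    fc_sum = pd.Series(0.0, index=genes)
    for t in tables:
        sig = (t["adj_p"] < alpha) & (t["log2fc"] > 0)
        n_sig = n_sig.add(sig.astype(int), fill_value=0)
        fc_sum = fc_sum.add(t["log2fc"], fill_value=0.0)
    mean_fc = fc_sum / len(tables)

    keep = n_sig[n_sig >= min_sections].index
    df = pd.DataFrame(
        {"n_sections_significant": n_sig.loc[keep], "mean_log2fc": mean_fc.loc[keep]}
    )
    order = np.lexsort(
        (
            df.index.to_numpy(),
            -df["mean_log2fc"].to_numpy(),
            -df["n_sections_significant"].to_numpy(),
        )
    )
    df = df.iloc[order]
    n_top = int(np.ceil(top_fraction * len(genes)))
    df["selected"] = False
    df.iloc[: min(n_top, len(df)), df.columns.get_loc("selected")] = True
    return df
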