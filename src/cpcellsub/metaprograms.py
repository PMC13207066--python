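"""Intratumoral NMF expression programs and cross-sample meta-modules.

Per sample, the log-normalized HVG x cell matrix is factorized with
non-negative matrix factorization at every rank K in a range (default
2-10); each factor contributes one "program", summarized by its top-50
loading genes. Programs recurring across samples are then consolidated
into meta-modules by an iterative founder rule on pairwise signature
overlap, and each module is summarized by its most recurrent genes.

Everything here is deterministic: NMF uses non-negative double-SVD
initialization, and every ranking tie is broken lexicographically by gene
or program identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .data_model import CellAnnotation, ExpressionMatrix, Layer
from .stats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "Program",
    "ProgramSet",
    "Module",
    "ModuleSet",
    "select_hvgs",
    "extract_programs",
    "consolidate_modules",
    "associate_modules",
]


@dataclass
class Program:
    """One NMF factor: its sample, rank, factor index and top-gene signature."""

    sample_id: str
    k_value: int
    factor_index: int
    signature: list[str]

    @property
    def program_id(self) -> str:
        return f"{self.sample_id}|K{self.k_value}|f{self.factor_index}"


@dataclass
class ProgramSet:
    programs: list[Program] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.programs)

    def by_id(self) -> dict[str, Program]:
        return {p.program_id: p for p in self.programs}


@dataclass
class Module:
    module_id: str
    member_programs: list[str]
    gene_recurrence: dict[str, int]
    top_genes: list[str]


@dataclass
class ModuleSet:
    modules: list[Module] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modules)


def select_hvgs(
    lognorm: ExpressionMatrix, n_hvg: int = 2000, n_bins: int = 20
) -> list[str]:
    """Highly variable genes by binned dispersion ranking.

    Dispersion = variance / mean of the log-normalized values, standardized
    (z-scored) within ``n_bins`` mean-expression bins so that selection is
    not driven by expression level. Ties break lexicographically.
    """
    mat = lognorm.values
    mean = mat.mean(axis=1)
    var = mat.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = var / mean
    disp = disp.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    expressed = mean > 0
    df = pd.DataFrame({"mean": mean, "disp": disp})[expressed]
    if df.empty:
        return []
    try:
        df["bin"] = pd.qcut(df["mean"], min(n_bins, len(df)), duplicates="drop")
    except ValueError:
        df["bin"] = 0
    z = df.groupby("bin", observed=True)["disp"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1) if s.std(ddof=1) > 0 else s * 0.0
    )
    df["z"] = z.fillna(0.0)
    ranked = df.sort_values(["z"], ascending=False, kind="stable")
    # stable sort on z then lexicographic among exact ties
    ranked = ranked.iloc[
        np.lexsort((ranked.index.to_numpy(), -ranked["z"].to_numpy()))
    ]
    return list(ranked.index[:n_hvg])


def _top_genes(loadings: pd.Series, top_n: int) -> list[str]:
    order = np.lexsort((loadings.index.to_numpy(), -loadings.to_numpy()))
    return list(loadings.index[order][:top_n])


def extract_programs(
    lognorm: ExpressionMatrix,
    sample_id: str,
    k_range: range | list[int] = range(2, 11),
    top_n: int = 50,
    n_hvg: int = 2000,
    seed: int = 0,
    *,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> ProgramSet:
    """Factorize one sample's cells at every K; one program per factor.

    The HVG x cell matrix of log-normalized values is centered per gene
    with negative residuals clipped to zero before factorization — the
    convention of intratumoral meta-program studies — so factors load on
    genes expressed *above* their sample average rather than on
    ubiquitously high genes. K values at or above min(n_hvg_used, n_cells)
    are skipped with a warning. Deterministic under a fixed seed (NNDSVD
    initialization; the seed only affects the zero-fill variant).
    """
    if lognorm.layer != Layer.lognorm:
        raise ValueError("extract_programs expects a lognorm-layer matrix")
    hvgs = select_hvgs(lognorm, n_hvg=n_hvg)
    sub = lognorm.values.loc[hvgs]
    # center per gene, clip negatives: non-negative "above-average" signal
    sub = sub.sub(sub.mean(axis=1), axis=0).clip(lower=0.0)
    # drop all-zero rows: NMF cannot place loading mass on them
    sub = sub[sub.sum(axis=1) > 0]
    mat = sub.to_numpy()

    programs: list[Program] = []
    for k in k_range:
        if k >= min(mat.shape):
            logger.warning("sample %s: K=%d >= min(dims)=%d; skipped",
                           sample_id, k, min(mat.shape))
            continue
        model = NMF(
            n_components=k,
            init="nndsvda",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        w = model.fit_transform(mat)  # genes x k loadings
        for fi in range(k):
            loadings = pd.Series(w[:, fi], index=sub.index)
            sig = _top_genes(loadings, top_n)
            programs.append(Program(sample_id, k, fi, sig))
    return ProgramSet(programs)


def _overlap(a: Program, b: Program) -> int:
    return len(set(a.signature) & set(b.signature))


def consolidate_modules(
    programs: ProgramSet,
    min_overlap_genes: int = 10,
    min_cluster_size: int = 3,
    top_genes_out: int = 10,
) -> ModuleSet:
    """Cluster recurrent programs across samples into meta-modules.

    1. *Robust* programs share >= ``min_overlap_genes`` signature genes with
       at least one program from a different sample.
    2. Iteratively, the unassigned program with the most "considerable
       overlaps" (pairs above threshold) founds a module; all unassigned
       programs overlapping the founder above threshold join it. Stops when
       no candidate module reaches ``min_cluster_size`` members.
    3. Module genes are ranked by the number of member programs containing
       them (ties lexicographic); the top ``top_genes_out`` are reported.

    The founder rule plus lexicographic tie-breaks make the output
    invariant to the order programs are supplied in.
    """
    samples = {p.sample_id for p in programs.programs}
    if len(programs) < 2 or len(samples) < 2:
        raise ValueError("need >= 2 programs from >= 2 samples")

    # deterministic processing order regardless of input order
    progs = sorted(programs.programs, key=lambda p: p.program_id)

    robust = [
        p for p in progs
        if any(
            q.sample_id != p.sample_id and _overlap(p, q) >= min_overlap_genes
            for q in progs
        )
    ]
    if not robust:
        logger.warning("no robust programs at min_overlap_genes=%d", min_overlap_genes)
        return ModuleSet([])

    unassigned = {p.program_id: p for p in robust}
    modules: list[Module] = []
    while True:
        # count considerable overlaps among unassigned programs
        counts = {
            pid: sum(
                1 for q in unassigned.values()
                if q.program_id != pid and _overlap(p, q) >= min_overlap_genes
            )
            for pid, p in unassigned.items()
        }
        if not counts:
            break
        founder_id = min(counts, key=lambda pid: (-counts[pid], pid))
        founder = unassigned[founder_id]
        members = [founder] + [
            q for qid, q in sorted(unassigned.items())
            if qid != founder_id and _overlap(founder, q) >= min_overlap_genes
        ]
        if len(members) < min_cluster_size:
            break
        recurrence: dict[str, int] = {}
        for m in members:
            for g in m.signature:
                recurrence[g] = recurrence.get(g, 0) + 1
        ranked = sorted(recurrence, key=lambda g: (-recurrence[g], g))
        modules.append(
            Module(
                module_id=f"module_{len(modules) + 1}",
                member_programs=[m.program_id for m in members],
                gene_recurrence=recurrence,
                top_genes=ranked[:top_genes_out],
            )
        )
        for m in members:
            del unassigned[m.program_id]
    return ModuleSet(modules)


def associate_modules(
    lognorm: ExpressionMatrix,
    annotation: CellAnnotation,
    modules: ModuleSet,
    *,
    seed: int = 0,
    n_bins: int = 20,
    n_background: int = 50,
) -> pd.DataFrame:
    """Score modules per cell and associate them with subpopulations.

    Per-cell module score = mean log-normalized expression of the module's
    genes minus the mean of an expression-bin-matched random background of
    equal size (fixed seed), the standard control for expression-level
    bias. Returns a module x subpopulation table of mean scores plus a
    Wilcoxon p of each subpopulation vs the rest.
    """
    rng = np.random.default_rng(seed)
    mat = lognorm.values
    gene_means = mat.mean(axis=1)
    bins = pd.qcut(gene_means.rank(method="first"), n_bins, labels=False)
    bin_members: dict[int, list[str]] = {
        b: list(gene_means.index[bins == b]) for b in range(n_bins)
    }

    cells = [c for c in lognorm.unit_ids if c in set(annotation.unit_ids)]
    subpops = annotation.subpopulations
    rows = []
    for module in modules.modules:
        genes = [g for g in module.gene_recurrence if g in mat.index]
        genes = sorted(set(genes))
        if not genes:
            logger.warning("module %s has no genes in the matrix; skipped",
                           module.module_id)
            continue
        fg_score = mat.loc[genes, cells].mean(axis=0)
        # per-bin background pools excluding the module's own genes (falling
        # back to the full bin if nothing else is left)
        gene_set = set(genes)
        pools = {}
        for g in genes:
            b = int(bins.loc[g])
            if b not in pools:
                # widen to neighboring bins if this bin holds only module genes
                pool: list[str] = []
                for delta in range(n_bins):
                    for bb in {b - delta, b + delta}:
                        if 0 <= bb < n_bins:
                            pool = [x for x in bin_members[bb] if x not in gene_set]
                            if pool:
                                break
                    if pool:
                        break
                pools[b] = pool if pool else bin_members[b]
        bg_scores = np.zeros(len(cells))
        for _ in range(n_background):
            bg_genes = [
                pools[int(bins.loc[g])][rng.integers(len(pools[int(bins.loc[g])]))]
                for g in genes
            ]
            bg_scores += mat.loc[bg_genes, cells].to_numpy().mean(axis=0)
        score = fg_score.to_numpy() - bg_scores / n_background
        score = pd.Series(score, index=cells)

        labels = annotation.table.loc[cells, "subpopulation"]
        for sp in subpops:
            in_s = score[labels == sp].to_numpy()
            out_s = score[labels != sp].to_numpy()
            if len(in_s) == 0 or len(out_s) == 0:
                continue
            _, p = wilcoxon_rank_sum(in_s, out_s, method="asymptotic")
            rows.append(
                {
                    "module_id": module.module_id,
                    "subpopulation": sp,
                    "mean_score": float(in_s.mean()),
                    "wilcoxon_p": p,
                }
            )
    return pd.DataFrame(rows)
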