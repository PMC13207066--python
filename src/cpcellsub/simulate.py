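"""Synthetic inputs with planted structure for every pipeline stage.

Generators for single-cell counts with planted subpopulation markers, bulk
cohorts whose clinical annotations are driven by a planted subpopulation's
abundance, spatial sections with planted co-localized signatures, and
scale-free regulatory networks with planted hubs. Counts follow a
negative-binomial model with lognormal gene-level means — the minimal model
reproducing the over-dispersion the rank-based downstream tests assume.

Every generator is a pure function of its spec (the seed included):
repeated calls are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .data_model import (
    CellAnnotation,
    ClinicalCohort,
    ExpressionMatrix,
    GeneSetCollection,
    Network,
    RegionLabel,
    SpatialSection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "simulate_scrna",
    "simulate_bulk_cohort",
    "simulate_spatial",
    "simulate_network",
]

# rough TCGA-KIRC-shaped stage marginals: more stage-I than stage-IV
DEFAULT_STAGE_MARGINALS: dict[str, list[float]] = {
    "T": [0.50, 0.12, 0.32, 0.06],
    "N": [0.93, 0.07],
    "M": [0.85, 0.15],
    "TNM": [0.49, 0.11, 0.23, 0.17],
}


@dataclass
class SimulationSpec:
    """Parameters of the planted statistical structure.

    ``marker_strength`` is in log2-fold units; ``hazard_ratio_per_sd`` is
    the hazard ratio per standard deviation of the planted subpopulation's
    abundance; ``stage_score_rho`` the target Spearman correlation between
    abundance and each ordinal stage axis; ``coloc_effect`` controls
    spatial bump amplitude (sign selects co- vs anti-localization, 0 means
    independent flat fields).
    """

    seed: int = 0
    n_genes: int = 2000
    n_cells_per_subpop: int = 200
    n_subpops: int = 3
    n_samples: int = 300
    n_markers_per_subpop: int = 50
    marker_strength: float = 2.0
    nb_dispersion: float = 2.0
    hazard_ratio_per_sd: float = 2.0
    stage_score_rho: float = 0.4
    censoring_rate: float = 0.3
    coloc_effect: float = 3.0
    grid_side: int = 15
    n_network_nodes: int = 500
    n_hubs: int = 1
    hub_extra_degree: int = 150
    stage_marginals: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_STAGE_MARGINALS.items()}
    )

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_subpop <= 0 or self.n_samples <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if not -1 <= self.stage_score_rho <= 1:
            raise ValueError("stage_score_rho must lie in [-1, 1]")
        if self.hazard_ratio_per_sd <= 0:
            raise ValueError("hazard_ratio_per_sd must be positive")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _subpop_names(n: int) -> list[str]:
    return [f"subpop_{i:02d}" for i in range(1, n + 1)]


def _base_means(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    # lognormal gene means, median ~0.3 counts/cell — sparse, scRNA-like
    return rng.lognormal(mean=np.log(0.3), sigma=1.0, size=n_genes)


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws: var = mu + mu^2 / dispersion."""
    shape = dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def planted_marker_map(spec: SimulationSpec) -> dict[str, list[str]]:
    """Deterministic disjoint marker assignment: first blocks of the gene list."""
    genes = _gene_ids(spec.n_genes)
    need = spec.n_subpops * spec.n_markers_per_subpop
    if need > spec.n_genes:
        raise ValueError(
            f"{need} marker genes requested but only {spec.n_genes} genes"
        )
    out: dict[str, list[str]] = {}
    for i, name in enumerate(_subpop_names(spec.n_subpops)):
        lo = i * spec.n_markers_per_subpop
        out[name] = genes[lo:lo + spec.n_markers_per_subpop]
    return out


def simulate_scrna(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, CellAnnotation, dict[str, list[str]]]:
    """Single-cell counts with planted subpopulation markers.

    Each subpopulation's marker genes are up-shifted by ``marker_strength``
    log2-fold in its cells. Returns the counts, the cell annotation, and
    the planted marker map (subpopulation -> gene list).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    markers = planted_marker_map(spec)
    seen: set[str] = set()
    for gs in markers.values():
        if seen & set(gs):
            raise ValueError("marker lists overlap between subpopulations")
        seen |= set(gs)

    base = _base_means(rng, spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    blocks = []
    cell_ids = []
    labels = []
    for name in _subpop_names(spec.n_subpops):
        mu = base.copy()
        idx = [gene_pos[g] for g in markers[name]]
        mu[idx] = mu[idx] * 2.0**spec.marker_strength
        counts = _nb_sample(
            rng,
            np.repeat(mu[:, None], spec.n_cells_per_subpop, axis=1),
            spec.nb_dispersion,
        )
        blocks.append(counts)
        cell_ids += [f"{name}_c{j:04d}" for j in range(spec.n_cells_per_subpop)]
        labels += [name] * spec.n_cells_per_subpop
    mat = np.concatenate(blocks, axis=1).astype(float)
    # guard against all-zero cells (possible at tiny depth): add one count
    zero_cells = mat.sum(axis=0) == 0
    if zero_cells.any():
        mat[0, zero_cells] = 1.0

    expr = ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=cell_ids))
    ann = CellAnnotation(
        pd.DataFrame(
            {"subpopulation": labels, "sample_id": "sample_01"}, index=cell_ids
        )
    )
    return expr, ann, markers


def _binned_spearman_ceiling(probs: np.ndarray) -> float:
    """Spearman of (binned U, U) in the continuum limit — the attainable
    maximum correlation after discretizing one margin to the given bin
    probabilities (average midranks per bin)."""
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    mid = (cum[:-1] + cum[1:]) / 2.0  # average rank quantile per bin
    # Cov(U, m(U)) over U ~ Uniform(0,1)
    cov = sum(
        m * (cum[j + 1] ** 2 - cum[j] ** 2) / 2.0 for j, m in enumerate(mid)
    ) - 0.5 * float(probs @ mid)
    var_m = float(probs @ mid**2) - float(probs @ mid) ** 2
    var_u = 1.0 / 12.0
    if var_m <= 0:
        return 0.0
    return cov / np.sqrt(var_u * var_m)


def _draw_stages(
    rng: np.random.Generator,
    z_abundance: np.ndarray,
    rho: float,
    marginals: dict[str, list[float]],
) -> dict[str, np.ndarray]:
    """Gaussian-copula stage draws targeting Spearman(stage, abundance) = rho.

    The latent correlation is inflated by each axis's discretization
    ceiling so the realized (post-binning) Spearman lands near the target;
    an unattainable target raises with the feasible range.
    """
    n = len(z_abundance)
    out: dict[str, np.ndarray] = {}
    for axis, probs in marginals.items():
        probs_arr = np.asarray(probs, dtype=float)
        probs_arr = probs_arr / probs_arr.sum()
        ceiling = _binned_spearman_ceiling(probs_arr)
        if abs(rho) > ceiling:
            raise ValueError(
                f"stage_score_rho={rho} unattainable for axis {axis}: "
                f"feasible range is [-{ceiling:.3f}, {ceiling:.3f}] "
                f"given its stage marginals"
            )
        # Spearman of two normals ~ (6/pi) arcsin(r/2); invert, then divide
        # by the binning ceiling
        r_latent = 2.0 * np.sin(np.pi / 6.0 * (rho / ceiling))
        r_latent = float(np.clip(r_latent, -0.999, 0.999))
        latent = r_latent * z_abundance + np.sqrt(1 - r_latent**2) * rng.standard_normal(n)
        u = scipy.stats.norm.cdf(latent)
        edges = np.cumsum(probs_arr)[:-1]
        codes = np.searchsorted(edges, u)
        start = 0 if axis in ("N", "M") else 1
        out[axis] = codes + start
    return out


def simulate_bulk_cohort(
    spec: SimulationSpec,
    markers: dict[str, list[str]],
    planted: str | None = None,
) -> tuple[ExpressionMatrix, ClinicalCohort, pd.DataFrame]:
    """Bulk cohort whose clinical structure tracks one planted subpopulation.

    Per-sample subpopulation proportions are Dirichlet(2, ..., 2) — cell
    fractions live on the simplex, so each subpopulation's marginal
    abundance is Beta-distributed — and bulk expression is the
    proportion-weighted mixture of the subpopulation mean profiles plus
    lognormal noise. Survival is exponential with log-hazard proportional
    to the standardized planted abundance (``hazard_ratio_per_sd`` per SD),
    censored independently at ``censoring_rate``; ordinal stages follow a
    Gaussian copula targeting Spearman ``stage_score_rho`` with the planted
    abundance. Returns expression, clinical cohort, and the true abundance
    table (samples x subpopulations).
    """
    rng = np.random.default_rng(spec.seed + 1)
    subpops = list(markers)
    if planted is None:
        planted = subpops[0]
    if planted not in markers:
        raise ValueError(f"planted subpopulation {planted!r} not in marker map")

    genes = _gene_ids(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = _base_means(np.random.default_rng(spec.seed), spec.n_genes)

    profiles = {}
    for name in subpops:
        mu = base.copy()
        idx = [gene_pos[g] for g in markers[name] if g in gene_pos]
        mu[idx] = mu[idx] * 2.0**spec.marker_strength
        profiles[name] = mu

    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    abundance = pd.DataFrame(
        rng.dirichlet(np.full(len(subpops), 2.0), size=n),
        index=sample_ids,
        columns=subpops,
    )

    bulk = np.zeros((spec.n_genes, n))
    for name in subpops:
        bulk += np.outer(profiles[name], abundance[name].to_numpy())
    bulk *= rng.lognormal(mean=0.0, sigma=0.3, size=bulk.shape)
    expr = ExpressionMatrix(pd.DataFrame(bulk, index=genes, columns=sample_ids))

    a = abundance[planted].to_numpy()
    z = (a - a.mean()) / a.std(ddof=0)
    base_rate = 1.0 / 1000.0  # median survival ~ 700 time units
    rates = base_rate * spec.hazard_ratio_per_sd**z
    event_times = rng.exponential(1.0 / rates)
    if spec.censoring_rate > 0:
        c_rate = base_rate * spec.censoring_rate / max(1e-9, 1 - spec.censoring_rate)
        censor_times = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(float)
    os_time = np.maximum(os_time, 1e-3)

    stages = _draw_stages(rng, z, spec.stage_score_rho, spec.stage_marginals)
    clin = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "t_stage": stages["T"].astype(float),
            "n_stage": stages["N"].astype(float),
            "m_stage": stages["M"].astype(float),
            "tnm_stage": stages["TNM"].astype(float),
        },
        index=sample_ids,
    )
    return expr, ClinicalCohort(clin, time_unit="days"), abundance


def simulate_program_samples(
    spec: SimulationSpec,
    n_samples: int = 6,
    n_cells: int = 80,
    n_program_genes: int = 50,
    program_strength: float = 4.0,
) -> tuple[ExpressionMatrix, CellAnnotation, dict[str, list[str]]]:
    """Multi-sample single-cell counts sharing two planted expression programs.

    Two disjoint ``n_program_genes``-gene programs are active in disjoint
    thirds of each sample's cells (the remaining third expresses neither),
    with per-cell gamma-distributed activity scaled by
    ``program_strength``. Every sample carries both programs, so they
    recur across samples and should consolidate into two meta-modules.
    Returns pooled counts, an annotation with ``sample_id`` per cell, and
    the planted program gene lists.
    """
    rng = np.random.default_rng(spec.seed + 4)
    genes = _gene_ids(spec.n_genes)
    if 2 * n_program_genes > spec.n_genes:
        raise ValueError("not enough genes for two disjoint programs")
    prog_a = genes[:n_program_genes]
    prog_b = genes[n_program_genes: 2 * n_program_genes]
    programs = {"program_A": prog_a, "program_B": prog_b}
    base = _base_means(np.random.default_rng(spec.seed), spec.n_genes)
    pos = {g: i for i, g in enumerate(genes)}
    ia = [pos[g] for g in prog_a]
    ib = [pos[g] for g in prog_b]

    blocks, cell_ids, samples = [], [], []
    third = n_cells // 3
    for si in range(n_samples):
        sample = f"patient_{si + 1:02d}"
        mu = np.repeat(base[:, None], n_cells, axis=1)
        act_a = rng.gamma(4.0, 1.0, size=third) * program_strength / 4.0
        act_b = rng.gamma(4.0, 1.0, size=third) * program_strength / 4.0
        mu[np.ix_(ia, range(third))] *= 1.0 + act_a[None, :]
        mu[np.ix_(ib, range(third, 2 * third))] *= 1.0 + act_b[None, :]
        counts = _nb_sample(rng, mu, spec.nb_dispersion).astype(float)
        zero = counts.sum(axis=0) == 0
        counts[0, zero] = 1.0
        blocks.append(counts)
        cell_ids += [f"{sample}_c{j:04d}" for j in range(n_cells)]
        samples += [sample] * n_cells
    mat = np.concatenate(blocks, axis=1)
    expr = ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=cell_ids))
    ann = CellAnnotation(
        pd.DataFrame({"subpopulation": "cancer", "sample_id": samples},
                     index=cell_ids)
    )
    return expr, ann, programs


def simulate_spatial(
    spec: SimulationSpec, n_sections: int = 1
) -> tuple[list[SpatialSection], GeneSetCollection]:
    """Spatial sections with two planted signature blocks on a square grid.

    The two 50-gene blocks receive Gaussian-bump intensity fields:
    ``coloc_effect > 0`` puts both bumps at the same (random) center
    (co-localized), ``< 0`` at mirrored opposite corners (anti-localized),
    and ``== 0`` leaves both fields flat (independent). Returns the
    sections and the two signature gene sets.
    """
    rng = np.random.default_rng(spec.seed + 2)
    side = spec.grid_side
    n_spots = side * side
    genes = _gene_ids(spec.n_genes)
    block_a = genes[: spec.n_markers_per_subpop]
    block_b = genes[spec.n_markers_per_subpop: 2 * spec.n_markers_per_subpop]
    sets = GeneSetCollection({"signature_A": block_a, "signature_B": block_b})

    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    base = _base_means(np.random.default_rng(spec.seed), spec.n_genes)

    def bump(center: np.ndarray, width: float) -> np.ndarray:
        d2 = ((coords - center) ** 2).sum(axis=1)
        return np.exp(-d2 / (2 * width**2))

    sections = []
    amp = abs(spec.coloc_effect)
    for si in range(n_sections):
        width = side / 4.0
        if spec.coloc_effect > 0:
            center = rng.uniform(side * 0.25, side * 0.75, size=2)
            field_a = bump(center, width)
            field_b = bump(center, width)
        elif spec.coloc_effect < 0:
            center = rng.uniform(side * 0.15, side * 0.35, size=2)
            field_a = bump(center, width)
            field_b = bump(np.array([side - 1, side - 1]) - center, width)
        else:
            field_a = np.zeros(n_spots)
            field_b = np.zeros(n_spots)
            rng.uniform(size=2)  # keep stream alignment across modes

        mu = np.repeat(base[:, None], n_spots, axis=1) * 3.0  # spots are minibulks
        pos = {g: i for i, g in enumerate(genes)}
        ia = [pos[g] for g in block_a]
        ib = [pos[g] for g in block_b]
        mu[ia, :] *= 1.0 + amp * field_a[None, :]
        mu[ib, :] *= 1.0 + amp * field_b[None, :]
        counts = _nb_sample(rng, mu, spec.nb_dispersion).astype(float)
        zero_spots = counts.sum(axis=0) == 0
        counts[0, zero_spots] = 1.0

        spot_ids = [f"spot_{i:04d}" for i in range(n_spots)]
        sections.append(
            SpatialSection(
                section_id=f"section_{si + 1:02d}",
                spots=ExpressionMatrix(
                    pd.DataFrame(counts, index=genes, columns=spot_ids)
                ),
                coordinates=pd.DataFrame(coords, index=spot_ids, columns=["x", "y"]),
                region_label=RegionLabel.tumor_core,
            )
        )
    return sections, sets


def simulate_network(spec: SimulationSpec) -> tuple[Network, list[str]]:
    """Scale-free TF->target network with planted extra-degree hubs.

    A preferential-attachment (Barabasi-Albert) skeleton; ``n_hubs``
    designated nodes each gain ``hub_extra_degree`` extra random
    neighbors, making them unambiguous hubs. Edge direction is assigned
    randomly. Returns the network and the planted hub names.
    """
    rng = np.random.default_rng(spec.seed + 3)
    n = spec.n_network_nodes
    g = nx.barabasi_albert_graph(n, m=2, seed=int(rng.integers(2**31)))
    names = {i: f"G{i:05d}" for i in g.nodes}
    hubs = [names[i] for i in range(spec.n_hubs)]
    edges: set[tuple[int, int]] = {tuple(sorted(e)) for e in g.edges}
    for h in range(spec.n_hubs):
        targets = rng.choice(
            [i for i in range(n) if i != h], size=spec.hub_extra_degree, replace=False
        )
        for t in targets:
            edges.add(tuple(sorted((h, int(t)))))
    edge_list = []
    for a, b in sorted(edges):
        if rng.uniform() < 0.5:
            a, b = b, a
        edge_list.append((names[a], names[b], 1.0))
    return Network(edge_list, directed=True), hubs
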