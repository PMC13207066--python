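# Methods

`cpcellsub` identifies cell subpopulations whose inferred abundance in bulk
tumor cohorts is associated with cancer progression, and provides three
companion analyses: intratumoral NMF meta-programs, order-statistics fusion
of network centralities, and spatial co-localization of subpopulation
signatures. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data tests do and do not show.

## 1. Subpopulation gene sets

Counts are depth-normalized and log-transformed,
`x(g,c) = ln(1 + n(g,c) · s / N(c))` with scale factor `s = 10 000`. For
each annotated subpopulation, every gene detected in ≥ 1% of cells of
either group is tested one-vs-rest with a two-sided Wilcoxon rank-sum test
(normal approximation with tie correction, vectorized across genes).
Fold-change is computed on the depth-normalized scale,
`log2((mean expm1 in + ε)/(mean expm1 out + ε))` with `ε = 1e-9`; p-values
are Benjamini–Hochberg adjusted per subpopulation. The subpopulation's gene
set is `{adj_p < 0.05 and log2FC > 1}`, both strict. BH was chosen over
Bonferroni for power; both thresholds and the detection filter are
configurable.

The 1e-9 pseudocount means a gene absent from the background has a large
but finite fold-change; the adjusted-p filter, not the fold-change, is
what excludes noise genes.

## 2. ssGSEA abundance scores

Within each bulk sample (or spot), genes are ranked by expression
(average ranks for ties). Walking the list from the top, the score is

    ES = Σ_i [ P_in(i) − P_out(i) ],

where `P_in` accumulates `w_g / Σ_{g∈S} w_g` for in-set genes with
`w_g = (rank from bottom)^α`, and `P_out` accumulates `1/(G − |S|)` for
out-of-set genes. `α = 0.25` is the convention of the dominant reference
implementation; `α = 0` reduces to uniform weights and is used as the
analytic check in the tests. With `normalize=true` (default) all scores
are divided by the matrix-wide max − min. Set genes absent from the matrix
are intersected away; sets with < 5 overlapping genes are dropped with a
warning.

Because the statistic depends only on within-sample ranks, scores are
invariant to any strictly increasing per-sample transform — asserted
numerically to 1e-12. A consequence worth knowing: the score measures
*relative* concentration of the set near the top of the sample's ranking,
so it tracks the subpopulation's *fraction* of the sample, not its
absolute cell count.

## 3. Progression calling

Samples are split at the median score (quantile configurable) into
high/low infiltration groups. Prognosis is tested with the two-group
log-rank test; the direction label (`high_worse`/`high_better`) comes from
comparing restricted mean survival up to the largest observed time. A
stratum left empty, a cohort with no events, or risk sets that never
overlap raise errors rather than returning a meaningless p.

Each staging axis is tested two ways: a group-difference test of scores
across stage levels — Wilcoxon rank-sum for the binary axes (N, M) or
whenever only two levels have ≥ 3 samples, Kruskal–Wallis otherwise — and
a Spearman correlation of score against the ordinal stage code. When the
total sample size admits ≤ 5·10⁵ distinct group assignments, rank-sum and
Kruskal–Wallis p-values come from exact enumeration of the permutation
distribution (correct under ties); otherwise the normal-with-tie-correction
and chi-square approximations are used. An axis is *significant* when both
the group test and the Spearman test fall below α = 0.05 and the
correlation is nonzero. The literal "|R| > 0" criterion is vacuous for any
nonzero sample correlation; it is implemented literally, with significance
carried by the Spearman p — noted here rather than silently replaced by an
effect-size floor.

A subpopulation is *called* progression-associated when the log-rank
p < α and at least `min_axes` axes are significant. `min_axes` defaults to
4 (the strict reading: all of T, N, M, TNM); per-axis flags are always
emitted so `min_axes = 1` summaries are reproducible. By default all
significant axes must also agree in correlation sign — a subpopulation
whose abundance rises with T but falls with M is biologically incoherent
and is not called; this can be disabled. No multiplicity correction across
subpopulations enters the call (per-subpopulation p < 0.05), but a
BH-adjusted log-rank column is emitted for transparency.

Stage strings are canonicalized at load time: sub-stages collapse to the
major numeral (T1a → 1), Stage I–IV → 1–4, TX/NX/MX → missing (never 0).
N2/N3 collapse to N1 by default, treating nodal involvement as a binary
progression axis; configurable. Survival time is carried in the unit
declared at load and never converted.

## 4. NMF meta-programs

Per sample, the 2000 most variable genes (dispersion = var/mean of
log-normalized values, z-scored within 20 mean-expression bins, ties
lexicographic) are factorized at every rank K in 2..10. The input matrix
is per-gene centered with negative residuals clipped to zero — the
meta-program convention — so factors load on genes expressed *above* their
sample average. Without this step, factor top-genes are dominated by
ubiquitously high-expressed genes and cross-sample consolidation collapses
into one indiscriminate module; with it, planted 50-gene programs are
recovered exactly on synthetic data. NMF uses the Frobenius objective,
multiplicative updates, NNDSVDa initialization, 500 max iterations,
tol 1e-4 — deterministic under a fixed seed.

Each factor yields a program: its top-50 loading genes (ties
lexicographic). Programs overlapping ≥ 10 genes with a program of another
sample are *robust*. Consolidation is iterative: the unassigned program
with the most above-threshold overlaps founds a module (ties by program
id); all unassigned programs overlapping the founder above threshold join;
iteration stops when no candidate module reaches 3 members. Module genes
are ranked by the number of member programs containing them (ties
lexicographic); the top 10 are reported. All tie-breaks being
deterministic makes the output invariant to program input order, which is
asserted by permutation in the tests. Only the cross-sample robustness
criterion is applied; recurrence across K values within a sample is not
additionally required.

Module–subpopulation association scores each cell as the mean
log-normalized expression of module genes minus an expression-bin-matched
random background (50 draws, fixed seed). Background pools exclude the
module's own genes, widening to neighboring bins when a bin contains
nothing else — with few genes per bin, sampling the module's own genes as
their own control cancels the signal exactly.

## 5. Critical genes by order-statistics fusion

Five centralities are computed per node: degree, betweenness, eigenvector,
and harmonic closeness on the undirected view (path-based indices on
sparse directed regulatory graphs are mostly zero), PageRank (damping
0.85, uniform teleport) on the directed view; `--directed-all` switches
everything to the directed view. Eigenvector centrality is computed per
connected component (the global power iteration is ill-posed on
disconnected graphs); harmonic closeness is finite on disconnected graphs
by construction.

Each index is converted to a rank ratio `r = average rank / n` with
centrality sorted descending, so smaller is more central and ties share
average ranks. The fused statistic is the joint probability that the order
statistics of N independent Uniform(0,1) variables fall below the node's
sorted ratios:

    V_0 = 1,  V_k = Σ_{j=1..k} (−1)^{j−1} V_{k−j} / j! · r_{N−k+1}^j,
    Q = N! · V_N.

The recursion with `V_{k−j}` (not `V_{k−1}`) is the unique reading under
which Q(1,…,1) = 1 and Q stays in (0,1]; the alternative is explicitly
shown to violate the certainty identity in the tests, and the
implementation is verified against closed forms (N ≤ 3) and a 10⁶-draw
Monte-Carlo estimate (N = 5). Genes are ranked by ascending Q and the top
`ceil(0.01 · n)` reported; ties at the cut break lexicographically and are
logged. Ranks are computed over all nodes jointly (TFs and targets);
restriction to a gene list is available on the CLI.

## 6. Spatial co-localization

Spot counts are log-normalized and each signature scored per spot, by
default as the mean over set genes of per-gene z-scores across spots
(genes with numerically zero variance contribute 0; the tolerance is
`sd ≤ 1e-12·(1+|mean|)`, guarding against float residue being amplified
into spurious ±1 z-scores). ssGSEA scoring per spot is available as an
alternative and preserves orderings on test data. For a signature pair,
the per-section Spearman correlation over spots classifies the pair:
positive if r > 0.2 and p < 0.05, negative if r < −0.2 and p < 0.05,
otherwise ns (strict inequalities; constant score vectors yield ns with a
degenerate flag). Sections are summarized as per-pair
positive/negative/ns proportions.

The *co-localization region* of a pair is the set of spots where both
scores exceed their per-section 75th percentile (configurable); regions
under 10 spots skip the section. Region-vs-rest differential expression
reuses the marker machinery on spots; recurrent genes are those
significantly up in ≥ `min_sections` sections, ranked by (sections
significant, mean log2FC, gene id), with the top 1% flagged. Spot scores
are signature-based, not deconvolution-based; externally computed per-spot
proportions can be supplied as a drop-in score matrix.

## 7. Synthetic data: what it models and what it does not

All generators are pure functions of their spec (seed included) and write
the same plain-text formats the readers consume.

*Single cell.* Negative-binomial counts (`var = μ + μ²/θ`, θ = 2) with
lognormal gene-level means (median ≈ 0.3 counts/cell, σ = 1) — the minimal
model with scRNA-like over-dispersion and sparsity. Each subpopulation's
markers (50 disjoint genes) are up-shifted `marker_strength` = 2 log2-fold.

*Bulk cohort.* Per-sample subpopulation proportions are Dirichlet(2,…,2):
cell fractions live on the simplex, so one subpopulation's marginal is
Beta-distributed and expression is genuinely compositional. Bulk
expression is the proportion-weighted mixture of subpopulation mean
profiles times lognormal noise (σ = 0.3). Survival is exponential with
hazard `λ0 · HR^z`, `z` the standardized planted proportion, HR = 2 per SD,
λ0 = 1/1000 per time unit; censoring is independent exponential tuned to
≈ 30%. Ordinal stages come from a Gaussian copula against the planted
proportion, binned to TCGA-KIRC-shaped marginals (more stage I than IV;
N and M binary with 7%/15% positivity). The latent correlation is
inflated by each axis's analytic discretization ceiling so the realized
Spearman lands near the requested ρ (verified within ±0.1 at n = 300); a
requested ρ above the ceiling raises with the feasible range.

*Spatial.* A square grid (15×15 spots) with two 50-gene signature blocks
whose intensity fields are Gaussian bumps: same center (co-localized),
mirrored corners (anti-localized), or flat (independent), with NB counts
per spot.

*Network.* A Barabási–Albert skeleton (m = 2) with designated hub nodes
given 150 extra random neighbors; edge directions random.

What passing tests show: the pipeline recovers planted markers, tracks
planted abundance, calls hazard- and stage-linked subpopulations with few
false calls, consolidates shared programs, classifies planted spatial
relationships, and surfaces planted hubs — under a generative model whose
assumptions (independent genes given the mixture, no batch effects, no
doublets, clean labels, exponential survival) are far milder than real
data. They do not validate symbol matching across real platforms,
annotation quality, deconvolution accuracy against histology, or
robustness to batch structure.

## 8. Problem sizes used in validation

The acceptance script and test suite run at desk scale, chosen to make
every recovery property measurable while keeping the whole suite fast:
1000–2000 genes, 200 cells per subpopulation, cohorts of 300 samples with
20 subpopulations over 10–20 seeds, 6-sample program recovery at 500
genes with K = 2–6, ten 225-spot sections per spatial mode, and 500-node
networks over 10 seeds.

## 9. Known limitations

- Gene identifiers are matched as exact strings; no alias resolution.
- The ssGSEA score is compositional (relative abundance); cohorts with
  globally shifted cellularity will shift all scores together.
- The final call's `min_axes = 4` default demands every axis be
  significant, which is conservative in small cohorts where the binary M
  axis may have few positive samples; per-axis flags are always emitted.
- Exact test enumeration is capped at 5·10⁵ arrangements; beyond that the
  standard approximations apply.
- The spatial analysis is spot-wise; it uses no neighborhood graph, so
  spatial autocorrelation is not modeled in the correlation p-values.
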