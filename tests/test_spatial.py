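"""Spot scoring, pairwise co-localization classification, and region DE."""

import numpy as np
import pandas as pd
import pytest

from cpcellsub import (
    ExpressionMatrix,
    GeneSetCollection,
    SpatialSection,
    coloc_region_de,
    correlate_pair,
    recurrent_genes,
    score_spots,
    summarize_sections,
)
from cpcellsub.spatial import SectionColocResult
from cpcellsub.ssgsea import ScoreMatrix


def toy_section(n_side=4, left_genes=("L0", "L1"), seed=0):
    """Grid section where `left_genes` are expressed only in the left half."""
    rng = np.random.default_rng(seed)
    n_spots = n_side * n_side
    spots = [f"sp{i:02d}" for i in range(n_spots)]
    xs = np.repeat(np.arange(n_side), n_side)
    ys = np.tile(np.arange(n_side), n_side)
    genes = list(left_genes) + [f"bg{i}" for i in range(8)] + ["const"]
    mat = rng.uniform(1, 3, size=(len(genes), n_spots))
    left = xs < n_side / 2
    for gi in range(len(left_genes)):
        mat[gi, :] = np.where(left, 20.0, 0.1)
    mat[-1, :] = 2.0  # constant gene
    coords = pd.DataFrame({"x": xs, "y": ys}, index=spots).astype(float)
    return SpatialSection(
        section_id="toy",
        spots=ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=spots)),
        coordinates=coords,
    ), left


class TestScoreSpots:
    def test_left_half_scores_higher(self):
        section, left = toy_section()
        sets = GeneSetCollection({"sig": ["L0", "L1"]})
        sm = score_spots(section, sets)
        scores = sm.row("sig").to_numpy()
        assert scores[left].min() > scores[~left].max()

    def test_constant_gene_contributes_zero(self):
        # spot totals equalized so the constant gene stays constant after
        # depth normalization; its z-score is then defined as 0
        spots = [f"sp{i}" for i in range(12)]
        l0 = np.where(np.arange(12) < 6, 20.0, 0.1)
        const = np.full(12, 2.0)
        filler = 30.0 - l0 - const
        mat = pd.DataFrame([l0, const, filler], index=["L0", "const", "filler"],
                           columns=spots)
        coords = pd.DataFrame({"x": np.arange(12), "y": np.zeros(12)}, index=spots)
        section = SpatialSection("eq", ExpressionMatrix(mat), coords.astype(float))
        s_with = score_spots(section, GeneSetCollection({"s": ["L0", "const"]}))
        s_half = score_spots(section, GeneSetCollection({"s": ["L0"]}))
        np.testing.assert_allclose(
            s_with.row("s").to_numpy(), s_half.row("s").to_numpy() / 2, atol=1e-12
        )

    def test_ssgsea_method_preserves_ordering(self):
        section, left = toy_section()
        sets = GeneSetCollection({"sig": ["L0", "L1"]})
        sm = score_spots(section, sets, method="ssgsea", min_overlap=1)
        scores = sm.row("sig").to_numpy()
        assert scores[left].mean() > scores[~left].mean()

    def test_no_overlap_dropped(self):
        section, _ = toy_section()
        with pytest.raises(ValueError, match="no gene set"):
            score_spots(section, GeneSetCollection({"alien": ["zz"]}))


class TestCorrelatePair:
    def _scores(self, a, b):
        df = pd.DataFrame([a, b], index=["A", "B"],
                          columns=[f"sp{i}" for i in range(len(a))])
        return ScoreMatrix(df)

    def test_identical_positive(self):
        v = list(np.arange(12.0))
        res = correlate_pair(self._scores(v, v), ("A", "B"))
        assert res.spearman_r == pytest.approx(1.0)
        assert res.classification == "positive"

    def test_reversed_negative(self):
        v = list(np.arange(12.0))
        res = correlate_pair(self._scores(v, v[::-1]), ("A", "B"))
        assert res.spearman_r == pytest.approx(-1.0)
        assert res.classification == "negative"

    def test_threshold_strict(self):
        # r = 1 exactly: with the threshold raised to 1.0 the strict
        # inequality r > threshold must fail -> ns
        v = list(np.arange(12.0))
        res = correlate_pair(self._scores(v, v), ("A", "B"), r_threshold=1.0)
        assert res.classification == "ns"

    def test_constant_vector_degenerate_ns(self):
        v = list(np.arange(12.0))
        res = correlate_pair(self._scores(v, [3.0] * 12), ("A", "B"))
        assert res.classification == "ns" and res.degenerate

    def test_too_few_spots(self):
        v = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="spots"):
            correlate_pair(self._scores(v, v), ("A", "B"))

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        r1 = correlate_pair(self._scores(list(a), list(b)), ("A", "B"))
        r2 = correlate_pair(self._scores(list(np.exp(a)), list(b**3)), ("A", "B"))
        assert r1.spearman_r == pytest.approx(r2.spearman_r, abs=1e-12)
        assert r1.classification == r2.classification


class TestSummarize:
    def _res(self, cls, sid):
        return SectionColocResult(sid, ("A", "B"), 0.5, 0.01, cls, 100)

    def test_proportions(self):
        results = [self._res("positive", f"s{i}") for i in range(9)] + [
            self._res("ns", f"s{i + 9}") for i in range(7)
        ]
        df = summarize_sections(results)
        row = df.iloc[0]
        assert row["n_sections"] == 16
        assert row["prop_positive"] == pytest.approx(9 / 16)
        assert row["prop_negative"] == 0.0
        assert row["prop_ns"] == pytest.approx(7 / 16)
        assert row["prop_positive"] + row["prop_negative"] + row["prop_ns"] == pytest.approx(1.0)

    def test_all_ns(self):
        df = summarize_sections([self._res("ns", "s1")])
        assert df.iloc[0]["prop_ns"] == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            summarize_sections([])


class TestRegionDE:
    def _section_with_corner(self, seed=0):
        """10x10 grid; two signatures and a DE gene all high in one corner."""
        rng = np.random.default_rng(seed)
        side = 10
        spots = [f"sp{i:03d}" for i in range(side * side)]
        xs = np.repeat(np.arange(side), side)
        ys = np.tile(np.arange(side), side)
        corner = (xs < 5) & (ys < 5)
        # many background genes keep the planted genes' library share small,
        # so depth normalization does not induce compositional DE
        genes = (["sigA0", "sigA1", "sigB0", "sigB1", "de_gene"]
                 + [f"bg{i}" for i in range(1000)])
        mat = rng.uniform(1, 2, size=(len(genes), side * side))
        for gi, g in enumerate(genes[:5]):
            mat[gi, :] = np.where(corner, rng.uniform(8, 12, size=corner.size),
                                  rng.uniform(0.1, 0.5, size=corner.size))
        section = SpatialSection(
            section_id=f"sec{seed}",
            spots=ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=spots)),
            coordinates=pd.DataFrame({"x": xs, "y": ys}, index=spots).astype(float),
        )
        sets = GeneSetCollection({"A": ["sigA0", "sigA1"], "B": ["sigB0", "sigB1"]})
        return section, sets

    def test_planted_corner_gene_significant(self):
        section, sets = self._section_with_corner()
        sm = score_spots(section, sets)
        de = coloc_region_de(section, sm, ("A", "B"))
        assert de is not None
        row = de.loc["de_gene"]
        assert row["adj_p"] < 0.05 and row["log2fc"] > 0

    def test_uniform_gene_not_significant(self):
        section, sets = self._section_with_corner()
        sm = score_spots(section, sets)
        de = coloc_region_de(section, sm, ("A", "B"))
        bg = de.loc[[g for g in de.index if g.startswith("bg")]]
        assert bg["adj_p"].median() > 0.5
        # no background gene is called up-regulated in the region
        assert not ((bg["adj_p"] < 0.05) & (bg["log2fc"] > 0)).any()

    def test_small_region_skipped(self):
        section, sets = self._section_with_corner()
        sm = score_spots(section, sets)
        assert coloc_region_de(section, sm, ("A", "B"), high_quantile=0.99) is None

    def test_recurrent_genes_min_sections_rule(self):
        tables = []
        for seed in range(4):
            section, sets = self._section_with_corner(seed)
            sm = score_spots(section, sets)
            tables.append(coloc_region_de(section, sm, ("A", "B")))
        rec = recurrent_genes(tables, min_sections=3)
        assert "de_gene" in rec.index
        assert rec.loc["de_gene", "n_sections_significant"] >= 3
        # a gene significant in fewer sections than required is excluded
        fake = tables[0].copy()
        fake.loc[:, "adj_p"] = 1.0
        fake.loc["only_once", ["log2fc", "p_value", "adj_p"]] = [2.0, 1e-6, 1e-6]
        rec2 = recurrent_genes([fake] + [t.drop(index="de_gene") for t in tables[1:]],
                               min_sections=3)
        assert "only_once" not in rec2.index
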