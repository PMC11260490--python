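import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.special import comb

from tfcrkit.genomic_io import ExpressionTable
from tfcrkit.regscore import (
    build_gene_table,
    cluster_species,
    decile_of,
    hypergeom_enrich,
    regulatory_score,
    score_grid,
    species_specific_genes,
    top_fraction_genes,
)

from .conftest import make_gene, make_tfcr


class TestRegulatoryScore:
    def test_max_at_nine_nine(self):
        assert regulatory_score(9, 9) == pytest.approx(1.0)

    def test_zero_factor(self):
        assert regulatory_score(0, 7) == 0.0
        assert regulatory_score(7, 0) == 0.0

    def test_five_five(self):
        assert regulatory_score(5, 5) == pytest.approx(25 / 81)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            regulatory_score(10, 3)
        with pytest.raises(ValueError):
            regulatory_score(-1, 3)

    def test_symmetry_all_pairs(self):
        for a in range(10):
            for b in range(10):
                assert regulatory_score(a, b) == pytest.approx(regulatory_score(b, a))

    def test_monotone_in_product_at_fixed_gap(self):
        for gap in range(10):
            pairs = [(a, a + gap) for a in range(10 - gap)]
            scores = [regulatory_score(a, b) for a, b in pairs]
            products = [a * b for a, b in pairs]
            for i in range(len(pairs) - 1):
                if products[i + 1] > products[i]:
                    assert scores[i + 1] > scores[i]

    def test_grid_extremes(self):
        g = score_grid()
        assert g.max() == pytest.approx(1.0)
        assert g[9, 9] == pytest.approx(1.0)
        assert g.min() == 0.0
        zero_mask = g == 0.0
        expected_zero = np.zeros((10, 10), dtype=bool)
        expected_zero[0, :] = True
        expected_zero[:, 0] = True
        assert (zero_mask == expected_zero).all()

    def test_high_sync_threshold_region(self):
        # both groups >= 5 with gap <= 1 always clears the 0.3 threshold;
        # the gap-2 pair (5, 7) is the lone sub-threshold exception
        for a in range(5, 10):
            for b in range(5, 10):
                if abs(a - b) <= 1:
                    assert regulatory_score(a, b) > 0.3
        assert regulatory_score(5, 7) < 0.3
        assert regulatory_score(6, 8) > 0.3


class TestDeciles:
    def test_equal_count(self):
        groups = decile_of(list(range(100)))
        assert np.bincount(groups, minlength=10).tolist() == [10] * 10

    def test_tie_determinism(self):
        values = [1.0] * 50
        ids = [f"g{i:02d}" for i in range(50)]
        a = decile_of(values, tiebreak=ids)
        b = decile_of(list(values), tiebreak=list(ids))
        assert (a == b).all()

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            decile_of([1.0] * 9)


class TestBuildGeneTable:
    def _setup(self):
        genes = [make_gene(f"g{i}", "chr1", 50_000 * i + 10_000) for i in range(12)]
        tfcrs = [
            make_tfcr("chr1", 50_000 * i + 9_000, 50_000 * i + 9_400, complexity=i + 1)
            for i in range(12)
        ]
        expr = ExpressionTable("s", {f"g{i}": float(i + 1) for i in range(12)})
        return tfcrs, genes, expr

    def test_gene_gets_tfcr_group(self):
        tfcrs, genes, expr = self._setup()
        table = build_gene_table(tfcrs, genes, expr)
        row = table[table["gene_id"] == "g11"].iloc[0]
        assert row["g_tfcr"] == 9
        assert row["g_expr"] == 9
        assert row["score"] == pytest.approx(1.0)
        assert row["distance"] == 0

    def test_max_complexity_tfcr_wins(self):
        genes = [make_gene(f"g{i}", "chr1", 50_000 * i + 10_000) for i in range(12)]
        tfcrs = [
            make_tfcr("chr1", 50_000 * i + 9_000, 50_000 * i + 9_400, complexity=i + 1)
            for i in range(12)
        ]
        # second, more complex TFCR also nearest to g0
        tfcrs.append(make_tfcr("chr1", 10_500, 10_900, complexity=50))
        expr = ExpressionTable("s", {f"g{i}": float(i + 1) for i in range(12)})
        table = build_gene_table(tfcrs, genes, expr)
        row = table[table["gene_id"] == "g0"].iloc[0]
        assert row["g_tfcr"] == 9  # from the complexity-50 TFCR

    def test_gene_without_tfcr_unscored(self):
        tfcrs, genes, expr = self._setup()
        genes.append(make_gene("lonely", "chr2", 10_000))
        expr.values["lonely"] = 3.0
        table = build_gene_table(tfcrs, genes, expr)
        row = table[table["gene_id"] == "lonely"].iloc[0]
        assert pd.isna(row["score"])

    def test_empty_expression_errors(self):
        tfcrs, genes, _ = self._setup()
        with pytest.raises(ValueError):
            build_gene_table(tfcrs, genes, ExpressionTable("s", {}))

    def test_planted_high_genes_rank_top(self):
        # strong complexity/expression coupling: planted genes recoverable
        from tfcrkit.caller import call_tfcrs, merge_family_overlaps
        from tfcrkit.synthetic import SynthConfig, make_dataset

        cfg = SynthConfig(
            seed=31, n_chroms=4, chrom_length=2_000_000, n_genes=400, n_clusters=400,
            promoter_cluster_prob=1.0, cluster_size_dist=("geometric", 0.25),
            expr_coupling_rho=0.9, make_sequences=False,
        )
        data = make_dataset(cfg)
        tfcrs = call_tfcrs(merge_family_overlaps(data.hits_by_stage[0]))
        table = build_gene_table(tfcrs, data.genes, data.expression_by_stage[0])
        top = set(top_fraction_genes(table, 0.2))
        sizes = data.promoter_cluster_sizes(0)
        expr = data.expression_by_stage[0].values
        planted = sorted(
            (g for g in sizes if sizes[g] > 0),
            key=lambda g: (sizes[g], expr[g]),
            reverse=True,
        )[: len(top)]
        overlap = len(top & set(planted)) / len(top)
        assert overlap >= 0.8


class TestSpeciesSpecific:
    def _tables(self):
        genes = [f"g{i}" for i in range(20)]

        def table(scores):
            return pd.DataFrame({"gene_id": genes, "score": scores})

        base = np.linspace(0.1, 0.9, 20)
        t1 = table(base)  # top genes: g19..g16
        t2 = table(base[::-1])  # top genes: g0..g3
        rng = np.random.default_rng(0)
        mid = base.copy()
        rng.shuffle(mid)
        t3 = table(mid)
        return {"sp1": t1, "sp2": t2, "sp3": t3}

    def test_specific_and_excluded(self):
        tables = self._tables()
        specific, conserved = species_specific_genes(tables, top_frac=0.2)
        tops = {
            sp: set(top_fraction_genes(t, 0.2)) for sp, t in tables.items()
        }
        for sp in tables:
            for g in specific[sp]:
                assert g in tops[sp]
                others = [o for o in tables if o != sp]
                assert all(g not in tops[o] for o in others)
        # genes in >1 top set are nowhere specific
        from collections import Counter

        counts = Counter(g for s in tops.values() for g in s)
        multi = {g for g, c in counts.items() if c > 1}
        for s in specific.values():
            assert not s & multi
        assert conserved == {g for g, c in counts.items() if c == 3}

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            species_specific_genes({"sp1": pd.DataFrame({"gene_id": [], "score": []})})

    def test_homolog_map_translation(self):
        t1 = pd.DataFrame({"gene_id": ["a1", "a2"] + [f"a{i}" for i in range(3, 13)],
                           "score": np.linspace(1, 0, 12)})
        t2 = pd.DataFrame({"gene_id": ["b1", "b2"] + [f"b{i}" for i in range(3, 13)],
                           "score": np.linspace(1, 0, 12)})
        hmap = {
            "sp1": {f"a{i}": f"h{i}" for i in range(1, 13)},
            "sp2": {f"b{i}": f"h{i}" for i in range(1, 13)},
        }
        specific, conserved = species_specific_genes(
            {"sp1": t1, "sp2": t2}, homolog_map=hmap, top_frac=0.2
        )
        assert conserved == {"h1", "h2"}
        assert specific == {"sp1": set(), "sp2": set()}


class TestClusterSpecies:
    def test_identical_vectors_merge_first(self, rng):
        base = rng.random(30)
        other = rng.random(30)
        frame = pd.DataFrame({"s1": base, "s2": base, "s3": other})
        z = cluster_species(frame)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        v = np.arange(12, dtype=float)
        frame = pd.DataFrame({"s1": v, "s2": v[::-1], "s3": np.r_[v[3:], v[:3]]})
        z = cluster_species(frame)
        assert z[:, 2].max() <= 2.0 + 1e-12

    def test_planted_two_plus_two(self, rng):
        a = rng.random(50)
        b = rng.random(50)
        frame = pd.DataFrame(
            {
                "a1": a + rng.normal(0, 0.01, 50),
                "a2": a + rng.normal(0, 0.01, 50),
                "b1": b + rng.normal(0, 0.01, 50),
                "b2": b + rng.normal(0, 0.01, 50),
            }
        )
        z = cluster_species(frame)
        labels = fcluster(z, t=2, criterion="maxclust")
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_constant_vector_errors(self):
        frame = pd.DataFrame(
            {"s1": np.ones(12), "s2": np.arange(12.0), "s3": np.arange(12.0)[::-1]}
        )
        with pytest.raises(ValueError):
            cluster_species(frame)


class TestHypergeomEnrich:
    def test_trivial_certainty(self):
        u = {f"g{i}" for i in range(10)}
        assert hypergeom_enrich(u, u, u) == pytest.approx(1.0)

    def test_zero_overlap_large_expected(self):
        u = {f"g{i}" for i in range(100)}
        hit = {f"g{i}" for i in range(50)}
        gs = {f"g{i}" for i in range(50, 100)}
        assert hypergeom_enrich(hit, gs, u) > 0.999

    def test_exact_combinatorics(self):
        u = {f"g{i}" for i in range(20)}
        gs = {f"g{i}" for i in range(10)}
        hit = {f"g{i}" for i in range(5)}
        expected = comb(10, 5) / comb(20, 5)
        assert hypergeom_enrich(hit, gs, u) == pytest.approx(expected)
        assert expected == pytest.approx(0.01625, abs=5e-5)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(set(), set(), set())
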