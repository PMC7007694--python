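import math

import numpy as np
import pytest
from scipy import stats

from seednet.expression import coexpression_edges, filter_expressed
from seednet.io_formats import write_edge_list, write_gmt
from seednet.pathway_bipartite import build_bipartite, pathway_enrichment
from seednet.synthetic_data import (
    SimulationConfig,
    gene_symbols,
    planted_degs,
    simulate_expression,
    simulate_pathways,
    simulate_ppi,
    simulate_seed_sets,
)


def tiny_config(**kw):
    base = dict(
        n_genes=200,
        n_deg=30,
        n_coexpr_blocks=2,
        block_size=10,
        seed_set_sizes={"a": 20},
        n_pathways=10,
        planted_enriched_pathways=1,
        pathway_size_range=(15, 30),
        rng_seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 5},
            {"within_block_correlation": 1.5},
            {"ppi_mean_degree": 500},
            {"n_coexpr_blocks": 50, "block_size": 50},
            {"planted_enrichment_odds": 0.5},
            {"pathway_size_range": (0, 10)},
            {"ppi_model": "smallworld"},
            {"dispersion": 0.0},
        ],
    )
    def test_rejects_bad_values(self, kw):
        with pytest.raises(ValueError):
            tiny_config(**kw)


class TestSimulatePpi:
    def test_erdos_renyi_edge_count(self):
        cfg = SimulationConfig(
            n_genes=100, ppi_model="erdos_renyi", ppi_mean_degree=4, rng_seed=1,
            n_coexpr_blocks=2, block_size=10, n_deg=10,
            seed_set_sizes={"a": 10}, n_pathways=5, planted_enriched_pathways=0,
            pathway_size_range=(5, 20),
        )
        assert len(simulate_ppi(cfg)) == 200  # n * k / 2

    def test_deterministic_bytes(self, tmp_path):
        cfg = tiny_config(rng_seed=9)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_edge_list(simulate_ppi(cfg), p1)
        write_edge_list(simulate_ppi(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_scale_free_attachment_one_is_tree(self):
        cfg = SimulationConfig(
            n_genes=10, ppi_model="scale_free", ppi_mean_degree=2, rng_seed=3,
            n_coexpr_blocks=1, block_size=5, n_deg=2,
            seed_set_sizes={"a": 3}, n_pathways=3, planted_enriched_pathways=0,
            pathway_size_range=(2, 5),
        )
        edges = simulate_ppi(cfg)
        assert len(edges) == 9  # preferential-attachment tree on 10 nodes

    def test_no_self_loops(self):
        edges = simulate_ppi(tiny_config())
        assert all(e.gene_a != e.gene_b for e in edges)

    def test_scale_free_is_heavy_tailed(self):
        cfg = tiny_config(n_genes=500, rng_seed=5)
        edges = simulate_ppi(cfg)
        degree: dict[str, int] = {}
        for e in edges:
            degree[e.gene_a] = degree.get(e.gene_a, 0) + 1
            degree[e.gene_b] = degree.get(e.gene_b, 0) + 1
        degs = np.array(sorted(degree.values()))
        assert degs.max() > 5 * np.median(degs)


class TestSimulateExpression:
    def test_shape_and_groups(self):
        m = simulate_expression(tiny_config())
        assert m.counts.shape == (200, 6)
        assert sorted(set(m.groups.values())) == ["mut", "wt"]

    def test_determinism(self):
        cfg = tiny_config(rng_seed=4)
        a = simulate_expression(cfg)
        b = simulate_expression(cfg)
        assert a.counts.equals(b.counts) and a.fpkm.equals(b.fpkm)

    def test_rho_one_identical_block_profiles(self):
        cfg = tiny_config(within_block_correlation=1.0, n_deg=0)
        m = simulate_expression(cfg)
        block = m.counts.iloc[:10].to_numpy()
        assert (block == block[0]).all()

    def test_planted_deg_shift(self):
        cfg = tiny_config(n_genes=400, n_deg=60, lfc_mean=2.0, rng_seed=8,
                          n_coexpr_blocks=0, block_size=1)
        m = simulate_expression(cfg)
        wt = m.counts.iloc[:60, :3].to_numpy().mean()
        mut = m.counts.iloc[:60, 3:].to_numpy().mean()
        assert mut / wt == pytest.approx(4.0, rel=0.25)

    def test_null_case_equal_means(self):
        cfg = tiny_config(n_genes=400, n_deg=0, rng_seed=8, n_coexpr_blocks=0,
                          block_size=1)
        m = simulate_expression(cfg)
        wt = m.counts.iloc[:, :3].to_numpy().mean()
        mut = m.counts.iloc[:, 3:].to_numpy().mean()
        assert mut / wt == pytest.approx(1.0, rel=0.1)

    def test_block_correlation_monte_carlo(self):
        # block of 20 genes, rho=0.9, 6 samples: mean off-diagonal sample
        # Pearson r within +-0.1 of the generative rho over 300 sims
        means = []
        for seed in range(300):
            cfg = SimulationConfig(
                n_genes=20, n_coexpr_blocks=1, block_size=20, n_deg=0,
                within_block_correlation=0.9, rng_seed=seed,
                seed_set_sizes={"a": 5}, n_pathways=3, planted_enriched_pathways=0,
                pathway_size_range=(5, 10),
            )
            x = simulate_expression(cfg).counts.to_numpy(float)
            keep = x.std(axis=1) > 0
            if keep.sum() < 2:
                continue
            corr = np.corrcoef(x[keep])
            iu = np.triu_indices(keep.sum(), k=1)
            means.append(corr[iu].mean())
        assert abs(np.mean(means) - 0.9) < 0.1

    def test_fpkm_lengths_in_declared_range(self):
        m = simulate_expression(tiny_config())
        assert m.gene_lengths.between(500, 5000).all()

    def test_expressed_filter_recovers_most_genes(self):
        m = simulate_expression(tiny_config())
        assert len(filter_expressed(m)) > 150


class TestSimulateSeedSets:
    def test_sizes_as_configured(self):
        cfg = tiny_config(seed_set_sizes={"a": 20, "b": 15})
        sets = simulate_seed_sets(cfg, planted_degs(cfg))
        assert {k: len(v) for k, v in sets.items()} == {"a": 20, "b": 15}

    def test_odds_one_matches_hypergeometric(self):
        # no enrichment: DEG hits follow the central hypergeometric
        cfg = tiny_config(planted_enrichment_odds=1.0, n_genes=500, n_deg=100,
                          seed_set_sizes={"a": 50})
        hits = []
        for seed in range(200):
            sets = simulate_seed_sets(cfg.with_seed(seed), planted_degs(cfg))
            hits.append(len(sets["a"].genes & planted_degs(cfg).genes))
        expected = 50 * 100 / 500
        se = math.sqrt(stats.hypergeom.var(500, 100, 50) / 200)
        assert abs(np.mean(hits) - expected) < 4 * se

    def test_odds_infinity_subset_of_degs(self):
        cfg = tiny_config(planted_enrichment_odds=math.inf, n_deg=50,
                          seed_set_sizes={"a": 20})
        sets = simulate_seed_sets(cfg, planted_degs(cfg))
        assert sets["a"].genes <= planted_degs(cfg).genes

    def test_odds_recovery_monte_carlo(self):
        # empirical membership odds ratio over replicates covers the
        # planted odds of 3
        cfg = tiny_config(planted_enrichment_odds=3.0, n_genes=600, n_deg=120,
                          seed_set_sizes={"a": 60})
        deg = planted_degs(cfg)
        n_deg, n_non = 120, 480
        ors = []
        for seed in range(300):
            sets = simulate_seed_sets(cfg.with_seed(seed), deg)
            k = len(sets["a"].genes & deg.genes)
            m = 60 - k
            ors.append((k / (n_deg - k)) / (m / (n_non - m)))
        mean_or = np.mean(ors)
        assert 2.4 < mean_or < 3.8

    def test_size_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(seed_set_sizes={"a": 10_000})


class TestSimulatePathways:
    def test_planted_pathway_below_threshold(self):
        cfg = tiny_config(n_genes=2000, n_deg=100, seed_set_sizes={"a": 150},
                          n_pathways=10, planted_enriched_pathways=2,
                          pathway_size_range=(30, 60))
        sets = simulate_seed_sets(cfg, planted_degs(cfg))
        records = simulate_pathways(cfg, sets)
        universe = gene_symbols(cfg.n_genes)
        planted = [r for r in records if r.description.startswith("planted")]
        assert len(planted) == 2
        for rec in planted:
            x = len(rec.members & sets["a"].genes)
            p = stats.hypergeom.sf(x - 1, len(universe), len(rec.members), 150)
            assert p < 1e-6 and x >= 10

    def test_uniform_pathways_not_kept(self):
        cfg = tiny_config(n_genes=2000, n_deg=100, seed_set_sizes={"a": 150},
                          n_pathways=20, planted_enriched_pathways=0,
                          pathway_size_range=(30, 60))
        sets = simulate_seed_sets(cfg, planted_degs(cfg))
        records = simulate_pathways(cfg, sets)
        net = build_bipartite(
            records,
            planted_degs(cfg).__class__.from_symbols(
                "u", gene_symbols(cfg.n_genes), normalize=False
            ),
        )
        rows = pathway_enrichment(net, sets["a"])
        assert not any(r.kept for r in rows)

    def test_deterministic_gmt_bytes(self, tmp_path):
        cfg = tiny_config(rng_seed=13)
        sets = simulate_seed_sets(cfg, planted_degs(cfg))
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gmt(simulate_pathways(cfg, sets), p1)
        write_gmt(simulate_pathways(cfg, sets), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_infeasible_size_range_rejected(self):
        cfg = tiny_config(n_genes=2000, seed_set_sizes={"a": 12},
                          pathway_size_range=(2000, 2000),
                          n_pathways=2, planted_enriched_pathways=1)
        sets = simulate_seed_sets(cfg, planted_degs(cfg))
        with pytest.raises(ValueError, match="plant"):
            simulate_pathways(cfg, sets)


class TestGenerativeRecovery:
    def test_coexpression_recovers_planted_blocks(self):
        # within-block pairs pass the 0.75 cutoff far more often than
        # cross-block pairs at rho=0.95
        cfg = tiny_config(n_genes=60, n_coexpr_blocks=2, block_size=15,
                          within_block_correlation=0.95, n_deg=0, rng_seed=21)
        m = simulate_expression(cfg)
        edges = coexpression_edges(m, cutoff=0.75)
        blocks = [set(gene_symbols(60)[:15]), set(gene_symbols(60)[15:30])]
        within = sum(
            1 for a, b in edges.pairs
            if any(a in blk and b in blk for blk in blocks)
        )
        n_within_pairs = 2 * (15 * 14 // 2)
        assert within / n_within_pairs > 0.8
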