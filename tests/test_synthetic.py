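import numpy as np
import pandas as pd
import pytest

from methylhub.config import SimConfig
from methylhub.preprocess import assign_promoter_probes
from methylhub.survival import km_estimate
from methylhub.synthetic import (
    simulate_methylation_expression,
    simulate_ppi,
    simulate_survival,
)


SMALL = dict(n_genes=120, ppi_n_nodes=120, n_ei_planted=6, n_es_planted=6,
             n_hubs_planted=2, seed=42)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_pairs", 1),
            ("n_ei_planted", 200),
            ("beta_shift", 1.5),
            ("hub_ei_frac", 1.2),
            ("censor_rate", -0.1),
            ("hazard_ratio", 0.0),
            ("ppi_attach_m", 0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        kwargs = dict(SMALL)
        kwargs[field] = value
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SimConfig(**kwargs)

    def test_ppi_smaller_than_gene_panel_rejected(self):
        with pytest.raises(ValueError, match="ppi_n_nodes"):
            SimConfig(n_genes=100, ppi_n_nodes=50)


class TestMethylationExpression:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(**SMALL)
        a1, b1, e1, t1 = simulate_methylation_expression(cfg)
        a2, b2, e2, t2 = simulate_methylation_expression(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1.values, b2.values)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        _, b1, _, _ = simulate_methylation_expression(SimConfig(**SMALL))
        _, b2, _, _ = simulate_methylation_expression(
            SimConfig(**{**SMALL, "seed": 43})
        )
        assert not b1.values.equals(b2.values)

    def test_beta_values_within_unit_interval(self):
        _, beta, _, _ = simulate_methylation_expression(SimConfig(**SMALL))
        vals = beta.values.to_numpy()
        observed = vals[~np.isnan(vals)]
        assert (observed > 0).all() and (observed < 1).all()

    def test_planted_shifts_realized(self):
        cfg = SimConfig(**SMALL)
        ann, beta, expr, truth = simulate_methylation_expression(cfg)
        t_cols, n_cols = beta.paired_samples()
        probe_gene = ann.set_index("probe_id")["gene"]
        for label, bsign, esign in [("EI", -1, 1), ("ES", 1, -1)]:
            genes = set(truth.index[truth["label"] == label])
            probes = [p for p in beta.feature_ids if probe_gene.get(p) in genes]
            d_beta = (
                beta.values.loc[probes, t_cols].mean(axis=1)
                - beta.values.loc[probes, n_cols].mean(axis=1)
            )
            assert np.mean(d_beta) == pytest.approx(bsign * cfg.beta_shift, abs=0.05)
            d_expr = np.log2(expr.values.loc[sorted(genes), t_cols]).mean(
                axis=1
            ) - np.log2(expr.values.loc[sorted(genes), n_cols]).mean(axis=1)
            assert np.mean(d_expr) == pytest.approx(esign * cfg.expr_log2fc, abs=0.4)

    def test_planted_genes_methylation_expression_anticorrelated(self):
        cfg = SimConfig(**{**SMALL, "beta_shift": 0.0, "expr_log2fc": 0.0})
        ann, beta, expr, truth = simulate_methylation_expression(cfg)
        probe_gene = ann.set_index("probe_id")["gene"]
        corrs = []
        for gene in truth.index[truth["label"] != "null"]:
            probes = [p for p in beta.feature_ids if probe_gene.get(p) == gene]
            b = beta.values.loc[probes[0]].to_numpy(float)
            e = np.log2(expr.values.loc[gene].to_numpy(float))
            corrs.append(np.corrcoef(b, e)[0, 1])
        # coupling through the shared latent factor, even with zero shift
        assert np.mean(corrs) < -0.2

    def test_null_simulation_has_no_systematic_shift(self):
        cfg = SimConfig(**{**SMALL, "beta_shift": 0.0, "expr_log2fc": 0.0})
        _, beta, expr, truth = simulate_methylation_expression(cfg)
        t_cols, n_cols = beta.paired_samples()
        d = (beta.values[t_cols].to_numpy() - beta.values[n_cols].to_numpy())
        assert np.nanmean(d) == pytest.approx(0.0, abs=0.01)

    def test_point_mass_distribution_gives_single_promoter_probe(self):
        cfg = SimConfig(**{**SMALL, "probes_per_promoter_dist": {1: 1.0}})
        ann, _, _, truth = simulate_methylation_expression(cfg)
        assignments = assign_promoter_probes(ann)
        per_gene = assignments[assignments["gene"].isin(truth.index)].groupby("gene").size()
        assert (per_gene == 1).all()
        assert set(per_gene.index) == set(truth.index)


class TestPpi:
    def test_preferential_attachment_tree(self):
        cfg = SimConfig(
            n_genes=10, ppi_n_nodes=10, ppi_attach_m=1, n_ei_planted=0,
            n_es_planted=0, n_hubs_planted=0, seed=3,
        )
        _, _, _, truth = simulate_methylation_expression(cfg)
        g, _ = simulate_ppi(cfg, truth)
        assert g.number_of_edges() == 9
        import networkx as nx

        assert nx.is_connected(g)

    def test_same_seed_identical_graph(self):
        cfg = SimConfig(**SMALL)
        _, _, _, truth = simulate_methylation_expression(cfg)
        g1, h1 = simulate_ppi(cfg, truth)
        g2, h2 = simulate_ppi(cfg, truth)
        assert set(g1.edges) == set(g2.edges)
        pd.testing.assert_frame_equal(h1, h2)

    def test_planted_hub_neighborhoods_enriched(self):
        cfg = SimConfig(**SMALL)
        _, _, _, truth = simulate_methylation_expression(cfg)
        g, hub_truth = simulate_ppi(cfg, truth)
        planted = set(truth.index[truth["label"] != "null"])
        for hub in hub_truth.index[hub_truth["is_hub"]]:
            neigh = set(g.neighbors(hub))
            target = min(
                int(np.ceil(cfg.hub_ei_frac * len(neigh))), len(planted)
            )
            assert len(neigh & planted) >= min(target, len(planted))

    def test_degree_distribution_heavy_tailed(self):
        cfg = SimConfig(**{**SMALL, "n_genes": 500, "ppi_n_nodes": 500})
        _, _, _, truth = simulate_methylation_expression(cfg)
        g, _ = simulate_ppi(cfg, truth)
        degs = np.array([d for _, d in g.degree()])
        assert degs.max() > 5 * np.median(degs)

    def test_simple_graph_no_self_loops(self):
        cfg = SimConfig(**SMALL)
        _, _, _, truth = simulate_methylation_expression(cfg)
        g, _ = simulate_ppi(cfg, truth)
        assert all(u != v for u, v in g.edges)


class TestSurvivalSimulation:
    def _groups(self, n=50):
        return pd.Series(["high"] * n + ["low"] * n, index=[f"s{i}" for i in range(2 * n)])

    def test_deterministic(self):
        cfg = SimConfig(**SMALL)
        s1 = simulate_survival(self._groups(), cfg)
        s2 = simulate_survival(self._groups(), cfg)
        pd.testing.assert_frame_equal(s1, s2)

    def test_censor_rate_one_gives_flat_km_curve(self):
        cfg = SimConfig(**{**SMALL, "censor_rate": 1.0})
        surv = simulate_survival(self._groups(), cfg)
        assert (surv["event"] == 0).all()
        km = km_estimate(surv)
        assert (km["survival"] == 1.0).all()

    def test_hazard_ratio_shortens_high_group_times(self):
        cfg = SimConfig(**{**SMALL, "hazard_ratio": 5.0, "censor_rate": 0.0})
        surv = simulate_survival(self._groups(n=300), cfg)
        assert (
            surv.loc[surv["group"] == "high", "time"].mean()
            < surv.loc[surv["group"] == "low", "time"].mean() / 2
        )

    def test_unknown_group_label_rejected(self):
        cfg = SimConfig(**SMALL)
        with pytest.raises(ValueError, match="unknown expression groups"):
            simulate_survival(pd.Series(["mid"], index=["s0"]), cfg)
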