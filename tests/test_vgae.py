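"""GRN construction, VGAE training, knockout inference and KL ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ionbridge import vgae


def _posterior(mu, logsig, genes=None):
    mu = np.atleast_2d(np.asarray(mu, float))
    logsig = np.atleast_2d(np.asarray(logsig, float))
    genes = genes or [f"g{i}" for i in range(mu.shape[0])]
    return vgae.LatentPosterior(index=pd.Index(genes), mu=mu, logsig=logsig)


class TestKLPerGene:
    def test_identical_posteriors_zero(self):
        wt = _posterior([[0.3, -0.5]], [[0.1, 0.2]])
        ko = _posterior([[0.3, -0.5]], [[0.1, 0.2]])
        assert vgae.kl_per_gene(wt, ko).iloc[0] == 0.0

    def test_unit_mean_shift_half(self):
        wt = _posterior([[0.0]], [[0.0]])
        ko = _posterior([[1.0]], [[0.0]])
        assert vgae.kl_per_gene(wt, ko).iloc[0] == pytest.approx(0.5)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        mu_ko, mu_wt = rng.normal(size=(2, 1, 5))
        ls_ko, ls_wt = rng.normal(scale=0.3, size=(2, 1, 5))
        closed = vgae.kl_per_gene(
            _posterior(mu_wt, ls_wt), _posterior(mu_ko, ls_ko)
        ).iloc[0]
        n = 1_000_000
        z = mu_ko + rng.standard_normal((n, 5)) * np.exp(ls_ko)

        def logpdf(x, mu, ls):
            return (-0.5 * ((x - mu) / np.exp(ls)) ** 2 - ls
                    - 0.5 * np.log(2 * np.pi)).sum(axis=1)

        mc = np.mean(logpdf(z, mu_ko[0], ls_ko[0]) - logpdf(z, mu_wt[0], ls_wt[0]))
        assert abs(mc - closed) / closed < 0.05

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vgae.kl_per_gene(_posterior([[0.0]], [[0.0]]),
                             _posterior([[0.0, 0.0]], [[0.0, 0.0]]))


class TestRankAndPercentile:
    def test_rank_one_of_500(self):
        kl = pd.Series(np.arange(500, dtype=float),
                       index=[f"g{i}" for i in range(500)])
        table = vgae.rank_and_percentile(kl)
        assert table.loc["g499", "rank"] == 1
        assert table.loc["g499", "percentile"] == pytest.approx(99.8)
        assert table.loc["g0", "percentile"] == 0.0

    def test_tie_at_top_shares_best_rank(self):
        kl = pd.Series([9.0, 9.0] + [1.0] * 498,
                       index=[f"g{i}" for i in range(500)])
        table = vgae.rank_and_percentile(kl)
        assert table.loc["g0", "rank"] == 1 and table.loc["g1", "rank"] == 1
        assert table.loc["g0", "percentile"] == pytest.approx(99.8)

    @pytest.mark.parametrize("n", [10, 500, 2000])
    def test_formula_for_all_ranks(self, n):
        kl = pd.Series(np.arange(n, dtype=float)[::-1],
                       index=[f"g{i}" for i in range(n)])
        table = vgae.rank_and_percentile(kl)
        expected = (1.0 - table["rank"] / n) * 100.0
        assert np.allclose(table["percentile"], expected)
        assert table["percentile"].between(0, 100, inclusive="left").all()


def _toy_counts(seed=0, n_genes=30, n_cells=80):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene")
    base = rng.normal(2.0, 0.5, size=(n_genes, 1))
    x = np.exp(base + 0.3 * rng.normal(size=(n_genes, n_cells)))
    return pd.DataFrame(np.log1p(x), index=genes,
                        columns=[f"c{j}" for j in range(n_cells)])


class TestBuildGRN:
    def test_knn_edges_follow_correlation(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        counts = pd.DataFrame(
            np.column_stack([base, 0.95 * base + 0.1 * rng.normal(size=100),
                             rng.normal(size=100)]).T,
            index=["g1", "g2", "g3"],
            columns=[f"c{j}" for j in range(100)],
        )
        g = vgae.build_grn(counts, v=3, k=1)
        i1, i2, i3 = (g.index_of(x) for x in ("g1", "g2", "g3"))
        assert g.adjacency[i1, i2] == 1.0

    def test_constant_gene_isolated(self):
        counts = _toy_counts(seed=2)
        counts.iloc[5] = 3.0
        g = vgae.build_grn(counts, v=30, k=3)
        assert g.adjacency[g.index_of("g005")].sum() == 0.0

    def test_required_gene_outside_top_v_included(self):
        counts = _toy_counts(seed=3)
        counts.iloc[7] *= 0.0
        counts.iloc[7] += 1.0  # zero variance: never in top-V
        g = vgae.build_grn(counts, v=5, k=2, required_genes=["g007"])
        assert "g007" in g.nodes

    def test_missing_required_gene_listed_in_error(self):
        with pytest.raises(ValueError, match="gXXX"):
            vgae.build_grn(_toy_counts(), v=10, k=2, required_genes=["gXXX"])


class TestTraining:
    def _block_graph(self, seed=0, n=40, block=20):
        """Two feature blocks; edges mostly within blocks."""
        rng = np.random.default_rng(seed)
        genes = pd.Index([f"g{i:03d}" for i in range(n)])
        f1, f2 = rng.normal(size=(2, 60))
        feats = np.vstack([
            np.vstack([f1 + 0.4 * rng.normal(size=60) for _ in range(block)]),
            np.vstack([f2 + 0.4 * rng.normal(size=60) for _ in range(block)]),
        ])
        adj = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < block) == (j < block)
                if rng.random() < (0.35 if same else 0.02):
                    adj[i, j] = adj[j, i] = 1.0
        return vgae.GRNGraph(nodes=genes, features=vgae.standardize_rows(feats),
                             adjacency=adj, k=0)

    def test_same_seed_identical_training(self):
        g = self._block_graph()
        m1, _ = vgae.train_vgae(g, vgae.VGAEConfig(epochs=30), seed=5)
        m2, _ = vgae.train_vgae(g, vgae.VGAEConfig(epochs=30), seed=5)
        assert m1.loss_trace == m2.loss_trace
        assert m1.weights_hash() == m2.weights_hash()

    def test_loss_decreases(self):
        g = self._block_graph(seed=1)
        model, _ = vgae.train_vgae(g, vgae.VGAEConfig(epochs=80), seed=0)
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_within_block_reconstruction_exceeds_between(self):
        g = self._block_graph(seed=2)
        model, wt = vgae.train_vgae(g, vgae.VGAEConfig(epochs=150), seed=0)
        z = wt.mu
        probs = 1.0 / (1.0 + np.exp(-(z @ z.T)))
        within = np.r_[probs[:20, :20][np.triu_indices(20, 1)],
                       probs[20:, 20:][np.triu_indices(20, 1)]]
        between = probs[:20, 20:].ravel()
        assert within.mean() > between.mean()

    def test_edgeless_graph_rejected(self):
        g = vgae.GRNGraph(nodes=pd.Index(["a", "b"]),
                          features=np.zeros((2, 4)),
                          adjacency=np.zeros((2, 2)), k=0)
        with pytest.raises(ValueError, match="no edges"):
            vgae.train_vgae(g)

    def test_frozen_weights_survive_knockouts(self):
        g = self._block_graph(seed=3)
        model, wt = vgae.train_vgae(g, vgae.VGAEConfig(epochs=30), seed=1)
        before = model.weights_hash()
        for gene in list(g.nodes[:5]):
            vgae.kl_per_gene(wt, vgae.virtual_ko(model, g, gene))
        assert model.weights_hash() == before


class TestVirtualKO:
    def _trained(self, seed=0):
        g = TestTraining()._block_graph(seed=seed)
        model, wt = vgae.train_vgae(g, vgae.VGAEConfig(epochs=60), seed=0)
        return g, model, wt

    def test_isolated_zero_feature_gene_identity_perturbation(self):
        g, model, wt = self._trained()
        g2 = vgae.GRNGraph(
            nodes=g.nodes.append(pd.Index(["ghost"])),
            features=np.vstack([g.features, np.zeros((1, g.features.shape[1]))]),
            adjacency=np.pad(g.adjacency, ((0, 1), (0, 1))),
            k=0,
        )
        wt2 = model.encode(g2.features, g2.adjacency, g2.nodes)
        ko = vgae.virtual_ko(model, g2, "ghost")
        kl = vgae.kl_per_gene(wt2, ko)
        assert np.allclose(kl, 0.0, atol=1e-12)

    def test_ko_gene_own_posterior_changes(self):
        g, model, wt = self._trained(seed=1)
        # pick a gene whose wild-type posterior is clearly nonzero
        gi = int(np.argmax(np.abs(wt.mu).sum(axis=1)))
        gene = str(g.nodes[gi])
        ko = vgae.virtual_ko(model, g, gene)
        assert not np.allclose(ko.mu[gi], wt.mu[gi])

    def test_neighbors_more_perturbed_than_nonneighbors(self):
        g, model, wt = self._trained(seed=2)
        gene = str(g.nodes[0])
        kl = vgae.kl_per_gene(wt, vgae.virtual_ko(model, g, gene))
        gi = g.index_of(gene)
        nbr = g.adjacency[gi] > 0
        non = ~nbr
        non[gi] = False
        assert np.median(kl[nbr]) > np.median(kl[non])

    def test_unfrozen_model_rejected(self):
        g, model, _ = self._trained()
        model.frozen = False
        with pytest.raises(ValueError, match="frozen"):
            vgae.virtual_ko(model, g, str(g.nodes[0]))


class TestBaggingAndControls:
    def test_zero_permutations_rejected(self, strong_perturb):
        ds, _ = strong_perturb
        norm = vgae.normalize_counts(ds.counts)
        g = vgae.build_grn(norm, v=50, k=3, seed=0)
        model, _ = vgae.train_vgae(g, vgae.VGAEConfig(epochs=5), seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            vgae.bagging_consistency(model, g, norm, str(g.nodes[0]),
                                     [str(g.nodes[1])], n_perm=0)

    def test_control_percentile_100_when_hub_dominates(self):
        g = TestTraining()._block_graph(seed=4)
        model, wt = vgae.train_vgae(g, vgae.VGAEConfig(epochs=40), seed=0)
        hub = str(g.nodes[0])
        target = str(g.nodes[1])
        hub_kl = {hub: vgae.kl_per_gene(wt, vgae.virtual_ko(model, g, hub))}
        hub_kl[hub][:] = 1e9  # dominate every control by construction
        with pytest.warns(UserWarning, match="non-hub"):
            res = vgae.negative_control(
                model, g, wt, hub_kl, pairs={hub: [target]},
                n_controls=100, seed=0,
            )
        assert res.pair_percentiles.loc[0, "percentile"] == 100.0
        assert len(res.control_genes) == len(g.nodes) - 1

    def test_mann_whitney_null_calibrated(self):
        """Pseudo-hubs drawn from the control pool give uniform-ish p."""
        g = TestTraining()._block_graph(seed=5)
        model, wt = vgae.train_vgae(g, vgae.VGAEConfig(epochs=40), seed=0)
        totals = {}
        for gene in map(str, g.nodes):
            totals[gene] = float(
                vgae.kl_per_gene(wt, vgae.virtual_ko(model, g, gene)).sum()
            )
        rng = np.random.default_rng(0)
        from scipy.stats import mannwhitneyu

        hits = 0
        reps = 50
        names = list(totals)
        for _ in range(reps):
            chosen = rng.choice(names, size=5, replace=False)
            rest = [n for n in names if n not in chosen]
            _, p = mannwhitneyu([totals[c] for c in chosen],
                                [totals[r] for r in rest],
                                alternative="greater")
            hits += p < 0.05
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestClassifyValidation:
    def test_channel_met_in_one_dataset_validated(self):
        results = {
            "ds1": pd.Series({"C": 10.0, "X": 0.0}),
            "ds2": pd.Series({"C": 97.0, "X": 0.0}),
        }
        status, validated = vgae.classify_validation(results, ("H", "X", "C"))
        assert status == vgae.VALIDATED
        assert validated == [("C", "ds2")]

    def test_intermediate_only_partial(self):
        results = {"ds1": pd.Series({"C": 10.0, "X": 99.0})}
        status, validated = vgae.classify_validation(results, ("H", "X", "C"))
        assert status == vgae.PARTIAL
        assert validated == [("X", "ds1")]

    def test_nothing_met_none(self):
        results = {"ds1": pd.Series({"C": 10.0, "X": 20.0})}
        status, validated = vgae.classify_validation(results, ("H", "X", "C"))
        assert status == vgae.NONE
        assert validated == []
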