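"""Seven-strategy rubrics, statistics and the evidence matrix."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionbridge import evidence as ev
from ionbridge import synthetic as syn


class TestRubrics:
    @pytest.mark.parametrize("padj,score", [
        (0.03, 3.0), (0.05, 2.0), (0.07, 2.0), (0.15, 1.0), (0.2, 0.0),
        (0.5, 0.0), (float("nan"), 0.0),
    ])
    def test_s1_and_s4(self, padj, score):
        assert ev.score_s1(padj) == score
        assert ev.score_s4(padj) == score

    @pytest.mark.parametrize("nes,p,score", [
        (-1.81, 0.001, 3.0), (1.6, 0.2, 2.0), (1.4, 0.5, 2.0),
        (1.1, 0.9, 1.0), (0.9, 0.001, 0.0), (1.0, 0.001, 0.0),
    ])
    def test_s2(self, nes, p, score):
        assert ev.score_s2(nes, p) == score

    @pytest.mark.parametrize("pct,score", [
        (3.7, 3.0), (5.0, 2.0), (8.3, 2.0), (10.0, 1.0), (19.9, 1.0),
        (20.0, 0.0), (50.0, 0.0),
    ])
    def test_s3(self, pct, score):
        assert ev.score_s3(pct) == score

    @pytest.mark.parametrize("klass,score", [
        ("validated", 3.0), ("predicted", 2.0), ("weak", 1.0), ("none", 0.0),
    ])
    def test_s5(self, klass, score):
        assert ev.score_s5(klass) == score

    @pytest.mark.parametrize("z,score", [
        (0.610, 3.0), (0.5, 2.0), (0.35, 2.0), (0.3, 1.0), (0.15, 1.0),
        (0.1, 0.0), (0.05, 0.0),
    ])
    def test_s6(self, z, score):
        assert ev.score_s6(z) == score

    @pytest.mark.parametrize("drho,score", [
        (-0.277, 3.0), (0.25, 3.0), (-0.18, 2.0), (0.12, 1.0), (-0.05, 0.0),
        (0.1, 0.0), (float("nan"), 0.0),
    ])
    def test_s7(self, drho, score):
        assert ev.score_s7(drho) == score

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_s1_monotone_in_significance(self, a, b):
        lo, hi = sorted([a, b])
        assert ev.score_s1(lo) >= ev.score_s1(hi)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_s3_monotone_in_rank(self, a, b):
        lo, hi = sorted([a, b])
        assert ev.score_s3(lo) >= ev.score_s3(hi)


class TestTotals:
    def test_sum_and_cap(self):
        total, klass = ev.total_evidence(
            {f"S{i}": 3.0 for i in range(1, 8)}
        )
        assert total == 21.0
        assert klass == "high (>=15)"

    def test_missing_strategy_counts_zero(self):
        total, _ = ev.total_evidence({"S1": 2.0})
        assert total == 2.0

    @pytest.mark.parametrize("total,klass", [
        (15.5, "high (>=15)"), (15.0, "high (>=15)"),
        (10.0, "moderate (10-15)"), (5.0, "low (5-10)"),
        (4.9, "minimal (<5)"), (0.0, "minimal (<5)"),
    ])
    def test_strength_classes(self, total, klass):
        assert ev.strength_class(total) == klass


def es_brute_force(metric, is_hit, weight=1.0):
    """Running-sum enrichment-score oracle, plain loop."""
    w = np.abs(metric) ** weight
    nr = w[is_hit].sum()
    n_miss = (~is_hit).sum()
    best, running = 0.0, 0.0
    for m, hit, wi in zip(metric, is_hit, w):
        running += wi / nr if hit else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestPrerankedGSEA:
    def test_matches_running_sum_oracle_on_toys(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            metric = np.sort(rng.normal(size=10))[::-1]
            is_hit = rng.random(10) < 0.4
            if not is_hit.any() or is_hit.all():
                continue
            got = ev._enrichment_score(metric, is_hit, 1.0)
            assert got == pytest.approx(es_brute_force(metric, is_hit))

    def test_top_heavy_set_positive_and_significant(self):
        ranking = pd.Series(np.linspace(3, -3, 200),
                            index=[f"g{i}" for i in range(200)])
        es, nes, p = ev.preranked_gsea(ranking, {f"g{i}" for i in range(10)},
                                       n_perm=200, seed=0)
        assert es > 0 and nes > 1.0 and p < 0.05

    def test_random_set_null_centered(self):
        rng = np.random.default_rng(1)
        ranking = pd.Series(rng.normal(size=300),
                            index=[f"g{i}" for i in range(300)])
        nes_vals, ps = [], []
        for i in range(20):
            gene_set = set(rng.choice(ranking.index, size=15, replace=False))
            _, nes, p = ev.preranked_gsea(ranking, gene_set, n_perm=100,
                                          seed=i)
            nes_vals.append(abs(nes))
            ps.append(p)
        assert 0.7 < np.mean(nes_vals) < 1.3
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_disjoint_gene_set_rejected(self):
        ranking = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="intersect"):
            ev.preranked_gsea(ranking, {"zzz"})


class TestPseudobulk:
    def test_planted_mediator_significant(self, strong_perturb):
        ds, _ = strong_perturb
        de = ev.pseudobulk_de(ds, "G00001")
        assert de.loc["G00050", "padj"] < 0.05
        assert de.loc["G00050", "log2FC"] > 1.0

    def test_control_split_null_calibrated(self, control_split):
        de = ev.pseudobulk_de(control_split, "FAKE")
        assert (de["p"] < 0.05).mean() <= 0.08

    def test_single_batch_rejected(self, strong_perturb):
        ds, _ = strong_perturb
        one_batch = ev.SingleCellKODataset(
            counts=ds.counts, ko_label=ds.ko_label,
            batch=pd.Series("b1", index=ds.counts.columns),
        )
        with pytest.raises(ValueError, match="batch"):
            ev.pseudobulk_de(one_batch, "G00001")

    def test_all_zero_gene_excluded(self, strong_perturb):
        ds, _ = strong_perturb
        counts = ds.counts.copy()
        counts.loc["G00399"] = 0
        ds2 = ev.SingleCellKODataset(counts=counts, ko_label=ds.ko_label,
                                     batch=ds.batch)
        de = ev.pseudobulk_de(ds2, "G00001")
        assert "G00399" not in de.index


class TestTranscriptomeRank:
    def test_planted_knockdown_ranks_top(self, strong_perturb):
        ds, _ = strong_perturb
        # the KO gene itself carries the largest |log2FC|
        assert ev.transcriptome_rank(ds, "G00001", "G00001") <= 5.0
        assert ev.transcriptome_rank(ds, "G00001", "G00050") <= 5.0

    def test_largest_lfc_gene_gets_top_slot(self, strong_perturb):
        ds, _ = strong_perturb
        sig = ev.ko_signature(ds, "G00001").abs()
        best = sorted(sig.index, key=lambda g: (-sig[g], g))[0]
        n = ds.counts.shape[0]
        assert ev.transcriptome_rank(ds, "G00001", best) == pytest.approx(
            100.0 / n)


class TestHurdle:
    def test_detection_rate_effect_detected(self):
        rng = np.random.default_rng(3)
        n = 200
        genes = [f"g{i}" for i in range(30)]
        cells = [f"c{j}" for j in range(2 * n)]
        counts = rng.poisson(2.0, size=(30, 2 * n))
        # g0: detection 50% in control, 10% in KO, same positive mean
        detect_ctrl = rng.random(n) < 0.5
        detect_ko = rng.random(n) < 0.1
        counts[0, :n] = np.where(detect_ko, 1 + rng.poisson(3.0, n), 0)
        counts[0, n:] = np.where(detect_ctrl, 1 + rng.poisson(3.0, n), 0)
        ds = ev.SingleCellKODataset(
            counts=pd.DataFrame(counts, index=genes, columns=cells),
            ko_label=pd.Series(["KO"] * n + [ev.CONTROL] * n, index=cells),
            batch=pd.Series("b1", index=cells),
        )
        padj = ev.hurdle_test(ds, "KO", "g0")
        assert padj < 0.05

    def test_all_detected_gene_part_two_carries(self, strong_perturb):
        ds, _ = strong_perturb
        counts = ds.counts.copy()
        counts.loc["G00010"] += 1  # detected everywhere: part 1 degenerate
        ds2 = ev.SingleCellKODataset(counts=counts, ko_label=ds.ko_label,
                                     batch=ds.batch)
        table = ev.hurdle_test_all(ds2, "G00001", genes=["G00010"])
        assert table.loc["G00010", "df"] == 1

    def test_null_calibrated(self, control_split):
        table = ev.hurdle_test_all(
            control_split, "FAKE",
            genes=list(control_split.counts.index[:150]),
        )
        assert (table["p"] < 0.05).mean() <= 0.08

    def test_too_few_cells_rejected(self, strong_perturb):
        ds, _ = strong_perturb
        few = list(ds.cells_of("G00001")[:5]) + list(ds.cells_of(ev.CONTROL))
        sub = ev.SingleCellKODataset(counts=ds.counts[few],
                                     ko_label=ds.ko_label.loc[few],
                                     batch=ds.batch.loc[few])
        with pytest.raises(ValueError, match="20 cells"):
            ev.hurdle_test_all(sub, "G00001")


class TestMediatorNetwork:
    def _de(self, sig_genes):
        idx = [f"g{i}" for i in range(10)] + ["MED"]
        padj = pd.Series(0.9, index=idx)
        padj[sig_genes] = 0.001
        return pd.DataFrame({"padj": padj})

    def _ppi(self, combined, experimental=0.0, textmining=0.0):
        g = nx.Graph()
        g.add_edge("MED", "TGT", combined_score=combined,
                   experimental=experimental, database=0.0,
                   textmining=textmining, coexpression=0.0)
        return g

    def test_experimental_edge_validated(self):
        klass, meds = ev.mediator_network(
            self._de(["MED"]), self._ppi(600.0, experimental=300.0),
            "KO", "TGT")
        assert klass == "validated" and meds == ["MED"]

    def test_textmining_edge_predicted(self):
        klass, _ = ev.mediator_network(
            self._de(["MED"]), self._ppi(600.0, textmining=600.0),
            "KO", "TGT")
        assert klass == "predicted"

    def test_below_threshold_weak(self):
        klass, _ = ev.mediator_network(
            self._de(["MED"]), self._ppi(300.0, experimental=300.0),
            "KO", "TGT")
        assert klass == "weak"

    def test_no_significant_neighbors_none(self):
        klass, meds = ev.mediator_network(
            self._de([]), self._ppi(600.0, experimental=300.0), "KO", "TGT")
        assert klass == "none" and meds == []


class TestGlobalPerturbation:
    def test_null_below_first_breakpoint(self, control_split):
        assert ev.global_perturbation(control_split, "FAKE") < 0.1

    def test_planted_global_effect_exceeds_null(self, control_split):
        """10% of genes shifted -> statistic above the control-split null."""
        spec = syn.PerturbSimSpec(
            n_cells_per_group=250, n_genes=300, ko_genes=("G00001",),
            knockdown_fraction=0.9,
            mediator_effects=tuple(
                ("G00001", f"G{i:05d}", 1.0) for i in range(10, 40)
            ),
            n_batches=4, seed=13,
        )
        ds, _ = syn.generate_perturbseq(spec)
        planted = ev.global_perturbation(ds, "G00001")
        null = ev.global_perturbation(control_split, "FAKE")
        assert planted > null

    def test_copied_cells_near_zero(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, size=(20, 60))
        mat = np.hstack([counts, counts])
        cells = [f"c{j}" for j in range(120)]
        ds = ev.SingleCellKODataset(
            counts=pd.DataFrame(mat, index=[f"g{i}" for i in range(20)],
                                columns=cells),
            ko_label=pd.Series(["KO"] * 60 + [ev.CONTROL] * 60, index=cells),
            batch=pd.Series("b1", index=cells),
        )
        assert ev.global_perturbation(ds, "KO") == pytest.approx(0.0, abs=1e-9)


class TestCoexpressionDisruption:
    def test_planted_disruption_recovered(self):
        """Mean over three replicates (Monte-Carlo error reduction)."""
        drhos = []
        for seed in (21, 22, 23):
            spec = syn.PerturbSimSpec(
                n_cells_per_group=500, n_genes=120, ko_genes=("G00001",),
                knockdown_fraction=0.0,
                coexpr_pairs=(("G00001", "G00060", 0.52, 0.25),),
                n_batches=4, seed=seed,
            )
            ds, _ = syn.generate_perturbseq(spec)
            drhos.append(ev.coexpression_disruption(ds, "G00001", "G00060"))
        assert np.mean(drhos) == pytest.approx(-0.27, abs=0.1)

    def test_identical_distribution_near_zero(self, null_perturb):
        # well-expressed target: rank correlation is stable, not tie-dominated
        means = null_perturb.counts.mean(axis=1).drop("G00001")
        target = means.idxmax()
        drho = ev.coexpression_disruption(null_perturb, "G00001", target)
        assert abs(drho) < 0.15

    def test_constant_gene_flagged_missing(self, null_perturb):
        counts = null_perturb.counts.copy()
        counts.loc["G00100"] = 0  # constant after normalization too
        ds = ev.SingleCellKODataset(counts=counts,
                                    ko_label=null_perturb.ko_label,
                                    batch=null_perturb.batch)
        drho = ev.coexpression_disruption(ds, "G00001", "G00100")
        assert np.isnan(drho)
        assert ev.score_s7(drho) == 0.0
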