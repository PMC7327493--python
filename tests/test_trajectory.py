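import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosstage.trajectory import (
    compute_entropy,
    infer_lineage_links,
    loess_smooth,
    pseudotime_order,
    som_modules,
    zscore_profiles,
)


class TestEntropy:
    def test_uniform_profile_maximal(self):
        assert compute_entropy(np.ones(64)) == pytest.approx(np.log(64))

    def test_single_gene_zero(self):
        p = np.zeros(10)
        p[3] = 7.0
        assert compute_entropy(p) == 0.0

    def test_half_half(self):
        assert compute_entropy([0.5, 0.5]) == pytest.approx(np.log(2))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, 50)
            h = compute_entropy(p)
            assert 0 <= h <= np.log((p > 0).sum()) + 1e-12

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_entropy(np.zeros(5))


class TestLineageLinks:
    def test_two_clusters_single_significant_link(self):
        from crosstage import qc, synthio
        from crosstage.cluster import cluster_cells

        cfg = synthio.SynthConfig(
            seed=21, n_genes=150, n_cells_per_stage=120, n_clusters_stage_a=2,
            shared_clusters=(),
        )
        mat, _, _ = synthio.generate_stage_pair(cfg)
        tcm, _ = qc.run_qc(mat.counts.astype(float), qc.QcConfig(mintotal=1.0))
        model = cluster_cells(tcm, k_max=4)
        graph = infer_lineage_links(model, tcm)
        assert len(graph.edges) == 1
        assert graph.edges.iloc[0]["pval"] < graph.pthr
        assert graph.edges.iloc[0]["significant"]

    def test_collinear_chain_topology(self, chain_dataset):
        """Three clusters along a gradient: terminal link not significant."""
        cfg, tcm, truth, model = chain_dataset
        graph = infer_lineage_links(model, tcm)
        conv = {
            c: truth.labels_a[model.labels.index[model.labels == c]].mode().iloc[0]
            for c in model.labels.unique()
        }
        sig = {
            frozenset((conv[r.cluster_a], conv[r.cluster_b]))
            for r in graph.edges.itertuples()
            if r.significant
        }
        assert frozenset((0, 1)) in sig
        assert frozenset((1, 2)) in sig
        assert frozenset((0, 2)) not in sig

    def test_small_clusters_excluded_by_cthr(self, chain_dataset):
        _, tcm, _, model = chain_dataset
        graph = infer_lineage_links(model, tcm)
        assert set(graph.nodes["cluster"]) == set(model.eligible_clusters())
        sizes = model.labels.value_counts()
        assert (graph.nodes.set_index("cluster")["size"] >= model.cthr).all()

    def test_scores_and_pvalues_in_range(self, chain_dataset):
        _, tcm, _, model = chain_dataset
        graph = infer_lineage_links(model, tcm)
        assert graph.edges["score"].between(0, 1).all()
        assert ((graph.edges["pval"] > 0) & (graph.edges["pval"] <= 1)).all()


class TestPseudotime:
    def test_gradient_gene_order_recovered(self, chain_dataset):
        cfg, tcm, truth, model = chain_dataset
        conv = {
            truth.labels_a[model.labels.index[model.labels == c]].mode().iloc[0]: c
            for c in model.labels.unique()
        }
        chain = [conv[c] for c in cfg.trajectory_chain]
        res = pseudotime_order(tcm, chain, model)
        rc = stats.spearmanr(
            res.pseudotime.values, truth.pseudotime[res.cell_order].values
        )[0]
        assert rc >= 0.9

    def test_constant_gene_flat_profile(self, chain_dataset):
        cfg, tcm, truth, model = chain_dataset
        chain = sorted(model.medoids)
        flat = tcm.counts.iloc[[0]].copy() * 0 + 5.0
        tcm2 = type(tcm)(
            counts=pd.concat([tcm.counts, flat.rename(index={flat.index[0]: "FLAT"})]),
            pre_filter_totals=tcm.pre_filter_totals,
            reference_total=tcm.reference_total,
            feature_genes=tcm.feature_genes,
        )
        res = pseudotime_order(tcm2, chain, model, genes=["FLAT"])
        prof = res.smoothed.loc["FLAT"].values
        assert prof.max() - prof.min() < 1e-6 * abs(prof.mean())

    def test_chain_reversal_reverses_order(self, chain_dataset):
        cfg, tcm, truth, model = chain_dataset
        chain = sorted(model.medoids)
        fwd = pseudotime_order(tcm, chain, model, genes=tcm.feature_genes[:5])
        rev = pseudotime_order(
            tcm, chain[::-1], model, genes=tcm.feature_genes[:5]
        )
        assert fwd.cell_order == rev.cell_order[::-1]

    def test_empty_chain_rejected(self, chain_dataset):
        _, tcm, _, model = chain_dataset
        with pytest.raises(ValueError):
            pseudotime_order(tcm, [], model)


class TestLoess:
    def test_recovers_smooth_trend(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 200)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, 200)
        sm = loess_smooth(y, x, span=0.3)
        assert np.corrcoef(sm, np.sin(2 * np.pi * x))[0, 1] > 0.98

    def test_constant_input_constant_output(self):
        sm = loess_smooth(np.full(50, 3.0))
        assert np.allclose(sm, 3.0)


class TestSomModules:
    def _two_wave_profiles(self, n_early=20, n_late=20, n_pos=100, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, n_pos)
        early = np.stack([-t + rng.normal(0, noise, n_pos) for _ in range(n_early)])
        late = np.stack([t + rng.normal(0, noise, n_pos) for _ in range(n_late)])
        genes = [f"e{i}" for i in range(n_early)] + [f"l{i}" for i in range(n_late)]
        return pd.DataFrame(np.vstack([early, late]), index=genes)

    def test_two_antagonistic_waves_give_two_pure_modules(self):
        prof = self._two_wave_profiles()
        mods = som_modules(prof, n_epochs=200, random_state=0)
        assert mods["module"].nunique() == 2
        truth = pd.Series(
            ["early"] * 20 + ["late"] * 20, index=prof.index
        )
        purity = mods.groupby("module").apply(
            lambda d: truth[d.index].value_counts().max() / len(d)
        )
        assert (purity >= 0.95).all()

    def test_duplicated_genes_same_structure(self):
        prof = self._two_wave_profiles(n_early=10, n_late=10)
        doubled = pd.concat(
            [prof, prof.rename(index=lambda g: g + "_dup")]
        )
        m1 = som_modules(prof, n_epochs=100, random_state=0)
        m2 = som_modules(doubled, n_epochs=100, random_state=0)
        assert m2["module"].nunique() == m1["module"].nunique()
        for g in prof.index:
            assert m2.loc[g, "module"] == m2.loc[g + "_dup", "module"]

    def test_single_gene_single_module(self):
        prof = pd.DataFrame([np.sin(np.linspace(0, 3, 50))], index=["g"])
        mods = som_modules(prof)
        assert mods["module"].tolist() == [0]

    def test_all_constant_rejected(self):
        prof = pd.DataFrame(np.ones((3, 30)))
        with pytest.raises(ValueError):
            som_modules(prof)

    def test_seeded_determinism(self):
        prof = self._two_wave_profiles(seed=3)
        m1 = som_modules(prof, n_epochs=50, random_state=7)
        m2 = som_modules(prof, n_epochs=50, random_state=7)
        assert m1.equals(m2)

    def test_module_count_non_increasing_in_merge_threshold(self):
        prof = self._two_wave_profiles(seed=4)
        counts = [
            som_modules(prof, n_epochs=100, merge_correlation=thr)["module"].nunique()
            for thr in (0.95, 0.85, 0.5)
        ]
        assert counts[0] >= counts[1] >= counts[2]


def test_zscore_profiles_normalized(chain_dataset):
    cfg, tcm, truth, model = chain_dataset
    chain = sorted(model.medoids)
    res = pseudotime_order(tcm, chain, model, genes=tcm.feature_genes[:20])
    Z = zscore_profiles(res.smoothed).values
    keep = res.smoothed.values.std(axis=1) > 0
    assert np.allclose(Z[keep].mean(axis=1), 0, atol=1e-6)
    assert np.allclose(Z[keep].std(axis=1), 1, atol=1e-6)
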