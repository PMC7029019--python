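"""Unit tests for multi-block sparse discriminant integration."""

import numpy as np
import pandas as pd
import pytest

from ifomics.diablo import DIABLO, cim_order, full_design, tune_keepx
from ifomics.plsda import plsda_fit
from ifomics.synth import SynthConfig, generate_study


def shared_latent_blocks(seed, n=20, p1=12, p2=10, loading=2.0, sep=3.0):
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    u = (y == "b") * sep + rng.normal(size=n)
    mk = lambda p: np.column_stack(
        [u * loading + rng.normal(size=n) if j < 5 else rng.normal(size=n)
         for j in range(p)])
    return {"one": mk(p1), "two": mk(p2)}, y


class TestFit:
    def test_reduction_to_plsda(self, rng):
        X = rng.normal(size=(16, 10))
        y = np.array(["a"] * 8 + ["b"] * 8)
        fit = DIABLO({"x": X}, y).fit(keepx=10, n_components=1)
        pls = plsda_fit(X, y, n_components=1)
        assert np.abs(fit.weights["x"][:, 0] - pls.weights[:, 0]).max() < 1e-8

    def test_exact_sparsity_per_component(self, rng):
        blocks, y = shared_latent_blocks(1)
        fit = DIABLO(blocks, y).fit(keepx={"one": 4, "two": 7},
                                    n_components=2)
        for b, k in (("one", 4), ("two", 7)):
            for comp in range(2):
                assert int((fit.weights[b][:, comp] != 0).sum()) == k

    def test_deflation_orthogonal_scores(self):
        blocks, y = shared_latent_blocks(2)
        fit = DIABLO(blocks, y).fit(keepx=5, n_components=2)
        for b in blocks:
            t = fit.scores[b]
            assert abs(t[:, 0] @ t[:, 1]) < 1e-8

    def test_shared_latent_factor_recovered(self):
        hits = 0
        for seed in range(3):
            blocks, y = shared_latent_blocks(10 + seed)
            fit = DIABLO(blocks, y).fit(keepx=5, n_components=1)
            r = fit.component_correlations().loc["one", "two"]
            hits += r >= 0.8
        assert hits >= 2

    def test_design_validation_and_keepx_bounds(self, rng):
        blocks, y = shared_latent_blocks(3)
        bad = full_design(["one", "two"])
        bad.iloc[0, 1] = 2.0
        with pytest.raises(ValueError):
            DIABLO(blocks, y, design=bad)
        with pytest.raises(ValueError):
            DIABLO(blocks, y).fit(keepx={"one": 0, "two": 5})

    def test_misaligned_blocks_error(self, rng):
        with pytest.raises(ValueError):
            DIABLO({"a": rng.normal(size=(10, 3)),
                    "b": rng.normal(size=(9, 3))}, ["x"] * 5 + ["y"] * 5)


class TestPredict:
    def test_training_votes_and_recount(self):
        blocks, y = shared_latent_blocks(4, loading=4.0, sep=8.0)
        fit = DIABLO(blocks, y).fit(keepx=5, n_components=1)
        pred, per_block = fit.predict(blocks)
        assert (pred == y).mean() == 1.0
        # majority recount oracle
        for i in range(len(y)):
            votes = per_block.iloc[i].to_numpy()
            vals, counts = np.unique(votes, return_counts=True)
            if counts.max() > len(votes) / 2:
                assert pred[i] == vals[np.argmax(counts)]

    def test_missing_block_errors(self):
        blocks, y = shared_latent_blocks(5)
        fit = DIABLO(blocks, y).fit(keepx=3)
        with pytest.raises(ValueError, match="missing"):
            fit.predict({"one": blocks["one"]})


class TestComponentCorrelations:
    def test_duplicated_block_perfectly_correlated(self, rng):
        X = rng.normal(size=(14, 6))
        y = np.array(["a"] * 7 + ["b"] * 7)
        fit = DIABLO({"x": X, "copy": X.copy()}, y).fit(keepx=6)
        assert fit.component_correlations().loc["x", "copy"] == pytest.approx(
            1.0, abs=1e-8)

    def test_matches_recomputation_from_scores(self):
        blocks, y = shared_latent_blocks(6)
        fit = DIABLO(blocks, y).fit(keepx=5)
        r = fit.component_correlations().loc["one", "two"]
        oracle = np.corrcoef(fit.scores["one"][:, 0],
                             fit.scores["two"][:, 0])[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)


class TestCircosLinks:
    def test_threshold_one_keeps_only_collinear(self, rng):
        X = rng.normal(size=(15, 3))
        Y2 = np.column_stack([X[:, 0], rng.normal(size=15)])
        y = np.array(["a"] * 7 + ["b"] * 8)
        fit = DIABLO({"p": X, "q": Y2}, y).fit(keepx={"p": 3, "q": 2})
        links = fit.circos_links(r_threshold=1.0)
        for _, e in links.iterrows():
            assert abs(e.r) == pytest.approx(1.0, abs=1e-10)

    def test_edge_count_monotone_in_threshold(self):
        blocks, y = shared_latent_blocks(7)
        fit = DIABLO(blocks, y).fit(keepx=5)
        counts = [len(fit.circos_links(t)) for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_shared_loading_features_linked_positive(self):
        hits = 0
        for seed in range(5):
            blocks, y = shared_latent_blocks(20 + seed, loading=2.0)
            fit = DIABLO(blocks, y).fit(keepx=5)
            links = fit.circos_links(0.7)
            hits += ((links.sign == "positive") & links.r.ge(0.7)).any()
        assert hits >= 4

    def test_threshold_validation(self):
        blocks, y = shared_latent_blocks(8)
        fit = DIABLO(blocks, y).fit(keepx=3)
        with pytest.raises(ValueError):
            fit.circos_links(0.0)


class TestTuneKeepx:
    def test_single_value_grid_returned(self):
        blocks, y = shared_latent_blocks(9)
        out = tune_keepx(blocks, y, grid=[4], folds=4, seed=0)
        assert out == {"one": 4, "two": 4}

    def test_recovers_planted_cardinality(self):
        """With 5 informative features per block (independent moderate
        shifts, so extra features genuinely help), the planted cardinality
        is the modal keepX selection pooled over blocks and seeds."""
        from collections import Counter

        def indep_blocks(seed, n=60, delta=0.6):
            r = np.random.default_rng(seed)
            y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
            b = (y == "b").astype(float)
            mk = lambda p: np.column_stack(
                [b * delta + r.normal(size=n) if j < 5
                 else r.normal(size=n) for j in range(p)])
            return {"one": mk(12), "two": mk(10)}, y

        selections = []
        for seed in range(5):
            blocks, y = indep_blocks(seed)
            out = tune_keepx(blocks, y, grid=[2, 5, 9], folds=10, seed=seed)
            selections += list(out.values())
        assert Counter(selections).most_common(1)[0][0] == 5

    def test_empty_grid_errors(self):
        blocks, y = shared_latent_blocks(10)
        with pytest.raises(ValueError):
            tune_keepx(blocks, y, grid=[])


class TestCimOrder:
    def test_identical_rows_adjacent(self, rng):
        X = rng.normal(size=(5, 4))
        X[3] = X[0]
        rows, cols, _, _ = cim_order(pd.DataFrame(X))
        pos = {r: i for i, r in enumerate(rows)}
        assert abs(pos[0] - pos[3]) == 1

    def test_block_structure_contiguous(self, rng):
        a = rng.normal(0, 0.2, size=(4, 6))
        b = rng.normal(8, 0.2, size=(4, 6))
        X = pd.DataFrame(np.vstack([a, b]))
        rows, _, _, _ = cim_order(X)
        first_half = {0, 1, 2, 3}
        order_sets = [set(rows[:4]), set(rows[4:])]
        assert first_half in order_sets

    def test_merge_heights_match_brute_force(self, rng):
        """Complete-linkage merge heights on a 5x4 toy equal a hand-rolled
        agglomeration."""
        X = rng.normal(size=(5, 4))
        _, _, link, _ = cim_order(pd.DataFrame(X))

        # brute-force complete linkage
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        clusters = {i: [i] for i in range(5)}
        heights = []
        while len(clusters) > 1:
            best = None
            for i in clusters:
                for j in clusters:
                    if i < j:
                        h = max(d[a, b] for a in clusters[i]
                                for b in clusters[j])
                        if best is None or h < best[0]:
                            best = (h, i, j)
            h, i, j = best
            heights.append(h)
            clusters[i] = clusters[i] + clusters.pop(j)
        np.testing.assert_allclose(sorted(link[:, 2]), sorted(heights),
                                   atol=1e-12)

    def test_too_small_matrix_errors(self):
        with pytest.raises(ValueError):
            cim_order(pd.DataFrame([[1.0, 2.0]]))


class TestOnSyntheticStudy:
    def test_selected_features_mostly_planted(self):
        from ifomics.preprocess import autoscale, clr_transform
        study = generate_study(SynthConfig(seed=33, n_informative_taxa=10))
        y = study.group.to_numpy()
        blocks = {
            "genes": autoscale(study.gene_block).values,
            "otus": autoscale(clr_transform(study.otu_block).values.T).values,
            "metabolites": autoscale(
                np.log(study.metabolite_block)).values,
        }
        fit = DIABLO(blocks, y).fit(keepx=10)
        overlap = len(set(fit.selected["genes"])
                      & set(study.truth["informative_genes"]))
        assert overlap >= 8
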