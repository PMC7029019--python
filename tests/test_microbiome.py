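"""Unit tests for diversity, ordination, permutation tests and ANCOM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ifomics.microbiome import (DistanceMatrix, ancom_w, bray_curtis,
                                cap_partial, clr_phenotype_correlations,
                                observed_richness, pcoa, permanova)
from ifomics.preprocess import CountTable, clr_transform


def make_table(counts):
    counts = np.asarray(counts)
    return CountTable([f"t{i + 1}" for i in range(counts.shape[0])],
                      [f"s{j + 1}" for j in range(counts.shape[1])], counts)


class TestRichness:
    def test_counts_positive_taxa(self):
        t = make_table(np.array([[3, 0], [0, 0], [1, 0], [0, 0]]))
        rich = observed_richness(t)
        assert rich["s1"] == 2
        assert rich["s2"] == 0


class TestBrayCurtis:
    def test_identical_and_disjoint_and_half(self):
        X = np.array([[1.0, 1.0, 0.0],
                      [1.0, 1.0, 0.0],
                      [0.0, 1.0, 1.0],
                      [2.0, 0.0, 0.0]])
        dm = bray_curtis(X, sample_ids=list("abcd"))
        assert dm.data[0, 1] == pytest.approx(0.0)
        # x=[1,1,0] vs y=[0,1,1]: 1 - 2*1/4 = 0.5
        assert dm.data[0, 2] == pytest.approx(0.5)
        # disjoint supports -> 1
        assert dm.data[2, 3] == pytest.approx(1.0)

    def test_bounds_symmetry_zero_diagonal(self, rng):
        X = rng.random((10, 6))
        dm = bray_curtis(X)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(dm.data), 0.0)

    def test_all_zero_sample_named_in_error(self):
        X = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zz"):
            bray_curtis(X, sample_ids=["ok", "zz"])

    def test_matches_scikit_bio(self, rng):
        skbio_dist = pytest.importorskip("skbio.diversity")
        X = rng.integers(0, 50, (6, 8))
        X[:, 0] += 1
        ours = bray_curtis(X.astype(float)).data
        theirs = skbio_dist.beta_diversity(
            "braycurtis", X, ids=[str(i) for i in range(6)]).data
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        d = np.array([[0.0, 1.0, 3.0],
                      [1.0, 0.0, 2.0],
                      [3.0, 2.0, 0.0]])
        res = pcoa(DistanceMatrix(list("abc"), d))
        x = res.coordinates.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(abs(x[0] - x[1]), 1.0, atol=1e-8)
        np.testing.assert_allclose(abs(x[0] - x[2]), 3.0, atol=1e-8)
        assert res.coordinates.shape[1] == 1  # second eigenvalue ~ 0

    def test_duplicate_samples_identical_coordinates(self):
        d = np.array([[0.0, 0.0, 1.0],
                      [0.0, 0.0, 1.0],
                      [1.0, 1.0, 0.0]])
        res = pcoa(DistanceMatrix(list("abc"), d))
        np.testing.assert_allclose(res.coordinates.loc["a"],
                                   res.coordinates.loc["b"], atol=1e-10)

    def test_non_euclidean_negative_eigenvalues_reported(self):
        d = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 1, (0, 2): 1, (0, 3): 1, (1, 2): 1.9,
                          (1, 3): 1.9, (2, 3): 1.9}.items():
            d[i, j] = d[j, i] = v
        res = pcoa(DistanceMatrix(list("abcd"), d))
        assert len(res.negative_eigenvalues) > 0

    def test_matches_scikit_bio_eigenvalues(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = pcoa(DistanceMatrix([str(i) for i in range(7)], d))
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d, ids=[str(i) for i in range(7)]))
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[:len(ours.eigenvalues)],
            atol=1e-8)


class TestPermanova:
    def test_equidistant_samples_give_p_one(self):
        n = 6
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix([str(i) for i in range(n)], d)
        res = permanova(dm, ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_clouds_reject(self, rng):
        for i in range(5):
            r = np.random.default_rng(100 + i)
            pts = np.vstack([r.normal(0, 1, (10, 3)),
                             r.normal(5, 1, (10, 3))])
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix([str(k) for k in range(20)], d)
            res = permanova(dm, ["a"] * 10 + ["b"] * 10,
                            n_permutations=199, seed=i)
            assert res.p_value <= 0.01

    def test_statistic_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        pts = rng.normal(size=(12, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [str(i) for i in range(12)]
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(DistanceMatrix(ids, d), groups,
                         n_permutations=99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(d, ids=ids),
                              grouping=groups, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"],
                                              abs=1e-10)

    def test_seed_determinism_and_validation(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([str(i) for i in range(8)], d)
        g = ["a"] * 4 + ["b"] * 4
        assert permanova(dm, g, 99, seed=7).p_value == permanova(
            dm, g, 99, seed=7).p_value
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 8, 99)


class TestCapPartial:
    @staticmethod
    def _dist_from(X):
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        return DistanceMatrix([f"s{i}" for i in range(X.shape[0])], d)

    def test_constraint_identical_to_condition_fully_partialled(self, rng):
        n = 16
        g = np.array(["a", "b"] * (n // 2))
        X = rng.normal(size=(n, 4)) + 2.0 * (g == "b")[:, None]
        dm = self._dist_from(X)
        fac = pd.DataFrame({"g": g}, index=dm.sample_ids)
        res = cap_partial(dm, fac, condition=fac.rename(columns={"g": "c"}),
                          n_permutations=49, seed=0)
        assert res.constrained == pytest.approx(0.0, abs=1e-8)

    def test_inertia_decomposition_sums_to_one(self, study):
        from ifomics.preprocess import css_normalize
        dm = None
        css = css_normalize(study.otu_block)
        from ifomics.microbiome import bray_curtis
        dm = bray_curtis(css.values.T)
        res = cap_partial(dm, study.metadata[["group"]],
                          study.metadata[["timepoint"]].astype(float),
                          n_permutations=49, seed=0)
        total = res.constrained + res.conditioned + res.residual
        assert total == pytest.approx(1.0, abs=1e-8)
        assert 0 <= res.term_variance["group"] <= 1

    def test_conditioning_on_orthogonal_time_preserves_group_variance(self):
        """Planted group shift with an orthogonal time shift: conditioning
        on time leaves the group variance fraction within 20% of a
        no-time-simulation baseline."""
        from ifomics.synth import SynthConfig, generate_study
        fracs = {"with": [], "without": []}
        for i in range(5):
            with_time = generate_study(SynthConfig(seed=700 + i))
            no_time = generate_study(SynthConfig(seed=700 + i,
                                                 time_shift=1e-12))
            for tag, s in (("with", with_time), ("without", no_time)):
                from ifomics.preprocess import css_normalize
                from ifomics.microbiome import bray_curtis
                dm = bray_curtis(css_normalize(s.otu_block).values.T)
                cond = (s.metadata[["timepoint"]].astype(float)
                        if tag == "with" else None)
                res = cap_partial(dm, s.metadata[["group"]], cond,
                                  n_permutations=19, seed=i)
                fracs[tag].append(res.term_variance["group"])
        a, b = np.mean(fracs["with"]), np.mean(fracs["without"])
        assert abs(a - b) / b <= 0.20

    def test_rank_deficient_constraints_error(self, rng):
        n = 12
        X = rng.normal(size=(n, 3))
        dm = self._dist_from(X)
        g = np.array(["a", "b"] * (n // 2))
        dup = pd.DataFrame({"g1": g, "g2": g}, index=dm.sample_ids)
        with pytest.raises(ValueError, match="rank"):
            cap_partial(dm, dup, n_permutations=9)

    def test_null_pvalues_roughly_uniform(self):
        """Random labels: permutation p over repeated nulls is uniform
        (KS p > 0.01)."""
        rng = np.random.default_rng(42)
        pvals = []
        for i in range(100):
            X = rng.normal(size=(16, 4))
            dm = self._dist_from(X)
            g = rng.permutation(np.array(["a", "b"] * 8))
            res = cap_partial(dm, pd.DataFrame({"g": g}, index=dm.sample_ids),
                              n_permutations=49, seed=i)
            pvals.append(res.term_p["g"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAncom:
    def test_three_taxon_constructed_case(self):
        """Taxon 1 differs from both others -> W = [2, <=1, <=1]."""
        n = 10
        jitter = np.arange(2 * n) % 5  # deterministic within-group variation
        taxon1 = np.r_[100 + jitter[:n], 1600 + jitter[n:]]
        base = np.vstack([taxon1, np.full(2 * n, 100), np.full(2 * n, 100)])
        t = make_table(base)
        res = ancom_w(t, ["a"] * n + ["b"] * n)
        assert res.w[0] == 2
        assert res.w[1] <= 1 and res.w[2] <= 1

    def test_requires_three_taxa_and_two_groups(self):
        t = make_table(np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValueError):
            ancom_w(t, ["a", "b"])
        t3 = make_table(np.array([[1, 2], [3, 4], [5, 6]]))
        with pytest.raises(ValueError):
            ancom_w(t3, ["a", "a"])


class TestClrPhenotypeCorrelations:
    def test_identity_phenotype_gives_r_one(self, rng):
        counts = rng.integers(1, 100, size=(5, 8))
        t = make_table(counts)
        clr = clr_transform(t)
        ph = pd.DataFrame({"x": clr.values.loc["t1"]},
                          index=clr.values.columns)
        out = clr_phenotype_correlations(clr, ph)
        row = out[(out.taxon == "t1") & (out.phenotype == "x")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p < 1e-6

    def test_matches_brute_force_pearson(self, rng):
        vals = pd.DataFrame(rng.normal(size=(5, 4)),
                            index=[f"t{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(4)])
        ph = pd.DataFrame({"y": rng.normal(size=4)}, index=vals.columns)
        out = clr_phenotype_correlations(vals, ph)
        for _, row in out.iterrows():
            x = vals.loc[row.taxon].to_numpy()
            y = ph["y"].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r_oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert row.r == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_phenotype_errors(self, rng):
        vals = pd.DataFrame(rng.normal(size=(3, 4)),
                            columns=[f"s{j}" for j in range(4)])
        ph = pd.DataFrame({"y": np.ones(4)}, index=vals.columns)
        with pytest.raises(ValueError, match="y"):
            clr_phenotype_correlations(vals, ph)
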