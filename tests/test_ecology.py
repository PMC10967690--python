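import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from intersoil import InvariantError, NMDS, OtuTable, alpha_diversity, \
    anosim, bray_curtis, nmds, rda, relative_abundance, variation_partition, \
    vif_screen
from intersoil.ecology import hellinger


def _otu(counts: np.ndarray, prefix="s") -> OtuTable:
    n_s, n_o = counts.shape
    cols = [f"OTU{i}" for i in range(n_o)]
    tax = {c: f"k__B;p__Phy{i % 6}" for i, c in enumerate(cols)}
    return OtuTable(pd.DataFrame(counts,
                                 index=[f"{prefix}{j}" for j in range(n_s)],
                                 columns=cols), tax)


class TestRelativeAbundance:
    def test_two_phyla_fractions(self):
        counts = np.array([[30, 70]])
        otu = _otu(counts)
        ra = relative_abundance(otu, "phylum", min_frac=0.0)
        assert ra.iloc[0].tolist() == pytest.approx([0.3, 0.7])

    def test_lumping_matches_brute_force(self, rng):
        counts = rng.integers(0, 40, size=(12, 60))
        counts[0, 0] += 1  # guard against an all-zero sample
        otu = _otu(counts)
        ra = relative_abundance(otu, "phylum", min_frac=0.15)
        # brute-force oracle: aggregate then filter on the mean
        rel = counts / counts.sum(axis=1, keepdims=True)
        agg = {}
        for i in range(60):
            agg.setdefault(f"Phy{i % 6}", np.zeros(12))
            agg[f"Phy{i % 6}"] += rel[:, i]
        kept = {k for k, v in agg.items() if v.mean() >= 0.15}
        assert set(ra.columns) - {"others"} == kept
        np.testing.assert_allclose(ra.sum(axis=1), 1.0, atol=1e-9)


class TestAlphaDiversity:
    def test_uniform_community_closed_form(self):
        otu = _otu(np.full((1, 16), 5))
        assert alpha_diversity(otu, "shannon").iloc[0] == \
            pytest.approx(np.log(16))
        assert alpha_diversity(otu, "richness").iloc[0] == 16

    def test_single_otu(self):
        otu = _otu(np.array([[9, 0, 0]]))
        assert alpha_diversity(otu, "shannon").iloc[0] == 0.0
        assert alpha_diversity(otu, "richness").iloc[0] == 1

    def test_chao1_singleton_doubleton_formula(self):
        # S_obs=20 with f1=4 singletons, f2=2 doubletons -> 20 + 16/4 = 24
        row = np.r_[np.ones(4), np.full(2, 2), np.full(14, 5), np.zeros(3)]
        otu = _otu(row[None, :].astype(int))
        assert alpha_diversity(otu, "chao1").iloc[0] == pytest.approx(24.0)


class TestBrayCurtis:
    def test_trivial_values(self):
        counts = np.array([[3, 0, 1], [1, 2, 1], [3, 0, 1], [0, 5, 0]])
        dm = bray_curtis(_otu(counts))
        assert dm[0, 1] == pytest.approx(0.5)   # (2+2+0)/(4+2+2)
        assert dm[0, 2] == 0.0                   # identical
        assert dm[0, 3] == 1.0                   # disjoint support

    def test_scale_and_column_permutation_invariance(self, rng):
        counts = rng.integers(1, 50, size=(6, 10))
        dm = bray_curtis(_otu(counts))
        np.testing.assert_allclose(bray_curtis(_otu(counts * 7)).data,
                                   dm.data, atol=1e-12)
        perm = rng.permutation(10)
        np.testing.assert_allclose(bray_curtis(_otu(counts[:, perm])).data,
                                   dm.data, atol=1e-12)

    def test_two_zero_samples_rejected(self):
        counts = np.array([[0, 0], [0, 0], [1, 2]])
        with pytest.raises(InvariantError, match="all-zero"):
            bray_curtis(_otu(counts))


class TestNmds:
    def test_perfect_line_embeds_exactly(self):
        pts = np.column_stack([np.arange(8.0), np.zeros(8)])
        D = squareform(pdist(pts))
        model = nmds(D, seed=0)
        assert model.stress_ < 1e-3

    def test_determinism_under_seed(self, rng):
        D = squareform(pdist(rng.uniform(size=(9, 4))))
        a = NMDS(random_state=3, n_restarts=5).fit(D)
        b = NMDS(random_state=3, n_restarts=5).fit(D)
        np.testing.assert_array_equal(a.embedding_, b.embedding_)
        assert a.stress_ == b.stress_

    def test_stress_history_non_increasing(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            D = squareform(pdist(r.uniform(size=(10, 3))))
            model = NMDS(random_state=seed, n_restarts=3).fit(D)
            hist = np.array(model.stress_history_)
            assert (np.diff(hist) <= 1e-12).all()

    def test_higher_dimension_no_worse_than_planar(self, rng):
        D = squareform(pdist(rng.uniform(size=(8, 5))))
        s_high = NMDS(n_components=6, random_state=0).fit(D).stress_
        s_2d = NMDS(n_components=2, random_state=0).fit(D).stress_
        assert s_high <= s_2d + 1e-9


class TestAnosim:
    def test_separated_clusters_give_r_one(self, rng):
        a = rng.normal(0, 0.01, size=(4, 6)) + 1.0
        b = rng.normal(0, 0.01, size=(4, 6)) + 50.0
        dm = bray_curtis(_otu(np.abs(np.r_[a, b] * 100).astype(int)))
        res = anosim(dm, ["A"] * 4 + ["B"] * 4, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_small_n(self, rng):
        counts = rng.integers(1, 60, size=(6, 12))
        dm = bray_curtis(_otu(counts))
        groups = ["A", "A", "A", "B", "B", "B"]
        res = anosim(dm, groups, exact=True)
        assert res.n_permutations == 20
        # oracle: enumerate the 20 label placements directly
        ranks = None
        from scipy.stats import rankdata
        iu = np.triu_indices(6, 1)
        ranks = rankdata(dm.data[iu])
        m = ranks.size

        def r_stat(lab):
            lab = np.asarray(lab)
            same = lab[iu[0]] == lab[iu[1]]
            return (ranks[~same].mean() - ranks[same].mean()) / (m / 2)

        obs = r_stat(groups)
        rs = [r_stat(p) for p in set(itertools.permutations(groups))]
        expect = sum(r >= obs - 1e-12 for r in rs) / len(rs)
        assert res.p_value == pytest.approx(expect)

    def test_matches_skbio_r_statistic(self, rng):
        counts = rng.integers(1, 60, size=(12, 20))
        dm = bray_curtis(_otu(counts))
        groups = ["A", "B", "C"] * 4
        ours = anosim(dm, groups, n_permutations=999, seed=1)
        theirs = skbio_anosim(DistanceMatrix(dm.data, dm.ids), groups,
                              permutations=0)
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_rank_based_invariance_to_monotone_transform(self, rng):
        counts = rng.integers(1, 60, size=(9, 15))
        dm = bray_curtis(_otu(counts))
        groups = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
        r1 = anosim(dm, groups, n_permutations=0, seed=0).r
        transformed = DistanceMatrix(np.sqrt(dm.data), dm.ids)
        r2 = anosim(transformed, groups, n_permutations=0, seed=0).r
        assert r1 == pytest.approx(r2)


class TestVif:
    def test_orthogonal_variables_untouched(self):
        n = 40
        t = np.arange(n)
        X = pd.DataFrame({"a": np.sin(t), "b": np.cos(t),
                          "c": np.sin(2 * t)})
        rep = vif_screen(X, cutoff=10)
        assert rep.dropped == []
        assert (rep.rounds[0] < 1.2).all()

    def test_near_duplicate_removed(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"x1": x, "x2": x + rng.normal(scale=1e-6, size=50),
                          "y": rng.normal(size=50)})
        rep = vif_screen(X, cutoff=10)
        assert len(rep.dropped) == 1
        assert rep.dropped[0] in {"x1", "x2"}

    def test_perfect_duplicate_dropped_first_with_warning(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x1": x, "x2": x.copy(), "y": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="collinear"):
            rep = vif_screen(X, cutoff=10)
        assert rep.dropped[0] in {"x1", "x2"}
        assert set(rep.retained) >= {"y"}

    def test_matches_least_squares_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        X["b"] += 0.8 * X["a"]
        rep = vif_screen(X, cutoff=1e9)
        from numpy.linalg import lstsq
        for i, name in enumerate(X.columns):
            y = X[name].to_numpy()
            others = X.drop(columns=[name]).to_numpy()
            design = np.column_stack([np.ones(30), others])
            beta = lstsq(design, y, rcond=None)[0]
            r2 = 1 - ((y - design @ beta) ** 2).sum() / \
                ((y - y.mean()) ** 2).sum()
            assert rep.rounds[0][name] == pytest.approx(1 / (1 - r2))


class TestRda:
    def test_perfect_fit_concentrates_first_axis(self, rng):
        env = pd.DataFrame({"a": rng.normal(size=20)})
        Y = pd.DataFrame(np.outer(env["a"], [2.0, -1.0, 0.5]) + 10)
        res = rda(Y, env, hellinger_transform=False, n_permutations=0)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-9)
        assert res.axis_fractions[0] / res.constrained_fraction > 0.99

    def test_variance_decomposition_identity(self, rng):
        env = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.uniform(0.1, 1.0, size=(25, 8)))
        res = rda(Y, env, n_permutations=0)
        assert res.total_variance == pytest.approx(
            res.constrained_variance + res.unconstrained_variance, abs=1e-9)
        assert (np.diff(res.axis_fractions) <= 1e-12).all()

    def test_too_many_env_variables_rejected(self, rng):
        env = pd.DataFrame(rng.normal(size=(4, 5)))
        Y = pd.DataFrame(rng.uniform(0.1, 1, size=(4, 3)))
        with pytest.raises(InvariantError, match="n-1"):
            rda(Y, env)

    def test_hellinger_rows(self, rng):
        Y = pd.DataFrame(rng.integers(1, 30, size=(5, 4)).astype(float))
        H = hellinger(Y)
        np.testing.assert_allclose((H ** 2).sum(axis=1), 1.0)


class TestVariationPartition:
    def test_identical_sets_all_shared(self, rng):
        env = pd.DataFrame({"a": rng.normal(size=20)})
        Y = pd.DataFrame(np.outer(env["a"], [1.0, 2.0]) +
                         rng.normal(scale=0.1, size=(20, 2)) + 10)
        twin = env.rename(columns={"a": "a2"})
        vp = variation_partition(Y, {"e1": env, "e2": twin},
                                 hellinger_transform=False)
        # adjusted R2 penalizes the redundant predictor, so "unique"
        # fractions are only approximately zero
        assert vp.fractions["e1_unique"] == pytest.approx(0.0, abs=0.01)
        assert vp.fractions["shared"] == pytest.approx(vp.total_adjusted,
                                                       abs=0.01)

    def test_orthogonal_drivers_no_overlap(self):
        n = 60
        t = np.arange(n)
        e1 = pd.DataFrame({"a": np.sin(t)})
        e2 = pd.DataFrame({"b": np.cos(t)})
        Y = pd.DataFrame({"y1": 3 * np.sin(t) + 10, "y2": 2 * np.cos(t) + 10})
        vp = variation_partition(Y, {"e1": e1, "e2": e2},
                                 hellinger_transform=False)
        assert abs(vp.fractions["shared"]) < 0.05
        assert vp.fractions["e1_unique"] > 0.2

    def test_fractions_sum_to_total(self, rng):
        Y = pd.DataFrame(rng.uniform(0.1, 1, size=(30, 5)))
        groups = {"g1": pd.DataFrame(rng.normal(size=(30, 2)),
                                     columns=["a", "b"]),
                  "g2": pd.DataFrame(rng.normal(size=(30, 1)),
                                     columns=["c"]),
                  "g3": pd.DataFrame(rng.normal(size=(30, 1)),
                                     columns=["d"])}
        for g in groups.values():
            g.index = Y.index
        vp = variation_partition(Y, groups)
        assert sum(vp.fractions.values()) == pytest.approx(
            vp.total_adjusted, abs=1e-9)
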