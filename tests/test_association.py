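import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from litterlink.association import (
    Bicluster,
    classify_dependency,
    hierarchical_clusters,
    link_clusters,
    plaid_biclustering,
    select_top_biclusters,
    spearman_matrix,
    spearman_screen,
)
from litterlink.config import PipelineConfig
from litterlink.screening import LitterMatrix


def litter(values, features=None, dams=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    dams = dams or [f"d{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=dams)
    return LitterMatrix(df, pd.Series(2, index=df.columns))


def naive_spearman(x, y):
    """Rank-by-sorting oracle, independent of scipy's rankdata."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


class TestSpearmanScreen:
    def test_monotone_pair_retained(self):
        f = litter([[1, 2, 3, 4, 5, 6]])
        g = litter([[10, 20, 25, 40, 55, 80]], features=["g0"])
        out = spearman_screen(f, g, 0.9, use_absolute=True)
        assert len(out) == 1
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_anticorrelated_needs_absolute(self):
        f = litter([[1, 2, 3, 4, 5, 6]])
        g = litter([[6, 5, 4, 3, 2, 1]], features=["g0"])
        assert len(spearman_screen(f, g, 0.9, use_absolute=True)) == 1
        assert len(spearman_screen(f, g, 0.9, use_absolute=False)) == 0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(12)
        fv = rng.normal(size=(50, 6))
        gv = rng.normal(size=(80, 6))
        out = spearman_screen(litter(fv), litter(gv, features=[f"g{i}" for i in range(80)]),
                              0.6, use_absolute=True)
        got = {(r.feature_id, r.gene_id) for r in out.itertuples()}
        expected = set()
        for i in range(50):
            for j in range(80):
                rho = naive_spearman(fv[i], gv[j])
                if abs(rho) > 0.6:
                    expected.add((f"f{i}", f"g{j}"))
        assert got == expected

    def test_constant_vectors_excluded(self):
        f = litter([[3, 3, 3, 3, 3, 3], [1, 2, 3, 4, 5, 6]])
        g = litter([[1, 2, 3, 4, 5, 6]], features=["g0"])
        out = spearman_screen(f, g, 0.9)
        assert set(out["feature_id"]) == {"f1"}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        f = litter(rng.normal(size=(20, 6)))
        g = litter(rng.normal(size=(20, 6)), features=[f"g{i}" for i in range(20)])
        loose = spearman_screen(f, g, 0.6)
        tight = spearman_screen(f, g, 0.9)
        pairs = lambda df: {(r.feature_id, r.gene_id) for r in df.itertuples()}
        assert pairs(tight) <= pairs(loose)

    def test_mismatched_dams_rejected(self):
        f = litter(np.ones((2, 6)), dams=[f"a{i}" for i in range(6)])
        g = litter(np.ones((2, 6)), dams=[f"b{i}" for i in range(6)])
        with pytest.raises(ValueError, match="mismatched dam"):
            spearman_screen(f, g, 0.9)

    def test_too_few_dams_rejected(self):
        f = litter(np.ones((2, 3)))
        g = litter(np.ones((2, 3)))
        with pytest.raises(ValueError, match="fewer than 4"):
            spearman_screen(f, g, 0.9)

    @given(
        st.lists(st.floats(1, 100, allow_nan=False), min_size=5, max_size=8,
                 unique=True).filter(lambda v: len(v) >= 5)
    )
    def test_invariant_to_monotone_transform(self, values):
        # Spearman depends only on ranks: squaring preserves order on positives
        x = np.array(values)
        n = len(x)
        rng = np.random.default_rng(0)
        y = rng.normal(size=n)
        a = spearman_matrix(x[None, :], y[None, :])[0, 0]
        b = spearman_matrix((x * x)[None, :], y[None, :])[0, 0]
        assert a == pytest.approx(b, abs=1e-12)
        # symmetry
        c = spearman_matrix(y[None, :], x[None, :])[0, 0]
        assert a == pytest.approx(c, abs=1e-12)


class TestHierarchicalClusters:
    def test_identical_items_merge_at_zero(self):
        lm = litter([[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]])
        cs = hierarchical_clusters(lm, (1, 2), kind="gene")
        assert cs.labels["f0"] == cs.labels["f1"]

    def test_anticorrelated_merge_height_two(self):
        lm = litter([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]])
        cs = hierarchical_clusters(lm, (2, 3), kind="gene")
        # forced single cluster at mean size 2: the only merge is at 1-(-1)=2
        assert cs.cut_height == pytest.approx(2.0)

    def test_three_item_dendrogram_matches_hand_computation(self):
        # A,B nearly identical (rho=0.9428...), C moderately related:
        # complete linkage merges A,B first at 1-rho(A,B)=12/210,
        # then C at max(1-rho(A,C), 1-rho(B,C)) = 72/210
        a = [1, 2, 3, 4, 5, 6]
        b = [1, 2, 3, 4, 6, 5]
        c = [3, 1, 4, 2, 6, 5]
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rho = spearman_matrix(np.array([a, b, c], float), np.array([a, b, c], float))
        dis = 1 - rho
        np.fill_diagonal(dis, 0)
        z = linkage(squareform(dis, checks=False), method="complete")
        assert z[0, 2] == pytest.approx(12 / 210)
        assert z[1, 2] == pytest.approx(72 / 210)

    def test_constant_vectors_become_singletons(self):
        lm = litter([[5, 5, 5, 5, 5, 5], [1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7]])
        cs = hierarchical_clusters(lm, (1, 2), kind="feature")
        assert cs.labels["f0"] not in {cs.labels["f1"], cs.labels["f2"]}

    def test_cut_achieves_target_mean_size(self):
        rng = np.random.default_rng(2)
        lm = litter(rng.normal(size=(60, 6)))
        cs = hierarchical_clusters(lm, (7, 15), kind="feature")
        mean_size = 60 / cs.labels.nunique()
        assert 7 <= mean_size <= 15


class TestLinkClusters:
    @staticmethod
    def _cluster_of(ids, label=1):
        from litterlink.association import ClusterSet

        return ClusterSet(pd.Series(label, index=pd.Index(ids, name="item_id")),
                          "gene", 0.5, (1, 99), float(len(ids)))

    def test_copies_of_one_vector_link_at_one(self):
        base = np.array([1, 2, 3, 4, 5, 6], float)
        genes = litter(np.tile(base, (3, 1)), features=["g0", "g1", "g2"])
        feats = litter(np.tile(base, (2, 1)), features=["m0", "m1"])
        links = link_clusters(self._cluster_of(["g0", "g1", "g2"]),
                              self._cluster_of(["m0", "m1"]),
                              genes, feats, threshold=0.7)
        assert len(links) == 1
        assert links.loc[0, "mean_rho"] == pytest.approx(1.0)

    def test_noise_clusters_not_linked(self):
        max_seen = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = litter(rng.normal(size=(10, 6)),
                           features=[f"g{i}" for i in range(10)])
            feats = litter(rng.normal(size=(8, 6)),
                           features=[f"m{i}" for i in range(8)])
            links = link_clusters(self._cluster_of([f"g{i}" for i in range(10)]),
                                  self._cluster_of([f"m{i}" for i in range(8)]),
                                  genes, feats, threshold=0.7)
            assert links.empty
            loose = link_clusters(self._cluster_of([f"g{i}" for i in range(10)]),
                                  self._cluster_of([f"m{i}" for i in range(8)]),
                                  genes, feats, threshold=-1.0)
            max_seen = max(max_seen, loose["mean_rho"].abs().max())
        assert max_seen < 0.5

    def test_threshold_nesting(self):
        rng = np.random.default_rng(9)
        base = np.array([1, 2, 3, 4, 5, 6], float)
        gv = base[None, :] + rng.normal(0, 1.2, size=(6, 6))
        fv = base[None, :] + rng.normal(0, 1.2, size=(4, 6))
        genes = litter(gv, features=[f"g{i}" for i in range(6)])
        feats = litter(fv, features=[f"m{i}" for i in range(4)])
        gc, fc = self._cluster_of([f"g{i}" for i in range(6)]), \
            self._cluster_of([f"m{i}" for i in range(4)])
        at_07 = link_clusters(gc, fc, genes, feats, threshold=0.7)
        at_06 = link_clusters(gc, fc, genes, feats, threshold=0.6)
        assert len(at_07) <= len(at_06)


class TestPlaid:
    @staticmethod
    def _planted(seed, shape=(100, 100), block=((10, 25), (30, 50)), lift=0.6):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 0.2, shape)
        (r0, r1), (c0, c1) = block
        y[r0:r1, c0:c1] = np.clip(y[r0:r1, c0:c1] + lift, 0, 1)
        return pd.DataFrame(y, index=[f"r{i}" for i in range(shape[0])],
                            columns=[f"c{j}" for j in range(shape[1])])

    def test_constant_matrix_yields_no_layers(self):
        y = pd.DataFrame(np.full((20, 20), 0.4),
                         index=[f"r{i}" for i in range(20)],
                         columns=[f"c{j}" for j in range(20)])
        assert plaid_biclustering(y, PipelineConfig(), seed=0) == []

    def test_planted_block_recovered(self):
        y = self._planted(1)
        layers = plaid_biclustering(y, PipelineConfig(), seed=1)
        assert layers
        b = layers[0]
        tr = {f"r{i}" for i in range(10, 25)}
        tc = {f"c{j}" for j in range(30, 50)}
        assert len(set(b.row_ids) & tr) / len(set(b.row_ids) | tr) >= 0.9
        assert len(set(b.col_ids) & tc) / len(set(b.col_ids) | tc) >= 0.9
        assert b.importance > 0

    def test_transpose_recovers_transposed_block(self):
        y = self._planted(2, shape=(60, 80), block=((5, 20), (40, 60)))
        a = plaid_biclustering(y, PipelineConfig(), seed=2)[0]
        b = plaid_biclustering(y.T, PipelineConfig(), seed=2)[0]
        assert set(a.row_ids) == set(b.col_ids)
        assert set(a.col_ids) == set(b.row_ids)

    def test_residual_sum_of_squares_non_increasing(self):
        y = self._planted(3)
        cfg = PipelineConfig()
        layers = plaid_biclustering(y, cfg, seed=3)
        z = y.to_numpy() - y.to_numpy().mean()
        sse = [float((z**2).sum())]
        row_pos = {r: i for i, r in enumerate(y.index)}
        col_pos = {c: j for j, c in enumerate(y.columns)}
        for b in layers:
            ri = [row_pos[r] for r in b.row_ids]
            ci = [col_pos[c] for c in b.col_ids]
            z[np.ix_(ri, ci)] -= b.layer_mean
            sse.append(float((z**2).sum()))
        assert all(b <= a + 1e-9 for a, b in zip(sse, sse[1:]))

    def test_out_of_range_input_rejected(self):
        y = pd.DataFrame(np.full((5, 5), 1.2))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            plaid_biclustering(y, PipelineConfig(), seed=0)
        with pytest.raises(ValueError, match="2 x 2"):
            plaid_biclustering(pd.DataFrame([[0.5]]), PipelineConfig(), seed=0)


class TestSelectTop:
    @staticmethod
    def _bic(mic, n=2, layer_index=0, row_prefix="r", col_prefix="c"):
        return Bicluster(
            row_ids=tuple(f"{row_prefix}{mic}{i}" for i in range(n)),
            col_ids=tuple(f"{col_prefix}{mic}{i}" for i in range(n)),
            background=0.3, layer_mean=0.2, importance=1.0,
            mean_internal_corr=mic, layer_index=layer_index,
        )

    def test_single_bicluster_returned(self):
        b = self._bic(0.8)
        assert select_top_biclusters([b]) == [b]

    def test_top_half_retained(self):
        bics = [self._bic(m, layer_index=i)
                for i, m in enumerate((0.9, 0.5, 0.4, 0.2))]
        top = select_top_biclusters(bics)
        assert [b.mean_internal_corr for b in top] == [0.9, 0.5]

    def test_tie_broken_by_area_then_rows(self):
        small = self._bic(0.7, n=2, layer_index=0)
        big = self._bic(0.7, n=3, layer_index=1, row_prefix="q", col_prefix="d")
        top = select_top_biclusters([small, big], n_top=1)
        assert top == [big]

    def test_empty_input(self):
        assert select_top_biclusters([]) == []

    def test_echo_layer_does_not_consume_slot(self):
        # same column space refit later with higher mic: treated as a refit
        primary = Bicluster(("r1", "r2", "r3"), ("c1", "c2", "c3", "c4"),
                            0.3, 0.3, 9.0, 0.75, layer_index=0)
        echo = Bicluster(("r7", "r8"), ("c1", "c2", "c3"),
                         0.3, 0.2, 2.0, 0.80, layer_index=3)
        other = Bicluster(("r4", "r5"), ("d1", "d2", "d3"),
                          0.3, 0.25, 4.0, 0.70, layer_index=1)
        top = select_top_biclusters([primary, echo, other], n_top=2)
        assert top == [primary, other]


class TestClassifyDependency:
    @staticmethod
    def _means(gf, spf):
        return pd.DataFrame({"GF": gf, "SPF": spf}, index=[f"g{i}" for i in range(len(gf))])

    def test_negative_rho_with_gf_down_is_discordant(self):
        pairs = pd.DataFrame({"feature_id": ["m0"], "gene_id": ["g0"], "rho": [-0.95]})
        out = classify_dependency(pairs, self._means([1.0], [5.0]))
        assert out.loc[0, "label"] == "nonlinear_discordant"

    def test_negative_rho_with_gf_up_is_consistent(self):
        pairs = pd.DataFrame({"feature_id": ["m0"], "gene_id": ["g0"], "rho": [-0.95]})
        out = classify_dependency(pairs, self._means([5.0], [1.0]))
        assert out.loc[0, "label"] == "linear_consistent"

    def test_positive_rho_with_gf_down_is_consistent(self):
        pairs = pd.DataFrame({"feature_id": ["m0"], "gene_id": ["g0"], "rho": [0.95]})
        out = classify_dependency(pairs, self._means([1.0], [5.0]))
        assert out.loc[0, "label"] == "linear_consistent"

    def test_zero_shift_flagged_consistent(self):
        pairs = pd.DataFrame({"feature_id": ["m0"], "gene_id": ["g0"], "rho": [0.95]})
        out = classify_dependency(pairs, self._means([2.0], [2.0]))
        assert out.loc[0, "label"] == "linear_consistent"
        assert bool(out.loc[0, "zero_effect"])

    def test_undefined_rho_excluded(self):
        pairs = pd.DataFrame({"feature_id": ["m0", "m1"], "gene_id": ["g0", "g1"],
                              "rho": [np.nan, 0.95]})
        out = classify_dependency(pairs, self._means([1.0, 1.0], [5.0, 5.0]))
        assert list(out["feature_id"]) == ["m1"]

    def test_planted_discordant_pairs_recovered(self, default_study):
        from litterlink.io import subset_metadata
        from litterlink.screening import average_litters, normalize_counts, prefilter_genes

        counts, intens, md, _, truth = default_study
        tx = subset_metadata(md, tissue="intestine", assay="transcriptome")
        mb = subset_metadata(md, tissue="intestine", assay="metabolome")
        norm, _ = normalize_counts(prefilter_genes(
            counts.subset_samples(list(tx["sample_id"])), 5, 12))
        gl = average_litters(norm, tx)
        fl = average_litters(intens.subset_samples(list(mb["sample_id"])), mb)
        spf = [d for d in gl.dam_ids if d.startswith("SPF")]
        gls, fls = gl.restrict_dams(spf), fl.restrict_dams(spf)
        gpos = {g: i for i, g in enumerate(gls.feature_ids)}
        fpos = {f: i for i, f in enumerate(fls.feature_ids)}
        rho = spearman_matrix(fls.data.to_numpy(), gls.data.to_numpy())
        pairs = pd.DataFrame(
            [
                {"feature_id": f, "gene_id": g, "rho": rho[fpos[f], gpos[g]]}
                for f, g in truth.discordant_pairs
                if g in gpos
            ]
        )
        grp = tx.set_index("sample_id").loc[norm.sample_ids, "group"]
        gmeans = norm.data.T.groupby(grp).mean().T
        out = classify_dependency(pairs, gmeans)
        assert (out["label"] == "nonlinear_discordant").mean() >= 0.95
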