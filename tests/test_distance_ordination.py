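from itertools import combinations

import numpy as np
import pytest

from citrus_snp.distance_ordination import (
    DistanceMatrix, simple_matching, nj_tree, bootstrap_support, pca,
)
from conftest import gm_from_tokens


class TestSimpleMatching:
    def test_single_locus_values(self):
        gm = gm_from_tokens({"a": ["AA"], "b": ["AB"], "c": ["BB"]})
        d = simple_matching(gm).to_frame()
        assert d.loc["a", "a"] == 0.0
        assert d.loc["a", "b"] == pytest.approx(0.5)   # one shared allele
        assert d.loc["a", "c"] == pytest.approx(1.0)   # none shared

    def test_three_locus_hand_enumeration(self):
        # (AA,AB,BB) vs (AA,BB,BB): matches 2,1,2 -> d = 1 - 2.5/3
        gm = gm_from_tokens({"x": ["AA", "AB", "BB"],
                             "y": ["AA", "BB", "BB"]})
        d = simple_matching(gm).values[0, 1]
        assert d == pytest.approx(1 - (1 + 0.5 + 1) / 3)
        assert d == pytest.approx(0.1667, abs=5e-5)

    def test_symmetry_and_zero_diagonal(self, default_ds, wona_loci,
                                        germplasm_ids):
        dm = simple_matching(default_ds.genotypes, loci=wona_loci,
                             accessions=germplasm_ids)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert np.nanmin(dm.values) >= 0 and np.nanmax(dm.values) <= 1

    def test_allele_relabeling_invariance(self):
        # swapping A and B at every locus leaves distances unchanged
        swap = {"AA": "BB", "BB": "AA", "AB": "AB", "00": "00"}
        rows = {"a": ["AA", "AB", "BB"], "b": ["AB", "AA", "AA"],
                "c": ["BB", "BB", "AB"]}
        gm1 = gm_from_tokens(rows)
        gm2 = gm_from_tokens({k: [swap[t] for t in v]
                              for k, v in rows.items()})
        assert np.allclose(simple_matching(gm1).values,
                           simple_matching(gm2).values)

    def test_null_state_matching_under_flag(self):
        gm = gm_from_tokens({"a": ["00"], "b": ["00"], "c": ["AA"]})
        d = simple_matching(gm, null_as_state=True).to_frame()
        assert d.loc["a", "b"] == 0.0          # 00 matches 00
        assert d.loc["a", "c"] == 1.0          # 00 matches nothing else

    def test_pair_without_shared_loci(self):
        gm = gm_from_tokens({"a": ["AA", "--"], "b": ["--", "AA"]})
        dm = simple_matching(gm)
        assert np.isnan(dm.values[0, 1])
        with pytest.raises(ValueError, match="shared typed"):
            simple_matching(gm, strict=True)


def _dm(ids, m):
    return DistanceMatrix(ids, np.array(m, float),
                          np.ones((len(ids), len(ids)), int))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = _dm(["a", "b", "c"],
                 [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        t = nj_tree(dm)
        lengths = {c.name: l for c, l in t.root.children}
        # three-point formulas: la=(dab+dac-dbc)/2 etc.
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.3)
        assert lengths["c"] == pytest.approx(0.5)

    def test_additive_four_taxon_topology(self):
        # additive matrix for ((a,b),(c,d)) with internal edge 0.3
        dm = _dm(["a", "b", "c", "d"],
                 [[0.0, 0.3, 0.8, 0.9],
                  [0.3, 0.0, 0.9, 1.0],
                  [0.8, 0.9, 0.0, 0.3],
                  [0.9, 1.0, 0.3, 0.0]])
        t = nj_tree(dm)
        assert frozenset({"c", "d"}) in t.bipartitions() \
            or frozenset({"a", "b"}) in t.bipartitions()
        # the alternative pairings are worse least-squares fits: check
        # the recovered tree's path lengths reproduce the input exactly
        paths = _path_lengths(t)
        for i, j in combinations("abcd", 2):
            assert paths[frozenset((i, j))] == pytest.approx(
                dm.values[dm.ids.index(i), dm.ids.index(j)], abs=1e-9)

    def test_identical_accessions_make_zero_cherry(self):
        gm = gm_from_tokens({"a": ["AA", "AB"], "a2": ["AA", "AB"],
                             "b": ["BB", "AA"], "c": ["AB", "BB"]})
        t = nj_tree(simple_matching(gm))
        paths = _path_lengths(t)
        assert paths[frozenset(("a", "a2"))] == pytest.approx(0.0)

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        n = 8
        # additive-ish random distances from random points
        pts = rng.random((n, 4))
        m = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(n)]
        ours = nj_tree(_dm(ids, m))
        sk = skbio.tree.nj(skbio.DistanceMatrix(m, ids))
        sk_bips = set()
        for node in sk.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                side = tips if "t0" not in tips \
                    else frozenset(set(ids) - tips)
                sk_bips.add(side)
        assert ours.bipartitions() == sk_bips

    def test_incomplete_matrix_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(_dm(["a", "b", "c"], m))


def _path_lengths(tree):
    """Leaf-to-leaf path lengths of an NJTree, by graph traversal."""
    paths = {}
    leaves = tree.root.leaves()
    adj = {}

    def build(node):
        for c, l in node.children:
            adj.setdefault(id(node), []).append((id(c), l, c))
            adj.setdefault(id(c), []).append((id(node), l, node))
            build(c)

    build(tree.root)
    node_of = {}

    def collect(node):
        node_of[id(node)] = node
        for c, _ in node.children:
            collect(c)

    collect(tree.root)
    leaf_ids = {n.name: i for i, n in node_of.items() if n.is_leaf()}
    for a, b in combinations(leaves, 2):
        # BFS
        start, goal = leaf_ids[a], leaf_ids[b]
        seen = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, l, _ in adj.get(cur, []):
                if nxt not in seen:
                    seen[nxt] = seen[cur] + l
                    stack.append(nxt)
        paths[frozenset((a, b))] = seen[goal]
    return paths


class TestBootstrap:
    def test_single_replicate_supports_binary(self, default_ds,
                                              wona_loci, germplasm_ids):
        t = bootstrap_support(default_ds.genotypes, loci=wona_loci[:60],
                              accessions=germplasm_ids[:10], n_reps=1,
                              seed=3)
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_same_seed_identical_supports(self, default_ds, wona_loci,
                                          germplasm_ids):
        kw = dict(loci=wona_loci[:60], accessions=germplasm_ids[:10],
                  n_reps=25, seed=7)
        t1 = bootstrap_support(default_ds.genotypes, **kw)
        t2 = bootstrap_support(default_ds.genotypes, **kw)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_clean_two_cluster_split_fully_supported(self):
        rows = {}
        for i in range(4):
            rows[f"x{i}"] = ["AA"] * 30 + ["AB"] * 2
            rows[f"y{i}"] = ["BB"] * 30 + ["AB"] * 2
        # add mild within-cluster noise so the tree is not degenerate
        rows["x0"][30] = "BB"
        rows["y0"][31] = "AA"
        gm = gm_from_tokens(rows)
        t = bootstrap_support(gm, n_reps=100, seed=1)
        split = frozenset({f"y{i}" for i in range(4)})
        assert t.supports.get(split, 0.0) == pytest.approx(100.0)


class TestPCA:
    def test_supplementary_does_not_move_active_axes(self, default_ds,
                                                     wona_loci,
                                                     germplasm_ids):
        gm = default_ds.genotypes
        act = germplasm_ids[:12]
        rest = germplasm_ids[12:20]
        r1 = pca(gm, loci=wona_loci, active=act, supplementary=[])
        r2 = pca(gm, loci=wona_loci, active=act, supplementary=rest)
        a1 = r1.coordinates.loc[act].to_numpy()
        a2 = r2.coordinates.loc[act].to_numpy()
        assert np.allclose(np.abs(a1), np.abs(a2))
        assert np.allclose(r1.percent_variance, r2.percent_variance)

    def test_f1_hybrid_projects_between_fixed_parent_pools(self):
        rows = {}
        for i in range(4):
            rows[f"p{i}"] = ["AA"] * 20
            rows[f"q{i}"] = ["BB"] * 20
        rows["p0"] = ["AB"] + ["AA"] * 19      # break zero variance
        rows["q0"] = ["AB"] + ["BB"] * 19
        rows["hyb"] = ["AB"] * 20
        gm = gm_from_tokens(rows)
        act = [f"p{i}" for i in range(4)] + [f"q{i}" for i in range(4)]
        res = pca(gm, active=act, supplementary=["hyb"])
        pc1 = res.coordinates["PC1"]
        p_c = pc1[[f"p{i}" for i in range(4)]].mean()
        q_c = pc1[[f"q{i}" for i in range(4)]].mean()
        assert pc1["hyb"] == pytest.approx((p_c + q_c) / 2, abs=0.05)

    def test_percent_variance_bounded(self, default_ds, wona_loci,
                                      germplasm_ids):
        r = pca(default_ds.genotypes, loci=wona_loci,
                active=germplasm_ids)
        assert r.percent_variance.sum() <= 100.0 + 1e-9
        assert (np.diff(r.percent_variance) <= 1e-9).all()

    def test_cos2_tracks_locus_fst(self, default_ds, wona_loci):
        # loci loading the axis separating two taxa are the loci
        # differentiating them: per-locus cos2 on that axis correlates
        # strongly with per-locus Fst
        from citrus_snp.diversity_stats import weir_cockerham
        ds = default_ds
        sch = ds.scheme
        act = [a for a in sch.groups["reticulata_like"]
               + sch.groups["maxima_like"]
               if sch.roles[a] == "germplasm"]
        res = pca(ds.genotypes, loci=wona_loci, active=act)
        fs = weir_cockerham(ds.genotypes, sch, loci=res.loci,
                            groups=["reticulata_like", "maxima_like"])
        fst = fs.per_locus["fst"].dropna()
        joint = res.variable_cos2["PC1"].reindex(fst.index).dropna()
        fst = fst[joint.index]
        r = np.corrcoef(joint, fst)[0, 1]
        assert r ** 2 > 0.8
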