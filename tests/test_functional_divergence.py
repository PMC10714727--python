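import io

import numpy as np
import pytest

from parevol import synthetic_data as syn
from parevol._phylo import IndexedTree
from parevol.core_io import Alignment, ValidationError, read_timed_tree
from parevol.functional_divergence import (
    ClusterPair,
    SiteChangeCounts,
    build_coordinate_map,
    count_site_changes,
    estimate_theta_I,
    estimate_theta_II,
    flag_divergent_sites,
    SitePosterior,
)

NWK2 = ("(((p1_2000:1,p2_2000:1):1,(p3_2000:1,p4_2000:1):1):2,"
        "((q1_2000:1,q2_2000:1):1,(q3_2000:1,q4_2000:1):1):2);")
C1 = ["p1_2000", "p2_2000", "p3_2000", "p4_2000"]
C2 = ["q1_2000", "q2_2000", "q3_2000", "q4_2000"]


def _aln(cols):
    """Build a protein alignment from per-taxon strings (taxa in NWK2 order)."""
    taxa = C1 + C2
    return Alignment(taxa, cols, "protein")


@pytest.fixture()
def two_cluster_tree():
    return read_timed_tree(io.StringIO(NWK2))


class TestFitchCounts:
    def test_invariant_column_counts_zero(self, two_cluster_tree):
        aln = _aln(["A"] * 8)
        c = count_site_changes(aln, two_cluster_tree, ClusterPair(C1, C2))
        assert c.x1[0] == 0 and c.x2[0] == 0

    def test_clean_split_costs_one(self, two_cluster_tree):
        # cluster 1 splits (p1,p2)=A vs (p3,p4)=S across one internal edge
        aln = _aln(list("AASS") + list("GGGG"))
        c = count_site_changes(aln, two_cluster_tree, ClusterPair(C1, C2))
        assert c.x1[0] == 1 and c.x2[0] == 0

    def test_counts_match_sankoff_oracle(self):
        tt = syn.simulate_timed_tree(n_taxa=10, seed=26, isochronous=True, pop_size=30)
        labels = sorted(tt.tip_labels())
        itree = IndexedTree.from_timed_tree(tt)
        # clusters = the two clades under the root (coalescent tree is binary)
        root_children = itree.children[itree.root]
        g1 = sorted(itree.tip_labels[i] for i in itree.clade_tips(root_children[0]))
        g2 = sorted(itree.tip_labels[i] for i in itree.clade_tips(root_children[1]))
        if min(len(g1), len(g2)) < 4:
            pytest.skip("root split too uneven in this draw")
        rng = np.random.default_rng(0)
        aas = np.array(list("ACDEFG-"))
        cols = ["".join(rng.choice(aas, size=50)) for _ in labels]
        aln = Alignment(labels, cols, "protein")
        counts = count_site_changes(aln, tt, ClusterPair(g1, g2))

        def sankoff(sub_root, column_states):
            INF = 10**6
            def rec(node):
                if node < itree.n_tips:
                    s = column_states.get(node)
                    return {a: 0 for a in range(20)} if s is None else \
                        {a: (0 if a == s else INF) for a in range(20)}
                costs = {a: 0 for a in range(20)}
                for ch in itree.children[node]:
                    sub = rec(ch)
                    for a in range(20):
                        costs[a] += min(sub[b] + (0 if a == b else 1) for b in range(20))
                return costs
            return min(rec(sub_root).values())

        arr = aln.subset(itree.tip_labels).as_array()
        code = {a: i for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        for j, col in enumerate(counts.columns):
            for k, (mrca_tips, xs) in enumerate(((g1, counts.x1), (g2, counts.x2))):
                m = itree.mrca(mrca_tips)
                states = {t: code[arr[t, col]] for t in itree.clade_tips(m)
                          if arr[t, col] in code}
                assert xs[j] == sankoff(m, states), f"column {col} cluster {k}"

    def test_counts_bounded_by_taxa_minus_one(self, two_cluster_tree):
        rng = np.random.default_rng(3)
        aln = _aln(["".join(rng.choice(list("ACDE"), size=30)) for _ in range(8)])
        c = count_site_changes(aln, two_cluster_tree, ClusterPair(C1, C2))
        assert (c.x1 <= 3).all() and (c.x2 <= 3).all()

    def test_non_monophyletic_cluster_rejected(self, two_cluster_tree):
        with pytest.raises(ValidationError, match="monophyletic"):
            count_site_changes(_aln(["A"] * 8), two_cluster_tree,
                               ClusterPair(C1[:3] + [C2[0]], C2[1:] + [C1[3]]))

    def test_small_clusters_rejected(self):
        with pytest.raises(ValidationError, match=">= 4"):
            ClusterPair(C1[:3], C2)


def _counts(theta, seed, n=500, alpha=0.5):
    x1, x2, div = syn.simulate_change_counts(theta, alpha, 1.0, 10.0, 10.0, n, seed)
    return SiteChangeCounts(x1, x2, 10.0, 10.0, np.arange(n)), div


class TestThetaI:
    def test_perfectly_correlated_counts_give_near_zero_theta(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(5.0, size=300)
        c = SiteChangeCounts(x, x.copy(), 10.0, 10.0, np.arange(300))
        est, _ = estimate_theta_I(c)
        assert est.theta <= 0.05

    def test_theta_zero_vs_one_medians_separate(self):
        med0 = np.median([estimate_theta_I(_counts(0.0, 3000 + r, n=300)[0])[0].theta
                          for r in range(15)])
        med1 = np.median([estimate_theta_I(_counts(1.0, 3100 + r, n=300)[0])[0].theta
                          for r in range(15)])
        assert med1 - med0 >= 0.5

    def test_all_zero_counts_rejected(self):
        z = np.zeros(100, dtype=int)
        with pytest.raises(ValidationError):
            estimate_theta_I(SiteChangeCounts(z, z, 10.0, 10.0, np.arange(100)))

    def test_likelihood_nests_at_theta_zero(self):
        c, _ = _counts(0.2, 77)
        est, _ = estimate_theta_I(c)
        # the null fit reported in aux is the single shared-rate model
        assert est.aux["lnL"] >= est.aux["lnL_theta0"] - 1e-6

    def test_decorrelating_shuffle_raises_theta(self):
        rng = np.random.default_rng(5)
        up = 0
        for r in range(10):
            c, _ = _counts(0.0, 4000 + r, n=400)
            est0, _ = estimate_theta_I(c)
            shuffled = SiteChangeCounts(c.x1, rng.permutation(c.x2), 10.0, 10.0,
                                        c.columns)
            est1, _ = estimate_theta_I(shuffled)
            up += est1.theta >= est0.theta
        assert up >= 8

    def test_qk_in_unit_interval_and_flagging(self):
        c, div = _counts(0.3, 99)
        est, post = estimate_theta_I(c)
        assert ((post.qk >= 0) & (post.qk <= 1)).all()
        assert set(post.flagged) <= set(range(c.x1.size))


class TestThetaII:
    def test_identical_conserved_columns_give_zero(self, two_cluster_tree):
        aln = _aln(["AC" * 10] * 8)
        est, _ = estimate_theta_II(aln, two_cluster_tree, ClusterPair(C1, C2))
        assert est.theta <= 0.02

    def test_planted_radical_columns_recovered(self, two_cluster_tree):
        meds = []
        for r in range(25):
            rng = np.random.default_rng(6000 + r)
            n = 200
            cats = rng.random(n) < 0.2
            cols = []
            for t in range(8):
                row = []
                for j in range(n):
                    if cats[j]:
                        row.append("K" if t < 4 else "D")  # charge-class swap
                    else:
                        row.append("A")
                cols.append("".join(row))
            est, post = estimate_theta_II(Alignment(C1 + C2, cols, "protein"),
                                          two_cluster_tree, ClusterPair(C1, C2))
            meds.append(est.theta)
        assert 0.1 <= float(np.median(meds)) <= 0.3

    def test_all_variable_columns_rejected(self, two_cluster_tree):
        rng = np.random.default_rng(8)
        cols = ["".join(rng.choice(list("ACDEFGHIKL"), size=30)) for _ in range(8)]
        with pytest.raises(ValidationError, match="theta_II undefined"):
            estimate_theta_II(_aln(cols), two_cluster_tree, ClusterPair(C1, C2),
                              consensus_threshold=1.01)


class TestFlagging:
    def test_cutoff_flags_correct_columns(self):
        post = SitePosterior(np.array([0.99, 0.97, 0.981]), cutoff=0.98)
        table = flag_divergent_sites(post)
        assert table.loc[table["flagged"], "column"].tolist() == [1, 3]

    def test_empty_flag_set_below_cutoff(self):
        post = SitePosterior(np.array([0.5, 0.9]), cutoff=0.98)
        assert flag_divergent_sites(post)["flagged"].sum() == 0

    def test_coordinate_remap_against_gapped_reference(self):
        cmap = build_coordinate_map("A-CD--E")
        assert cmap == {1: 1, 2: None, 3: 2, 4: 3, 5: None, 6: None, 7: 4}
        post = SitePosterior(np.array([0.99] * 7), cutoff=0.98)
        table = flag_divergent_sites(post, coordinate_map=cmap)
        import pandas as pd
        got = [None if pd.isna(x) else int(x) for x in table["ref_position"]]
        assert got == [1, None, 2, 3, None, None, 4]
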