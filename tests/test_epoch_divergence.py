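import io

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from parevol import synthetic_data as syn
from parevol._phylo import (
    IndexedTree,
    codon_states,
    f3x4_codon_freqs,
)
from parevol.core_io import SENSE_CODONS, ValidationError, read_timed_tree
from parevol.epoch_divergence import (
    AdaptiveDivergenceSeries,
    BranchSiteFit,
    KappaEstimate,
    adaptive_divergence,
    assign_epochs,
    branch_site_log_likelihood,
    estimate_epoch_kappa,
    fit_branch_site_model,
    lrt,
)


class TestAssignEpochs:
    def test_shallow_tree_single_latest_epoch(self):
        tt = read_timed_tree(io.StringIO("((A_2010:20,B_2015:25):5,C_2020:35);"))
        part = assign_epochs(tt, n_epochs=3, window_years=50)
        for b, e in part.midpoint_epoch.items():
            assert e == 3
            assert part.fractions[b][2] == pytest.approx(1.0)

    def test_branch_split_across_boundary(self):
        # tip A's terminal branch spans 60 -> 40 years before present
        tt = read_timed_tree(io.StringIO(
            "((A_1980:20,B_1990:30):10,(C_2020:40,D_2020:40):30);"))
        part = assign_epochs(tt, n_epochs=2, window_years=50)
        itree = IndexedTree.from_timed_tree(tt)
        a = itree.tip_labels.index("A_1980")
        np.testing.assert_allclose(part.fractions[a], [0.5, 0.5])

    def test_three_epochs_on_deep_tree(self):
        tt = read_timed_tree(io.StringIO(
            "((A_1862:6,B_1872:16):6,(C_2020:90,D_2020:90):80);"))
        part = assign_epochs(tt, n_epochs=3, window_years=50)
        assert part.boundaries == [1920.0, 1970.0]
        occupied = set(part.midpoint_epoch.values())
        assert {1, 3} <= occupied
        # C's terminal branch spans 1930 -> 2020: split 4/9 vs 5/9 at 1970
        itree = IndexedTree.from_timed_tree(tt)
        c = itree.tip_labels.index("C_2020")
        np.testing.assert_allclose(part.fractions[c], [0, 4 / 9, 5 / 9], atol=1e-9)

    def test_fraction_weighted_lengths_sum_to_branch_length(self, het_tree):
        part = assign_epochs(het_tree, n_epochs=3, window_years=50)
        itree = IndexedTree.from_timed_tree(het_tree)
        for b in itree.branch_ids():
            total = (part.fractions[b] * itree.blen[b]).sum()
            assert total == pytest.approx(itree.blen[b], abs=1e-9)


class TestEpochKappa:
    def test_single_epoch_kappa_recovered(self):
        hits = 0
        for r in range(30):
            tt = syn.simulate_timed_tree(n_taxa=8, seed=900 + r, isochronous=True,
                                         pop_size=30)
            aln = syn.simulate_dna(tt, kappa=5.0, length=300, seed=r, rate=5e-3)
            part = assign_epochs(tt, n_epochs=1, window_years=1e4)
            est = estimate_epoch_kappa(aln, tt, part)[0]
            hits += 3.5 <= est.kappa <= 7.0
        assert hits >= 26

    def test_no_bias_when_kappa_is_one(self):
        vals = []
        for r in range(20):
            tt = syn.simulate_timed_tree(n_taxa=8, seed=950 + r, isochronous=True,
                                         pop_size=30)
            aln = syn.simulate_dna(tt, kappa=1.0, length=300, seed=r, rate=5e-3)
            part = assign_epochs(tt, n_epochs=1, window_years=1e4)
            vals.append(estimate_epoch_kappa(aln, tt, part)[0].kappa)
        assert 0.7 <= float(np.median(vals)) <= 1.4

    def test_two_epoch_ordering(self):
        wins = 0
        for r in range(20):
            tt = syn.simulate_timed_tree(n_taxa=16, seed=980 + r,
                                         sampling_window=60, pop_size=50)
            part = assign_epochs(tt, n_epochs=2, window_years=60)
            aln = syn.simulate_dna(tt, kappa=[20.0, 2.0], length=500, seed=r,
                                   rate=2e-3, partition=part)
            k = estimate_epoch_kappa(aln, tt, part)
            if np.isfinite(k[0].kappa) and np.isfinite(k[1].kappa):
                wins += k[0].kappa > k[1].kappa
            else:
                wins += 1  # epoch empty in this draw: no ordering to violate
        assert wins >= 18

    def test_empty_epoch_reported_missing_with_warning(self):
        tt = read_timed_tree(io.StringIO("((A_2010:20,B_2015:25):5,C_2020:35);"))
        aln = syn.simulate_dna(tt, kappa=3.0, length=200, seed=1, rate=2e-3)
        part = assign_epochs(tt, n_epochs=3, window_years=50)
        with pytest.warns(UserWarning, match="no branch"):
            est = estimate_epoch_kappa(aln, tt, part)
        assert np.isnan(est[0].kappa) and np.isfinite(est[2].kappa)


class TestLrt:
    def test_zero_delta(self):
        assert lrt(-10.0, -10.0, 1) == (0.0, 1.0)

    def test_borderline_chi2_quantile(self):
        stat, p = lrt(-8.07927, -10.0, 1)
        assert stat == pytest.approx(3.84146, abs=1e-4)
        assert p == pytest.approx(0.050, abs=1e-3)

    def test_alt_below_null_raises(self):
        with pytest.raises(ValidationError, match="optimizer"):
            lrt(-10.5, -10.0, 1)


def _oracle_gy94_loglik(blens, tip_codons, kappa, omega0, omega2, p0, p1,
                        fg_index, pi):
    """Brute-force 4-class mixture likelihood on a 3-taxon star tree, built
    from first principles (genetic code + expm), independent of the package
    pruning machinery."""
    from Bio.Data import CodonTable

    code = CodonTable.unambiguous_dna_by_id[1].forward_table
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = len(SENSE_CODONS)

    def build_q(omega):
        Q = np.zeros((n, n))
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    continue
                diff = [p for p in range(3) if ci[p] != cj[p]]
                if len(diff) != 1:
                    continue
                rate = pi[j]
                if (ci[diff[0]], cj[diff[0]]) in ts_pairs:
                    rate *= kappa
                if code[ci] != code[cj]:
                    rate *= omega
                Q[i, j] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    # shared neutral normalizer
    Qn = build_q(1.0)
    mu = -(pi * np.diag(Qn)).sum()

    def P(omega, t):
        return expm(build_q(omega) / mu * t)

    p2 = 1 - p0 - p1
    weights = [p0, p1, p2 * p0 / (p0 + p1), p2 * p1 / (p0 + p1)]
    regimes = [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]
    total = 0.0
    n_sites = len(tip_codons[0])
    for s in range(n_sites):
        site = 0.0
        for w, (bg, fg) in zip(weights, regimes):
            Ps = [P(fg if k == fg_index else bg, blens[k]) for k in range(3)]
            like = sum(
                pi[r] * Ps[0][r, tip_codons[0][s]] * Ps[1][r, tip_codons[1][s]]
                * Ps[2][r, tip_codons[2][s]]
                for r in range(n)
            )
            site += w * like
        total += np.log(site)
    return total


class TestBranchSiteModel:
    def test_pinned_likelihood_matches_brute_force(self):
        tt = read_timed_tree(io.StringIO("(x_2000:0.2,y_2000:0.35,z_2000:0.5);"))
        itree = IndexedTree.from_timed_tree(tt)
        aln, _ = syn.simulate_codon(tt, kappa=3.0, omega0=0.2, omega2=4.0,
                                    p0=0.4, p1=0.3, foreground=set(), n_codons=10,
                                    seed=17, rate=1.0)
        sub = aln.subset(itree.tip_labels)
        states = codon_states(sub.seqs)
        pi = f3x4_codon_freqs(sub.seqs)
        fg_tip = itree.tip_labels.index("y_2000")
        params = dict(kappa=2.4, omega0=0.15, omega2=5.0, p0=0.5, p1=0.2)
        got = branch_site_log_likelihood(itree, states, pi, {fg_tip},
                                         scale=1.0, **params)
        blens = [itree.blen[itree.tip_labels.index(t)]
                 for t in ("x_2000", "y_2000", "z_2000")]
        tips = [states[itree.tip_labels.index(t)]
                for t in ("x_2000", "y_2000", "z_2000")]
        want = _oracle_gy94_loglik(blens, tips, fg_index=1, pi=pi, **params)
        assert got == pytest.approx(want, abs=1e-8)

    def test_alt_with_omega2_pinned_equals_null(self, balanced_codon_tree,
                                                foreground_branch):
        itree, fg = foreground_branch
        aln, _ = syn.simulate_codon(balanced_codon_tree, foreground=fg,
                                    omega2=1.0, n_codons=60, seed=3, rate=1.0)
        sub = aln.subset(itree.tip_labels)
        states = codon_states(sub.seqs)
        pi = f3x4_codon_freqs(sub.seqs)
        ll_a = branch_site_log_likelihood(itree, states, pi, fg, 2.0, 0.3, 1.0,
                                          0.5, 0.3, 1.0)
        ll_n = branch_site_log_likelihood(itree, states, pi, set(fg), 2.0, 0.3,
                                          1.0 + 1e-12, 0.5, 0.3, 1.0)
        assert ll_a == pytest.approx(ll_n, abs=1e-6)

    def test_likelihood_invariant_to_taxon_order_and_rerooting(
            self, balanced_codon_tree, foreground_branch):
        import dendropy

        itree, fg = foreground_branch
        aln, _ = syn.simulate_codon(balanced_codon_tree, foreground=fg,
                                    n_codons=40, seed=5, rate=1.0)
        sub = aln.subset(itree.tip_labels)
        pi = f3x4_codon_freqs(sub.seqs)
        params = dict(kappa=2.0, omega0=0.2, omega2=3.0, p0=0.5, p1=0.3)
        base = branch_site_log_likelihood(itree, codon_states(sub.seqs), pi,
                                          fg, scale=1.0, **params)
        # background-only model (empty-equivalent foreground never fires on
        # reordered tree); here: permute alignment rows only
        perm = aln.subset(list(reversed(itree.tip_labels)))
        again = branch_site_log_likelihood(
            itree, codon_states(aln.subset(itree.tip_labels).seqs), pi, fg,
            scale=1.0, **params)
        assert again == pytest.approx(base, abs=1e-9)
        assert sorted(perm.ids) == sorted(sub.ids)

        # rerooting leaves a reversible background-only likelihood unchanged
        tree2 = dendropy.Tree.get(data=balanced_codon_tree.as_newick(False),
                                  schema="newick")
        tree2.is_rooted = True
        node = tree2.seed_node.child_nodes()[0]
        tree2.reroot_at_edge(node.edge, update_bipartitions=False,
                             length1=node.edge.length / 2,
                             length2=node.edge.length / 2)
        tree2.suppress_unifurcations()
        it2 = IndexedTree.from_dendropy(tree2)
        sub2 = aln.subset(it2.tip_labels)
        # homogeneous setting (p0 = 1: omega0 on every branch) is reversible
        bg1 = branch_site_log_likelihood(itree, codon_states(sub.seqs), pi,
                                         fg, 2.0, 0.2, 3.0, 1.0, 0.0, 1.0)
        bg2 = branch_site_log_likelihood(it2, codon_states(sub2.seqs), pi,
                                         {it2.mrca(["e_2000", "f_2000", "g_2000", "h_2000"])},
                                         2.0, 0.2, 3.0, 1.0, 0.0, 1.0)
        assert bg2 == pytest.approx(bg1, abs=1e-6)

    def test_fit_recovers_selection_on_foreground(self, balanced_codon_tree,
                                                  foreground_branch):
        itree, fg = foreground_branch
        aln, _ = syn.simulate_codon(balanced_codon_tree, kappa=2.0, omega0=0.1,
                                    omega2=6.0, p0=0.4, p1=0.4, foreground=fg,
                                    n_codons=300, seed=301, rate=1.0)
        fit = fit_branch_site_model(aln, itree, fg, freq_model="equal",
                                    seed=1, n_restarts=1)
        assert fit.omega2 > 1.0
        assert fit.p_value < 0.05
        assert fit.lnL_alt >= fit.lnL_null - 1e-6
        assert 0 < fit.omega0 < 1 and fit.p0 >= 0 and fit.p1 >= 0

    def test_empty_foreground_rejected(self, balanced_codon_tree):
        aln, _ = syn.simulate_codon(balanced_codon_tree, n_codons=30, seed=1, rate=1.0)
        with pytest.raises(ValidationError, match="foreground"):
            fit_branch_site_model(aln, balanced_codon_tree, set())


def _fit(branch, omega2, p):
    return BranchSiteFit(frozenset({branch}), -10.0, -12.0, 0.5, 0.3, 0.1,
                         omega2, 2.0, 4.0, 1, p, p < 0.05)


class TestAdaptiveDivergence:
    def _partition(self):
        tt = read_timed_tree(io.StringIO(
            "((A_1862:6,B_1872:16):6,(C_2020:90,D_2020:90):80);"))
        return tt, assign_epochs(tt, n_epochs=3, window_years=50)

    def test_single_branch_arithmetic(self):
        tt, part = self._partition()
        itree = IndexedTree.from_timed_tree(tt)
        b = itree.tip_labels.index("C_2020")  # midpoint 1970: most recent window
        kappas = [KappaEstimate(e, 2.0, 0.1, 100) for e in (1, 2, 3)]
        series = adaptive_divergence({b: _fit(b, 4.0, 0.01)}, part, kappas)
        row = series.table[series.table["sum_omega2"] > 0].iloc[0]
        assert row["ad"] == pytest.approx(2.0)
        assert row["kappa"] == 2.0

    def test_no_significant_branches_all_zero(self):
        tt, part = self._partition()
        kappas = [KappaEstimate(e, 2.0, 0.1, 100) for e in (1, 2, 3)]
        series = adaptive_divergence({}, part, kappas)
        assert (series.table["ad"] == 0).all()

    def test_three_branches_two_windows_hand_computed(self):
        tt, part = self._partition()
        itree = IndexedTree.from_timed_tree(tt)
        c = itree.tip_labels.index("C_2020")  # midpoint 1970
        d = itree.tip_labels.index("D_2020")  # midpoint 1975
        a = itree.tip_labels.index("A_1862")  # midpoint 1859
        kap = {1: 2.0, 2: 5.0, 3: 5.0}
        kappas = [KappaEstimate(e, kap[e], 0.1, 100) for e in (1, 2, 3)]
        fits = {c: _fit(c, 2.0, 0.01), d: _fit(d, 3.0, 0.01), a: _fit(a, 5.0, 0.01)}
        series = adaptive_divergence(fits, part, kappas)
        tab = series.table.set_index("window_start")
        # window [1970, 2020): omega sum 5 / kappa 5 = 1.0 (epoch 3)
        assert tab.loc[1970.0, "ad"] == pytest.approx(1.0)
        # window [1820, 1870): omega 5 / kappa 2 = 2.5 (epoch 1)
        assert tab.loc[1820.0, "ad"] == pytest.approx(2.5)

    def test_doubling_kappa_halves_ad(self):
        tt, part = self._partition()
        itree = IndexedTree.from_timed_tree(tt)
        b = itree.tip_labels.index("C_2020")
        fits = {b: _fit(b, 4.0, 0.001)}
        k1 = [KappaEstimate(e, 2.0, 0.1, 100) for e in (1, 2, 3)]
        k2 = [KappaEstimate(e, 4.0, 0.1, 100) for e in (1, 2, 3)]
        s1 = adaptive_divergence(fits, part, k1).table["ad"].to_numpy()
        s2 = adaptive_divergence(fits, part, k2).table["ad"].to_numpy()
        np.testing.assert_allclose(s2, s1 / 2.0)

    def test_missing_kappa_for_needed_epoch_raises(self):
        tt, part = self._partition()
        itree = IndexedTree.from_timed_tree(tt)
        a = itree.tip_labels.index("A_1862")
        kappas = [KappaEstimate(1, float("nan"), float("nan"), 0),
                  KappaEstimate(2, 2.0, 0.1, 100), KappaEstimate(3, 2.0, 0.1, 100)]
        with pytest.raises(ValidationError, match="kappa missing"):
            adaptive_divergence({a: _fit(a, 4.0, 0.01)}, part, kappas)
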