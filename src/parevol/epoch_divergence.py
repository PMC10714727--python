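"""Epoch partitioning, per-epoch transition/transversion bias, branch-site
positive-selection tests and the adaptive-divergence statistic.

The adaptive-divergence (AD) series summarizes episodic Darwinian selection
per 50-year window of a time-calibrated tree: the sum of statistically
supported foreground omega_2 (dN/dS) values in the window divided by the
window's epoch-specific transition/transversion ratio kappa — high omega_2
during periods of transversion-rich mutation accumulation (low kappa) marks a
raised fixation probability for new lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from ._phylo import (
    batched_transitions,
    compress_site_patterns,
    site_log_likelihoods_multi,
    IndexedTree,
    RevEigen,
    dna_states,
    empirical_base_freqs,
    f3x4_codon_freqs,
    codon_states,
    gy94_rate_matrix,
    hky_rate_matrix,
    rev_eigen,
    site_log_likelihoods,
)
from .core_io import Alignment, TimedTree, ValidationError

__all__ = [
    "EpochPartition",
    "KappaEstimate",
    "BranchSiteFit",
    "AdaptiveDivergenceSeries",
    "assign_epochs",
    "estimate_epoch_kappa",
    "fit_branch_site_model",
    "branch_site_log_likelihood",
    "lrt",
    "adaptive_divergence",
    "OptimizerError",
]


class OptimizerError(RuntimeError):
    """Raised when numerical optimization fails; carries the best lnL found."""

    def __init__(self, message: str, best_lnl: float):
        super().__init__(message)
        self.best_lnl = best_lnl


# ---------------------------------------------------------------------------
# Epoch partition
# ---------------------------------------------------------------------------


@dataclass
class EpochPartition:
    """Assignment of branches to calendar-time epochs.

    Epoch 1 is the oldest; epoch ``n_epochs`` ends at the latest tip date.
    ``boundaries`` are the interior calendar-year cut points (ascending).
    ``midpoint_epoch[b]`` is the epoch of branch b's temporal midpoint;
    ``fractions[b]`` is the exact share of the branch's time span per epoch.
    """

    n_epochs: int
    window_years: float
    boundaries: list[float]
    latest_date: float
    midpoint_epoch: dict[int, int]
    fractions: dict[int, np.ndarray]
    branch_mid_dates: dict[int, float] = field(default_factory=dict)

    def epoch_of_date(self, date: float) -> int:
        """Epoch (1-based) of a calendar date."""
        e = self.n_epochs
        for b in reversed(self.boundaries):
            if date > b:
                return e
            e -= 1
        return 1


def assign_epochs(tree: TimedTree, n_epochs: int = 3,
                  window_years: float = 50.0) -> EpochPartition:
    """Partition a time tree into epochs anchored at the latest tip date.

    Boundaries step back from the latest tip by ``window_years``; epochs that
    would fall beyond the root simply stay empty.  Each branch is assigned the
    epoch of its temporal midpoint plus exact per-epoch time fractions.
    """
    itree = IndexedTree.from_timed_tree(tree)
    dates = itree.node_times(tree.tip_dates)
    latest = tree.latest_date
    boundaries = [latest - window_years * k for k in range(n_epochs - 1, 0, -1)]

    # epoch interval e (1-based): (lo_e, hi_e], with lo_1 = -inf
    edges = [-np.inf] + boundaries + [np.inf]
    mid_epoch: dict[int, int] = {}
    fracs: dict[int, np.ndarray] = {}
    mids: dict[int, float] = {}
    for b in itree.branch_ids():
        t0 = dates[itree.parent[b]]
        t1 = dates[b]
        lo, hi = min(t0, t1), max(t0, t1)
        mid = 0.5 * (lo + hi)
        mids[b] = mid
        e_mid = 1
        for e in range(1, n_epochs + 1):
            if edges[e - 1] < mid <= edges[e] or (e == n_epochs and mid > edges[e]):
                e_mid = e
                break
        mid_epoch[b] = e_mid
        f = np.zeros(n_epochs)
        span = hi - lo
        if span <= 0:
            f[e_mid - 1] = 1.0
        else:
            for e in range(1, n_epochs + 1):
                a = max(lo, edges[e - 1])
                z = min(hi, edges[e]) if e < n_epochs else hi
                f[e - 1] = max(z - a, 0.0) / span
            f /= f.sum()
        fracs[b] = f
    return EpochPartition(n_epochs, window_years, boundaries, latest,
                          mid_epoch, fracs, mids)


# ---------------------------------------------------------------------------
# Per-epoch kappa (HKY with one kappa per epoch, joint ML)
# ---------------------------------------------------------------------------


@dataclass
class KappaEstimate:
    epoch: int
    kappa: float  # nan when the epoch holds no branch
    se: float
    n_informative_sites: int


def estimate_epoch_kappa(aln: Alignment, tree: TimedTree,
                         partition: EpochPartition) -> list[KappaEstimate]:
    """Joint ML fit of an HKY model with one free kappa per epoch.

    Branch lengths (years) are rescaled by a single free ML rate; branches map
    to epochs by temporal midpoint; empirical base frequencies; likelihood by
    pruning.  Standard errors come from the observed-information diagonal
    (finite-difference curvature on the log-kappa scale, delta method).
    """
    if aln.alphabet != "dna":
        raise ValidationError("estimate_epoch_kappa expects a DNA alignment")
    itree = IndexedTree.from_timed_tree(tree)
    missing_tips = set(itree.tip_labels) - set(aln.ids)
    if missing_tips:
        raise ValidationError(f"tree tips absent from alignment: {sorted(missing_tips)}")
    sub = aln.subset(itree.tip_labels)
    states = dna_states(sub.seqs)
    pi = empirical_base_freqs(sub.seqs)

    branch_epoch = {b: partition.midpoint_epoch[b] for b in itree.branch_ids()}
    used_epochs = sorted(set(branch_epoch.values()))
    e_index = {e: i for i, e in enumerate(used_epochs)}
    n_free = len(used_epochs)

    obs = states >= 0
    n_informative = int(((states.max(axis=0) != states.min(axis=0)) & obs.all(axis=0)).sum())

    blen = itree.blen

    def negll(x: np.ndarray) -> float:
        kappas = np.exp(x[:n_free])
        rate = np.exp(x[n_free])
        eigs = {e: rev_eigen(hky_rate_matrix(k, pi), pi) for e, k in zip(used_epochs, kappas)}
        P = {b: eigs[branch_epoch[b]].transition(rate * blen[b]) for b in itree.branch_ids()}
        ll = site_log_likelihoods(itree, states, P, pi).sum()
        return -ll if np.isfinite(ll) else 1e12

    # moment-style init: start kappa at 4, rate so mean branch length ~ diversity
    x0 = np.concatenate([np.full(n_free, np.log(4.0)), [np.log(0.01)]])
    # pick a rate init from mean pairwise difference per unit time
    tot_time = blen.sum()
    if tot_time > 0:
        pdiff = float((states[0] != states[-1])[obs[0] & obs[-1]].mean() or 0.01)
        x0[-1] = np.log(max(pdiff / max(tot_time, 1e-9) * itree.n_tips, 1e-6))
    best = None
    for start in (x0, x0 + 0.5, x0 - 0.5):
        res = minimize(negll, start, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    xhat = best.x
    kappas = np.exp(xhat[:n_free])

    # observed information on log-kappa via central differences
    ses = np.full(n_free, np.nan)
    h = 1e-3
    f0 = best.fun
    for i in range(n_free):
        xp, xm = xhat.copy(), xhat.copy()
        xp[i] += h
        xm[i] -= h
        d2 = (negll(xp) - 2 * f0 + negll(xm)) / h**2
        if d2 > 0:
            ses[i] = kappas[i] / np.sqrt(d2)  # delta method from log scale

    out = []
    for e in range(1, partition.n_epochs + 1):
        if e in e_index:
            i = e_index[e]
            out.append(KappaEstimate(e, float(kappas[i]), float(ses[i]), n_informative))
        else:
            warnings.warn(f"epoch {e} contains no branch; kappa reported as missing")
            out.append(KappaEstimate(e, float("nan"), float("nan"), n_informative))
    return out


# ---------------------------------------------------------------------------
# Branch-site model A / A1
# ---------------------------------------------------------------------------


@dataclass
class BranchSiteFit:
    """Branch-site test result: model A (alt) vs model A1 (omega_2 = 1)."""

    foreground: frozenset[int]
    lnL_alt: float
    lnL_null: float
    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    lrt_stat: float
    df: int
    p_value: float
    significant: bool
    scale: float = 1.0
    null_params: dict = field(default_factory=dict)


def _class_weights(p0: float, p1: float) -> np.ndarray:
    """Weights of site classes (0, 1, 2a, 2b) in model A."""
    p2 = 1.0 - p0 - p1
    tot01 = p0 + p1
    if tot01 <= 0:
        return np.array([0.0, 0.0, p2 * 0.5, p2 * 0.5])
    return np.array([p0, p1, p2 * p0 / tot01, p2 * p1 / tot01])


def _branch_site_class_logliks(itree: IndexedTree, states: np.ndarray,
                               codon_pi: np.ndarray, foreground: frozenset[int],
                               kappa: float, omega0: float, omega2: float,
                               scale: float) -> np.ndarray:
    """(4, n_sites) per-class site log-likelihoods of model A."""
    omegas = sorted({omega0, 1.0, omega2})
    ts = scale * itree.blen
    P_all = {w: batched_transitions(
        rev_eigen(gy94_rate_matrix(kappa, w, codon_pi), codon_pi), ts)
        for w in omegas}
    fg_idx = np.array(sorted(foreground), dtype=int)
    # regimes: (background omega, foreground omega) for classes 0/1/2a/2b
    regimes = [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]
    P = np.empty((4, itree.n_nodes) + P_all[omegas[0]].shape[1:])
    for c, (bg, fg) in enumerate(regimes):
        P[c] = P_all[bg]
        if fg != bg and fg_idx.size:
            P[c, fg_idx] = P_all[fg][fg_idx]
    return site_log_likelihoods_multi(itree, states, P, codon_pi)


def branch_site_log_likelihood(itree: IndexedTree, states: np.ndarray,
                               codon_pi: np.ndarray, foreground: set[int],
                               kappa: float, omega0: float, omega2: float,
                               p0: float, p1: float, scale: float = 1.0,
                               site_weights: np.ndarray | None = None) -> float:
    """Model-A mixture log-likelihood at pinned parameter values.

    Site classes: 0 (omega0 everywhere), 1 (neutral everywhere), 2a (omega0
    background / omega2 foreground), 2b (neutral background / omega2
    foreground).  GY94 rate matrices share kappa and the codon frequencies.
    ``site_weights`` supports collapsed site patterns.
    """
    site_lls = _branch_site_class_logliks(itree, states, codon_pi,
                                          frozenset(foreground), kappa,
                                          omega0, omega2, scale)
    w = _class_weights(p0, p1)
    mx = site_lls.max(axis=0)
    mix = np.log((w[:, None] * np.exp(site_lls - mx)).sum(axis=0)) + mx
    if site_weights is not None:
        return float(mix @ site_weights)
    return float(mix.sum())


def _weights_from_ab(a: float, b: float) -> np.ndarray:
    ea, eb = np.exp(a), np.exp(b)
    denom = 1.0 + ea + eb
    return _class_weights(ea / denom, eb / denom)


def _profile_class_weights(site_lls: np.ndarray, counts: np.ndarray
                           ) -> tuple[float, float, float]:
    """Maximize the mixture likelihood over (p0, p1) given per-class site
    log-likelihoods; returns (lnL, p0, p1).

    This inner problem reuses the pruning output, so the outer optimizer only
    carries the parameters that change the rate matrices.
    """
    mx = site_lls.max(axis=0)
    F = np.exp(site_lls - mx)  # (4, n_patterns)
    base = float(mx @ counts)

    def nll(ab):
        ea, eb = np.exp(ab)
        d = 1.0 + ea + eb
        s = ea + eb
        w1, w2 = ea / d, eb / d
        w3, w4 = ea / (d * s), eb / (d * s)
        w = np.array([w1, w2, w3, w4])
        mix = w @ F
        if not (mix > 0).all():
            return 1e12, np.zeros(2)
        ratio = counts / mix
        g_w = -(F @ ratio)  # d(-ll)/dw_c
        dw_da = np.array([w1 * (1 - w1), -w1 * w2,
                          w3 * (1 - w1 - ea / s), -w4 * (w1 + ea / s)])
        dw_db = np.array([-w1 * w2, w2 * (1 - w2),
                          -w3 * (w2 + eb / s), w4 * (1 - w2 - eb / s)])
        return (-(counts @ np.log(mix)),
                np.array([g_w @ dw_da, g_w @ dw_db]))

    res = minimize(nll, np.array([np.log(3.0), 0.0]), jac=True,
                   method="L-BFGS-B", options={"maxiter": 200, "ftol": 1e-12})
    ea, eb = np.exp(res.x)
    denom = 1.0 + ea + eb
    return base - float(res.fun), ea / denom, eb / denom


def _unpack_rates(x: np.ndarray, fix_omega2: bool) -> tuple[float, float, float, float]:
    kappa = np.exp(x[0])
    omega0 = 1.0 / (1.0 + np.exp(-x[1]))  # (0,1)
    scale = np.exp(x[2])
    omega2 = 1.0 if fix_omega2 else 1.0 + np.exp(x[3])
    return kappa, omega0, omega2, scale


def _fit_one(itree, states, codon_pi, foreground, fix_omega2: bool,
             n_restarts: int, seed: int, site_weights: np.ndarray | None = None,
             x_init: np.ndarray | None = None) -> tuple[float, dict, np.ndarray]:
    rng = np.random.default_rng(seed)
    nx = 3 if fix_omega2 else 4
    counts = (np.ones(states.shape[1]) if site_weights is None
              else np.asarray(site_weights, float))
    last_w = {}

    def negll(x):
        kappa, w0, w2, scale = _unpack_rates(x, fix_omega2)
        site_lls = _branch_site_class_logliks(itree, states, codon_pi,
                                              foreground, kappa, w0, w2, scale)
        if not np.isfinite(site_lls).all():
            return 1e12
        ll, p0, p1 = _profile_class_weights(site_lls, counts)
        last_w[tuple(x)] = (p0, p1)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.array([np.log(2.0), 0.0, np.log(1.0), np.log(2.0)][:nx])
    starts = [x0] if x_init is None else [x_init, x0]
    while len(starts) < n_restarts:
        starts.append(x0 + rng.normal(0, 0.7, size=nx))
    best = None
    for start in starts[:n_restarts]:
        res = minimize(negll, start, method="L-BFGS-B",
                       options={"maxiter": 150, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise OptimizerError("branch-site optimization failed to find a finite optimum",
                             -best.fun)
    fun = negll(best.x)  # refresh last_w at the optimum
    kappa, w0, w2, scale = _unpack_rates(best.x, fix_omega2)
    p0, p1 = last_w[tuple(best.x)]
    return -fun, {"kappa": kappa, "omega0": w0, "omega2": w2,
                  "p0": p0, "p1": p1, "scale": scale}, best.x


def fit_branch_site_model(aln: Alignment, tree: TimedTree | IndexedTree,
                          foreground: set[int] | frozenset[int],
                          fix_omega2: bool = False, n_restarts: int = 3,
                          alpha: float = 0.05, seed: int = 0,
                          freq_model: str = "F3x4") -> BranchSiteFit:
    """Branch-site test of episodic positive selection on foreground branches.

    Fits model A1 (null, omega_2 = 1) and — unless ``fix_omega2`` — model A
    (alternative, omega_2 >= 1), then contrasts them by a chi^2_1 LRT.
    Codon columns containing gaps or ambiguity are excluded.
    """
    if aln.alphabet != "codon":
        raise ValidationError("branch-site model requires a codon alignment")
    itree = tree if isinstance(tree, IndexedTree) else IndexedTree.from_timed_tree(tree)
    foreground = frozenset(foreground)
    if not foreground:
        raise ValidationError("foreground branch set must be non-empty")
    bad = foreground - set(itree.branch_ids())
    if bad:
        raise ValidationError(f"foreground ids not branches of the tree: {sorted(bad)}")

    sub = aln.subset(itree.tip_labels)
    states = codon_states(sub.seqs)
    keep = (states >= 0).all(axis=0)  # drop codon columns with gap/ambiguity
    states = states[:, keep]
    if states.shape[1] == 0:
        raise ValidationError("no complete codon columns to analyse")
    states, site_weights = compress_site_patterns(states)
    if freq_model == "F3x4":
        codon_pi = f3x4_codon_freqs(sub.seqs)
    elif freq_model == "F1x4":
        base = empirical_base_freqs(sub.seqs)
        from .core_io import SENSE_CODONS
        from ._phylo import NUC_INDEX
        codon_pi = np.array([base[NUC_INDEX[c[0]]] * base[NUC_INDEX[c[1]]] * base[NUC_INDEX[c[2]]]
                             for c in SENSE_CODONS])
        codon_pi /= codon_pi.sum()
    elif freq_model == "equal":
        codon_pi = np.full(61, 1.0 / 61.0)
    else:
        raise ValidationError(f"unknown freq_model {freq_model!r}")

    lnl_null, par_null, x_null = _fit_one(itree, states, codon_pi, foreground,
                                          True, n_restarts, seed,
                                          site_weights=site_weights)
    if fix_omega2:
        return BranchSiteFit(foreground, lnl_null, lnl_null,
                             par_null["p0"], par_null["p1"], par_null["omega0"],
                             1.0, par_null["kappa"], 0.0, 1, 1.0, False,
                             par_null["scale"], par_null)
    # warm-start the alternative from the null optimum (omega2 slightly > 1)
    x_warm = np.append(x_null, np.log(1.0))
    lnl_alt, par_alt, _ = _fit_one(itree, states, codon_pi, foreground, False,
                                   n_restarts, seed + 1,
                                   site_weights=site_weights, x_init=x_warm)
    if lnl_alt < lnl_null - 1e-6:
        # omega2=1 is inside the alternative's closure: refit from the null optimum
        lnl_alt = lnl_null
        par_alt = dict(par_null, omega2=1.0)
    stat, p = lrt(lnl_alt, lnl_null, df=1)
    return BranchSiteFit(foreground, lnl_alt, lnl_null,
                         par_alt["p0"], par_alt["p1"], par_alt["omega0"],
                         par_alt["omega2"], par_alt["kappa"], stat, 1, p,
                         p < alpha and par_alt["omega2"] > 1.0,
                         par_alt["scale"], par_null)


def lrt(lnL_alt: float, lnL_null: float, df: int,
        tolerance: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio test: 2*(lnL_alt - lnL_null) against chi^2_df."""
    delta = lnL_alt - lnL_null
    if delta < -tolerance:
        raise ValidationError(
            f"lnL_alt < lnL_null by {-delta:.6g}: optimizer failure upstream")
    stat = max(2.0 * delta, 0.0)
    p = float(chi2.sf(stat, df))
    return stat, p


# ---------------------------------------------------------------------------
# Adaptive divergence series
# ---------------------------------------------------------------------------


@dataclass
class AdaptiveDivergenceSeries:
    """Per-window adaptive divergence: AD = sum(omega_2) / kappa_epoch."""

    table: pd.DataFrame  # window_start, window_end, epoch, sum_omega2, kappa, ad


def adaptive_divergence(fits: dict[int, BranchSiteFit],
                        partition: EpochPartition,
                        kappas: list[KappaEstimate],
                        alpha: float = 0.05) -> AdaptiveDivergenceSeries:
    """Adaptive divergence per 50-year window.

    A branch contributes its omega_2 to the window containing its temporal
    midpoint when its branch-site test is significant (p < alpha) with
    omega_2 > 1; each window's sum is divided by the kappa of the window's
    epoch.
    """
    kap = {k.epoch: k.kappa for k in kappas}
    latest = partition.latest_date
    W = partition.window_years
    mids = partition.branch_mid_dates
    if not mids:
        raise ValidationError("partition carries no branch midpoints")
    oldest = min(mids.values())
    n_windows = max(int(np.ceil((latest - oldest) / W)), 1)

    sums = np.zeros(n_windows)
    for b, fit in fits.items():
        if not (fit.p_value < alpha and fit.omega2 > 1.0):
            continue
        if b not in mids:
            raise ValidationError(f"branch {b} not present in epoch partition")
        k = min(int((latest - mids[b]) // W), n_windows - 1)
        sums[k] += fit.omega2

    rows = []
    for k in range(n_windows):  # window 0 = most recent
        w_end = latest - k * W
        w_start = w_end - W
        epoch = partition.epoch_of_date(w_end - 0.5 * W)
        kappa = kap.get(epoch, float("nan"))
        if sums[k] > 0 and not np.isfinite(kappa):
            raise ValidationError(f"kappa missing for epoch {epoch} needed by "
                                  f"window [{w_start}, {w_end}]")
        ad = sums[k] / kappa if sums[k] > 0 else 0.0
        rows.append((w_start, w_end, epoch, sums[k], kappa, ad))
    df = pd.DataFrame(rows, columns=["window_start", "window_end", "epoch",
                                     "sum_omega2", "kappa", "ad"])
    return AdaptiveDivergenceSeries(df.iloc[::-1].reset_index(drop=True))
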