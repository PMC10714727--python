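"""Type I / type II functional divergence between two sequence clusters.

Type I (covarion-like) divergence means a site's evolutionary rate differs
between clusters (fast in one, conserved in the other).  It is modelled as a
two-state mixture over alignment columns: with probability 1-theta the
column's rate lambda is shared by both clusters, with probability theta each
cluster draws an independent rate.  Rates are Gamma distributed and observed
through Poisson substitution counts (minimum changes by Fitch parsimony on
each cluster's subtree), giving marginal negative-binomial forms.

Type II ("constant-but-different") divergence means a site is conserved
within each cluster but fixed for residues of different physicochemical class
between clusters.  theta_II is estimated by the excess of such columns over
the neutral expectation given the between-cluster branch length.

Each estimator returns a site-specific posterior probability Q_k of
membership in the divergent class; sites with Q_k above a cutoff (0.98 by
default) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import chi2

from ._phylo import IndexedTree
from .core_io import Alignment, TimedTree, ValidationError

__all__ = [
    "ClusterPair",
    "SiteChangeCounts",
    "ThetaEstimate",
    "SitePosterior",
    "count_site_changes",
    "estimate_theta_I",
    "estimate_theta_II",
    "flag_divergent_sites",
    "DEFAULT_PROPERTY_SCHEME",
]

# 5-class physicochemical reduction (shared with the coevolution module)
DEFAULT_PROPERTY_SCHEME: dict[str, str] = {
    **{a: "nonpolar" for a in "GAVLIMPC"},
    **{a: "polar" for a in "STNQ"},
    **{a: "positive" for a in "KRH"},
    **{a: "negative" for a in "DE"},
    **{a: "aromatic" for a in "FWY"},
}

_MISSING = set("-.?X*BZJ")


@dataclass
class ClusterPair:
    """Two disjoint, monophyletic tip clusters on a rooted tree."""

    cluster1: list[str]
    cluster2: list[str]

    def __post_init__(self) -> None:
        s1, s2 = set(self.cluster1), set(self.cluster2)
        if s1 & s2:
            raise ValidationError(f"clusters overlap: {sorted(s1 & s2)}")
        if len(s1) < 4 or len(s2) < 4:
            raise ValidationError("each cluster needs >= 4 taxa")


@dataclass
class SiteChangeCounts:
    """Minimum substitution counts per column within each cluster subtree."""

    x1: np.ndarray  # (n_cols,) int
    x2: np.ndarray
    tree_length1: float
    tree_length2: float
    columns: np.ndarray  # original 0-based alignment columns kept


def _subtree(itree: IndexedTree, tips: list[str]) -> tuple[int, set[int]]:
    node = itree.mrca(tips)
    clade = itree.clade_tips(node)
    want = {itree.tip_labels.index(t) for t in tips}
    if clade != want:
        extra = sorted(itree.tip_labels[i] for i in clade - want)
        raise ValidationError(f"cluster not monophyletic; clade also contains: {extra}")
    return node, want


def _subtree_length(itree: IndexedTree, mrca: int) -> float:
    total = 0.0
    stack = list(itree.children[mrca])
    while stack:
        n = stack.pop()
        total += itree.blen[n]
        stack.extend(itree.children[n])
    return float(total)


def _fitch_column(itree: IndexedTree, mrca: int, states: dict[int, int]) -> int:
    """Fitch parsimony count within the clade under ``mrca``.

    ``states`` maps tip index -> residue code; missing tips are absent and
    contribute no information (and no changes).
    """
    sets: dict[int, frozenset[int] | None] = {}
    count = 0
    stack: list[tuple[int, bool]] = [(mrca, False)]
    while stack:
        n, done = stack.pop()
        if n < itree.n_tips:
            s = states.get(n)
            sets[n] = None if s is None else frozenset((s,))
            continue
        if not done:
            stack.append((n, True))
            stack.extend((c, False) for c in itree.children[n])
            continue
        child_sets = [sets[c] for c in itree.children[n] if sets[c] is not None]
        if not child_sets:
            sets[n] = None
            continue
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[n] = inter
        else:
            # Fitch generalized to multifurcations: greedy union; each child
            # set disjoint from the running consensus costs one change.
            cur = child_sets[0]
            for cs in child_sets[1:]:
                nxt = cur & cs
                if nxt:
                    cur = nxt
                else:
                    cur = cur | cs
                    count += 1
            sets[n] = cur
    return count


def count_site_changes(aln: Alignment, tree: TimedTree | IndexedTree,
                       clusters: ClusterPair) -> SiteChangeCounts:
    """Fitch-parsimony substitution counts per column within each cluster.

    Gap/ambiguous residues are treated as missing.  Columns that are entirely
    missing across both clusters are removed; ``columns`` records the kept
    0-based alignment columns.
    """
    if aln.alphabet != "protein":
        raise ValidationError("count_site_changes expects a protein alignment")
    itree = tree if isinstance(tree, IndexedTree) else IndexedTree.from_timed_tree(tree)
    m1, tips1 = _subtree(itree, clusters.cluster1)
    m2, tips2 = _subtree(itree, clusters.cluster2)
    arr = aln.subset(itree.tip_labels).as_array()

    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY"):
        codes[arr == a] = i

    x1, x2, kept = [], [], []
    for j in range(arr.shape[1]):
        col = codes[:, j]
        s1 = {t: int(col[t]) for t in tips1 if col[t] >= 0}
        s2 = {t: int(col[t]) for t in tips2 if col[t] >= 0}
        if not s1 and not s2:
            continue
        x1.append(_fitch_column(itree, m1, s1))
        x2.append(_fitch_column(itree, m2, s2))
        kept.append(j)
    return SiteChangeCounts(np.array(x1), np.array(x2),
                            _subtree_length(itree, m1), _subtree_length(itree, m2),
                            np.array(kept))


@dataclass
class ThetaEstimate:
    type: str  # "I" | "II"
    theta: float
    se: float
    lrt_stat: float
    p_value: float
    aux: dict = field(default_factory=dict)


@dataclass
class SitePosterior:
    """Per-column posterior probability of the divergent class."""

    qk: np.ndarray
    cutoff: float = 0.98
    columns: np.ndarray | None = None  # 0-based alignment columns

    @property
    def flagged(self) -> np.ndarray:
        return np.flatnonzero(self.qk > self.cutoff)


# -- type I ------------------------------------------------------------------


def _log_nb(x: np.ndarray, alpha: float, beta: float, T: float) -> np.ndarray:
    """log P(x) for Poisson(lambda*T) with lambda ~ Gamma(alpha, rate=beta)."""
    return (gammaln(alpha + x) - gammaln(alpha) - gammaln(x + 1)
            + alpha * np.log(beta / (beta + T)) + x * np.log(T / (beta + T)))


def _log_shared(x1: np.ndarray, x2: np.ndarray, alpha: float, beta: float,
                T1: float, T2: float) -> np.ndarray:
    """Joint log P(x1, x2) under one shared Gamma rate."""
    s = T1 + T2
    return (gammaln(alpha + x1 + x2) - gammaln(alpha)
            - gammaln(x1 + 1) - gammaln(x2 + 1)
            + alpha * np.log(beta / (beta + s))
            + x1 * np.log(T1 / (beta + s)) + x2 * np.log(T2 / (beta + s)))


def estimate_theta_I(counts: SiteChangeCounts, qk_cutoff: float = 0.98,
                     per_cluster_rates: bool = False,
                     n_restarts: int = 4, seed: int = 0
                     ) -> tuple[ThetaEstimate, SitePosterior]:
    """ML estimate of the type I functional-divergence coefficient theta.

    Mixture over columns: shared-rate state (probability 1-theta, one Gamma
    rate driving Poisson counts in both clusters) vs independent-rate state
    (probability theta; with ``per_cluster_rates`` each cluster has its own
    Gamma shape and mean).  The LRT against theta=0 uses the boundary-aware
    50:50 chi^2_0 / chi^2_1 mixture.
    """
    x1, x2 = counts.x1.astype(float), counts.x2.astype(float)
    T1, T2 = counts.tree_length1, counts.tree_length2
    if T1 <= 0 or T2 <= 0:
        raise ValidationError("cluster subtree length must be positive")
    if np.all(x1 + x2 == 0):
        raise ValidationError("all substitution counts are zero; theta undefined")
    n = x1.size
    if n < 50:
        warnings.warn(f"only {n} columns; theta_I estimate may be unstable")

    mu_init = max((x1.mean() / T1 + x2.mean() / T2) / 2, 1e-3)

    def unpack(z: np.ndarray):
        z = np.clip(z, -25.0, 25.0)
        theta = expit(z[0])
        a0, m0 = np.exp(z[1]), np.exp(z[2])
        if per_cluster_rates:
            a1, m1, a2, m2 = np.exp(z[3]), np.exp(z[4]), np.exp(z[5]), np.exp(z[6])
        else:
            a1, m1, a2, m2 = a0, m0, a0, m0
        return theta, a0, m0, a1, m1, a2, m2

    def mixture_parts(z: np.ndarray):
        theta, a0, m0, a1, m1, a2, m2 = unpack(z)
        ls = _log_shared(x1, x2, a0, a0 / m0, T1, T2)
        li = _log_nb(x1, a1, a1 / m1, T1) + _log_nb(x2, a2, a2 / m2, T2)
        return theta, ls, li

    def negll(z: np.ndarray) -> float:
        theta, ls, li = mixture_parts(z)
        mx = np.maximum(ls, li)
        ll = (np.log((1 - theta) * np.exp(ls - mx) + theta * np.exp(li - mx)) + mx).sum()
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    nz = 7 if per_cluster_rates else 3
    z0 = np.zeros(nz)
    z0[0] = 0.0  # theta ~ 0.5
    z0[1], z0[2] = np.log(1.0), np.log(mu_init)
    if per_cluster_rates:
        z0[3:] = [np.log(1.0), np.log(mu_init), np.log(1.0), np.log(mu_init)]
    best = None
    for r in range(n_restarts):
        start = z0 if r == 0 else z0 + rng.normal(0, 0.8, nz)
        res = minimize(negll, start, method="L-BFGS-B", options={"maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta, a0, m0, a1, m1, a2, m2 = unpack(best.x)
    ll_full = -best.fun

    # null fit: theta = 0 (shared state only -> plain bivariate NB)
    def negll0(z: np.ndarray) -> float:
        z = np.clip(z, -25.0, 25.0)
        a, m = np.exp(z[0]), np.exp(z[1])
        return -_log_shared(x1, x2, a, a / m, T1, T2).sum()

    best0 = None
    for r in range(n_restarts):
        s0 = np.array([0.0, np.log(mu_init)])
        start = s0 if r == 0 else s0 + rng.normal(0, 0.8, 2)
        res = minimize(negll0, start, method="L-BFGS-B", options={"maxiter": 300})
        if best0 is None or res.fun < best0.fun:
            best0 = res
    ll_null = -best0.fun
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 1.0

    # SE on the logit scale via finite-difference curvature, delta method
    h = 1e-3
    zp, zm = best.x.copy(), best.x.copy()
    zp[0] += h
    zm[0] -= h
    d2 = (negll(zp) - 2 * best.fun + negll(zm)) / h**2
    se = theta * (1 - theta) / np.sqrt(d2) if d2 > 0 else float("nan")

    _, ls, li = mixture_parts(best.x)
    mx = np.maximum(ls, li)
    num = theta * np.exp(li - mx)
    qk = num / (num + (1 - theta) * np.exp(ls - mx))

    est = ThetaEstimate("I", float(theta), float(se), float(stat), float(p),
                        aux={"alpha_shared": a0, "mu_shared": m0,
                             "alpha1": a1, "mu1": m1, "alpha2": a2, "mu2": m2,
                             "lnL": ll_full, "lnL_theta0": ll_null})
    return est, SitePosterior(qk, qk_cutoff, counts.columns)


# -- type II -----------------------------------------------------------------


def _consensus(column: np.ndarray, threshold: float = 0.6) -> str | None:
    vals = [c for c in column if c not in _MISSING]
    if not vals:
        return None
    top, cnt = max(((v, vals.count(v)) for v in set(vals)), key=lambda t: t[1])
    return top if cnt / len(vals) >= threshold else None


def _radical_fraction(scheme: dict[str, str]) -> float:
    """Fraction of random residue replacements that change property class."""
    aas = sorted(scheme)
    pairs = [(a, b) for a in aas for b in aas if a != b]
    return sum(scheme[a] != scheme[b] for a, b in pairs) / len(pairs)


def estimate_theta_II(aln: Alignment, tree: TimedTree | IndexedTree,
                      clusters: ClusterPair,
                      property_scheme: dict[str, str] | None = None,
                      consensus_threshold: float = 0.6,
                      qk_cutoff: float = 0.98
                      ) -> tuple[ThetaEstimate, SitePosterior]:
    """Moment estimate of the type II ("constant-but-different") coefficient.

    Columns conserved in both clusters (majority consensus >= threshold) are
    classified as identical, different-conservative, or different-radical
    (consensus residues in different physicochemical classes).  theta_II is
    the excess of radical columns over the neutral expectation
    ``(1 - exp(-d)) * r`` given the between-cluster branch length ``d`` and
    the scheme's radical replacement fraction ``r``.
    """
    scheme = property_scheme or DEFAULT_PROPERTY_SCHEME
    itree = tree if isinstance(tree, IndexedTree) else IndexedTree.from_timed_tree(tree)
    m1, tips1 = _subtree(itree, clusters.cluster1)
    m2, tips2 = _subtree(itree, clusters.cluster2)
    arr = aln.subset(itree.tip_labels).as_array()
    i1, i2 = sorted(tips1), sorted(tips2)

    d = _path_length(itree, m1, m2)  # between-cluster branch length (reference)
    r = _radical_fraction(scheme)

    cats: list[str] = []  # per column: identical | conservative | radical | variable
    cols: list[int] = []
    for j in range(arr.shape[1]):
        c1 = _consensus(arr[i1, j], consensus_threshold)
        c2 = _consensus(arr[i2, j], consensus_threshold)
        if c1 is None or c2 is None:
            cats.append("variable")
        elif c1 == c2:
            cats.append("identical")
        elif scheme.get(c1) == scheme.get(c2):
            cats.append("conservative")
        else:
            cats.append("radical")
        cols.append(j)

    cats_a = np.array(cats)
    n_cons = int((cats_a != "variable").sum())
    if n_cons == 0:
        raise ValidationError("theta_II undefined: no conserved columns")
    n_c = int((cats_a == "conservative").sum())
    n_rad = int((cats_a == "radical").sum())

    # Neutral expectation calibrated from the data: conservative differences
    # arise only from ordinary substitution on the connecting lineage, so the
    # substitution fraction among non-divergent conserved columns is
    # p_change = n_c / ((1 - theta) * n_cons * (1 - r)), and radical counts
    # decompose as n_rad/n_cons = theta + (1 - theta) * p_change * r.
    # Solving the two moment equations:
    A = n_c / (n_cons * (1.0 - r))  # = (1 - theta) * p_change
    theta = float(np.clip(n_rad / n_cons - A * r, 0.0, 1.0))
    f0 = A * r  # expected radical fraction without functional divergence
    f = n_rad / n_cons
    se = float(np.sqrt(max(f * (1 - f), 1e-12) / n_cons))

    # binomial LRT: among differing conserved columns, are radical changes in
    # excess of the scheme's neutral radical fraction r?  (boundary-aware)
    n_diff = n_c + n_rad
    if n_diff > 0:
        phat = min(max(n_rad / n_diff, 1e-12), 1 - 1e-12)
        if phat > r:
            ll1 = n_rad * np.log(phat) + n_c * np.log(1 - phat)
            ll0 = n_rad * np.log(r) + n_c * np.log(1 - r)
            stat = max(2.0 * (ll1 - ll0), 0.0)
        else:
            stat = 0.0
    else:
        stat = 0.0
    p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 1.0

    qk = np.zeros(len(cats))
    if theta > 0:
        q_rad = theta / (theta + max(f0, 1e-12) * (1 - theta)) if f0 > 0 else 1.0
        qk[cats_a == "radical"] = min(q_rad, 1.0)
    est = ThetaEstimate("II", theta, se, float(stat), float(p),
                        aux={"n_conserved": n_cons, "n_radical": n_rad,
                             "n_conservative": n_c,
                             "expected_fraction": f0, "between_cluster_length": d,
                             "radical_fraction": r,
                             "categories": cats_a})
    return est, SitePosterior(qk, qk_cutoff, np.array(cols))


def _path_length(itree: IndexedTree, a: int, b: int) -> float:
    anc_a: dict[int, float] = {}
    n, dist = a, 0.0
    while n >= 0:
        anc_a[n] = dist
        dist += itree.blen[n]
        n = itree.parent[n]
    n, dist = b, 0.0
    while n >= 0:
        if n in anc_a:
            return dist + anc_a[n]
        dist += itree.blen[n]
        n = itree.parent[n]
    raise ValidationError("nodes share no ancestor (corrupt tree)")


# -- reporting ---------------------------------------------------------------


def build_coordinate_map(reference_row: str) -> dict[int, int | None]:
    """Map 1-based alignment columns to 1-based ungapped reference positions.

    Columns where the reference has a gap map to ``None``.
    """
    out: dict[int, int | None] = {}
    pos = 0
    for j, ch in enumerate(reference_row, start=1):
        if ch in "-.":
            out[j] = None
        else:
            pos += 1
            out[j] = pos
    return out


def flag_divergent_sites(post: SitePosterior, cutoff: float | None = None,
                         coordinate_map: dict[int, int | None] | None = None
                         ) -> pd.DataFrame:
    """Table of sites with Q_k above the cutoff, in alignment and reference
    coordinates (both 1-based)."""
    cut = post.cutoff if cutoff is None else cutoff
    cols0 = post.columns if post.columns is not None else np.arange(post.qk.size)
    rows = []
    for i, q in enumerate(post.qk):
        col1 = int(cols0[i]) + 1
        ref = coordinate_map.get(col1) if coordinate_map else None
        rows.append((col1, ref, float(q), bool(q > cut)))
    return pd.DataFrame(rows, columns=["column", "ref_position", "qk", "flagged"])
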