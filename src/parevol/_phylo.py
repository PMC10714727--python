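"""Shared phylogenetic machinery: indexed trees, HKY/GY94 rate matrices,
reversible-matrix exponentials, Felsenstein pruning and state simulation.

Branch ids throughout are the index of the branch's child node.  Tips take
indices ``0 .. n_tips-1`` (leaf-iteration order of the source tree); internal
nodes follow in postorder, the root last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .core_io import CODON_INDEX, SENSE_CODONS, TimedTree, normalize_label

NUC = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUC)}
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_std = CodonTable.unambiguous_dna_by_id[1]
CODON_AA = np.array([_std.forward_table[c] for c in SENSE_CODONS])

# 0/1 masks over sense-codon pairs, precomputed once at import
_N = len(SENSE_CODONS)
_single_diff = np.full((_N, _N), -1, dtype=np.int8)  # differing position or -1
_is_ts = np.zeros((_N, _N), dtype=bool)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        diffs = [p for p in range(3) if _ci[p] != _cj[p]]
        if len(diffs) == 1:
            _p = diffs[0]
            _single_diff[_i, _j] = _p
            _is_ts[_i, _j] = (_ci[_p], _cj[_p]) in TRANSITIONS
_NONSYN = CODON_AA[:, None] != CODON_AA[None, :]
_SINGLE = _single_diff >= 0


@dataclass
class IndexedTree:
    """Array view of a rooted tree for vectorized likelihood work."""

    tip_labels: list[str]
    parent: np.ndarray  # (n_nodes,), -1 at root
    blen: np.ndarray  # (n_nodes,), branch length above each node; 0 at root
    children: list[list[int]]
    postorder: list[int]  # internal nodes only, children-before-parent
    root: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def branch_ids(self) -> list[int]:
        """All non-root node indices (= branch ids)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    @classmethod
    def from_timed_tree(cls, tt: TimedTree) -> "IndexedTree":
        return cls.from_dendropy(tt.tree)

    @classmethod
    def from_dendropy(cls, tree) -> "IndexedTree":
        leaves = list(tree.leaf_node_iter())
        index: dict[int, int] = {id(n): i for i, n in enumerate(leaves)}
        internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
        for n in internals:
            index[id(n)] = len(index)
        n_nodes = len(index)
        parent = np.full(n_nodes, -1, dtype=int)
        blen = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for n in tree.preorder_node_iter():
            i = index[id(n)]
            blen[i] = n.edge.length or 0.0
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
        root = index[id(tree.seed_node)]
        tips = [normalize_label(n.taxon.label) for n in leaves]
        post = [index[id(n)] for n in internals]
        return cls(tips, parent, blen, children, post, root)

    def node_times(self, tip_dates: dict[str, float]) -> np.ndarray:
        """Calendar date of every node, assuming branch lengths in years."""
        # root-to-node distances
        dist = np.zeros(self.n_nodes)
        order = [self.root]
        seen = [self.root]
        while order:
            n = order.pop()
            for c in self.children[n]:
                dist[c] = dist[n] + self.blen[c]
                order.append(c)
                seen.append(c)
        root_height = max(dist[i] for i in range(self.n_tips))
        latest = max(tip_dates[l] for l in self.tip_labels)
        root_date = latest - root_height
        return root_date + dist

    def mrca(self, tips: list[str]) -> int:
        """Index of the most recent common ancestor of the named tips."""
        want = {self.tip_labels.index(t) for t in tips}
        below: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            below[i] = {i}
        for n in self.postorder:
            for c in self.children[n]:
                below[n] |= below[c]
        # smallest clade containing all wanted tips
        best = self.root
        for n in list(range(self.n_tips)) + self.postorder:
            if want <= below[n] and len(below[n]) < len(below[best]):
                best = n
        return best

    def clade_tips(self, node: int) -> set[int]:
        if node < self.n_tips:
            return {node}
        out: set[int] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n < self.n_tips:
                out.add(n)
            else:
                stack.extend(self.children[n])
        return out


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------


def hky_rate_matrix(kappa: float, pi: np.ndarray, normalize: bool = True) -> np.ndarray:
    """HKY85 rate matrix (A,C,G,T order), scaled to 1 substitution/site/unit."""
    Q = np.zeros((4, 4))
    for i, bi in enumerate(NUC):
        for j, bj in enumerate(NUC):
            if i == j:
                continue
            rate = pi[j] * (kappa if (bi, bj) in TRANSITIONS else 1.0)
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
    return Q


def gy94_rate_matrix(kappa: float, omega: float, codon_pi: np.ndarray,
                     normalize: bool = True) -> np.ndarray:
    """Goldman-Yang codon rate matrix over the 61 sense codons.

    Single-nucleotide changes only; transition bias ``kappa``; nonsynonymous
    changes scaled by ``omega``; target-codon frequencies ``codon_pi``.
    Normalization divides by the mean rate of the *neutral* (omega = 1)
    matrix with the same kappa, so that in a site-class mixture omega > 1
    classes evolve genuinely faster than omega < 1 classes and one branch
    length unit equals one expected neutral substitution per codon.
    """
    Q = np.where(_SINGLE, codon_pi[None, :], 0.0)
    Q = Q * np.where(_is_ts, kappa, 1.0)
    if normalize:
        mu_neutral = float((codon_pi[:, None] * Q).sum())
        if mu_neutral > 0:
            Q = Q / mu_neutral
    Q = Q * np.where(_NONSYN, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class RevEigen:
    """Eigendecomposition of a reversible rate matrix: P(t) = (L e^{wt}) R."""

    w: np.ndarray
    L: np.ndarray
    R: np.ndarray

    def transition(self, t: float) -> np.ndarray:
        # eigenvalues of a reversible generator are <= 0; clamp numerical +eps
        P = (self.L * np.exp(np.minimum(self.w * t, 0.0))) @ self.R
        np.clip(P, 0.0, None, out=P)
        return P


def rev_eigen(Q: np.ndarray, pi: np.ndarray) -> RevEigen:
    d = np.sqrt(pi)
    B = Q * (d[:, None] / d[None, :])
    B = 0.5 * (B + B.T)  # symmetrize numerical noise
    w, V = np.linalg.eigh(B)
    L = V / d[:, None]
    R = V.T * d[None, :]
    return RevEigen(w, L, R)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def site_log_likelihoods(itree: IndexedTree, tip_states: np.ndarray,
                         P: dict[int, np.ndarray] | list, pi: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood by Felsenstein pruning with rescaling.

    ``tip_states``: (n_tips, n_sites) int array, -1 = missing (partial of
    ones).  ``P[b]`` is the transition matrix of the branch above node ``b``.
    """
    n_sites = tip_states.shape[1]
    S = pi.size
    logscale = np.zeros(n_sites)
    partial: dict[int, np.ndarray] = {}
    for node in itree.postorder:
        M = np.ones((n_sites, S))
        for c in itree.children[node]:
            Pc = P[c]
            if c < itree.n_tips:
                states = tip_states[c]
                msg = Pc.T[states.clip(min=0)]
                miss = states < 0
                if miss.any():
                    msg = msg.copy()
                    msg[miss] = 1.0
            else:
                msg = partial.pop(c) @ Pc.T
            M *= msg
        mx = M.max(axis=1)
        ok = mx > 0
        with np.errstate(divide="ignore"):
            logscale += np.where(ok, np.log(np.where(ok, mx, 1.0)), -np.inf)
        M = M / np.where(ok, mx, 1.0)[:, None]
        partial[node] = M
    root_like = partial[itree.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(root_like) + logscale


def compress_site_patterns(tip_states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns; returns (patterns, counts)."""
    uniq, counts = np.unique(tip_states.T, axis=0, return_counts=True)
    return uniq.T.copy(), counts


def batched_transitions(eig: RevEigen, ts: np.ndarray) -> np.ndarray:
    """Transition matrices for many branch lengths at once: (n, S, S)."""
    E = np.exp(np.minimum(np.outer(ts, eig.w), 0.0))
    P = np.matmul(eig.L[None, :, :] * E[:, None, :], eig.R)
    np.clip(P, 0.0, None, out=P)
    return P


def site_log_likelihoods_multi(itree: IndexedTree, tip_states: np.ndarray,
                               P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Pruning over several rate regimes at once.

    ``P`` has shape (C, n_nodes, S, S): one transition matrix per regime and
    branch (the root entry is ignored).  Returns (C, n_sites) log-likelihoods.
    """
    C = P.shape[0]
    n_sites = tip_states.shape[1]
    S = pi.size
    logscale = np.zeros((C, n_sites))
    partial: dict[int, np.ndarray] = {}
    for node in itree.postorder:
        M = np.ones((C, n_sites, S))
        for c in itree.children[node]:
            PcT = P[:, c].transpose(0, 2, 1)
            if c < itree.n_tips:
                states = tip_states[c]
                msg = PcT[:, states.clip(min=0), :]
                miss = states < 0
                if miss.any():
                    msg[:, miss, :] = 1.0
            else:
                msg = np.matmul(partial.pop(c), PcT)
            M *= msg
        mx = M.max(axis=2)
        ok = mx > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            logscale += np.where(ok, np.log(np.where(ok, mx, 1.0)), -np.inf)
            M /= np.where(ok, mx, 1.0)[:, :, None]
        np.nan_to_num(M, copy=False, nan=0.0)
        partial[node] = M
    root_like = partial[itree.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(root_like) + logscale


# ---------------------------------------------------------------------------
# Simulation of discrete states along a tree
# ---------------------------------------------------------------------------


def evolve_states(itree: IndexedTree, P: dict[int, np.ndarray] | list,
                  pi: np.ndarray, n_sites: int,
                  rng: np.random.Generator,
                  root_states: np.ndarray | None = None) -> np.ndarray:
    """Simulate site-independent evolution; returns (n_tips, n_sites) states."""
    S = pi.size
    states = np.empty((itree.n_nodes, n_sites), dtype=np.int64)
    if root_states is None:
        states[itree.root] = rng.choice(S, size=n_sites, p=pi)
    else:
        states[itree.root] = root_states
    order = [self_n for self_n in _preorder(itree)]
    for n in order:
        if n == itree.root:
            continue
        Pn = P[n]
        cum = Pn.cumsum(axis=1)
        u = rng.random(n_sites)
        par = states[itree.parent[n]]
        rows = cum[par]
        states[n] = (u[:, None] > rows).sum(axis=1).clip(max=S - 1)
    return states[: itree.n_tips]


def _preorder(itree: IndexedTree) -> list[int]:
    out = []
    stack = [itree.root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(itree.children[n])
    return out


# ---------------------------------------------------------------------------
# Frequency helpers
# ---------------------------------------------------------------------------


def empirical_base_freqs(seqs: list[str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        for i, b in enumerate(NUC):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def f3x4_codon_freqs(seqs: list[str]) -> np.ndarray:
    """F3x4 codon frequencies: per-codon-position base frequencies,
    product over positions, stops removed and renormalized."""
    counts = np.zeros((3, 4))
    for s in seqs:
        for k in range(len(s) // 3):
            cod = s[3 * k : 3 * k + 3]
            for p, b in enumerate(cod):
                if b in NUC_INDEX:
                    counts[p, NUC_INDEX[b]] += 1
    rowsum = counts.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    posfreq = counts / rowsum
    pi = np.array([
        posfreq[0, NUC_INDEX[c[0]]] * posfreq[1, NUC_INDEX[c[1]]] * posfreq[2, NUC_INDEX[c[2]]]
        for c in SENSE_CODONS
    ])
    if pi.sum() == 0:
        return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    return pi / pi.sum()


def codon_states(seqs: list[str]) -> np.ndarray:
    """(n_seqs, n_codons) sense-codon indices; -1 for gap/ambiguous codons."""
    n_codons = len(seqs[0]) // 3
    out = np.full((len(seqs), n_codons), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        for k in range(n_codons):
            out[i, k] = CODON_INDEX.get(s[3 * k : 3 * k + 3], -1)
    return out


def dna_states(seqs: list[str]) -> np.ndarray:
    """(n_seqs, n_sites) base indices; -1 for gaps/ambiguity codes."""
    arr = np.array([list(s) for s in seqs], dtype="U1")
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in NUC_INDEX.items():
        out[arr == b] = i
    return out
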