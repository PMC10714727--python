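"""Tree-aware detection of coevolving residue pairs after physicochemical
alphabet reduction.

Each alignment column is summarized by its *block signature*: the set of
maximal monophyletic groups of tips within which the (property-reduced)
residue is uniform.  Two columns whose blocks segregate on the same edges of
the tree receive a high co-segregation score (Jaccard agreement of block
sets; 1 = identical partitions).  Significance comes from tip permutations
within one column of the pair; significant pairs are single-linkage clustered
and summarized into intra-/inter-domain interaction weights (direct pair
scores plus indirect contributions through shared cluster members).

The scoring is inspired by blocks-in-sequences (BIS-style) coevolution
analysis for small alignments but is an independent formulation; exact
equivalence with any external tool is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._phylo import IndexedTree
from .core_io import Alignment, TimedTree, ValidationError
from .functional_divergence import DEFAULT_PROPERTY_SCHEME

__all__ = [
    "ReducedAlignment",
    "CoevolutionPair",
    "InteractionWeightMatrix",
    "DomainAnnotation",
    "reduce_alphabet",
    "column_tree_pattern",
    "signature_score",
    "detect_coevolving_pairs",
    "summarize_weights",
    "IDENTITY_SCHEME",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
IDENTITY_SCHEME: dict[str, str] = {a: a for a in AA20}
_MISSING = set("-.?X")


@dataclass
class ReducedAlignment:
    """Protein alignment recoded into property classes (-1 = gap/missing)."""

    ids: list[str]
    classes: np.ndarray  # (n_seqs, n_cols) int codes, -1 missing
    scheme_id: str
    class_names: list[str]

    @property
    def n_cols(self) -> int:
        return self.classes.shape[1]

    def constant_columns(self) -> np.ndarray:
        """Boolean mask of columns with <= 1 observed class (incl. all-gap)."""
        out = np.zeros(self.n_cols, dtype=bool)
        for j in range(self.n_cols):
            vals = set(self.classes[:, j][self.classes[:, j] >= 0])
            out[j] = len(vals) <= 1
        return out


def reduce_alphabet(aln: Alignment, scheme: dict[str, str] | str = "default"
                    ) -> ReducedAlignment:
    """Recode a protein alignment into physicochemical classes.

    ``scheme`` is a residue->class mapping covering the 20 standard residues,
    or ``"default"`` (5 classes: nonpolar, polar, positive, negative,
    aromatic) or ``"identity"`` (20 classes, alignment unchanged).
    """
    if aln.alphabet != "protein":
        raise ValidationError("reduce_alphabet expects a protein alignment")
    if scheme == "default":
        table, sid = DEFAULT_PROPERTY_SCHEME, "property5"
    elif scheme == "identity":
        table, sid = IDENTITY_SCHEME, "identity"
    else:
        table, sid = dict(scheme), "custom"
    missing = set(AA20) - set(table)
    if missing:
        raise ValidationError(f"scheme does not cover residue(s): {sorted(missing)}")
    class_names = sorted(set(table.values()))
    code = {a: class_names.index(c) for a, c in table.items()}
    arr = aln.as_array()
    out = np.full(arr.shape, -1, dtype=np.int64)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            ch = arr[i, j]
            if ch in _MISSING:
                continue
            if ch not in code:
                raise ValidationError(f"unknown residue {ch!r} in {aln.ids[i]} column {j + 1}")
            out[i, j] = code[ch]
    return ReducedAlignment(list(aln.ids), out, sid, class_names)


# ---------------------------------------------------------------------------
# Block signatures
# ---------------------------------------------------------------------------


def _prepare_tree(itree: IndexedTree):
    """Cache per-node tip bitmasks and a root-first node order."""
    masks = np.zeros(itree.n_nodes, dtype=object)
    for i in range(itree.n_tips):
        masks[i] = 1 << i
    for n in itree.postorder:
        m = 0
        for c in itree.children[n]:
            m |= masks[c]
        masks[n] = m
    return masks


_WILD = -2
_CONFLICT = -1


def column_tree_pattern(col: np.ndarray, itree: IndexedTree,
                        _masks=None) -> frozenset[int]:
    """Block signature of a column: maximal monophyletic uniform-state blocks.

    ``col`` holds one class code per tip (-1 = missing, which is compatible
    with any state).  Returns a frozenset of tip bitmasks, one per block.
    """
    masks = _prepare_tree(itree) if _masks is None else _masks
    state = np.empty(itree.n_nodes, dtype=np.int64)
    state[: itree.n_tips] = np.where(col < 0, _WILD, col)
    for n in itree.postorder:
        s = _WILD
        for c in itree.children[n]:
            sc = state[c]
            if sc == _CONFLICT:
                s = _CONFLICT
                break
            if sc == _WILD:
                continue
            if s == _WILD:
                s = sc
            elif s != sc:
                s = _CONFLICT
                break
        state[n] = s
    blocks: list[int] = []
    stack = [itree.root]
    while stack:
        n = stack.pop()
        if state[n] != _CONFLICT:
            blocks.append(int(masks[n]))
        else:
            stack.extend(itree.children[n])
    return frozenset(blocks)


def signature_score(sig_i: frozenset[int], sig_j: frozenset[int]) -> float:
    """Jaccard agreement of two block signatures (1 = identical partitions)."""
    inter = len(sig_i & sig_j)
    union = len(sig_i | sig_j)
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# Pair detection
# ---------------------------------------------------------------------------


@dataclass
class CoevolutionPair:
    column_i: int  # 1-based alignment coordinate, i < j
    column_j: int
    score: float
    p_value: float
    q_value: float
    cluster: int


def _bh(pvals: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg: returns (reject mask, q-values)."""
    m = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.clip(q, 0, 1)
    return qvals <= alpha, qvals


def detect_coevolving_pairs(raln: ReducedAlignment, tree: TimedTree | IndexedTree,
                            n_permutations: int = 1000, alpha: float = 0.05,
                            seed: int = 0) -> list[CoevolutionPair]:
    """Detect column pairs whose states co-segregate on the tree.

    For each non-constant column pair the co-segregation score is the Jaccard
    agreement of block signatures; the null distribution comes from permuting
    one column's states across tips (``n_permutations`` seeded draws).  Pairs
    with permutation p <= ``alpha`` are retained and single-linkage clustered
    (columns sharing a pair join a cluster); Benjamini-Hochberg q-values over
    all pairs are reported alongside for stricter filtering (the permutation
    floor of 1/(n_permutations+1) makes q-values too coarse to threshold
    directly at practicable permutation counts).
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations < 100: permutation resolution too coarse")
    itree = tree if isinstance(tree, IndexedTree) else IndexedTree.from_timed_tree(tree)
    order = [raln.ids.index(l) for l in itree.tip_labels]
    classes = raln.classes[order]

    keep = np.flatnonzero(~raln.constant_columns())
    if keep.size < 2:
        raise ValidationError("need >= 2 non-constant columns")
    masks = _prepare_tree(itree)
    rng = np.random.default_rng(seed)

    sigs = {j: column_tree_pattern(classes[:, j], itree, masks) for j in keep}
    perm_sigs: dict[int, list[frozenset[int]]] = {}
    for j in keep:
        col = classes[:, j]
        perms = []
        for _ in range(n_permutations):
            perms.append(column_tree_pattern(rng.permutation(col), itree, masks))
        perm_sigs[j] = perms

    pairs = []
    pvals = []
    for a in range(keep.size):
        for b in range(a + 1, keep.size):
            i, j = int(keep[a]), int(keep[b])
            obs = signature_score(sigs[i], sigs[j])
            null_ge = sum(1 for ps in perm_sigs[j] if signature_score(sigs[i], ps) >= obs)
            p = (1 + null_ge) / (n_permutations + 1)
            pairs.append((i, j, obs))
            pvals.append(p)
    pvals = np.array(pvals)
    _, qvals = _bh(pvals, alpha)
    reject = pvals <= alpha

    # single-linkage clustering of significant pairs via shared columns
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    sig_pairs = [(i, j, s, p, q) for (i, j, s), p, q, r in
                 zip(pairs, pvals, qvals, reject) if r]
    sig_pairs.sort(key=lambda t: (t[0], t[1]))
    for i, j, *_ in sig_pairs:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        union(i, j)
    roots = sorted({find(i) for i, j, *_ in sig_pairs} | {find(j) for i, j, *_ in sig_pairs})
    cluster_id = {r: k + 1 for k, r in enumerate(roots)}

    return [CoevolutionPair(i + 1, j + 1, s, p, q, cluster_id[find(i)])
            for i, j, s, p, q in sig_pairs]


# ---------------------------------------------------------------------------
# Domain weights
# ---------------------------------------------------------------------------


@dataclass
class DomainAnnotation:
    """Domain table with 1-based inclusive residue ranges."""

    table: pd.DataFrame  # columns: domain, start, end

    def __post_init__(self) -> None:
        need = {"domain", "start", "end"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"domain table needs columns {sorted(need)}")
        rows = self.table.sort_values("start").reset_index(drop=True)
        for k in range(1, len(rows)):
            if rows.loc[k, "start"] <= rows.loc[k - 1, "end"]:
                raise ValidationError(
                    f"overlapping domain ranges: {rows.loc[k - 1, 'domain']} and "
                    f"{rows.loc[k, 'domain']}")
        self.table = rows

    def domain_of(self, position: int) -> str:
        hit = self.table[(self.table["start"] <= position) & (position <= self.table["end"])]
        return str(hit.iloc[0]["domain"]) if len(hit) else "other"

    @classmethod
    def from_tsv(cls, path) -> "DomainAnnotation":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class InteractionWeightMatrix:
    """Symmetric domain-by-domain sum of interaction weights."""

    matrix: pd.DataFrame
    direct: pd.DataFrame = field(repr=False, default=None)
    indirect: pd.DataFrame = field(repr=False, default=None)


def summarize_weights(pairs: list[CoevolutionPair],
                      domains: DomainAnnotation) -> InteractionWeightMatrix:
    """Domain-level interaction weights from significant pairs.

    Direct weight: each pair adds its score to (domain_i, domain_j).
    Indirect weight: within each coevolution cluster, every path a-b-c
    through a shared member b adds min(score(a,b), score(b,c)) to
    (domain_a, domain_c), counted once per path.
    """
    names = list(domains.table["domain"]) + ["other"]
    direct = pd.DataFrame(0.0, index=names, columns=names)
    indirect = pd.DataFrame(0.0, index=names, columns=names)

    def add(df: pd.DataFrame, d1: str, d2: str, w: float) -> None:
        df.loc[d1, d2] += w
        if d1 != d2:
            df.loc[d2, d1] += w

    for p in pairs:
        add(direct, domains.domain_of(p.column_i), domains.domain_of(p.column_j), p.score)

    by_cluster: dict[int, list[CoevolutionPair]] = {}
    for p in pairs:
        by_cluster.setdefault(p.cluster, []).append(p)
    for members in by_cluster.values():
        adj: dict[int, dict[int, float]] = {}
        for p in members:
            adj.setdefault(p.column_i, {})[p.column_j] = p.score
            adj.setdefault(p.column_j, {})[p.column_i] = p.score
        for b, nbrs in adj.items():
            cols = sorted(nbrs)
            for x in range(len(cols)):
                for y in range(x + 1, len(cols)):
                    a, c = cols[x], cols[y]
                    w = min(nbrs[a], nbrs[c])
                    add(indirect, domains.domain_of(a), domains.domain_of(c), w)

    return InteractionWeightMatrix(direct + indirect, direct, indirect)
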