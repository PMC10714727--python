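"""Seeded generators for every analysis stage in the package.

Each generator emulates the statistical structure its downstream estimator
assumes — heterochronous/isochronous tip sampling on clocklike trees, HKY
sequence evolution with epoch-varying transition bias, GY94 codon evolution
with branch-site omega classes, two-cluster protein alignments with a planted
fraction of rate-shifted or constant-but-different sites, alignments with
planted co-segregating column pairs, and 5'UTR sets with SD-like motifs at
known frequency and spacing — and returns a truth envelope sufficient to
score downstream recovery.

A single global seed fans out to per-stage child seeds through
``stage_rng(seed, stage_name)`` (CRC32 of the stage name mixed into a
``SeedSequence``), so stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass

import dendropy
import msprime
import numpy as np

from ._phylo import (
    IndexedTree,
    NUC,
    dna_states,
    evolve_states,
    gy94_rate_matrix,
    hky_rate_matrix,
    rev_eigen,
)
from .core_io import SENSE_CODONS, Alignment, TimedTree, ValidationError
from .epoch_divergence import EpochPartition, assign_epochs
from .functional_divergence import DEFAULT_PROPERTY_SCHEME
from .sd_motifs import AnnotatedSegment, CANONICAL

__all__ = [
    "SimulationConfig",
    "stage_rng",
    "simulate_timed_tree",
    "as_divergence_tree",
    "simulate_dna",
    "simulate_codon",
    "simulate_divergent_clusters",
    "simulate_change_counts",
    "simulate_coevolving_alignment",
    "simulate_utr_set",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named stage, derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclass
class SimulationConfig:
    """Bundle of generator settings (the defaults are the study conditions)."""

    seed: int = 0
    n_taxa: int = 20
    tree_model: str = "coalescent"  # or "birth-death"
    pop_size: float = 50.0
    birth_rate: float = 1.0
    death_rate: float = 0.3
    sampling_window: float = 100.0  # years; 0 = isochronous
    latest_year: float = 2020.0
    clock_rate: float = 1e-3  # substitutions/site/year
    sequence_length: int = 300
    kappa: float | list[float] = 4.0
    omega0: float = 0.1
    omega2: float = 6.0
    p0: float = 0.5
    p1: float = 0.3
    theta: float = 0.3
    gamma_shape: float = 0.5
    sd_frequency: float = 0.6
    sd_mutation_rate: float = 0.0


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_timed_tree(n_taxa: int = 20, model: str = "coalescent",
                        pop_size: float = 50.0, sampling_window: float = 100.0,
                        isochronous: bool = False, latest_year: float = 2020.0,
                        birth_rate: float = 1.0, death_rate: float = 0.3,
                        seed: int = 0, max_retries: int = 100) -> TimedTree:
    """Simulate a rooted timed tree with dated tips (branch lengths in years).

    Coalescent trees come from msprime (haploid samples, population size in
    units of years); heterochronous tips are spread evenly over
    ``sampling_window`` years before ``latest_year``.  The birth-death model
    is a forward simulation stopped when ``n_taxa`` lineages are extant
    (isochronous tips); draws that go extinct first are retried.
    """
    if n_taxa < 3:
        raise ValidationError("need >= 3 taxa")
    rng = stage_rng(seed, "timed-tree")
    if isochronous or sampling_window == 0:
        times = np.zeros(n_taxa)
    else:
        times = np.linspace(0.0, sampling_window, n_taxa)
    if model == "coalescent":
        samples = [msprime.SampleSet(1, time=float(t), ploidy=1) for t in times]
        ts = msprime.sim_ancestry(samples=samples, ploidy=1,
                                  population_size=pop_size,
                                  random_seed=int(rng.integers(1, 2**31 - 1)))
        tables = ts
        tree = tables.first()
        node_labels = {}
        node_time = {}
        for k, u in enumerate(ts.samples()):
            t = ts.node(u).time
            date = latest_year - t
            node_labels[u] = f"t{k}_{date:.4f}"
            node_time[u] = t
        newick = tree.as_newick(node_labels=node_labels)
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.is_rooted = True
        dates = {lbl: latest_year - node_time[u] for u, lbl in node_labels.items()}
        return TimedTree(dtree, {k: float(v) for k, v in dates.items()})
    if model == "birth-death":
        for _ in range(max_retries):
            tt = _birth_death_once(n_taxa, birth_rate, death_rate, latest_year, rng)
            if tt is not None:
                return tt
        raise ValidationError(f"birth-death simulation went extinct {max_retries} times")
    raise ValidationError(f"unknown tree model {model!r}")


def _birth_death_once(n_taxa, lam, mu, latest_year, rng) -> TimedTree | None:
    # forward simulation; node = [parent, birth_time]; stop at n_taxa extant
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    extant = [(tree.seed_node, 0.0)]
    t = 0.0
    while len(extant) < n_taxa:
        k = len(extant)
        if k == 0:
            return None
        rate = k * (lam + mu)
        t += rng.exponential(1.0 / rate)
        idx = int(rng.integers(k))
        node, birth = extant.pop(idx)
        node.edge.length = t - birth
        if rng.random() < lam / (lam + mu):
            for _ in range(2):
                child = dendropy.Node()
                node.add_child(child)
                extant.append((child, t))
        # else: death, lineage dropped (will be pruned implicitly)
    dates = {}
    for i, (node, birth) in enumerate(extant):
        node.edge.length = t - birth
        lbl = f"t{i}_{latest_year:.4f}"
        node.taxon = taxon_ns.new_taxon(lbl)
        dates[lbl] = latest_year
    # prune extinct lineages (leaves without taxa)
    changed = True
    while changed:
        changed = False
        for leaf in list(tree.leaf_node_iter()):
            if leaf.taxon is None and leaf is not tree.seed_node:
                leaf.parent_node.remove_child(leaf)
                changed = True
    tree.suppress_unifurcations()
    if len(tree.leaf_nodes()) != n_taxa:
        return None
    return TimedTree(tree, dates)


def as_divergence_tree(tt: TimedTree, rate: float, noise_sd: float = 0.0,
                       seed: int = 0) -> TimedTree:
    """Rescale a time tree (years) to genetic distance at ``rate``
    substitutions/site/year, optionally adding Gaussian noise to terminal
    branches (clipped at zero)."""
    out = tt.clone()
    rng = stage_rng(seed, "divergence-noise")
    for edge in out.tree.preorder_edge_iter():
        if edge.length is None:
            continue
        L = edge.length * rate
        if noise_sd > 0 and edge.head_node.is_leaf():
            L = max(L + rng.normal(0.0, noise_sd), 0.0)
        edge.length = L
    return out


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def simulate_dna(tree: TimedTree, kappa: float | list[float],
                 base_freqs: np.ndarray | None = None, length: int = 300,
                 seed: int = 0, rate: float = 1.0,
                 partition: EpochPartition | None = None) -> Alignment:
    """HKY evolution along a timed tree; per-epoch kappa when a list is given.

    Branch lengths are years times ``rate`` (substitutions/site/year); each
    branch takes the kappa of its temporal-midpoint epoch.
    """
    rng = stage_rng(seed, "dna")
    itree = IndexedTree.from_timed_tree(tree)
    pi = np.full(4, 0.25) if base_freqs is None else np.asarray(base_freqs, float)
    if np.isscalar(kappa) or isinstance(kappa, float):
        kappas = [float(kappa)]
        branch_epoch = {b: 1 for b in itree.branch_ids()}
    else:
        kappas = [float(k) for k in kappa]
        if partition is None:
            partition = assign_epochs(tree, n_epochs=len(kappas))
        branch_epoch = {b: partition.midpoint_epoch[b] for b in itree.branch_ids()}
    eigs = {e + 1: rev_eigen(hky_rate_matrix(k, pi), pi) for e, k in enumerate(kappas)}
    P = {b: eigs[branch_epoch[b]].transition(rate * itree.blen[b])
         for b in itree.branch_ids()}
    tips = evolve_states(itree, P, pi, length, rng)
    seqs = ["".join(NUC[s] for s in row) for row in tips]
    return Alignment(list(itree.tip_labels), seqs, "dna")


def simulate_codon(tree: TimedTree, kappa: float = 2.0, omega0: float = 0.1,
                   omega2: float = 6.0, p0: float = 0.5, p1: float = 0.3,
                   foreground: set[int] | None = None,
                   codon_freqs: np.ndarray | None = None, n_codons: int = 300,
                   seed: int = 0, rate: float = 1.0
                   ) -> tuple[Alignment, dict]:
    """GY94 codon evolution with branch-site (model A) site classes.

    Site classes 0 / 1 / 2a / 2b get weights (p0, p1, p2*p0/(p0+p1),
    p2*p1/(p0+p1)); classes 2a/2b take ``omega2`` on the foreground branches.
    Returns the codon alignment and a truth envelope with the per-site class.
    """
    if p0 < 0 or p1 < 0 or p0 + p1 > 1:
        raise ValidationError("need p0, p1 >= 0 and p0 + p1 <= 1")
    rng = stage_rng(seed, "codon")
    itree = IndexedTree.from_timed_tree(tree)
    fg = frozenset(foreground or ())
    pi = (np.full(61, 1.0 / 61.0) if codon_freqs is None
          else np.asarray(codon_freqs, float))
    p2 = 1.0 - p0 - p1
    tot = p0 + p1 if p0 + p1 > 0 else 1.0
    weights = np.array([p0, p1, p2 * p0 / tot, p2 * p1 / tot])
    weights /= weights.sum()
    site_class = rng.choice(4, size=n_codons, p=weights)

    regimes = [(omega0, omega0), (1.0, 1.0), (omega0, omega2), (1.0, omega2)]
    eig = {w: rev_eigen(gy94_rate_matrix(kappa, w, pi), pi)
           for w in {omega0, 1.0, omega2}}
    tip_states = np.empty((itree.n_tips, n_codons), dtype=np.int64)
    for c, (bg, fgw) in enumerate(regimes):
        cols = np.flatnonzero(site_class == c)
        if cols.size == 0:
            continue
        P = {b: eig[fgw if b in fg else bg].transition(rate * itree.blen[b])
             for b in itree.branch_ids()}
        tip_states[:, cols] = evolve_states(itree, P, pi, cols.size, rng)
    seqs = ["".join(SENSE_CODONS[s] for s in row) for row in tip_states]
    aln = Alignment(list(itree.tip_labels), seqs, "codon")
    truth = {"site_class": site_class, "foreground": sorted(fg),
             "kappa": kappa, "omega0": omega0, "omega2": omega2,
             "p0": p0, "p1": p1, "seed": seed}
    return aln, truth


# ---------------------------------------------------------------------------
# Functional-divergence generators
# ---------------------------------------------------------------------------


def simulate_change_counts(theta: float, alpha: float, mu: float,
                           tree_length1: float, tree_length2: float,
                           n_columns: int = 500, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column substitution counts under the type-I rate mixture.

    With probability ``theta`` a column draws independent Gamma(alpha,
    alpha/mu) rates per cluster, otherwise one shared rate; counts are
    Poisson(rate * tree_length).  Returns (x1, x2, divergent_mask).
    """
    if not 0.0 <= theta <= 1.0:
        raise ValidationError("theta must lie in [0, 1]")
    rng = stage_rng(seed, "change-counts")
    div = rng.random(n_columns) < theta
    lam1 = rng.gamma(alpha, mu / alpha, size=n_columns)
    lam2 = np.where(div, rng.gamma(alpha, mu / alpha, size=n_columns), lam1)
    x1 = rng.poisson(lam1 * tree_length1)
    x2 = rng.poisson(lam2 * tree_length2)
    return x1, x2, div


_CLASS_MEMBERS: dict[str, str] = {}
for _a, _c in DEFAULT_PROPERTY_SCHEME.items():
    _CLASS_MEMBERS[_c] = _CLASS_MEMBERS.get(_c, "") + _a


def simulate_divergent_clusters(tree: TimedTree, cluster1: list[str],
                                cluster2: list[str], theta: float = 0.3,
                                divergence_type: str = "I",
                                gamma_shape: float = 0.5, mean_rate: float = 1.0,
                                length: int = 500, seed: int = 0
                                ) -> tuple[Alignment, dict]:
    """Two-cluster protein alignment with a planted fraction theta of
    divergent columns.

    Type I: divergent columns evolve with independent Gamma rates per cluster
    (shared otherwise) under a 20-state equal-rates model.  Type II:
    divergent columns are held constant within each cluster but fixed for
    residues of different physicochemical classes; the rest are constant and
    identical (a small background of freely evolving columns is added so the
    alignment is not wholly invariant).
    """
    rng = stage_rng(seed, "divergent-clusters")
    itree = IndexedTree.from_timed_tree(tree)
    tips1 = {itree.tip_labels.index(t) for t in cluster1}
    tips2 = {itree.tip_labels.index(t) for t in cluster2}
    div = rng.random(length) < theta
    n_aa = 20
    pi = np.full(n_aa, 1.0 / n_aa)
    Q = (np.ones((n_aa, n_aa)) - n_aa * np.eye(n_aa)) / (n_aa - 1)
    eig = rev_eigen(Q, pi)

    def branch_cluster(b: int) -> int:
        tips = itree.clade_tips(b)
        if tips <= tips1:
            return 1
        if tips <= tips2:
            return 2
        return 0

    bcl = {b: branch_cluster(b) for b in itree.branch_ids()}
    cols = np.empty((itree.n_tips, length), dtype=np.int64)
    if divergence_type == "I":
        lam1 = rng.gamma(gamma_shape, mean_rate / gamma_shape, size=length)
        lam2 = np.where(div, rng.gamma(gamma_shape, mean_rate / gamma_shape, size=length), lam1)
        lam0 = 0.5 * (lam1 + lam2)
        for j in range(length):
            mult = {0: lam0[j], 1: lam1[j], 2: lam2[j]}
            P = {b: eig.transition(mult[bcl[b]] * itree.blen[b])
                 for b in itree.branch_ids()}
            cols[:, j] = evolve_states(itree, P, pi, 1, rng)[:, 0]
    elif divergence_type == "II":
        classes = list(_CLASS_MEMBERS)
        for j in range(length):
            if div[j]:
                c1, c2 = rng.choice(len(classes), size=2, replace=False)
                a1 = _CLASS_MEMBERS[classes[c1]][rng.integers(len(_CLASS_MEMBERS[classes[c1]]))]
                a2 = _CLASS_MEMBERS[classes[c2]][rng.integers(len(_CLASS_MEMBERS[classes[c2]]))]
                i1, i2 = AA20.index(a1), AA20.index(a2)
                for t in range(itree.n_tips):
                    cols[t, j] = i1 if t in tips1 else (i2 if t in tips2 else i1)
            elif rng.random() < 0.2:  # variable background
                P = {b: eig.transition(mean_rate * itree.blen[b])
                     for b in itree.branch_ids()}
                cols[:, j] = evolve_states(itree, P, pi, 1, rng)[:, 0]
            else:
                cols[:, j] = rng.integers(n_aa)
    else:
        raise ValidationError("divergence_type must be 'I' or 'II'")
    seqs = ["".join(AA20[s] for s in row) for row in cols]
    aln = Alignment(list(itree.tip_labels), seqs, "protein")
    return aln, {"divergent": div, "theta": theta, "type": divergence_type, "seed": seed}


# ---------------------------------------------------------------------------
# Coevolution generator
# ---------------------------------------------------------------------------


def simulate_coevolving_alignment(tree: TimedTree, n_background: int = 30,
                                  n_planted_pairs: int = 1, seed: int = 0
                                  ) -> tuple[Alignment, dict]:
    """Protein alignment with planted co-segregating column pairs.

    Each planted pair splits jointly on one internal edge of the tree: inside
    the clade both columns carry residues of one physicochemical class,
    outside of another, so their block signatures agree exactly.  Background
    columns are iid uniform residues per tip (the permutation null).
    """
    rng = stage_rng(seed, "coevolution")
    itree = IndexedTree.from_timed_tree(tree)
    # plant only on edges with >= 4 tips per side (falling back to 3): smaller
    # clades leave the permutation null too little entropy to reach small p
    def edges_with(min_side: int) -> list[int]:
        return [b for b in itree.branch_ids()
                if b >= itree.n_tips
                and min_side <= len(itree.clade_tips(b)) <= itree.n_tips - min_side]

    internal = edges_with(4) or edges_with(3)
    if not internal:
        raise ValidationError("tree has no internal edge suitable for planting")
    n_cols = n_background + 2 * n_planted_pairs
    arr = np.empty((itree.n_tips, n_cols), dtype="U1")
    for j in range(n_cols):
        arr[:, j] = [AA20[i] for i in rng.integers(20, size=itree.n_tips)]
    classes = list(_CLASS_MEMBERS)
    truth_pairs = []
    for k in range(n_planted_pairs):
        edge = internal[int(rng.integers(len(internal)))]
        clade = itree.clade_tips(edge)
        c_in, c_out = rng.choice(len(classes), size=2, replace=False)
        j1, j2 = n_background + 2 * k, n_background + 2 * k + 1
        for j, jitter in ((j1, 0), (j2, 1)):
            a_in = _CLASS_MEMBERS[classes[c_in]][jitter % len(_CLASS_MEMBERS[classes[c_in]])]
            a_out = _CLASS_MEMBERS[classes[c_out]][jitter % len(_CLASS_MEMBERS[classes[c_out]])]
            for t in range(itree.n_tips):
                arr[t, j] = a_in if t in clade else a_out
        truth_pairs.append((j1 + 1, j2 + 1))
    seqs = ["".join(row) for row in arr]
    aln = Alignment(list(itree.tip_labels), seqs, "protein")
    return aln, {"pairs": truth_pairs, "seed": seed}


# ---------------------------------------------------------------------------
# SD motif generator
# ---------------------------------------------------------------------------


def _random_no_gg(length: int, rng: np.random.Generator) -> str:
    """Random DNA without any GG dinucleotide (so no spurious core match)."""
    out = []
    prev = ""
    for _ in range(length):
        pool = "ACT" if prev == "G" else "ACGT"
        b = pool[int(rng.integers(len(pool)))]
        out.append(b)
        prev = b
    return "".join(out)


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    body = "".join(SENSE_CODONS[int(rng.integers(61))] for _ in range(n_codons))
    return "ATG" + body + "TAA"


def simulate_utr_set(n: int = 100, sd_frequency: float = 0.6,
                     spacer_choices: tuple[int, ...] = (3, 4, 5, 6, 7),
                     spacer_weights: tuple[float, ...] | None = None,
                     mutation_rate: float = 0.0, na_fraction: float = 0.1,
                     utr_length: int = 30, seed: int = 0
                     ) -> tuple[list[AnnotatedSegment], dict]:
    """Genome segments whose 5'UTRs carry a planted canonical SD motif.

    With probability ``sd_frequency`` the canonical AGGAGGT is planted with a
    spacer drawn from ``spacer_choices``; ``na_fraction`` of the remaining
    strains get a UTR too short to scan; the rest carry a GG-free background
    (category *absent*).  The whole UTR is then point-mutated at
    ``mutation_rate`` per base.  The truth table records the planted category
    and spacer per strain.
    """
    rng = stage_rng(seed, "utr-set")
    if spacer_weights is None:
        w = np.ones(len(spacer_choices)) / len(spacer_choices)
    else:
        w = np.asarray(spacer_weights, float)
        w = w / w.sum()
    segments = []
    truth = {}
    for i in range(n):
        sid = f"s{i:03d}"
        planted = rng.random() < sd_frequency
        if planted:
            spacer = int(rng.choice(spacer_choices, p=w))
            head = _random_no_gg(utr_length - 7 - spacer, rng)
            tail = _random_no_gg(spacer, rng)
            utr = head + CANONICAL + tail
            truth[sid] = {"category": "canonical", "spacer": spacer}
        elif rng.random() < na_fraction:
            utr = _random_no_gg(int(rng.integers(0, 9)), rng)
            truth[sid] = {"category": "NA", "spacer": None}
        else:
            utr = _random_no_gg(utr_length, rng)
            truth[sid] = {"category": "absent", "spacer": None}
        if mutation_rate > 0 and utr:
            chars = list(utr)
            for k in range(len(chars)):
                if rng.random() < mutation_rate:
                    chars[k] = "ACGT".replace(chars[k], "")[int(rng.integers(3))]
            utr = "".join(chars)
        orf = _random_orf(10, rng)
        seq = utr + orf
        segments.append(AnnotatedSegment(sid, seq, [("ORF1", len(utr) + 1, len(utr) + len(orf))]))
    return segments, {"truth": truth, "sd_frequency": sd_frequency,
                      "mutation_rate": mutation_rate, "seed": seed}
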