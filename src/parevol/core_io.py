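"""Readers, writers and validated containers for trees, alignments and metadata.

Trees are time-aware: every tip carries a decimal calendar year, either parsed
from the label (``name_2004`` / ``name_2004.37``, date after the last
underscore) or supplied in a sidecar TSV.  Node heights are expressed in years
before the most recent tip.  Alignments are thin validated wrappers around
Biopython parsing with DNA / codon / protein alphabets.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TimedTree",
    "Alignment",
    "StrainMetadata",
    "read_timed_tree",
    "write_timed_tree",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CODON_INDEX",
    "normalize_label",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "TCAG"
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_DATE_RE = re.compile(r"^(?P<name>.+)_(?P<year>\d{1,4}(?:\.\d+)?)$")


def normalize_label(label: str) -> str:
    """Normalize a tip/sequence label: strip whitespace, spaces to underscores.

    Idempotent by construction.
    """
    return re.sub(r"\s+", "_", label.strip())


class ValidationError(ValueError):
    """Raised when an input file violates a documented contract."""


# ---------------------------------------------------------------------------
# TimedTree
# ---------------------------------------------------------------------------


@dataclass
class TimedTree:
    """A rooted tree whose tips carry decimal calendar-year dates.

    ``tree`` is a rooted :class:`dendropy.Tree`; branch lengths are in years
    for time-calibrated trees, or in substitutions/site for divergence trees
    used by root-to-tip regression.  ``tip_dates`` maps normalized tip labels
    to decimal years.
    """

    tree: dendropy.Tree
    tip_dates: dict[str, float]

    def __post_init__(self) -> None:
        tips = self.tip_labels()
        missing = [t for t in tips if t not in self.tip_dates]
        if missing:
            raise ValidationError(f"missing date for tip(s): {', '.join(sorted(missing))}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in tree")

    # -- basic accessors ----------------------------------------------------
    def tip_labels(self) -> list[str]:
        return [normalize_label(l.taxon.label) for l in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def latest_date(self) -> float:
        return max(self.tip_dates[t] for t in self.tip_labels())

    @property
    def earliest_date(self) -> float:
        return min(self.tip_dates[t] for t in self.tip_labels())

    def is_isochronous(self, tol: float = 1e-12) -> bool:
        dates = [self.tip_dates[t] for t in self.tip_labels()]
        return max(dates) - min(dates) <= tol

    # -- derived geometry ---------------------------------------------------
    def root_to_tip_distances(self) -> dict[str, float]:
        """Path length (sum of branch lengths) from the root to each tip."""
        out: dict[str, float] = {}
        dist: dict[int, float] = {id(self.tree.seed_node): 0.0}
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node:
                dist[id(node)] = dist[id(node.parent_node)] + (node.edge.length or 0.0)
            if node.is_leaf():
                out[normalize_label(node.taxon.label)] = dist[id(node)]
        return out

    def node_heights(self) -> dict[dendropy.Node, float]:
        """Height of every node in years before the most recent tip.

        Assumes branch lengths are in years (a time tree).  Heights are
        computed from root-to-node path lengths; the root height equals the
        maximum root-to-tip path length.
        """
        dist: dict[dendropy.Node, float] = {self.tree.seed_node: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node:
                dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
        root_height = max(d for n, d in dist.items() if n.is_leaf())
        return {n: root_height - d for n, d in dist.items()}

    def node_dates(self) -> dict[dendropy.Node, float]:
        """Calendar year of every node on a time tree."""
        heights = self.node_heights()
        latest = self.latest_date
        return {n: latest - h for n, h in heights.items()}

    def check_time_consistency(self, tol: float = 1e-6) -> None:
        """Verify branch lengths (years) agree with tip dates.

        For a time tree the height of each tip must equal
        ``latest_date - tip_date``.
        """
        heights = self.node_heights()
        latest = self.latest_date
        for node in self.tree.leaf_node_iter():
            lbl = normalize_label(node.taxon.label)
            expect = latest - self.tip_dates[lbl]
            if abs(heights[node] - expect) > tol:
                raise ValidationError(
                    f"tip {lbl}: height {heights[node]:.6g} inconsistent with "
                    f"date (expected {expect:.6g})"
                )

    # -- serialization ------------------------------------------------------
    def as_newick(self, date_in_label: bool = True) -> str:
        tree = self.tree.clone(depth=1)
        if date_in_label:
            for leaf in tree.leaf_node_iter():
                lbl = normalize_label(leaf.taxon.label)
                if _DATE_RE.match(lbl) is None:
                    leaf.taxon.label = f"{lbl}_{self.tip_dates[lbl]!r}"
        return tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "TimedTree":
        return TimedTree(self.tree.clone(depth=1), dict(self.tip_dates))


def _parse_label_date(label: str) -> float | None:
    m = _DATE_RE.match(label)
    if m is None:
        return None
    return float(m.group("year"))


def read_timed_tree(
    path: str | Path | io.StringIO,
    date_source: str = "label-suffix",
    date_table: str | Path | Mapping[str, float] | None = None,
) -> TimedTree:
    """Read a rooted Newick tree and resolve a decimal-year date per tip.

    Parameters
    ----------
    path:
        Newick file (or a string buffer).
    date_source:
        ``"label-suffix"`` parses ``name_YYYY[.frac]`` after the last
        underscore; ``"table"`` requires ``date_table`` (TSV with columns
        ``strain_id`` and ``year``, or a mapping).  A table always overrides
        label dates for the tips it lists.
    """
    if isinstance(path, io.StringIO):
        tree = dendropy.Tree.get(data=path.getvalue(), schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True

    table: dict[str, float] = {}
    if date_table is not None:
        if isinstance(date_table, Mapping):
            table = {normalize_label(k): float(v) for k, v in date_table.items()}
        else:
            df = pd.read_csv(date_table, sep="\t")
            table = {
                normalize_label(str(r["strain_id"])): float(r["year"])
                for _, r in df.iterrows()
            }
    if date_source == "table" and not table:
        raise ValidationError("date_source='table' requires a date_table")

    dates: dict[str, float] = {}
    missing: list[str] = []
    for leaf in tree.leaf_node_iter():
        lbl = normalize_label(leaf.taxon.label)
        if lbl in table:
            dates[lbl] = table[lbl]
            continue
        if date_source == "label-suffix":
            d = _parse_label_date(lbl)
            if d is not None:
                dates[lbl] = d
                continue
        missing.append(lbl)
    if missing:
        raise ValidationError(f"no date resolvable for tip(s): {', '.join(sorted(missing))}")
    return TimedTree(tree, dates)


def write_timed_tree(tt: TimedTree, path: str | Path, date_in_label: bool = True) -> None:
    Path(path).write_text(tt.as_newick(date_in_label=date_in_label) + "\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

_DNA_CHARS = set("ACGTUACGT" "RYSWKMBDHVN" "-.?X")
_PROT_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO" "-.?*")
_AMBIG_DNA = set("RYSWKMBDHVNX?")

GAP = "-"


@dataclass
class Alignment:
    """An equal-length multiple sequence alignment over a declared alphabet.

    ``alphabet`` is one of ``dna``, ``codon``, ``protein``.  Codon alignments
    must have length divisible by 3 and contain no in-frame stop codon.
    """

    ids: list[str]
    seqs: list[str]
    alphabet: str

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "codon", "protein"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and sequences differ in number")
        if not self.seqs:
            raise ValidationError("empty alignment")
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise ValidationError(f"ragged alignment: sequence {sid} has length {len(s)} != {L}")
        self.ids = [normalize_label(i) for i in self.ids]
        self.seqs = [s.upper().replace("U", "T") if self.alphabet != "protein" else s.upper()
                     for s in self.seqs]
        allowed = _PROT_CHARS if self.alphabet == "protein" else _DNA_CHARS
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - allowed
            if bad:
                raise ValidationError(f"sequence {sid}: illegal character(s) {sorted(bad)}")
        if self.alphabet == "codon":
            if L % 3 != 0:
                raise ValidationError(f"codon alignment length {L} not divisible by 3")
            for sid, s in zip(self.ids, self.seqs):
                for k in range(L // 3):
                    cod = s[3 * k : 3 * k + 3]
                    if cod in STOP_CODONS:
                        raise ValidationError(
                            f"in-frame stop codon {cod} in sequence {sid} at codon {k + 1}"
                        )

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    @property
    def n_codons(self) -> int:
        if self.alphabet != "codon":
            raise ValidationError("n_codons defined for codon alignments only")
        return self.n_cols // 3

    def column(self, j: int) -> str:
        """0-based column as a string over sequences."""
        return "".join(s[j] for s in self.seqs)

    def codon_column(self, k: int) -> list[str]:
        return [s[3 * k : 3 * k + 3] for s in self.seqs]

    def as_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def row(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    def subset(self, keep: Iterable[str]) -> "Alignment":
        keep = [normalize_label(k) for k in keep]
        idx = {i: n for n, i in enumerate(self.ids)}
        missing = [k for k in keep if k not in idx]
        if missing:
            raise ValidationError(f"sequences absent from alignment: {missing}")
        return Alignment([k for k in keep], [self.seqs[idx[k]] for k in keep], self.alphabet)

    def as_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in zip(self.ids, self.seqs))


def read_alignment(path: str | Path | io.StringIO, alphabet: str) -> Alignment:
    """Read a FASTA alignment and validate it against ``alphabet``."""
    handle = path if isinstance(path, io.StringIO) else open(path)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if not isinstance(path, io.StringIO):
            handle.close()
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records], alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    Path(path).write_text(aln.as_fasta())


# ---------------------------------------------------------------------------
# Strain metadata
# ---------------------------------------------------------------------------


@dataclass
class StrainMetadata:
    """Per-strain metadata table (species, host, country, collection year)."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("strain_id", "species", "host", "country", "year")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing column(s): {missing}")
        self.table = self.table.copy()
        self.table["strain_id"] = self.table["strain_id"].astype(str).map(normalize_label)
        if self.table["strain_id"].duplicated().any():
            dups = self.table.loc[self.table["strain_id"].duplicated(), "strain_id"].tolist()
            raise ValidationError(f"duplicate strain_id(s): {dups}")

    def ids(self) -> set[str]:
        return set(self.table["strain_id"])

    def check_matches(self, labels: Sequence[str]) -> None:
        labels = {normalize_label(l) for l in labels}
        missing = labels - self.ids()
        if missing:
            raise ValidationError(f"strain(s) absent from metadata: {sorted(missing)}")

    def lookup(self, strain_id: str) -> pd.Series:
        row = self.table[self.table["strain_id"] == normalize_label(strain_id)]
        if row.empty:
            raise KeyError(strain_id)
        return row.iloc[0]


def read_metadata(path: str | Path | io.StringIO) -> StrainMetadata:
    df = pd.read_csv(path, sep="\t")
    return StrainMetadata(df)
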