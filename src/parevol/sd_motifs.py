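"""Shine-Dalgarno-like motif characterization in 5'UTR / intergenic regions.

The canonical prokaryotic ribosome-binding signal is AGGAGGU (U and T are
interchangeable here), sitting about 5 +/- 2 nt upstream of the ATG start
codon.  The scanner classifies each upstream region as carrying the canonical
7-mer, a *variant* matching the degenerate core xGGxGGx, *absent* (no core
match in the spacer window) or *NA* (region missing or too short to scan).
Per-position Shannon entropy over detected motifs quantifies motif stability;
a probability logo matrix supports sequence-logo rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import StrainMetadata, ValidationError, normalize_label

__all__ = [
    "AnnotatedSegment",
    "Region",
    "SDHit",
    "PositionEntropyProfile",
    "MotifSummary",
    "extract_regions",
    "scan_sd",
    "position_entropy",
    "logo_matrix",
    "summarize_by_metadata",
]

STOPS = {"TAA", "TAG", "TGA"}
CANONICAL = "AGGAGGT"
CORE = "xGGxGGx"
CATEGORIES = ("canonical", "variant", "absent", "NA")


@dataclass
class Region:
    name: str  # 5utr | intergenic | 3utr
    start: int  # 1-based inclusive; start > end encodes an empty region
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return max(self.end - self.start + 1, 0)


@dataclass
class AnnotatedSegment:
    """A genome segment (coding strand) with validated ORF annotations."""

    strain_id: str
    sequence: str
    orfs: list[tuple[str, int, int]]  # (name, start, end) 1-based inclusive

    def __post_init__(self) -> None:
        self.strain_id = normalize_label(self.strain_id)
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - set("ACGTN-")
        if bad:
            raise ValidationError(f"{self.strain_id}: non-DNA character(s) {sorted(bad)}")
        if not self.orfs:
            raise ValidationError(f"{self.strain_id}: at least one ORF required")
        self.orfs = sorted(self.orfs, key=lambda o: o[1])
        prev_end = 0
        for name, start, end in self.orfs:
            if start <= prev_end:
                raise ValidationError(f"{self.strain_id}: ORF {name} overlaps previous ORF")
            if end > len(self.sequence) or start < 1:
                raise ValidationError(f"{self.strain_id}: ORF {name} outside sequence")
            if (end - start + 1) % 3 != 0:
                raise ValidationError(f"{self.strain_id}: ORF {name} length not multiple of 3")
            if self.sequence[start - 1 : start + 2] != "ATG":
                raise ValidationError(f"{self.strain_id}: ORF {name} does not start with ATG")
            if self.sequence[end - 3 : end] not in STOPS:
                raise ValidationError(f"{self.strain_id}: ORF {name} does not end with a stop codon")
            prev_end = end


def extract_regions(record: AnnotatedSegment) -> dict[str, Region | list[Region]]:
    """Derive 5'UTR, intergenic region(s) and 3'UTR from ORF annotations."""
    seq = record.sequence
    orfs = record.orfs
    utr5 = Region("5utr", 1, orfs[0][1] - 1, seq[: orfs[0][1] - 1])
    inter = []
    for (_, _, e_prev), (_, s_next, _) in zip(orfs, orfs[1:]):
        inter.append(Region("intergenic", e_prev + 1, s_next - 1, seq[e_prev : s_next - 1]))
    utr3 = Region("3utr", orfs[-1][2] + 1, len(seq), seq[orfs[-1][2]:])
    return {"5utr": utr5, "intergenic": inter, "3utr": utr3}


@dataclass
class SDHit:
    category: str  # canonical | variant | absent | NA
    motif: str | None = None
    spacer: int | None = None  # nt between motif 3' end and the ATG
    position: int | None = None  # 1-based motif start within the region


def _core_matches(seven: str, core: str, max_mismatch: int) -> bool:
    mism = sum(1 for a, b in zip(seven, core) if b != "x" and a != b)
    return mism <= max_mismatch


def scan_sd(utr: str, core: str = CORE, canonical: str = CANONICAL,
            spacer_center: int = 5, spacer_tol: int = 2,
            max_core_mismatch: int = 0) -> SDHit:
    """Scan the region immediately upstream of an ATG for an SD-like motif.

    The 7-mer windows end ``spacer`` nt before the start codon, with spacer
    ranging over ``spacer_center +/- spacer_tol``.  Among core-matching
    windows the hit closest to the center spacer is reported, ties broken
    toward the shorter spacer.  ``NA`` is returned when the region is shorter
    than ``7 + (spacer_center - spacer_tol)``.
    """
    utr = utr.upper().replace("U", "T")
    bad = set(utr) - set("ACGTN-")
    if bad:
        raise ValidationError(f"non-DNA character(s) in UTR: {sorted(bad)}")
    utr = utr.replace("-", "")
    min_spacer = max(spacer_center - spacer_tol, 0)
    if len(utr) < 7 + min_spacer:
        return SDHit("NA")
    spacers = sorted(range(min_spacer, spacer_center + spacer_tol + 1),
                     key=lambda s: (abs(s - spacer_center), s))
    for s in spacers:
        if len(utr) < s + 7:
            continue
        start = len(utr) - s - 7
        seven = utr[start : start + 7]
        if _core_matches(seven, core, max_core_mismatch):
            cat = "canonical" if seven == canonical.upper().replace("U", "T") else "variant"
            return SDHit(cat, seven, s, start + 1)
    return SDHit("absent")


@dataclass
class PositionEntropyProfile:
    entropies: np.ndarray  # bits per motif position
    stable: bool
    threshold: float = 0.5

    @property
    def mean_entropy(self) -> float:
        return float(self.entropies.mean())


def position_entropy(motifs: list[str], stability_threshold: float = 0.5
                     ) -> PositionEntropyProfile:
    """Per-position Shannon entropy (bits, log2 over A/C/G/T) of aligned 7-mers.

    No pseudocounts: the sum runs over observed bases only.  The group is
    called *stable* when the mean entropy across positions is at or below the
    threshold.
    """
    if not motifs:
        raise ValidationError("position_entropy needs >= 1 motif")
    L = len(motifs[0])
    if any(len(m) != L for m in motifs):
        raise ValidationError("motifs have mixed lengths")
    motifs = [m.upper().replace("U", "T") for m in motifs]
    H = np.zeros(L)
    for j in range(L):
        col = [m[j] for m in motifs]
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        H[j] = float(-(p * np.log2(p)).sum())
    return PositionEntropyProfile(H, bool(H.mean() <= stability_threshold),
                                  stability_threshold)


def logo_matrix(motifs: list[str]) -> pd.DataFrame:
    """Column-stochastic base-probability matrix (rows A,C,G,T; one column
    per motif position)."""
    if not motifs:
        raise ValidationError("logo_matrix needs >= 1 motif")
    L = len(motifs[0])
    if any(len(m) != L for m in motifs):
        raise ValidationError("motifs have mixed lengths")
    motifs = [m.upper().replace("U", "T") for m in motifs]
    mat = pd.DataFrame(0.0, index=list("ACGT"), columns=range(1, L + 1))
    for j in range(L):
        col = [m[j] for m in motifs]
        for b in "ACGT":
            mat.loc[b, j + 1] = col.count(b) / len(col)
    return mat


@dataclass
class MotifSummary:
    """Category proportions overall and cross-tabulated by metadata."""

    overall: pd.Series
    by_group: dict[str, pd.DataFrame]
    long_table: pd.DataFrame
    n_excluded: int = 0
    warnings: list[str] = field(default_factory=list)


def summarize_by_metadata(hits: dict[str, SDHit], metadata: StrainMetadata,
                          epochs=None) -> MotifSummary:
    """Join per-strain SD hits to metadata and tabulate category proportions.

    ``epochs`` may be an :class:`~parevol.epoch_divergence.EpochPartition`;
    strains then also get an epoch label from their collection year.
    Unjoinable strains are excluded with a warning.
    """
    rows = []
    warns: list[str] = []
    excluded = 0
    meta_ids = metadata.ids()
    for sid, hit in hits.items():
        sid_n = normalize_label(sid)
        if sid_n not in meta_ids:
            excluded += 1
            warns.append(f"strain {sid_n} absent from metadata; excluded")
            continue
        m = metadata.lookup(sid_n)
        row = {"strain_id": sid_n, "category": hit.category, "motif": hit.motif,
               "spacer": hit.spacer, "species": m["species"], "host": m["host"],
               "country": m["country"], "year": m["year"]}
        if epochs is not None:
            row["epoch"] = epochs.epoch_of_date(float(m["year"]))
        rows.append(row)
    if warns:
        warnings.warn(f"{excluded} strain(s) excluded: not in metadata")
    if not rows:
        raise ValidationError("no strain joined to metadata")
    long = pd.DataFrame(rows)

    def proportions(df: pd.DataFrame) -> pd.Series:
        p = df["category"].value_counts(normalize=True)
        return p.reindex(CATEGORIES, fill_value=0.0)

    overall = proportions(long)
    group_cols = ["species", "host", "country"] + (["epoch"] if epochs is not None else [])
    by_group = {g: long.groupby(g).apply(proportions, include_groups=False)
                for g in group_cols}
    return MotifSummary(overall, by_group, long, excluded, warns)
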