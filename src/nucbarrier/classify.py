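"""Genomic classification of DHSs and the five-way length grouping.

Each DHS is assigned to exactly one of five categories by where its
midpoint falls relative to annotated genes, tested in precedence order
proximal > distal > genic > downstream > intergenic:

* proximal promoter  — within 200 bp upstream of a TSS (strand-aware)
* distal promoter    — 200–1000 bp upstream of a TSS
* genic              — inside a gene body
* downstream         — within 200 bp past the transcription end site
* intergenic         — everywhere else

Categories are therefore exhaustive and mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import DHS
from .types import GeneModel

CATEGORY_ORDER = ("proximal", "distal", "genic", "downstream", "intergenic")

#: half-open length bins, labelled as in the five-group analysis
LENGTH_GROUPS = (
    (20, 80, "20-80"),
    (80, 140, "80-140"),
    (140, 200, "140-200"),
    (200, 320, "200-320"),
    (320, 480, "320-480"),
)


@dataclass(frozen=True)
class CategoryRule:
    proximal_bp: int = 200
    distal_bp: int = 1000
    downstream_bp: int = 200

    def windows(self, gene: GeneModel) -> Dict[str, Tuple[int, int]]:
        """Strand-aware half-open windows for one gene, keyed by category."""
        iv = gene.interval
        tss, tes = gene.tss, gene.tes
        if iv.strand == "+":
            return {
                "proximal": (tss - self.proximal_bp, tss),
                "distal": (tss - self.distal_bp, tss - self.proximal_bp),
                "genic": (iv.start, iv.end),
                "downstream": (tes + 1, tes + 1 + self.downstream_bp),
            }
        return {
            "proximal": (tss + 1, tss + 1 + self.proximal_bp),
            "distal": (tss + 1 + self.proximal_bp, tss + 1 + self.distal_bp),
            "genic": (iv.start, iv.end),
            "downstream": (tes - self.downstream_bp, tes),
        }


class _WindowIndex:
    """Membership tests for the union of one category's windows."""

    def __init__(self, windows: Sequence[Tuple[str, int, int]]):
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        grouped: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in windows:
            if e > s:
                grouped.setdefault(chrom, []).append((max(0, s), e))
        for chrom, pairs in grouped.items():
            arr = np.array(sorted(pairs), dtype=np.int64)
            self._by_chrom[chrom] = (arr[:, 0], np.maximum.accumulate(arr[:, 1]))

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, cummax_end = self._by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right")
        return i > 0 and cummax_end[i - 1] > pos


class GenomeAnnotation:
    """Precomputed category windows for a gene set under one rule."""

    def __init__(self, genes: Sequence[GeneModel], rule: CategoryRule | None = None):
        self.rule = rule or CategoryRule()
        per_cat: Dict[str, List[Tuple[str, int, int]]] = {c: [] for c in CATEGORY_ORDER[:4]}
        for gene in genes:
            for cat, (s, e) in self.rule.windows(gene).items():
                per_cat[cat].append((gene.interval.chrom, s, e))
        self._indexes = {cat: _WindowIndex(w) for cat, w in per_cat.items()}

    def category_of(self, chrom: str, pos: int) -> str:
        for cat in CATEGORY_ORDER[:4]:
            if self._indexes[cat].contains(chrom, pos):
                return cat
        return "intergenic"


def classify_dhs(
    dhs: DHS, genes: Sequence[GeneModel] | GenomeAnnotation, rule: CategoryRule | None = None
) -> str:
    """Category of a single DHS, decided by its midpoint."""
    ann = genes if isinstance(genes, GenomeAnnotation) else GenomeAnnotation(genes, rule)
    return ann.category_of(dhs.chrom, dhs.midpoint)


def length_group(dhs: DHS | int) -> Optional[str]:
    """Five-way length group label, or None outside the 20–480 bp range."""
    length = dhs if isinstance(dhs, int) else dhs.length
    for lo, hi, label in LENGTH_GROUPS:
        if lo <= length < hi:
            return label
    return None


def classify_all(
    dhss: Sequence[DHS], genes: Sequence[GeneModel], rule: CategoryRule | None = None
) -> List[DHS]:
    """Annotate every DHS in place with its category and length group."""
    ann = GenomeAnnotation(genes, rule)
    for d in dhss:
        d.category = ann.category_of(d.chrom, d.midpoint)
        d.length_group = length_group(d.length)
    return list(dhss)


def category_summary(
    dhss: Sequence[DHS], genes: Sequence[GeneModel] | None = None, rule: CategoryRule | None = None
) -> pd.DataFrame:
    """Per-category count and length statistics.

    Columns: count, frac_35_150 (length within [35, 150] bp),
    frac_gt_150 (length > 150 bp) and median_length. DHSs are classified
    first if ``genes`` is given and a DHS has no category yet.
    """
    if genes is not None:
        ann = GenomeAnnotation(genes, rule)
        for d in dhss:
            if d.category is None:
                d.category = ann.category_of(d.chrom, d.midpoint)
    rows = []
    for cat in CATEGORY_ORDER:
        lengths = np.array([d.length for d in dhss if d.category == cat])
        n = lengths.size
        rows.append(
            {
                "category": cat,
                "count": int(n),
                "frac_35_150": float(np.mean((lengths >= 35) & (lengths <= 150))) if n else 0.0,
                "frac_gt_150": float(np.mean(lengths > 150)) if n else 0.0,
                "median_length": float(np.median(lengths)) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("category")
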