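"""Positional lncRNA classification, cis targets and target intersections.

Coordinates are 0-based half-open throughout (BED convention at the I/O
boundary). lncRNAs are classified against protein-coding loci by
gene-body overlap; intergenic lncRNAs (lincRNAs) get putative cis
targets from a symmetric genomic window (300 kb by default) measured
between closest interval edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

POSITIONAL_CLASSES = ("intergenic", "antisense_overlap", "sense_overlap",
                      "bidirectional")

#: Conventional bidirectional-promoter window (bp between divergent 5' ends).
BIDIRECTIONAL_WINDOW = 1_000

#: Default cis-regulation window in bp, upstream or downstream.
CIS_WINDOW = 300_000


@dataclass(frozen=True)
class GenomicFeature:
    """A stranded genomic interval with identity and biotype."""

    feature_id: str
    gene_symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"{self.feature_id}: start must be < end "
                f"({self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.feature_id}: strand must be + or -")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def gap_to(self, other: "GenomicFeature") -> int | None:
        """Closest-edge distance on the same chromosome; 0 when overlapping."""
        if self.chrom != other.chrom:
            return None
        return max(other.start - self.end, self.start - other.end, 0)


def _trees_by_chrom(features: Iterable[GenomicFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for feat in features:
        trees.setdefault(feat.chrom, IntervalTree())[feat.start:feat.end] = feat
    return trees


def _is_divergent(lnc: GenomicFeature, gene: GenomicFeature,
                  window: int) -> bool:
    """Head-to-head: opposite strands, no overlap, 5' ends within window."""
    if gene.strand == lnc.strand or lnc.overlaps(gene):
        return False
    if lnc.strand == "+":
        # gene transcribes leftward, sits upstream of the lncRNA
        return gene.strand == "-" and 0 <= lnc.five_prime - gene.five_prime <= window
    return gene.strand == "+" and 0 <= gene.five_prime - lnc.five_prime <= window


def classify_lncrna(lncrnas: Sequence[GenomicFeature],
                    coding: Sequence[GenomicFeature],
                    bidirectional_window: int = BIDIRECTIONAL_WINDOW,
                    ) -> pd.DataFrame:
    """Assign each lncRNA exactly one positional class.

    Precedence: sense_overlap (gene-body overlap, same strand) >
    antisense_overlap (overlap, opposite strand only) > bidirectional
    (divergent 5' ends within ``bidirectional_window``) > intergenic.
    lncRNAs on chromosomes absent from the coding annotation are
    reported intergenic with a logged warning.
    """
    trees = _trees_by_chrom(coding)
    unknown_chroms = set()
    rows = []
    for lnc in lncrnas:
        tree = trees.get(lnc.chrom)
        if tree is None:
            unknown_chroms.add(lnc.chrom)
            rows.append((lnc.feature_id, "intergenic"))
            continue
        overlapping = [iv.data for iv in tree.overlap(lnc.start, lnc.end)]
        if any(g.strand == lnc.strand for g in overlapping):
            cls = "sense_overlap"
        elif overlapping:
            cls = "antisense_overlap"
        else:
            nearby = [iv.data for iv in tree.overlap(
                lnc.start - bidirectional_window,
                lnc.end + bidirectional_window)]
            if any(_is_divergent(lnc, g, bidirectional_window) for g in nearby):
                cls = "bidirectional"
            else:
                cls = "intergenic"
        rows.append((lnc.feature_id, cls))
    if unknown_chroms:
        logger.warning(
            "chromosome(s) %s absent from the coding annotation; "
            "their lncRNAs were classified intergenic",
            sorted(unknown_chroms))
    return pd.DataFrame(rows, columns=["lncrna_id", "positional_class"])


def cis_targets(lincrnas: Sequence[GenomicFeature],
                coding: Sequence[GenomicFeature],
                window: int = CIS_WINDOW) -> pd.DataFrame:
    """(lincRNA, gene) pairs whose loci lie within ``window`` bp.

    The distance is the closest-edge gap between the two gene bodies
    (0 for overlap), symmetric upstream/downstream and strand-agnostic.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    trees = _trees_by_chrom(coding)
    rows = []
    for lnc in lincrnas:
        tree = trees.get(lnc.chrom)
        if tree is None:
            continue
        # +1 keeps genes at exactly `window` bp inside the half-open query
        for iv in tree.overlap(lnc.start - window - 1, lnc.end + window + 1):
            gene = iv.data
            gap = lnc.gap_to(gene)
            if gap is not None and gap <= window:
                rows.append((lnc.feature_id, gene.feature_id,
                             gene.gene_symbol, gap))
    out = pd.DataFrame(rows, columns=["lincrna_id", "gene_id", "gene_symbol",
                                      "gap_bp"])
    return out.sort_values(["lincrna_id", "gene_id"]).reset_index(drop=True)


class IntersectionResult(NamedTuple):
    """Target pairs restricted to differential targets, plus their count."""

    pairs: pd.DataFrame
    distinct_targets: int


def _intersect_targets(target_pairs: pd.DataFrame,
                       de_records: pd.DataFrame,
                       target_class: str) -> IntersectionResult:
    pairs = target_pairs
    if "target_class" in pairs.columns:
        pairs = pairs[pairs["target_class"] == target_class]
    sig = de_records.index[de_records["significant"]] \
        if "significant" in de_records.columns else de_records.index
    kept = (pairs[pairs["target_id"].isin(set(sig))]
            .drop_duplicates(subset=["mirna_id", "target_id"])
            .reset_index(drop=True))
    return IntersectionResult(kept, kept["target_id"].nunique())


def intersect_mrna_targets(target_pairs: pd.DataFrame,
                           degs: pd.DataFrame) -> IntersectionResult:
    """Keep miRNA->mRNA pairs whose target accession is a significant DEG.

    Identity is the transcript accession, so one gene symbol probed by
    several transcripts contributes several distinct targets.
    """
    return _intersect_targets(target_pairs, degs, "mRNA")


def intersect_lncrna_targets(target_pairs: pd.DataFrame,
                             dels: pd.DataFrame) -> IntersectionResult:
    """Keep miRNA->lncRNA pairs whose target is a significant DEL."""
    return _intersect_targets(target_pairs, dels, "lncRNA")


def cis_differential_pairs(cis_pairs: pd.DataFrame,
                           dels: pd.DataFrame,
                           degs: pd.DataFrame) -> pd.DataFrame:
    """cis pairs where the lincRNA is a DEL and the gene a DEG."""
    sig_l = set(dels.index[dels["significant"]])
    sig_g = set(degs.index[degs["significant"]])
    kept = cis_pairs[cis_pairs["lincrna_id"].isin(sig_l)
                     & cis_pairs["gene_id"].isin(sig_g)]
    return kept.reset_index(drop=True)
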