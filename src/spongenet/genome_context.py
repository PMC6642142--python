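"""Positional classification of lncRNAs and cis candidate pairing.

Long non-coding RNAs are conventionally subclassed by where they lie
relative to protein-coding genes — intergenic (lincRNA), natural antisense
(exon overlap on the opposite strand), intronic antisense, sense overlap,
or bidirectional (divergent promoter) — because genomic context is the
main a-priori hint at a cis-regulatory mechanism.  This module implements
that classification plus two candidate-pair generators: proximity pairing
(coding gene within a base-pair window of the lncRNA, default 300 kbp,
strand-blind) and antisense pairing (opposite-strand interval overlap).

Coordinates are 0-based half-open throughout (BED convention); GTF
conversion happens at the I/O boundary.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicFeature",
    "LNC_CLASSES",
    "ProximityPair",
    "classify_lncrna",
    "classify_all",
    "proximity_pairs",
    "antisense_pairs",
    "summarize_lncrna",
]

#: Recognised lncRNA positional classes, in classification priority order.
LNC_CLASSES = (
    "natural_antisense",
    "intronic_antisense",
    "sense_overlap",
    "bidirectional",
    "intergenic",
)

#: Head-to-head TSS distance (bp) below which a non-overlapping
#: opposite-strand lncRNA is called bidirectional.
BIDIRECTIONAL_TSS_WINDOW = 1000


@dataclass(frozen=True)
class GenomicFeature:
    """A located, stranded, biotyped gene record.

    ``start``/``end`` are 0-based half-open.  ``exons`` is an optional
    sorted tuple of (start, end) sub-intervals; when empty the whole span
    is treated as a single exon (so intronic classes are unreachable for
    partners without exon structure).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "other"
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"feature {self.id!r}: empty chromosome")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start: left end on '+', right end on '-'."""
        return self.start if self.strand != "-" else self.end

    def exon_intervals(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.exons else ((self.start, self.end),)

    def intron_intervals(self) -> tuple[tuple[int, int], ...]:
        ex = self.exons
        if len(ex) < 2:
            return ()
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ProximityPair:
    """A cis lncRNA-mRNA candidate: ``distance_bp`` is the body gap
    (0 when the intervals overlap)."""

    lnc_id: str
    mrna_id: str
    distance_bp: int
    relation: str  # "proximal" | "antisense_overlap"


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _contained(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def classify_lncrna(
    lnc: GenomicFeature, coding_features: Iterable[GenomicFeature]
) -> str:
    """Assign one positional class to ``lnc`` against coding genes.

    Priority order (first match wins):

    1. ``natural_antisense`` — overlaps a coding exon, opposite strand;
    2. ``intronic_antisense`` — fully inside a coding intron, opposite strand;
    3. ``sense_overlap`` — any same-strand overlap with a coding gene;
    4. ``bidirectional`` — no overlap, opposite strand, TSS-to-TSS
       distance below 1 kb (divergent promoter);
    5. ``intergenic`` — none of the above.
    """
    if lnc.biotype != "lncRNA":
        raise ValueError(f"{lnc.id!r} is not a lncRNA (biotype {lnc.biotype!r})")
    span = (lnc.start, lnc.end)
    hit = {cls: False for cls in LNC_CLASSES}
    for gene in coding_features:
        if gene.chrom != lnc.chrom or gene.biotype != "coding":
            continue
        opposite = (
            lnc.strand in "+-" and gene.strand in "+-" and lnc.strand != gene.strand
        )
        if lnc.overlaps(gene):
            exonic = any(_intervals_overlap(span, ex) for ex in gene.exon_intervals())
            if opposite and exonic:
                return "natural_antisense"
            if opposite and any(
                _contained(span, intr) for intr in gene.intron_intervals()
            ):
                hit["intronic_antisense"] = True
            elif not opposite:
                hit["sense_overlap"] = True
        elif opposite and abs(lnc.tss - gene.tss) < BIDIRECTIONAL_TSS_WINDOW:
            hit["bidirectional"] = True
    for cls in ("intronic_antisense", "sense_overlap", "bidirectional"):
        if hit[cls]:
            return cls
    return "intergenic"


def classify_all(
    lnc_features: Iterable[GenomicFeature],
    coding_features: Sequence[GenomicFeature],
) -> dict[str, str]:
    """Classify every lncRNA; returns id -> class."""
    by_chrom: dict[str, list[GenomicFeature]] = defaultdict(list)
    for g in coding_features:
        if g.biotype == "coding":
            by_chrom[g.chrom].append(g)
    return {
        lnc.id: classify_lncrna(lnc, by_chrom.get(lnc.chrom, ()))
        for lnc in lnc_features
    }


def _gap(a: GenomicFeature, b: GenomicFeature) -> int:
    """Body gap between two same-chromosome intervals; 0 on overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def proximity_pairs(
    lnc_set: Iterable[GenomicFeature],
    mrna_set: Iterable[GenomicFeature],
    window: int = 300_000,
) -> list[ProximityPair]:
    """Pair each lncRNA with every coding gene whose body gap is strictly
    below ``window`` bp on the same chromosome.  Strand is ignored;
    overlapping intervals pair at distance 0.

    Uses a per-chromosome sweep over start-sorted genes; equivalent to the
    all-pairs scan (property-tested against it).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    genes_by_chrom: dict[str, list[GenomicFeature]] = defaultdict(list)
    for g in mrna_set:
        genes_by_chrom[g.chrom].append(g)
    for glist in genes_by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.end, g.id))
    out: list[ProximityPair] = []
    for lnc in lnc_set:
        lo, hi = lnc.start - window, lnc.end + window
        for g in genes_by_chrom.get(lnc.chrom, ()):
            if g.start >= hi:
                break
            if g.end <= lo:
                continue
            d = _gap(lnc, g)
            if d < window:
                out.append(ProximityPair(lnc.id, g.id, d, "proximal"))
    out.sort(key=lambda p: (p.lnc_id, p.mrna_id))
    return out


def antisense_pairs(
    lnc_set: Iterable[GenomicFeature],
    mrna_set: Iterable[GenomicFeature],
) -> list[ProximityPair]:
    """Pairs where the lncRNA and coding gene intervals overlap on
    opposite strands (any overlap length counts)."""
    genes_by_chrom: dict[str, list[GenomicFeature]] = defaultdict(list)
    for g in mrna_set:
        genes_by_chrom[g.chrom].append(g)
    out = [
        ProximityPair(lnc.id, g.id, 0, "antisense_overlap")
        for lnc in lnc_set
        for g in genes_by_chrom.get(lnc.chrom, ())
        if lnc.strand in "+-"
        and g.strand in "+-"
        and lnc.strand != g.strand
        and lnc.overlaps(g)
    ]
    out.sort(key=lambda p: (p.lnc_id, p.mrna_id))
    return out


#: Default transcript-length bins (nt) for the size summary.
SIZE_BINS = (0, 200, 1_000, 5_000, 10_000, 50_000)


def summarize_lncrna(
    features: Sequence[GenomicFeature],
    classes: Mapping[str, str],
    size_bins: Sequence[int] = SIZE_BINS,
) -> pd.DataFrame:
    """Tabulate lncRNAs by positional class, size bin and chromosome.

    Returns a tidy frame with columns (facet, level, count, percent);
    percentages within each facet sum to 100 up to rounding.
    """
    lncs = [f for f in features if f.biotype == "lncRNA"]
    if not lncs:
        raise ValueError("no lncRNA features to summarize")
    n = len(lncs)
    rows: list[tuple[str, str, int]] = []

    cls_counts: dict[str, int] = defaultdict(int)
    for f in lncs:
        cls_counts[classes[f.id]] += 1
    for cls in LNC_CLASSES:
        if cls_counts.get(cls):
            rows.append(("class", cls, cls_counts[cls]))

    edges = list(size_bins)
    labels = [f"{edges[i]}-{edges[i + 1]}" for i in range(len(edges) - 1)]
    labels.append(f">={edges[-1]}")
    bin_counts = [0] * len(labels)
    for f in lncs:
        i = len(edges) - 1
        for j in range(len(edges) - 1):
            if edges[j] <= f.length < edges[j + 1]:
                i = j
                break
        bin_counts[i] += 1
    for lab, c in zip(labels, bin_counts):
        if c:
            rows.append(("size", lab, c))

    chrom_counts: dict[str, int] = defaultdict(int)
    for f in lncs:
        chrom_counts[f.chrom] += 1
    for chrom in sorted(chrom_counts):
        rows.append(("chromosome", chrom, chrom_counts[chrom]))

    df = pd.DataFrame(rows, columns=["facet", "level", "count"])
    df["percent"] = 100.0 * df["count"] / n
    return df
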