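"""Genomic annotation of association results.

Three reporting steps sit downstream of the permutation scan:

* cis/trans classification — a SNP-transcript association is *cis* when
  the variant lies on the same chromosome within a distance window
  (default 1 Mb, closed boundary) of the probe's target gene, *trans*
  otherwise, and *unknown* when either locus lacks coordinates;
* per-SNP counts of significant associations at a ladder of permutation-P
  thresholds (default 0.05 / 0.01 / 0.001, strict ``<``);
* cross-SNP overlap of the significant transcript sets (intersection sizes
  and per-SNP percentages), for loci carrying several correlated variants.

All coordinates are held internally as 0-based half-open intervals, the
BED convention; 1-based SNP positions are converted on construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .assocscan import AssociationRecord
from .qcnorm import ValidationError

logger = logging.getLogger(__name__)

CIS = "cis"
TRANS = "trans"
UNKNOWN = "unknown"

KIND_SNP = "snp_point"
KIND_GENE = "gene_interval"

ANCHOR_EDGE = "interval-edge"
ANCHOR_START = "gene-start"

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class GenomicLocus:
    """A SNP point or gene interval, 0-based half-open.

    ``from_snp_1based`` converts the 1-based position convention of SNP
    tables; BED intervals are already in the internal convention. A locus
    with ``chrom=None`` means the position is unknown.
    """

    chrom: str | None
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in (KIND_SNP, KIND_GENE):
            raise ValidationError(f"unknown locus kind {self.kind!r}")
        if self.chrom is not None:
            if self.start > self.end:
                raise ValidationError(f"locus start {self.start} > end {self.end}")
            if self.kind == KIND_SNP and self.end - self.start != 1:
                raise ValidationError("SNP locus must span exactly one base")

    @classmethod
    def from_snp_1based(cls, chrom: str, pos: int) -> "GenomicLocus":
        if pos < 1:
            raise ValidationError(f"1-based SNP position must be >= 1, got {pos}")
        return cls(chrom=chrom, start=pos - 1, end=pos, kind=KIND_SNP)

    @classmethod
    def gene_interval(cls, chrom: str, start: int, end: int) -> "GenomicLocus":
        return cls(chrom=chrom, start=start, end=end, kind=KIND_GENE)

    @classmethod
    def unknown(cls, kind: str = KIND_GENE) -> "GenomicLocus":
        return cls(chrom=None, start=0, end=0, kind=kind)


def _edge_distance(point: int, start: int, end: int) -> int:
    """bp from a 0-based point to the nearest base of [start, end); 0 inside."""
    if point < start:
        return start - point
    if point >= end:
        return point - (end - 1)
    return 0


def classify_cis_trans(
    snp: GenomicLocus,
    gene: GenomicLocus,
    window: int = DEFAULT_WINDOW_BP,
    anchor: str = ANCHOR_EDGE,
) -> str:
    """cis iff same chromosome and SNP-to-gene distance <= window (closed).

    ``anchor`` selects the distance definition: ``interval-edge`` (default)
    measures to the nearest gene boundary (0 when the SNP falls inside the
    gene); ``gene-start`` measures to the interval start.
    """
    if window < 0:
        raise ValidationError(f"window must be non-negative, got {window}")
    if anchor not in (ANCHOR_EDGE, ANCHOR_START):
        raise ValidationError(f"unknown distance anchor {anchor!r}")
    if snp.chrom is None or gene.chrom is None:
        return UNKNOWN
    if snp.chrom != gene.chrom:
        return TRANS
    point = snp.start
    if anchor == ANCHOR_EDGE:
        dist = _edge_distance(point, gene.start, gene.end)
    else:
        dist = abs(point - gene.start)
    return CIS if dist <= window else TRANS


def annotate_cis_trans(
    records: list[AssociationRecord],
    snp_loci: dict[str, GenomicLocus],
    gene_loci: dict[str, GenomicLocus],
    window: int = DEFAULT_WINDOW_BP,
    anchor: str = ANCHOR_EDGE,
) -> list[AssociationRecord]:
    """Set ``cis_trans`` on every record; unmapped IDs become unknown."""
    for rec in records:
        snp = snp_loci.get(rec.snp_id)
        gene = gene_loci.get(rec.probe_id)
        if snp is None or gene is None:
            rec.cis_trans = UNKNOWN
        else:
            rec.cis_trans = classify_cis_trans(snp, gene, window=window, anchor=anchor)
    n_cis = sum(1 for r in records if r.cis_trans == CIS)
    logger.info("cis/trans annotation: %d cis of %d records (window %d bp)",
                n_cis, len(records), window)
    return records


def threshold_counts(
    records: list[AssociationRecord],
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.001),
) -> pd.DataFrame:
    """Per-SNP counts of records with perm_p strictly below each threshold.

    Returns a DataFrame indexed by threshold (descending) with one column
    per SNP, mirroring the usual summary table layout (``P<0.05`` etc.).
    """
    missing = [r for r in records if r.perm_p is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} records lack perm_p; run the permutation scan first"
        )
    thresholds = tuple(sorted(thresholds, reverse=True))
    snp_ids = list(dict.fromkeys(r.snp_id for r in records))
    table = pd.DataFrame(0, index=list(thresholds), columns=snp_ids, dtype=int)
    table.index.name = "threshold"
    for rec in records:
        for t in thresholds:
            if rec.perm_p < t:
                table.loc[t, rec.snp_id] += 1
    return table


def significant_sets(
    records: list[AssociationRecord], threshold: float = 0.05
) -> dict[str, set[str]]:
    """Probe sets with perm_p < threshold, keyed by SNP."""
    sets: dict[str, set[str]] = {}
    for rec in records:
        sets.setdefault(rec.snp_id, set())
        if rec.perm_p is not None and rec.perm_p < threshold:
            sets[rec.snp_id].add(rec.probe_id)
    return sets


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass
class OverlapSummary:
    """Intersection bookkeeping across >= 2 significant-probe sets."""

    set_sizes: dict[str, int]
    intersection_size: int
    percentages: dict[str, int | None]  # None where the set is empty
    pairwise: dict[tuple[str, str], int]


def overlap_summary(sig_sets: dict[str, set[str]]) -> OverlapSummary:
    """Size of the all-way intersection and its share of each SNP's set.

    Percentages are 100 * |intersection| / |set|, rounded to the nearest
    integer (half away from zero); an empty set's percentage is undefined
    and reported as None.
    """
    if len(sig_sets) < 2:
        raise ValidationError("overlap summary needs at least 2 sets")
    snp_ids = list(sig_sets)
    inter = set.intersection(*(sig_sets[s] for s in snp_ids))
    percentages: dict[str, int | None] = {}
    for s in snp_ids:
        size = len(sig_sets[s])
        if size == 0:
            percentages[s] = None
            logger.warning("overlap percentage undefined for %s (empty set)", s)
        else:
            percentages[s] = _round_half_away(100.0 * len(inter) / size)
    pairwise = {
        (a, b): len(sig_sets[a] & sig_sets[b]) for a, b in combinations(snp_ids, 2)
    }
    return OverlapSummary(
        set_sizes={s: len(sig_sets[s]) for s in snp_ids},
        intersection_size=len(inter),
        percentages=percentages,
        pairwise=pairwise,
    )
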