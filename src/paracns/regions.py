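"""Gene-associated regions and CNS assignment.

Regions are built strand-relatively around the protein-coding span of a
gene model, all in 0-based half-open genomic coordinates:

* promoters of 1500/1000/500 bp upstream of the start codon, omitting the
  100 bp immediately upstream (``ATG -100``),
* a 5' UTR proxy: the 100 bp immediately upstream of the start codon,
* introns inside the protein-coding region,
* a 3' UTR proxy: 200 bp downstream of the stop codon,
* a downstream window 300-1000 bp past the stop codon.

Where a neighboring gene span (nearest annotated gene on either side,
strand ignored) reaches into an upstream/downstream region, the region is
shortened to the free intergenic space; fully covered regions become
empty.  A CNS is assigned to a region only when it lies entirely within
it — intervals straddling a boundary count for neither side — and genes
without any CNS in a region score an explicit zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from paracns.divergence import CorrelationResult

__all__ = [
    "GeneModel",
    "RegionSet",
    "CNSRecord",
    "RegionCNSCounts",
    "REGION_CLASSES",
    "PROMOTER_WINDOWS",
    "define_regions",
    "assign_cns",
    "count_cns_for_genes",
    "kendall_tau_b",
    "ratio_vs_cns_correlation",
]

logger = logging.getLogger(__name__)

PROMOTER_WINDOWS = (500, 1000, 1500)
#: region classes in reporting order
REGION_CLASSES = (
    "promoter_1500",
    "promoter_1000",
    "promoter_500",
    "utr5",
    "introns",
    "utr3",
    "downstream",
)

#: bp kept out of promoters immediately upstream of the start codon
_ATG_OFFSET = 100
_UTR5_LEN = 100
_UTR3_LEN = 200
_DOWNSTREAM_NEAR = 300
_DOWNSTREAM_FAR = 1000


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene coordinates (0-based half-open CDS span)."""

    gene: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    introns: tuple[tuple[int, int], ...] = ()
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_start < self.cds_end:
            raise ValueError(
                f"{self.gene}: cds_start ({self.cds_start}) must be < cds_end ({self.cds_end})"
            )
        prev_end = self.cds_start
        for s, e in sorted(self.introns):
            if s < self.cds_start or e > self.cds_end:
                raise ValueError(f"{self.gene}: intron [{s}, {e}) outside CDS span")
            if s < prev_end:
                raise ValueError(f"{self.gene}: overlapping introns")
            if s >= e:
                raise ValueError(f"{self.gene}: empty intron [{s}, {e})")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)


@dataclass(frozen=True)
class RegionSet:
    """Per-gene intervals of every region class (possibly empty)."""

    gene: str
    chrom: str
    intervals: Mapping[str, tuple[tuple[int, int], ...]]

    def __getitem__(self, region_class: str) -> tuple[tuple[int, int], ...]:
        return self.intervals[region_class]


@dataclass(frozen=True)
class CNSRecord:
    """A conserved non-coding sequence interval from one CNS dataset."""

    chrom: str
    start: int
    end: int
    dataset: int = 1
    name: str = ""
    sequence: str | None = None
    gc: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"CNS interval [{self.start}, {self.end}) is empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionCNSCounts:
    gene: str
    counts: Mapping[str, int]
    base_sums: Mapping[str, int]


def _clip(
    interval: tuple[int, int],
    lo: int,
    hi: int,
) -> tuple[int, int] | None:
    s = max(interval[0], lo)
    e = min(interval[1], hi)
    return (s, e) if s < e else None


def define_regions(
    gene: GeneModel,
    neighbors: tuple[GeneModel | None, GeneModel | None] = (None, None),
    windows: Sequence[int] = PROMOTER_WINDOWS,
    chrom_length: int | None = None,
) -> RegionSet:
    """Build the region set of a gene, shortened by its nearest neighbors.

    ``neighbors`` holds the nearest annotated gene span to the left and
    right on the chromosome (either may be ``None``).  Upstream and
    downstream regions are clipped to the free space between the
    neighbors' spans and to the chromosome ends.
    """
    for w in windows:
        if w not in PROMOTER_WINDOWS:
            raise ValueError(f"promoter window must be one of {PROMOTER_WINDOWS}, got {w}")
    left, right = neighbors
    lo = 0
    hi = chrom_length if chrom_length is not None else math.inf
    if left is not None:
        if left.chrom != gene.chrom:
            raise ValueError("left neighbor on a different chromosome")
        lo = max(lo, left.cds_end)
    if right is not None:
        if right.chrom != gene.chrom:
            raise ValueError("right neighbor on a different chromosome")
        hi = min(hi, right.cds_start)

    s, e = gene.cds_start, gene.cds_end
    if gene.strand == "+":
        raw: dict[str, tuple[int, int]] = {
            f"promoter_{w}": (s - w, s - _ATG_OFFSET) for w in windows
        }
        raw["utr5"] = (s - _UTR5_LEN, s)
        raw["utr3"] = (e, e + _UTR3_LEN)
        raw["downstream"] = (e + _DOWNSTREAM_NEAR, e + _DOWNSTREAM_FAR)
    else:
        raw = {f"promoter_{w}": (e + _ATG_OFFSET, e + w) for w in windows}
        raw["utr5"] = (e, e + _UTR5_LEN)
        raw["utr3"] = (s - _UTR3_LEN, s)
        raw["downstream"] = (s - _DOWNSTREAM_FAR, s - _DOWNSTREAM_NEAR)

    hi_int = int(hi) if hi is not math.inf else None
    intervals: dict[str, tuple[tuple[int, int], ...]] = {}
    for name, iv in raw.items():
        clipped = _clip(iv, lo, hi_int if hi_int is not None else iv[1])
        intervals[name] = (clipped,) if clipped is not None else ()
    intervals["introns"] = tuple(sorted(gene.introns))
    return RegionSet(gene=gene.gene, chrom=gene.chrom, intervals=intervals)


def assign_cns(
    cns: Iterable[CNSRecord],
    regions: RegionSet,
) -> RegionCNSCounts:
    """Count CNSs situated entirely within each region class of a gene.

    Strict containment: a CNS counts for a region iff
    ``region_start <= cns_start`` and ``cns_end <= region_end``; CNSs on
    other chromosomes are ignored.  Base sums add CNS lengths.
    """
    counts = {k: 0 for k in regions.intervals}
    base_sums = {k: 0 for k in regions.intervals}
    for record in cns:
        if record.chrom != regions.chrom:
            continue
        for region_class, intervals in regions.intervals.items():
            if any(s <= record.start and record.end <= e for s, e in intervals):
                counts[region_class] += 1
                base_sums[region_class] += record.length
    return RegionCNSCounts(gene=regions.gene, counts=counts, base_sums=base_sums)


def count_cns_for_genes(
    annotation: Sequence[GeneModel],
    cns: Sequence[CNSRecord],
    neighbors: Mapping[str, tuple[GeneModel | None, GeneModel | None]],
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, RegionCNSCounts]:
    """Per-gene CNS counts/base sums for a whole annotation (batch form).

    Equivalent to calling :func:`define_regions` + :func:`assign_cns` per
    gene, but indexes the CNS track per chromosome (sorted starts plus a
    running maximum of ends) so genome-scale runs stay fast.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in cns}:
        recs = sorted((r for r in cns if r.chrom == chrom), key=lambda r: (r.start, r.end))
        starts = np.array([r.start for r in recs], dtype=np.int64)
        ends = np.array([r.end for r in recs], dtype=np.int64)
        by_chrom[chrom] = (starts, ends)

    out: dict[str, RegionCNSCounts] = {}
    for gene in annotation:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        regions = define_regions(gene, neighbors.get(gene.gene, (None, None)),
                                 chrom_length=clen)
        counts = {k: 0 for k in regions.intervals}
        base_sums = {k: 0 for k in regions.intervals}
        track = by_chrom.get(gene.chrom)
        if track is not None:
            starts, ends = track
            for region_class, intervals in regions.intervals.items():
                for s, e in intervals:
                    lo = int(np.searchsorted(starts, s, side="left"))
                    hi = int(np.searchsorted(starts, e, side="left"))
                    contained = ends[lo:hi] <= e
                    counts[region_class] += int(contained.sum())
                    base_sums[region_class] += int(
                        (ends[lo:hi][contained] - starts[lo:hi][contained]).sum()
                    )
        out[gene.gene] = RegionCNSCounts(gene=gene.gene, counts=counts, base_sums=base_sums)
    return out


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall rank correlation tau-b (adjusts for tied values).

    Two-sided p-value via the tie-corrected normal approximation.  Raises
    when either vector is constant (tau-b undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("Kendall tau-b requires n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall tau-b undefined: all values tied in one vector")
    tau, p = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult(float(tau), int(x.size), float(p), "kendall_tau_b")


def ratio_vs_cns_correlation(
    differential_pairs: Sequence,
    counts_by_gene: Mapping[str, RegionCNSCounts],
    role: str,
    region_class: str,
    measure: str = "count",
) -> CorrelationResult:
    """Kendall tau-b between pair expression ratio and per-gene CNS measure.

    For every differential pair the gene in the requested role (``higher``
    or ``lower``) contributes its CNS count or base sum in the chosen
    region class; pairs whose role gene lacks counts are skipped with a
    log entry.  Because tau-b is rank-based, the log2-scale expression
    ratio can be used directly (any monotone rescaling leaves tau-b
    unchanged).
    """
    if role not in ("higher", "lower"):
        raise ValueError(f"role must be 'higher' or 'lower', got {role!r}")
    if measure not in ("count", "base_sum"):
        raise ValueError(f"measure must be 'count' or 'base_sum', got {measure!r}")
    ratios: list[float] = []
    values: list[float] = []
    for pair in differential_pairs:
        gene = getattr(pair, role)
        if gene is None:
            raise ValueError(f"pair ({pair.gene_a}, {pair.gene_b}) lacks role assignment")
        if gene not in counts_by_gene:
            logger.info("pair (%s, %s) skipped: no CNS counts for %s",
                        pair.gene_a, pair.gene_b, gene)
            continue
        record = counts_by_gene[gene]
        source = record.counts if measure == "count" else record.base_sums
        ratios.append(pair.ratio)
        values.append(source[region_class])
    return kendall_tau_b(ratios, values)
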