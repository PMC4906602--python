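"""CNS sequence properties and TF binding-site enrichment.

GC content and length of CNS groups are compared against the genome-wide
promoter-CNS pool by resampling without replacement; transcription-factor
binding sites (an external table, e.g. an AthaMap export) are first
filtered to a sequence-conservation score of at least 50 % and counted as
inside a CNS when the site starts no more than 2 bases upstream of the
CNS start or overlaps it by at least 4 bases.  Family-level enrichment or
depletion is judged against motif counts in same-size CNS sets resampled
from the pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from paracns.regions import CNSRecord

__all__ = [
    "TFBSRecord",
    "EnrichmentResult",
    "tfbs_in_cns",
    "filter_tfbs",
    "resample_mean_test",
    "tfbs_family_enrichment",
    "gc_content",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TFBSRecord:
    """A transcription-factor binding site with a conservation score."""

    factor: str
    family: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    conservation_score: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TFBS interval [{self.start}, {self.end}) is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    family: str
    observed: float
    expected: float
    fold: float
    p_value: float
    n_iterations: int
    direction: str  # enriched | depleted | absent


def tfbs_in_cns(site: TFBSRecord, cns: CNSRecord) -> bool:
    """Whether a binding site counts as inside a CNS.

    True iff the site starts at most 2 bases upstream of the CNS start
    (in genomic coordinates, strand-agnostic) or overlaps the CNS by at
    least 4 bases.  Different chromosomes never match.
    """
    if site.chrom != cns.chrom:
        return False
    if 0 <= cns.start - site.start <= 2:
        return True
    overlap = min(site.end, cns.end) - max(site.start, cns.start)
    return overlap >= 4


def filter_tfbs(
    sites: Sequence[TFBSRecord], min_score: float = 0.5
) -> list[TFBSRecord]:
    """Keep sites whose conservation score is at least ``min_score``."""
    for site in sites:
        if not 0.0 <= site.conservation_score <= 1.0:
            raise ValueError(
                f"conservation score outside [0, 1] for {site.factor}: "
                f"{site.conservation_score}"
            )
    return [s for s in sites if s.conservation_score >= min_score]


def resample_mean_test(
    observed_values: Sequence[float],
    pool_values: Sequence[float],
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided resampling test of a group mean against a pool.

    Draws ``len(observed)`` values from the pool without replacement per
    iteration and records the mean; the empirical two-sided p doubles the
    smaller tail with a +1 correction (so p is never 0):
    ``p = min(1, 2 * min(P_ge, P_le))`` with
    ``P_ge = (1 + #{resampled mean >= observed mean}) / (iterations + 1)``.
    Returns ``(p_value, fold)`` with fold = observed mean / pool mean.
    """
    observed = np.asarray(observed_values, dtype=float)
    pool = np.asarray(pool_values, dtype=float)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if observed.size == 0:
        raise ValueError("observed group is empty")
    if observed.size > pool.size:
        raise ValueError(
            f"observed group ({observed.size}) larger than pool ({pool.size})"
        )
    rng = np.random.default_rng(seed)
    tiled = np.tile(pool, (iterations, 1))
    resampled = rng.permuted(tiled, axis=1)[:, : observed.size].mean(axis=1)
    obs_mean = observed.mean()
    p_ge = (1 + int((resampled >= obs_mean).sum())) / (iterations + 1)
    p_le = (1 + int((resampled <= obs_mean).sum())) / (iterations + 1)
    p = min(1.0, 2.0 * min(p_ge, p_le))
    fold = float(obs_mean / pool.mean()) if pool.mean() != 0 else np.inf
    return float(p), fold


def _count_sites_per_cns(
    cns_list: Sequence[CNSRecord],
    sites: Sequence[TFBSRecord],
) -> np.ndarray:
    """Per-CNS count of sites matching the in-CNS rule (one family)."""
    counts = np.zeros(len(cns_list), dtype=np.int64)
    by_chrom: dict[str, list[TFBSRecord]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for i, cns in enumerate(cns_list):
        for site in by_chrom.get(cns.chrom, ()):
            if tfbs_in_cns(site, cns):
                counts[i] += 1
    return counts


def tfbs_family_enrichment(
    group_cns: Sequence[CNSRecord],
    all_promoter_cns: Sequence[CNSRecord],
    sites: Sequence[TFBSRecord],
    families: Sequence[str],
    iterations: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per-family motif enrichment of group CNSs vs. the promoter pool.

    ``sites`` should already be filtered by conservation score.  For every
    family the observed motif count within the group CNSs is compared to
    counts in ``iterations`` same-size CNS sets drawn from the pool
    without replacement (one shared sequence of draws across families).
    Fold is observed / resampled mean; families missing from the site
    table, or with zero motifs in the group despite motifs in the pool,
    are reported as ``absent``.
    """
    if len(group_cns) == 0:
        raise ValueError("group CNS set is empty")
    if len(group_cns) > len(all_promoter_cns):
        raise ValueError("group larger than the promoter-CNS pool")
    sites_by_family: dict[str, list[TFBSRecord]] = {f: [] for f in families}
    for s in sites:
        if s.family in sites_by_family:
            sites_by_family[s.family].append(s)

    rng = np.random.default_rng(seed)
    k = len(group_cns)
    pool_n = len(all_promoter_cns)
    draw_index = np.empty((iterations, k), dtype=np.int64)
    for i in range(iterations):
        draw_index[i] = rng.choice(pool_n, size=k, replace=False)

    results: list[EnrichmentResult] = []
    for family in families:
        fam_sites = sites_by_family[family]
        if not fam_sites:
            logger.warning("family %r absent from the binding-site table", family)
            results.append(
                EnrichmentResult(family, 0.0, 0.0, 0.0, 1.0, iterations, "absent")
            )
            continue
        observed = int(_count_sites_per_cns(group_cns, fam_sites).sum())
        per_pool_cns = _count_sites_per_cns(all_promoter_cns, fam_sites)
        null_totals = per_pool_cns[draw_index].sum(axis=1)
        expected = float(null_totals.mean())
        p_ge = (1 + int((null_totals >= observed).sum())) / (iterations + 1)
        p_le = (1 + int((null_totals <= observed).sum())) / (iterations + 1)
        p = min(1.0, 2.0 * min(p_ge, p_le))
        fold = observed / expected if expected > 0 else np.inf
        if observed == 0 and per_pool_cns.sum() > 0:
            direction = "absent"
        elif fold >= 1.0:
            direction = "enriched"
        else:
            direction = "depleted"
        results.append(
            EnrichmentResult(
                family=family,
                observed=float(observed),
                expected=expected,
                fold=float(fold),
                p_value=float(p),
                n_iterations=iterations,
                direction=direction,
            )
        )
    return results


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T) of a nucleotide string; N bases excluded."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid nucleotide characters: {sorted(invalid)}")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return (seq.count("G") + seq.count("C")) / acgt
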