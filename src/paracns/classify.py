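"""Paralog-pair filtering, expression-ratio classification and group roles.

Pairs are kept when both genes are annotated, both are present in the
expression data, and the protein lengths differ by at most 5 % relative to
the longer protein.  The per-pair expression ratio (larger mean / smaller
mean, computed by default on the stored log2-scale values) splits pairs
into ``similar`` (ratio < 1.25), ``differential`` (ratio >= 7) and an
``intermediate`` remainder; differential pairs get higher/lower role
assignments.  For group contrasts one gene of every similar pair is
sampled uniformly under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParalogPair",
    "filter_pairs",
    "expression_ratio",
    "classify_pairs",
    "sample_similar",
    "PROTEIN_LENGTH_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: maximal relative protein-length difference (vs. the longer protein)
PROTEIN_LENGTH_TOLERANCE = 0.05


@dataclass(frozen=True)
class ParalogPair:
    """A WGD-derived paralog pair with expression-based classification."""

    gene_a: str
    gene_b: str
    protein_len_a: int | None = None
    protein_len_b: int | None = None
    expr_a: float | None = None
    expr_b: float | None = None
    ratio: float | None = None
    group: str | None = None  # similar | differential | intermediate
    higher: str | None = None
    lower: str | None = None

    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def filter_pairs(
    pairs: Iterable[ParalogPair],
    protein_lengths: Mapping[str, int],
    expressed_genes: Iterable[str],
    tolerance: float = PROTEIN_LENGTH_TOLERANCE,
) -> list[ParalogPair]:
    """Apply the annotation / expression / protein-length filters.

    A pair survives iff both genes have an annotated protein length, both
    occur in ``expressed_genes``, and the length difference relative to
    the longer protein is <= ``tolerance``.  Dropped pairs are logged with
    the reason, never discarded silently.
    """
    expressed = set(expressed_genes)
    kept: list[ParalogPair] = []
    for pair in pairs:
        a, b = pair.gene_a, pair.gene_b
        if a not in protein_lengths or b not in protein_lengths:
            missing = [g for g in (a, b) if g not in protein_lengths]
            logger.info("pair (%s, %s) dropped: no annotation for %s", a, b, missing)
            continue
        if a not in expressed or b not in expressed:
            missing = [g for g in (a, b) if g not in expressed]
            logger.info("pair (%s, %s) dropped: not in expression data: %s", a, b, missing)
            continue
        la, lb = protein_lengths[a], protein_lengths[b]
        if abs(la - lb) / max(la, lb) > tolerance:
            logger.info(
                "pair (%s, %s) dropped: protein lengths %d vs %d differ by > %.0f %%",
                a, b, la, lb, 100 * tolerance,
            )
            continue
        kept.append(replace(pair, protein_len_a=la, protein_len_b=lb))
    return kept


def expression_ratio(
    pair: ParalogPair, expression_means: Mapping[str, float]
) -> float:
    """Ratio of the larger to the smaller overall expression mean (>= 1)."""
    ea = expression_means[pair.gene_a]
    eb = expression_means[pair.gene_b]
    if ea <= 0 or eb <= 0:
        raise ValueError(
            f"expression ratio undefined for pair ({pair.gene_a}, {pair.gene_b}): "
            f"non-positive mean ({ea}, {eb})"
        )
    return max(ea, eb) / min(ea, eb)


def classify_pairs(
    pairs: Sequence[ParalogPair],
    expression_means: Mapping[str, float],
    similar_max: float = 1.25,
    differential_min: float = 7.0,
) -> list[ParalogPair]:
    """Annotate pairs with ratio, group label, and higher/lower roles.

    Boundary conventions follow the study design exactly: strict ``<`` for
    the similar group, inclusive ``>=`` for the differential group; the
    gap in between is labelled ``intermediate``.
    """
    if similar_max >= differential_min:
        raise ValueError(
            f"similar_max ({similar_max}) must be < differential_min ({differential_min})"
        )
    out: list[ParalogPair] = []
    for pair in pairs:
        ea = expression_means[pair.gene_a]
        eb = expression_means[pair.gene_b]
        ratio = expression_ratio(pair, expression_means)
        higher = lower = None
        if ratio < similar_max:
            group = "similar"
        elif ratio >= differential_min:
            group = "differential"
            if ea == eb:  # unreachable given ratio >= differential_min > 1
                raise ValueError(
                    f"tied expression in differential pair ({pair.gene_a}, {pair.gene_b})"
                )
            higher = pair.gene_a if ea > eb else pair.gene_b
            lower = pair.gene_b if ea > eb else pair.gene_a
        else:
            group = "intermediate"
        out.append(
            replace(
                pair,
                expr_a=float(ea),
                expr_b=float(eb),
                ratio=float(ratio),
                group=group,
                higher=higher,
                lower=lower,
            )
        )
    return out


def sample_similar(similar_pairs: Sequence[ParalogPair], seed: int) -> list[str]:
    """Select one gene of every similarly expressed pair, uniformly.

    Reproducible under ``seed``; returns one gene id per pair, in pair
    order.
    """
    if len(similar_pairs) == 0:
        raise ValueError("no similar pairs to sample from")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=len(similar_pairs))
    return [
        pair.gene_a if bit == 0 else pair.gene_b
        for pair, bit in zip(similar_pairs, bits)
    ]
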