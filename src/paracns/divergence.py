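"""Coding-sequence and expression-profile divergence contrasts.

Operations: best-ortholog selection (max % identity, ties broken by the
lowest dS), the 2x2 ortholog-retention table for differential pairs with
a two-sided Fisher exact test, Kruskal-Wallis with Dunn's pairwise
post-hoc z-tests on dN/dS by group, Spearman rank correlation of
expression Z scores, the permutation distribution of Spearman rho over
random one-gene-per-pair selections from the similar group, and Fisher
z-comparison of two correlation coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "OrthologRecord",
    "CorrelationResult",
    "PermutationDistribution",
    "GroupDnDsResult",
    "select_ortholog",
    "ortholog_retention_table",
    "fisher_exact_two_sided",
    "group_dnds_test",
    "spearman_rho",
    "permutation_rho_distribution",
    "compare_correlations",
]


@dataclass(frozen=True)
class OrthologRecord:
    """Cross-species ortholog entry for one focal gene."""

    gene: str
    ortholog: str | None = None
    pct_identity: float | None = None
    dN: float | None = None
    dS: float | None = None
    z_expr_self: float | None = None
    z_expr_ortholog: float | None = None

    @property
    def present(self) -> bool:
        return self.ortholog is not None

    @property
    def dnds(self) -> float | None:
        """dN/dS, or None when dS is zero/missing (no rate ratio defined)."""
        if self.dN is None or self.dS is None or self.dS == 0:
            return None
        return self.dN / self.dS


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    p_value: float
    method: str  # "spearman" | "kendall_tau_b"

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12):
            raise ValueError(f"correlation coefficient out of range: {self.coefficient}")


@dataclass(frozen=True)
class PermutationDistribution:
    """Empirical distribution of a statistic over random selections."""

    iterations: int
    coefficients: np.ndarray
    median: float = field(init=False)
    interval_95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.size != self.iterations:
            raise ValueError("coefficient vector length must equal iterations")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "median", float(np.median(coef)))
        lo, hi = np.percentile(coef, [2.5, 97.5])
        object.__setattr__(self, "interval_95", (float(lo), float(hi)))


@dataclass(frozen=True)
class GroupDnDsResult:
    h_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]
    medians: dict[str, float]
    means: dict[str, float]


def select_ortholog(candidates: Sequence[OrthologRecord]) -> OrthologRecord:
    """Pick the best ortholog among candidates for one focal gene.

    Highest percent identity wins; identical identity is broken by the
    lowest dS; a residual tie falls to the lexicographically smallest
    ortholog id so the choice is deterministic.
    """
    if not candidates:
        raise ValueError("select_ortholog requires a nonempty candidate list")
    return min(
        candidates,
        key=lambda r: (
            -(r.pct_identity if r.pct_identity is not None else -math.inf),
            r.dS if r.dS is not None else math.inf,
            r.ortholog or "",
        ),
    )


def ortholog_retention_table(
    differential_pairs: Iterable,
    ortholog_presence: Mapping[str, bool],
) -> np.ndarray:
    """2x2 counts of ortholog retention for differential pairs.

    Rows are the lower- and higher-expressed paralogs, columns are
    ortholog present/absent; each row sums to the number of pairs.
    """
    table = np.zeros((2, 2), dtype=int)
    for pair in differential_pairs:
        for row, gene in enumerate((pair.lower, pair.higher)):
            if gene is None:
                raise ValueError(
                    f"pair ({pair.gene_a}, {pair.gene_b}) lacks higher/lower roles"
                )
            if gene not in ortholog_presence:
                raise ValueError(
                    f"ortholog presence unknown for gene {gene!r} of pair "
                    f"({pair.gene_a}, {pair.gene_b})"
                )
            table[row, 0 if ortholog_presence[gene] else 1] += 1
    return table


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass rule).

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the
    observed table.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(int)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _dunn_pairwise(
    samples: Mapping[str, np.ndarray], adjust: str = "bonferroni"
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on pooled ranks with tie correction."""
    names = list(samples)
    pooled = np.concatenate([samples[k] for k in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks: dict[str, float] = {}
    start = 0
    for k in names:
        size = samples[k].size
        mean_ranks[k] = float(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    variance_scale = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_comparisons = len(names) * (len(names) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = math.sqrt(variance_scale * (1.0 / samples[a].size + 1.0 / samples[b].size))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_comparisons)
            out[(a, b)] = float(p)
    return out


def group_dnds_test(
    dnds_by_group: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
) -> GroupDnDsResult:
    """Kruskal-Wallis omnibus test with Dunn's post-hoc on grouped dN/dS.

    Pairwise p-values are Dunn z-tests with a Bonferroni-type adjustment
    over the comparisons (``adjust='none'`` disables it).  Both medians
    and means are reported since central-tendency conventions differ.
    """
    samples = {k: np.asarray(v, dtype=float) for k, v in dnds_by_group.items()}
    for name, values in samples.items():
        if values.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 observations")
    h, p = stats.kruskal(*samples.values())
    return GroupDnDsResult(
        h_statistic=float(h),
        p_value=float(p),
        pairwise_p=_dunn_pairwise(samples, adjust=adjust),
        medians={k: float(np.median(v)) for k, v in samples.items()},
        means={k: float(v.mean()) for k, v in samples.items()},
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), int(x.size), float(p), "spearman")


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of ``a`` against the same row of ``b``."""
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def permutation_rho_distribution(
    pair_z: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    iterations: int = 10000,
    seed: int = 0,
) -> PermutationDistribution:
    """Spearman-rho distribution over random one-gene-per-pair selections.

    Each pair contributes the (z_self, z_ortholog) scores of its two
    genes; per iteration one gene per pair is chosen uniformly and the
    Spearman correlation between the chosen self and ortholog Z scores is
    recorded.  The summary reports the median and the empirical central
    95 % interval (2.5th-97.5th percentiles, no smoothing).
    """
    if len(pair_z) == 0:
        raise ValueError("no eligible pairs with Z scores for both genes")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    a = np.asarray([p[0] for p in pair_z], dtype=float)  # (n, 2): gene A
    b = np.asarray([p[1] for p in pair_z], dtype=float)  # (n, 2): gene B
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, 2, size=(iterations, len(pair_z)))
    z_self = np.where(picks == 0, a[:, 0], b[:, 0])
    z_orth = np.where(picks == 0, a[:, 1], b[:, 1])
    coefficients = _rowwise_spearman(z_self, z_orth)
    return PermutationDistribution(iterations=iterations, coefficients=coefficients)


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher z-comparison of two correlation coefficients.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p
    from the standard normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"n must exceed 3, got {n}")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
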