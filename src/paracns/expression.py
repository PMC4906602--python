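"""Tissue expression profiles: replicate averaging, overall mean and the
tissue-specificity index tau.

Expression values are kept on the scale they arrive on (RMA-style log2
units for microarray data); tau is applied to that scale directly, without
de-logging.  tau ranges from 0 (uniform expression across tissues) to 1
(expression confined to a single tissue):

    tau = sum_i(1 - x_i / max(x)) / (N - 1)

where N is the number of tissues and x_i the profile component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "average_replicates",
    "overall_mean",
    "tissue_specificity_tau",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene expression vector over tissues with derived summaries."""

    gene: str
    values: tuple[float, ...]
    mean: float = field(init=False)
    tau: float | None = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "mean", overall_mean(arr))
        tau = None
        if arr.size >= 2 and arr.min() >= 0 and arr.max() > 0:
            tau = tissue_specificity_tau(arr)
        object.__setattr__(self, "tau", tau)

    @property
    def n_tissues(self) -> int:
        return len(self.values)


def average_replicates(
    sample_matrix: pd.DataFrame,
    grouping: Mapping[str, str],
    tissue_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Collapse replicate sample columns to one column per tissue.

    Parameters
    ----------
    sample_matrix
        Genes x samples; column names are sample ids.
    grouping
        Maps every sample id to a tissue name.  Samples left unassigned
        raise ``ValueError`` naming the offender.
    tissue_order
        Declared output column order; defaults to first-appearance order
        of the tissues over the sample columns.
    """
    unassigned = [s for s in sample_matrix.columns if s not in grouping]
    if unassigned:
        raise ValueError(f"samples not assigned to a tissue: {unassigned}")
    if tissue_order is None:
        seen: dict[str, None] = {}
        for s in sample_matrix.columns:
            seen.setdefault(grouping[s], None)
        tissue_order = list(seen)
    columns = {}
    for tissue in tissue_order:
        samples = [s for s in sample_matrix.columns if grouping[s] == tissue]
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        columns[tissue] = sample_matrix[samples].mean(axis=1)
    return pd.DataFrame(columns, index=sample_matrix.index)[list(tissue_order)]


def overall_mean(profile: Sequence[float] | np.ndarray) -> float:
    """Arithmetic mean of a tissue profile (the gene's overall expression)."""
    arr = np.asarray(profile, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty expression profile")
    return float(arr.mean())


def tissue_specificity_tau(profile: Sequence[float] | np.ndarray) -> float:
    """Tissue-specificity index tau of a nonnegative tissue profile.

    Components are normalized by the maximal component value; an all-zero
    profile leaves tau undefined and raises ``ValueError``.
    """
    arr = np.asarray(profile, dtype=float)
    if arr.size < 2:
        raise ValueError("tau requires at least two tissues")
    if (arr < 0).any():
        raise ValueError("tau requires nonnegative expression values")
    m = arr.max()
    if m == 0:
        raise ValueError("tau is undefined for an all-zero profile")
    return float((1.0 - arr / m).sum() / (arr.size - 1))


def profile_table(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene overall mean and tau for a genes x tissues matrix.

    Genes whose profile is all-zero get ``NaN`` tau (they are excluded
    from tau analyses rather than assigned 0).
    """
    means = expression.mean(axis=1)
    arr = expression.to_numpy(dtype=float)
    maxima = arr.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        taus = (1.0 - arr / maxima[:, None]).sum(axis=1) / (arr.shape[1] - 1)
    taus = np.where(maxima > 0, taus, np.nan)
    return pd.DataFrame({"mean": means, "tau": taus}, index=expression.index)
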