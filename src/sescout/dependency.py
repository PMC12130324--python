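"""CRISPR gene-effect normalization and dependency calls.

Raw gene-effect scores (lower = more depleted) are rescaled per cell line so
that the median effect of known non-essential control genes is exactly 0 and
the median effect of known essential control genes is exactly -1:

    normalized = (raw - m_N) / (m_N - m_E)

with m_N, m_E the per-line control medians.  A line is called dependent on a
gene when its normalized score falls strictly below -0.5 (half the effect
size of knocking out an essential gene).  The normalization is invariant to
any per-line affine rescaling of the raw scores.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = [
    "NormalizationError",
    "InsufficientDataError",
    "GeneEffectMatrix",
    "AssociationResult",
    "normalize_gene_effect",
    "call_dependent",
    "expression_dependency_association",
    "read_gene_effect",
    "write_gene_effect",
]

DEFAULT_DEPENDENCY_CUTOFF = -0.5
EXACT_PERMUTATION_MAX_N = 9


class NormalizationError(ValueError):
    """Control medians are unusable for a cell line (m_N <= m_E)."""


class InsufficientDataError(ValueError):
    """Too few paired observations for an association test."""


@dataclass
class GeneEffectMatrix:
    """Gene x cell-line effect scores plus essential/non-essential controls."""

    scores: pd.DataFrame  # rows: genes; columns: cell lines
    essential: tuple[str, ...]
    nonessential: tuple[str, ...]

    def __post_init__(self) -> None:
        self.essential = tuple(self.essential)
        self.nonessential = tuple(self.nonessential)
        if set(self.essential) & set(self.nonessential):
            raise ValidationError("essential and non-essential control lists overlap")
        missing = (set(self.essential) | set(self.nonessential)) - set(self.scores.index)
        if missing:
            raise ValidationError(
                f"control genes absent from matrix rows: {sorted(missing)[:5]}"
            )
        if not self.essential or not self.nonessential:
            raise ValidationError("both control lists must be non-empty")


def normalize_gene_effect(raw: GeneEffectMatrix) -> GeneEffectMatrix:
    """Map each line's scores so control medians become exactly 0 and -1.

    Median is the standard midpoint-of-two-middle-values median (control
    lists may be even-sized).  Raises naming the offending line when a
    line's non-essential median does not exceed its essential median.
    """
    m_n = raw.scores.loc[list(raw.nonessential)].median(axis=0)
    m_e = raw.scores.loc[list(raw.essential)].median(axis=0)
    bad = m_n[m_n <= m_e]
    if len(bad) > 0:
        raise NormalizationError(
            f"non-essential median <= essential median for line(s) "
            f"{list(bad.index[:5])}; cannot normalize"
        )
    normalized = (raw.scores - m_n) / (m_n - m_e)
    return GeneEffectMatrix(
        scores=normalized, essential=raw.essential, nonessential=raw.nonessential
    )


def call_dependent(
    normalized: pd.DataFrame | GeneEffectMatrix,
    cutoff: float = DEFAULT_DEPENDENCY_CUTOFF,
) -> pd.DataFrame:
    """Boolean gene x line matrix: True iff normalized score < cutoff (strict)."""
    scores = normalized.scores if isinstance(normalized, GeneEffectMatrix) else normalized
    return scores < cutoff


@dataclass(frozen=True)
class AssociationResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact-permutation" or "asymptotic"
    degenerate: bool = False


def expression_dependency_association(
    expression: Sequence[float],
    dependency: Sequence[float],
) -> AssociationResult:
    """Spearman rank correlation between expression and dependency scores.

    For n <= 9 the two-sided p-value comes from the exact permutation null
    (all n! pairings enumerated); larger n uses the asymptotic
    approximation.  A constant input vector makes rho undefined; the result
    is flagged degenerate with NaN statistics rather than raising.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(dependency, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("expression and dependency must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(float("nan"), float("nan"), n, "degenerate", True)
    if n <= EXACT_PERMUTATION_MAX_N:
        rho, p = _exact_spearman(x, y)
        return AssociationResult(rho, p, n, "exact-permutation")
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(float(rho), float(p), n, "asymptotic")


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def _exact_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Observed rho plus exact two-sided permutation p-value (ties handled
    by Pearson correlation on midranks)."""
    xr = _rank(x)
    yr = _rank(y)
    xs = (xr - xr.mean()) / xr.std()
    ys = (yr - yr.mean()) / yr.std()
    n = len(x)
    rho_obs = float(np.dot(xs, ys) / n)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rho_null = (ys[perms] @ xs) / n
    p = float(np.mean(np.abs(rho_null) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_gene_effect(
    matrix_path: str | Path,
    essential_path: str | Path,
    nonessential_path: str | Path,
) -> GeneEffectMatrix:
    """Gene x line TSV (first column gene ids) plus one-gene-per-line lists."""
    scores = pd.read_csv(matrix_path, sep="\t", index_col=0)
    essential = _read_gene_list(essential_path)
    nonessential = _read_gene_list(nonessential_path)
    return GeneEffectMatrix(scores=scores, essential=essential, nonessential=nonessential)


def _read_gene_list(path: str | Path) -> tuple[str, ...]:
    with open(path, "rt", encoding="utf-8") as fh:
        return tuple(line.strip() for line in fh if line.strip())


def write_gene_effect(matrix: GeneEffectMatrix, path: str | Path) -> None:
    matrix.scores.to_csv(path, sep="\t", float_format="%.10g")
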