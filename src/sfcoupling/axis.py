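"""Alignment of regional effect maps with the sensorimotor-association axis.

Regional coupling, group-effect, and individual-effect maps are
compared with the cortical axis ranks by Spearman rank correlation,
after excluding outlier regions (beyond mean +/- 3 SD of the map), with
significance assessed against the spin-test null: each spatial
rotation permutes the map, the same outlier/missing mask is applied,
and the null correlation is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError
from .nulls import tail_pvalue

__all__ = ["spearman_rho", "outlier_mask", "AlignmentResult", "align_map"]


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need equal-length vectors of length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise DegenerateInputError("constant vector: rank correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def outlier_mask(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """True where a value lies within mean +/- k*SD of the finite values.

    Non-finite entries are False.  A constant vector has SD 0 and keeps
    every (finite) value, all being equal to the mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InvalidInputError("need at least 3 values")
    finite = np.isfinite(values)
    mean = values[finite].mean()
    sd = values[finite].std(ddof=1)
    mask = finite.copy()
    mask[finite] = np.abs(values[finite] - mean) <= k * sd
    return mask


@dataclass
class AlignmentResult:
    """Spearman alignment of one map with the axis, spin-test corrected."""

    rho: float
    p_spin: float
    n_regions_used: int
    outliers_excluded: list[int]
    null_correlations: np.ndarray


def align_map(values: np.ndarray, axis_ranks: np.ndarray,
              permutations: np.ndarray, outlier_k: float = 3.0,
              two_sided: bool = False) -> AlignmentResult:
    """Axis alignment of a regional map with outlier exclusion.

    Outliers (and missing regions) are masked from the map; Spearman
    rho is computed on the surviving regions.  Each spin permutation is
    applied to the full-length map first, then the same region mask is
    applied, so empirical and null statistics see identical exclusions.
    """
    values = np.asarray(values, dtype=float)
    axis_ranks = np.asarray(axis_ranks, dtype=float)
    if values.size != axis_ranks.size:
        raise InvalidInputError("map and axis ranks must be node-aligned")
    keep = outlier_mask(values, k=outlier_k)
    outliers = np.flatnonzero(np.isfinite(values) & ~keep)
    if keep.sum() < 3:
        raise DegenerateInputError("fewer than 3 regions survive masking")
    rho = spearman_rho(values[keep], axis_ranks[keep])
    n_rot = permutations.shape[0]
    nulls = np.empty(n_rot)
    for t in range(n_rot):
        permuted = values[permutations[t]]
        ok = keep & np.isfinite(permuted)
        nulls[t] = spearman_rho(permuted[ok], axis_ranks[ok])
    p = tail_pvalue(nulls, rho, two_sided=two_sided)
    return AlignmentResult(rho=rho, p_spin=p,
                           n_regions_used=int(keep.sum()),
                           outliers_excluded=outliers.tolist(),
                           null_correlations=nulls)
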