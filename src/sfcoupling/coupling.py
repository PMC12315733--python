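"""Structure-function coupling and its group/individual decomposition.

Coupling is the Pearson correlation between a structural profile and an
empirical FC profile.  Two approaches are supported:

* ``correlation`` — the structural profile is the SC edge vector
  itself, restricted to edges with nonzero SC in the source subject
  (direct connections only);
* ``gnn`` — the structural profile is the GNN-predicted FC, over all
  (unmasked) unique edges, so indirect communication is included.

Computing coupling between every ordered pair of subjects (source
subject's SC or predicted FC against target subject's FC) yields an
N x N asymmetric coupling matrix whose diagonal is the within-subject
("matched") coupling and whose off-diagonal entries are between-subject
("mismatched") couplings.  The decomposition reads off:

    total      = mean(diagonal)
    group      = mean(off-diagonal)        (group-common effect)
    individual = total - group             (individual-specific effect)

with a per-subject matched-vs-mismatched paired t-test for the
significance of the individual effect.  The same machinery applies per
region, using row profiles, to yield regional effect maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "edge_vector",
    "coupling_pair",
    "regional_coupling",
    "cross_coupling_matrix",
    "CouplingDecomposition",
    "decompose",
    "normalized_individual",
    "regional_effect_maps",
]

_SYM_ATOL = 1e-9


def edge_vector(m: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Upper-triangle (i < j) values in row-major order.

    With a boolean ``mask``, only mask-true entries are returned;
    unmasked, the length is K(K-1)/2.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError("matrix must be square")
    if np.max(np.abs(m - m.T)) > _SYM_ATOL:
        raise InvalidInputError("matrix is not symmetric within 1e-9")
    iu = np.triu_indices(m.shape[0], 1)
    vals = m[iu]
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)[iu]]
    return vals


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise DegenerateInputError("constant profile: correlation undefined")
    return float(np.dot(xc, yc) / denom)


def coupling_pair(source: np.ndarray, fc: np.ndarray, approach: str,
                  sc_mask: np.ndarray | None = None) -> float:
    """Global coupling between one source subject and one FC subject.

    ``approach='correlation'`` correlates SC with FC over edges with
    nonzero SC in the *source* subject (intersected with the
    consistency mask); ``approach='gnn'`` correlates predicted FC with
    FC over all unmasked unique edges.
    """
    src = edge_vector(source, sc_mask)
    tgt = edge_vector(fc, sc_mask)
    if approach == "correlation":
        nz = src != 0
        src, tgt = src[nz], tgt[nz]
    elif approach != "gnn":
        raise InvalidInputError(f"unknown approach {approach!r}")
    if src.size < 3:
        raise DegenerateInputError(
            f"only {src.size} usable edges after masking")
    return _pearson(src, tgt)


def regional_coupling(source: np.ndarray, fc: np.ndarray, region: int,
                      approach: str,
                      sc_mask: np.ndarray | None = None) -> float:
    """Coupling of one region's connection profile (its matrix row,
    excluding the diagonal entry; correlation approach restricted to
    the row's nonzero SC entries)."""
    k = source.shape[0]
    keep = np.ones(k, dtype=bool)
    keep[region] = False
    if sc_mask is not None:
        keep &= np.asarray(sc_mask, dtype=bool)[region]
    src = source[region, keep]
    tgt = fc[region, keep]
    if approach == "correlation":
        nz = src != 0
        src, tgt = src[nz], tgt[nz]
    elif approach != "gnn":
        raise InvalidInputError(f"unknown approach {approach!r}")
    if src.size < 3:
        raise DegenerateInputError(
            f"region {region}: only {src.size} usable entries")
    return _pearson(src, tgt)


def _corr_one_to_many(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r between ``x`` (E,) and each column of ``ys`` (E, N)."""
    xc = x - x.mean()
    yc = ys - ys.mean(axis=0)
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2, axis=0))
    if np.any(denom == 0):
        raise DegenerateInputError("constant profile: correlation undefined")
    return (xc @ yc) / denom


def cross_coupling_matrix(sources: list[np.ndarray], fcs: list[np.ndarray],
                          approach: str,
                          sc_mask: np.ndarray | None = None,
                          region: int | None = None) -> np.ndarray:
    """N x N coupling matrix: entry (i, j) couples source i with FC j.

    The diagonal holds matched (within-subject) couplings, off-diagonal
    entries mismatched (between-subject) couplings.  ``region=None``
    gives global coupling; an integer gives that region's row-profile
    coupling.  For the correlation approach the source subject's
    nonzero-edge set defines the edge set of its whole row.
    """
    if len(sources) != len(fcs) or not sources:
        raise InvalidInputError("need equal-length, non-empty source/FC lists")
    n = len(sources)
    k = sources[0].shape[0]

    if region is None:
        tgt_cols = np.column_stack([edge_vector(f, sc_mask) for f in fcs])
        src_vecs = [edge_vector(s, sc_mask) for s in sources]
    else:
        keep = np.ones(k, dtype=bool)
        keep[region] = False
        if sc_mask is not None:
            keep &= np.asarray(sc_mask, dtype=bool)[region]
        tgt_cols = np.column_stack([f[region, keep] for f in fcs])
        src_vecs = [s[region, keep] for s in sources]

    cp = np.empty((n, n))
    for i, src in enumerate(src_vecs):
        if approach == "correlation":
            nz = src != 0
            if nz.sum() < 3:
                raise DegenerateInputError(
                    f"source {i}: fewer than 3 nonzero edges")
            cp[i] = _corr_one_to_many(src[nz], tgt_cols[nz])
        elif approach == "gnn":
            if src.size < 3:
                raise DegenerateInputError(f"source {i}: profile too short")
            cp[i] = _corr_one_to_many(src, tgt_cols)
        else:
            raise InvalidInputError(f"unknown approach {approach!r}")
    return cp


@dataclass
class CouplingDecomposition:
    """Group/individual decomposition of one coupling matrix."""

    total: float                 # mean matched (diagonal) coupling
    group: float                 # mean mismatched (off-diagonal) coupling
    individual: float            # total - group
    individual_fraction: float   # individual / total (NaN when total == 0)
    matched: np.ndarray          # per-subject diagonal values
    mismatched: np.ndarray       # per-subject symmetrized off-diagonal means
    t_statistic: float
    p_value: float


def _paired_t(matched: np.ndarray, mismatched: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test from its closed form (df = N - 1)."""
    d = matched - mismatched
    n = d.size
    if n < 3:
        return np.nan, np.nan
    sd = d.std(ddof=1)
    if sd == 0:
        return (np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else np.nan),
                0.0 if d.mean() != 0 else np.nan)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def decompose(cp: np.ndarray) -> CouplingDecomposition:
    """Split a coupling matrix into group-common and individual effects.

    total = mean diagonal; group = mean off-diagonal; individual =
    total - group.  Per subject i, the mismatched coupling averages the
    i-th row and i-th column excluding the diagonal,
    (1/(2(N-1))) sum_{j != i} (cp_ij + cp_ji).
    """
    cp = np.asarray(cp, dtype=float)
    if cp.ndim != 2 or cp.shape[0] != cp.shape[1]:
        raise InvalidInputError("coupling matrix must be square")
    n = cp.shape[0]
    if n < 2:
        raise InvalidInputError("decomposition needs N >= 2 subjects")
    matched = np.diag(cp).copy()
    off = ~np.eye(n, dtype=bool)
    total = float(matched.mean())
    group = float(cp[off].mean())
    individual = total - group
    mismatched = (cp.sum(axis=1) + cp.sum(axis=0) - 2 * matched) / (2 * (n - 1))
    t, p = _paired_t(matched, mismatched)
    frac = individual / total if total != 0 else np.nan
    return CouplingDecomposition(
        total=total, group=group, individual=individual,
        individual_fraction=frac, matched=matched, mismatched=mismatched,
        t_statistic=t, p_value=p)


def normalized_individual(dec: CouplingDecomposition) -> float:
    """Individual effect as a proportion of the total coupling."""
    if dec.total == 0:
        import warnings
        warnings.warn("total coupling is 0; normalized individual effect "
                      "undefined", RuntimeWarning, stacklevel=2)
        return np.nan
    return dec.individual / dec.total


def regional_effect_maps(sources: list[np.ndarray], fcs: list[np.ndarray],
                         approach: str,
                         sc_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-region decomposition of the regional coupling matrices.

    Returns a DataFrame indexed by region_id with columns total, group,
    individual, normalized_individual, t_statistic, p_value.  Regions
    with degenerate profiles are reported as NaN rows, not errors.
    """
    k = sources[0].shape[0]
    rows = []
    for r in range(k):
        try:
            cp = cross_coupling_matrix(sources, fcs, approach,
                                       sc_mask=sc_mask, region=r)
            dec = decompose(cp)
            rows.append({
                "region_id": r, "approach": approach, "total": dec.total,
                "group": dec.group, "individual": dec.individual,
                "normalized_individual": (dec.individual / dec.total
                                          if dec.total != 0 else np.nan),
                "t_statistic": dec.t_statistic, "p_value": dec.p_value,
            })
        except DegenerateInputError:
            rows.append({"region_id": r, "approach": approach,
                         "total": np.nan, "group": np.nan,
                         "individual": np.nan,
                         "normalized_individual": np.nan,
                         "t_statistic": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows).set_index("region_id")
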