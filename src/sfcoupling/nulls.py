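"""Null models: topology-randomizing rewiring and spatial spin permutations.

* :func:`rewire_sc` randomizes SC topology by Maslov-Sneppen double-edge
  swaps (degree-preserving), then reassigns the original weight multiset
  to the new edges by rank-matching weights to edge strength-sums, so
  nodal strength distributions are approximately preserved.  Training a
  GNN on rewired SC (but testing on intact SC) quantifies how much of
  the structure-function coupling rides on topology.

* :func:`spin_rotations` / :func:`spin_pvalue` implement the spin test:
  random 3D rotations of the regional sphere coordinates (mirrored
  across hemispheres) induce region permutations that preserve spatial
  autocorrelation, giving a null distribution for map-to-map
  correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import special_ortho_group

from .errors import InvalidInputError
from .gnn import GnnConfig, predict_fc, train_model
from .coupling import cross_coupling_matrix

__all__ = [
    "rewire_sc",
    "RewiredComparison",
    "rewired_training_run",
    "spin_rotations",
    "SpinNull",
    "spin_pvalue",
]


def rewire_sc(sc: np.ndarray, swaps_per_edge: int = 10,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Degree-preserving topology randomization with weight rank-matching.

    Binary topology is randomized by repeated double-edge swaps (each
    swap rewires edges (a,b),(c,d) to (a,d),(c,b), preserving every
    node's degree).  The original weight multiset is then reassigned to
    the new edge set: edges are ranked by the sum of their endpoints'
    original strengths and matched to the sorted weights, approximately
    preserving nodal strengths.  If no valid swap exists (e.g. a
    complete graph) the input is returned unchanged with a warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    sc = np.asarray(sc, dtype=float)
    k = sc.shape[0]
    iu = np.triu_indices(k, 1)
    edges = np.column_stack([iu[0], iu[1]])[sc[iu] > 0]
    n_edges = edges.shape[0]
    if n_edges < 4:
        raise InvalidInputError("need at least 4 edges to rewire")

    adj = sc > 0
    edges = [tuple(e) for e in edges]
    target = swaps_per_edge * n_edges
    max_attempts = 20 * target
    done = 0
    attempts = 0
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed new edges: (a, d) and (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        done += 1

    if done == 0:
        warnings.warn("no valid double-edge swap found; returning the input "
                      "unchanged", RuntimeWarning, stacklevel=2)
        return sc.copy()

    strength = sc.sum(axis=1)
    new_edges = np.array(edges)
    scores = strength[new_edges[:, 0]] + strength[new_edges[:, 1]]
    order = np.argsort(scores, kind="stable")
    weights = np.sort(sc[iu][sc[iu] > 0])
    out = np.zeros_like(sc)
    rows = new_edges[order, 0]
    cols = new_edges[order, 1]
    out[rows, cols] = weights
    out += out.T
    return out


@dataclass
class RewiredComparison:
    """Empirical-vs-rewired GNN coupling comparison on the test set."""

    r_empirical: np.ndarray     # per-test-subject matched coupling, intact model
    r_rewired: np.ndarray       # same, model trained on rewired SC
    r2_drop: float              # mean(r_emp^2) - mean(r_null^2)
    loss_trace: np.ndarray


def rewired_training_run(train_scs: list[np.ndarray],
                         train_fcs: list[np.ndarray],
                         test_scs: list[np.ndarray],
                         test_fcs: list[np.ndarray],
                         config: GnnConfig,
                         r_empirical: np.ndarray,
                         swaps_per_edge: int = 10,
                         rng: np.random.Generator | None = None,
                         sc_mask: np.ndarray | None = None
                         ) -> RewiredComparison:
    """Train a topological-null GNN on rewired training SC.

    Every training subject's SC is independently rewired; empirical FC
    targets and test SC stay intact.  Per-test-subject matched coupling
    of the null model is compared against the supplied empirical-model
    couplings via the drop in mean variance accounted for,
    ``mean(r_emp^2) - mean(r_null^2)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    rew_scs = [rewire_sc(sc, swaps_per_edge=swaps_per_edge, rng=rng)
               for sc in train_scs]
    model, losses = train_model(rew_scs, train_fcs, config)
    preds = [predict_fc(sc, model) for sc in test_scs]
    cp = cross_coupling_matrix(preds, test_fcs, "gnn", sc_mask=sc_mask)
    r_rewired = np.diag(cp).copy()
    r_empirical = np.asarray(r_empirical, dtype=float)
    drop = float(np.mean(r_empirical**2) - np.mean(r_rewired**2))
    return RewiredComparison(r_empirical=r_empirical, r_rewired=r_rewired,
                             r2_drop=drop, loss_trace=losses)


def _greedy_nn_assignment(rotated: np.ndarray, original: np.ndarray) -> np.ndarray:
    """Bijective greedy nearest-neighbor matching.

    Returns ``perm`` with ``perm[i] = j`` meaning original position i
    receives the region whose rotated coordinates land nearest to it;
    pairs are assigned globally closest-first, without replacement.
    """
    n = original.shape[0]
    d = np.linalg.norm(original[:, None, :] - rotated[None, :, :], axis=2)
    perm = np.full(n, -1, dtype=int)
    big = np.inf
    d = d.copy()
    for _ in range(n):
        flat = np.argmin(d)
        i, j = np.unravel_index(flat, d.shape)
        perm[i] = j
        d[i, :] = big
        d[:, j] = big
    return perm


def spin_rotations(coords: np.ndarray, hemispheres: np.ndarray,
                   n_rotations: int,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Region permutations induced by random sphere rotations.

    Each rotation draws a uniform random 3D rotation, applies it to the
    left hemisphere and the x-mirrored rotation to the right, then
    bijectively reassigns rotated regions to original regions by greedy
    nearest-neighbor matching within each hemisphere.  Returns an
    (n_rotations, K) integer array of permutations: the null value of a
    map at region i is ``map[perm[i]]``.
    """
    if rng is None:
        rng = np.random.default_rng()
    coords = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise InvalidInputError("sphere coordinates must be unit-norm")
    hemispheres = np.asarray(hemispheres)
    labels = np.unique(hemispheres)
    if labels.size > 2:
        raise InvalidInputError("expected at most two hemisphere labels")
    mirror = np.diag([-1.0, 1.0, 1.0])

    k = coords.shape[0]
    perms = np.empty((n_rotations, k), dtype=int)
    idx_by_hemi = {lab: np.flatnonzero(hemispheres == lab) for lab in labels}
    for t in range(n_rotations):
        rot = special_ortho_group.rvs(3, random_state=rng)
        for h_i, lab in enumerate(labels):
            idx = idx_by_hemi[lab]
            r = rot if h_i == 0 else mirror @ rot @ mirror
            rotated = coords[idx] @ r.T
            local = _greedy_nn_assignment(rotated, coords[idx])
            perms[t, idx] = idx[local]
    return perms


@dataclass
class SpinNull:
    """Spin-test outcome for one pair of regional maps."""

    empirical: float
    null_correlations: np.ndarray
    p_spin: float
    n_rotations: int


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise InvalidInputError("constant map: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def tail_pvalue(nulls: np.ndarray, empirical: float,
                two_sided: bool = False) -> float:
    """Fraction of nulls at least as extreme as the empirical value,
    in the direction of the empirical sign (or on |.| if two_sided)."""
    nulls = np.asarray(nulls, dtype=float)
    if two_sided:
        return float(np.mean(np.abs(nulls) >= abs(empirical)))
    if empirical >= 0:
        return float(np.mean(nulls >= empirical))
    return float(np.mean(nulls <= empirical))


def spin_pvalue(map_a: np.ndarray, map_b: np.ndarray,
                permutations: np.ndarray,
                two_sided: bool = False) -> SpinNull:
    """Spin-test p-value for the Spearman correlation of two maps.

    ``map_a`` is permuted by each rotation; regions that are NaN in
    either map are dropped pairwise (after permutation, identically
    for empirical and null).  The p-value is the proportion of null
    correlations at least as extreme as the empirical one in the
    direction of its sign; the smallest reportable value is 0, to be
    read as < 1/n_rotations.
    """
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    keep = np.isfinite(map_a) & np.isfinite(map_b)
    emp = _rank_corr(map_a[keep], map_b[keep])
    n_rot = permutations.shape[0]
    nulls = np.empty(n_rot)
    for t in range(n_rot):
        pa = map_a[permutations[t]]
        ok = np.isfinite(pa) & np.isfinite(map_b)
        nulls[t] = _rank_corr(pa[ok], map_b[ok])
    p = tail_pvalue(nulls, emp, two_sided=two_sided)
    return SpinNull(empirical=emp, null_correlations=nulls, p_spin=p,
                    n_rotations=n_rot)
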