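"""Connectome construction and quality control.

The rules implemented here sit downstream of image processing:

* functional connectivity as Fisher-z-transformed Pearson correlation
  between regional time series;
* structural edge-weight normalization by the average volume of the
  two connected regions, followed by a log transform;
* group-consistency thresholding, removing the top quartile of edges
  by across-subject coefficient of variation;
* motion-based run exclusion from framewise-displacement traces
  (per-run spike fraction, then an outlier fence on pooled mean FD,
  then a minimum surviving-run count per subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "compute_fc",
    "normalize_and_log_sc",
    "ConsistencyMask",
    "consistency_mask",
    "QcResult",
    "qc_filter_runs",
]

# |r| is clipped here before atanh so perfectly correlated series give a
# large finite z instead of +/-inf.
_R_CLIP = 1.0 - 1e-7


def compute_fc(ts: np.ndarray) -> np.ndarray:
    """Fisher-z functional connectivity from a frames-by-regions matrix.

    Off-diagonal (i, j) is ``atanh(pearson(ts[:, i], ts[:, j]))`` with
    |r| clipped at 1 - 1e-7; the diagonal is zero.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise InvalidInputError("time series must be a frames-by-regions matrix")
    t, k = ts.shape
    if t < 3:
        raise InvalidInputError(f"need at least 3 frames, got {t}")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise DegenerateInputError(
            f"zero-variance time series for region(s) {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z = 0.5 * (z + z.T)
    np.fill_diagonal(z, 0.0)
    return z


def normalize_and_log_sc(counts: np.ndarray, volumes: np.ndarray,
                         log_mode: str = "log1p") -> np.ndarray:
    """Volume-normalize streamline counts, then log-transform.

    ``w(i, j) = counts(i, j) / ((volumes[i] + volumes[j]) / 2)`` followed
    by ``ln(1 + w)`` (default) or ``ln(w)`` on nonzero entries
    (``log_mode='log_nonzero'``).  Zeros stay zero either way; the
    default keeps all weights nonnegative even when volume
    normalization pushes them below 1.
    """
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0):
        raise InvalidInputError("all region volumes must be positive")
    if counts.shape[0] != counts.shape[1] or counts.shape[0] != volumes.size:
        raise InvalidInputError("counts must be K x K with K volumes")
    if np.any(counts < 0):
        raise InvalidInputError("streamline counts must be nonnegative")
    avg_vol = 0.5 * (volumes[:, None] + volumes[None, :])
    w = counts / avg_vol
    if log_mode == "log1p":
        out = np.log1p(w)
    elif log_mode == "log_nonzero":
        out = np.zeros_like(w)
        nz = w > 0
        out[nz] = np.log(w[nz])
    else:
        raise InvalidInputError(f"unknown log_mode {log_mode!r}")
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class ConsistencyMask:
    """Edges kept by group-consistency thresholding.

    ``keep`` is a symmetric boolean matrix with zero diagonal; ``cv``
    holds the across-subject coefficient of variation for edges present
    in at least one subject (NaN elsewhere).
    """

    keep: np.ndarray
    cv: np.ndarray
    percentile: float
    threshold: float
    n_evaluated: int
    n_removed_by_cv: int

    def apply(self, m: np.ndarray) -> np.ndarray:
        return np.where(self.keep, m, 0.0)


def consistency_mask(scs: list[np.ndarray], percentile: float = 75.0,
                     quantile_method: str = "linear") -> ConsistencyMask:
    """Mask out the top quartile of edges by across-subject weight CV.

    For every upper-triangle edge nonzero in at least one subject, the
    coefficient of variation (sample sd / mean, zeros counted as
    0-weight observations) is computed across subjects; edges with CV
    strictly above the given percentile of the CV distribution are
    removed, as are edges absent in every subject.
    """
    if len(scs) < 2:
        raise InvalidInputError("consistency mask needs at least 2 subjects")
    stack = np.stack([np.asarray(m, dtype=float) for m in scs])
    k = stack.shape[1]
    if stack.shape[1] != stack.shape[2]:
        raise InvalidInputError("matrices must be square")
    iu = np.triu_indices(k, 1)
    w = stack[:, iu[0], iu[1]]                     # subjects x edges
    evaluated = (w > 0).any(axis=0)
    mean = w.mean(axis=0)
    sd = w.std(axis=0, ddof=1)
    cv = np.full(iu[0].size, np.nan)
    cv[evaluated] = sd[evaluated] / mean[evaluated]

    cvs = cv[evaluated]
    threshold = float(np.percentile(cvs, percentile, method=quantile_method))
    keep_edges = evaluated & ~(cv > threshold)

    keep = np.zeros((k, k), dtype=bool)
    keep[iu] = keep_edges
    keep |= keep.T
    cv_mat = np.full((k, k), np.nan)
    cv_mat[iu] = cv
    cv_mat[(iu[1], iu[0])] = cv
    return ConsistencyMask(
        keep=keep, cv=cv_mat, percentile=percentile, threshold=threshold,
        n_evaluated=int(evaluated.sum()),
        n_removed_by_cv=int((evaluated & (cv > threshold)).sum()),
    )


@dataclass
class QcResult:
    """Outcome of motion-based run filtering."""

    kept_runs: list[list[int]]            # surviving run indices per subject
    excluded_subjects: list[int]          # subjects with too few surviving runs
    dropped_rule1: list[tuple[int, int]]  # (subject, run) dropped by spike fraction
    dropped_rule2: list[tuple[int, int]]  # (subject, run) dropped by mean-FD fence
    mean_fd_threshold: float = field(default=np.nan)


def qc_filter_runs(fd_runs_per_subject: list[list[np.ndarray]],
                   fd_spike_mm: float = 0.2,
                   max_spike_frac: float = 0.25,
                   min_runs: int = 4,
                   quantile_method: str = "linear") -> QcResult:
    """Motion QC in the fixed order: spike rule, fence rule, minimum runs.

    Rule 1 drops any run whose fraction of frames with FD > 0.2 mm
    exceeds 25%.  Rule 2 pools the mean FD of all surviving runs across
    subjects, computes Q3 + 1.5*IQR of that distribution, and drops
    runs with mean FD strictly above the fence.  Subjects left with
    fewer than ``min_runs`` runs are excluded.
    """
    for si, runs in enumerate(fd_runs_per_subject):
        for ri, fd in enumerate(runs):
            fd = np.asarray(fd)
            if fd.size == 0:
                raise InvalidInputError(f"subject {si} run {ri}: empty FD trace")
            if np.any(fd < 0):
                raise InvalidInputError(f"subject {si} run {ri}: negative FD")

    survivors: list[list[int]] = []
    dropped1: list[tuple[int, int]] = []
    for si, runs in enumerate(fd_runs_per_subject):
        kept = []
        for ri, fd in enumerate(runs):
            fd = np.asarray(fd, dtype=float)
            if np.mean(fd > fd_spike_mm) > max_spike_frac:
                dropped1.append((si, ri))
            else:
                kept.append(ri)
        survivors.append(kept)

    pooled = [np.mean(fd_runs_per_subject[si][ri])
              for si, kept in enumerate(survivors) for ri in kept]
    dropped2: list[tuple[int, int]] = []
    fence = np.nan
    if pooled:
        q1, q3 = np.percentile(pooled, [25, 75], method=quantile_method)
        fence = float(q3 + 1.5 * (q3 - q1))
        new_survivors = []
        for si, kept in enumerate(survivors):
            still = []
            for ri in kept:
                if np.mean(fd_runs_per_subject[si][ri]) > fence:
                    dropped2.append((si, ri))
                else:
                    still.append(ri)
            new_survivors.append(still)
        survivors = new_survivors

    excluded = [si for si, kept in enumerate(survivors) if len(kept) < min_runs]
    return QcResult(kept_runs=survivors, excluded_subjects=excluded,
                    dropped_rule1=dropped1, dropped_rule2=dropped2,
                    mean_fd_threshold=fence)
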