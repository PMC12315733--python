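"""Synthetic connectome cohort generator.

Produces cohorts of node-aligned (SC, FC) matrix pairs with *known*
group-common and individual-specific structure, standing in for a
real multi-subject diffusion/resting-state MRI cohort:

* a shared sparse weighted structural backbone with modular topology
  (stochastic block model) plus densely connected hub nodes;
* small per-subject jitter of the backbone (lognormal weight noise and
  rare edge flips), emulating the low across-subject variability of
  structural connectivity;
* functional connectivity synthesized from multi-hop structural
  topology (a polynomial in the symmetrically normalized adjacency),
  plus a cohort-shared non-structural component, plus a per-subject
  component whose regional scale increases along a synthetic
  sensorimotor-to-association-like cortical axis, plus i.i.d. noise;
* per-run framewise-displacement traces for motion-QC fixtures.

Because every component scale is a parameter of :class:`CohortSpec`,
downstream estimators (coupling decomposition, GNN prediction, null
models, axis alignment) can be tested for parameter recovery rather
than merely smoke-tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateInputError, GenerationError, InvalidSpecError

__all__ = [
    "CohortSpec",
    "SubjectData",
    "Cohort",
    "build_region_meta",
    "region_sigma",
    "sample_group_sc",
    "sample_subject_sc",
    "multi_hop_latent",
    "forward_fc",
    "generate_cohort",
    "generate_fd_trace",
]

# Probability that a hub node gains each absent edge, on top of the
# block-model draw.  Kept internal: hub density is part of what "a
# backbone with hubs" means here, not a study condition.
_HUB_EXTRA_EDGE_PROB = 0.3

# Bounded retries for backbone connectivity / subject isolation.
_MAX_RETRIES = 100


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    The defaults are the desk-scale default cohort: N=80 subjects,
    K=60 regions, two-hop structure-to-function mapping
    ``betas=(0.5, 0.5)``, moderate shared non-structural component,
    and an individual component whose regional scale triples from the
    sensorimotor-like to the association-like pole of the axis.
    """

    n_subjects: int = 80
    n_regions: int = 60
    n_modules: int = 4
    p_within: float = 0.45
    p_between: float = 0.10
    hub_frac: float = 0.10
    weight_logmean: float = 0.0
    weight_logsd: float = 0.5
    sc_jitter: float = 0.10        # tau_sc: biological edge-weight jitter (enters FC)
    sc_obs_sd: float = 0.20        # measurement weight noise on observed SC only
    flip_rate: float = 0.02        # measurement edge flips on observed SC only
    betas: tuple[float, ...] = (0.5, 0.5)   # multi-hop SC->FC weights
    group_scale: float = 1.0       # gamma_g
    group_rank: int = 3            # rank of the shared non-structural component
    indiv_scale: float = 0.5       # gamma_i: base regional scale of the individual part
    axis_slope: float = 3.0        # s: relative increase of indiv scale along the axis
    structural_share_lo: float = 0.3   # SC-driven variance share at the sensorimotor pole
    structural_share_hi: float = 0.9   # SC-driven variance share at the association pole
    indiv_betas: tuple[float, ...] = (0.0, 1.0)  # hop weights of that structural part
    noise_sd: float = 0.2          # epsilon
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise InvalidSpecError("n_subjects must be >= 2")
        if self.n_regions < 6:
            raise InvalidSpecError("n_regions must be >= 6")
        if self.n_regions % 2:
            raise InvalidSpecError("n_regions must be even (two hemispheres)")
        if self.n_modules < 1:
            raise InvalidSpecError("n_modules must be >= 1")
        for name in ("p_within", "p_between", "hub_frac", "flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        for name in ("weight_logsd", "sc_jitter", "sc_obs_sd", "group_scale",
                     "indiv_scale", "axis_slope", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if len(self.betas) < 1:
            raise InvalidSpecError("betas must contain at least one coefficient")
        if self.group_rank < 1:
            raise InvalidSpecError("group_rank must be >= 1")
        for name in ("structural_share_lo", "structural_share_hi"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1]")

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["betas"] = list(self.betas)
        d["indiv_betas"] = list(self.indiv_betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["betas"] = tuple(d["betas"])
        d["indiv_betas"] = tuple(d["indiv_betas"])
        return cls(**d)


@dataclass
class SubjectData:
    """One subject's node-aligned connectome pair plus optional raw inputs."""

    subject_id: str
    sc: np.ndarray
    fc: np.ndarray
    ts: np.ndarray | None = None
    counts: np.ndarray | None = None
    fd_runs: list[np.ndarray] | None = None

    def validate(self) -> None:
        for name, m in (("sc", self.sc), ("fc", self.fc)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise InvalidSpecError(f"{name} must be square")
            if not np.allclose(m, m.T, atol=1e-9):
                raise InvalidSpecError(f"{name} must be symmetric")
            if np.any(np.diag(m) != 0):
                raise InvalidSpecError(f"{name} must have zero diagonal")
        if np.any(self.sc < 0):
            raise InvalidSpecError("sc must be nonnegative")


@dataclass
class Cohort:
    """A list of subjects plus region metadata and generation provenance."""

    subjects: list[SubjectData]
    regions: pd.DataFrame
    spec: CohortSpec | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5.0)) / 2
    theta = 2 * np.pi * i / phi
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def build_region_meta(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Region metadata table: hemisphere, axis rank, sphere coords, volume.

    Axis ranks (1..K; 1 = sensorimotor-like pole, K = association-like
    pole) follow a smooth random scalar field on the sphere, mirrored
    across hemispheres, so that the axis is spatially autocorrelated —
    the property the spin test relies on.  The per-region individual
    variance scale ``sigma(r) = indiv_scale * (1 + axis_slope*(rank-1)/(K-1))``
    is then strictly increasing in axis rank whenever axis_slope > 0.
    """
    spec.validate()
    k = spec.n_regions
    half = k // 2
    left = _fibonacci_sphere(half)
    right = left * np.array([-1.0, 1.0, 1.0])  # mirror through x=0 plane
    xyz = np.vstack([left, right])
    hemi = np.array(["L"] * half + ["R"] * half)

    # Smooth field on the left hemisphere, mirrored to the right, so the
    # axis is bilaterally symmetric like its empirical counterpart.
    centers = rng.normal(size=(8, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    amps = rng.normal(size=8)
    ls = 0.8

    def field_at(pts: np.ndarray) -> np.ndarray:
        d2 = np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        return np.exp(-d2 / (2 * ls**2)) @ amps

    vals = np.concatenate([field_at(left), field_at(left)])
    # Average ranks of tied mirrored pairs are broken deterministically
    # by index via stable argsort.
    order = np.argsort(vals, kind="stable")
    axis_rank = np.empty(k, dtype=int)
    axis_rank[order] = np.arange(1, k + 1)

    volumes = rng.lognormal(mean=np.log(100.0), sigma=0.3, size=k)
    return pd.DataFrame({
        "region_id": np.arange(k),
        "hemisphere": hemi,
        "axis_rank": axis_rank,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "volume": volumes,
    })


def region_sigma(regions: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """Per-region scale of the individual FC component.

    sigma(r) = indiv_scale * (1 + axis_slope * (axis_rank_r - 1) / (K - 1)).
    """
    k = len(regions)
    rank = regions["axis_rank"].to_numpy(dtype=float)
    return spec.indiv_scale * (1.0 + spec.axis_slope * (rank - 1.0) / (k - 1.0))


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(adj > 0, directed=False)
    return n_comp == 1


def sample_group_sc(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Group-level structural backbone: SBM with hubs, lognormal weights.

    Edges are drawn from a stochastic block model over ``n_modules``
    contiguous, equal-as-possible modules; the first
    ``ceil(hub_frac * K)`` nodes additionally gain each absent edge
    with a fixed boost probability, creating high-degree hubs.
    Nonzero weights are i.i.d. lognormal.  Resamples (bounded) until
    the graph is connected.
    """
    spec.validate()
    k = spec.n_regions
    module = (np.arange(k) * spec.n_modules) // k
    same = module[:, None] == module[None, :]
    n_hubs = int(np.ceil(spec.hub_frac * k))
    iu = np.triu_indices(k, 1)

    for _ in range(_MAX_RETRIES):
        p = np.where(same, spec.p_within, spec.p_between)
        edges = rng.random((k, k)) < p
        if n_hubs:
            hub = np.zeros(k, dtype=bool)
            hub[:n_hubs] = True
            hub_pair = hub[:, None] | hub[None, :]
            boost = rng.random((k, k)) < _HUB_EXTRA_EDGE_PROB
            edges |= hub_pair & boost
        adj = np.zeros((k, k), dtype=bool)
        adj[iu] = edges[iu]
        adj |= adj.T
        if not _is_connected(adj):
            continue
        w = np.zeros((k, k))
        nz = np.flatnonzero(adj[iu])
        vals = rng.lognormal(mean=spec.weight_logmean, sigma=spec.weight_logsd,
                             size=nz.size)
        rows, cols = iu[0][nz], iu[1][nz]
        w[rows, cols] = vals
        w += w.T
        return w
    raise GenerationError(
        f"could not generate a connected backbone in {_MAX_RETRIES} tries "
        f"(p_within={spec.p_within}, p_between={spec.p_between}, "
        f"hub_frac={spec.hub_frac})")


def sample_subject_sc(group_sc: np.ndarray, spec: CohortSpec,
                      rng: np.random.Generator,
                      jitter_sd: float | None = None,
                      flip_rate: float | None = None) -> np.ndarray:
    """Jittered copy of a backbone SC: weight noise plus rare edge flips.

    Existing edge weights are multiplied by ``exp(N(0, jitter_sd))``
    (drawn in upper-triangle row-major order, one vectorized draw, so
    the stream is reconstructable from the same seed); each existing
    edge is then deleted, and each absent pair created with a fresh
    backbone-scale lognormal weight, independently at ``flip_rate``.
    ``jitter_sd`` / ``flip_rate`` default to the spec's ``sc_jitter`` /
    ``flip_rate``; the cohort generator calls this twice per subject —
    once with the biological jitter (which propagates into FC) and once
    with the measurement noise and flips (observed SC only).
    """
    if jitter_sd is None:
        jitter_sd = spec.sc_jitter
    if flip_rate is None:
        flip_rate = spec.flip_rate
    k = group_sc.shape[0]
    iu = np.triu_indices(k, 1)
    upper = group_sc[iu]
    present = upper > 0

    jitter = rng.normal(0.0, jitter_sd, size=int(present.sum()))
    new_upper = upper.copy()
    new_upper[present] = upper[present] * np.exp(jitter)

    delete = rng.random(int(present.sum())) < flip_rate
    idx_present = np.flatnonzero(present)
    new_upper[idx_present[delete]] = 0.0

    absent = ~present
    create = rng.random(int(absent.sum())) < flip_rate
    idx_absent = np.flatnonzero(absent)
    created = idx_absent[create]
    if created.size:
        new_upper[created] = rng.lognormal(
            mean=spec.weight_logmean, sigma=spec.weight_logsd, size=created.size)

    out = np.zeros_like(group_sc)
    out[iu] = new_upper
    out += out.T
    return out


def _normalized_adjacency_no_loops(sc: np.ndarray) -> np.ndarray:
    """D^{-1/2} SC D^{-1/2} with D = diag(row sums); errors on isolated nodes."""
    strength = sc.sum(axis=1)
    if np.any(strength <= 0):
        bad = np.flatnonzero(strength <= 0)
        raise DegenerateInputError(
            f"isolated node(s) with zero strength: {bad.tolist()}")
    d_inv_sqrt = 1.0 / np.sqrt(strength)
    return sc * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _standardize_offdiag(m: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance over off-diagonal entries; diagonal zeroed."""
    k = m.shape[0]
    mask = ~np.eye(k, dtype=bool)
    vals = m[mask]
    sd = vals.std()
    if sd == 0:
        raise DegenerateInputError("latent FC is constant off-diagonal")
    out = np.zeros_like(m, dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return out


def multi_hop_latent(sc: np.ndarray, betas: Sequence[float]) -> np.ndarray:
    """Standardized polynomial in the normalized adjacency,
    standardize(sum_p beta_p * Abar^p) with Abar = D^{-1/2} SC D^{-1/2}."""
    abar = _normalized_adjacency_no_loops(sc)
    latent = np.zeros_like(abar)
    power = np.eye(sc.shape[0])
    for beta in betas:
        power = power @ abar
        latent += beta * power
    return _standardize_offdiag(latent)


def forward_fc(sc: np.ndarray, spec: CohortSpec, group_component: np.ndarray,
               subject_component: np.ndarray, regions: pd.DataFrame,
               rng: np.random.Generator,
               reference_latent: np.ndarray | None = None) -> np.ndarray:
    """Forward model: FC from multi-hop SC topology plus known components.

    FC = L_i + group_scale * group_component
         + sqrt(sigma_u * sigma_v) * I_i + N(0, noise_sd),

    where ``L_i = standardize(sum_p beta_p * Abar^p)`` is the subject's
    multi-hop structural latent (Abar = D^{-1/2} SC D^{-1/2}) and the
    individual component ``I_i`` mixes, with variance shares
    ``structural_share`` / ``1 - structural_share``,

    * the subject's standardized deviation of the ``indiv_betas``
      multi-hop latent (by default pure two-hop) from the cohort
      backbone's (``reference_latent``) — individual variation that is
      *structurally coupled*, i.e. predictable from that subject's own
      SC, but riding on indirect communication that direct edgewise
      correlation largely misses; and
    * the fresh i.i.d. ``subject_component`` — individual variation
      with no structural counterpart.

    The structural share of that mix itself increases along the axis,
    from ``structural_share_lo`` at the sensorimotor-like pole to
    ``structural_share_hi`` at the association-like pole (region r has
    share w_r; edge (u, v) weights the structural part by
    sqrt(w_u w_v) and the noise part by sqrt((1-w_u)(1-w_v))):
    association-like regions carry not just more individual variance
    but more *structurally coupled* individual variance.

    Without a ``reference_latent`` (or when the subject latent equals
    it, e.g. no SC jitter) the structural part is zero and only the
    noise part remains.  ``reference_latent`` must be the backbone's
    ``multi_hop_latent`` under ``indiv_betas``.
    """
    fc = multi_hop_latent(sc, spec.betas)

    k = sc.shape[0]
    rank = regions["axis_rank"].to_numpy(dtype=float)
    w = spec.structural_share_lo + \
        (spec.structural_share_hi - spec.structural_share_lo) * \
        (rank - 1.0) / (k - 1.0)
    noise_w = np.sqrt(np.outer(1.0 - w, 1.0 - w))
    struct_w = np.sqrt(np.outer(w, w))

    indiv = noise_w * subject_component
    if reference_latent is not None:
        dev = multi_hop_latent(sc, spec.indiv_betas) - reference_latent
        off = ~np.eye(k, dtype=bool)
        if dev[off].std() > 1e-12:
            indiv = indiv + struct_w * _standardize_offdiag(dev)

    sigma = region_sigma(regions, spec)
    scale = np.sqrt(np.outer(sigma, sigma))
    fc = fc + spec.group_scale * group_component + scale * indiv

    k = sc.shape[0]
    iu = np.triu_indices(k, 1)
    noise = np.zeros((k, k))
    noise[iu] = rng.normal(0.0, spec.noise_sd, size=iu[0].size)
    noise += noise.T
    fc = fc + noise

    fc = 0.5 * (fc + fc.T)
    np.fill_diagonal(fc, 0.0)
    return fc


def _symmetric_standard_normal(k: int, rng: np.random.Generator) -> np.ndarray:
    iu = np.triu_indices(k, 1)
    m = np.zeros((k, k))
    m[iu] = rng.standard_normal(iu[0].size)
    m += m.T
    return m


def _low_rank_group_component(k: int, rank: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Shared non-structural FC component: a standardized low-rank
    symmetric matrix, sum_m u_m u_m^T / sqrt(rank), emulating shared
    functional-system structure that is tied to region identity but not
    to the structural backbone."""
    u = rng.standard_normal((k, rank))
    g = (u @ u.T) / np.sqrt(rank)
    np.fill_diagonal(g, 0.0)
    return _standardize_offdiag(g)


def generate_cohort(spec: CohortSpec, with_fd: bool = False,
                    fd_frames: int = 200, fd_runs: int = 4) -> Cohort:
    """Generate a full cohort from one spec; bit-reproducible given its seed.

    One backbone and one shared group component are drawn once; each
    subject gets a jittered SC, a fresh individual component, and an FC
    from :func:`forward_fc`.  With ``with_fd``, each subject also gets
    ``fd_runs`` framewise-displacement traces for QC fixtures.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    (meta_seed, backbone_seed, group_seed, subj_seed, fd_seed) = ss.spawn(5)

    regions = build_region_meta(spec, np.random.default_rng(meta_seed))
    group_sc = sample_group_sc(spec, np.random.default_rng(backbone_seed))
    group_component = _low_rank_group_component(
        spec.n_regions, spec.group_rank, np.random.default_rng(group_seed))
    reference_latent = multi_hop_latent(group_sc, spec.indiv_betas)

    subj_rngs = [np.random.default_rng(s) for s in subj_seed.spawn(spec.n_subjects)]
    fd_rng = np.random.default_rng(fd_seed)

    subjects: list[SubjectData] = []
    for i, rng in enumerate(subj_rngs):
        # Biological SC: weight jitter only — this is what shapes FC.
        for _ in range(_MAX_RETRIES):
            sc_bio = sample_subject_sc(group_sc, spec, rng, flip_rate=0.0)
            if np.all(sc_bio.sum(axis=1) > 0):
                break
        else:
            raise GenerationError(f"subject {i}: could not avoid isolated nodes")
        indiv = _symmetric_standard_normal(spec.n_regions, rng)
        fc = forward_fc(sc_bio, spec, group_component, indiv, regions, rng,
                        reference_latent=reference_latent)
        # Observed SC: measurement weight noise and edge flips on top of
        # the biological SC; this is what downstream estimators see.
        for _ in range(_MAX_RETRIES):
            sc = sample_subject_sc(sc_bio, spec, rng,
                                   jitter_sd=spec.sc_obs_sd)
            if np.all(sc.sum(axis=1) > 0):
                break
        else:
            raise GenerationError(f"subject {i}: could not avoid isolated nodes")
        subj = SubjectData(subject_id=f"sub-{i:03d}", sc=sc, fc=fc)
        if with_fd:
            subj.fd_runs = [
                generate_fd_trace(fd_frames, base_fd=0.05, spike_prob=0.02,
                                  spike_fd=0.3, rng=fd_rng)
                for _ in range(fd_runs)
            ]
        subj.validate()
        subjects.append(subj)

    return Cohort(subjects=subjects, regions=regions, spec=spec,
                  provenance={"spec": spec.to_dict(), "seed": spec.seed,
                              "generator": "sfcoupling.synth.generate_cohort"})


def generate_fd_trace(n_frames: int, base_fd: float, spike_prob: float,
                      spike_fd: float, rng: np.random.Generator) -> np.ndarray:
    """Framewise displacement trace: baseline plus Bernoulli motion spikes.

    Each frame equals ``base_fd``, plus ``spike_fd`` with probability
    ``spike_prob`` (one vectorized uniform draw of length ``n_frames``).
    """
    if n_frames < 1:
        raise InvalidSpecError("n_frames must be >= 1")
    if base_fd < 0 or spike_fd < 0 or not 0 <= spike_prob <= 1:
        raise InvalidSpecError("fd parameters must be nonnegative, "
                               "spike_prob in [0, 1]")
    spikes = rng.random(n_frames) < spike_prob
    return base_fd + spike_fd * spikes.astype(float)
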