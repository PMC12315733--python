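"""Synthetic cohort generator: determinism, invariants, analytic cases."""

import numpy as np
import pandas as pd
import pytest

from sfcoupling import synth
from sfcoupling.errors import (DegenerateInputError, GenerationError,
                               InvalidSpecError)


def toy_regions(k: int) -> pd.DataFrame:
    half = max(1, k // 2)
    return pd.DataFrame({
        "region_id": np.arange(k),
        "hemisphere": ["L"] * half + ["R"] * (k - half),
        "axis_rank": np.arange(1, k + 1),
        "x": [1.0] * k, "y": [0.0] * k, "z": [0.0] * k,
        "volume": [100.0] * k,
    })


class TestRegionMeta:
    def test_sigma_endpoints_follow_axis_formula(self):
        # sigma(r) = gamma_i * (1 + s*(rank-1)/(K-1)):  0.1 .. 0.2 at s=1
        spec = synth.CohortSpec(n_regions=8, indiv_scale=0.1, axis_slope=1.0)
        sigma = synth.region_sigma(toy_regions(8), spec)
        assert sigma[0] == pytest.approx(0.1, abs=1e-15)
        assert sigma[7] == pytest.approx(0.2, abs=1e-15)
        assert np.all(np.diff(sigma) > 0)

    def test_meta_deterministic_given_seed(self):
        spec = synth.CohortSpec(n_regions=30)
        a = synth.build_region_meta(spec, np.random.default_rng(3))
        b = synth.build_region_meta(spec, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)

    def test_sphere_coords_unit_norm_and_ranks_permutation(self):
        spec = synth.CohortSpec(n_regions=60)
        meta = synth.build_region_meta(spec, np.random.default_rng(0))
        norms = np.linalg.norm(meta[["x", "y", "z"]].to_numpy(), axis=1)
        assert np.all(np.abs(norms - 1) < 1e-9)
        assert sorted(meta["axis_rank"]) == list(range(1, 61))
        assert (meta["hemisphere"] == "L").sum() == 30
        assert np.all(meta["volume"] > 0)

    def test_odd_region_count_rejected(self):
        with pytest.raises(InvalidSpecError):
            synth.CohortSpec(n_regions=7).validate()


class TestGroupSc:
    def test_full_probabilities_give_complete_graph(self):
        spec = synth.CohortSpec(n_regions=12, p_within=1.0, p_between=1.0,
                                hub_frac=0.0)
        sc = synth.sample_group_sc(spec, np.random.default_rng(0))
        off = ~np.eye(12, dtype=bool)
        assert np.all(sc[off] > 0)
        assert np.all(np.diag(sc) == 0)
        assert np.array_equal(sc, sc.T)

    def test_empty_probabilities_fail_connectivity(self):
        spec = synth.CohortSpec(n_regions=12, p_within=0.0, p_between=0.0,
                                hub_frac=0.0)
        with pytest.raises(GenerationError):
            synth.sample_group_sc(spec, np.random.default_rng(0))

    def test_planted_partition_beats_random_partition_modularity(self):
        # brute-force Newman modularity of the binarized graph
        def modularity(adj, labels):
            a = (adj > 0).astype(float)
            two_m = a.sum()
            deg = a.sum(axis=1)
            q = 0.0
            for i in range(a.shape[0]):
                for j in range(a.shape[0]):
                    if labels[i] == labels[j]:
                        q += a[i, j] - deg[i] * deg[j] / two_m
            return q / two_m

        spec = synth.CohortSpec(n_regions=20, n_modules=4, p_within=0.8,
                                p_between=0.05, hub_frac=0.0)
        sc = synth.sample_group_sc(spec, np.random.default_rng(5))
        planted = (np.arange(20) * 4) // 20
        rng = np.random.default_rng(11)
        random_part = rng.permutation(planted)
        assert modularity(sc, planted) > modularity(sc, random_part)


class TestSubjectSc:
    def test_zero_jitter_zero_flips_is_identity(self):
        spec = synth.CohortSpec(n_regions=12, p_within=0.8, sc_jitter=0.0,
                                flip_rate=0.0)
        group = synth.sample_group_sc(spec, np.random.default_rng(0))
        subj = synth.sample_subject_sc(group, spec, np.random.default_rng(1))
        assert np.array_equal(subj, group)

    def test_zero_flip_rate_preserves_support(self):
        spec = synth.CohortSpec(n_regions=14, sc_jitter=0.3, flip_rate=0.0)
        group = synth.sample_group_sc(spec, np.random.default_rng(2))
        subj = synth.sample_subject_sc(group, spec, np.random.default_rng(3))
        assert np.array_equal(subj > 0, group > 0)

    def test_jitter_matches_regenerated_normal_stream(self):
        # the multiplicative jitter is one vectorized normal draw in
        # upper-triangle order, so it can be reconstructed from the seed
        spec = synth.CohortSpec(n_regions=10, p_within=0.9, sc_jitter=0.1,
                                flip_rate=0.0)
        group = synth.sample_group_sc(spec, np.random.default_rng(4))
        subj = synth.sample_subject_sc(group, spec, np.random.default_rng(99))
        iu = np.triu_indices(10, 1)
        present = group[iu] > 0
        expected = np.exp(
            np.random.default_rng(99).normal(0.0, 0.1, int(present.sum())))
        ratio = subj[iu][present] / group[iu][present]
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)


class TestForwardFc:
    def test_one_hop_identity_case(self):
        # betas=(1,), no group/individual/noise -> FC is standardized Abar
        spec = synth.CohortSpec(n_regions=6, betas=(1.0,), group_scale=0.0,
                                indiv_scale=0.0, noise_sd=0.0)
        sc = np.zeros((6, 6))
        for i, j, w in [(0, 1, 1.0), (1, 2, 2.0), (2, 3, 0.5), (3, 4, 1.5),
                        (4, 5, 1.0), (0, 5, 2.0)]:
            sc[i, j] = sc[j, i] = w
        fc = synth.forward_fc(sc, spec, np.zeros((6, 6)), np.zeros((6, 6)),
                              toy_regions(6), np.random.default_rng(0))
        d = sc.sum(axis=1)
        abar = sc / np.sqrt(np.outer(d, d))
        off = ~np.eye(6, dtype=bool)
        expect = np.zeros((6, 6))
        expect[off] = (abar[off] - abar[off].mean()) / abar[off].std()
        np.testing.assert_allclose(fc, expect, atol=1e-12)

    def test_two_hop_path_graph_hand_computed(self):
        # path 0-1-2: Abar^2 has its largest off-diagonal at (0, 2)
        spec = synth.CohortSpec(betas=(0.0, 1.0), group_scale=0.0,
                                indiv_scale=0.0, noise_sd=0.0)
        sc = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        fc = synth.forward_fc(sc, spec, np.zeros((3, 3)), np.zeros((3, 3)),
                              toy_regions(3), np.random.default_rng(0))
        # Abar = [[0, 1/sqrt2, 0], [1/sqrt2, 0, 1/sqrt2], [0, 1/sqrt2, 0]]
        # Abar^2 off-diagonals: (0,1)=0, (1,2)=0, (0,2)=1/2
        off = ~np.eye(3, dtype=bool)
        assert fc[0, 2] == np.max(fc[off])
        assert fc[0, 1] == fc[1, 2]

    def test_deterministic_without_noise(self):
        spec = synth.CohortSpec(n_regions=8, noise_sd=0.0)
        sc = synth.sample_group_sc(
            synth.CohortSpec(n_regions=8, p_within=0.9), np.random.default_rng(1))
        g = np.random.default_rng(2).normal(size=(8, 8))
        g = 0.5 * (g + g.T); np.fill_diagonal(g, 0)
        e = np.random.default_rng(3).normal(size=(8, 8))
        e = 0.5 * (e + e.T); np.fill_diagonal(e, 0)
        a = synth.forward_fc(sc, spec, g, e, toy_regions(8),
                             np.random.default_rng(0))
        b = synth.forward_fc(sc, spec, g, e, toy_regions(8),
                             np.random.default_rng(0))
        assert np.array_equal(a, b)

    def test_isolated_node_rejected(self):
        spec = synth.CohortSpec(n_regions=6)
        sc = np.zeros((6, 6))
        sc[0, 1] = sc[1, 0] = 1.0
        sc[2, 3] = sc[3, 2] = 1.0
        sc[3, 4] = sc[4, 3] = 1.0  # node 5 isolated
        with pytest.raises(DegenerateInputError):
            synth.forward_fc(sc, spec, np.zeros((6, 6)), np.zeros((6, 6)),
                             toy_regions(6), np.random.default_rng(0))


class TestGenerateCohort:
    def test_no_individual_sources_gives_identical_fc(self):
        spec = synth.CohortSpec(n_subjects=2, n_regions=16, sc_jitter=0.0,
                                flip_rate=0.0, sc_obs_sd=0.0, indiv_scale=0.0,
                                noise_sd=0.0, seed=0)
        cohort = synth.generate_cohort(spec)
        np.testing.assert_array_equal(cohort.subjects[0].fc,
                                      cohort.subjects[1].fc)
        np.testing.assert_array_equal(cohort.subjects[0].sc,
                                      cohort.subjects[1].sc)

    def test_bit_identical_given_seed(self):
        spec = synth.CohortSpec(n_subjects=6, n_regions=20, seed=42)
        a = synth.generate_cohort(spec)
        b = synth.generate_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.sc, sb.sc)
            assert np.array_equal(sa.fc, sb.fc)
        pd.testing.assert_frame_equal(a.regions, b.regions)

    def test_individual_scale_lowers_subject_to_mean_fc_similarity(self):
        # brute force: mean over subjects of corr(subject FC, mean FC)
        def mean_similarity(spec):
            cohort = synth.generate_cohort(spec)
            fcs = np.stack([s.fc for s in cohort.subjects])
            mean_fc = fcs.mean(axis=0)
            iu = np.triu_indices(spec.n_regions, 1)
            return np.mean([np.corrcoef(f[iu], mean_fc[iu])[0, 1] for f in fcs])

        base = synth.CohortSpec(n_subjects=10, n_regions=20, seed=9)
        assert mean_similarity(base.replace(indiv_scale=0.5)) < \
            mean_similarity(base.replace(indiv_scale=0.0))

    def test_emitted_matrices_satisfy_subject_invariants(self, small_cohort):
        for s in small_cohort.subjects:
            assert np.array_equal(s.sc, s.sc.T)
            assert np.array_equal(s.fc, s.fc.T)
            assert np.all(np.diag(s.sc) == 0)
            assert np.all(np.diag(s.fc) == 0)
            assert np.all(s.sc >= 0)


class TestFdTrace:
    def test_no_spikes_constant(self):
        fd = synth.generate_fd_trace(50, 0.05, 0.0, 0.5,
                                     np.random.default_rng(0))
        assert np.all(fd == 0.05)

    def test_all_spikes_exceed_spike_level(self):
        fd = synth.generate_fd_trace(50, 0.05, 1.0, 0.5,
                                     np.random.default_rng(0))
        assert np.all(fd >= 0.5)

    def test_spike_count_matches_regenerated_stream(self):
        fd = synth.generate_fd_trace(100, 0.05, 0.3, 0.5,
                                     np.random.default_rng(17))
        expected = int(np.sum(np.random.default_rng(17).random(100) < 0.3))
        assert int(np.sum(fd > 0.05)) == expected

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidSpecError):
            synth.generate_fd_trace(0, 0.05, 0.1, 0.5, rng)
        with pytest.raises(InvalidSpecError):
            synth.generate_fd_trace(10, -0.05, 0.1, 0.5, rng)
        with pytest.raises(InvalidSpecError):
            synth.generate_fd_trace(10, 0.05, 1.5, 0.5, rng)
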