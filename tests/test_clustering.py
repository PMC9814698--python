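"""Pooled RMSD clustering: seeding, medoids, composition, robustness."""

import numpy as np
import pytest

from peptraj.clustering import (
    PooledConformers,
    cluster_khybrid,
    composition,
    enrichment_test,
    medoid_structures,
    pool,
    subset_robustness,
)
from peptraj.geometry import pairwise_rmsd_matrix
from peptraj.synthetic import (
    EnsembleSpec,
    H3K36_SEQUENCE,
    SSK36_SEQUENCE,
    generate_two_state_ensemble,
)


def two_condition_ensembles(frac_a=0.7, frac_b=0.3, n_reps=4, n_frames=80,
                            noise=0.3, seed=0, dwell=5.0):
    spec_a = EnsembleSpec.from_stationary(
        frac_a, mean_dwell_frames=dwell, n_replicates=n_reps,
        n_frames_per_replicate=n_frames, coordinate_noise_sd=noise,
        seed=seed + 1, condition_label="ssK36", sequence=SSK36_SEQUENCE,
    )
    spec_b = EnsembleSpec.from_stationary(
        frac_b, mean_dwell_frames=dwell, n_replicates=n_reps,
        n_frames_per_replicate=n_frames, coordinate_noise_sd=noise,
        seed=seed + 2, condition_label="H3K36", sequence=H3K36_SEQUENCE,
    )
    ta, la = generate_two_state_ensemble(spec_a)
    tb, lb = generate_two_state_ensemble(spec_b)
    return ta + tb, la + lb


class TestPool:
    def test_bookkeeping_counts_and_provenance(self):
        trajs, _ = two_condition_ensembles(n_reps=2, n_frames=10)
        pooled = pool(trajs)
        assert len(pooled) == 40
        assert pooled.coords.shape == (40, 45, 3)
        assert pooled.provenance[0] == ("ssK36", 0, 0)
        assert pooled.provenance[-1] == ("H3K36", 1, 9)

    def test_input_order_preserved_within_trajectories(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=5)
        pooled = pool(trajs)
        frames = [p[2] for p in pooled.provenance]
        assert frames == [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]

    def test_study_scale_design_yields_350000_conformers(self):
        # 2 conditions x 50 replicates x (70 ns / 20 ps) frames, by arithmetic
        n_frames = int(70_000 / 20)
        assert 2 * 50 * n_frames == 350_000

    def test_heterogeneous_layout_rejected(self, peptide_templates,
                                           complex_topology):
        from peptraj.trajectory import Frame, Trajectory

        topology, hairpin, _ = peptide_templates
        t1 = Trajectory(topology=topology, frames=[hairpin])
        coords = np.zeros((len(complex_topology), 3))
        t2 = Trajectory(topology=complex_topology, frames=[Frame(coords)])
        with pytest.raises(ValueError, match="layout"):
            pool([t1, t2])


class TestKHybrid:
    def test_separates_planted_templates(self):
        trajs, labels = two_condition_ensembles(noise=0.3)
        pooled = pool(trajs)
        model = cluster_khybrid(pooled, k=2, seed=0)
        truth = np.concatenate(labels)
        agreement = np.mean((model.assignments == 0) == truth)
        assert max(agreement, 1 - agreement) >= 0.99

    def test_k_equals_pool_size_gives_singletons(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=4)
        pooled = pool(trajs)
        model = cluster_khybrid(pooled, k=len(pooled), seed=0)
        assert len(set(model.assignments.tolist())) == len(pooled)
        mat = pairwise_rmsd_matrix(pooled.coords)
        for j in range(model.k):
            members = model.cluster_members(j)
            assert len(members) == 1

    def test_duplicated_pool_partitions_duplicates_identically(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=20)
        pooled = pool(trajs)
        doubled = PooledConformers(
            coords=np.concatenate([pooled.coords, pooled.coords]),
            provenance=pooled.provenance + pooled.provenance,
        )
        model = cluster_khybrid(doubled, k=2, seed=0)
        n = len(pooled)
        assert np.array_equal(model.assignments[:n], model.assignments[n:])

    def test_deterministic_given_seed_and_pool_order_invariant(self):
        trajs, _ = two_condition_ensembles()
        pooled_ab = pool(trajs)
        pooled_ba = pool(trajs[len(trajs) // 2:] + trajs[: len(trajs) // 2])
        m1 = cluster_khybrid(pooled_ab, k=2, seed=3)
        m2 = cluster_khybrid(pooled_ab, k=2, seed=3)
        assert np.array_equal(m1.assignments, m2.assignments)
        # pooling order: same partition up to relabelling
        m3 = cluster_khybrid(pooled_ba, k=2, seed=3)
        by_key_ab = dict(zip(pooled_ab.provenance, m1.assignments))
        by_key_ba = dict(zip(pooled_ba.provenance, m3.assignments))
        flips = {(by_key_ab[k], by_key_ba[k]) for k in by_key_ab}
        assert len(flips) <= 2  # a permutation of cluster labels

    def test_invalid_k_rejected(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=3)
        pooled = pool(trajs)
        with pytest.raises(ValueError):
            cluster_khybrid(pooled, k=1)
        with pytest.raises(ValueError):
            cluster_khybrid(pooled, k=len(pooled) + 1)

    def test_labels_ordered_by_descending_size(self):
        trajs, _ = two_condition_ensembles(frac_a=0.8, frac_b=0.8)
        model = cluster_khybrid(pool(trajs), k=2, seed=1)
        sizes = np.bincount(model.assignments)
        assert sizes[0] >= sizes[1]


class TestMedoids:
    def test_singleton_cluster_returns_its_member(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=4)
        pooled = pool(trajs)
        model = cluster_khybrid(pooled, k=len(pooled), seed=0)
        structures = medoid_structures(model)
        for j, structure in enumerate(structures):
            members = model.cluster_members(j)
            assert np.allclose(structure, pooled.coords[members[0]])

    def test_matches_exhaustive_search(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=25, frac_a=0.5,
                                           frac_b=0.5)
        pooled = pool(trajs)
        model = cluster_khybrid(pooled, k=2, seed=0)
        medoid_structures(model)  # refreshes medoid indices exactly
        mat = pairwise_rmsd_matrix(pooled.coords)
        for j in range(model.k):
            members = model.cluster_members(j)
            sums = mat[np.ix_(members, members)].sum(axis=1)
            best = members[np.argmin(sums)]
            assert model.medoid_indices[j] == best

    def test_tie_break_lowest_pooled_index(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=3)
        pooled = pool(trajs)
        # all-duplicate cluster: every member is an equally good medoid
        dup = PooledConformers(
            coords=np.repeat(pooled.coords[:1], 6, axis=0),
            provenance=[("c", 0, i) for i in range(6)],
        )
        from peptraj.clustering import _best_medoid

        assert _best_medoid(np.arange(6), dup.coords) == 0

    def test_medoids_are_members(self):
        trajs, _ = two_condition_ensembles()
        pooled = pool(trajs)
        model = cluster_khybrid(pooled, k=3, seed=2)
        for j in range(3):
            assert model.assignments[model.medoid_indices[j]] == j


class TestComposition:
    def test_single_condition_is_everywhere_100(self):
        trajs, _ = two_condition_ensembles()
        only_a = [t for t in trajs if t.condition_label == "ssK36"]
        model = cluster_khybrid(pool(only_a), k=2, seed=0)
        comp = composition(model)
        for j in range(2):
            assert comp.percentage(j, "ssK36") == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        trajs, _ = two_condition_ensembles()
        comp = composition(cluster_khybrid(pool(trajs), k=3, seed=0))
        for j in range(3):
            if comp.counts[j]:
                assert sum(comp.percentages[j].values()) == pytest.approx(100.0)

    def test_recovers_planted_condition_mixing(self):
        # both conditions contribute equal frame totals; the hairpin cluster
        # share of condition A approaches fracA/(fracA+fracB)
        frac_a, frac_b = 0.7, 0.3
        trajs, labels = two_condition_ensembles(
            frac_a=frac_a, frac_b=frac_b, n_reps=6, n_frames=250, seed=5, dwell=4.0
        )
        model = cluster_khybrid(pool(trajs), k=2, seed=0)
        comp = composition(model)
        truth = np.concatenate(labels)
        # identify the hairpin cluster via agreement with the planted labels
        hairpin_cluster = int(
            np.mean(truth[model.assignments == 0]) < np.mean(
                truth[model.assignments == 1])
        )
        expected = 100.0 * frac_a / (frac_a + frac_b)
        # delta-method SE of X/(X+Y) with Markov-inflated binomial variances
        n_per = 6 * 250

        def inflated_var(pi, dwell):
            leave_h = 1.0 / dwell
            leave_e = leave_h * pi / (1.0 - pi)
            rho = 1.0 - leave_h - leave_e
            return n_per * pi * (1 - pi) * (1 + rho) / (1 - rho)

        ex, ey = n_per * frac_a, n_per * frac_b
        total = ex + ey
        var = (ey / total**2) ** 2 * inflated_var(frac_a, 4.0) + (
            ex / total**2
        ) ** 2 * inflated_var(frac_b, 4.0)
        se = 100.0 * np.sqrt(var)
        observed = comp.percentage(hairpin_cluster, "ssK36")
        assert abs(observed - expected) <= 3 * se


class TestSubsetRobustness:
    def test_full_fraction_reproduces_model(self):
        trajs, _ = two_condition_ensembles(n_reps=2, n_frames=40)
        pooled = pool(trajs)
        report = subset_robustness(pooled, k=2, fractions=(1.0,), n_repeats=1, seed=0)
        assert len(report) == 1
        assert report[0].medoid_rmsd == pytest.approx([0.0, 0.0], abs=1e-5)
        for deltas in report[0].composition_delta.values():
            for value in deltas.values():
                assert value == pytest.approx(0.0)

    def test_ten_percent_subset_composition_close_on_separated_data(self):
        # the pool is sized so that hypergeometric subsampling error at 10%
        # stays within the 5-point bound: a 10% draw holds ~900 conformers of
        # each planted state, giving sigma ~ 1.6 points per composition cell
        trajs, _ = two_condition_ensembles(n_reps=10, n_frames=900, seed=9,
                                           dwell=3.0)
        pooled = pool(trajs)
        report = subset_robustness(pooled, k=2, fractions=(0.1,), n_repeats=2, seed=1)
        assert report
        for entry in report:
            for deltas in entry.composition_delta.values():
                for value in deltas.values():
                    assert abs(value) <= 5.0

    def test_subsets_smaller_than_k_skipped(self):
        trajs, _ = two_condition_ensembles(n_reps=1, n_frames=5)
        pooled = pool(trajs)
        report = subset_robustness(pooled, k=5, fractions=(0.1,), n_repeats=2, seed=0)
        assert report == []

    def test_seeded_reproducibility(self):
        trajs, _ = two_condition_ensembles(n_reps=2, n_frames=50)
        pooled = pool(trajs)
        a = subset_robustness(pooled, k=2, fractions=(0.5,), n_repeats=2, seed=4)
        b = subset_robustness(pooled, k=2, fractions=(0.5,), n_repeats=2, seed=4)
        assert [e.medoid_rmsd for e in a] == [e.medoid_rmsd for e in b]


class TestEnrichment:
    def test_identical_compositions(self):
        result = enrichment_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (result.statistic, result.p_value) == (0.0, 1.0)

    def test_separated_groups_highly_significant(self):
        jitter = [1e-4, -1e-4, 0.0]
        a = [0.7 + j for j in jitter]
        b = [0.3 + j for j in jitter]
        assert enrichment_test(a, b).p_value < 0.001

    def test_symmetric_under_label_swap(self, rng):
        a = rng.uniform(0.4, 0.8, size=4)
        b = rng.uniform(0.2, 0.6, size=4)
        assert enrichment_test(a, b).p_value == pytest.approx(
            enrichment_test(b, a).p_value
        )


def test_landmark_mode_flags_and_approximates():
    trajs, labels = two_condition_ensembles(n_reps=4, n_frames=150, seed=7)
    pooled = pool(trajs)
    model = cluster_khybrid(pooled, k=2, seed=0, max_exact=500, n_landmarks=200)
    assert model.landmark_approximation
    truth = np.concatenate(labels)
    agreement = np.mean((model.assignments == 0) == truth)
    assert max(agreement, 1 - agreement) >= 0.98
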