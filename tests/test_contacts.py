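"""Residue contact maps, frequency profiles and difference filtering."""

import itertools

import numpy as np
import pytest

from peptraj.contacts import (
    ContactCriteria,
    conditional_frequency,
    contact_frequency,
    difference_profile,
    distance_to_reference,
    frame_contacts,
    pooled_frequency,
)
from peptraj.detectors import ts_series
from peptraj.synthetic import ComplexSpec, generate_complex_ensemble
from peptraj.trajectory import Frame, Trajectory


def brute_force_contacts(frame, topology, criteria):
    """O(n^2) all-pairs oracle for residue contacts."""
    residues = {}
    for i, atom in enumerate(topology.atoms):
        if criteria.heavy_only and not atom.is_heavy:
            continue
        residues.setdefault((atom.chain_id, atom.residue_seq), []).append(i)
    out = set()
    for (ra, ia), (rb, ib) in itertools.combinations(residues.items(), 2):
        if ra[0] == rb[0] and abs(ra[1] - rb[1]) <= criteria.neighbor_exclusion:
            continue
        dmin = min(
            np.linalg.norm(frame.coordinates[x] - frame.coordinates[y])
            for x in ia for y in ib
        )
        if dmin < criteria.cutoff:
            out.add(frozenset((ra, rb)))
    return out


def shifted_frame(topology, base_coords, moves):
    coords = base_coords.copy()
    for (chain, res, name), xyz in moves.items():
        coords[topology.index_of(res, name, chain)] = xyz
    return Frame(coordinates=coords)


@pytest.fixture(scope="module")
def complex_frame():
    spec = ComplexSpec(n_replicates=1, n_frames=1, seed=0, backbone_noise_sd=0.0)
    [traj], _ = generate_complex_ensemble(spec)
    return traj.topology, traj.frames[0].coordinates


class TestFrameContacts:
    @staticmethod
    def _plant_near_residue29(topology, base, distance):
        """Move an enzyme atom so the closest residue-29 heavy atom is at
        exactly ``distance`` (checked, so the strictness test is exact)."""
        res29 = [i for i, a in enumerate(topology.atoms)
                 if a.chain_id == "P" and a.residue_seq == 29 and a.is_heavy]
        target = base[topology.index_of(29, "C", "P")] + np.array([0.0, -distance, 0.0])
        dmin = min(np.linalg.norm(base[i] - target) for i in res29)
        assert dmin == pytest.approx(distance, abs=1e-9)
        return shifted_frame(topology, base, {("E", 1602, "CG"): target})

    def test_pair_just_below_cutoff_counts(self, complex_frame):
        topology, base = complex_frame
        frame = self._plant_near_residue29(topology, base, 4.4)
        assert frozenset((("P", 29), ("E", 1602))) in frame_contacts(frame, topology)

    def test_pair_at_cutoff_excluded(self, complex_frame):
        topology, base = complex_frame
        frame = self._plant_near_residue29(topology, base, 4.5)
        pair = frozenset((("P", 29), ("E", 1602)))
        assert pair not in frame_contacts(frame, topology)

    def test_sequence_neighbours_excluded_within_chain(self, peptide_templates):
        # hairpin backbone: residues i and i+2 CA sit 2 steps (~7 A) apart,
        # but their N/C atoms come within 4.5 A - still excluded
        topology, hairpin, _ = peptide_templates
        contacts = frame_contacts(hairpin, topology)
        for (c1, r1), (c2, r2) in (tuple(sorted(p)) for p in contacts):
            assert abs(r1 - r2) > 2

    def test_cross_chain_pairs_never_excluded(self, complex_frame):
        topology, base = complex_frame
        # lysine NZ sits ~2.5 A from the cofactor methyl region in TS frames;
        # here plant an explicit 3 A peptide-enzyme contact
        ca36 = base[topology.index_of(36, "CA", "P")]
        frame = shifted_frame(
            topology, base, {("E", 1695, "CG"): ca36 + np.array([3.0, 0.0, 0.0])}
        )
        assert frozenset((("P", 36), ("E", 1695))) in frame_contacts(frame, topology)

    def test_matches_brute_force_oracle(self, rng, complex_frame):
        topology, base = complex_frame
        criteria = ContactCriteria()
        for _ in range(5):
            coords = base + rng.normal(0.0, 4.0, size=base.shape)
            frame = Frame(coordinates=coords)
            assert frame_contacts(frame, topology, criteria) == brute_force_contacts(
                frame, topology, criteria
            )

    def test_monotone_in_cutoff(self, rng, complex_frame):
        topology, base = complex_frame
        frame = Frame(coordinates=base + rng.normal(0.0, 3.0, size=base.shape))
        tight = frame_contacts(frame, topology, ContactCriteria(cutoff=4.5))
        loose = frame_contacts(frame, topology, ContactCriteria(cutoff=6.0))
        assert tight <= loose


class TestContactFrequency:
    def _trajectory_with_square_wave(self, on_fraction, n_frames=10):
        spec = ComplexSpec(n_replicates=1, n_frames=1, seed=0, backbone_noise_sd=0.0)
        [traj], _ = generate_complex_ensemble(spec)
        topology = traj.topology
        base = traj.frames[0].coordinates
        ca30 = base[topology.index_of(30, "CA", "P")]
        n_on = int(round(on_fraction * n_frames))
        frames = []
        for t in range(n_frames):
            moves = {}
            if t < n_on:
                moves[("E", 1609, "CG")] = ca30 + np.array([3.0, 0.0, 0.0])
            frames.append(shifted_frame(topology, base, moves))
            frames[-1].frame_index = t
        return Trajectory(topology=topology, frames=frames), frozenset(
            (("P", 30), ("E", 1609))
        )

    def test_square_wave_fraction_exact(self):
        traj, pair = self._trajectory_with_square_wave(0.3)
        profile = contact_frequency(traj)
        assert profile.frequencies[pair] == pytest.approx(0.3)

    def test_permanent_contact_is_one(self):
        traj, pair = self._trajectory_with_square_wave(1.0)
        assert contact_frequency(traj).frequencies[pair] == 1.0

    def test_frequency_invariant_under_frame_reordering(self):
        traj, pair = self._trajectory_with_square_wave(0.4)
        reordered = Trajectory(topology=traj.topology, frames=traj.frames[::-1])
        assert contact_frequency(reordered).frequencies[pair] == pytest.approx(
            contact_frequency(traj).frequencies[pair]
        )

    def test_no_contacts_gives_empty_profile(self, peptide_templates):
        topology, _, extended = peptide_templates
        traj = Trajectory(topology=topology, frames=[extended])
        profile = contact_frequency(traj)
        assert profile.frequencies == {}


class TestDifferenceProfile:
    def test_identical_profiles_empty_at_any_threshold(self, complex_frame):
        topology, base = complex_frame
        traj = Trajectory(topology=topology, frames=[Frame(base)])
        profile = contact_frequency(traj)
        assert len(difference_profile(profile, profile, 0.01)) == 0

    def test_threshold_rule_keeps_only_large_changes(self):
        spec_a = ComplexSpec(
            n_replicates=1, n_frames=200, seed=5,
            contact_plan=(((30, 1609), 0.9), ((40, 1636), 0.55)),
        )
        spec_b = ComplexSpec(
            n_replicates=1, n_frames=200, seed=6,
            contact_plan=(((30, 1609), 0.2), ((40, 1636), 0.45)),
        )
        [ta], _ = generate_complex_ensemble(spec_a)
        [tb], _ = generate_complex_ensemble(spec_b)
        diff = difference_profile(contact_frequency(ta), contact_frequency(tb), 0.35)
        pair_big = frozenset((("P", 30), ("E", 1609)))
        pair_small = frozenset((("P", 40), ("E", 1636)))
        assert pair_big in diff.differences
        assert diff.differences[pair_big] > 0
        assert pair_small not in diff.differences

    def test_antisymmetric_under_argument_swap(self):
        spec = ComplexSpec(n_replicates=1, n_frames=100, seed=7,
                           contact_plan=(((31, 1674), 0.8),))
        [ta], _ = generate_complex_ensemble(spec)
        spec_b = ComplexSpec(n_replicates=1, n_frames=100, seed=8)
        [tb], _ = generate_complex_ensemble(spec_b)
        fwd = difference_profile(contact_frequency(ta), contact_frequency(tb), 0.35)
        rev = difference_profile(contact_frequency(tb), contact_frequency(ta), 0.35)
        assert set(fwd.differences) == set(rev.differences)
        for pair, delta in fwd.differences.items():
            assert rev.differences[pair] == pytest.approx(-delta)


class TestConditionalFrequency:
    def test_full_mask_equals_unconditional(self):
        spec = ComplexSpec(n_replicates=1, n_frames=50, ts_occupancy=0.3, seed=9)
        [traj], _ = generate_complex_ensemble(spec)
        full = contact_frequency(traj)
        masked = conditional_frequency(traj, np.ones(50, dtype=bool))
        assert masked.frequencies == full.frequencies

    def test_ts_only_contacts_saturate_conditional_profile(self):
        spec = ComplexSpec(
            n_replicates=1, n_frames=400, ts_occupancy=0.3, mean_dwell_frames=5,
            seed=10, ts_contact_pairs=((39, 1666),),
        )
        [traj], [labels] = generate_complex_ensemble(spec)
        assert np.array_equal(ts_series(traj), labels)
        pair = frozenset((("P", 39), ("E", 1666)))
        conditional = conditional_frequency(traj, labels)
        unconditional = contact_frequency(traj)
        assert conditional.frequencies[pair] == pytest.approx(1.0)
        assert unconditional.frequencies[pair] < 1.0

    def test_single_frame_mask_gives_binary_profile(self):
        spec = ComplexSpec(n_replicates=1, n_frames=20, ts_occupancy=0.5, seed=11)
        [traj], _ = generate_complex_ensemble(spec)
        mask = np.zeros(20, dtype=bool)
        mask[3] = True
        profile = conditional_frequency(traj, mask)
        assert all(v in (0.0, 1.0) for v in profile.frequencies.values())

    def test_empty_mask_rejected(self):
        spec = ComplexSpec(n_replicates=1, n_frames=5, seed=12)
        [traj], _ = generate_complex_ensemble(spec)
        with pytest.raises(ValueError):
            conditional_frequency(traj, np.zeros(5, dtype=bool))


class TestDistanceToReference:
    def test_static_distance_recovered(self, complex_frame):
        topology, base = complex_frame
        traj = Trajectory(topology=topology, frames=[Frame(base)])
        distances = distance_to_reference(traj)
        ref = base[topology.index_of(1625, "CA", "E")]
        for res_seq, value in distances.items():
            idx = [topology.index_of(res_seq, name, "P") for name in ("N", "CA", "C")]
            expected = np.linalg.norm(base[idx].mean(axis=0) - ref)
            assert value == pytest.approx(expected)

    def test_two_frame_mean(self, complex_frame):
        topology, base = complex_frame
        shifted = base.copy()
        pep = [i for i, a in enumerate(topology.atoms) if a.chain_id == "P"]
        shifted[pep] += np.array([0.0, 4.0, 0.0])
        traj1 = Trajectory(topology=topology, frames=[Frame(base)])
        traj2 = Trajectory(topology=topology, frames=[Frame(shifted)])
        both = Trajectory(topology=topology, frames=[Frame(base), Frame(shifted)])
        d1 = distance_to_reference(traj1)
        d2 = distance_to_reference(traj2)
        dm = distance_to_reference(both)
        # per-frame distances averaged (not distances of averaged frames)
        for res in dm:
            assert dm[res] == pytest.approx((d1[res] + d2[res]) / 2.0)

    def test_matches_brute_force_average(self, rng, complex_frame):
        topology, base = complex_frame
        frames = [Frame(base + rng.normal(0, 1.0, size=base.shape)) for _ in range(4)]
        traj = Trajectory(topology=topology, frames=frames)
        result = distance_to_reference(traj)
        ref_idx = topology.index_of(1625, "CA", "E")
        for res_seq, value in result.items():
            idx = [topology.index_of(res_seq, name, "P") for name in ("N", "CA", "C")]
            expected = np.mean([
                np.linalg.norm(f.coordinates[idx].mean(axis=0)
                               - f.coordinates[ref_idx])
                for f in frames
            ])
            assert value == pytest.approx(expected)

    def test_empty_selection_rejected(self, complex_frame):
        topology, base = complex_frame
        traj = Trajectory(topology=topology, frames=[Frame(base)])
        with pytest.raises(ValueError):
            distance_to_reference(traj, reference_selection="chain E and name XX")


def test_pooled_frequency_weights_by_frames():
    spec = ComplexSpec(n_replicates=3, n_frames=60, ts_occupancy=0.0, seed=13,
                       contact_plan=(((30, 1609), 0.5),))
    trajs, _ = generate_complex_ensemble(spec)
    pooled = pooled_frequency(trajs)
    pair = frozenset((("P", 30), ("E", 1609)))
    per_traj = [contact_frequency(t).frequencies.get(pair, 0.0) for t in trajs]
    assert pooled.frequencies[pair] == pytest.approx(np.mean(per_traj))
    assert pooled.n_frames == 180
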