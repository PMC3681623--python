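"""Contact tables, interaction classes, occupancy, symmetry and RMSD."""

import numpy as np
import pytest

from floodsite.cavity_pathway import RegionSpec, Sphere
from floodsite.contacts_occupancy import (
    InteractionClass,
    backbone_rmsd_series,
    classify_interaction,
    residue_contact_frequencies,
    site_occupancy_series,
    subunit_symmetry_table,
)
from floodsite.core_model import Frame, Topology, Trajectory, minimum_image


def make_system(ligand_xyz, protein_residues, box=(40.0, 40.0, 40.0), n_frames=1):
    """One ligand molecule plus protein residues at fixed positions.

    ``ligand_xyz``: (n_lig_atoms, 3) or (n_frames, n_lig_atoms, 3);
    ``protein_residues``: list of (subunit, resseq, positions (m, 3)).
    """
    ligand_xyz = np.asarray(ligand_xyz, dtype=float)
    if ligand_xyz.ndim == 2:
        ligand_xyz = np.repeat(ligand_xyz[None], n_frames, axis=0)
    n_lig = ligand_xyz.shape[1]
    names = ["C" for _ in range(n_lig)]
    masses = [12.011] * n_lig
    res_seq = [1] * n_lig
    res_names = ["LIG"] * n_lig
    chains = ["L"] * n_lig
    prot_pos = []
    for sub, seq, pos in protein_residues:
        for p in np.atleast_2d(pos):
            names.append("CA")
            masses.append(12.011)
            res_seq.append(seq)
            res_names.append("ALA")
            chains.append(sub)
            prot_pos.append(p)
    n = len(names)
    top = Topology(
        names=tuple(names),
        masses=np.array(masses),
        residue_seq=np.array(res_seq),
        residue_names=tuple(res_names),
        subunit_ids=tuple(chains),
        selections={
            "ligand": np.arange(n_lig),
            "protein": np.arange(n_lig, n),
            "water_oxygen": np.array([], dtype=int),
        },
    )
    frames = []
    for fi in range(ligand_xyz.shape[0]):
        pos = np.vstack([ligand_xyz[fi], np.array(prot_pos)])
        frames.append(Frame(time=fi + 1.0, box=np.asarray(box, float), positions=pos))
    return Trajectory(topology=top, frames=frames)


class TestContactFrequencies:
    def test_contact_inside_cutoff_counts_fully(self):
        traj = make_system(
            [[10.0, 10, 10]], [("A", 1, [[14.9, 10, 10]])], n_frames=4
        )
        table = residue_contact_frequencies(traj, cutoff=5.0)
        assert table["contact_frequency_pct"].iloc[0] == 100.0

    def test_contact_outside_cutoff_is_zero(self):
        traj = make_system(
            [[10.0, 10, 10]], [("A", 1, [[15.1, 10, 10]])], n_frames=4
        )
        table = residue_contact_frequencies(traj, cutoff=5.0)
        assert table["contact_frequency_pct"].iloc[0] == 0.0

    def test_minimum_image_contact_across_boundary(self):
        traj = make_system(
            [[0.5, 10, 10]], [("A", 1, [[39.0, 10, 10]])]
        )  # 1.5 Å apart through the boundary
        table = residue_contact_frequencies(traj, cutoff=5.0)
        assert table["contact_frequency_pct"].iloc[0] == 100.0

    def test_matches_all_pairs_oracle_on_random_frames(self):
        rng = np.random.default_rng(21)
        box = np.array([25.0, 25.0, 25.0])
        n_frames, cutoff = 6, 5.0
        lig = rng.uniform(0, 25, (n_frames, 4, 3))
        residues = [
            ("A", seq, rng.uniform(0, 25, (5, 3))) for seq in range(1, 9)
        ]
        traj = make_system(lig, residues, box=box, n_frames=n_frames)
        table = residue_contact_frequencies(traj, cutoff=cutoff)
        # brute-force all-pairs minimum-image oracle
        for row_idx, (sub, seq, pos) in enumerate(residues):
            hits = 0
            for fi in range(n_frames):
                d = lig[fi][:, None, :] - np.atleast_2d(pos)[None, :, :]
                dist = np.linalg.norm(minimum_image(d, box), axis=2)
                if (dist < cutoff).any():
                    hits += 1
            expected = 100.0 * hits / n_frames
            assert table["contact_frequency_pct"].iloc[row_idx] == pytest.approx(
                expected
            )

    def test_raising_cutoff_never_removes_contacts(self):
        rng = np.random.default_rng(22)
        lig = rng.uniform(0, 25, (3, 2, 3))
        residues = [("A", s, rng.uniform(0, 25, (4, 3))) for s in range(1, 6)]
        traj = make_system(lig, residues, box=(25.0, 25.0, 25.0), n_frames=3)
        f_small = residue_contact_frequencies(traj, cutoff=4.0)["contact_frequency_pct"]
        f_large = residue_contact_frequencies(traj, cutoff=7.0)["contact_frequency_pct"]
        assert np.all(f_large.to_numpy() >= f_small.to_numpy())

    def test_empty_residue_set_rejected(self):
        traj = make_system([[0.0, 0, 0]], [("A", 1, [[5.0, 0, 0]])])
        with pytest.raises(ValueError, match="empty"):
            residue_contact_frequencies(traj, residues=[])


class TestInteractionClass:
    @pytest.mark.parametrize(
        "freq,expected",
        [
            (0.0, InteractionClass.NON),
            (9.9, InteractionClass.NON),
            (10.0, InteractionClass.POSSIBLY),
            (49.9, InteractionClass.POSSIBLY),
            (50.0, InteractionClass.LIKELY),
            (100.0, InteractionClass.LIKELY),
        ],
    )
    def test_three_way_boundaries(self, freq, expected):
        assert classify_interaction(freq) is expected

    def test_monotone_in_frequency(self):
        order = [InteractionClass.NON, InteractionClass.POSSIBLY, InteractionClass.LIKELY]
        ranks = [order.index(classify_interaction(f)) for f in np.linspace(0, 100, 201)]
        assert ranks == sorted(ranks)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            classify_interaction(50.0, thresholds=(60.0, 40.0))


class TestOccupancySeries:
    def _sphere_region(self, center=(10.0, 10.0, 10.0), radius=3.0):
        return RegionSpec(name="site", primitives=(Sphere(center, radius),))

    def test_resident_molecule_single_full_episode(self):
        traj = make_system(
            [[10.0, 10, 10]], [("A", 1, [[30.0, 30, 30]])], n_frames=6
        )
        occ = site_occupancy_series(traj, "ligand", self._sphere_region())
        np.testing.assert_array_equal(occ.counts, np.ones(6))
        assert len(occ.episodes) == 1
        assert (occ.episodes[0].enter_frame, occ.episodes[0].leave_frame) == (0, 6)

    def test_crossing_molecule_episode_bounds(self):
        pos = np.zeros((30, 1, 3))
        pos[:, 0] = [30.0, 30, 30]
        pos[10:20, 0] = [10.0, 10, 10]  # inside during frames [10, 20)
        traj = make_system(pos, [("A", 1, [[5.0, 5, 5]])], n_frames=30)
        occ = site_occupancy_series(traj, "ligand", self._sphere_region())
        assert len(occ.episodes) == 1
        ep = occ.episodes[0]
        assert (ep.enter_frame, ep.leave_frame) == (10, 20)

    def test_debounce_merges_brief_exits(self):
        pos = np.zeros((30, 1, 3))
        pos[:, 0] = [10.0, 10, 10]
        pos[14:16, 0] = [30.0, 30, 30]  # 2-frame excursion
        traj = make_system(pos, [("A", 1, [[5.0, 5, 5]])], n_frames=30)
        occ0 = site_occupancy_series(traj, "ligand", self._sphere_region(), debounce=0)
        occ3 = site_occupancy_series(traj, "ligand", self._sphere_region(), debounce=3)
        assert len(occ0.episodes) == 2
        assert len(occ3.episodes) == 1


class TestSubunitSymmetry:
    def test_equal_copies_symmetric(self):
        df = subunit_symmetry_table({"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5})
        assert df.attrs["asymmetric"] is False

    def test_two_of_four_occupied_flags_asymmetric(self):
        df = subunit_symmetry_table({"a": 0.9, "b": 0.9, "c": 0.02, "d": 0.01})
        assert df.attrs["asymmetric"] is True

    def test_scale_invariance_of_flag(self):
        base = {"a": 0.9, "b": 0.9, "c": 0.02, "d": 0.01}
        for factor in (0.1, 1.0, 7.0):
            scaled = {k: v * factor for k, v in base.items()}
            assert (
                subunit_symmetry_table(scaled).attrs["asymmetric"]
                is subunit_symmetry_table(base).attrs["asymmetric"]
            )

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError, match="two"):
            subunit_symmetry_table({"a": 1.0})


class TestBackboneRmsd:
    def _traj_with_frames(self, ref, frames_pos):
        n = ref.shape[0]
        top = Topology(
            names=tuple("CA" for _ in range(n)),
            masses=np.full(n, 12.011),
            residue_seq=np.arange(1, n + 1),
            residue_names=tuple("ALA" for _ in range(n)),
            subunit_ids=tuple("A" for _ in range(n)),
            selections={"protein": np.arange(n)},
        )
        frames = [
            Frame(time=i + 1.0, box=np.array([99.0, 99.0, 99.0]), positions=p)
            for i, p in enumerate(frames_pos)
        ]
        return Trajectory(topology=top, frames=frames), frames[0]

    def test_reference_frame_gives_zero(self):
        rng = np.random.default_rng(23)
        ref = rng.uniform(0, 10, (6, 3))
        traj, _ = self._traj_with_frames(ref, [ref.copy()])
        ref_frame = Frame(time=0.5, box=np.array([99.0, 99.0, 99.0]), positions=ref)
        out = backbone_rmsd_series(traj, ref_frame, ["protein"])
        assert out["protein"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed_by_superposition(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(24)
        ref = rng.uniform(0, 10, (8, 3))
        rot = Rotation.from_euler("zyx", [0.4, 1.2, -0.8]).as_matrix()
        moved = ref @ rot.T + np.array([3.0, -5.0, 7.0])
        traj, _ = self._traj_with_frames(ref, [moved])
        ref_frame = Frame(time=0.5, box=np.array([99.0, 99.0, 99.0]), positions=ref)
        out = backbone_rmsd_series(traj, ref_frame, ["protein"])
        assert out["protein"].iloc[0] == pytest.approx(0.0, abs=1e-7)

    def test_pair_stretch_hand_computed(self):
        # two atoms 4 Å apart stretched to 5 Å: optimal superposition leaves
        # each atom 0.5 Å from its reference -> RMSD exactly 0.5
        ref = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        stretched = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        traj, _ = self._traj_with_frames(ref, [stretched])
        ref_frame = Frame(time=0.5, box=np.array([99.0, 99.0, 99.0]), positions=ref)
        out = backbone_rmsd_series(traj, ref_frame, ["protein"])
        assert out["protein"].iloc[0] == pytest.approx(0.5, abs=1e-9)
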