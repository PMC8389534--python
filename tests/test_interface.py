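import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from condock import (CA_SELECTION, PartnerPartition, Trajectory,
                     contact_retention, detect_contacts, detect_hbonds,
                     detect_salt_bridges, generate_trajectory, load_hotspots,
                     make_toy_complex, native_contacts, rmsd_timeseries, rmsf)
from condock.errors import PartitionError
from condock.structio import Atom, Structure

from conftest import numpy_kabsch_rmsd


def two_residue_structure(distance):
    """Two single-residue chains with closest heavy atoms at `distance` Å."""
    return Structure([
        Atom(1, "CA", "C", "ALA", "A", 1, " ", (0.0, 0.0, 0.0)),
        Atom(2, "CA", "C", "ALA", "B", 1, " ", (distance, 0.0, 0.0)),
    ])


def brute_force_contacts(st, partition, cutoff):
    pairs = {}
    for i, a in enumerate(st.atoms):
        if not a.is_heavy or a.chain not in partition.side_a:
            continue
        for j, b in enumerate(st.atoms):
            if not b.is_heavy or b.chain not in partition.side_b:
                continue
            d = float(np.linalg.norm(st.coords[i] - st.coords[j]))
            if d <= cutoff:
                key = ((a.chain, a.resseq), (b.chain, b.resseq))
                if key not in pairs or d < pairs[key]:
                    pairs[key] = d
    return pairs


def rigid_copy(st, seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.from_rotvec(rng.normal(size=3))
    return st.with_coords(st.coords @ rot.as_matrix().T + rng.normal(size=3) * 8)


class TestDetectContacts:
    def test_pair_inside_cutoff(self, partition):
        cs = detect_contacts(two_residue_structure(4.9), partition)
        assert len(cs) == 1
        assert cs.pairs[(("A", 1), ("B", 1))] == pytest.approx(4.9)

    def test_pair_outside_cutoff(self, partition):
        assert len(detect_contacts(two_residue_structure(5.1), partition)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, partition, seed):
        from condock import perturb_pose
        st = perturb_pose(make_toy_complex(25, seed=seed), 30, 4, 0.5,
                          seed=seed)
        cs = detect_contacts(st, partition)
        assert cs.pairs == pytest.approx(brute_force_contacts(st, partition, 5.0))

    def test_side_symmetry(self, toy, partition):
        a = detect_contacts(toy, partition)
        b = detect_contacts(toy, partition.swapped())
        assert a.canonical() == b.canonical()

    def test_rigid_motion_invariance(self, toy, partition):
        a = detect_contacts(toy, partition)
        b = detect_contacts(rigid_copy(toy, 3), partition)
        assert set(a.pairs) == set(b.pairs)

    def test_empty_side_rejected(self, toy):
        with pytest.raises(PartitionError):
            detect_contacts(toy, PartnerPartition.of("A", "Z"))


class TestNativeContacts:
    def _hotspots(self, rows):
        return pd.DataFrame(rows, columns=["chain", "resseq", "resname",
                                           "delta_aff"])

    def test_hotspot_contact_included(self, toy, partition):
        all_contacts = detect_contacts(toy, partition)
        (ra, rb), _ = next(iter(sorted(all_contacts.pairs.items())))
        hs = self._hotspots([(ra[0], ra[1], "ALA", 15.0)])
        nc = native_contacts(toy, partition, hs)
        assert (ra, rb) in nc.pairs

    def test_non_hotspot_contacts_excluded(self, toy, partition):
        hs = self._hotspots([("A", 999, "ALA", 50.0)])  # not at the interface
        nc = native_contacts(toy, partition, hs)
        assert len(nc) == 0

    def test_threshold_filters_weak_hotspots(self, toy, partition):
        all_contacts = detect_contacts(toy, partition)
        (ra, _), _ = next(iter(sorted(all_contacts.pairs.items())))
        hs = self._hotspots([(ra[0], ra[1], "ALA", 5.0)])  # below 10 kcal/mol
        nc = native_contacts(toy, partition, hs, threshold=10.0)
        assert len(nc) == 0

    def test_hotspots_on_either_side_count(self, toy, partition):
        all_contacts = detect_contacts(toy, partition)
        (_, rb), _ = next(iter(sorted(all_contacts.pairs.items())))
        hs = self._hotspots([(rb[0], rb[1], "ALA", 20.0)])
        nc = native_contacts(toy, partition, hs)
        assert len(nc) >= 1

    def test_load_hotspots_roundtrip(self, tmp_path):
        p = tmp_path / "hs.tsv"
        p.write_text("chain\tresseq\tresname\tdelta_aff\nA\t5\tGLU\t12.5\n")
        df = load_hotspots(p)
        assert df["delta_aff"].iloc[0] == 12.5
        bad = tmp_path / "bad.tsv"
        bad.write_text("chain\tresseq\tresname\tdelta_aff\nA\t5\tGLU\tinf\n")
        with pytest.raises(ValueError):
            load_hotspots(bad)


class TestRetention:
    def test_identical_frames_full_retention(self, toy, partition):
        traj = Trajectory([toy] * 4)
        native = detect_contacts(toy, partition)
        series = contact_retention(traj, native, partition)
        assert np.all(series.fractions == 1.0)

    def test_separation_breaks_all_contacts(self, toy, partition):
        far = toy.with_coords(toy.coords + np.where(
            np.array([a.chain == "B" for a in toy.atoms])[:, None],
            np.array([0.0, 50.0, 0.0]), 0.0))
        traj = Trajectory([toy, toy, far, far])
        native = detect_contacts(toy, partition)
        series = contact_retention(traj, native, partition)
        assert list(series.fractions) == [1.0, 1.0, 0.0, 0.0]

    def test_dissociation_is_monotone(self, toy, partition):
        traj = generate_trajectory(toy, "dissociating", n_frames=8, seed=31)
        native = detect_contacts(traj.frames[0], partition)
        series = contact_retention(traj, native, partition)
        assert series.fractions[0] == 1.0
        assert np.all(np.diff(series.fractions) <= 0)
        assert series.fractions[-1] == 0.0

    def test_empty_native_set_rejected(self, toy, partition):
        from condock.interface import ContactSet
        traj = Trajectory([toy, toy])
        with pytest.raises(ValueError):
            contact_retention(traj, ContactSet({}, 5.0), partition)


class TestHbonds:
    def _nh_o_structure(self, distance, angle_deg):
        """Donor N with H, acceptor O; D-H...A angle set by geometry."""
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)
        o = h + (distance - 1.0) * np.array([np.cos(theta), np.sin(theta), 0.0])
        return Structure([
            Atom(1, "N", "N", "ALA", "A", 1, " ", tuple(n)),
            Atom(2, "H", "H", "ALA", "A", 1, " ", tuple(h)),
            Atom(3, "O", "O", "ALA", "B", 9, " ", tuple(o)),
        ])

    def test_good_geometry_counted(self):
        bs = detect_hbonds(self._nh_o_structure(2.9, 165.0))
        assert bs.count == 1
        assert bs.used_hydrogen_angles

    def test_long_distance_rejected(self):
        assert detect_hbonds(self._nh_o_structure(3.8, 165.0)).count == 0

    def test_bad_angle_rejected(self):
        assert detect_hbonds(self._nh_o_structure(2.9, 90.0)).count == 0

    def test_no_hydrogens_distance_only_flagged(self, toy):
        bs = detect_hbonds(toy)
        assert not bs.used_hydrogen_angles
        assert bs.count > 0  # helix backbone N...O pairs

    def test_helix_matches_brute_force_oracle(self, toy):
        bs = detect_hbonds(toy)
        # oracle: every donor-N/acceptor-O pair <= 3.5 Å, excluding
        # same/adjacent residues of one chain (no hydrogens in the toy)
        expected = set()
        for i, a in enumerate(toy.atoms):
            if a.name != "N":
                continue
            for j, b in enumerate(toy.atoms):
                if b.name not in ("O", "OXT"):
                    continue
                if a.chain == b.chain and abs(a.resseq - b.resseq) <= 1:
                    continue
                if np.linalg.norm(toy.coords[i] - toy.coords[j]) <= 3.5:
                    expected.add(((a.chain, a.resseq), (b.chain, b.resseq)))
        got = {((r.donor_chain, r.donor_resseq),
                (r.acceptor_chain, r.acceptor_resseq))
               for r in bs.bonds.itertuples(index=False)}
        assert got == expected

    def test_scope_filters(self, toy, partition):
        within = detect_hbonds(toy, scope="within-chain")
        cross = detect_hbonds(toy, scope="cross-partition", partition=partition)
        everything = detect_hbonds(toy, scope="all")
        assert within.count + cross.count == everything.count

    def test_rigid_motion_invariance(self, toy):
        a = detect_hbonds(toy).count
        b = detect_hbonds(rigid_copy(toy, 41)).count
        assert a == b


class TestSaltBridges:
    def _pair(self, distance):
        return Structure([
            Atom(1, "NZ", "N", "LYS", "A", 1, " ", (0.0, 0.0, 0.0)),
            Atom(2, "OE1", "O", "GLU", "B", 1, " ", (distance, 0.0, 0.0)),
        ])

    def test_close_pair_counted(self):
        assert detect_salt_bridges(self._pair(3.0)).count == 1

    def test_distant_pair_rejected(self):
        assert detect_salt_bridges(self._pair(4.5)).count == 0

    def test_planted_bridge_found(self, charged_toy):
        bs = detect_salt_bridges(charged_toy)
        assert bs.count == 1
        row = bs.bonds.iloc[0]
        assert (row.acid_resname, row.base_resname) == ("GLU", "LYS")

    def test_matches_brute_force_oracle(self, charged_toy):
        from condock.interface import _ACIDIC, _BASIC
        st = charged_toy
        expected = set()
        for i, a in enumerate(st.atoms):
            if a.name not in _ACIDIC.get(a.resname, ()):
                continue
            for j, b in enumerate(st.atoms):
                if b.name not in _BASIC.get(b.resname, ()):
                    continue
                if np.linalg.norm(st.coords[i] - st.coords[j]) <= 4.0:
                    expected.add((a.residue_key, b.residue_key))
        got = {((r.acid_chain, r.acid_resseq, " "),
                (r.base_chain, r.base_resseq, " "))
               for r in detect_salt_bridges(st).bonds.itertuples(index=False)}
        assert got == expected

    def test_rigid_motion_invariance(self, charged_toy):
        assert detect_salt_bridges(rigid_copy(charged_toy, 43)).count == \
            detect_salt_bridges(charged_toy).count


class TestRmsdTimeseries:
    def test_identical_frames_zero(self, toy):
        ts = rmsd_timeseries(Trajectory([toy] * 3))
        assert np.abs(ts).max() <= 1e-6

    def test_rotated_frame_zero_after_fit(self, toy):
        ts = rmsd_timeseries(Trajectory([toy, rigid_copy(toy, 47)]))
        assert ts[1] <= 1e-6

    def test_matches_per_frame_oracle(self, toy):
        traj = generate_trajectory(toy, "stable", n_frames=5, seed=53,
                                   jitter_ang=0.2)
        ts = rmsd_timeseries(traj)
        idx = CA_SELECTION.indices(traj.frames[0])
        ref = traj.frames[0].coords[idx]
        for f in range(5):
            expected = numpy_kabsch_rmsd(traj.frames[f].coords[idx], ref)
            assert ts[f] == pytest.approx(expected, abs=1e-9)

    def test_bad_reference_index(self, toy):
        with pytest.raises(IndexError):
            rmsd_timeseries(Trajectory([toy, toy]), reference_frame=5)


class TestRmsf:
    def test_identical_frames_zero(self, toy):
        table = rmsf(Trajectory([toy] * 3))
        assert table["rmsf"].max() <= 1e-9

    def test_single_frame_rejected(self, toy):
        with pytest.raises(ValueError):
            rmsf(Trajectory([toy]))

    def test_one_oscillating_residue(self):
        """A residue moving ±d along x has RMSF ≈ d; fixed residues ≈ 0."""
        base = make_toy_complex(20, seed=5)
        d = 0.5
        osc = np.array([a.chain == "A" and a.resseq == 10
                        for a in base.atoms])
        up = base.coords.copy()
        up[osc, 0] += d
        down = base.coords.copy()
        down[osc, 0] -= d
        traj = Trajectory([base.with_coords(up), base.with_coords(down)] * 2)
        table = rmsf(traj).set_index(["chain", "resseq"])
        assert table.loc[("A", 10), "rmsf"] == pytest.approx(d, abs=0.05)
        others = table.drop(index=("A", 10))
        assert others["rmsf"].max() < 0.05

    def test_matches_independent_oracle(self, toy):
        """Dual route: independent superposition + direct fluctuation formula."""
        traj = generate_trajectory(toy, "stable", n_frames=6, seed=59,
                                   jitter_ang=0.15)
        table = rmsf(traj).set_index(["chain", "resseq"])
        idx = CA_SELECTION.indices(traj.frames[0])
        coords = traj.coords[:, idx, :].copy()
        ref = coords[0]
        for _ in range(3):
            refc = ref - ref.mean(axis=0)
            for f in range(len(coords)):
                xc = coords[f] - coords[f].mean(axis=0)
                h = xc.T @ refc
                u, s, vt = np.linalg.svd(h)
                dd = np.diag([1, 1, np.sign(np.linalg.det(vt.T @ u.T))])
                r = vt.T @ dd @ u.T
                coords[f] = xc @ r.T
            ref = coords.mean(axis=0)
        mean_pos = coords.mean(axis=0)
        fluct = np.sqrt(((coords - mean_pos) ** 2).sum(-1).mean(0))
        atoms = [traj.frames[0].atoms[i] for i in idx]
        for a, expected in zip(atoms, fluct):
            assert table.loc[(a.chain, a.resseq), "rmsf"] == \
                pytest.approx(expected, abs=1e-9)
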