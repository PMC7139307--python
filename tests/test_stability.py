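"""Order parameter, bound-frame masking, contact probability, summary report."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fibrilkit import (
    AtomRecord,
    DistortionSpec,
    Structure,
    Trajectory,
    bound_frames,
    make_trajectory,
    min_distance,
    order_parameter,
    plant_ligand,
    residue_contact_probability,
    select,
    summarize_complex,
)


def ca_only_structure(n_chains=2, n_res=4, z_step=0.48):
    """Planar CA-only chains stacked along z (exact-geometry test object)."""
    pos = np.array([[0.0, 0.0], [0.4, 0.0], [0.4, 0.4], [0.0, 0.4]])[:n_res]
    atoms = []
    serial = 0
    for c in range(n_chains):
        for n in range(n_res):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial, "CA", "C", "GLY", n + 1, chr(ord("A") + c),
                    (pos[n, 0], pos[n, 1], c * z_step),
                )
            )
    return Structure(atoms)


def rotate_chains(structure, angle_deg, axis="z", rng=None):
    """Rotate every chain about the given axis through its own CA centroid."""
    coords = structure.coords.copy()
    for c in structure.chain_order:
        idx = structure.chain_indices(c)
        com = coords[idx].mean(axis=0)
        if rng is None:
            R = Rotation.from_euler(axis, angle_deg, degrees=True).as_matrix()
        else:
            R = Rotation.random(random_state=rng).as_matrix()
        coords[idx] = (coords[idx] - com) @ R.T + com
    return coords


class TestOrderParameter:
    def test_identity_on_self_referential_trajectory(self):
        s = ca_only_structure()
        frames = np.repeat(s.coords[None], 4, axis=0)
        r = order_parameter(Trajectory(s, frames), fit=True)
        assert np.allclose(r.per_frame, 1.0, atol=1e-9)
        assert r.mean == pytest.approx(1.0, abs=1e-9)

    def test_quarter_turn_per_chain_gives_zero_without_fit(self):
        s = ca_only_structure()
        rotated = rotate_chains(s, 90.0)
        frames = np.stack([s.coords, rotated])
        r = order_parameter(Trajectory(s, frames), fit=False)
        assert r.per_frame[1] == pytest.approx(0.0, abs=1e-9)

    def test_global_rigid_transform_removed_by_fit(self, rng):
        s = ca_only_structure(n_chains=3)
        frames = [s.coords]
        for k in range(4):
            R = Rotation.random(
                random_state=np.random.RandomState(100 + k)
            ).as_matrix()
            frames.append(s.coords @ R.T + rng.normal(size=3))
        r = order_parameter(Trajectory(s, np.stack(frames)), fit=True)
        assert np.allclose(r.per_frame, 1.0, atol=1e-9)

    def test_scrambled_orientations_average_to_zero(self):
        """Monte-Carlo null: random chain rotations have mean dot product 0."""
        rng = np.random.RandomState(2024)
        base = np.random.default_rng(9).normal(scale=0.5, size=(5, 8, 3))
        atoms = []
        serial = 0
        for c in range(5):
            for n in range(8):
                serial += 1
                atoms.append(
                    AtomRecord(serial, "CA", "C", "GLY", n + 1, chr(ord("A") + c),
                               tuple(base[c, n])))
        s = Structure(atoms)
        frames = [s.coords]
        for _ in range(1000):
            frames.append(rotate_chains(s, None, rng=rng))
        r = order_parameter(Trajectory(s, np.stack(frames)), fit=False,
                            window=np.arange(1, 1001))
        se = r.per_frame.std() / np.sqrt(len(r.per_frame))
        assert abs(r.mean) < 3 * se

    def test_bounded_and_one_at_reference(self, small_stable_traj):
        r = order_parameter(small_stable_traj)
        assert np.all(r.per_frame <= 1 + 1e-9)
        assert np.all(r.per_frame >= -1 - 1e-9)
        assert r.per_frame[0] == pytest.approx(1.0, abs=1e-9)

    def test_monotone_degradation_with_jitter(self, pentamer):
        means = []
        for amp in (0.01, 0.05, 0.1, 0.2):
            ds = DistortionSpec(mode="stable", amplitude=amp, n_frames=30, seed=11)
            r = order_parameter(make_trajectory(pentamer, ds),
                                window=np.arange(1, 30))
            means.append(r.mean)
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_residue_com_mode_runs_and_stays_bounded(self, small_stable_traj):
        r = order_parameter(small_stable_traj, com_mode="residue",
                            window=np.arange(3))
        assert np.all(np.abs(r.per_frame) <= 1 + 1e-9)

    def test_chain_with_single_residue_rejected(self):
        s = ca_only_structure(n_res=1)
        frames = np.repeat(s.coords[None], 2, axis=0)
        with pytest.raises(ValueError, match="at least 2"):
            order_parameter(Trajectory(s, frames))


class TestBoundFrames:
    @staticmethod
    def _system(lig_x):
        """One receptor CA at origin-ish + one ligand atom per frame at lig_x."""
        atoms = [
            AtomRecord(1, "CA", "C", "GLY", 1, "A", (0.0, 0.0, 0.0)),
            AtomRecord(2, "CA", "C", "GLY", 2, "A", (0.38, 0.0, 0.0)),
            AtomRecord(3, "C1", "C", "LIG", 901, "X", (0.0, 0.0, 0.0), True),
        ]
        s = Structure(atoms)
        frames = np.repeat(s.coords[None], len(lig_x), axis=0)
        frames[:, 2, 1] = lig_x
        return Trajectory(s, frames)

    def test_glued_ligand_included_every_frame(self):
        t = self._system([0.1] * 6)
        lig = select(t.topology, hetero=True)
        rec = select(t.topology, hetero=False)
        assert bound_frames(t, lig, rec).tolist() == list(range(6))

    def test_departed_ligand_excluded_for_second_half(self):
        t = self._system([0.1, 0.1, 0.1, 5.0, 5.0, 5.0])
        lig = select(t.topology, hetero=True)
        rec = select(t.topology, hetero=False)
        assert bound_frames(t, lig, rec).tolist() == [0, 1, 2]

    def test_exact_cutoff_distance_is_excluded(self):
        t = self._system([0.35])
        lig = select(t.topology, hetero=True)
        rec = select(t.topology, hetero=False)
        assert min_distance(t.frames[0], lig, rec) == 0.35
        assert bound_frames(t, lig, rec, cutoff=0.35).size == 0

    def test_empty_ligand_mask_rejected(self):
        t = self._system([0.1])
        rec = select(t.topology, hetero=False)
        with pytest.raises(ValueError, match="ligand"):
            bound_frames(t, select(t.topology, names=["ZZ"]), rec)


def contact_system(rng, n_chains=2, n_res=4, n_frames=6):
    """Random small fibril-like system with a 3-atom ligand."""
    atoms = []
    serial = 0
    for c in range(n_chains):
        for n in range(n_res):
            for name in ("CA", "CB"):
                serial += 1
                atoms.append(
                    AtomRecord(serial, name, "C", "GLY", n + 1,
                               chr(ord("A") + c), (0.0, 0.0, 0.0)))
    for k in range(3):
        serial += 1
        atoms.append(AtomRecord(serial, f"C{k + 1}", "C", "LIG", 901, "X",
                                (0.0, 0.0, 0.0), True))
    s = Structure(atoms)
    frames = rng.normal(scale=0.4, size=(n_frames, s.n_atoms, 3))
    return Trajectory(s, frames)


def brute_contact_probabilities(traj, cutoff, frame_mask):
    """Per-chain exhaustive scan, then union over chains per identity."""
    top = traj.topology
    lig = [i for i, a in enumerate(top.atoms) if a.is_hetero]
    out = {}
    identities = {(a.residue_id, a.residue_name)
                  for a in top.atoms if not a.is_hetero}
    for key in identities:
        hits = 0
        for f in frame_mask:
            contact = False
            for i, a in enumerate(top.atoms):
                if a.is_hetero or (a.residue_id, a.residue_name) != key:
                    continue
                for j in lig:
                    d = np.linalg.norm(traj.frames[f][i] - traj.frames[f][j])
                    if d < cutoff:
                        contact = True
            hits += contact
        out[key] = hits / len(frame_mask)
    return out


class TestContactProbability:
    def test_trivial_probabilities(self):
        rng = np.random.default_rng(3)
        t = contact_system(rng)
        lig = select(t.topology, hetero=True)
        # glue ligand onto residue 1 of chain A in every frame
        t.frames[:, -3:, :] = t.frames[:, 0:1, :] + 0.01
        m = residue_contact_probability(t, lig, cutoff=0.35)
        assert m.probabilities[(1, "GLY")] == pytest.approx(1.0)
        # push ligand 50 nm away in half the frames
        t.frames[3:, -3:, :] += 50.0
        m = residue_contact_probability(t, lig, cutoff=0.35)
        assert m.probabilities[(1, "GLY")] == pytest.approx(0.5)

    def test_any_chain_union_rule_matches_brute_force(self, rng):
        for _ in range(30):
            t = contact_system(rng)
            lig = select(t.topology, hetero=True)
            got = residue_contact_probability(t, lig, cutoff=0.5)
            want = brute_contact_probabilities(t, 0.5, range(t.n_frames))
            assert got.probabilities == pytest.approx(want)

    def test_mask_restriction_is_count_weighted(self, rng):
        t = contact_system(rng, n_frames=8)
        lig = select(t.topology, hetero=True)
        m_a = residue_contact_probability(t, lig, frame_mask=np.arange(3))
        m_b = residue_contact_probability(t, lig, frame_mask=np.arange(3, 8))
        m_all = residue_contact_probability(t, lig, frame_mask=np.arange(8))
        for key in m_all.probabilities:
            combined = (3 * m_a.probabilities[key] + 5 * m_b.probabilities[key]) / 8
            assert m_all.probabilities[key] == pytest.approx(combined)

    def test_empty_frame_mask_rejected(self, rng):
        t = contact_system(rng)
        lig = select(t.topology, hetero=True)
        with pytest.raises(ValueError, match="bound frames"):
            residue_contact_probability(t, lig, frame_mask=np.array([], dtype=int))


class TestSummarizeComplex:
    def test_ligand_free_report_has_empty_contact_map(self, small_fibril):
        ds = DistortionSpec(mode="stable", amplitude=0.005, n_frames=8, seed=1,
                            time_per_frame=0.25)
        traj = make_trajectory(small_fibril, ds)
        report = summarize_complex(traj, window_ns=1.0, sasa_points=240)
        assert report.contacts.probabilities == {}
        assert report.contacts.frames_considered == 0
        assert 0 <= report.beta_mean <= 1
        assert len(report.frame_indices) == 4

    def test_window_longer_than_trajectory_rejected(self, small_stable_traj):
        with pytest.raises(ValueError, match="longer than trajectory"):
            summarize_complex(small_stable_traj, window_ns=1e6)

    def test_pocket_complex_matches_wild_type_within_noise(self, pentamer):
        """A stably bound pocket ligand leaves the stability triple unchanged."""
        ds_wt = DistortionSpec(mode="stable", amplitude=0.01, n_frames=16,
                               seed=21, time_per_frame=0.25)
        wt = summarize_complex(make_trajectory(pentamer, ds_wt),
                               window_ns=2.0, sasa_points=240)
        holo_s = plant_ligand(pentamer, "pocket", seed=4)
        ds_holo = DistortionSpec(mode="stable", amplitude=0.01, n_frames=16,
                                 seed=22, time_per_frame=0.25)
        holo = summarize_complex(
            make_trajectory(holo_s, ds_holo),
            ligand_mask=select(holo_s, hetero=True),
            window_ns=2.0, sasa_points=240,
        )
        assert abs(holo.beta_mean - wt.beta_mean) <= 2 * max(wt.beta_sd, holo.beta_sd, 0.01)
        assert abs(holo.ordp.mean - wt.ordp.mean) <= 0.01
        assert abs(holo.area.mean - wt.area.mean) <= 2 * max(wt.area.sd, holo.area.sd, 0.5)
        assert holo.contacts.frames_considered == 8

    def test_detach_run_reduces_area_and_order(self, pentamer):
        ds_stable = DistortionSpec(mode="stable", amplitude=0.01, n_frames=16,
                                   seed=31, time_per_frame=0.25)
        ds_detach = DistortionSpec(mode="detach", amplitude=3.0, onset=4,
                                   n_frames=16, seed=31, time_per_frame=0.25)
        stable = summarize_complex(make_trajectory(pentamer, ds_stable),
                                   window_ns=2.0, sasa_points=240)
        detach = summarize_complex(make_trajectory(pentamer, ds_detach),
                                   window_ns=2.0, sasa_points=240)
        assert detach.area.mean < stable.area.mean
        assert detach.ordp.mean < stable.ordp.mean
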