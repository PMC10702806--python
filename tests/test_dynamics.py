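import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memlens as m
from conftest import make_trajectory, model_trajectory
from memlens.dynamics import kabsch_rotation


def scripted_head_trajectory(z_series_by_lipid):
    """Heads-only trajectory from explicit per-lipid z time series."""
    n_lipids = len(z_series_by_lipid)
    n_frames = len(z_series_by_lipid[0])
    frames = []
    for f in range(n_frames):
        coords = [[10.0 * i, 0.0, z_series_by_lipid[i][f]]
                  for i in range(n_lipids)]
        frames.append(coords)
    return make_trajectory(frames, ["P"] * n_lipids,
                           list(range(1, n_lipids + 1)),
                           ["POPC"] * n_lipids)


class TestLeafletAssignment:
    def test_heads_split_half_and_half(self):
        z = np.array([17.0, -17.0] * 5)
        labels = m.assign_leaflets(z, midplane=0.0)
        assert (labels == 1).sum() == 5 and (labels == -1).sum() == 5

    def test_oscillation_inside_the_dead_zone_never_flips(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(-1, 1, 200)       # wobbling within +-1 A of midplane
        labels = np.ones(1, dtype=int)
        for zt in z:
            labels = m.assign_leaflets([zt], 0.0, hysteresis_gap=10.0,
                                       prev_labels=labels)
            assert labels[0] == 1

    def test_labels_match_generator_truth_every_frame(self):
        spec = m.TrajectorySpec(n_lipids=60, n_frames=200, flip_rate=3e-3,
                                seed=21)
        traj, truth = m.gen_lipid_trajectory(spec)
        heads = traj.head_indices()
        # reconstruct truth labels from the event log
        labels_truth = np.where(np.arange(60) % 2 == 0, 1, -1)
        by_frame = {}
        for ev in truth.events:
            by_frame.setdefault(ev.frame, []).append(ev)
        detected = m.assign_leaflets(traj.coords[0, heads, 2], 0.0)
        for f in range(1, traj.n_frames):
            for ev in by_frame.get(f, []):
                i = ev.lipid_id - 1
                labels_truth[i] = 1 if ev.direction == "up" else -1
            z = traj.coords[f, heads, 2]
            detected = m.assign_leaflets(z, float(z.mean()), 10.0, detected)
            np.testing.assert_array_equal(detected, labels_truth)

    def test_no_lipids_is_a_selection_error(self):
        with pytest.raises(m.SelectionError):
            m.assign_leaflets([], 0.0)


class TestFlipflopDetection:
    def test_zero_rate_means_zero_events_over_many_seeds(self):
        for seed in range(20):
            traj, _ = m.gen_lipid_trajectory(
                m.TrajectorySpec(n_lipids=30, n_frames=40, flip_rate=0.0,
                                 seed=seed))
            assert len(m.detect_flipflops(traj)) == 0

    def test_single_scripted_crossing(self):
        # lipid 2 moves from the lower to the upper leaflet at frame 3
        z = [[17.0] * 6, [-17.0] * 6, [-17, -17, -17, 17, 17, 17.0],
             [-17.0] * 6]
        traj = scripted_head_trajectory(z)
        log = m.detect_flipflops(traj, hysteresis_gap=10.0)
        assert len(log) == 1
        ev = log.events[0]
        assert ev.lipid_id == 3 and ev.frame == 3 and ev.direction == "up"

    def test_detected_events_equal_generator_truth_exactly(self):
        spec = m.TrajectorySpec(n_lipids=200, n_frames=2000,
                                flip_rate=2.5e-4, seed=11)
        traj, truth = m.gen_lipid_trajectory(spec)
        log = m.detect_flipflops(traj, hysteresis_gap=10.0)
        assert len(log) == len(truth)
        got = sorted((e.lipid_id, e.frame, e.direction) for e in log.events)
        want = sorted((e.lipid_id, e.frame, e.direction)
                      for e in truth.events)
        assert got == want

    def test_cumulative_curve_is_non_decreasing_and_totals(self):
        traj, truth = m.gen_lipid_trajectory(
            m.TrajectorySpec(n_lipids=100, n_frames=500, flip_rate=1e-3,
                             seed=5))
        log = m.detect_flipflops(traj)
        curve = log.cumulative_curve
        assert np.all(np.diff(curve) >= 0)
        assert curve[-1] == len(log)

    def test_label_changes_equal_event_count_per_lipid(self):
        traj, _ = m.gen_lipid_trajectory(
            m.TrajectorySpec(n_lipids=50, n_frames=400, flip_rate=2e-3,
                             seed=6))
        log = m.detect_flipflops(traj)
        df = log.to_frame()
        heads = traj.head_indices()
        z = traj.coords[:, heads, 2]
        for i, lip in enumerate(traj.res_id[heads]):
            changes = int(np.sum(np.sign(z[1:, i]) != np.sign(z[:-1, i])))
            assert changes == (df.lipid_id == lip).sum()

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=12.0))
    def test_doubling_the_gap_never_increases_event_count(self, gap):
        traj, _ = m.gen_lipid_trajectory(
            m.TrajectorySpec(n_lipids=40, n_frames=200, flip_rate=3e-3,
                             seed=17))
        assert len(m.detect_flipflops(traj, 2 * gap)) <= \
            len(m.detect_flipflops(traj, gap))

    def test_single_frame_is_an_error(self):
        traj, _ = m.gen_lipid_trajectory(m.TrajectorySpec(n_lipids=4,
                                                          n_frames=1))
        with pytest.raises(m.ParameterError):
            m.detect_flipflops(traj)


class TestGateDistance:
    def test_static_ideal_helices(self):
        model = m.gen_toy_structure("two_helices", separation=12.0)
        traj = model_trajectory([model, model])
        sel = m.GateSelection("A", (1, 20), "B", (1, 20))
        series = m.gate_distance(traj, sel)
        np.testing.assert_allclose(series, 12.0, atol=1e-9)

    def test_mid_trajectory_translation_steps_the_distance(self):
        model = m.gen_toy_structure("two_helices", separation=12.0)
        moved = model.subset(np.arange(len(model)))
        moved.coords = moved.coords.copy()
        moved.coords[moved.chain_id == "B", 0] += 3.0
        traj = model_trajectory([model, moved])
        series = m.gate_distance(
            traj, m.GateSelection("A", (1, 20), "B", (1, 20)))
        np.testing.assert_allclose(series, [12.0, 15.0], atol=1e-9)

    def test_center_of_geometry_matches_brute_force(self):
        model = m.gen_toy_structure("two_helices", separation=9.0)
        traj = model_trajectory([model])
        series = m.gate_distance(
            traj, m.GateSelection("A", (1, 20), "B", (1, 20)))
        a = model.coords[model.chain_id == "A"]
        b = model.coords[model.chain_id == "B"]
        brute = np.linalg.norm(sum(p for p in a) / len(a)
                               - sum(p for p in b) / len(b))
        assert abs(series[0] - brute) < 1e-9

    def test_unresolved_selection_names_missing_residues(self):
        model = m.gen_toy_structure("two_helices", separation=9.0, n_res=5)
        traj = model_trajectory([model])
        with pytest.raises(m.SelectionError, match="77"):
            m.gate_distance(traj, m.GateSelection("A", (77, 79), "B", (1, 5)))


class TestSuperposeRmsd:
    def test_identical_frame_gives_zero(self):
        model = m.gen_toy_structure("two_helices", separation=10.0)
        traj = model_trajectory([model])
        assert m.superpose_rmsd(traj, model)[0] < 1e-12

    def test_rigid_transform_invariance(self):
        model = m.gen_toy_structure("two_helices", separation=10.0)
        rng = np.random.default_rng(0)
        # random proper rotation via QR with positive determinant
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = model.subset(np.arange(len(model)))
        moved.coords = model.coords @ q.T + np.array([5.0, -3.0, 11.0])
        traj = model_trajectory([moved])
        assert m.superpose_rmsd(traj, model)[0] < 1e-9

    def test_kabsch_rotation_is_proper(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(30, 3))
        Q = rng.normal(size=(30, 3))
        R = kabsch_rotation(P - P.mean(0), Q - Q.mean(0))
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_displacement_rmsd_is_sigma_root_three(self):
        rng = np.random.default_rng(2)
        n, sigma = 5000, 0.8
        ref = rng.uniform(-50, 50, size=(n, 3))
        frame = ref + rng.normal(0, sigma, size=(n, 3))
        traj = make_trajectory([frame], [f"A{i}" for i in range(n)],
                               np.arange(n), ["X"] * n)
        rmsd = m.superpose_rmsd(traj, ref)[0]
        assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_atom_count_mismatch_is_a_selection_error(self):
        model = m.gen_toy_structure("two_helices", separation=10.0)
        traj = model_trajectory([model])
        with pytest.raises(m.SelectionError):
            m.superpose_rmsd(traj, model.coords[:5])


class TestHbondOccupancy:
    def test_ideal_pair_has_full_occupancy(self):
        model = m.gen_toy_structure("hbond_pair", d_DA=2.9)
        traj = model_trajectory([model, model, model])
        table = m.hbond_occupancy(traj, donors=[0], acceptors=[2])
        assert table.occupancy.iloc[0] == 1.0

    def test_distant_pair_has_zero_occupancy(self):
        model = m.gen_toy_structure("hbond_pair", d_DA=5.0)
        traj = model_trajectory([model, model])
        table = m.hbond_occupancy(traj, donors=[0], acceptors=[2])
        assert table.occupancy.iloc[0] == 0.0

    def test_scripted_thirty_percent_contact(self):
        near = m.gen_toy_structure("hbond_pair", d_DA=2.9)
        far = m.gen_toy_structure("hbond_pair", d_DA=6.0)
        frames = [near if f < 3 else far for f in range(10)]
        traj = model_trajectory(frames)
        table = m.hbond_occupancy(traj, donors=[0], acceptors=[2])
        assert table.occupancy.iloc[0] == pytest.approx(0.30)

    def test_bent_geometry_fails_the_angle_criterion(self):
        model = m.gen_toy_structure("hbond_pair", d_DA=2.9)
        bent = model.subset(np.arange(3))
        bent.coords = bent.coords.copy()
        bent.coords[1] = [0.0, 1.0, 0.0]   # H at 90 degrees off the D-A axis
        traj = model_trajectory([bent])
        table = m.hbond_occupancy(traj, donors=[0], acceptors=[2])
        assert table.occupancy.iloc[0] == 0.0

    def test_heavy_atom_only_ignores_geometry_of_h(self):
        model = m.gen_toy_structure("hbond_pair", d_DA=2.9)
        bent = model.subset(np.arange(3))
        bent.coords = bent.coords.copy()
        bent.coords[1] = [0.0, 1.0, 0.0]
        traj = model_trajectory([bent])
        table = m.hbond_occupancy(traj, donors=[0], acceptors=[2],
                                  crit=m.HBondCriteria(heavy_atom_only=True))
        assert table.occupancy.iloc[0] == 1.0

    def test_empty_selection_is_an_error(self):
        model = m.gen_toy_structure("hbond_pair")
        traj = model_trajectory([model])
        with pytest.raises(m.SelectionError):
            m.hbond_occupancy(traj, donors=[], acceptors=[2])
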