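"""Kabsch superposition, RMSD series, stability onset, post-onset distances."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gatemap.bridges import charged_pair_distance
from gatemap.model import StructureEnsemble, transform_ensemble
from gatemap.synth import PairProcess, TrajectorySpec, canonical_pairs, gen_trajectory
from gatemap.trajectory import (
    RmsdSeries,
    TrajectoryMeta,
    kabsch_superpose,
    pair_distance_series,
    rmsd_series,
    stability_onset,
)

from conftest import rigid_transform


def _grid_min_rmsd(ref: np.ndarray, mov: np.ndarray, n_grid: int = 8000, seed: int = 0) -> float:
    """Independent oracle: rotation-space grid search plus local polish.

    Scans a deterministic quasi-random quaternion grid for the best rotation
    of the centered point sets, then polishes with Nelder-Mead on the
    rotation vector.  Never touches the SVD path under test.
    """
    p = ref - ref.mean(axis=0)
    q = mov - mov.mean(axis=0)
    n = p.shape[0]

    def rmsd_of(rot: Rotation) -> float:
        return float(np.sqrt(((rot.apply(q) - p) ** 2).sum() / n))

    grid = Rotation.random(n_grid, random_state=seed)
    mats = grid.as_matrix()
    rotated = np.einsum("rij,nj->rni", mats, q)
    vals = np.sqrt(((rotated - p) ** 2).sum(axis=(1, 2)) / n)
    best = grid[int(np.argmin(vals))]

    res = minimize(
        lambda v: rmsd_of(Rotation.from_rotvec(v)),
        best.as_rotvec(),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return float(res.fun)


def test_identical_sets_superpose_to_zero_with_identity_rotation():
    pts = np.random.default_rng(0).uniform(-5, 5, (10, 3))
    rot, t, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t, np.zeros(3), atol=1e-12)


def test_rigid_motion_recovers_zero_rmsd():
    pts = np.random.default_rng(1).uniform(-5, 5, (12, 3))
    rot_true = Rotation.from_euler("z", 37, degrees=True).as_matrix()
    mov = pts @ rot_true.T + np.array([5.0, -2.0, 1.0])
    rot, t, rmsd = kabsch_superpose(pts, mov)
    assert rmsd < 1e-9
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_matches_quaternion_grid_oracle(seed):
    """8 noisy points: SVD minimum within 1e-3 A of the grid-search oracle."""
    rng = np.random.default_rng(seed)
    ref = rng.uniform(-5, 5, (8, 3))
    rot = Rotation.random(random_state=seed + 100)
    mov = rot.apply(ref) + rng.normal(0, 0.3, (8, 3)) + rng.uniform(-3, 3, 3)
    _, _, rmsd = kabsch_superpose(ref, mov)
    oracle = _grid_min_rmsd(ref, mov, seed=seed)
    assert rmsd == pytest.approx(oracle, abs=1e-3)
    assert rmsd <= oracle + 1e-9  # the closed form is the true minimum


def test_rotation_always_proper():
    rng = np.random.default_rng(3)
    for _ in range(20):
        ref = rng.uniform(-5, 5, (6, 3))
        mov = rng.uniform(-5, 5, (6, 3))
        rot, _, _ = kabsch_superpose(ref, mov)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


def test_symmetry_and_degenerate_inputs():
    rng = np.random.default_rng(4)
    a = rng.uniform(-5, 5, (7, 3))
    b = rng.uniform(-5, 5, (7, 3))
    assert kabsch_superpose(a, b)[2] == pytest.approx(kabsch_superpose(b, a)[2], abs=1e-9)
    with pytest.raises(ValueError):
        kabsch_superpose(a, a[:5])
    with pytest.raises(ValueError):
        kabsch_superpose(a[:2], b[:2])


def test_aligned_rmsd_never_exceeds_unaligned():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = rng.uniform(-5, 5, (9, 3))
        b = a + rng.normal(0, 1.0, (9, 3))
        unaligned = np.sqrt(((a - b) ** 2).sum() / 9)
        assert kabsch_superpose(a, b)[2] <= unaligned + 1e-12


# -- rmsd series ------------------------------------------------------------

def test_identical_frames_give_zero_series(planted_trajectory):
    _, _, traj, _ = planted_trajectory
    frozen = StructureEnsemble(
        models=[traj.models[0]] * 5, source_label=""
    )
    s = rmsd_series(frozen, TrajectoryMeta())
    np.testing.assert_allclose(s.values, 0.0, atol=1e-12)
    assert s.values[s.reference_index] == 0.0


def test_series_matches_generator_ground_truth(planted_trajectory):
    _, spec, traj, truth = planted_trajectory
    s = rmsd_series(traj, TrajectoryMeta(frame_interval=spec.frame_interval))
    np.testing.assert_allclose(s.values, truth["rmsd_A"].to_numpy(), atol=1e-9)
    np.testing.assert_allclose(s.times, truth["time_ns"].to_numpy())


def test_series_invariant_under_global_rigid_motion(planted_trajectory):
    _, _, traj, _ = planted_trajectory
    short = StructureEnsemble(models=traj.models[:40])
    moved = transform_ensemble(short, rigid_transform(np.random.default_rng(8)))
    s0 = rmsd_series(short, TrajectoryMeta())
    s1 = rmsd_series(moved, TrajectoryMeta())
    np.testing.assert_allclose(s1.values, s0.values, atol=1e-9)


# -- stability onset --------------------------------------------------------

def _series(values, dt=0.2):
    return RmsdSeries(times=np.arange(len(values)) * dt, values=np.asarray(values, float), reference_index=0)


def test_constant_series_onset_zero():
    r = stability_onset(_series(np.ones(100)), window=50)
    assert r.onset_index == 0 and r.onset_time == 0.0


def test_planted_changepoint_recovered_within_window(planted_trajectory):
    _, spec, traj, _ = planted_trajectory
    s = rmsd_series(traj, TrajectoryMeta())
    r = stability_onset(s, window=50, slope_tol=0.05)
    assert abs(r.onset_index - spec.changepoint) <= 50


def test_steep_series_falls_back_to_last_window(caplog):
    values = np.arange(100) * 0.2  # slope 1 A/ns, far above tolerance
    with caplog.at_level("WARNING", logger="gatemap.trajectory"):
        r = stability_onset(_series(values), window=50, slope_tol=0.05)
    assert r.onset_index == 50
    assert any("onset" in rec.message for rec in caplog.records)


def test_onset_non_decreasing_as_tolerance_shrinks(planted_trajectory):
    _, _, traj, _ = planted_trajectory
    s = rmsd_series(traj, TrajectoryMeta())
    onsets = [
        stability_onset(s, window=50, slope_tol=tol).onset_index
        for tol in (0.2, 0.1, 0.05, 0.02)
    ]
    assert onsets == sorted(onsets)


def test_window_longer_than_series_rejected():
    with pytest.raises(ValueError):
        stability_onset(_series(np.ones(10)), window=50)


# -- pair distance series ---------------------------------------------------

def test_fluctuating_distance_mean_recovered():
    pair = canonical_pairs()[0]
    spec = TrajectorySpec(
        pairs=(PairProcess(pair, 6.0, fluct_sd_A=0.3),),
        n_frames=200,
        changepoint=0,
        seed=21,
    )
    traj, truth = gen_trajectory(spec)
    _, values, stat = pair_distance_series(traj, pair)
    np.testing.assert_allclose(values, truth["d_HLH-TDhC"].to_numpy(), atol=1e-9)
    assert abs(stat.mean_A - 6.0) < 3 * 0.3 / np.sqrt(200)


def test_post_onset_statistics_use_final_window_only(planted_trajectory):
    pair, spec, traj, _ = planted_trajectory
    s = rmsd_series(traj, TrajectoryMeta())
    last = stability_onset(s, window=50, slope_tol=0.0)  # never flat -> fallback
    _, values, stat = pair_distance_series(traj, pair, last)
    assert stat.n == 50
    assert stat.mean_A == pytest.approx(values[-50:].mean(), abs=1e-12)


def test_mean_equals_naive_loop(planted_trajectory):
    pair, _, traj, _ = planted_trajectory
    _, values, stat = pair_distance_series(traj, pair)
    total = 0.0
    for model in traj.models:
        total += charged_pair_distance(model, pair)
    assert stat.mean_A == pytest.approx(total / traj.n_models, abs=1e-9)
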