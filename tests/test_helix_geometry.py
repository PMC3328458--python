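"""Reference frames, step parameters, superposition and B-factors."""

import numpy as np
import pytest

from bzdyn import build_duplex, perturb_trajectory
from bzdyn._bases import RING_ATOMS, base_template
from bzdyn._geom import rotation_about_axis
from bzdyn.helix_geometry import (
    ReferenceFrame,
    average_structure,
    base_frame,
    bfactors,
    compose_step,
    pair_parameters,
    step_parameters,
    superpose,
)


def _random_frame(r):
    R = rotation_about_axis(r.normal(size=3), r.uniform(0, 360))
    return ReferenceFrame(r.normal(size=3) * 5, R)


def test_base_frame_identity():
    tpl = base_template("G")
    f = base_frame(tpl, "G")
    assert np.allclose(f.axes, np.eye(3), atol=1e-9)
    assert np.allclose(f.origin, 0.0, atol=1e-9)


@pytest.mark.parametrize("base", ["G", "C"])
def test_base_frame_recovers_known_rotation(base, rng):
    tpl = base_template(base)
    R = rotation_about_axis(rng.normal(size=3), 73.0)
    t = np.array([1.0, -2.0, 3.0])
    moved = {k: v @ R.T + t for k, v in tpl.items()}
    f = base_frame(moved, base)
    assert np.allclose(f.axes, R, atol=1e-6)
    assert np.allclose(f.origin, t, atol=1e-6)


def test_base_frame_noise_tolerance(rng):
    """Fitted frame error stays of the order of the coordinate noise and
    scales down with it.  (The frame origin lies a few Angstrom outside the
    ring centroid, so angular noise is lever-arm amplified by a small
    factor.)"""
    tpl = base_template("C")

    def mean_err(sigma, reps=40):
        errs = []
        for _ in range(reps):
            noisy = {k: v + rng.normal(0, sigma, 3) for k, v in tpl.items()}
            errs.append(np.linalg.norm(base_frame(noisy, "C").origin))
        return np.mean(errs)

    assert mean_err(0.1) < 0.3
    assert mean_err(0.02) < 0.06


def test_base_frame_requires_three_ring_atoms():
    tpl = base_template("C")
    partial = {k: tpl[k] for k in list(RING_ATOMS["C"])[:2]}
    with pytest.raises(ValueError, match="ring atoms"):
        base_frame(partial, "C")


def test_step_parameters_identity_and_round_trip(rng):
    f = _random_frame(rng)
    assert np.allclose(step_parameters(f, f), 0.0, atol=1e-9)
    for _ in range(100):
        params = np.array([
            rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(2, 5),
            rng.uniform(-25, 25), rng.uniform(-25, 25), rng.uniform(-170, 170),
        ])
        f1 = _random_frame(rng)
        f2 = compose_step(f1, params)
        assert np.allclose(step_parameters(f1, f2), params, atol=1e-8)


def test_step_parameters_rigid_motion_invariant(rng):
    params = np.array([0.3, -0.5, 3.3, 4.0, -7.0, 35.0])
    f1 = _random_frame(rng)
    f2 = compose_step(f1, params)
    R = rotation_about_axis(rng.normal(size=3), 211.0)
    t = rng.normal(size=3) * 10
    g1 = ReferenceFrame(R @ f1.origin + t, R @ f1.axes)
    g2 = ReferenceFrame(R @ f2.origin + t, R @ f2.axes)
    assert np.allclose(step_parameters(g1, g2), params, atol=1e-8)


def test_step_parameters_strand_reversal_parity(rng):
    """Reading the step in the reverse strand direction negates the
    sign-odd parameters (shift, tilt) and preserves the rest."""
    params = np.array([0.5, -0.3, 3.3, 5.0, -8.0, 30.0])
    f1 = _random_frame(rng)
    f2 = compose_step(f1, params)
    rev = step_parameters(f2.flipped(), f1.flipped())
    assert np.allclose(rev, params * np.array([-1, 1, 1, -1, 1, 1]), atol=1e-8)


def test_pair_parameters_ideal_pair(rng):
    """A perfectly paired complementary frame gives all-zero parameters and
    a pair frame equal to the Watson frame."""
    fw = _random_frame(rng)
    fc = fw.flipped()
    params, mid = pair_parameters(fw, fc)
    assert np.allclose(params, 0.0, atol=1e-9)
    assert np.allclose(mid.axes, fw.axes, atol=1e-9)


def test_superpose_identity_and_rotation(rng):
    pts = rng.normal(size=(30, 3))
    _, _, r0 = superpose(pts, pts)
    assert r0 == pytest.approx(0.0, abs=1e-9)
    R = rotation_about_axis([0.3, 1, 2], 97.0)
    _, _, r1 = superpose(pts @ R.T + np.array([1, 2, 3.0]), pts)
    assert r1 == pytest.approx(0.0, abs=1e-9)


def test_superpose_uniform_offset_matches_oracle(rng):
    """A rigid 0.5 A x-offset is removed by recentering: RMSD equals the
    brute-force residual after centering (zero)."""
    pts = rng.normal(size=(25, 3))
    shifted = pts + np.array([0.5, 0.0, 0.0])
    _, _, r = superpose(shifted, pts)
    centered = shifted - shifted.mean(axis=0) - (pts - pts.mean(axis=0))
    brute = np.sqrt(np.mean(np.sum(centered**2, axis=-1)))
    assert r == pytest.approx(brute, abs=1e-9)


def test_rmsd_symmetry_and_triangle(rng):
    def d(a, b):
        return superpose(a, b)[2]

    for _ in range(20):
        a, b, c = rng.normal(size=(3, 12, 3))
        assert d(a, b) == pytest.approx(d(b, a), abs=1e-8)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-8


def test_superpose_rejects_too_few_points():
    with pytest.raises(ValueError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_bfactors_static_trajectory(b_duplex):
    traj = perturb_trajectory(b_duplex, 5, 0.0, seed=0)
    b = bfactors(traj, b_duplex)
    assert np.allclose(b.to_numpy(), 0.0, atol=1e-12)
    # terminal residues excluded per the end-effect convention
    assert set(b.index) == {r.number for i, r in enumerate(b_duplex.residues)
                            if i not in b_duplex.terminal_residue_indices()}


def test_bfactors_match_isotropic_closed_form(b_duplex):
    """Isotropic sigma=0.3 A noise: B ~= 8 pi^2 sigma^2 = 7.11 A^2."""
    traj = perturb_trajectory(b_duplex, 1500, 0.3, seed=5)
    b = bfactors(traj, b_duplex)
    assert b.mean() == pytest.approx(8 * np.pi**2 * 0.09, rel=0.03)


def test_bfactors_quadratic_in_sigma(b_duplex):
    b1 = bfactors(perturb_trajectory(b_duplex, 800, 0.15, seed=6), b_duplex)
    b2 = bfactors(perturb_trajectory(b_duplex, 800, 0.30, seed=6), b_duplex)
    assert b2.mean() / b1.mean() == pytest.approx(4.0, rel=0.05)


def test_bfactors_single_frame_rejected(b_duplex):
    with pytest.raises(ValueError, match="two frames"):
        bfactors(perturb_trajectory(b_duplex, 1, 0.1, seed=0), b_duplex)


def test_average_structure_of_noisy_trajectory(b_duplex):
    traj = perturb_trajectory(b_duplex, 400, 0.2, seed=7)
    avg = average_structure(traj.frames)
    _, _, r = superpose(avg, b_duplex.coords)
    assert r < 0.05
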