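"""Bead-rod integrator: force oracles, projections, determinism, equilibrium."""

import numpy as np
import pytest

from wlctube import gbr
from wlctube.errors import ConfigurationError
from wlctube.fixtures import (
    FixtureChainSampler,
    langevin,
    sample_equilibrium_wlc,
)
from wlctube.theory import ChannelGeometry, ForceState
from wlctube.units import kBT

LP = 50.0


class _ZeroRng:
    """Stub generator: zero noise, for deterministic-step fixed points."""

    def standard_normal(self, n):
        return np.zeros(n)


# ---------------------------------------------------------------------------
# construction and forces
# ---------------------------------------------------------------------------


def test_init_straight_chain():
    ch = gbr.init_straight_chain(3, 2.0)
    assert np.allclose(ch.positions[:, 2], [-2.0, 0.0, 2.0])
    assert np.allclose(ch.positions[:, :2], 0.0)
    assert ch.extension() == pytest.approx((ch.N - 1) * ch.b)
    assert ch.max_rod_error() == 0.0
    with pytest.raises(ConfigurationError):
        gbr.init_straight_chain(2, 2.0)
    with pytest.raises(ConfigurationError):
        gbr.GBRChain(np.zeros((5, 3)), b=60.0, a=1.0, Lp=50.0)  # b >= Lp


def test_bending_forces_straight_chain_zero():
    ch = gbr.init_straight_chain(20, 2.0)
    assert np.abs(gbr.bending_forces(ch)).max() == 0.0


def test_bending_forces_match_finite_differences():
    """Analytic bending gradient vs central differences on a bent chain,
    including a right-angle joint (Lp/b = 25)."""
    pos = np.array(
        [[0, 0, 0], [0, 0, 2], [0, 2, 2], [0, 2, 4], [2, 2, 4]], dtype=float
    )
    ch = gbr.GBRChain(pos, b=2.0, a=1.0, Lp=50.0)
    F = gbr.bending_forces(ch)

    def energy(p):
        u = np.diff(p, axis=0)
        u = u / np.linalg.norm(u, axis=1)[:, None]
        return kBT() * (50.0 / 2.0) * np.sum(1 - np.sum(u[:-1] * u[1:], axis=1))

    eps = 1e-6
    num = np.zeros_like(F)
    for i in range(pos.shape[0]):
        for d in range(3):
            pp = pos.copy()
            pp[i, d] += eps
            ep = energy(pp)
            pp[i, d] -= 2 * eps
            em = energy(pp)
            num[i, d] = -(ep - em) / (2 * eps)
    assert np.abs(F - num).max() / np.abs(F).max() < 1e-6
    # translation invariance: total force zero; total torque zero
    assert np.abs(F.sum(axis=0)).max() < 1e-12
    torque = np.cross(pos, F).sum(axis=0)
    assert np.abs(torque).max() < 1e-10


def test_external_forces():
    ch = gbr.init_straight_chain(10, 2.0)
    F = gbr.external_forces(ch, 0.0)
    assert not F.any()
    F = gbr.external_forces(ch, 1.5)
    assert F[0, 2] == -1.5 and F[-1, 2] == 1.5
    assert np.abs(F.sum(axis=0)).max() == 0.0
    assert not F[1:-1].any()


def test_diffusion_matrix_free_draining_and_rpy():
    ch = gbr.init_straight_chain(10, 3.0, a=1.85)
    p_free = gbr.IntegratorParams(dt=5.0, steps=1)
    D = gbr.diffusion_matrix(ch, p_free)
    D0 = kBT() / (6 * np.pi * 1.005725e-4 * 1e6 * 1.85)
    assert np.allclose(np.diag(D), D0)
    assert np.abs(D - np.diag(np.diag(D))).max() == 0.0
    # pairwise mobility: SPD on a random non-overlapping configuration
    p_rpy = gbr.IntegratorParams(
        dt=5.0, steps=1, hydrodynamics=gbr.Hydrodynamics.PAIRWISE_MOBILITY
    )
    chain = sample_equilibrium_wlc(FixtureChainSampler(Lp=LP, b=4.0, N=12, seed=5))
    Dr = gbr.diffusion_matrix(chain, p_rpy)
    assert np.allclose(Dr, Dr.T)
    assert np.linalg.eigvalsh(Dr).min() > 0


def test_random_displacements_covariance():
    """Sample covariance of the correlated noise matches 2 D dt (3 SE)."""
    rng = np.random.default_rng(123)
    pos = np.array([[0, 0, 0], [0, 0, 3.0]])
    D = np.array(
        [[2.0, 0.3, 0, 0.5, 0, 0],
         [0.3, 2.0, 0, 0, 0.2, 0],
         [0, 0, 2.0, 0, 0, 0.1],
         [0.5, 0, 0, 2.0, 0, 0],
         [0, 0.2, 0, 0, 2.0, 0],
         [0, 0, 0.1, 0, 0, 2.0]]
    )
    dt = 0.5
    n = 40_000
    draws = np.array([gbr.random_displacements(D, dt, rng) for _ in range(n)])
    assert np.abs(draws.mean(axis=0)).max() < 3 * np.sqrt(2 * D.max() * dt / n)
    cov = np.cov(draws.T)
    se = 2 * D.max() * dt * np.sqrt(2.0 / n)  # scale of covariance noise
    assert np.abs(cov - 2 * D * dt).max() < 3 * se
    # identical generator state, identical stream
    a = gbr.random_displacements(D, dt, np.random.default_rng(7))
    b = gbr.random_displacements(D, dt, np.random.default_rng(7))
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# wall penalty and constraint projection
# ---------------------------------------------------------------------------


def test_wall_penalty_rules():
    g = ChannelGeometry.rectangular(Hh=10.0, Hw=10.0)
    inside = np.array([[1.0, -2.0, 5.0]])
    assert not gbr.wall_penalty(inside, g).any()
    out_x = np.array([[6.0, 0.0, 1.0]])
    assert np.allclose(gbr.wall_penalty(out_x, g)[0], [-1.0, 0.0, 0.0])
    corner = np.array([[-7.0, 8.5, -2.0]])
    assert np.allclose(gbr.wall_penalty(corner, g)[0], [2.0, -3.5, 0.0])
    # unconfined: no penalty ever
    assert not gbr.wall_penalty(corner, None).any()
    # z untouched in all cases
    assert gbr.wall_penalty(corner, g)[0, 2] == 0.0


def test_constraint_projection_properties():
    ch = gbr.init_straight_chain(7, 2.0)
    # on-manifold input unchanged
    out = gbr.constraint_projection(ch.positions, 2.0)
    assert np.abs(out - ch.positions).max() < 1e-12
    # two beads stretched to 1.1 b: restored with midpoint preserved
    two = np.array([[0, 0, 0], [0, 0, 2.2], [0, 0, 4.2]])
    fixed = gbr.constraint_projection(two, 2.0)
    lengths = np.linalg.norm(np.diff(fixed, axis=0), axis=1)
    assert np.abs(lengths - 2.0).max() < 1e-10 * 2.0
    assert np.allclose(fixed.mean(axis=0), two.mean(axis=0), atol=1e-12)
    # random perturbations: projection restores all rods to tolerance
    rng = np.random.default_rng(99)
    for _ in range(5):
        pert = ch.positions + 0.1 * rng.standard_normal(ch.positions.shape)
        proj = gbr.constraint_projection(pert, 2.0)
        err = np.abs(np.linalg.norm(np.diff(proj, axis=0), axis=1) - 2.0).max()
        assert err < 1e-10 * 2.0


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def test_step_fixed_point_without_noise():
    """Straight interior chain, no force, no noise: the step is identity."""
    ch = gbr.init_straight_chain(9, 2.0)
    g = ChannelGeometry.square(10.0)
    params = gbr.IntegratorParams(dt=5.0, steps=1)
    out = gbr.step(ch, g, ForceState(0.0), params, _ZeroRng())
    assert np.abs(out.positions - ch.positions).max() < 1e-12


def test_step_and_trajectory_determinism():
    ch = gbr.init_straight_chain(11, 2.0)
    g = ChannelGeometry.square(10.0)
    params = gbr.IntegratorParams(dt=5.0, steps=300, seed=42)
    t1 = gbr.run_trajectory(ch, g, ForceState(0.0), params)
    t2 = gbr.run_trajectory(ch, g, ForceState(0.0), params)
    assert np.array_equal(t1.extension, t2.extension)
    # python path determinism too
    rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
    s1 = gbr.step(ch, g, ForceState(0.0), params, rng1)
    s2 = gbr.step(ch, g, ForceState(0.0), params, rng2)
    assert np.array_equal(s1.positions, s2.positions)


def test_trajectory_invariants_tube_run():
    """Rod lengths and containment hold after every accepted step."""
    ch = gbr.init_straight_chain(21, 3.0)
    g = ChannelGeometry.square(12.0)
    params = gbr.IntegratorParams(dt=5.0, steps=2000, seed=3)
    t = gbr.run_trajectory(ch, g, ForceState(5.0), params)
    assert t.max_rod_error < 1e-10 * ch.b
    assert t.max_wall_violation <= 1e-9
    final = t.final_positions
    assert np.abs(final[:, 0]).max() <= 6.0 + 1e-9
    assert np.abs(final[:, 1]).max() <= 6.0 + 1e-9
    assert (t.extension <= (ch.N - 1) * ch.b + 1e-9).all()


def test_zero_steps_edge():
    ch = gbr.init_straight_chain(5, 2.0)
    params = gbr.IntegratorParams(dt=5.0, steps=0, seed=1)
    t = gbr.run_trajectory(ch, None, ForceState(0.0), params)
    assert len(t.extension) == 0


def test_strong_force_extends_chain():
    """Large tension, no walls: the chain drifts toward full extension."""
    sampler = FixtureChainSampler(Lp=LP, b=2.0, N=41, seed=8)
    ch = sample_equilibrium_wlc(sampler)
    params = gbr.IntegratorParams(dt=5.0, steps=100_000, seed=11)
    t = gbr.run_trajectory(ch, None, ForceState.from_physical(8.0, LP), params)
    L = (ch.N - 1) * ch.b
    assert t.extension[-100:].mean() > 0.85 * L
    assert t.extension[-100:].mean() > t.extension[:100].mean()


def test_equilibrium_tangent_correlation_preserved():
    """Starting from an exact Boltzmann draw, a short BD run keeps the
    per-joint tangent correlation at the discrete closed form (3 SE)."""
    rng = np.random.default_rng(21)
    sampler = FixtureChainSampler(Lp=LP, b=2.0, N=51, a=1.85)
    vals = []
    for k in range(8):
        ch = sample_equilibrium_wlc(sampler, rng)
        params = gbr.IntegratorParams(dt=2.5, steps=3000, seed=300 + k)
        t = gbr.run_trajectory(ch, None, ForceState(0.0), params)
        u = np.diff(t.final_positions, axis=0)
        u /= np.linalg.norm(u, axis=1)[:, None]
        vals.append(float((u[:-1] * u[1:]).sum(axis=1).mean()))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - langevin(LP / 2.0)) < 3 * se + 1e-4


def test_hydrodynamics_model_does_not_shift_equilibrium():
    """Free-draining and pairwise-mobility runs agree on the mean
    extension within combined uncertainty (equilibrium is mobility-free)."""
    sampler = FixtureChainSampler(Lp=LP, b=3.0, N=11, a=1.4)
    force = ForceState(10.0)

    def mean_ext(hydro, seeds):
        outs = []
        for s in seeds:
            ch = sample_equilibrium_wlc(sampler, np.random.default_rng(1000 + s))
            params = gbr.IntegratorParams(dt=5.0, steps=1500, seed=s, hydrodynamics=hydro)
            t = gbr.run_trajectory(ch, None, force, params)
            outs.append(t.extension[len(t.extension) // 4 :].mean())
        return np.asarray(outs)

    a = mean_ext(gbr.Hydrodynamics.FREE_DRAINING, [1, 2, 3, 4])
    b = mean_ext(gbr.Hydrodynamics.PAIRWISE_MOBILITY, [5, 6, 7, 8])
    se = np.sqrt(a.std(ddof=1) ** 2 / len(a) + b.std(ddof=1) ** 2 / len(b))
    assert abs(a.mean() - b.mean()) < 3 * se + 0.02 * (a.mean() + b.mean()) / 2
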