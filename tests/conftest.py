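"""Shared fixtures: study conditions for the simulation-vs-theory checks.

The heavy Brownian-dynamics ensembles are session-scoped so the
comparison grid is integrated once and reused by the extension-accuracy,
theory-ordering, scaling-collapse and invariant tests.

Conditions (chosen once, on physical grounds):
 * comparison grid at channel size H/Lp = 0.3 (square tube and slit) with
   reduced tensions {0, 5, 20}; the 4.8-Lp square-tube chains keep
   free-end effects well below the scale on which the competing theories
   differ, slit chains stay at 3 Lp with longer runs because the slow
   in-plane extension mode relaxes as the contour length squared, and
   3 nm rods with a 5 ps step keep time-discretisation bias at the
   percent level;
 * free-chain and stretched-chain oracles start from exact Boltzmann
   draws, so the integrator is tested for preserving equilibrium rather
   than for reaching it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from wlctube.analysis import average_extension, ComparisonCondition
from wlctube.fixtures import (
    FixtureChainSampler,
    sample_equilibrium_wlc,
    sample_stretched_wlc,
)
from wlctube.gbr import (
    GBRChain,
    IntegratorParams,
    Trajectory,
    init_straight_chain,
    run_ensemble,
)
from wlctube.theory import ChainSpec, ChannelGeometry, ForceState

LP = 50.0  # nm, double-stranded DNA scale
N_TRAJ = 12


def make_synthetic_trajectory(extension: np.ndarray, L: float = 1.0, seed: int = 0) -> Trajectory:
    """Wrap a bare extension series in a Trajectory for analysis tests."""
    n = len(extension)
    return Trajectory(
        extension=np.asarray(extension, dtype=float),
        record_every=1,
        params=IntegratorParams(dt=1.0, steps=n, seed=seed),
        f_hat=0.0,
        geometry=None,
        chain_b=L,  # chain of 2 beads: L = (N-1) b
        chain_a=1.0,
        chain_Lp=10 * L,
        chain_N=2,
    )


def _grid_condition(geom, L_nm, f_hat, base_seed, steps=500_000, b=3.0):
    """Integrate one (geometry, force) cell: 12 straight-start trajectories."""
    N = int(round(L_nm / b)) + 1
    chain0 = init_straight_chain(N, b=b, a=1.85, Lp=LP)
    params = IntegratorParams(dt=5.0, steps=steps, seed=base_seed)
    trajs = run_ensemble(
        chain0, geom, ForceState(f_hat=float(f_hat)), params,
        n_traj=N_TRAJ, record_every=10,
    )
    est = average_extension(trajs)
    cond = ComparisonCondition(
        geom=geom,
        chain=ChainSpec(Lp=LP, L=L_nm),
        force=ForceState(f_hat=float(f_hat)),
        label=f"{geom.kind.value}_H{geom.Hh / LP:g}_f{f_hat:g}",
    )
    return {"estimate": est, "condition": cond, "trajectories": trajs}


@pytest.fixture(scope="session")
def bd_grid():
    """Comparison grid: square tube H/Lp=0.3 at f^ in {0,5,20}, slit
    Hh/Lp=0.3 (Hw/Lp=1000) at f^ in {5,20}, plus square H/Lp=0.2 at f^=0
    for the Odijk scaling collapse.

    A slit without tension has no preferred axis in the slit plane (the
    chain random-walks in-plane and the axial extension is not close to
    L), so zero force is only meaningful for tube geometries.
    """
    sq3 = ChannelGeometry.square(0.3 * LP)
    sq2 = ChannelGeometry.square(0.2 * LP)
    slit = ChannelGeometry.slit(0.3 * LP, width=1000.0 * LP)
    cells = {}
    cells["square_f0"] = _grid_condition(sq3, 240.0, 0.0, 12000)
    cells["square_f5"] = _grid_condition(sq3, 240.0, 5.0, 13000)
    cells["square_f20"] = _grid_condition(sq3, 240.0, 20.0, 14000)
    cells["slit_f5"] = _grid_condition(slit, 150.0, 5.0, 15000, steps=1_200_000)
    cells["slit_f20"] = _grid_condition(slit, 150.0, 20.0, 16000, steps=1_200_000)
    cells["square_H02_f0"] = _grid_condition(sq2, 240.0, 0.0, 11000)
    return cells


@pytest.fixture(scope="session")
def free_chain_ensemble():
    """Free chain, L = 4 Lp (N=101, b=2), started from exact equilibrium
    draws and integrated briefly; frames every 500 steps."""
    rng = np.random.default_rng(17000)
    sampler = FixtureChainSampler(Lp=LP, b=2.0, N=101, a=1.85)
    starts = [sample_equilibrium_wlc(sampler, rng) for _ in range(N_TRAJ)]
    params = IntegratorParams(dt=5.0, steps=20_000, seed=17100)
    trajs = []
    for k, start in enumerate(starts):
        pk = dataclasses.replace(params, seed=params.seed + k)
        from wlctube.gbr import run_trajectory

        trajs.append(
            run_trajectory(start, None, ForceState(0.0), pk, record_every=10, frame_every=500)
        )
    return trajs


@pytest.fixture(scope="session")
def stretch_ensemble():
    """Unconfined chain under tension f^=25, L=16 Lp (N=401, b=2), started
    from exact stretched-equilibrium draws."""
    rng = np.random.default_rng(18000)
    sampler = FixtureChainSampler(Lp=LP, b=2.0, N=401, a=1.85)
    starts = [sample_stretched_wlc(sampler, 25.0, rng) for _ in range(N_TRAJ)]
    chain0 = starts[0]
    params = IntegratorParams(dt=2.5, steps=15_000, seed=18100)
    trajs = run_ensemble(
        chain0, None, ForceState(25.0), params, n_traj=N_TRAJ,
        record_every=10, initial_chains=starts,
    )
    return trajs
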