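"""Generalized bead-rod (GBR) Brownian dynamics of a confined, stretched chain.

The discrete wormlike chain is a string of N bead centres linked by N-1
inextensible rods of length b; bending stiffness enters through the
discrete wormlike-chain energy E = kBT (Lp/b) sum_j (1 - cos theta_j),
which reproduces persistence length Lp for b << Lp.  One time step
composes, in order: the wall penalty displacement, the deterministic drift
(dt/kBT) D F, the Gaussian displacement with covariance 2 D dt, and a
projection back onto the rod-length constraint manifold:

    r(n+1) = P[ r(n) + chi_wall + (dt/kBT) D F + xi ].

The projection is realised as a Newton iteration on the rod-length
constraints (a linearised constraint projection followed by iterative
correction to relative tolerance 1e-10), alternated with wall clamping
until the chain both satisfies every rod length and sits inside the
channel.  Beads are treated as points at the walls: the channel dimension
is the accessible span of bead centres.

Hydrodynamics: the default is free draining (scalar Stokes mobility per
bead); a pairwise far-field Rotne-Prager-Yamakawa mobility is available
for the correlated-noise variant.  Equilibrium averages do not depend on
the mobility model, only relaxation time scales do.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .errors import ConfigurationError, StepRejectionError
from .theory import ChannelGeometry, ForceState
from .units import (
    DEFAULT_TEMPERATURE,
    DEFAULT_VISCOSITY,
    PA_S_TO_INTERNAL,
    bead_diffusion_coefficient,
    kBT,
)

#: relative rod-length tolerance enforced after every accepted step
ROD_TOL_REL = 1e-10

#: absolute wall-containment tolerance, nm
WALL_TOL = 1e-9

#: practical bead-count bound above which a configuration warning is issued
_N_WARN = 100_000


class Hydrodynamics(enum.Enum):
    FREE_DRAINING = "free_draining"
    PAIRWISE_MOBILITY = "pairwise_mobility"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GBRChain:
    """Discrete bead-rod chain state.

    ``positions``: (N, 3) bead centres in nm; ``b`` rod length; ``a`` bead
    radius; ``Lp`` persistence length.
    """

    positions: np.ndarray
    b: float
    a: float
    Lp: float

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ConfigurationError("positions must have shape (N, 3)")
        if self.N < 3:
            raise ConfigurationError(f"need at least 3 beads, got {self.N}")
        if not (self.b > 0 and self.a > 0 and self.Lp > 0):
            raise ConfigurationError("b, a and Lp must be positive")
        if self.b >= self.Lp:
            raise ConfigurationError(
                f"rod length b={self.b} must be well below Lp={self.Lp} for the "
                "discrete chain to represent a wormlike chain"
            )

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    @property
    def L(self) -> float:
        """Contour length (N-1) b, nm."""
        return (self.N - 1) * self.b

    def rod_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def max_rod_error(self) -> float:
        return float(np.max(np.abs(self.rod_lengths() - self.b)))

    def extension(self) -> float:
        """Axial end-to-end distance z_N - z_1, nm."""
        return float(self.positions[-1, 2] - self.positions[0, 2])

    def copy(self) -> "GBRChain":
        return GBRChain(self.positions.copy(), self.b, self.a, self.Lp)


@dataclass(frozen=True)
class IntegratorParams:
    """Brownian-dynamics integration parameters.

    ``dt`` in ps, ``temperature`` in K, ``viscosity`` in Pa s.
    """

    dt: float
    steps: int
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = DEFAULT_VISCOSITY
    hydrodynamics: Hydrodynamics = Hydrodynamics.FREE_DRAINING

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.steps < 0:
            raise ConfigurationError(f"steps must be >= 0, got {self.steps}")
        if not (0 <= int(self.seed) < 2**32):
            raise ConfigurationError("seed must fit in 32 bits")


@dataclass
class Trajectory:
    """Extension time series plus full provenance of the producing run."""

    extension: np.ndarray
    record_every: int
    params: IntegratorParams
    f_hat: float
    geometry: Optional[ChannelGeometry]
    chain_b: float
    chain_a: float
    chain_Lp: float
    chain_N: int
    max_rod_error: float = 0.0
    max_wall_violation: float = 0.0
    frames: Optional[np.ndarray] = None
    final_positions: Optional[np.ndarray] = None

    @property
    def L(self) -> float:
        return (self.chain_N - 1) * self.chain_b

    @property
    def seed(self) -> int:
        return self.params.seed

    def relative_extension(self) -> np.ndarray:
        return self.extension / self.L

    def metadata(self) -> dict:
        geom = None
        if self.geometry is not None:
            geom = {
                "Hh": self.geometry.Hh,
                "Hw": self.geometry.Hw,
                "kind": self.geometry.kind.value,
            }
        p = dataclasses.asdict(self.params)
        p["hydrodynamics"] = self.params.hydrodynamics.value
        return {
            "params": p,
            "f_hat": self.f_hat,
            "geometry": geom,
            "chain": {
                "N": self.chain_N,
                "b": self.chain_b,
                "a": self.chain_a,
                "Lp": self.chain_Lp,
                "L": self.L,
            },
            "record_every": self.record_every,
            "max_rod_error": self.max_rod_error,
            "max_wall_violation": self.max_wall_violation,
            "n_recorded": int(len(self.extension)),
        }


# ---------------------------------------------------------------------------
# chain construction and forces
# ---------------------------------------------------------------------------


def init_straight_chain(
    N: int, b: float, a: float = 1.85, Lp: float = 50.0, axis: str = "z"
) -> GBRChain:
    """Straight chain along the channel axis, centred in the cross-section."""
    if N < 3:
        raise ConfigurationError(f"need at least 3 beads, got {N}")
    if N > _N_WARN:
        warnings.warn(f"chain of {N} beads is beyond practical bounds", stacklevel=2)
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise ConfigurationError(f"axis must be x, y or z, got {axis!r}")
    pos = np.zeros((N, 3))
    coords = b * np.arange(N, dtype=np.float64)
    pos[:, ax] = coords - coords.mean()
    return GBRChain(pos, b=b, a=a, Lp=Lp)


def bending_forces(chain: GBRChain, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Bending forces (pN) on each bead; sums to zero force and torque."""
    F = np.empty_like(chain.positions)
    kappa = kBT(temperature) * chain.Lp / chain.b
    _kernels.bending_forces_kernel(chain.positions, kappa, F)
    if np.isnan(F[0, 0]):
        raise FloatingPointError("degenerate (zero-length) bond in bending forces")
    return F


def external_forces(chain: GBRChain, fs: float) -> np.ndarray:
    """Tension +-fs z on the end beads (pN); net force on the chain is zero."""
    if fs < 0:
        raise ConfigurationError(f"fs must be non-negative, got {fs}")
    F = np.zeros_like(chain.positions)
    F[0, 2] = -fs
    F[-1, 2] = fs
    return F


def diffusion_matrix(chain: GBRChain, params: IntegratorParams) -> np.ndarray:
    """Translational diffusion matrix D (3N x 3N), nm^2/ps.

    Free draining: D0 I with the Stokes-Einstein D0.  Pairwise mobility:
    Rotne-Prager-Yamakawa far-field tensor (with the overlap-regularised
    branch for r < 2a), symmetric positive definite for non-overlapping
    beads.
    """
    N = chain.N
    D0 = bead_diffusion_coefficient(chain.a, params.temperature, params.viscosity)
    if params.hydrodynamics is Hydrodynamics.FREE_DRAINING:
        return np.eye(3 * N) * D0
    a = chain.a
    eta = params.viscosity * PA_S_TO_INTERNAL
    kbt = kBT(params.temperature)
    pref = kbt / (8.0 * math.pi * eta)
    D = np.zeros((3 * N, 3 * N))
    pos = chain.positions
    for i in range(N):
        D[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = D0 * np.eye(3)
        for j in range(i + 1, N):
            rij = pos[j] - pos[i]
            r = float(np.linalg.norm(rij))
            if r <= 1e-12:
                raise FloatingPointError("coincident beads in pairwise mobility")
            e = rij / r
            ee = np.outer(e, e)
            if r >= 2 * a:
                block = (pref / r) * (
                    (1.0 + 2.0 * a * a / (3.0 * r * r)) * np.eye(3)
                    + (1.0 - 2.0 * a * a / (r * r)) * ee
                )
            else:
                # overlap-regularised branch keeps D positive definite
                block = (kbt / (6.0 * math.pi * eta * a)) * (
                    (1.0 - 9.0 * r / (32.0 * a)) * np.eye(3) + (3.0 * r / (32.0 * a)) * ee
                )
            D[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            D[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
    return D


def random_displacements(D: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian displacement with zero mean and covariance 2 D dt.

    Realised through the Cholesky factor of D; deterministic for a given
    generator state.
    """
    n = D.shape[0]
    try:
        Lc = np.linalg.cholesky(D)
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError("diffusion matrix is not positive definite") from exc
    return math.sqrt(2.0 * dt) * (Lc @ rng.standard_normal(n))


def wall_penalty(positions: np.ndarray, geom: Optional[ChannelGeometry]) -> np.ndarray:
    """Penalty displacement returning outside bead centres to the nearest
    wall plane, per coordinate; z is never modified."""
    chi = np.zeros_like(positions)
    if geom is None:
        return chi
    half_w, half_h = geom.Hw / 2.0, geom.Hh / 2.0
    x, y = positions[:, 0], positions[:, 1]
    chi[:, 0] = np.clip(x, -half_w, half_w) - x
    chi[:, 1] = np.clip(y, -half_h, half_h) - y
    return chi


def constraint_projection(
    positions: np.ndarray,
    b: float,
    tol_rel: float = ROD_TOL_REL,
    max_newton: int = 50,
) -> np.ndarray:
    """Project bead positions onto the rod-length constraint manifold.

    Linearised multiplier solve about the current bonds, iterated
    (Newton) until every rod length is within ``tol_rel * b``.  Positions
    already on the manifold are returned unchanged (to round-off).
    """
    r = np.ascontiguousarray(positions, dtype=np.float64).copy()
    M = r.shape[0] - 1
    scratch = (np.zeros(M), np.zeros(M), np.zeros(M), np.zeros((M, 3)))
    err = _kernels.newton_shake_kernel(r, b, tol_rel * b, max_newton, *scratch)
    if err < 0:
        raise StepRejectionError(
            "constraint projection failed to converge; reduce the time step"
        )
    return r


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def step(
    chain: GBRChain,
    geom: Optional[ChannelGeometry],
    force: ForceState,
    params: IntegratorParams,
    rng: np.random.Generator,
) -> GBRChain:
    """One Brownian-dynamics step (generic path, any mobility model).

    Returns a new chain; raises ``StepRejectionError`` if the constraint
    projection cannot converge.
    """
    kbt = kBT(params.temperature)
    fs = force.physical(chain.Lp, params.temperature)
    F = bending_forces(chain, params.temperature) + external_forces(chain, fs)
    D = diffusion_matrix(chain, params)
    xi = random_displacements(D, params.dt, rng).reshape(-1, 3)
    drift = (params.dt / kbt) * (D @ F.ravel()).reshape(-1, 3)
    pos = chain.positions + wall_penalty(chain.positions, geom) + drift + xi

    M = chain.N - 1
    scratch = (np.zeros(M), np.zeros(M), np.zeros(M), np.zeros((M, 3)))
    half_w = geom.Hw / 2.0 if geom is not None else -1.0
    half_h = geom.Hh / 2.0 if geom is not None else -1.0
    rod_err, viol = _kernels.project_kernel(
        pos, chain.b, half_w, half_h, ROD_TOL_REL * chain.b, WALL_TOL, *scratch
    )
    if rod_err < 0:
        raise StepRejectionError(
            "constraint projection failed to converge; reduce the time step"
        )
    return GBRChain(pos, chain.b, chain.a, chain.Lp)


def run_trajectory(
    chain0: GBRChain,
    geom: Optional[ChannelGeometry],
    force: ForceState,
    params: IntegratorParams,
    record_every: int = 1,
    frame_every: int = 0,
    log_every: int = 0,
) -> Trajectory:
    """Integrate a chain and record the axial end-to-end extension.

    Free-draining runs use a fused compiled loop; the pairwise-mobility
    model steps through the generic path.  The trajectory carries its full
    provenance (seed, parameters, geometry) and the worst rod-length and
    containment errors seen over all accepted steps.
    """
    if record_every < 1:
        raise ConfigurationError("record_every must be >= 1")
    n_rec = 0 if params.steps == 0 else (params.steps + record_every - 1) // record_every
    chain = chain0.copy()
    fs = force.physical(chain.Lp, params.temperature)

    if params.hydrodynamics is Hydrodynamics.FREE_DRAINING:
        ext = np.zeros(max(n_rec, 1))
        n_fr = 0 if frame_every <= 0 else (params.steps + frame_every - 1) // frame_every
        frames = np.zeros((max(n_fr, 1), chain.N, 3))
        D0 = bead_diffusion_coefficient(chain.a, params.temperature, params.viscosity)
        kappa = kBT(params.temperature) * chain.Lp / chain.b
        half_w = geom.Hw / 2.0 if geom is not None else -1.0
        half_h = geom.Hh / 2.0 if geom is not None else -1.0
        max_rod, max_wall, got, gotf = _kernels.run_free_draining_kernel(
            chain.positions,
            chain.b,
            kappa,
            fs,
            half_w,
            half_h,
            D0,
            kBT(params.temperature),
            params.dt,
            params.steps,
            int(params.seed),
            record_every,
            ext,
            frames,
            frame_every if frame_every > 0 else 0,
            ROD_TOL_REL * chain.b,
            WALL_TOL,
        )
        if max_rod < 0:
            raise StepRejectionError(
                f"constraint projection failed at step {int(-max_wall)}; "
                "reduce the time step"
            )
        return Trajectory(
            extension=ext[:got],
            record_every=record_every,
            params=params,
            f_hat=force.f_hat,
            geometry=geom,
            chain_b=chain.b,
            chain_a=chain.a,
            chain_Lp=chain.Lp,
            chain_N=chain.N,
            max_rod_error=max_rod,
            max_wall_violation=max_wall,
            frames=frames[:gotf] if frame_every > 0 else None,
            final_positions=chain.positions.copy(),
        )

    # generic (pairwise-mobility) path
    rng = np.random.default_rng(params.seed)
    ext_list = []
    frames_list = []
    max_rod = 0.0
    max_wall = 0.0
    for n in range(params.steps):
        chain = step(chain, geom, force, params, rng)
        max_rod = max(max_rod, chain.max_rod_error())
        if geom is not None:
            viol = _kernels.wall_violation_kernel(
                chain.positions, geom.Hw / 2.0, geom.Hh / 2.0
            )
            max_wall = max(max_wall, viol)
        if n % record_every == 0:
            ext_list.append(chain.extension())
        if frame_every > 0 and n % frame_every == 0:
            frames_list.append(chain.positions.copy())
        if log_every and n % log_every == 0:
            print(f"step {n}/{params.steps} extension {chain.extension():.2f} nm")
    return Trajectory(
        extension=np.asarray(ext_list),
        record_every=record_every,
        params=params,
        f_hat=force.f_hat,
        geometry=geom,
        chain_b=chain.b,
        chain_a=chain.a,
        chain_Lp=chain.Lp,
        chain_N=chain.N,
        max_rod_error=max_rod,
        max_wall_violation=max_wall,
        frames=np.asarray(frames_list) if frames_list else None,
        final_positions=chain.positions.copy(),
    )


def run_ensemble(
    chain0: GBRChain,
    geom: Optional[ChannelGeometry],
    force: ForceState,
    params: IntegratorParams,
    n_traj: int,
    record_every: int = 1,
    seed_stride: int = 1,
    initial_chains: "Optional[list[GBRChain]]" = None,
) -> "list[Trajectory]":
    """Independent trajectories with seeds ``seed + k * seed_stride``.

    ``initial_chains`` optionally supplies a distinct starting
    configuration per trajectory (e.g. equilibrium draws).
    """
    out = []
    for k in range(n_traj):
        pk = dataclasses.replace(params, seed=params.seed + k * seed_stride)
        start = initial_chains[k] if initial_chains is not None else chain0
        out.append(run_trajectory(start, geom, force, pk, record_every=record_every))
    return out
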