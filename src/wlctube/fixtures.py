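"""Synthetic equilibrium configurations and closed-form oracles.

Everything here is exact at the level of the discrete wormlike chain and
independent of the Brownian-dynamics integrator, so these generators and
formulas serve as references against which the simulator is validated:

* ``sample_equilibrium_wlc`` draws a free discrete wormlike chain from its
  Boltzmann distribution exactly (each joint angle from the density
  proportional to exp((Lp/b) cos theta) on the sphere, uniform azimuth).
* ``sample_stretched_wlc`` draws a discrete wormlike chain under axial
  tension exactly, by backward transfer-operator messages in cos(theta)
  (the tension field keeps messages azimuthally symmetric) followed by
  forward sampling with von Mises-Fisher proposals.
* ``stretched_deficit_exact`` evaluates the exact mean extension deficit
  of the finite discrete chain under tension by transfer-matrix
  quadrature -- the free-end, finite-length analogue of the asymptotic
  1/(2 sqrt(f^)) law.
* closed forms for the free-chain mean-square end-to-end distance and the
  per-joint tangent correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline
from scipy.special import ive

from .gbr import GBRChain


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def langevin(x: float) -> float:
    """coth(x) - 1/x, the mean joint cosine of the discrete chain at stiffness x."""
    if x == 0:
        return 0.0
    if x > 500:
        return 1.0 - 1.0 / x
    return 1.0 / math.tanh(x) - 1.0 / x


def tangent_correlation(Lp: float, b: float, lag: int = 1) -> float:
    """Exact <u_i . u_{i+lag}> of the free discrete wormlike chain."""
    return langevin(Lp / b) ** lag


def wlc_mean_square_end_to_end(L: float, Lp: float) -> float:
    """Continuous WLC closed form <R^2> = 2 Lp L - 2 Lp^2 (1 - exp(-L/Lp))."""
    return 2.0 * Lp * L - 2.0 * Lp**2 * (1.0 - math.exp(-L / Lp))


def discrete_mean_square_end_to_end(N: int, b: float, Lp: float) -> float:
    """Exact <R^2> of the free discrete chain via the telescoping
    correlation sum: b^2 [M (1+g)/(1-g) - 2g(1-g^M)/(1-g)^2], g = <u.u'>."""
    M = N - 1
    g = langevin(Lp / b)
    if g == 0.0:
        return M * b * b
    return b * b * (M * (1 + g) / (1 - g) - 2 * g * (1 - g**M) / (1 - g) ** 2)


# ---------------------------------------------------------------------------
# free-chain sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureChainSampler:
    """Parameters of the synthetic equilibrium chain generator."""

    Lp: float
    b: float
    N: int
    seed: int = 0
    a: float = 1.85

    def __post_init__(self):
        if not (self.Lp > 0 and self.b > 0):
            raise ValueError("Lp and b must be positive")
        if self.N < 3:
            raise ValueError(f"need at least 3 beads, got {self.N}")


def _vmf_cos(kappa: float, rng: np.random.Generator):
    """Exact draw of cos(theta) from the density prop. to exp(kappa cos theta)."""
    U = rng.random()
    if kappa < 1e-12:
        return 2.0 * U - 1.0
    # inverse CDF of the exponential-tilted uniform measure on [-1, 1]
    return 1.0 + np.log(U + (1.0 - U) * np.exp(-2.0 * kappa)) / kappa


def _rotate_about(u: np.ndarray, ct: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle arccos(ct), azimuth phi, about axis u."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    helper = (
        np.array([1.0, 0.0, 0.0]) if abs(u[2]) > 0.5 else np.array([0.0, 0.0, 1.0])
    )
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    v = ct * u + st * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return v / np.linalg.norm(v)


def sample_equilibrium_wlc(
    sampler: FixtureChainSampler, rng: np.random.Generator | None = None
) -> GBRChain:
    """Exact Boltzmann draw of a free discrete wormlike chain.

    Bond directions form a Markov chain: each joint angle has density
    proportional to exp((Lp/b) cos theta) with uniform azimuth about the
    previous bond.  Rod constraints hold exactly by construction.
    """
    rng = np.random.default_rng(sampler.seed) if rng is None else rng
    kappa = sampler.Lp / sampler.b
    M = sampler.N - 1
    u = np.zeros((M, 3))
    u[0] = (0.0, 0.0, 1.0)
    for j in range(1, M):
        ct = _vmf_cos(kappa, rng)
        u[j] = _rotate_about(u[j - 1], ct, 2.0 * math.pi * rng.random())
    pos = np.zeros((sampler.N, 3))
    pos[1:] = np.cumsum(sampler.b * u, axis=0)
    pos -= pos.mean(axis=0)
    return GBRChain(pos, b=sampler.b, a=sampler.a, Lp=sampler.Lp)


# ---------------------------------------------------------------------------
# stretched-chain transfer matrix
# ---------------------------------------------------------------------------


def _transfer_matrix(kappa: float, nq: int):
    """Azimuth-integrated bond-to-bond transfer operator on Gauss nodes.

    T(c, c') = I0(kappa s s') exp(kappa (c c' + s s')) scaled by exp(-kappa)
    to stay in range; the constant rescaling drops out of all averages.
    """
    c, w = leggauss(nq)
    s = np.sqrt(1.0 - c * c)
    T = ive(0, kappa * np.outer(s, s)) * np.exp(
        kappa * (np.outer(c, c) + np.outer(s, s)) - kappa
    )
    return c, w, T


def stretched_deficit_exact(
    N: int, b: float, Lp: float, f_hat: float, nq: int = 200
) -> float:
    """Exact extension deficit 1 - <z>/L of the discrete chain under tension.

    Free ends, finite length: the log-partition-function derivative with
    respect to the reduced field h = f^ b / Lp, evaluated by transfer-matrix
    quadrature.  Approaches 1/(2 sqrt(f^)) as L and Lp/b grow.
    """
    kappa = Lp / b
    M = N - 1
    c, w, T = _transfer_matrix(kappa, nq)

    def logZ(h: float) -> float:
        v = np.exp(h * c)
        log = 0.0
        for _ in range(M - 1):
            v = np.exp(h * c) * (T @ (w * v))
            nrm = v.max()
            v /= nrm
            log += math.log(nrm)
        return log + math.log(float(np.sum(w * v)))

    h = f_hat * b / Lp
    dh = 1e-5 * max(1.0, h)
    dlog = (logZ(h + dh) - logZ(h - dh)) / (2.0 * dh)
    return 1.0 - dlog / M


def sample_stretched_wlc(
    sampler: FixtureChainSampler,
    f_hat: float,
    rng: np.random.Generator | None = None,
    nq: int = 120,
) -> GBRChain:
    """Exact Boltzmann draw of a discrete wormlike chain under axial tension.

    Backward messages over bond polar angles (exact by azimuthal symmetry
    of the tension field), then forward sampling of each bond direction
    with a von Mises-Fisher proposal about the previous bond accepted
    against the field-and-message weight.
    """
    rng = np.random.default_rng(sampler.seed) if rng is None else rng
    kappa = sampler.Lp / sampler.b
    h = f_hat * sampler.b / sampler.Lp
    M = sampler.N - 1
    c, w, T = _transfer_matrix(kappa, nq)

    # messages[j](c) = integral over bonds j+2..M of the remaining weight
    messages = [np.ones(nq)]
    v = np.ones(nq)
    for _ in range(M - 1):
        v = T @ (w * np.exp(h * c) * v)
        v = v / v.max()
        messages.append(v.copy())
    messages.reverse()
    splines = [CubicSpline(c, m) for m in messages]

    fine = np.linspace(-1.0, 1.0, 2001)
    u = np.zeros((M, 3))
    # first bond from its exact marginal via inverse CDF on a fine grid
    dens = np.exp(h * fine) * np.clip(splines[0](fine), 0.0, None)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    c1 = float(np.interp(rng.random(), cdf, fine))
    phi = 2.0 * math.pi * rng.random()
    s1 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    u[0] = (s1 * math.cos(phi), s1 * math.sin(phi), c1)
    for j in range(1, M):
        spl = splines[j]
        weights = np.exp(h * fine) * np.clip(spl(fine), 0.0, None)
        bound = float(weights.max())
        while True:
            ct = _vmf_cos(kappa, rng)
            cand = _rotate_about(u[j - 1], ct, 2.0 * math.pi * rng.random())
            wgt = math.exp(h * cand[2]) * max(float(spl(cand[2])), 0.0)
            if rng.random() * bound <= wgt:
                u[j] = cand
                break
    pos = np.zeros((sampler.N, 3))
    pos[1:] = np.cumsum(sampler.b * u, axis=0)
    pos -= pos.mean(axis=0)
    return GBRChain(pos, b=sampler.b, a=sampler.a, Lp=sampler.Lp)
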