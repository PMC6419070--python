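"""Closed-form deflection theory for stiff chains in rectangular channels.

A wormlike chain with persistence length ``Lp`` confined to a channel much
narrower than ``Lp`` bounces between the walls with a characteristic contour
distance -- the Odijk deflection length.  Two classical deflection lengths
are in use, one calibrated on the confinement free energy and one on the
average axial extension; their prefactors (``A_box`` and ``alpha_box``)
differ by an order of magnitude and the extension form is not even
consistent with the slit limit.  This module implements both classical
forms and the modified deflection length

    lambda_m / Lp = -(1/theta) * ln[1 - theta/A_box * (Hh^-2/3 + Hw^-2/3)^-1],

with channel sides measured in units of ``Lp`` and
``theta = 8 * A_box * alpha_box``, which reproduces the free-energy form in
the tight-channel limit while remaining accurate over a much wider range of
channel sizes, and which yields compact force-confinement-extension
relations without adjustable parameters.

All functions are pure; lengths carry the unit of ``Lp`` (nm throughout the
package) and energies are measured in kBT.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidityError
from .units import DEFAULT_TEMPERATURE, fhat_from_force, force_from_fhat


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TheoryConstants:
    """Dimensionless prefactors of the rectangular-channel deflection laws.

    ``A_box`` multiplies the confinement free energy per deflection segment,
    ``alpha_box`` the extension deficit.  ``theta = 8 A_box alpha_box`` is
    the combined constant entering the modified deflection length (the
    effective-segment contour factor and its reciprocal are absorbed into
    the closed forms and need no separate storage).
    """

    A_box: float = 1.1032
    alpha_box: float = 0.09143
    theta: float = field(init=False)

    def __post_init__(self):
        if not (self.A_box > 0 and self.alpha_box > 0):
            raise ValueError(
                f"prefactors must be positive (A_box={self.A_box}, alpha_box={self.alpha_box})"
            )
        object.__setattr__(self, "theta", 8.0 * self.A_box * self.alpha_box)


#: Most precise prefactor determination (eigenvalue method); package default.
DEFAULT_CONSTANTS = TheoryConstants()

#: Alternative literature determinations of the same prefactors.
CONSTANT_SETS = {
    "chen": TheoryConstants(1.1032, 0.09143),
    "burkhardt": TheoryConstants(1.1038, 0.09137),
}


class ChannelKind(enum.Enum):
    RECTANGULAR = "rectangular"
    SQUARE = "square"
    SLIT = "slit"


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel cross-section: height ``Hh`` (y), width ``Hw`` (x).

    The channel axis is z.  A slit is represented by a very large but finite
    width (``slit_ratio`` times the height by default), mirroring the
    numerical practice of treating a slit as an extreme rectangle.
    """

    Hh: float
    Hw: float
    kind: ChannelKind = ChannelKind.RECTANGULAR

    #: minimum aspect ratio for a geometry declared as a slit
    SLIT_MIN_RATIO = 100.0

    def __post_init__(self):
        if not (self.Hh > 0 and self.Hw > 0):
            raise ValueError(f"channel sides must be positive, got Hh={self.Hh}, Hw={self.Hw}")
        if self.kind is ChannelKind.SQUARE and self.Hh != self.Hw:
            raise ValueError("square channel requires Hh == Hw")
        if self.kind is ChannelKind.SLIT and self.Hw / self.Hh < self.SLIT_MIN_RATIO:
            raise ValueError(
                f"slit requires Hw/Hh >= {self.SLIT_MIN_RATIO}, got {self.Hw / self.Hh:g}"
            )

    @classmethod
    def square(cls, H: float) -> "ChannelGeometry":
        return cls(H, H, ChannelKind.SQUARE)

    @classmethod
    def rectangular(cls, Hh: float, Hw: float) -> "ChannelGeometry":
        return cls(Hh, Hw, ChannelKind.RECTANGULAR)

    @classmethod
    def slit(cls, H: float, width: Optional[float] = None) -> "ChannelGeometry":
        """Slit of height ``H`` modelled as a very wide rectangle.

        ``width`` defaults to ``1000 * H``; pass e.g. ``1000 * Lp`` to follow
        the convention of quoting the slit width in persistence lengths.
        """
        return cls(H, 1000.0 * H if width is None else width, ChannelKind.SLIT)

    @property
    def beta(self) -> float:
        """Aspect ratio Hh/Hw."""
        return self.Hh / self.Hw


@dataclass(frozen=True)
class ChainSpec:
    """Continuous wormlike chain: persistence length and contour length (nm)."""

    Lp: float
    L: float

    def __post_init__(self):
        if not (self.Lp > 0 and self.L > 0):
            raise ValueError(f"Lp and L must be positive, got Lp={self.Lp}, L={self.L}")


@dataclass(frozen=True)
class ForceState:
    """Axial tension: dimensionless ``f_hat = fs Lp / kBT`` (and optionally pN)."""

    f_hat: float
    fs: Optional[float] = None

    def __post_init__(self):
        if self.f_hat < 0:
            raise ValueError(f"f_hat must be non-negative, got {self.f_hat}")

    @classmethod
    def from_physical(
        cls, fs: float, Lp: float, temperature: float = DEFAULT_TEMPERATURE
    ) -> "ForceState":
        return cls(f_hat=fhat_from_force(fs, Lp, temperature), fs=fs)

    def physical(self, Lp: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
        """Force in pN."""
        if self.fs is not None:
            return self.fs
        return force_from_fhat(self.f_hat, Lp, temperature)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _hhat(geom: ChannelGeometry, chain: ChainSpec) -> tuple[float, float]:
    return geom.Hh / chain.Lp, geom.Hw / chain.Lp

def _inv23_sum(geom: ChannelGeometry, chain: ChainSpec) -> float:
    """Hh^-2/3 + Hw^-2/3 with sides in units of Lp."""
    hh, hw = _hhat(geom, chain)
    return hh ** (-2.0 / 3.0) + hw ** (-2.0 / 3.0)


def log_argument(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Argument ``1 - eps`` of the modified-deflection logarithm."""
    eps = (const.theta / const.A_box) / _inv23_sum(geom, chain)
    return 1.0 - eps


def validity_check(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> tuple[bool, dict]:
    """Is the geometry inside the domain of the modified deflection length?

    True iff ``Hh^-2/3 + Hw^-2/3 > theta / A_box`` (sides in units of Lp).
    The diagnostic reports both sides of the bound and the margin.
    """
    s = _inv23_sum(geom, chain)
    bound = const.theta / const.A_box
    return s > bound, {
        "inv23_sum": s,
        "bound": bound,
        "margin": s - bound,
        "log_argument": 1.0 - bound / s,
    }


def _require_valid(geom, chain, const):
    ok, diag = validity_check(geom, chain, const)
    if not ok:
        raise ValidityError(
            "channel too wide for the deflection picture: requires "
            f"(Hh/Lp)^-2/3 + (Hw/Lp)^-2/3 > theta/A_box = {diag['bound']:.5f}, "
            f"got {diag['inv23_sum']:.5f} (margin {diag['margin']:.5f})"
        )


# ---------------------------------------------------------------------------
# deflection lengths and free energies
# ---------------------------------------------------------------------------


def classical_deflection_fe(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Classical free-energy deflection length, nm.

    lambda_fe = (1/A_box) Lp^(1/3) (Hh^-2/3 + Hw^-2/3)^-1.
    """
    return chain.Lp / (const.A_box * _inv23_sum(geom, chain))


def classical_deflection_ext(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Classical extension deflection length, nm.

    lambda_ext = 2 alpha_box Lp^(1/3) (Hh^2/3 + Hw^2/3).  Note this grows
    without bound in the slit limit Hw -> infinity, which is the classical
    inconsistency the modified deflection length resolves.
    """
    hh, hw = _hhat(geom, chain)
    return 2.0 * const.alpha_box * chain.Lp * (hh ** (2.0 / 3.0) + hw ** (2.0 / 3.0))


def modified_deflection(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Modified deflection length lambda_m, nm.

    Always exceeds the classical ``lambda_fe`` (since -ln(1-x) > x) and
    reduces to it as the channel narrows.
    """
    _require_valid(geom, chain, const)
    return -(chain.Lp / const.theta) * math.log(log_argument(geom, chain, const))


def free_energy_classical(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Classical confinement free energy, units of kBT: F = L / lambda_fe.

    Equals ``A_box L Lp^(-1/3) (Hh^-2/3 + Hw^-2/3)``; for a rectangle this is
    the sum of two independent slit contributions.
    """
    return chain.L / classical_deflection_fe(geom, chain, const)


def free_energy_modified(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Confinement free energy from the modified deflection length, kBT.

    F = L / lambda_m = -theta (L/Lp) / ln[1 - theta/A_box (...)^-1];
    extensive in L by construction.
    """
    return chain.L / modified_deflection(geom, chain, const)


# ---------------------------------------------------------------------------
# extension relations
# ---------------------------------------------------------------------------


def wlc_tangent_projection(s_gap: float, chain: ChainSpec) -> float:
    """<r(s2) . u(s1)> for a free wormlike chain, nm.

    Projection of the end-to-end vector of a segment of contour length
    ``s_gap`` onto the tangent at one end: Lp (1 - exp(-s_gap/Lp)).
    """
    if s_gap < 0:
        raise ValueError(f"s_gap must be non-negative, got {s_gap}")
    return chain.Lp * (1.0 - math.exp(-s_gap / chain.Lp))


def extension_unstretched_classical(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Classical zero-force extension deficit 1 - R_par/L.

    alpha_box (Hh^2/3 + Hw^2/3) with sides in units of Lp.  Meaningful for
    tubes with both sides well below Lp; for a true slit the width term
    diverges, so this form is restricted to tube-like geometries.
    """
    hh, hw = _hhat(geom, chain)
    return const.alpha_box * (hh ** (2.0 / 3.0) + hw ** (2.0 / 3.0))


def extension_unstretched_modified(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> float:
    """Zero-force extension deficit from the modified deflection length.

    R_par/L = Lp/(theta lambda_m) (1 - exp(-theta lambda_m / Lp)), which
    reduces algebraically to eps / (-ln(1-eps)) with
    eps = theta/A_box (Hh^-2/3+Hw^-2/3)^-1; the small-eps limit is
    4 alpha_box (Hh^-2/3 + Hw^-2/3)^-1.
    """
    _require_valid(geom, chain, const)
    lam = modified_deflection(geom, chain, const)
    x = const.theta * lam / chain.Lp  # == -ln(1 - eps)
    rel = (1.0 - math.exp(-x)) / x
    return 1.0 - rel


def aspect_ratio_factor(beta: float) -> float:
    """phi(beta) = (1/4) (beta^1/3 + beta^-1/3)^2.

    Ratio by which the classical zero-force deficit exceeds the modified one
    for a rectangle of aspect ratio beta = Hh/Hw in the tight limit.
    Symmetric under beta -> 1/beta, minimum phi(1) = 1, divergent as
    beta -> 0 or infinity.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    t = beta ** (1.0 / 3.0)
    return 0.25 * (t + 1.0 / t) ** 2


# ---------------------------------------------------------------------------
# force-extension
# ---------------------------------------------------------------------------


def force_extension_unconfined(force: ForceState) -> float:
    """Strong-stretching deficit of an unconfined wormlike chain: 1/(2 sqrt(f^))."""
    if force.f_hat <= 0:
        raise ValueError(
            "the unconfined strong-stretching relation diverges at zero force; "
            "use the confinement branch instead"
        )
    return 0.5 / math.sqrt(force.f_hat)


def effective_confinement_force(
    geom: ChannelGeometry, chain: ChainSpec, const: TheoryConstants = DEFAULT_CONSTANTS
) -> ForceState:
    """Tension equivalent to the confinement, from the modified deflection length.

    f^_c = {-ln[1 - theta/A_box (...)^-1]}^-2 = (Lp / (theta lambda_m))^2.
    """
    _require_valid(geom, chain, const)
    x = -math.log(log_argument(geom, chain, const))
    return ForceState(f_hat=x ** (-2.0))


def effective_confinement_force_classical(
    geom: ChannelGeometry,
    chain: ChainSpec,
    const: TheoryConstants = DEFAULT_CONSTANTS,
    which: str = "fe",
) -> ForceState:
    """Classical confinement tension f^_c = Lp^2 / lambda^2 with lambda the
    classical free-energy (``which='fe'``) or extension (``which='ext'``)
    deflection length."""
    if which == "fe":
        lam = classical_deflection_fe(geom, chain, const)
    elif which == "ext":
        lam = classical_deflection_ext(geom, chain, const)
    else:
        raise ValueError(f"which must be 'fe' or 'ext', got {which!r}")
    return ForceState(f_hat=(chain.Lp / lam) ** 2)


def force_confinement_extension(
    geom: ChannelGeometry,
    chain: ChainSpec,
    force: ForceState,
    const: TheoryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Extension deficit under combined confinement and tension.

    1 - R_par/L = (1/2) [f^ + {-ln[1 - theta/A_box (...)^-1]}^-2]^(-1/2).

    At zero force this reduces to half the modified log-term (the tight-limit
    zero-force deficit); at large force it approaches the unconfined
    strong-stretching law.
    """
    _require_valid(geom, chain, const)
    fc = effective_confinement_force(geom, chain, const).f_hat
    return 0.5 / math.sqrt(force.f_hat + fc)


def force_confinement_extension_classical(
    geom: ChannelGeometry,
    chain: ChainSpec,
    force: ForceState,
    const: TheoryConstants = DEFAULT_CONSTANTS,
    which: str = "fe",
) -> float:
    """Deficit from the additive effective-force relation with a classical
    deflection length: 1 - R_par/L = (1/2) (f^ + Lp^2/lambda^2)^(-1/2)."""
    fc = effective_confinement_force_classical(geom, chain, const, which).f_hat
    return 0.5 / math.sqrt(force.f_hat + fc)
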