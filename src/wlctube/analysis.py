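"""From raw extension series to mean extensions and theory comparisons.

The estimation protocol is two-stage: within each trajectory the
extension is time-averaged after an equilibration (burn-in) window; the
ensemble mean and its standard error are then taken across independent
trajectories.  Trajectories -- not time samples -- are the independent
units, because extension series are strongly autocorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from . import theory as th
from .gbr import Trajectory

#: fraction of a series always discarded, even when the detector says less
BURN_IN_FLOOR = 0.10

#: smallest series length the equilibration detector accepts
MIN_SERIES = 20


# ---------------------------------------------------------------------------
# equilibration detection
# ---------------------------------------------------------------------------


def integrated_autocorrelation_time(x: np.ndarray, max_lag_frac: float = 0.1) -> float:
    """Integrated autocorrelation time by the initial-positive-sequence rule.

    tau = 1 + 2 sum_k rho_k over leading positive autocorrelations, capped
    at ``max_lag_frac`` of the series; 1 for white noise.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var <= 0:
        return 1.0
    tau = 1.0
    for k in range(1, max(2, int(max_lag_frac * n))):
        rho = float(xc[:-k] @ xc[k:]) / ((n - k) * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return tau


def detect_equilibration(series: np.ndarray, n_blocks: int = 20) -> tuple[int, bool]:
    """First index from which the series mean has stabilised.

    The target is the mean of the final half.  Scanning block boundaries
    from the start, the burn-in is the first index i such that the forward
    mean taken from every later checkpoint stays within an error band of
    the target; the band combines the target standard error with the
    overlap-corrected standard error of each forward mean (both inflated
    by the integrated autocorrelation time of the final half) and a
    three-sigma multiplier so that an equilibrated series is not rejected
    by the fluctuation of a single checkpoint.  Returns
    (burn_in, equilibrated); ``equilibrated`` is False when no checkpoint
    in the first half qualifies.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < MIN_SERIES:
        raise AnalysisError(f"series of length {n} too short to analyse (< {MIN_SERIES})")
    half = n // 2
    tail = x[half:]
    target = tail.mean()
    sigma = tail.std(ddof=1)
    tau = integrated_autocorrelation_time(tail)
    n_t = len(tail)
    se_target = sigma * np.sqrt(tau / n_t)

    # a series still drifting inside its final half never equilibrated:
    # compare the two halves of the tail with their own uncertainties
    a, b = tail[: n_t // 2], tail[n_t // 2 :]
    se_a = a.std(ddof=1) * np.sqrt(integrated_autocorrelation_time(a) / len(a))
    se_b = b.std(ddof=1) * np.sqrt(integrated_autocorrelation_time(b) / len(b))
    eps = 1e-12 * max(1.0, abs(target))
    if abs(a.mean() - b.mean()) > 3.0 * (se_a + se_b) + eps:
        return half, False

    suffix = np.cumsum(x[::-1])[::-1] / np.arange(n, 0, -1)
    block = max(1, n // n_blocks)
    checkpoints = np.arange(0, n - block + 1, block)

    # overlap-corrected sd of suffix-mean minus target: the two means are
    # nested, Var = ((m1-m2)/m1)^2 sigma^2 (1/(m1-m2) + 1/m2) with m1, m2
    # the larger/smaller counts
    checkpoints = checkpoints[(n - checkpoints) >= 2 * block]
    cnt = n - checkpoints
    m1 = np.maximum(cnt, n_t)
    m2 = np.minimum(cnt, n_t)
    diff = np.maximum(m1 - m2, 1)
    sd_overlap = (diff / m1) * sigma * np.sqrt(tau) * np.sqrt(1.0 / diff + 1.0 / m2)
    band = 3.0 * (se_target + sd_overlap) + eps

    ok = np.abs(suffix[checkpoints] - target) <= band
    stays = np.logical_and.accumulate(ok[::-1])[::-1]
    passing = np.nonzero(stays)[0]
    if len(passing) == 0 or checkpoints[passing[0]] > half:
        return half, False
    return int(checkpoints[passing[0]]), True


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------


@dataclass
class ExtensionEstimate:
    """Ensemble-averaged relative extension R_par / L with uncertainty."""

    mean_rel_extension: float
    std_error: float
    n_traj: int
    burn_in_steps: int
    equilibrated: bool

    def __post_init__(self):
        if not (-1e-9 <= self.mean_rel_extension <= 1.0 + 1e-6):
            raise AnalysisError(
                f"relative extension {self.mean_rel_extension} outside [0, 1]"
            )
        if self.std_error < 0:
            raise AnalysisError("standard error must be non-negative")

    @property
    def deficit(self) -> float:
        """1 - R_par/L."""
        return 1.0 - self.mean_rel_extension


def average_extension(
    trajectories: Sequence[Trajectory],
    L: Optional[float] = None,
    burn_in_floor: float = BURN_IN_FLOOR,
) -> ExtensionEstimate:
    """Two-stage average of the relative extension over an ensemble.

    Per trajectory: equilibration detection (never less than
    ``burn_in_floor`` of the series), then a time mean; across
    trajectories: mean and standard error from the scatter.
    Unequilibrated trajectories are dropped with a warning; fewer than two
    usable trajectories is an error.
    """
    if len(trajectories) < 2:
        raise AnalysisError("need at least 2 trajectories for an ensemble estimate")
    means = []
    burns = []
    for k, traj in enumerate(trajectories):
        x = traj.extension / (L if L is not None else traj.L)
        burn, ok = detect_equilibration(x)
        burn = max(burn, int(burn_in_floor * len(x)))
        if not ok:
            warnings.warn(
                f"trajectory {k} (seed {traj.seed}) never equilibrated; excluded",
                stacklevel=2,
            )
            continue
        means.append(x[burn:].mean())
        burns.append(burn)
    if len(means) < 2:
        raise AnalysisError("fewer than 2 equilibrated trajectories; cannot average")
    means = np.asarray(means)
    return ExtensionEstimate(
        mean_rel_extension=float(means.mean()),
        std_error=float(means.std(ddof=1) / np.sqrt(len(means))),
        n_traj=len(means),
        burn_in_steps=int(np.max(burns)),
        equilibrated=True,
    )


# ---------------------------------------------------------------------------
# theory comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonCondition:
    """One (geometry, chain, force) cell of a comparison grid."""

    geom: th.ChannelGeometry
    chain: th.ChainSpec
    force: th.ForceState
    label: str = ""


def build_comparison(
    estimates: Sequence[ExtensionEstimate],
    conditions: Sequence[ComparisonCondition],
    const: th.TheoryConstants = th.DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Simulation-vs-theory table across a (geometry, force) grid.

    Columns: simulated deficit with standard error and, per condition, the
    deficit from the modified deflection length and from the additive
    effective-force relation with each classical deflection length,
    together with relative errors of each theory against the simulation.
    """
    if len(estimates) != len(conditions):
        raise AnalysisError(
            f"grid mismatch: {len(estimates)} estimates vs {len(conditions)} conditions"
        )
    rows = []
    for est, cond in zip(estimates, conditions):
        sim = est.deficit
        mod = th.force_confinement_extension(cond.geom, cond.chain, cond.force, const)
        cfe = th.force_confinement_extension_classical(
            cond.geom, cond.chain, cond.force, const, which="fe"
        )
        cext = th.force_confinement_extension_classical(
            cond.geom, cond.chain, cond.force, const, which="ext"
        )
        rows.append(
            {
                "label": cond.label,
                "Hh_over_Lp": cond.geom.Hh / cond.chain.Lp,
                "Hw_over_Lp": cond.geom.Hw / cond.chain.Lp,
                "f_hat": cond.force.f_hat,
                "deficit_sim": sim,
                "deficit_sim_se": est.std_error,
                "n_traj": est.n_traj,
                "deficit_modified": mod,
                "deficit_classical_fe": cfe,
                "deficit_classical_ext": cext,
                "rel_err_modified": abs(sim - mod) / mod,
                "rel_err_classical_fe": abs(sim - cfe) / cfe,
                "rel_err_classical_ext": abs(sim - cext) / cext,
            }
        )
    return pd.DataFrame(rows)


def aggregate_errors(table: pd.DataFrame) -> dict:
    """Mean absolute relative error of each theory over a comparison table."""
    return {
        "modified": float(table["rel_err_modified"].mean()),
        "classical_fe": float(table["rel_err_classical_fe"].mean()),
        "classical_ext": float(table["rel_err_classical_ext"].mean()),
    }
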