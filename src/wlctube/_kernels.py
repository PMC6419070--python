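"""Numba kernels for the bead-rod Brownian dynamics integrator.

All kernels operate on plain float64 arrays in package units (nm, ps,
pN nm).  They are compiled lazily on first use; the Python wrappers in
``gbr`` expose validated, documented entry points.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True, fastmath=True)
def bending_forces_kernel(r, kappa, F):
    """Forces of the discrete wormlike-chain bending energy.

    E = kappa * sum_j (1 - cos theta_j) over interior joints, kappa in
    pN nm.  F is overwritten in place.
    """
    N = r.shape[0]
    for k in range(N):
        F[k, 0] = 0.0
        F[k, 1] = 0.0
        F[k, 2] = 0.0
    for j in range(N - 2):
        e1x = r[j + 1, 0] - r[j, 0]
        e1y = r[j + 1, 1] - r[j, 1]
        e1z = r[j + 1, 2] - r[j, 2]
        e2x = r[j + 2, 0] - r[j + 1, 0]
        e2y = r[j + 2, 1] - r[j + 1, 1]
        e2z = r[j + 2, 2] - r[j + 1, 2]
        b1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        b2 = np.sqrt(e2x * e2x + e2y * e2y + e2z * e2z)
        if b1 <= 0.0 or b2 <= 0.0:
            F[0, 0] = np.nan  # degenerate bond; wrapper raises
            return
        u1x, u1y, u1z = e1x / b1, e1y / b1, e1z / b1
        u2x, u2y, u2z = e2x / b2, e2y / b2, e2z / b2
        ct = u1x * u2x + u1y * u2y + u1z * u2z
        g1x = (u2x - ct * u1x) / b1
        g1y = (u2y - ct * u1y) / b1
        g1z = (u2z - ct * u1z) / b1
        g2x = (u1x - ct * u2x) / b2
        g2y = (u1y - ct * u2y) / b2
        g2z = (u1z - ct * u2z) / b2
        F[j, 0] -= kappa * g1x
        F[j, 1] -= kappa * g1y
        F[j, 2] -= kappa * g1z
        F[j + 1, 0] += kappa * (g1x - g2x)
        F[j + 1, 1] += kappa * (g1y - g2y)
        F[j + 1, 2] += kappa * (g1z - g2z)
        F[j + 2, 0] += kappa * g2x
        F[j + 2, 1] += kappa * g2y
        F[j + 2, 2] += kappa * g2z


@nb.njit(cache=True, fastmath=True)
def newton_shake_kernel(r, b, tol_abs, max_newton, dl, du, rhs, d):
    """Project positions onto the rod-length manifold.

    Newton iteration on the rod-length constraints; each iteration solves
    the tridiagonal Lagrange-multiplier system (equal bead weighting) by
    the Thomas algorithm and displaces beads along the current bonds.
    Returns the final max absolute rod-length error, or -1.0 on failure.
    """
    N = r.shape[0]
    M = N - 1
    b2 = b * b
    for _ in range(max_newton):
        errmax = 0.0
        for k in range(M):
            d[k, 0] = r[k + 1, 0] - r[k, 0]
            d[k, 1] = r[k + 1, 1] - r[k, 1]
            d[k, 2] = r[k + 1, 2] - r[k, 2]
            n2 = d[k, 0] ** 2 + d[k, 1] ** 2 + d[k, 2] ** 2
            e = abs(np.sqrt(n2) - b)
            if e > errmax:
                errmax = e
            rhs[k] = b2 - n2
            dl[k] = n2  # stash |d_k|^2 in dl temporarily
        if errmax < tol_abs:
            return errmax
        # tridiagonal system: diag 4|d_k|^2, off-diagonals -2 d_k.d_{k+1}
        cp = 4.0 * dl[0]
        if M > 1:
            dot = d[0, 0] * d[1, 0] + d[0, 1] * d[1, 1] + d[0, 2] * d[1, 2]
            du[0] = -2.0 * dot / cp
        rhs[0] = rhs[0] / cp
        for k in range(1, M):
            dot_lo = d[k, 0] * d[k - 1, 0] + d[k, 1] * d[k - 1, 1] + d[k, 2] * d[k - 1, 2]
            a_lo = -2.0 * dot_lo
            m = 4.0 * dl[k] - a_lo * du[k - 1]
            if m == 0.0:
                return -1.0
            if k < M - 1:
                dot_hi = d[k, 0] * d[k + 1, 0] + d[k, 1] * d[k + 1, 1] + d[k, 2] * d[k + 1, 2]
                du[k] = -2.0 * dot_hi / m
            rhs[k] = (rhs[k] - a_lo * rhs[k - 1]) / m
        for k in range(M - 2, -1, -1):
            rhs[k] = rhs[k] - du[k] * rhs[k + 1]
        for k in range(M):
            lx = rhs[k] * d[k, 0]
            ly = rhs[k] * d[k, 1]
            lz = rhs[k] * d[k, 2]
            r[k, 0] -= lx
            r[k, 1] -= ly
            r[k, 2] -= lz
            r[k + 1, 0] += lx
            r[k + 1, 1] += ly
            r[k + 1, 2] += lz
    errmax = 0.0
    for k in range(M):
        dx = r[k + 1, 0] - r[k, 0]
        dy = r[k + 1, 1] - r[k, 1]
        dz = r[k + 1, 2] - r[k, 2]
        e = abs(np.sqrt(dx * dx + dy * dy + dz * dz) - b)
        if e > errmax:
            errmax = e
    if errmax < tol_abs:
        return errmax
    return -1.0


@nb.njit(cache=True, fastmath=True)
def wall_violation_kernel(r, half_w, half_h):
    """Largest distance by which any bead centre sits outside the channel."""
    N = r.shape[0]
    viol = 0.0
    for k in range(N):
        if half_w > 0.0:
            v = abs(r[k, 0]) - half_w
            if v > viol:
                viol = v
        if half_h > 0.0:
            v = abs(r[k, 1]) - half_h
            if v > viol:
                viol = v
    return viol


@nb.njit(cache=True, fastmath=True)
def clamp_walls_kernel(r, half_w, half_h):
    """Move outside bead centres to the nearest wall plane, per coordinate.

    A non-positive half-extent disables that wall pair.  Returns the
    largest single-coordinate violation before clamping.
    """
    N = r.shape[0]
    viol = 0.0
    for k in range(N):
        if half_w > 0.0:
            if r[k, 0] > half_w:
                v = r[k, 0] - half_w
                if v > viol:
                    viol = v
                r[k, 0] = half_w
            elif r[k, 0] < -half_w:
                v = -half_w - r[k, 0]
                if v > viol:
                    viol = v
                r[k, 0] = -half_w
        if half_h > 0.0:
            if r[k, 1] > half_h:
                v = r[k, 1] - half_h
                if v > viol:
                    viol = v
                r[k, 1] = half_h
            elif r[k, 1] < -half_h:
                v = -half_h - r[k, 1]
                if v > viol:
                    viol = v
                r[k, 1] = -half_h
    return viol


@nb.njit(cache=True, fastmath=True)
def project_kernel(r, b, half_w, half_h, rod_tol, wall_tol, dl, du, rhs, d):
    """Joint projection onto rod constraints and channel interior.

    Alternates Newton rod projection with wall clamping until both are
    within tolerance.  Returns (rod_err, wall_viol); rod_err < 0 flags a
    failed projection.
    """
    rod_err = newton_shake_kernel(r, b, rod_tol, 25, dl, du, rhs, d)
    if rod_err < 0.0:
        return rod_err, 0.0
    if half_w <= 0.0 and half_h <= 0.0:
        return rod_err, 0.0
    viol = wall_violation_kernel(r, half_w, half_h)
    for _ in range(80):
        if viol < wall_tol:
            break
        clamp_walls_kernel(r, half_w, half_h)
        rod_err = newton_shake_kernel(r, b, rod_tol, 25, dl, du, rhs, d)
        if rod_err < 0.0:
            return rod_err, viol
        viol = wall_violation_kernel(r, half_w, half_h)
    return rod_err, viol


@nb.njit(cache=True, fastmath=True)
def run_free_draining_kernel(
    r,
    b,
    kappa,
    fs,
    half_w,
    half_h,
    D0,
    kbt,
    dt,
    steps,
    seed,
    record_every,
    ext,
    frames,
    frame_every,
    rod_tol,
    wall_tol,
):
    """Fused free-draining trajectory loop.

    Overwrites ``r``; records the axial end-to-end distance every
    ``record_every`` steps into ``ext`` and, if ``frame_every`` > 0, bead
    positions every ``frame_every`` steps into ``frames``.  Returns
    (max_rod_err, max_wall_viol, n_recorded, n_frames); max_rod_err < 0
    flags a projection failure at the step -int(max_wall_viol).
    """
    np.random.seed(seed)
    N = r.shape[0]
    M = N - 1
    F = np.zeros((N, 3))
    dl = np.zeros(M)
    du = np.zeros(M)
    rhs = np.zeros(M)
    d = np.zeros((M, 3))
    mob = dt * D0 / kbt
    sig = np.sqrt(2.0 * D0 * dt)
    max_rod = 0.0
    max_wall = 0.0
    nrec = 0
    nfr = 0
    for n in range(steps):
        bending_forces_kernel(r, kappa, F)
        if np.isnan(F[0, 0]):
            return -1.0, -float(n), nrec, nfr
        F[0, 2] -= fs
        F[M, 2] += fs
        xi = np.random.standard_normal(3 * N)
        for k in range(N):
            r[k, 0] += mob * F[k, 0] + sig * xi[3 * k]
            r[k, 1] += mob * F[k, 1] + sig * xi[3 * k + 1]
            r[k, 2] += mob * F[k, 2] + sig * xi[3 * k + 2]
        rod_err, viol = project_kernel(
            r, b, half_w, half_h, rod_tol, wall_tol, dl, du, rhs, d
        )
        if rod_err < 0.0:
            return -1.0, -float(n), nrec, nfr
        if rod_err > max_rod:
            max_rod = rod_err
        if viol > max_wall:
            max_wall = viol
        if record_every > 0 and n % record_every == 0:
            ext[nrec] = r[M, 2] - r[0, 2]
            nrec += 1
        if frame_every > 0 and n % frame_every == 0:
            for k in range(N):
                frames[nfr, k, 0] = r[k, 0]
                frames[nfr, k, 1] = r[k, 1]
                frames[nfr, k, 2] = r[k, 2]
            nfr += 1
    return max_rod, max_wall, nrec, nfr
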