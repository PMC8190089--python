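"""Compiled numerical kernels (numba) for the nucleosome-state model.

All kernels work on a shared time grid whose cells are short enough that
the temperature — and hence the heat-sensing signals — can be treated as
constant (signals) or linear (mean-field interpolation) within a cell.
The SSA kernel is an exact Gillespie simulation within each cell, with
propensities re-evaluated at every cell boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def signal_path(grid, cell_temp, sigma_J, lambda_J, T_J, sigma_S, lambda_S,
                T_S, T_D, kappa_D, rho_D, D_min):
    """Integrate the J/S/D signal ODEs exactly over piecewise-constant T.

    ``grid`` has M+1 points defining M cells; ``cell_temp`` has M entries,
    the temperature holding on each cell.  Within a cell every equation is
    linear with constant coefficients, so the update is the closed-form
    exponential relaxation toward the cell's fixed point.
    """
    n = grid.shape[0]
    J = np.zeros(n)
    S = np.zeros(n)
    D = np.ones(n)
    for c in range(n - 1):
        h = grid[c + 1] - grid[c]
        T = cell_temp[c]
        # J: dJ/dt = sigma_J*[T >= T_J] - lambda_J*J
        prod = sigma_J if T >= T_J else 0.0
        if lambda_J > 0.0:
            Jinf = prod / lambda_J
            J[c + 1] = Jinf + (J[c] - Jinf) * np.exp(-lambda_J * h)
        else:
            J[c + 1] = J[c] + prod * h
        # S: same structure
        prod = sigma_S if T >= T_S else 0.0
        if lambda_S > 0.0:
            Sinf = prod / lambda_S
            S[c + 1] = Sinf + (S[c] - Sinf) * np.exp(-lambda_S * h)
        else:
            S[c + 1] = S[c] + prod * h
        # D: decays toward D_min under damaging heat, recovers toward 1 otherwise
        if T >= T_D:
            if kappa_D > 0.0:
                D[c + 1] = D_min + (D[c] - D_min) * np.exp(-kappa_D * h)
            else:
                D[c + 1] = D[c]
        else:
            if rho_D > 0.0:
                D[c + 1] = 1.0 - (1.0 - D[c]) * np.exp(-rho_D * h)
            else:
                D[c + 1] = D[c]
    return J, S, D


@njit(cache=False, inline="always")
def _rhs(r, a, m, Jv, Sv, Dv, k_act, k_rep, k_noise, v0, vJphi, vUA_S,
         alpha, alpha0, delta):
    u = 1.0 - r - a
    dr = (k_rep * r + k_noise) * u - (k_act * a + k_noise + v0 + vJphi * Jv) * r
    da = (k_act * a + k_noise + vUA_S * Sv) * u - (k_rep * r + k_noise) * a
    dm = Dv * (alpha0 + alpha * Sv * a * (1.0 - r)) - delta * m
    return dr, da, dm


@njit(cache=False)
def mean_field_path(grid, J, S, D, k_act, k_rep, k_noise, v0, vJphi, vUA_S,
                    alpha, alpha0, delta, r0, a0):
    """RK4 integration of the mean-field fractions and mRNA on the grid.

    Signals are interpolated linearly within cells.  Returns the r, a, m
    arrays on grid points plus the largest simplex violation encountered
    (before the per-step clip), so callers can enforce a tolerance.
    """
    n = grid.shape[0]
    r = np.empty(n)
    a = np.empty(n)
    m = np.empty(n)
    r[0] = r0
    a[0] = a0
    m[0] = alpha0 / delta if delta > 0.0 else 0.0
    max_viol = 0.0
    for c in range(n - 1):
        h = grid[c + 1] - grid[c]
        J0, J1 = J[c], J[c + 1]
        S0, S1 = S[c], S[c + 1]
        D0, D1 = D[c], D[c + 1]
        Jm = 0.5 * (J0 + J1)
        Sm = 0.5 * (S0 + S1)
        Dm = 0.5 * (D0 + D1)
        rc, ac, mc = r[c], a[c], m[c]
        k1r, k1a, k1m = _rhs(rc, ac, mc, J0, S0, D0, k_act, k_rep, k_noise,
                             v0, vJphi, vUA_S, alpha, alpha0, delta)
        k2r, k2a, k2m = _rhs(rc + 0.5 * h * k1r, ac + 0.5 * h * k1a,
                             mc + 0.5 * h * k1m, Jm, Sm, Dm, k_act, k_rep,
                             k_noise, v0, vJphi, vUA_S, alpha, alpha0, delta)
        k3r, k3a, k3m = _rhs(rc + 0.5 * h * k2r, ac + 0.5 * h * k2a,
                             mc + 0.5 * h * k2m, Jm, Sm, Dm, k_act, k_rep,
                             k_noise, v0, vJphi, vUA_S, alpha, alpha0, delta)
        k4r, k4a, k4m = _rhs(rc + h * k3r, ac + h * k3a, mc + h * k3m,
                             J1, S1, D1, k_act, k_rep, k_noise, v0, vJphi,
                             vUA_S, alpha, alpha0, delta)
        rn = rc + h / 6.0 * (k1r + 2.0 * k2r + 2.0 * k3r + k4r)
        an = ac + h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        mn = mc + h / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        viol = 0.0
        if rn < 0.0:
            viol = max(viol, -rn)
            rn = 0.0
        if an < 0.0:
            viol = max(viol, -an)
            an = 0.0
        s = rn + an
        if s > 1.0:
            viol = max(viol, s - 1.0)
            rn /= s
            an /= s
        if viol > max_viol:
            max_viol = viol
        if mn < 0.0:
            mn = 0.0
        r[c + 1] = rn
        a[c + 1] = an
        m[c + 1] = mn
    return r, a, m, max_viol


@njit(cache=False)
def ssa_ensemble(grid, J, S, D, N, k_act, k_rep, k_noise, v0, vJphi, vUA_S,
                 alpha, alpha0, delta, nR0, nA0, seed, n_runs):
    """Gillespie ensemble of the N-nucleosome locus with cell-constant rates.

    Four reaction channels with global (all-to-all) recruitment:
    R->U, U->R, U->A, A->U.  Propensities are re-evaluated after every
    event and at every grid-cell boundary (rates are piecewise constant on
    the signal grid).  mRNA is integrated per run with the run's own
    piecewise-constant (r, a) path.  Runs are seeded ``seed + run`` for
    counter-style reproducibility.

    Returns per-grid-point sums and sums of squares of r, a, m over runs.
    """
    npts = grid.shape[0]
    sum_r = np.zeros(npts)
    sum_r2 = np.zeros(npts)
    sum_a = np.zeros(npts)
    sum_a2 = np.zeros(npts)
    sum_m = np.zeros(npts)
    sum_m2 = np.zeros(npts)
    Nf = float(N)
    for run in range(n_runs):
        np.random.seed(seed + run)
        nR = nR0
        nA = nA0
        m = alpha0 / delta if delta > 0.0 else 0.0
        sum_r[0] += nR / Nf
        sum_r2[0] += (nR / Nf) ** 2
        sum_a[0] += nA / Nf
        sum_a2[0] += (nA / Nf) ** 2
        sum_m[0] += m
        sum_m2[0] += m * m
        for c in range(npts - 1):
            t = grid[c]
            t_end = grid[c + 1]
            Jc = J[c]
            Sc = S[c]
            Dc = D[c]
            rc = nR / Nf
            ac = nA / Nf
            while True:
                u = N - nR - nA
                p1 = nR * (k_act * nA / Nf + k_noise + v0 + vJphi * Jc)
                p2 = u * (k_rep * nR / Nf + k_noise)
                p3 = u * (k_act * nA / Nf + k_noise + vUA_S * Sc)
                p4 = nA * (k_rep * nR / Nf + k_noise)
                tot = p1 + p2 + p3 + p4
                if tot <= 0.0:
                    break
                t_next = t + np.random.exponential(1.0 / tot)
                if t_next >= t_end:
                    break
                t = t_next
                x = np.random.random() * tot
                if x < p1:
                    nR -= 1
                elif x < p1 + p2:
                    nR += 1
                elif x < p1 + p2 + p3:
                    nA += 1
                else:
                    nA -= 1
            # mRNA: linear ODE with production from the cell-start state
            h = t_end - grid[c]
            prod = Dc * (alpha0 + alpha * Sc * ac * (1.0 - rc))
            if delta > 0.0:
                minf = prod / delta
                m = minf + (m - minf) * np.exp(-delta * h)
            else:
                m = m + prod * h
            rn = nR / Nf
            an = nA / Nf
            sum_r[c + 1] += rn
            sum_r2[c + 1] += rn * rn
            sum_a[c + 1] += an
            sum_a2[c + 1] += an * an
            sum_m[c + 1] += m
            sum_m2[c + 1] += m * m
    return sum_r, sum_r2, sum_a, sum_a2, sum_m, sum_m2


@njit(cache=False)
def ssa_first_flip_times(rate, seed, n_runs):
    """Waiting times of a single-channel exponential clock (test oracle)."""
    out = np.empty(n_runs)
    for run in range(n_runs):
        np.random.seed(seed + run)
        out[run] = np.random.exponential(1.0 / rate)
    return out
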