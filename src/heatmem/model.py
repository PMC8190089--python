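"""Stochastic and deterministic dynamics of an N-nucleosome heat-memory locus.

Each of the N nucleosomes at the locus is in one of three states:
R (repressively modified, H3K27me3), U (unmodified) or A (actively marked,
H3K4me3).  Conversions are two-step (R <-> U <-> A) and recruited: the
rate toward A is proportional to the current A fraction, the rate toward R
to the current R fraction, on top of a uniform noisy conversion rate.
Temperature couples in through three signals

* J — demethylase activity (induced above ``T_J``), adding a J-dependent
  R->U demethylation rate ``vJ * phi * J`` (``phi`` < 1 in the demethylase
  quadruple mutant),
* S — heat-shock-factor-like activator (induced above ``T_S``), adding an
  S-dependent U->A rate and gating transcription,
* D — cellular damage factor in [D_min, 1], dropping during damaging heat
  (above ``T_D``) and recovering afterwards; it multiplies transcription
  and produces the delayed, recovery-limited induction after a severe
  heat shock.

mRNA follows dm/dt = D*(alpha0 + alpha*S*a*(1-r)) - delta*m: transcription
needs the activating mark and is antagonised by the repressive mark.

Three engines are provided: a deterministic mean-field ODE
(:func:`simulate_mean_field`), an exact Gillespie ensemble
(:func:`simulate_ssa`) and, for small N, the full chemical master equation
(:func:`solve_master_equation`) used as a brute-force oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import _kernels
from .temperature import TemperatureProfile, temperature_at

__all__ = [
    "ModelParams",
    "ObservationParams",
    "LocusState",
    "SignalTrajectory",
    "Trajectory",
    "compute_signals",
    "mean_field_rhs",
    "simulate_mean_field",
    "simulate_ssa",
    "solve_master_equation",
    "observe",
    "GENOTYPES",
]

GENOTYPES = ("WT", "jmjq")

MAX_SEED = 2**31 - 1


def _normalize_genotype(genotype: str) -> str:
    g = str(genotype)
    for known in GENOTYPES:
        if g.lower() == known.lower():
            return known
    raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the nucleosome-state model (units: per hour).

    Defaults were calibrated once to the qualitative regime the experiments
    define — immediate expression on acclimation, gradual recovery-limited
    induction after heat shock, a memory phase of a few days, and a reduced
    demethylation rate in the mutant — see docs/methods.md.
    """

    N: int = 20                  # nucleosomes at the locus
    k_act: float = 0.2           # recruited conversion toward A
    k_rep: float = 0.2           # recruited conversion toward R
    k_noise: float = 0.02        # basal noisy conversion (every allowed step)
    v0: float = 0.002            # basal R->U demethylation
    vJ: float = 0.08             # J-dependent R->U coefficient (v_R_to_U drive)
    phi_jmj: float = 0.2         # mutant multiplier on vJ (WT = 1)
    sigma_J: float = 2.0         # J production above T_J
    lambda_J: float = 0.02       # J decay
    T_J: float = 30.0            # J activation threshold (degC)
    sigma_S: float = 4.0         # S production above T_S
    lambda_S: float = 0.25       # S decay
    T_S: float = 35.0            # S activation threshold (degC)
    vUA_S: float = 0.5           # S-driven U->A coefficient
    T_D: float = 42.0            # damage threshold (degC)
    kappa_D: float = 2.0         # damage accumulation rate
    rho_D: float = 0.05          # damage recovery rate
    D_min: float = 0.1           # damage floor
    alpha: float = 50.0          # max transcription rate (expression units/h)
    alpha0: float = 0.02         # basal transcription
    delta: float = 0.2           # mRNA decay
    r_init: float = 0.9          # initial R fraction (Polycomb-repressed locus)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        for name in ("k_act", "k_rep", "k_noise", "v0", "vJ", "sigma_J",
                     "lambda_J", "sigma_S", "lambda_S", "vUA_S", "kappa_D",
                     "rho_D", "alpha", "alpha0", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.D_min <= 1.0:
            raise ValueError("D_min must be in [0, 1]")
        if not 0.0 <= self.phi_jmj <= 1.0:
            raise ValueError("phi_jmj must be in [0, 1]")
        if not 0.0 <= self.r_init <= 1.0:
            raise ValueError("r_init must be in [0, 1]")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def phi(self, genotype: str) -> float:
        """Genotype multiplier on the J-dependent demethylation rate."""
        return 1.0 if _normalize_genotype(genotype) == "WT" else self.phi_jmj

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ObservationParams:
    """Affine maps from model state to assay readouts.

    ChIP signals are percent-of-input: K27 = c27*<r> + b27 and
    K4 = c4*<a> + b4.  Expression (relative to the internal reference gene)
    is expr = cm*m; cm defaults to 1 and is normally kept fixed because
    only the product of cm with the transcription rate is identifiable.
    """

    c27: float = 10.0
    b27: float = 0.5
    c4: float = 8.0
    b4: float = 0.3
    cm: float = 1.0

    def __post_init__(self):
        if min(self.c27, self.c4, self.cm) < 0:
            raise ValueError("slopes must be >= 0")
        if min(self.b27, self.b4) < 0:
            raise ValueError("intercepts must be >= 0")

    def replace(self, **kwargs) -> "ObservationParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class LocusState:
    """Nucleosome counts (n_R, n_U, n_A) of one locus; they sum to N."""

    n_R: int
    n_U: int
    n_A: int

    def __post_init__(self):
        if min(self.n_R, self.n_U, self.n_A) < 0:
            raise ValueError("nucleosome counts must be >= 0")

    @property
    def N(self) -> int:
        return self.n_R + self.n_U + self.n_A


@dataclass(frozen=True)
class SignalTrajectory:
    """Heat-sensing signals J, S and damage factor D on a time grid."""

    grid: np.ndarray
    J: np.ndarray
    S: np.ndarray
    D: np.ndarray
    cell_temp: np.ndarray  # temperature holding on each grid cell


@dataclass(frozen=True)
class Trajectory:
    """Simulated locus trajectory: mean fractions and mRNA versus time."""

    grid: np.ndarray
    r: np.ndarray
    a: np.ndarray
    m: np.ndarray
    genotype: str
    n_runs: int = 1
    sem_r: np.ndarray = None
    sem_a: np.ndarray = None
    sem_m: np.ndarray = None

    def __post_init__(self):
        for name in ("sem_r", "sem_a", "sem_m"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, np.zeros_like(self.grid))

    def at(self, t: float) -> dict:
        """Linearly interpolated state at time t."""
        return {
            "r": float(np.interp(t, self.grid, self.r)),
            "a": float(np.interp(t, self.grid, self.a)),
            "m": float(np.interp(t, self.grid, self.m)),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.grid, "r": self.r, "a": self.a, "m": self.m,
            "sem_r": self.sem_r, "sem_m": self.sem_m,
        })


def _build_grid(profile: TemperatureProfile, dt: float) -> np.ndarray:
    """Union of the regular dt lattice and the profile breakpoints."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    widths = np.diff(profile.breakpoints())
    widths = widths[widths > 1e-12]
    if widths.size and dt > widths.min() + 1e-12:
        raise ValueError(
            f"dt={dt} h exceeds the shortest profile step "
            f"({widths.min():.4g} h); the heat window would be skipped")
    lattice = np.arange(0.0, profile.duration, dt)
    grid = np.union1d(np.append(lattice, profile.duration),
                      profile.breakpoints())
    grid = grid[(grid >= 0) & (grid <= profile.duration + 1e-12)]
    # drop near-duplicate points created by float unions
    keep = np.concatenate(([True], np.diff(grid) > 1e-12))
    return grid[keep]


def compute_signals(profile: TemperatureProfile, params: ModelParams,
                    dt: float = 0.05) -> SignalTrajectory:
    """Integrate the J/S/D signal dynamics under a temperature profile.

    J and S obey dX/dt = sigma*[T(t) >= T_thr] - lambda*X from X(0) = 0;
    D obeys dD/dt = -kappa_D*(D - D_min) above the damage threshold and
    +rho_D*(1 - D) below it, from D(0) = 1.  Because T is piecewise
    constant, each grid cell is solved in closed form (exact).
    """
    grid = _build_grid(profile, dt)
    cell_temp = temperature_at(profile, grid[:-1])
    J, S, D = _kernels.signal_path(
        grid, np.asarray(cell_temp, dtype=float),
        params.sigma_J, params.lambda_J, params.T_J,
        params.sigma_S, params.lambda_S, params.T_S,
        params.T_D, params.kappa_D, params.rho_D, params.D_min)
    return SignalTrajectory(grid=grid, J=J, S=S, D=D,
                            cell_temp=np.asarray(cell_temp, dtype=float))


def mean_field_rhs(r: float, a: float, J: float, S: float, D: float,
                   params: ModelParams, genotype: str = "WT"):
    """Time derivatives (dr/dt, da/dt) of the mean-field fractions.

    With u = 1 - r - a:
    dr/dt = (k_rep*r + k_noise)*u - (k_act*a + k_noise + v0 + vJ*phi*J)*r
    da/dt = (k_act*a + k_noise + vUA_S*S)*u - (k_rep*r + k_noise)*a
    """
    if r < -1e-12 or a < -1e-12 or r + a > 1.0 + 1e-12:
        raise ValueError("fractions outside the simplex")
    phi = params.phi(genotype)
    u = 1.0 - r - a
    dr = (params.k_rep * r + params.k_noise) * u \
        - (params.k_act * a + params.k_noise + params.v0
           + params.vJ * phi * J) * r
    da = (params.k_act * a + params.k_noise + params.vUA_S * S) * u \
        - (params.k_rep * r + params.k_noise) * a
    return dr, da


def simulate_mean_field(params: ModelParams, profile: TemperatureProfile,
                        genotype: str = "WT", dt: float = 0.05,
                        signals: SignalTrajectory | None = None) -> Trajectory:
    """Deterministic mean-field trajectory of (r, a, m).

    ``signals`` may be passed to reuse a precomputed signal trajectory
    (the signals do not depend on the conversion-rate parameters).
    """
    genotype = _normalize_genotype(genotype)
    sig = signals if signals is not None else compute_signals(profile, params, dt)
    phi = params.phi(genotype)
    r, a, m, viol = _kernels.mean_field_path(
        sig.grid, sig.J, sig.S, sig.D,
        params.k_act, params.k_rep, params.k_noise, params.v0,
        params.vJ * phi, params.vUA_S,
        params.alpha, params.alpha0, params.delta,
        params.r_init, 0.0)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(a))
            and np.all(np.isfinite(m))):
        bad = np.flatnonzero(~(np.isfinite(r) & np.isfinite(a) & np.isfinite(m)))
        raise FloatingPointError(
            f"mean-field integration diverged at t={sig.grid[bad[0]]:.3f} h")
    if viol > 1e-6:
        raise FloatingPointError(
            f"simplex violation {viol:.2e} exceeds integrator tolerance 1e-6")
    return Trajectory(grid=sig.grid, r=r, a=a, m=m, genotype=genotype, n_runs=1)


def simulate_ssa(params: ModelParams, profile: TemperatureProfile,
                 genotype: str = "WT", n_runs: int = 200, seed: int = 0,
                 dt_signal: float = 0.05, force: bool = False,
                 signals: SignalTrajectory | None = None) -> Trajectory:
    """Exact Gillespie ensemble of the N-nucleosome locus.

    Rates are piecewise constant on the signal grid; within a cell the
    simulation is an exact SSA with per-event propensity updates, and
    propensities are re-evaluated at every cell boundary.  Runs are seeded
    ``seed + run_index``; results are reproducible given ``seed``.
    """
    genotype = _normalize_genotype(genotype)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if params.N > 500 and n_runs > 10_000 and not force:
        raise ValueError("N > 500 with n_runs > 10^4: pass force=True to override")
    if not (0 <= seed and seed + n_runs <= MAX_SEED):
        raise ValueError("seed must satisfy 0 <= seed and seed + n_runs < 2^31")
    sig = signals if signals is not None else compute_signals(profile, params, dt_signal)
    phi = params.phi(genotype)
    nR0 = int(round(params.r_init * params.N))
    sum_r, sum_r2, sum_a, sum_a2, sum_m, sum_m2 = _kernels.ssa_ensemble(
        sig.grid, sig.J, sig.S, sig.D, params.N,
        params.k_act, params.k_rep, params.k_noise, params.v0,
        params.vJ * phi, params.vUA_S,
        params.alpha, params.alpha0, params.delta,
        nR0, 0, seed, n_runs)
    n = float(n_runs)
    mean_r, mean_a, mean_m = sum_r / n, sum_a / n, sum_m / n

    def _sem(s, s2, mean):
        if n_runs == 1:
            return np.zeros_like(mean)
        var = np.maximum(s2 / n - mean**2, 0.0) * n / (n - 1.0)
        return np.sqrt(var / n)

    return Trajectory(grid=sig.grid, r=mean_r, a=mean_a, m=mean_m,
                      genotype=genotype, n_runs=n_runs,
                      sem_r=_sem(sum_r, sum_r2, mean_r),
                      sem_a=_sem(sum_a, sum_a2, mean_a),
                      sem_m=_sem(sum_m, sum_m2, mean_m))


# ---------------------------------------------------------------------------
# master equation (brute-force oracle for small N)


def _state_index(N: int):
    """Enumerate (n_R, n_A) states with n_R + n_A <= N."""
    states = [(nR, nA) for nR in range(N + 1) for nA in range(N + 1 - nR)]
    index = {s: i for i, s in enumerate(states)}
    return states, index


def _rate_matrix(N: int, states, index, k_act, k_rep, k_noise, v0, vJphi,
                 vUA_S, J, S):
    """Generator matrix Q (column convention: dp/dt = Q p) for fixed signals."""
    n = len(states)
    Q = np.zeros((n, n))
    for i, (nR, nA) in enumerate(states):
        nU = N - nR - nA
        moves = []
        if nR > 0:  # R -> U
            rate = nR * (k_act * nA / N + k_noise + v0 + vJphi * J)
            moves.append(((nR - 1, nA), rate))
        if nU > 0:  # U -> R
            moves.append(((nR + 1, nA), nU * (k_rep * nR / N + k_noise)))
            # U -> A
            moves.append(((nR, nA + 1), nU * (k_act * nA / N + k_noise + vUA_S * S)))
        if nA > 0:  # A -> U
            moves.append(((nR, nA - 1), nA * (k_rep * nR / N + k_noise)))
        for dest, rate in moves:
            if rate > 0.0:
                Q[index[dest], i] += rate
                Q[i, i] -= rate
    return Q


def solve_master_equation(params: ModelParams, profile: TemperatureProfile,
                          genotype: str = "WT", dt: float = 0.05,
                          signals: SignalTrajectory | None = None) -> Trajectory:
    """Exact distribution dynamics of the (n_R, n_A) chain for N <= 8.

    The generator is piecewise constant per signal-grid cell; propagation
    uses the matrix exponential per cell, so the only approximation is the
    piecewise-constant signal discretisation shared with the SSA engine.
    """
    genotype = _normalize_genotype(genotype)
    if params.N > 8:
        raise ValueError("master equation limited to N <= 8")
    sig = signals if signals is not None else compute_signals(profile, params, dt)
    phi = params.phi(genotype)
    N = params.N
    states, index = _state_index(N)
    nstates = len(states)
    p = np.zeros(nstates)
    nR0 = int(round(params.r_init * N))
    p[index[(nR0, 0)]] = 1.0

    r_of_state = np.array([s[0] / N for s in states])
    a_of_state = np.array([s[1] / N for s in states])
    npts = len(sig.grid)
    r = np.empty(npts)
    a = np.empty(npts)
    r[0], a[0] = p @ r_of_state, p @ a_of_state

    cache: dict = {}
    for c in range(npts - 1):
        h = sig.grid[c + 1] - sig.grid[c]
        key = (round(float(sig.J[c]), 12), round(float(sig.S[c]), 12),
               round(float(h), 12))
        P = cache.get(key)
        if P is None:
            Q = _rate_matrix(N, states, index, params.k_act, params.k_rep,
                             params.k_noise, params.v0, params.vJ * phi,
                             params.vUA_S, float(sig.J[c]), float(sig.S[c]))
            P = expm(Q * h)
            cache[key] = P
        p = P @ p
        mass = p.sum()
        if abs(mass - 1.0) > 1e-8:
            raise FloatingPointError(f"probability mass drifted to {mass}")
        r[c + 1] = p @ r_of_state
        a[c + 1] = p @ a_of_state

    # mRNA from the mean path, cell-exact linear updates
    m = np.empty(npts)
    m[0] = params.alpha0 / params.delta if params.delta > 0 else 0.0
    for c in range(npts - 1):
        h = sig.grid[c + 1] - sig.grid[c]
        prod = sig.D[c] * (params.alpha0
                           + params.alpha * sig.S[c] * a[c] * (1.0 - r[c]))
        if params.delta > 0:
            minf = prod / params.delta
            m[c + 1] = minf + (m[c] - minf) * np.exp(-params.delta * h)
        else:
            m[c + 1] = m[c] + prod * h
    return Trajectory(grid=sig.grid, r=r, a=a, m=m, genotype=genotype, n_runs=1)


def observe(traj: Trajectory, obs: ObservationParams,
            times: np.ndarray | None = None) -> pd.DataFrame:
    """Map a trajectory to predicted assay measurements.

    Returns a tidy frame with columns ``time_h, assay, value`` where assay
    is K27 (= c27*r + b27, ChIP %input), K4 (= c4*a + b4) or expr (= cm*m,
    expression relative to the reference gene).
    """
    if times is None:
        times = traj.grid
        r, a, m = traj.r, traj.a, traj.m
    else:
        times = np.asarray(times, dtype=float)
        r = np.interp(times, traj.grid, traj.r)
        a = np.interp(times, traj.grid, traj.a)
        m = np.interp(times, traj.grid, traj.m)
    frames = [
        pd.DataFrame({"time_h": times, "assay": "K27",
                      "value": obs.c27 * r + obs.b27}),
        pd.DataFrame({"time_h": times, "assay": "K4",
                      "value": obs.c4 * a + obs.b4}),
        pd.DataFrame({"time_h": times, "assay": "expr",
                      "value": obs.cm * m}),
    ]
    return pd.concat(frames, ignore_index=True)
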