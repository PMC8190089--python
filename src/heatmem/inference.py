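"""Fitting the nucleosome-state model to observed time courses.

The entry point is :class:`HistoneKineticsModel`, a statsmodels-style model
object built from a tidy table of measurements (qPCR expression relative to
a reference gene, ChIP %input for H3K27me3/H3K4me3) taken under a known
temperature profile.  ``fit()`` runs seeded multi-start Nelder–Mead on a
log-residual sum of squares and returns a :class:`HistoneKineticsResults`
carrying the estimates, per-start diagnostics, a ``summary()`` table and a
replicate-resampling ``bootstrap()`` for confidence intervals.

Genotypes are fitted jointly: all parameters are shared across genotypes
except ``phi_jmj``, the mutant's multiplier on the J-dependent R->U
demethylation rate, which only enters the mutant's dynamics — the fitted
quantity behind the "slower v_R->U in the demethylase mutant" comparison.

Measurement errors in qPCR/ChIP are multiplicative, so residuals are taken
on log(value + eps) with eps = 1e-3 guarding zeros.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .model import (ModelParams, ObservationParams, compute_signals,
                    simulate_mean_field, GENOTYPES)
from .temperature import TemperatureProfile

__all__ = [
    "ObservedTimeCourse",
    "FreeParamSpec",
    "HistoneKineticsModel",
    "HistoneKineticsResults",
    "FitResult",
    "sse_objective",
    "fit_params",
    "fit_joint_genotypes",
]

logger = logging.getLogger(__name__)

EPS = 1e-3
ASSAYS = ("K27", "K4", "expr")

#: canonical search bounds; all rates are positive and searched in log space
DEFAULT_BOUNDS = {
    "k_act": (0.005, 5.0), "k_rep": (0.005, 5.0), "k_noise": (1e-4, 1.0),
    "v0": (1e-5, 0.5), "vJ": (1e-3, 3.0), "phi_jmj": (0.01, 1.0),
    "sigma_J": (0.05, 50.0), "lambda_J": (1e-3, 1.0),
    "sigma_S": (0.05, 50.0), "lambda_S": (1e-3, 2.0), "vUA_S": (1e-3, 10.0),
    "kappa_D": (0.05, 20.0), "rho_D": (1e-3, 1.0), "D_min": (1e-3, 1.0),
    "alpha": (0.5, 1000.0), "alpha0": (1e-4, 10.0), "delta": (0.01, 5.0),
    "r_init": (0.3, 1.0),
    "c27": (0.1, 100.0), "b27": (1e-3, 10.0),
    "c4": (0.1, 100.0), "b4": (1e-3, 10.0), "cm": (0.01, 100.0),
}
OBS_PARAM_NAMES = ("c27", "b27", "c4", "b4", "cm")
SIGNAL_PARAM_NAMES = ("sigma_J", "lambda_J", "T_J", "sigma_S", "lambda_S",
                      "T_S", "T_D", "kappa_D", "rho_D", "D_min")


@dataclass
class ObservedTimeCourse:
    """Tidy measurement table for one condition.

    ``data`` columns: time_h, assay in {K27, K4, expr}, genotype in
    {WT, jmjq}, replicate (id), value (>= 0).
    """

    data: pd.DataFrame
    condition: str = ""

    REQUIRED = ("time_h", "assay", "genotype", "replicate", "value")

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("empty time course")
        if not np.all(np.isfinite(df["value"])) or (df["value"] < 0).any():
            raise ValueError("values must be finite and >= 0")
        bad = set(df["assay"]) - set(ASSAYS)
        if bad:
            raise ValueError(f"unknown assays: {sorted(bad)}")
        bad = set(df["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(bad)}")
        if (df["time_h"] < 0).any():
            raise ValueError("negative times")
        self.data = df.reset_index(drop=True)

    def genotypes(self):
        return sorted(set(self.data["genotype"]))

    @classmethod
    def from_tsv(cls, path, condition: str = "") -> "ObservedTimeCourse":
        return cls(pd.read_csv(path, sep="\t"), condition=condition)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def resample_replicates(self, rng: np.random.Generator) -> "ObservedTimeCourse":
        """Bootstrap copy: resample replicate rows within each
        (genotype, assay, time) cell with replacement."""
        parts = []
        for _, grp in self.data.groupby(["genotype", "assay", "time_h"],
                                        sort=True):
            idx = rng.integers(0, len(grp), size=len(grp))
            parts.append(grp.iloc[idx])
        return ObservedTimeCourse(pd.concat(parts, ignore_index=True),
                                  condition=self.condition)


@dataclass(frozen=True)
class FreeParamSpec:
    """Which parameters to fit, their box bounds and scales.

    ``phi_jmj`` is genotype-specific by construction (it only enters the
    mutant's equations); every other free parameter is shared across
    genotypes.
    """

    names: tuple
    bounds: dict = field(default_factory=dict)
    log_scale: dict = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        known = set(DEFAULT_BOUNDS) | {f.name for f in
                                       dataclasses.fields(ModelParams)}
        bounds = dict(self.bounds)
        logs = dict(self.log_scale)
        for n in names:
            if n not in known:
                raise ValueError(f"unknown parameter {n!r}")
            bounds.setdefault(n, DEFAULT_BOUNDS.get(n, (1e-4, 1e4)))
            lo, hi = bounds[n]
            if not lo < hi:
                raise ValueError(f"bounds for {n} must satisfy low < high")
            logs.setdefault(n, lo > 0)
        object.__setattr__(self, "bounds", bounds)
        object.__setattr__(self, "log_scale", logs)

    def transform(self, theta: np.ndarray) -> np.ndarray:
        """Natural values -> search space (log where flagged)."""
        z = np.array(theta, dtype=float)
        for i, n in enumerate(self.names):
            if self.log_scale[n]:
                z[i] = np.log(z[i])
        return z

    def untransform(self, z: np.ndarray) -> np.ndarray:
        theta = np.array(z, dtype=float)
        for i, n in enumerate(self.names):
            if self.log_scale[n]:
                theta[i] = np.exp(theta[i])
        return theta

    def z_bounds(self):
        out = []
        for n in self.names:
            lo, hi = self.bounds[n]
            out.append((np.log(lo), np.log(hi)) if self.log_scale[n]
                       else (lo, hi))
        return out

    def clip(self, theta: np.ndarray) -> np.ndarray:
        theta = np.array(theta, dtype=float)
        for i, n in enumerate(self.names):
            lo, hi = self.bounds[n]
            theta[i] = min(max(theta[i], lo), hi)
        return theta


class HistoneKineticsModel:
    """Model object binding data, temperature forcing and free parameters.

    Parameters
    ----------
    data : ObservedTimeCourse (or tidy DataFrame)
        Measurements; may contain one or both genotypes.
    profile : TemperatureProfile
        The temperature forcing the measurements were taken under.
    free : FreeParamSpec or sequence of names
        Parameters to estimate; the rest are fixed at ``fixed``/``obs``.
    fixed : ModelParams
        Values of all non-free kinetic parameters.
    obs : ObservationParams
        Values of all non-free observation-map parameters.
    dt : float
        Integration grid step (hours) for the mean-field engine.
    weights : dict assay -> float, optional
        Per-assay weights in the objective (default 1).
    """

    def __init__(self, data, profile: TemperatureProfile, free,
                 fixed: ModelParams | None = None,
                 obs: ObservationParams | None = None,
                 dt: float = 0.25, weights: dict | None = None):
        if not isinstance(data, ObservedTimeCourse):
            data = ObservedTimeCourse(data)
        if not isinstance(free, FreeParamSpec):
            free = FreeParamSpec(tuple(free))
        self.data = data
        self.profile = profile
        self.free = free
        self.fixed = fixed if fixed is not None else ModelParams()
        self.obs = obs if obs is not None else ObservationParams()
        self.dt = float(dt)
        self.weights = dict(weights or {})
        if (self.data.data["time_h"] > profile.duration).any():
            raise ValueError("data times exceed profile duration")
        # pre-index rows per genotype for fast prediction
        self._rows = {}
        for g in self.data.genotypes():
            sub = self.data.data[self.data.data["genotype"] == g]
            self._rows[g] = {
                "times": sub["time_h"].to_numpy(dtype=float),
                "assay": sub["assay"].to_numpy(),
                "value": sub["value"].to_numpy(dtype=float),
            }
        self._signal_cache = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, profile, free, **kwargs):
        return cls(ObservedTimeCourse(df), profile, free, **kwargs)

    # -- parameter plumbing -------------------------------------------------

    def split_theta(self, theta) -> tuple[ModelParams, ObservationParams]:
        theta = np.asarray(theta, dtype=float)
        if len(theta) != len(self.free.names):
            raise ValueError("theta length mismatch")
        mp_kw, ob_kw = {}, {}
        for name, val in zip(self.free.names, theta):
            if name in OBS_PARAM_NAMES:
                ob_kw[name] = float(val)
            else:
                mp_kw[name] = float(val)
        return self.fixed.replace(**mp_kw), self.obs.replace(**ob_kw)

    def _signals(self, params: ModelParams):
        key = tuple(getattr(params, n) for n in SIGNAL_PARAM_NAMES)
        sig = self._signal_cache.get(key)
        if sig is None:
            sig = compute_signals(self.profile, params, self.dt)
            self._signal_cache[key] = sig
        return sig

    def predict(self, theta, genotype: str) -> np.ndarray:
        """Predicted values for this genotype's data rows, in row order."""
        params, obsp = self.split_theta(theta)
        sig = self._signals(params)
        traj = simulate_mean_field(params, self.profile, genotype,
                                   dt=self.dt, signals=sig)
        rows = self._rows[genotype]
        pred = np.empty(len(rows["times"]))
        for assay, series, slope, icpt in (
                ("K27", traj.r, obsp.c27, obsp.b27),
                ("K4", traj.a, obsp.c4, obsp.b4),
                ("expr", traj.m, obsp.cm, 0.0)):
            mask = rows["assay"] == assay
            if mask.any():
                pred[mask] = slope * np.interp(rows["times"][mask],
                                               traj.grid, series) + icpt
        return pred

    # -- objective and fitting ----------------------------------------------

    def objective(self, theta) -> float:
        """Weighted SSE of log residuals; +inf on simulation failure."""
        total = 0.0
        for g, rows in self._rows.items():
            try:
                pred = self.predict(theta, g)
            except (FloatingPointError, ValueError) as exc:
                logger.warning("simulation failed at theta=%s (%s)", theta, exc)
                return np.inf
            res = np.log(rows["value"] + EPS) - np.log(np.maximum(pred, 0.0)
                                                       + EPS)
            w = np.array([self.weights.get(a, 1.0) for a in rows["assay"]])
            total += float(np.sum(w * res * res))
        return total

    def fit(self, seed: int = 0, n_starts: int = 20,
            x0: np.ndarray | None = None,
            maxfev: int | None = None) -> "HistoneKineticsResults":
        """Multi-start Nelder–Mead minimisation; deterministic given seed.

        Starts are Latin-hypercube samples in the (log-)bounded search box;
        ``x0``, if given, replaces the first start (used by the bootstrap
        to polish from the full-data optimum).
        """
        d = len(self.free.names)
        zb = np.array(self.free.z_bounds())
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        starts = qmc.scale(sampler.random(n_starts), zb[:, 0], zb[:, 1])
        if x0 is not None:
            starts[0] = self.free.transform(self.free.clip(x0))

        def f(z):
            return self.objective(self.free.untransform(z))

        best = None
        per_start = []
        n_conv = 0
        for z0 in starts:
            res = optimize.minimize(
                f, z0, method="Nelder-Mead",
                bounds=[tuple(b) for b in zb],
                options={"xatol": 1e-6, "fatol": 1e-10,
                         "maxfev": maxfev or 400 * d})
            ok = np.isfinite(res.fun)
            per_start.append(float(res.fun))
            n_conv += int(ok)
            if ok and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(
                "no start converged; per-start objectives: " + repr(per_start))
        theta_hat = self.free.untransform(best.x)
        return HistoneKineticsResults(
            model=self, theta_hat=dict(zip(self.free.names, theta_hat)),
            objective=float(best.fun), n_starts=n_starts,
            n_converged=n_conv, start_objectives=per_start, seed=seed)


@dataclass
class HistoneKineticsResults:
    """Fit result: estimates, objective, start diagnostics, bootstrap CI."""

    model: HistoneKineticsModel
    theta_hat: dict
    objective: float
    n_starts: int
    n_converged: int
    start_objectives: list
    seed: int
    conf_int: dict = field(default_factory=dict)

    @property
    def params(self) -> ModelParams:
        return self.model.split_theta(self.theta_vector())[0]

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta_hat[n] for n in self.model.free.names])

    def bootstrap(self, B: int = 200, seed: int | None = None,
                  level: float = 0.95, maxfev: int = 120) -> dict:
        """Replicate-resampling percentile intervals for all free parameters.

        Each of the B resamples refits from the full-data optimum with a
        single budget-limited Nelder–Mead polish.
        """
        rng = np.random.default_rng(self.seed if seed is None else seed)
        draws = []
        for _ in range(B):
            data_b = self.model.data.resample_replicates(rng)
            m_b = HistoneKineticsModel(
                data_b, self.model.profile, self.model.free,
                fixed=self.model.fixed, obs=self.model.obs,
                dt=self.model.dt, weights=self.model.weights)
            m_b._signal_cache = self.model._signal_cache  # shared, read-only
            try:
                r_b = m_b.fit(seed=0, n_starts=1, x0=self.theta_vector(),
                              maxfev=maxfev)
                draws.append(r_b.theta_vector())
            except RuntimeError:
                continue
        draws = np.array(draws)
        lo, hi = 50 * (1 - level), 50 * (1 + level)
        self.conf_int = {
            n: (float(np.percentile(draws[:, i], lo)),
                float(np.percentile(draws[:, i], hi)))
            for i, n in enumerate(self.model.free.names)}
        return self.conf_int

    def summary(self) -> str:
        lines = [
            "Histone kinetics fit",
            "=" * 54,
            f"condition:      {self.model.data.condition or '-'}",
            f"genotypes:      {', '.join(self.model.data.genotypes())}",
            f"n observations: {len(self.model.data.data)}",
            f"objective (log-SSE): {self.objective:.6g}",
            f"starts converged:    {self.n_converged}/{self.n_starts}"
            f"   (seed={self.seed})",
            "-" * 54,
            f"{'parameter':<12}{'estimate':>12}{'95% CI':>26}",
        ]
        for n in self.model.free.names:
            ci = self.conf_int.get(n)
            ci_s = f"[{ci[0]:.4g}, {ci[1]:.4g}]" if ci else "-"
            lines.append(f"{n:<12}{self.theta_hat[n]:>12.4g}{ci_s:>26}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def predict_frame(self, genotype: str) -> pd.DataFrame:
        """Observed vs fitted values for one genotype."""
        rows = self.model._rows[genotype]
        pred = self.model.predict(self.theta_vector(), genotype)
        return pd.DataFrame({"time_h": rows["times"], "assay": rows["assay"],
                             "observed": rows["value"], "fitted": pred})

    def to_dict(self) -> dict:
        return {"theta_hat": self.theta_hat, "objective": self.objective,
                "n_starts": self.n_starts, "n_converged": self.n_converged,
                "start_objectives": self.start_objectives, "seed": self.seed,
                "conf_int": self.conf_int}


#: spec-level alias: a fit outcome is a FitResult
FitResult = HistoneKineticsResults


def sse_objective(theta, data, profile, spec: FreeParamSpec,
                  fixed: ModelParams | None = None,
                  obs: ObservationParams | None = None,
                  dt: float = 0.25, weights: dict | None = None) -> float:
    """Log-residual weighted SSE of ``theta`` against a time course."""
    m = HistoneKineticsModel(data, profile, spec, fixed=fixed, obs=obs,
                             dt=dt, weights=weights)
    return m.objective(np.asarray(theta, dtype=float))


def fit_params(data, profile, spec, fixed: ModelParams | None = None,
               seed: int = 0, n_starts: int = 20,
               obs: ObservationParams | None = None,
               dt: float = 0.25) -> FitResult:
    """Fit free parameters to one time course (single or both genotypes)."""
    m = HistoneKineticsModel(data, profile, spec, fixed=fixed, obs=obs, dt=dt)
    return m.fit(seed=seed, n_starts=n_starts)


def fit_joint_genotypes(data_wt, data_jmjq, profile, spec,
                        fixed: ModelParams | None = None, seed: int = 0,
                        n_starts: int = 12, bootstrap_B: int = 200,
                        obs: ObservationParams | None = None,
                        dt: float = 0.25) -> FitResult:
    """Joint WT + mutant fit with shared parameters and free ``phi_jmj``.

    The two datasets are stacked (their genotype columns must be pure WT
    and pure jmjq); ``phi_jmj`` is added to the free set if absent.  The
    returned result carries a replicate-resampling bootstrap percentile
    interval for every free parameter (B resamples, seeded).
    """
    if not isinstance(data_wt, ObservedTimeCourse):
        data_wt = ObservedTimeCourse(data_wt)
    if not isinstance(data_jmjq, ObservedTimeCourse):
        data_jmjq = ObservedTimeCourse(data_jmjq)
    if data_wt.genotypes() != ["WT"] or data_jmjq.genotypes() != ["jmjq"]:
        raise ValueError("expected pure-WT and pure-jmjq datasets")
    if data_wt.condition != data_jmjq.condition:
        raise ValueError("datasets come from different conditions")
    if not isinstance(spec, FreeParamSpec):
        spec = FreeParamSpec(tuple(spec))
    if "phi_jmj" not in spec.names:
        spec = FreeParamSpec(spec.names + ("phi_jmj",), spec.bounds,
                             spec.log_scale)
    data = ObservedTimeCourse(
        pd.concat([data_wt.data, data_jmjq.data], ignore_index=True),
        condition=data_wt.condition)
    m = HistoneKineticsModel(data, profile, spec, fixed=fixed, obs=obs, dt=dt)
    result = m.fit(seed=seed, n_starts=n_starts)
    if bootstrap_B:
        result.bootstrap(B=bootstrap_B, seed=seed + 1)
    return result
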