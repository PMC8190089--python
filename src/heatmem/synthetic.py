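"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:
fluctuating field temperature series (diurnal sinusoid plus heat spikes),
noisy qPCR/ChIP time courses drawn around model predictions, and
negative-binomial count matrices with planted memory genes plus matched
ChIP region counts.  Each generator returns its truth object and is
bit-reproducible from its seed.

The chlorophyll helper converts spectrophotometric absorbances into total
chlorophyll (Chl a + b, µM), the phenotype readout used to quantify
acclimation success.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .inference import ObservedTimeCourse
from .model import (ModelParams, ObservationParams, observe,
                    simulate_mean_field)
from .screen import CountMatrix
from .temperature import TemperatureProfile

__all__ = [
    "FieldSpec",
    "AssayNoise",
    "PlantedTruth",
    "PhenotypeAssayParams",
    "gen_field_profile",
    "gen_timecourse",
    "default_screen_design",
    "gen_count_matrix",
    "gen_region_counts",
    "chlorophyll_content",
]


@dataclass(frozen=True)
class FieldSpec:
    """Stylised fluctuating field-temperature series.

    A diurnal sinusoid between ``night_temp`` and ``day_temp`` (warmest at
    14:00) with triangular heat spikes (3 h rise/fall, peak at 13:00) on
    the given days and seeded Gaussian noise.  Defaults give two spikes to
    >30 degC separated by a 2-day gap, the defining feature of the field
    conditions under which recurring-heat memory is assayed.
    """

    days: int = 6
    day_temp: float = 28.0
    night_temp: float = 18.0
    spike_days: tuple = (1, 3)
    spike_peaks: tuple = (36.0, 37.0)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if len(self.spike_days) < 2:
            raise ValueError("need at least two spikes")
        if len(self.spike_days) != len(self.spike_peaks):
            raise ValueError("spike_days and spike_peaks differ in length")
        if any(p <= 30.0 for p in self.spike_peaks):
            raise ValueError("spike peaks must exceed 30 degC")
        if any(d2 <= d1 for d1, d2 in zip(self.spike_days,
                                          self.spike_days[1:])):
            raise ValueError("spike days must be increasing")
        if max(self.spike_days) >= self.days:
            raise ValueError("spike day outside the series")
        if self.day_temp <= self.night_temp:
            raise ValueError("day_temp must exceed night_temp")

    @property
    def gap_days(self) -> float:
        return self.spike_days[1] - self.spike_days[0]


def gen_field_profile(spec: FieldSpec) -> TemperatureProfile:
    """Hourly field-like temperature series from a :class:`FieldSpec`."""
    rng = np.random.default_rng(spec.seed)
    hours = np.arange(spec.days * 24, dtype=float)
    mid = 0.5 * (spec.day_temp + spec.night_temp)
    amp = 0.5 * (spec.day_temp - spec.night_temp)
    # warmest at 14:00, coldest at 02:00
    temps = mid + amp * np.sin(2 * np.pi * (hours % 24 - 8.0) / 24.0)
    for day, peak in zip(spec.spike_days, spec.spike_peaks):
        center = day * 24 + 13.0
        w = np.clip(1.0 - np.abs(hours - center) / 3.0, 0.0, 1.0)
        temps = temps + w * np.maximum(peak - temps, 0.0)
    temps = temps + rng.normal(0.0, spec.noise_sd, size=len(hours))
    # noise must not push a scheduled spike below the calling threshold
    for day, peak in zip(spec.spike_days, spec.spike_peaks):
        i = int(day * 24 + 13)
        temps[i] = peak
    return TemperatureProfile(times=hours, temps=temps,
                              duration=float(spec.days * 24),
                              label=f"field:synthetic(seed={spec.seed})")


@dataclass(frozen=True)
class AssayNoise:
    """Multiplicative (lognormal) measurement noise per assay."""

    sd_expr: float = 0.2
    sd_chip: float = 0.2
    replicates: int = 3

    def __post_init__(self):
        if min(self.sd_expr, self.sd_chip) < 0:
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")

    def sd_for(self, assay: str) -> float:
        return self.sd_expr if assay == "expr" else self.sd_chip


@dataclass
class PlantedTruth:
    """Ground truth accompanying a generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    genes: pd.DataFrame | None = None
    regions: pd.DataFrame | None = None


@dataclass(frozen=True)
class PhenotypeAssayParams:
    """Chlorophyll quantification constants (µM per absorbance unit)."""

    chl_c1: float = 19.43  # coefficient of A at 646.8 nm
    chl_c2: float = 8.05   # coefficient of A at 663.8 nm


def chlorophyll_content(A646_8, A663_8,
                        params: PhenotypeAssayParams = PhenotypeAssayParams()):
    """Total chlorophyll (Chl a + b, µM) from DMF-extract absorbances."""
    a1 = np.asarray(A646_8, dtype=float)
    a2 = np.asarray(A663_8, dtype=float)
    if np.any(a1 < 0) or np.any(a2 < 0):
        raise ValueError("absorbances must be >= 0")
    out = params.chl_c1 * a1 + params.chl_c2 * a2
    return float(out) if out.ndim == 0 else out


def gen_timecourse(params: ModelParams, obs: ObservationParams,
                   profile: TemperatureProfile, genotypes, sample_times,
                   noise: AssayNoise = AssayNoise(), seed: int = 0,
                   assays=("expr", "K27"), condition: str = "",
                   dt: float = 0.25):
    """Noisy replicated measurements around mean-field model predictions.

    Values are prediction x LogNormal(0, sd) per replicate.  Returns the
    :class:`ObservedTimeCourse` and a :class:`PlantedTruth` holding the
    generating parameters.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if (sample_times < 0).any() or (sample_times > profile.duration).any():
        raise ValueError("sample times outside the profile")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in genotypes:
        traj = simulate_mean_field(params, profile, genotype, dt=dt)
        pred = observe(traj, obs, times=sample_times)
        pred = pred[pred["assay"].isin(assays)]
        for _, row in pred.iterrows():
            sd = noise.sd_for(row["assay"])
            for rep in range(1, noise.replicates + 1):
                factor = np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0
                rows.append((row["time_h"], row["assay"], genotype, rep,
                             row["value"] * factor))
    data = pd.DataFrame(rows, columns=["time_h", "assay", "genotype",
                                       "replicate", "value"])
    truth = PlantedTruth(seed=seed,
                         params={"model": params.to_dict(),
                                 "noise": asdict(noise)})
    return ObservedTimeCourse(data, condition=condition), truth


def default_screen_design(replicates: int = 3) -> pd.DataFrame:
    """Design table: WT/jmjq x {0, 4, 24} h x replicates."""
    rows = []
    for genotype in ("WT", "jmjq"):
        for t in (0, 4, 24):
            for rep in range(1, replicates + 1):
                rows.append((f"{genotype}_t{t}_r{rep}", genotype, t, rep))
    return pd.DataFrame(rows, columns=["sample", "genotype", "time_h",
                                       "replicate"]).set_index("sample")


def gen_count_matrix(n_genes: int = 5000, n_memory: int = 200,
                     design: pd.DataFrame | None = None, effect: float = 2.0,
                     dispersion: float = 0.1, seed: int = 0):
    """NB count matrix with planted memory genes.

    Gene baselines are lognormal; memory genes receive a genotype x time
    log2 effect of +-``effect`` in the mutant at 4 and/or 24 h and exactly
    0 at 0 h.  Library sizes are uniform in [0.8, 1.2] x 10^7.  Returns
    (:class:`CountMatrix`, :class:`PlantedTruth`); truth lists per-gene
    memory flag, direction and per-time log2 effects.
    """
    if n_memory > n_genes:
        raise ValueError("n_memory cannot exceed n_genes")
    if design is None:
        design = default_screen_design()
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base_cpm = rng.lognormal(mean=3.0, sigma=1.5, size=n_genes)

    is_memory = np.zeros(n_genes, dtype=bool)
    mem_idx = rng.choice(n_genes, size=n_memory, replace=False)
    is_memory[mem_idx] = True
    sign = np.zeros(n_genes)
    sign[mem_idx] = rng.choice([-1.0, 1.0], size=n_memory)
    which = rng.choice(3, size=n_memory, p=[0.6, 0.2, 0.2])  # both/4h/24h
    lfc4 = np.zeros(n_genes)
    lfc24 = np.zeros(n_genes)
    lfc4[mem_idx] = np.where(which != 2, sign[mem_idx] * effect, 0.0)
    lfc24[mem_idx] = np.where(which != 1, sign[mem_idx] * effect, 0.0)

    lib = rng.uniform(0.8e7, 1.2e7, size=len(design))
    counts = np.empty((n_genes, len(design)), dtype=np.int64)
    for j, (sample, row) in enumerate(design.iterrows()):
        lfc = np.zeros(n_genes)
        if row["genotype"] == "jmjq":
            if row["time_h"] == 4:
                lfc = lfc4
            elif row["time_h"] == 24:
                lfc = lfc24
        mu = base_cpm * 2.0 ** lfc / 1e6 * lib[j]
        if dispersion == 0.0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=design.index),
                     design, lib_sizes=pd.Series(lib, index=design.index))
    truth_genes = pd.DataFrame({
        "is_memory": is_memory,
        "direction": np.where(sign > 0, "up", np.where(sign < 0, "down", "")),
        "lfc4": lfc4, "lfc24": lfc24, "base_cpm": base_cpm}, index=genes)
    truth = PlantedTruth(seed=seed, genes=truth_genes,
                         params={"n_genes": n_genes, "n_memory": n_memory,
                                 "effect": effect, "dispersion": dispersion})
    return cm, truth


def gen_region_counts(n_regions: int = 2000,
                      planted_hyper_fraction: float = 0.2,
                      fc_true: float = 2.0, libsizes=(1e7, 1e7),
                      base_mean: float = 500.0, seed: int = 0,
                      planted_mask=None):
    """Poisson ChIP region counts with planted hypermethylated regions.

    Planted regions have mutant mean = fc_true x WT mean; the rest are
    equal.  ``planted_mask`` (bool array) overrides the random choice so
    planted regions can be tied to specific genes.  Returns a frame with
    columns region/count_wt/count_mut/planted_hyper and a PlantedTruth.
    """
    if not 0.0 <= planted_hyper_fraction <= 1.0:
        raise ValueError("planted fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if planted_mask is None:
        n_hyper = int(round(planted_hyper_fraction * n_regions))
        planted = np.zeros(n_regions, dtype=bool)
        planted[rng.choice(n_regions, size=n_hyper, replace=False)] = True
    else:
        planted = np.asarray(planted_mask, dtype=bool)
        n_regions = len(planted)
    mean_wt = rng.lognormal(mean=np.log(base_mean), sigma=0.4, size=n_regions)
    lib_wt, lib_mut = float(libsizes[0]), float(libsizes[1])
    mean_mut = mean_wt * np.where(planted, fc_true, 1.0) * (lib_mut / lib_wt)
    table = pd.DataFrame({
        "region": [f"R{i:05d}" for i in range(n_regions)],
        "count_wt": rng.poisson(mean_wt),
        "count_mut": rng.poisson(mean_mut),
        "planted_hyper": planted,
    }).set_index("region")
    truth = PlantedTruth(seed=seed, regions=table[["planted_hyper"]].copy(),
                         params={"fc_true": fc_true, "base_mean": base_mean,
                                 "libsizes": [lib_wt, lib_mut]})
    return table, truth
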