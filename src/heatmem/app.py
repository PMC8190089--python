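"""End-to-end demo pipelines and run configuration.

Each demo ties the modules together on synthetic inputs and writes plain
TSV/JSON bundles: the lab demo contrasts WT and mutant trajectories with
and without acclimation, the field demo runs the model under a fluctuating
field-like temperature series, and the screen demo exercises the full
count-based memory-gene screen against its planted truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (ModelParams, ObservationParams, simulate_mean_field,
                    simulate_ssa)
from .screen import (cluster_profiles, cpm_normalize,
                     estimate_common_dispersion, hypergeom_overlap, nb_lrt,
                     screen_memory_genes, call_fold_change_regions)
from .synthetic import (FieldSpec, gen_count_matrix, gen_field_profile,
                        gen_region_counts)
from .temperature import (LabProtocol, build_lab_profile, detect_spikes,
                          read_temperature_csv)

__all__ = ["RunConfig", "load_config", "run_demo_lab", "run_demo_field",
           "run_screen_demo"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    model: ModelParams = field(default_factory=ModelParams)
    obs: ObservationParams = field(default_factory=ObservationParams)
    free: tuple = ("vJ", "phi_jmj")
    engine: str = "ode"
    n_runs: int = 200
    seed: int = 0
    out_dir: str = "heatmem_out"
    field_csv: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.engine not in ("ode", "ssa", "me"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2^31)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    YAML sections: ``model`` and ``observation`` (field names exactly as
    in ModelParams / ObservationParams) and the remaining top-level keys
    of :class:`RunConfig`.  Unknown keys are rejected.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    model_kw = raw.pop("model", {}) or {}
    obs_kw = raw.pop("observation", {}) or {}
    known_model = {f.name for f in dataclasses.fields(ModelParams)}
    known_obs = {f.name for f in dataclasses.fields(ObservationParams)}
    bad = set(model_kw) - known_model
    if bad:
        raise ValueError(f"unknown model keys: {sorted(bad)}")
    bad = set(obs_kw) - known_obs
    if bad:
        raise ValueError(f"unknown observation keys: {sorted(bad)}")
    known_top = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - (known_top - {"model", "obs"})
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    raw.update(overrides)
    cfg = RunConfig(model=ModelParams(**model_kw),
                    obs=ObservationParams(**obs_kw), **raw)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg


def _simulate(cfg: RunConfig, profile, genotype, seed):
    if cfg.engine == "ssa":
        return simulate_ssa(cfg.model, profile, genotype,
                            n_runs=cfg.n_runs, seed=seed)
    return simulate_mean_field(cfg.model, profile, genotype)


def _write_traj(traj, path):
    traj.to_frame().to_csv(path, sep="\t", index=False)


def run_demo_lab(cfg: RunConfig) -> dict:
    """WT vs mutant under +ACC+HS and +HS: trajectories and summary table.

    The summary reports predicted expression at the end of ACC, end of HS
    and 4/24 h later; under +ACC+HS the WT exceeds the mutant at HS+4 h
    and the WT/mutant gap shrinks without acclimation.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = {
        "+ACC+HS": build_lab_profile(LabProtocol()),
        "+HS": build_lab_profile(LabProtocol(acc_enabled=False)),
    }
    proto = LabProtocol()
    acc_end = proto.acc_time + proto.acc_duration
    hs_end = proto.hs_time + proto.hs_duration
    landmarks = {"ACC+0h": acc_end, "HS+0h": hs_end,
                 "HS+4h": hs_end + 4, "HS+24h": hs_end + 24}
    rows = []
    paths = {}
    for tag, prof in scenarios.items():
        for i, genotype in enumerate(("WT", "jmjq")):
            traj = _simulate(cfg, prof, genotype, cfg.seed + i)
            name = f"traj_{tag.strip('+').replace('+', '_')}_{genotype}.tsv"
            _write_traj(traj, out / name)
            paths[(tag, genotype)] = out / name
            rows.append({"scenario": tag, "genotype": genotype,
                         **{k: traj.at(t)["m"] for k, t in landmarks.items()}})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary_lab.tsv", sep="\t", index=False)
    logger.info("lab demo written to %s", out)
    return {"summary": summary, "paths": paths, "out_dir": out}


def run_demo_field(cfg: RunConfig) -> dict:
    """WT vs mutant under a fluctuating field series with spike annotation."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.field_csv:
        profile = read_temperature_csv(cfg.field_csv)
    else:
        profile = gen_field_profile(FieldSpec(seed=cfg.seed))
    spikes = detect_spikes(profile)
    if len(spikes) == 0:
        logger.warning("no heat spikes detected in the field profile")
    trajs = {}
    for i, genotype in enumerate(("WT", "jmjq")):
        traj = _simulate(cfg, profile, genotype, cfg.seed + i)
        _write_traj(traj, out / f"traj_field_{genotype}.tsv")
        trajs[genotype] = traj
    ann = pd.DataFrame([{"start_h": s, "end_h": e, "max_c": m, "role": r}
                        for (s, e, m), r in zip(spikes.intervals,
                                                spikes.roles)])
    ann.to_csv(out / "spikes.tsv", sep="\t", index=False)
    # expression peak within 6 h after each spike end
    peaks = []
    for (s, e, mx), role in zip(spikes.intervals, spikes.roles):
        wt = trajs["WT"]
        win = (wt.grid >= e) & (wt.grid <= min(e + 6, profile.duration))
        t_peak = float(wt.grid[win][np.argmax(wt.m[win])]) if win.any() else np.nan
        peaks.append({"role": role, "spike_end_h": e, "expr_peak_h": t_peak})
    peak_df = pd.DataFrame(peaks)
    peak_df.to_csv(out / "expression_peaks.tsv", sep="\t", index=False)
    logger.info("field demo written to %s", out)
    return {"profile": profile, "spikes": spikes, "trajectories": trajs,
            "peaks": peak_df, "out_dir": out}


def run_screen_demo(cfg: RunConfig, n_genes: int = 5000,
                    n_memory: int = 200, alpha: float = 0.05,
                    k: int = 6) -> dict:
    """Full synthetic screen: DE at 0/4/24 h, selection, clustering, overlap.

    Region counts are planted so that 55% of the planted down-memory genes
    carry a hypermethylated gene-body region, mirroring the coupling
    between lost expression and retained repressive methylation; the
    hypergeometric overlap test should therefore be strongly significant.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, truth = gen_count_matrix(n_genes=n_genes, n_memory=n_memory,
                                     seed=cfg.seed)
    disp = estimate_common_dispersion(counts)
    de = {t: nb_lrt(counts, t, disp, alpha=alpha) for t in (0, 4, 24)}
    for t, d in de.items():
        d.table.to_csv(out / f"de_{t}h.tsv", sep="\t")
    screen = screen_memory_genes(de[0], de[4], de[24], alpha=alpha)

    # profile clustering on selected genes (mean log2 CPM per group)
    if len(screen.genes) >= k:
        logcpm = np.log2(cpm_normalize(counts) + 0.5)
        cols = {}
        for genotype in ("WT", "jmjq"):
            for t in (0, 4, 24):
                samples = counts.samples_at(genotype, t)
                cols[f"{genotype}_{t}h"] = logcpm.loc[screen.genes,
                                                      samples].mean(axis=1)
        clusters = cluster_profiles(pd.DataFrame(cols), k=k, seed=cfg.seed)
        screen.clusters = clusters
    screen.table.to_csv(out / "screen.tsv", sep="\t")

    # truth-aware confusion table
    truth_mem = set(truth.genes.index[truth.genes["is_memory"]])
    sel = set(screen.genes)
    tp = len(sel & truth_mem)
    sens = tp / max(len(truth_mem), 1)
    fdr = (len(sel) - tp) / max(len(sel), 1)

    # region counts: 55% of planted down genes carry a hyper region
    down_true = truth.genes.index[(truth.genes["is_memory"])
                                  & (truth.genes["direction"] == "down")]
    rng = np.random.default_rng(cfg.seed + 1)
    hyper_genes = set(rng.choice(down_true, size=int(round(0.55 * len(down_true))),
                                 replace=False))
    planted_mask = np.array([g in hyper_genes for g in counts.genes])
    regions, _ = gen_region_counts(planted_mask=planted_mask,
                                   seed=cfg.seed + 2)
    calls = call_fold_change_regions(regions["count_wt"],
                                     regions["count_mut"], 1e7, 1e7)
    hyper_called = set(np.asarray(counts.genes)[np.asarray(
        calls.table["call"] == "hyper")])
    down_called = set(screen.direction("down"))
    p_overlap = hypergeom_overlap(len(down_called), len(hyper_called),
                                  len(down_called & hyper_called), n_genes)
    confusion = pd.DataFrame([{
        "n_selected": len(sel), "n_true_memory": len(truth_mem),
        "true_positives": tp, "sensitivity": sens, "fdr": fdr,
        "n_down_called": len(down_called), "n_hyper_called": len(hyper_called),
        "n_overlap": len(down_called & hyper_called),
        "overlap_p": p_overlap, "dispersion_hat": disp,
    }])
    confusion.to_csv(out / "confusion.tsv", sep="\t", index=False)
    with open(out / "run.json", "w") as fh:
        json.dump({"seed": cfg.seed, "alpha": alpha, "k": k,
                   "n_genes": n_genes, "n_memory": n_memory}, fh, indent=2)
    logger.info("screen demo written to %s (sens=%.3f fdr=%.3f p=%.3g)",
                out, sens, fdr, p_overlap)
    return {"screen": screen, "confusion": confusion, "de": de,
            "overlap_p": p_overlap, "sensitivity": sens, "fdr": fdr,
            "out_dir": out}
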