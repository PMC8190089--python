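"""Memory-gene screening pipeline for count data.

Implements the screening logic used to find heat-memory genes from
RNA-seq-style count matrices of two genotypes (WT and the demethylase
quadruple mutant) sampled 0, 4 and 24 h after a triggering heat shock:

1. library-size (CPM) normalisation,
2. a self-contained negative-binomial likelihood-ratio test per gene and
   time point (common dispersion, library-size offsets, chi-square(1)
   p-values, Benjamini–Hochberg FDR),
3. the memory-gene criterion — no genotype difference at 0 h but a
   significant difference at 4 or 24 h,
4. k-means clustering of z-scored expression profiles (k = 6 by default),
5. a hypergeometric upper-tail test for overlap between gene sets (e.g.
   downregulated memory genes vs H3K27me3-hypermethylated genes),
6. 1.5-fold enrichment calls on per-region ChIP coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "ScreenResult",
    "RegionCallResult",
    "cpm_normalize",
    "estimate_common_dispersion",
    "nb_lrt",
    "bh_adjust",
    "screen_memory_genes",
    "cluster_profiles",
    "hypergeom_overlap",
    "read_bed",
    "call_fold_change_regions",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus a sample design table.

    ``design`` is indexed by sample id with columns ``genotype`` (WT/jmjq),
    ``time_h`` and ``replicate``.  Library sizes default to column sums.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    lib_sizes: pd.Series | None = None

    def __post_init__(self):
        counts = pd.DataFrame(self.counts)
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any() or np.any(vals != np.round(vals)):
            raise ValueError("counts must be non-negative integers")
        design = pd.DataFrame(self.design)
        for col in ("genotype", "time_h", "replicate"):
            if col not in design.columns:
                raise ValueError(f"design missing column {col!r}")
        missing = set(counts.columns) - set(design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        self.counts = counts.astype(np.int64)
        self.design = design.loc[counts.columns]
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes,
                                       index=counts.columns).astype(float)
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def genes(self):
        return self.counts.index

    def samples_at(self, genotype: str, time_h) -> list:
        d = self.design
        return list(d.index[(d["genotype"] == genotype)
                            & (d["time_h"] == time_h)])

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        return cls(counts, design)


@dataclass
class DEResult:
    """Per-gene differential test at one contrast time.

    ``table`` columns: log2fc (mutant vs WT), stat (LRT), pvalue, qvalue.
    """

    table: pd.DataFrame
    contrast_time: float

    def __post_init__(self):
        need = {"log2fc", "stat", "pvalue", "qvalue"}
        if not need <= set(self.table.columns):
            raise ValueError(f"DE table missing {need - set(self.table.columns)}")

    @property
    def genes(self):
        return self.table.index


@dataclass
class ScreenResult:
    """Outcome of the 0/4/24-h memory-gene screen.

    ``table`` is indexed by the selected genes with columns ``direction``
    ('up'/'down' in the mutant) and ``qualifying_times``; ``clusters`` (if
    clustering was run) maps selected genes to cluster labels 1..k.
    """

    table: pd.DataFrame
    alpha: float
    clusters: pd.Series | None = None

    @property
    def genes(self) -> list:
        return list(self.table.index)

    def direction(self, which: str) -> list:
        return list(self.table.index[self.table["direction"] == which])


@dataclass
class RegionCallResult:
    """Fold-enrichment calls per region: cpm_wt, cpm_mut, ratio, call."""

    table: pd.DataFrame
    fc: float

    def calls(self, which: str) -> list:
        return list(self.table.index[self.table["call"] == which])


def cpm_normalize(counts: CountMatrix | pd.DataFrame,
                  lib_sizes=None) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6."""
    if isinstance(counts, CountMatrix):
        lib_sizes = counts.lib_sizes
        counts = counts.counts
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = pd.Series(lib_sizes, index=counts.columns).astype(float)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lib_sizes, axis=1) * 1e6


def estimate_common_dispersion(counts: CountMatrix) -> float:
    """Pooled method-of-moments NB dispersion across replicate groups.

    Counts are first scaled to a common library size; within each
    (genotype, time) group the per-gene sample mean and variance enter the
    pooled solution of var = mu + phi*mu^2, clipped at 0.
    """
    sbar = counts.lib_sizes.mean()
    scaled = counts.counts * (sbar / counts.lib_sizes)
    groups = counts.design.groupby(["genotype", "time_h"]).groups
    num = 0.0
    den = 0.0
    any_replicated = False
    for _, samples in groups.items():
        samples = list(samples)
        if len(samples) < 2:
            continue
        any_replicated = True
        sub = scaled[samples].to_numpy()
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        keep = mu > 0
        num += float(np.sum(var[keep] - mu[keep]))
        den += float(np.sum(mu[keep] ** 2))
    if not any_replicated:
        raise ValueError("no replicated (genotype, time) group")
    return max(num / den, 0.0) if den > 0 else 0.0


def _nb_loglik(y, mu, phi):
    """NB log-likelihood (summed over samples axis) at mean mu, dispersion phi."""
    mu = np.maximum(mu, 1e-12)
    if phi == 0.0:
        return np.sum(y * np.log(mu) - mu - gammaln(y + 1), axis=-1)
    r = 1.0 / phi
    return np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                  + y * np.log(mu) - y * np.log(mu + r)
                  + r * np.log(r) - r * np.log(mu + r), axis=-1)


def _nb_mle_rate(y, s, phi, n_iter=50):
    """Per-gene MLE of the rate m in mu_i = s_i * m (vectorised Newton).

    y: (genes, samples); s: (samples,).  For phi = 0 this is the closed
    form sum(y)/sum(s); otherwise Newton iterations on log m.
    """
    ytot = y.sum(axis=1)
    stot = s.sum()
    m = ytot / stot
    if phi == 0.0:
        return m
    pos = m > 0
    logm = np.log(np.maximum(m, 1e-300))
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(logm)[:, None]
        w = phi * mu / (1.0 + phi * mu)
        grad = np.sum(y - (y + 1.0 / phi) * w, axis=1)
        hess = -np.sum((y + 1.0 / phi) * w / (1.0 + phi * mu), axis=1)
        step = np.where(hess < 0, grad / -hess, 0.0)
        step = np.clip(step, -2.0, 2.0)
        logm = np.where(pos, logm + step, logm)
        if not pos.any() or np.max(np.abs(step[pos])) < 1e-12:
            break
    out = np.exp(logm)
    out[~pos] = 0.0
    return out


def nb_lrt(counts: CountMatrix, contrast_time, dispersion: float,
           alpha: float = 0.05) -> DEResult:
    """Genotype likelihood-ratio test at one time point.

    Per gene, compares the two-genotype-mean NB model against a common
    mean (both with library-size offsets and the given common dispersion);
    the statistic is referred to chi-square with 1 df and q-values are
    Benjamini–Hochberg.  log2fc is mutant over WT on the CPM scale with a
    0.5 pseudocount.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    s_wt = counts.samples_at("WT", contrast_time)
    s_mut = counts.samples_at("jmjq", contrast_time)
    if len(s_wt) < 2 or len(s_mut) < 2:
        raise ValueError(f"both genotypes need >= 2 replicates at "
                         f"t={contrast_time}")
    y_wt = counts.counts[s_wt].to_numpy(dtype=float)
    y_mut = counts.counts[s_mut].to_numpy(dtype=float)
    lib_wt = counts.lib_sizes[s_wt].to_numpy()
    lib_mut = counts.lib_sizes[s_mut].to_numpy()

    m_wt = _nb_mle_rate(y_wt, lib_wt, dispersion)
    m_mut = _nb_mle_rate(y_mut, lib_mut, dispersion)
    y_all = np.concatenate([y_wt, y_mut], axis=1)
    lib_all = np.concatenate([lib_wt, lib_mut])
    m_null = _nb_mle_rate(y_all, lib_all, dispersion)

    ll_full = (_nb_loglik(y_wt, lib_wt[None, :] * m_wt[:, None], dispersion)
               + _nb_loglik(y_mut, lib_mut[None, :] * m_mut[:, None],
                            dispersion))
    ll_null = _nb_loglik(y_all, lib_all[None, :] * m_null[:, None], dispersion)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvalue = stats.chi2.sf(stat, df=1)
    qvalue = bh_adjust(pvalue)
    log2fc = np.log2((m_mut * 1e6 + 0.5) / (m_wt * 1e6 + 0.5))
    table = pd.DataFrame({"log2fc": log2fc, "stat": stat,
                          "pvalue": pvalue, "qvalue": qvalue},
                         index=counts.genes)
    return DEResult(table=table, contrast_time=contrast_time)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be in [0, 1] and not NaN")
    return multipletests(p, method="fdr_bh")[1]


def screen_memory_genes(de_0h: DEResult, de_4h: DEResult, de_24h: DEResult,
                        alpha: float = 0.05) -> ScreenResult:
    """Select genes equal at 0 h but different at 4 or 24 h after HS.

    A gene qualifies iff q(0h) >= alpha and min(q(4h), q(24h)) < alpha.
    Direction (up/down in the mutant) is the sign of log2fc at the
    earliest qualifying time.
    """
    idx = de_0h.genes
    for de in (de_4h, de_24h):
        if not idx.equals(de.genes):
            diff = idx.symmetric_difference(de.genes)
            raise ValueError(f"gene universes differ; e.g. {list(diff[:5])}")
    q0 = de_0h.table["qvalue"]
    q4 = de_4h.table["qvalue"]
    q24 = de_24h.table["qvalue"]
    selected = (q0 >= alpha) & ((q4 < alpha) | (q24 < alpha))
    rows = []
    for g in idx[selected]:
        times = [t for t, q in ((4, q4[g]), (24, q24[g])) if q < alpha]
        lfc = de_4h.table.loc[g, "log2fc"] if times[0] == 4 \
            else de_24h.table.loc[g, "log2fc"]
        rows.append((g, "up" if lfc > 0 else "down", tuple(times)))
    table = pd.DataFrame(rows, columns=["gene", "direction",
                                        "qualifying_times"]).set_index("gene")
    return ScreenResult(table=table, alpha=alpha)


def cluster_profiles(expr: pd.DataFrame, k: int = 6, seed: int = 0,
                     restarts: int = 100) -> pd.Series:
    """k-means on row-z-scored expression profiles (Pearson-equivalent).

    Rows are genes, columns (genotype x time) mean expression summaries.
    Constant rows carry no profile shape and are dropped with a warning.
    Returns a gene -> cluster (1..k) Series; deterministic given seed.
    """
    expr = pd.DataFrame(expr)
    sd = expr.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant profile(s)")
        expr = expr.loc[~const]
        sd = sd[~const]
    if k > len(expr):
        raise ValueError(f"k={k} exceeds {len(expr)} usable genes")
    z = expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels + 1, index=expr.index, name="cluster")


def hypergeom_overlap(n_A: int, n_B: int, n_overlap: int,
                      n_universe: int) -> float:
    """Upper-tail P[X >= n_overlap] for X ~ Hypergeom(universe, B, A draws)."""
    if not (0 <= n_overlap <= min(n_A, n_B) <= n_universe
            and max(n_A, n_B) <= n_universe
            and n_A + n_B - n_overlap <= n_universe):
        raise ValueError("inconsistent set sizes")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_B, n_A))


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file (0-based, half-open) into chrom/start/end/name."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i}: need >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {i}: {exc}") from None
            if not 0 <= start < end:
                raise ValueError(f"malformed BED line {i}: bad interval "
                                 f"[{start}, {end})")
            name = parts[3] if len(parts) > 3 else f"region_{i}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def call_fold_change_regions(cov_wt, cov_mut, lib_wt: float, lib_mut: float,
                             fc: float = 1.5,
                             regions: pd.DataFrame | None = None,
                             bed_path=None) -> RegionCallResult:
    """Call hyper/hypo regions from per-region coverage at a fold threshold.

    The reported ratio is (CPM_mut + 0.5) / (CPM_wt + 0.5), pseudocounts
    guarding zeros.  Calls compare the CPMs directly: ``hyper`` means
    CPM_mut >= fc * CPM_wt, ``hypo`` means CPM_wt >= fc * CPM_mut (regions
    with zero coverage in both channels are ``none``), so a region at
    exactly the fold threshold is called regardless of its coverage depth.
    Region identities may come from a BED file (0-based half-open) or an
    explicit frame; counts are assumed precomputed per region in the same
    order.
    """
    if fc <= 1:
        raise ValueError("fc must be > 1")
    if bed_path is not None:
        regions = read_bed(bed_path)
    cov_wt = np.asarray(cov_wt, dtype=float)
    cov_mut = np.asarray(cov_mut, dtype=float)
    if cov_wt.shape != cov_mut.shape:
        raise ValueError("coverage vectors differ in length")
    if lib_wt <= 0 or lib_mut <= 0:
        raise ValueError("library sizes must be positive")
    if regions is not None and len(regions) != len(cov_wt):
        raise ValueError("regions and coverage vectors differ in length")
    cpm_wt = cov_wt / lib_wt * 1e6
    cpm_mut = cov_mut / lib_mut * 1e6
    ratio = (cpm_mut + 0.5) / (cpm_wt + 0.5)
    nonzero = (cpm_wt > 0) | (cpm_mut > 0)
    call = np.where(nonzero & (cpm_mut >= fc * cpm_wt), "hyper",
                    np.where(nonzero & (cpm_wt >= fc * cpm_mut), "hypo",
                             "none"))
    index = (regions["name"].to_numpy() if regions is not None
             else np.arange(len(cov_wt)))
    table = pd.DataFrame({"cpm_wt": cpm_wt, "cpm_mut": cpm_mut,
                          "ratio": ratio, "call": call}, index=index)
    return RegionCallResult(table=table, fc=fc)
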