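# Methods

## Model structure and assumptions

The locus is a set of `N` independent-position nucleosomes (default 20)
with states R (H3K27me3), U (unmodified), A (H3K4me3) and two-step
conversions R ⇌ U ⇌ A. Recruitment is global ("all-to-all"): the recruited
conversion rates use the current state fractions over all `N` nucleosomes,
including the converting one. Per nucleosome,

```
R -> U : k_act·a + k_noise + v0 + vJ·φ·J
U -> R : k_rep·r + k_noise
U -> A : k_act·a + k_noise + vUA_S·S
A -> U : k_rep·r + k_noise
```

with `r, u, a` the locus fractions and `φ` the genotype multiplier on the
demethylase-dependent R→U rate (`φ = 1` in WT, `phi_jmj < 1` in the
quadruple demethylase mutant; every other parameter is shared between
genotypes). Heat sensing is thresholded and linear: `dJ/dt = σ_J·1[T ≥
30 °C] − λ_J·J`, likewise `S` above 35 °C; the damage factor obeys
`dD/dt = −κ_D(D − D_min)` above 42 °C and `+ρ_D(1 − D)` below. With these
thresholds the 37 °C acclimation pulse induces `J` and `S` but no damage,
while the 43.5 °C shock induces all three. Transcription is
`dm/dt = D·(α0 + α·S·a·(1−r)) − δ·m`: it needs the activator signal and
the active mark, is antagonised multiplicatively by the repressive mark
(a smooth stand-in for a poised/balanced-marks requirement), and is
damped by unrecovered damage — which is what delays induction after the
shock. The locus starts Polycomb-repressed, `r(0) = r_init = 0.9`,
`a(0) = 0`, `m(0) = α0/δ`.

Deliberate simplifications: no sequence-specific recruitment, no explicit
heat-shock-factor protein dynamics, no replication dilution or nucleosome
turnover, no neighbour-limited (spatial) recruitment.

## Default parameters and how they were chosen

Rate constants for this class of model are not tabulated anywhere;
defaults were calibrated once, by coarse grid search on the deterministic
engine, to the qualitative regime the experiments define, and then frozen:

* expression induced within ~2 h of the acclimation pulse;
* H3K27me3 declining gradually (tens of hours) after acclimation and
  staying low through the 72-h memory phase in WT but not in the mutant;
* gradual, recovery-limited induction after the shock, with acclimated WT
  expressing several-fold more than the acclimated mutant at HS+4 h and
  the genotype gap much smaller without acclimation;
* a naive locus that does *not* fully derepress within the first 4 h of
  the shock (otherwise acclimation would confer no advantage at the
  readout time);
* finite memory: a few days at small-to-moderate `N`, lengthening with `N`.

The resulting regime has weak recruitment feedback relative to the
demethylation drive (`k_act = k_rep = 0.2 /h`, `k_noise = 0.02 /h`,
`vJ = 0.08 /h` per unit J, `λ_J = 0.02 /h` so the demethylase signal
persists for days, `σ_J = 2 /h`; `σ_S = 4 /h`, `λ_S = 0.25 /h`,
`vUA_S = 0.5`; `κ_D = 2 /h`, `ρ_D = 0.05 /h`, `D_min = 0.1`; `α = 50`,
`α0 = 0.02`, `δ = 0.2 /h`; `phi_jmj = 0.2`). Units: rates per hour,
temperatures °C, expression in arbitrary units relative to `α0/δ`.

Two consequences worth knowing. First, in the deterministic (mean-field)
limit the derepressed state is stable, so the acclimation memory never
decays; relaxation back to the repressed state is purely stochastic,
nucleated by single noisy U→R conversions whose relative effect (1/N)
shrinks with locus size. That *is* the mechanism by which multiple
modified nucleosomes lengthen memory, and it is why memory-duration scans
use the Gillespie engine, why the 30-day relaxation check runs at a small
locus (N = 3), and why the default `N = 20` holds its memory well past 30
days. Second, memory duration is monotone in the feedback strength
`k_act = k_rep` only while the acclimation pulse can still flip the locus
(up to k ≈ 0.2–0.3 at the default drive); stronger feedback raises the
re-silencing barrier past what a 20-min pulse can cross and the memory
ratio collapses. The property test covers the flip-capable regime.

## Numerics

* **Grid.** All engines share a time grid that is the union of a regular
  `dt` lattice (default 0.05 h; 0.25 h for fitting) with the profile
  breakpoints, so no heat window can fall between grid points; `dt`
  larger than the shortest profile step is rejected.
* **Signals.** `T(t)` is piecewise constant, so the J/S/D equations are
  linear with constant coefficients within each cell and are advanced by
  the exact exponential update (no integrator error beyond the cell
  decomposition).
* **Mean field.** Classical RK4 per cell with linear interpolation of the
  signals; fractions are clipped to the simplex only within an 1e-6
  tolerance — larger violations raise instead of being hidden.
* **SSA.** Exact Gillespie within each grid cell (propensities updated
  after every event), with rates re-evaluated at cell boundaries where
  the signals change; mRNA is integrated per run by the exact linear
  update against the run's own piecewise-constant `(r, a)` path. Runs are
  seeded `seed + run_index`, making ensembles reproducible and
  embarrassingly parallel. Kernels are numba-compiled.
* **Master equation.** For `N ≤ 8` the lumped `(n_R, n_A)` chain
  (`(N+1)(N+2)/2` states) is propagated by the matrix exponential per
  cell, with exponentials cached per (J, S, Δt); probability mass is
  checked to 1e-8 at every step. This is the oracle the SSA is tested
  against.
* **Fitting.** Residuals are `log(value + ε) − log(prediction + ε)` with
  `ε = 1e-3`, because qPCR/ChIP errors are multiplicative; the objective
  is minimised by Nelder–Mead from Latin-hypercube starts in log-bounds
  (seeded, deterministic), with simulation failures mapped to +∞ rather
  than exceptions. Signals are cached across objective evaluations when
  no signal parameter is free. Known identifiability limits: `α` and the
  expression scale `cm` only enter as a product (`cm` is fixed at 1 by
  default), and `α0` is fixed. Bootstrap intervals resample replicates
  within (genotype, assay, time) cells and re-polish from the full-data
  optimum with a budget-limited simplex.
* **Ties and degenerate inputs.** Zero total propensity freezes the SSA
  state; `λ = 0` signal decay falls back to linear accumulation; all-zero
  genes get a zero rate and a zero LRT statistic; constant expression
  profiles are dropped (with a warning) before clustering.

## Screening pipeline choices

The differential test is a self-contained common-dispersion negative-
binomial likelihood-ratio test (library-size offsets; per-gene Newton
solve of the NB mean; χ²₁ p-values; Benjamini–Hochberg FDR via
statsmodels). It deliberately omits tagwise empirical-Bayes dispersion
shrinkage, so per-gene q-values will differ from edgeR-style tools on real
data; the screen's *logic* — q ≥ α at 0 h and q < α at 4 or 24 h, with
direction taken from the earliest qualifying time — is the contracted
behaviour. Dispersion is estimated by pooled method of moments on
common-scale counts. Clustering z-scores each gene's (genotype × time)
profile and runs seeded Lloyd k-means (k = 6 by default), the standard
Euclidean equivalent of Pearson-correlation distance; the choice k = 6 is
a fixed default, not re-derived. Set-overlap significance is the
hypergeometric upper tail with the universe defaulting to all tested
genes. Fold-enrichment calls report the pseudocounted CPM ratio
(+0.5 on both channels) but threshold the raw CPM comparison
(`hyper` iff CPM_mut ≥ fc·CPM_wt), so a region sitting exactly at the
fold threshold is called regardless of coverage depth.

## What the synthetic data does and does not emulate

The generators reproduce the *statistical structure* of the study's
assays: lognormal multiplicative noise with n = 3 replicates for
qPCR/ChIP time courses; negative-binomial counts with lognormal baselines,
genotype × time effects that are zero at 0 h and ±2 log2 units at 4/24 h
for planted memory genes, and library sizes uniform in [0.8, 1.2] × 10⁷;
Poisson ChIP region counts with a true fold change on planted regions;
and a diurnal sinusoid with two >30 °C spikes separated by a 2-day gap
for field-like temperature series. They do not emulate read-level
artefacts (mapping bias, GC effects), gene–gene correlation, tagwise
dispersion variation, or real meteorological series (hourly CSV replay is
supported for the latter). Passing tests therefore demonstrate that the
pipeline recovers known truth under its own error model, not that it
matches any particular sequencing data set.

## Problem sizes

Defaults keep every analysis interactive on one CPU: SSA ensembles of
200–10,000 runs on 0.05–0.25 h grids, master-equation oracles at N ≤ 8,
20 synthetic datasets × (6-start fit + 200 bootstrap refits) for the
recovery study, and 5,000-gene count matrices for the screen.

## Known limitations

* The three-state recruited-conversion scheme is one reconstruction of
  this model class; absolute parameter values are calibrated to regime,
  not measured, and only orderings/ratios should be interpreted.
* The mutant is encoded purely as a multiplier on the J-dependent
  demethylation rate; pleiotropic or basal-rate differences are not
  modelled.
* The mean-field engine used for fitting ignores finite-N fluctuations;
  at the default N = 20 the discrepancy is small on the fitted horizon
  but grows near flip transitions.
* Memory-duration values depend on the operational threshold (ratio ≥ 2
  at HS+4 h) and on the scanned gap grid (no interpolation between gaps).
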