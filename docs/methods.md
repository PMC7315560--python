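# Methods

## Model

A CpG dyad occupies one of three states — fully methylated (M),
hemimethylated (H), unmethylated (U). Per division, a methylated strand
is maintained with probability μ and an unmethylated strand gains de
novo methylation with probability δ_p (parent strand) or δ_d (daughter
strand). The one-step dyad map is

    M_t = μ m + δ_p δ_d u
    H_t = (1 − μ) m + [δ_d(1 − δ_p) + δ_p(1 − δ_d)] u

with strand frequency m = M + H/2 and u = 1 − m. The strand frequency
follows m_t = a + b m_{t−1}, a = δ/2, b = (1 + μ − δ)/2, with closed
form m_t = a/(1−b) + b^t (m_0 − a/(1−b)); b = 1 (no turnover) returns
the constant m_0. U_t is carried for completeness of the dyad model but
nothing downstream consumes it.

Gain-clock CpGs start unmethylated in fetal tissue, so maintenance is
taken as effectively perfect (μ ≈ 1), giving the saturating trajectory
β_t = 1 − (1 − δ/2)^t (1 − β₀) with lim_{t→∞} β_t = 1, and its
first-order form β = β₀ + (δ/2)(1 − β₀)·TNSC. Division count t is
accepted as a non-negative real throughout because fitting uses
t = age · IR with a continuous rate. Powers (1 − δ/2)^t are computed as
exp(t·log1p(−δ/2)) to retain precision at small δ and large t. When only
the total δ is supplied the strand split is symmetric (δ_p = δ_d = δ/2);
the trajectories depend only on the sum.

## Per-site estimation and the rate consensus

Each CpG is fitted separately by bounded trust-region least squares
(scipy `least_squares`, analytic Jacobian) over (δ, β₀, IR), restarted
from every triple of a 3-D grid of starting values: δ ∈ {1e−3, 7.5e−4,
5e−4, 2.5e−4, 1e−4, 5e−5, 1e−5}, β₀ ∈ {0, 0.01, …, 0.05}, IR ∈ {1, …, 5,
10, 15, …, 100}. Bounds are δ ∈ [1e−7, 0.01], β₀ ∈ [0, 0.1],
IR ∈ [0.01, 150] — wide enough to contain every start and every
literature division rate. Convergence tolerances are 1e−10 on cost,
gradient and step, 500 function evaluations per start; non-convergent
starts are dropped silently (debug-logged). Missing betas are dropped
pairwise per site with a floor of 30 complete pairs; samples with
missing or non-positive age are excluded with a warning. A site with no
beta variation is flagged degenerate (converged = False, δ·IR ≈ 0).

The per-site objective depends on (δ, IR) only through
λ = −IR·log(1 − δ/2) (≈ δ·IR/2), so the single-site problem has an
exactly flat ridge: all converged starts tie in RSS to machine
precision, and only the product is identified. The lowest-RSS solution
is kept, with ties (1e−9 relative) broken in favour of the solution
whose grid-snapped (δ, IR) cell — with β₀ re-profiled in closed form,
since the model is linear in β₀ at fixed (δ, IR) — has the lowest RSS,
then by lowest RSS at the original start. This picks, among equivalent
ridge solutions, the one best supported by an actual grid cell; a
simpler "closest start" rule is ambiguous because coarse β₀ starts trade
off against λ.

Sites with fitted δ·IR < 0.001 (less than ~1% methylation gain per
decade, the resolution of beadarray assays) are discarded. The
remaining sites' (δ̂, ÎR) are snapped to the starting grid — δ by
nearest neighbour in log10 (the δ grid is geometric), IR linearly — and
the modal (δ, IR) cell is the consensus; cell-count ties are broken by
the lowest summed RSS. Because the true IR cannot differ between CpGs
of one tissue, the mode across sites resolves the per-site
non-identifiability. Finally every retained site is refitted over
(δ, β₀) jointly with t(s) = age·modal IR fixed — a well-conditioned
2-parameter problem — to produce the parameter table the clocks
consume. The refit is joint in (δ, β₀) rather than holding β₀ at its
first-pass value, since the first-pass β₀ is itself entangled with the
ridge.

`FitGrid.reduced()` subsamples the β₀ and IR axes (every other start;
the δ axis and the IR = 35 start are kept) for full-cohort fitting at
desk scale — 252 instead of 1050 starts per site, about 100 s for
163 × 656 on one CPU. The full grid remains the default for `fit_site`.

## Clocks

* `estimate_tnsc`: the exact algebraic inverse of the first-order gain
  model, TNSC = (2/n)·Σ (β_i − β_i0)/(δ_i(1 − β_i0)) over non-missing
  panel probes (n = probes used). At least 80% of the panel must be
  present — the model never states a floor; 80% protects score
  comparability across samples. Negative per-probe contributions are not
  clipped and a net-negative TNSC is reported with a warning: clipping
  would bias cohort medians upward.
* `lifetime_rate` R = TNSC/age; `intrinsic_rate` is the cohort median of
  R (mean available as an option; the median is robust and gives nearly
  identical results on healthy cohorts). Ages must be supplied
  explicitly — no internal epigenetic-age surrogate is provided.
* `pcgt_age_score` / `hypo_score`: plain means over the respective
  panels. With β₀ = 0 and a site-independent δ, TNSC reduces to
  (2/δ)·mean(β), so the averaging clock is a special case of the kinetic
  one.
* `hypo_age_adjust` maps scores to (1 − score)/age (anti-correlative
  with the division rate); `hypo_rescale` applies the affine map
  max(1−h) − γ·max(adj) + γ·adj with γ = range(h)/range(adj), which
  restores the raw score's dynamic range exactly. The same map must
  cover every sample being compared; the CLI defaults to pooled
  rescaling and offers per-group as a flag.
* `turnover_to_ir` = 365/turnover-days. `skin_lifetime_ir` is the
  piecewise lifetime average for epidermis (21-day renewal to age 20,
  35-day to 50, then rd(age) = 1.5·age − 30 days); it evaluates the
  printed formula pointwise by default and offers a cohort-averaged mode
  for dispersed cohorts, which can differ by ~0.1 division/yr around
  age 50.
* `group_auc` is a Mann-Whitney AUC with a one-tailed rank-sum p-value —
  plumbing for group comparisons, not a modelling contribution.

## Synthetic cohorts

`simulate_cohort` emulates a large whole-blood ageing cohort: 656
individuals aged 19–101 drawn uniformly within six age bins with counts
(35, 74, 138, 167, 142, 100); 163 gain-clock loci with a shared ground
state β₀ = 0.05 and per-site δ cycling round-robin through {1e−3 …
1e−5} (round-robin keeps truth tables stable across runs; seeded random
assignment is available); true IR = 35/yr. Each (site, sample) beta is
drawn from a beta distribution matched by the method of moments —
a = (μ(1−μ)/σ² − 1)μ, b = a/μ − a — to the trajectory mean at
t = age·IR and an age-bin variance. The per-bin variance schedule
(1e−4, 2e−4, 3e−4, 5e−4, 7e−4, 1e−3) is this package's calibration
stand-in for the age-associated variance increase seen in real blood
data (the per-interval values of the reference cohort are not published)
and is fully overridable. Means are clamped to [1e−4, 1 − 1e−4] and
infeasible variances (σ² ≥ μ(1−μ)) shrunk to 99% of the bound with a
warning. Identical specs (including the mandatory seed) produce
bit-identical cohorts.

What the generator does not emulate: cell-type mixtures, batch and probe
chemistry effects, genotype effects, spatial correlation between CpGs,
and inter-individual rate variation (ER ≡ 0). A passing recovery test
therefore demonstrates identifiability of (δ_i, β_i0, IR) under the
stated noise model, not robustness to those real-data complications.
The `direction="loss"` mode (mean replaced by its complement) exists to
exercise the hypomethylation-clock code paths and is not calibrated to
real solo-WCGW kinetics.

## Numerical and design notes

* Beta values read from text are clamped into [0, 1] when off by at most
  1e−6 (round-trip artefacts); larger violations are errors. Missing
  values are NA (case-insensitive) or empty cells; delimiter (tab/comma)
  is auto-detected with an override.
* Problem sizes: the identifiability experiment and its test run the
  full 163 × 656 design with the reduced starting grid; smaller
  fixture cohorts (14–28 sites, 120–160 samples, variance table rescaled
  by largest-remainder rounding) back the unit tests. At very small site
  counts (~2 per δ level) the consensus mode can fragment across
  ridge-equivalent cells, so modal-equality checks use ≥4 sites per δ
  level.
* The extrinsic factor ER is exposed only as the derived quantity
  R/IR − 1; nothing estimates it independently.
* Real-cohort replication (TCGA/GEO comparisons of DNAm-derived vs
  experimentally derived rates) requires external downloads and is
  deliberately not bundled; the simulator is the package's testbed.

## Known limitations

The model ignores stem-cell pool size and tissue hierarchy; μ is fixed
at 1 for gain sites rather than estimated; per-site identifiability is
limited to δ·IR by construction, so the consensus inherits the grid's
resolution (IR is reported on the grid); and the uniform-within-bin age
draw is a convenience, not an estimate of any real cohort's age density.
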