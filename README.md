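# mitoclock

Mitotic-age clocks from DNA methylation: estimate how many times the
stem cells of a tissue have divided — and how fast they divide per year —
from an Illumina-style beta-value matrix.

## The problem

Somatic tissues renew from stem cells, and the lifetime number of
stem-cell divisions is a major determinant of cancer risk. Divisions
leave an epigenetic footprint: at certain PRC2-marked promoter CpGs that
are unmethylated in fetal tissue, DNA methylation is gained
stochastically at each replication. `mitoclock` turns that footprint
into a clock.

The core model tracks a CpG dyad through divisions with a maintenance
probability μ and de novo probabilities δ_p, δ_d (δ = δ_p + δ_d). The
strand-level methylation frequency obeys m_t = a + b·m_{t−1} with
a = δ/2, b = (1 + μ − δ)/2, solved in closed form. For gain-clock CpGs
μ ≈ 1, giving the measured beta value after t divisions as

    β_t = 1 − (1 − δ/2)^t + β₀ (1 − δ/2)^t

Writing t = A(s)·IR(x) (age times the tissue's intrinsic annual
stem-cell division rate) and fitting this trajectory per CpG across a
large healthy cohort yields per-site (δ_i, β_i0) and a cohort-level IR:
each site alone identifies only the compound rate δ·IR, so sites are
fitted by grid-multi-start non-linear least squares, filtered at
δ·IR ≥ 0.001 (the ~1% per decade assay resolution), and the
(δ, IR) grid cell with the highest representation across sites gives the
consensus IR, after which sites are refitted with IR fixed.

With a parameter table in hand, the mitotic age of any sample is the
first-order inverse

    TNSC(s) = (2/n) Σ_i (β_is − β_i0) / (δ_i (1 − β_i0))

and IR(x) = median_s TNSC(s)/A(s). The package also provides the simple
gain-averaging score (mean beta over a PRC2 panel, a special case of the
kinetic clock), the solo-WCGW hypomethylation clock (HypoScore, its age
adjustment (1 − score)/age and dynamic-range rescaling), literature
turnover-rate converters (e.g. blood renewing every 10 days →
IR = 365/10 = 36.5/yr), and a synthetic-cohort simulator with
age-heteroscedastic beta-distributed noise for identifiability checks.

## Worked example

```python
from mitoclock import FitGrid, SimulationSpec, fit_cohort, simulate_cohort

spec = SimulationSpec(seed=1)          # 163 CpGs, 656 samples, true IR 35
cohort = simulate_cohort(spec)
result = fit_cohort(cohort.betas, cohort.ages.to_numpy(), FitGrid.reduced())
print(result.modal_ir, len(result.retained_probes))
```

prints

```
35.0 140
```

the consensus intrinsic rate (35.0 divisions/stem cell/year — exactly the
generating value) and the number of CpGs passing the δ·IR ≥ 0.001 filter
(140/163: the 23 sites with δ = 1e−5 carry too little signal, as
intended). The refitted per-site δ estimates rank-correlate with the
generating values at ρ ≈ 0.99.

Shorter narrative scripts live in `examples/`: the forward trajectory
model, the identifiability loop at desk scale, mitotic-age scoring with
both clock families, and the turnover-rate converters (blood 36.5/yr,
stomach ≈ 66.4/yr, skin's age-dependent lifetime average ≈ 13.2 at
age 50).

A thin CLI mirrors the library: `mitoclock simulate | fit | score |
rate | recover` operate on delimited-text beta matrices and metadata
tables (`mitoclock --help` for flags).

## Scope

The package expects normalized beta matrices with known sample ages;
array preprocessing (idat parsing, BMIQ/batch correction), epigenetic
age surrogates, and cell-type deconvolution are out of scope. Analyses
of real public cohorts require external downloads and are not bundled.
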