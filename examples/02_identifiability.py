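"""Parameter identifiability: simulate a cohort, refit it, compare to truth.

Generates a small synthetic ageing cohort (28 gain-clock CpGs, 160
individuals, true intrinsic rate 35 divisions/stem cell/year), runs the
full estimation pipeline — per-site grid-multi-start NLS, the delta*IR
filter, the (delta, IR)-mode consensus and the fixed-rate refit — and
reports how well the generating parameters are recovered.
"""

from scipy import stats

from mitoclock import FitGrid, SimulationSpec, fit_cohort, simulate_cohort
from mitoclock.simulate import AgeVarianceTable

spec = SimulationSpec(
    n_sites=28,
    n_samples=160,
    seed=3,
    variance_table=AgeVarianceTable().scaled_to(160),
)
cohort = simulate_cohort(spec)
result = fit_cohort(cohort.betas, cohort.ages.to_numpy(), FitGrid.reduced())

truth = cohort.truth.loc[list(result.retained_probes), "true_delta"]
est = result.final_params.loc[truth.index, "delta"]
rho = stats.spearmanr(truth, est).statistic

print(f"true intrinsic rate:      {spec.true_ir}")
print(f"modal intrinsic rate:     {result.modal_ir}")
print(f"retained probes:          {len(result.retained_probes)}/{spec.n_sites}")
print(f"delta rank correlation:   {rho:.3f}")
print()
print(
    "Each site alone only identifies the product delta*IR; the cohort-wide\n"
    "(delta, IR) mode pins the shared division rate, after which the\n"
    "per-site de novo probabilities are recovered by the fixed-rate refit."
)
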