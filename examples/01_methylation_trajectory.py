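"""Forward model: methylation gain across stem-cell divisions.

Starting from an unmethylated CpG dyad, iterate the per-division dyad
recursion and compare with the closed-form trajectory and its
perfect-maintenance approximation.
"""

from mitoclock import (
    DyadState,
    SiteKinetics,
    dyad_step,
    trajectory_approx,
    trajectory_exact,
)

# a typical gain-clock CpG: total de novo probability 5e-5 per division,
# near-perfect maintenance
kin = SiteKinetics.from_total(delta=5e-5, mu=1.0)

state = DyadState(M=0.0, H=0.0, U=1.0)
for _ in range(1000):
    state = dyad_step(state, kin)

closed = trajectory_exact(kin, m0=0.0, t=1000)
approx = trajectory_approx(5e-5, 0.0, 1000)

print(f"strand methylation after 1000 divisions (stepwise):   {state.m:.6f}")
print(f"strand methylation after 1000 divisions (closed form): {closed:.6f}")
print(f"perfect-maintenance approximation:                     {approx:.6f}")
print()
print(
    "All three agree: with delta = 5e-5 a CpG gains ~2.5% methylation "
    "per 1000 divisions,\nso a beta value read off an array reports the "
    "cell's cumulative division count."
)
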