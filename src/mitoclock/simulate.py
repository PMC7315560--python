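"""Synthetic DNAm cohorts with age-heteroscedastic beta-distributed noise.

Emulates a large whole-blood ageing cohort (656 individuals, ages 19-101
with a realistic age pyramid) in which methylation at gain-clock CpGs
accrues with mitotic age: each (site, sample) beta value is drawn from a
beta distribution whose mean follows the saturating-gain trajectory
``1 - (1 - delta_i/2)**(age*IR) * (1 - beta0)`` and whose variance is set
per age interval, increasing with age as observed in real blood data.
The method-of-moments conversion from (mean, variance) to beta shapes is
:func:`beta_shapes_from_moments`.

The generated cohorts carry their ground truth (per-site delta, shared
beta0, the tissue IR), so the full estimate pipeline
(:func:`mitoclock.fitting.fit_cohort`) can be checked for parameter
identifiability without any external data.  A ``direction="loss"`` mode
(mean replaced by its complement) emulates solo-WCGW-like hypomethylation
for testing the HypoClock operations; real loss dynamics are not
calibrated here and the mode is an extension for testing only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import trajectory_approx

__all__ = [
    "AgeVarianceTable",
    "SimulationSpec",
    "SimulatedCohort",
    "beta_shapes_from_moments",
    "sample_ages",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

# Hannum-like age pyramid: (lower, upper, n_samples, variance).  The
# variance schedule increases monotonically with age; the per-interval
# values are this package's calibration stand-ins (the source cohort's
# per-interval variances are not published) and are fully overridable.
_DEFAULT_BINS = (
    (19.0, 40.0, 35, 1e-4),
    (40.0, 50.0, 74, 2e-4),
    (50.0, 60.0, 138, 3e-4),
    (60.0, 70.0, 167, 5e-4),
    (70.0, 80.0, 142, 7e-4),
    (80.0, 101.0, 100, 1e-3),
)

_DEFAULT_DELTA_POOL = (0.001, 0.00075, 0.0005, 0.00025, 0.0001, 5e-5, 1e-5)

_MEAN_CLAMP = 1e-4


@dataclass(frozen=True)
class AgeVarianceTable:
    """Ordered, contiguous age bins with sample counts and DNAm variances."""

    intervals: tuple[tuple[float, float, int, float], ...] = _DEFAULT_BINS

    def __post_init__(self) -> None:
        ivs = tuple(
            (float(lo), float(hi), int(n), float(var)) for lo, hi, n, var in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        for (lo, hi, n, var) in ivs:
            if hi <= lo:
                raise ValueError("each bin must have upper > lower")
            if n < 1:
                raise ValueError("each bin needs at least one sample")
            if not (0.0 < var < 0.25):
                raise ValueError("bin variance must lie in (0, 0.25)")
        for (_, hi, _, _), (lo, _, _, _) in zip(ivs, ivs[1:]):
            if abs(hi - lo) > 1e-9:
                raise ValueError("bins must be contiguous and ordered")

    @property
    def total_samples(self) -> int:
        return sum(n for _, _, n, _ in self.intervals)

    def scaled_to(self, n_samples: int) -> "AgeVarianceTable":
        """Rescale the bin counts proportionally to sum to ``n_samples``.

        Uses largest-remainder rounding so every bin keeps at least one
        sample; bin edges and variances are unchanged.
        """
        if n_samples < len(self.intervals):
            raise ValueError("need at least one sample per age bin")
        total = self.total_samples
        raw = [n_samples * n / total for _, _, n, _ in self.intervals]
        counts = [max(1, int(r)) for r in raw]
        remainders = [r - int(r) for r in raw]
        order = sorted(
            range(len(raw)), key=lambda i: remainders[i], reverse=True
        )
        i = 0
        while sum(counts) < n_samples:
            counts[order[i % len(order)]] += 1
            i += 1
        while sum(counts) > n_samples:
            j = max(range(len(counts)), key=lambda k: counts[k])
            counts[j] -= 1
        return AgeVarianceTable(
            intervals=tuple(
                (lo, hi, c, var)
                for (lo, hi, _, var), c in zip(self.intervals, counts)
            )
        )

    def variance_for_age(self, age: float) -> float:
        for lo, hi, _, var in self.intervals:
            if lo <= age < hi:
                return var
        # ages at the closed upper end of the last bin
        if age == self.intervals[-1][1]:
            return self.intervals[-1][3]
        raise ValueError(f"age {age} outside the table's range")


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic cohort.

    Defaults reproduce the identifiability study design: 163 gain-clock
    loci, 656 individuals aged 19-101 with the stated age-bin counts,
    a shared ground state beta0 = 0.05, per-site de novo probabilities
    cycling through the 7-value pool, and a true intrinsic division rate
    of 35 divisions/stem cell/year.  The seed is mandatory: identical
    specs give bit-identical cohorts.
    """

    n_sites: int = 163
    n_samples: int = 656
    true_ir: float = 35.0
    beta0: float = 0.05
    delta_pool: tuple[float, ...] = _DEFAULT_DELTA_POOL
    age_range: tuple[float, float] = (19.0, 101.0)
    variance_table: AgeVarianceTable = field(default_factory=AgeVarianceTable)
    seed: int = 0
    direction: str = "gain"
    delta_assignment: str = "round_robin"

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_samples < 1:
            raise ValueError("n_sites and n_samples must be positive")
        if self.true_ir <= 0:
            raise ValueError("true_ir must be positive")
        if not (0.0 <= self.beta0 < 1.0):
            raise ValueError("beta0 must lie in [0, 1)")
        if not self.delta_pool or any(d <= 0 or d > 1 for d in self.delta_pool):
            raise ValueError("delta_pool must be positive probabilities")
        if self.age_range[1] <= self.age_range[0] or self.age_range[0] <= 0:
            raise ValueError("age_range must be increasing and positive")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if self.delta_assignment not in ("round_robin", "sampled"):
            raise ValueError("delta_assignment must be 'round_robin' or 'sampled'")

    def to_config(self, path) -> None:
        """Write the spec as a plain key=value config file."""
        lines = [
            f"n_sites={self.n_sites}",
            f"n_samples={self.n_samples}",
            f"true_ir={self.true_ir!r}",
            f"beta0={self.beta0!r}",
            "delta_pool=" + ",".join(repr(d) for d in self.delta_pool),
            f"age_range={self.age_range[0]!r},{self.age_range[1]!r}",
            f"seed={self.seed}",
            f"direction={self.direction}",
            f"delta_assignment={self.delta_assignment}",
        ] + [
            f"bin={lo!r},{hi!r},{n},{var!r}"
            for lo, hi, n, var in self.variance_table.intervals
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path) -> "SimulationSpec":
        """Read a spec back from a key=value config file."""
        fields: dict = {}
        bins = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "bin":
                    lo, hi, n, var = value.split(",")
                    bins.append((float(lo), float(hi), int(n), float(var)))
                elif key in ("n_sites", "n_samples", "seed"):
                    fields[key] = int(value)
                elif key in ("true_ir", "beta0"):
                    fields[key] = float(value)
                elif key == "delta_pool":
                    fields[key] = tuple(float(v) for v in value.split(","))
                elif key == "age_range":
                    lo, hi = value.split(",")
                    fields[key] = (float(lo), float(hi))
                elif key in ("direction", "delta_assignment"):
                    fields[key] = value
                else:
                    raise ValueError(f"unknown config key {key!r}")
        if bins:
            fields["variance_table"] = AgeVarianceTable(intervals=tuple(bins))
        return cls(**fields)


@dataclass(frozen=True)
class SimulatedCohort:
    """A synthetic cohort: beta matrix, ages, and its generating truth."""

    betas: pd.DataFrame  # sites x samples
    ages: pd.Series  # indexed by sample id
    truth: pd.DataFrame  # indexed by probe_id: true_delta, true_beta0, true_ir
    spec: SimulationSpec


def beta_shapes_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Beta-distribution shapes (a, b) matching a given mean and variance.

    Method of moments: a = (mean(1-mean)/variance - 1) * mean and
    b = a/mean - a.  A variance at or above the Bernoulli bound
    mean*(1-mean) is infeasible for a beta distribution and is shrunk to
    99% of the bound with a warning.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie strictly in (0, 1)")
    if variance <= 0.0:
        raise ValueError("variance must be positive")
    bound = mean * (1.0 - mean)
    if variance >= bound:
        logger.warning(
            "variance %.3g infeasible for mean %.3g; shrunk to 0.99*mean*(1-mean)",
            variance,
            mean,
        )
        variance = 0.99 * bound
    a = (bound / variance - 1.0) * mean
    b = a / mean - a
    return a, b


def sample_ages(spec: SimulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the cohort's ages honouring the per-bin counts.

    Ages are uniform within each bin (intersected with the spec's age
    range) and returned sorted by bin; the draw is reproducible from the
    spec seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    table = spec.variance_table
    if table.total_samples != spec.n_samples:
        raise ValueError(
            f"variance-table bin counts sum to {table.total_samples}, "
            f"but n_samples is {spec.n_samples}"
        )
    lo_all, hi_all = spec.age_range
    ages = []
    for lo, hi, n, _ in table.intervals:
        lo_eff, hi_eff = max(lo, lo_all), min(hi, hi_all)
        ages.append(rng.uniform(lo_eff, hi_eff, size=n))
    out = np.concatenate(ages)
    return np.clip(out, lo_all, hi_all)


def _assign_deltas(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    pool = np.asarray(spec.delta_pool, dtype=float)
    if spec.delta_assignment == "round_robin":
        return pool[np.arange(spec.n_sites) % pool.size]
    return rng.choice(pool, size=spec.n_sites, replace=True)


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate a full synthetic cohort from a :class:`SimulationSpec`.

    Per site the true de novo probability comes from the spec's pool
    (deterministic round-robin by default, so truth tables are stable);
    per (site, sample) the beta value is drawn from the beta distribution
    whose mean is the gain trajectory at t = age * IR (its complement for
    the loss mode) and whose variance is the sample's age-bin value.
    Means are clamped to [1e-4, 1 - 1e-4] before shape conversion to keep
    the beta shapes non-degenerate.
    """
    rng = np.random.default_rng(spec.seed)
    ages = sample_ages(spec, rng)
    deltas = _assign_deltas(spec, rng)
    variances = np.array(
        [spec.variance_table.variance_for_age(a) for a in ages]
    )

    # mean trajectory, sites x samples
    t = ages[None, :] * spec.true_ir
    mean = trajectory_approx(deltas[:, None], spec.beta0, t)
    if spec.direction == "loss":
        mean = 1.0 - mean
    mean = np.clip(mean, _MEAN_CLAMP, 1.0 - _MEAN_CLAMP)

    var = np.broadcast_to(variances[None, :], mean.shape).copy()
    bound = mean * (1.0 - mean)
    infeasible = var >= bound
    if np.any(infeasible):
        logger.warning(
            "%d (site, sample) variances infeasible; shrunk to 0.99*mean*(1-mean)",
            int(np.sum(infeasible)),
        )
        var[infeasible] = 0.99 * bound[infeasible]
    shape_a = (bound / var - 1.0) * mean
    shape_b = shape_a / mean - shape_a
    betas = rng.beta(shape_a, shape_b)

    probe_ids = [f"site_{i + 1:04d}" for i in range(spec.n_sites)]
    sample_ids = [f"sample_{j + 1:04d}" for j in range(spec.n_samples)]
    return SimulatedCohort(
        betas=pd.DataFrame(betas, index=probe_ids, columns=sample_ids),
        ages=pd.Series(ages, index=sample_ids, name="age"),
        truth=pd.DataFrame(
            {
                "true_delta": deltas,
                "true_beta0": spec.beta0,
                "true_ir": spec.true_ir,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        spec=spec,
    )
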