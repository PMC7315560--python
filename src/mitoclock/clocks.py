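"""Mitotic-age scores and stem-cell division-rate estimators.

Three clocks are supported:

* the kinetic gain clock (``epiTOC2``-style): inverts the first-order
  trajectory ``beta_i = beta_i0 + (delta_i/2)(1 - beta_i0) * TNSC`` across
  a panel of CpGs with per-site (delta_i, beta_i0) parameters to estimate
  the total number of stem-cell divisions TNSC of a sample
  (:func:`estimate_tnsc`);
* the simple gain-averaging clock (``pcgtAge``): the mean beta over
  PRC2-marked, fetally unmethylated CpGs (:func:`pcgt_age_score`) — the
  special case of the kinetic clock with beta0 = 0 and a site-independent
  delta;
* the hypomethylation clock (``HypoClock``): the mean beta over
  constitutively methylated solo-WCGW CpGs (:func:`hypo_score`), which
  decreases with accrued divisions; its age adjustment and dynamic-range
  rescaling follow.

Given ages, TNSC converts to a lifetime division rate R = TNSC/age per
sample and a cohort-level intrinsic rate IR = median_s(TNSC_s/age_s)
(:func:`intrinsic_rate`).  Literature turnover times convert to rates via
:func:`turnover_to_ir`; skin, whose turnover slows with age, gets the
piecewise lifetime-average model :func:`skin_lifetime_ir`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClockDefinition",
    "estimate_tnsc",
    "score_samples",
    "lifetime_rate",
    "intrinsic_rate",
    "pcgt_age_score",
    "hypo_score",
    "hypo_age_adjust",
    "hypo_rescale",
    "turnover_to_ir",
    "skin_lifetime_ir",
    "group_auc",
    "DivisionRateEstimate",
]

logger = logging.getLogger(__name__)

MIN_COVERAGE = 0.8


@dataclass(frozen=True)
class ClockDefinition:
    """A clock: its probes, optional per-probe kinetics, and direction.

    ``site_params`` (DataFrame indexed by probe_id with columns ``delta``,
    ``beta0``) is required for the kinetic clock and absent for the
    averaging clocks.  ``direction`` is "gain" for methylation-gain clocks
    and "loss" for the hypomethylation clock.
    """

    name: str
    probe_ids: tuple[str, ...]
    site_params: pd.DataFrame | None = None
    direction: str = "gain"

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("probe list must be non-empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe list must be unique")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if self.site_params is not None:
            missing = set(self.probe_ids) - set(self.site_params.index)
            if missing:
                raise ValueError(
                    f"site_params missing {len(missing)} probes, "
                    f"e.g. {sorted(missing)[:3]}"
                )


@dataclass(frozen=True)
class DivisionRateEstimate:
    """Cohort-level intrinsic stem-cell division rate for one tissue."""

    tissue_label: str
    ir: float
    estimator: str
    n_samples: int

    def __post_init__(self) -> None:
        if self.ir < 0:
            raise ValueError("ir must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")


def _coverage_check(betas: pd.Series, probe_ids: Sequence[str]) -> pd.Series:
    """Align sample betas to the clock probes, enforcing >=80% coverage."""
    aligned = betas.reindex(probe_ids)
    missing = aligned.index[aligned.isna()]
    coverage = 1.0 - len(missing) / len(probe_ids)
    if coverage < MIN_COVERAGE:
        raise ValueError(
            f"only {coverage:.0%} of clock probes covered (need >=80%); "
            f"missing e.g. {list(missing[:5])}"
        )
    return aligned.dropna()


def estimate_tnsc(betas: pd.Series, params: pd.DataFrame) -> float:
    """Estimate the total number of stem-cell divisions of one sample.

    Inverts the first-order gain model across the clock probes:

        TNSC = (2/n) * sum_i (beta_i - beta_i0) / (delta_i * (1 - beta_i0))

    where n counts the probes actually used (>=80% of the panel must be
    present).  Per-probe negative contributions (beta below the ground
    state) are kept as-is, not clipped — clipping would bias cohort
    medians; a net-negative TNSC is returned with a warning.
    """
    used = _coverage_check(betas, list(params.index))
    delta = params.loc[used.index, "delta"].to_numpy(dtype=float)
    beta0 = params.loc[used.index, "beta0"].to_numpy(dtype=float)
    if np.any(delta <= 0):
        raise ValueError("all probe deltas must be positive")
    vals = used.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    contrib = (vals - beta0) / (delta * (1.0 - beta0))
    tnsc = 2.0 * float(np.mean(contrib))
    if tnsc < 0:
        logger.warning("negative TNSC estimate (%.3g); reported unclipped", tnsc)
    return tnsc


def lifetime_rate(tnsc: float, age: float) -> float:
    """Average lifetime stem-cell division rate R = TNSC / age (per year)."""
    if not np.isfinite(age) or age <= 0:
        raise ValueError("age must be a positive number of years")
    return tnsc / age


def intrinsic_rate(
    tnscs: Sequence[float],
    ages: Sequence[float],
    estimator: str = "median",
    tissue_label: str = "",
) -> DivisionRateEstimate:
    """Cohort intrinsic division rate: median (or mean) of TNSC_s / age_s.

    The median is the default as it is robust to outlying samples; the
    mean gives largely indistinguishable results on healthy cohorts.
    """
    tnscs = np.asarray(tnscs, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if tnscs.size == 0:
        raise ValueError("need at least one sample")
    if tnscs.shape != ages.shape:
        raise ValueError("tnscs and ages must have equal length")
    if np.any(~np.isfinite(ages) | (ages <= 0)):
        raise ValueError("all ages must be positive")
    rates = tnscs / ages
    if estimator == "median":
        ir = float(np.median(rates))
    elif estimator == "mean":
        ir = float(np.mean(rates))
    else:
        raise ValueError("estimator must be 'median' or 'mean'")
    return DivisionRateEstimate(
        tissue_label=tissue_label,
        ir=ir,
        estimator=estimator,
        n_samples=int(tnscs.size),
    )


def pcgt_age_score(betas: pd.Series, probe_ids: Sequence[str]) -> float:
    """Averaging gain clock: mean beta over the panel's non-missing probes."""
    used = _coverage_check(betas, probe_ids)
    return float(used.mean())


def hypo_score(betas: pd.Series, probe_ids: Sequence[str]) -> float:
    """Hypomethylation clock: mean beta over solo-WCGW probes.

    Lower scores indicate more accrued divisions (methylation is lost
    under replicative stress at these sites).
    """
    return pcgt_age_score(betas, probe_ids)


def hypo_age_adjust(
    scores: Sequence[float], ages: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Age-adjusted hypomethylation score: (1 - score) / age per sample.

    Returns the per-sample adjusted values and their cohort median, an
    anti-correlative measure of the intrinsic division rate.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if scores.shape != ages.shape:
        raise ValueError("scores and ages must have equal length")
    if np.any(~np.isfinite(ages) | (ages <= 0)):
        raise ValueError("all ages must be positive")
    adjusted = (1.0 - scores) / ages
    return adjusted, float(np.median(adjusted))


def hypo_rescale(
    hypo_scores: Sequence[float], adjusted: Sequence[float]
) -> np.ndarray:
    """Rescale age-adjusted scores back to the raw score's dynamic range.

    With gamma = range(hypo) / range(adjusted), returns

        max(1 - hypo) - gamma * max(adjusted) + gamma * adjusted

    an affine map whose output range equals the raw HypoScore range and
    whose maximum equals max(1 - hypo).  The same map must be applied to
    every sample being compared, so cross-tissue comparisons must pool all
    samples before calling this.
    """
    hypo = np.asarray(hypo_scores, dtype=float)
    adj = np.asarray(adjusted, dtype=float)
    if hypo.shape != adj.shape:
        raise ValueError("hypo_scores and adjusted must have equal length")
    if hypo.size < 2 or np.ptp(adj) == 0.0:
        raise ValueError(
            "rescaling needs at least two samples with distinct adjusted values"
        )
    gamma = np.ptp(hypo) / np.ptp(adj)
    return np.max(1.0 - hypo) - gamma * np.max(adj) + gamma * adj


def turnover_to_ir(turnover_days: float) -> float:
    """Convert a tissue renewal time in days to divisions/stem cell/year."""
    if turnover_days <= 0:
        raise ValueError("turnover_days must be positive")
    return 365.0 / turnover_days


def _skin_rd(age: float) -> float:
    """Turnover time (days) past age 50: linear from 45d at 50 to 90d at 80."""
    return 1.5 * age - 30.0


def skin_lifetime_ir(age, cohort_average: bool = False):
    """Lifetime-average epidermal stem-cell division rate at a given age.

    Skin turnover slows with age: renewal every 21 days up to age 20,
    every 35 days between 20 and 50, and every rd(age) = 1.5*age - 30 days
    thereafter (45 days at 50, 90 at 80).  The lifetime average divides
    the cumulative division count by age:

        age <= 20:        365/21
        20 < age <= 50:   (20*365/21 + (age-20)*365/35) / age
        age > 50:         (20*365/21 + 30*365/35 + (age-50)*365/rd(age)) / age

    By default the formula is evaluated pointwise (vectorised over
    ``age``); with ``cohort_average=True`` the mean of the pointwise
    values over the supplied ages is returned, for dispersed cohorts
    summarised by one number.
    """
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(ages <= 0):
        raise ValueError("age must be positive")
    teen = 365.0 / 21.0
    cum20 = 20.0 * 365.0 / 21.0
    cum50 = cum20 + 30.0 * 365.0 / 35.0
    out = np.where(
        ages <= 20.0,
        teen,
        np.where(
            ages <= 50.0,
            (cum20 + (ages - 20.0) * 365.0 / 35.0) / ages,
            (cum50 + (ages - 50.0) * 365.0 / _skin_rd(ages)) / ages,
        ),
    )
    if cohort_average:
        return float(np.mean(out))
    return float(out[0]) if np.isscalar(age) or np.ndim(age) == 0 else out


def group_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Mann-Whitney AUC of scores discriminating two groups.

    Returns (AUC, one-tailed rank-sum p-value) for label-1 scores
    exceeding label-0 scores.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    u, p = stats.mannwhitneyu(pos, neg, alternative="greater")
    return float(u) / (len(pos) * len(neg)), float(p)


def score_samples(
    matrix: pd.DataFrame,
    ages: pd.Series,
    kinetic_params: pd.DataFrame | None = None,
    pcgt_probes: Sequence[str] | None = None,
    hypo_probes: Sequence[str] | None = None,
    cohort_ir: float | None = None,
) -> pd.DataFrame:
    """Score every sample of a beta matrix with the available clocks.

    ``matrix`` is probes x samples; ``ages`` is indexed by sample id.
    Produces a per-sample table with whichever of tnsc / rate / pcgt_age /
    hypo_score / hypo_age_adj / hypo_rescaled the supplied clock
    definitions permit.  When a cohort intrinsic rate is given, the
    derived extrinsic factor ER = R/IR - 1 (the sample-specific
    modulation of the tissue's intrinsic rate) is added.
    """
    out = pd.DataFrame(index=matrix.columns)
    if kinetic_params is not None:
        out["tnsc"] = [
            estimate_tnsc(matrix[s], kinetic_params) for s in matrix.columns
        ]
        out["rate"] = [
            lifetime_rate(t, ages.loc[s])
            for t, s in zip(out["tnsc"], matrix.columns)
        ]
        if cohort_ir is not None:
            if cohort_ir <= 0:
                raise ValueError("cohort_ir must be positive")
            out["extrinsic_factor"] = out["rate"] / cohort_ir - 1.0
    if pcgt_probes is not None:
        out["pcgt_age"] = [
            pcgt_age_score(matrix[s], pcgt_probes) for s in matrix.columns
        ]
    if hypo_probes is not None:
        out["hypo_score"] = [
            hypo_score(matrix[s], hypo_probes) for s in matrix.columns
        ]
        adjusted, _ = hypo_age_adjust(
            out["hypo_score"].to_numpy(), ages.loc[matrix.columns].to_numpy()
        )
        out["hypo_age_adj"] = adjusted
        if len(out) >= 2 and np.ptp(adjusted) > 0:
            out["hypo_rescaled"] = hypo_rescale(
                out["hypo_score"].to_numpy(), adjusted
            )
    return out
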