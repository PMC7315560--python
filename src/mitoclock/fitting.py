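"""Per-CpG kinetic parameter estimation and cohort-level rate consensus.

For each CpG *i* in a healthy single-tissue cohort, the measured beta value
of sample *s* is modelled as the saturating-gain trajectory

    beta_is = 1 - (1 - delta_i/2)**(A(s) * IR) + beta_i0 * (1 - delta_i/2)**(A(s) * IR)

with site-specific de novo probability ``delta_i`` and ground state
``beta_i0``, and a tissue-wide intrinsic stem-cell division rate ``IR``.
Each site is fitted separately by bounded non-linear least squares
restarted from every triple of a three-dimensional grid of starting
values (:class:`FitGrid`), keeping the lowest-RSS converged solution.

The per-site likelihood depends on (delta, IR) only through the compound
rate ``lambda = -IR * log(1 - delta/2)`` (to first order, the product
``delta * IR / 2``), so the single-site problem has a flat ridge and only
the product is identifiable.  The cohort resolves this: sites whose
estimated gain rate ``delta * IR`` falls below the assay-resolution
threshold 0.001 are discarded (:func:`filter_sites`), the remaining
(delta, IR) estimates are snapped back to the starting grid and the modal
cell is taken as the consensus (:func:`consensus_rate`), and finally every
retained site is refitted with IR frozen at the modal value to obtain
well-identified per-site (delta_i, beta_i0) tables
(:func:`refit_fixed_rate`).  :func:`fit_cohort` runs the whole pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FitGrid",
    "SiteFit",
    "CohortFit",
    "fit_site",
    "filter_sites",
    "consensus_rate",
    "refit_fixed_rate",
    "fit_cohort",
    "DELTA_BOUNDS",
    "BETA0_BOUNDS",
    "IR_BOUNDS",
]

logger = logging.getLogger(__name__)

# Bounds chosen to encompass every grid start and every literature IR.
DELTA_BOUNDS = (1e-7, 0.01)
BETA0_BOUNDS = (0.0, 0.1)
IR_BOUNDS = (0.01, 150.0)

MIN_SAMPLES = 30
DEFAULT_THRESHOLD = 1e-3


def _default_delta_starts() -> tuple[float, ...]:
    return (0.001, 0.00075, 0.0005, 0.00025, 0.0001, 5e-5, 1e-5)


def _default_beta0_starts() -> tuple[float, ...]:
    return (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)


def _default_ir_starts() -> tuple[float, ...]:
    return tuple(float(v) for v in (1, 2, 3, 4, 5, *range(10, 101, 5)))


@dataclass(frozen=True)
class FitGrid:
    """Three-dimensional grid of NLS starting values (delta, beta0, IR).

    The defaults are 7 de novo probabilities spanning 1e-5..1e-3, 6 ground
    states 0..0.05 and 25 division rates 1..100/yr — 1050 starts per site.
    :meth:`reduced` subsamples the beta0 and IR axes (every other start)
    for desk-scale runtime on full cohorts; the consensus grid then is the
    reduced one.
    """

    delta_starts: tuple[float, ...] = field(default_factory=_default_delta_starts)
    beta0_starts: tuple[float, ...] = field(default_factory=_default_beta0_starts)
    ir_starts: tuple[float, ...] = field(default_factory=_default_ir_starts)

    def __post_init__(self) -> None:
        for name in ("delta_starts", "beta0_starts", "ir_starts"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be non-negative")
            if name != "beta0_starts" and any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, tuple(sorted(vals)))

    @classmethod
    def full(cls) -> "FitGrid":
        return cls()

    @classmethod
    def reduced(cls) -> "FitGrid":
        full = cls()
        return cls(
            delta_starts=full.delta_starts,
            beta0_starts=full.beta0_starts[::2],
            ir_starts=full.ir_starts[::2],
        )

    @property
    def n_starts(self) -> int:
        return (
            len(self.delta_starts) * len(self.beta0_starts) * len(self.ir_starts)
        )


@dataclass(frozen=True)
class SiteFit:
    """Result of the per-site three-parameter fit (pre-consensus)."""

    probe_id: str
    delta_hat: float
    beta0_hat: float
    ir_hat: float
    rss: float
    converged: bool
    n_used: int
    degenerate: bool = False

    @property
    def rate_product(self) -> float:
        """Annual methylation gain rate delta_hat * ir_hat."""
        return self.delta_hat * self.ir_hat


@dataclass(frozen=True)
class CohortFit:
    """Full cohort fit: per-site fits, retained probes, consensus and refit."""

    site_fits: tuple[SiteFit, ...]
    retained_probes: tuple[str, ...]
    modal_delta: float
    modal_ir: float
    final_params: pd.DataFrame  # index probe_id, columns delta, beta0, rss

    @property
    def parameter_table(self) -> pd.DataFrame:
        """Round-trippable per-probe table (see :mod:`mitoclock.io`)."""
        rows = []
        final = self.final_params
        retained = set(self.retained_probes)
        for fit in self.site_fits:
            row = {
                "probe_id": fit.probe_id,
                "delta": (
                    final.loc[fit.probe_id, "delta"]
                    if fit.probe_id in final.index
                    else fit.delta_hat
                ),
                "beta0": (
                    final.loc[fit.probe_id, "beta0"]
                    if fit.probe_id in final.index
                    else fit.beta0_hat
                ),
                "ir_site": fit.ir_hat,
                "rss": fit.rss,
                "converged": fit.converged,
                "retained": fit.probe_id in retained,
            }
            rows.append(row)
        return pd.DataFrame(rows).set_index("probe_id")


def _model_and_jac(params: np.ndarray, ages: np.ndarray):
    """Trajectory model and analytic Jacobian at (delta, beta0, ir)."""
    delta, beta0, ir = params
    log_fac = np.log1p(-0.5 * delta)
    t = ages * ir
    c = np.exp(t * log_fac)
    model = 1.0 - (1.0 - beta0) * c
    # d model / d delta  = (1-beta0) * c * t * (1/2)/(1 - delta/2)
    dm_ddelta = (1.0 - beta0) * c * t * (0.5 / (1.0 - 0.5 * delta))
    dm_dbeta0 = c
    dm_dir = -(1.0 - beta0) * c * ages * log_fac
    return model, np.column_stack([dm_ddelta, dm_dbeta0, dm_dir])


def _clean_pairs(
    betas: Sequence[float], ages: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    betas = np.asarray(betas, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if betas.shape != ages.shape:
        raise ValueError("betas and ages must have equal length")
    bad_age = ~np.isfinite(ages) | (ages <= 0)
    if np.any(bad_age & np.isfinite(betas)):
        logger.warning(
            "excluding %d samples with missing or non-positive age",
            int(np.sum(bad_age)),
        )
    keep = np.isfinite(betas) & ~bad_age
    betas, ages = betas[keep], ages[keep]
    if np.any((betas < 0) | (betas > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    return betas, ages


def _snapped_cell_rss(
    x: np.ndarray, betas: np.ndarray, ages: np.ndarray, grid: FitGrid
) -> float:
    """RSS of a solution's grid-snapped (delta, IR) cell, beta0 profiled.

    With (delta, IR) pinned to the nearest grid cell, the model is linear
    in beta0 and the optimum is closed-form (clipped to its bounds);
    used only to rank RSS-tied solutions along the flat compound-rate
    ridge.
    """
    d_cell = _snap(float(x[0]), grid.delta_starts, log=True)
    ir_cell = _snap(float(x[2]), grid.ir_starts, log=False)
    c = np.exp(ir_cell * ages * np.log1p(-0.5 * d_cell))
    denom = float(np.sum(c * c))
    one_minus_b0 = float(np.sum(c * (1.0 - betas))) / denom if denom > 0 else 1.0
    beta0 = float(np.clip(1.0 - one_minus_b0, *BETA0_BOUNDS))
    resid = 1.0 - (1.0 - beta0) * c - betas
    return float(np.sum(resid * resid))


def fit_site(
    betas: Sequence[float],
    ages: Sequence[float],
    grid: FitGrid | None = None,
    probe_id: str = "",
) -> SiteFit:
    """Fit (delta, beta0, IR) for one CpG by grid-multi-start bounded NLS.

    Minimises sum_s [beta_s - trajectory(delta, beta0, A(s)*IR)]^2 with
    bounds delta in [1e-7, 0.01], beta0 in [0, 0.1], IR in [0.01, 150],
    restarting from every grid triple and keeping the lowest-RSS converged
    solution.  Missing betas are dropped pairwise; at least 30 complete
    (beta, age) pairs are required.

    A site with no variation in beta carries no accrual signal and is
    returned with ``converged=False`` and ``degenerate=True``.

    Because the single-site objective depends on (delta, IR) only through
    the compound rate lambda = -IR*log(1 - delta/2), converged starts tie
    in RSS along an exactly flat ridge.  Ties (within 1e-9 relative) are
    broken in favour of the solution whose grid-snapped (delta, IR) cell
    — with beta0 re-optimised in closed form — has the lowest RSS, i.e.
    the ridge solution best supported by a grid cell; remaining ties fall
    back to the lowest initial RSS.  The consensus step then reads the
    winning cell.
    """
    grid = grid or FitGrid()
    betas, ages = _clean_pairs(betas, ages)
    if betas.size < MIN_SAMPLES:
        raise ValueError(
            f"need at least {MIN_SAMPLES} complete (beta, age) pairs, "
            f"got {betas.size}"
        )
    if np.ptp(betas) == 0.0:
        return SiteFit(
            probe_id=probe_id,
            delta_hat=DELTA_BOUNDS[0],
            beta0_hat=float(np.clip(betas[0], *BETA0_BOUNDS)),
            ir_hat=IR_BOUNDS[0],
            rss=0.0,
            converged=False,
            n_used=int(betas.size),
            degenerate=True,
        )

    def residuals(p: np.ndarray) -> np.ndarray:
        model, _ = _model_and_jac(p, ages)
        return model - betas

    def jac(p: np.ndarray) -> np.ndarray:
        _, J = _model_and_jac(p, ages)
        return J

    lo = np.array([DELTA_BOUNDS[0], BETA0_BOUNDS[0], IR_BOUNDS[0]])
    hi = np.array([DELTA_BOUNDS[1], BETA0_BOUNDS[1], IR_BOUNDS[1]])

    starts = np.array(
        [
            (d0, b0, ir0)
            for d0 in grid.delta_starts
            for b0 in grid.beta0_starts
            for ir0 in grid.ir_starts
        ]
    )
    starts = np.clip(starts, lo, hi)
    # initial RSS at every grid triple, vectorised
    c0 = np.exp(
        (starts[:, 2:3] * np.log1p(-0.5 * starts[:, 0:1])) * ages[None, :]
    )
    init_rss = np.sum(
        ((1.0 - (1.0 - starts[:, 1:2]) * c0) - betas[None, :]) ** 2, axis=1
    )

    solutions = []  # (rss, init_rss, x)
    for x0, irss in zip(starts, init_rss):
        try:
            res = least_squares(
                residuals,
                x0,
                jac=jac,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=1e-10,
                xtol=1e-10,
                gtol=1e-10,
                max_nfev=500,
            )
        except Exception:  # pragma: no cover - optimizer edge case
            logger.debug("start %s raised", x0, exc_info=True)
            continue
        if not res.success:
            logger.debug("start %s did not converge", x0)
            continue
        solutions.append((float(2.0 * res.cost), float(irss), res.x))
    best = None
    if solutions:
        min_rss = min(s[0] for s in solutions)
        tol = 1e-9 * max(min_rss, 1e-300)
        tied = [s for s in solutions if s[0] <= min_rss + tol]
        best = min(
            tied,
            key=lambda s: (_snapped_cell_rss(s[2], betas, ages, grid), s[1]),
        )
    if best is None:
        return SiteFit(
            probe_id=probe_id,
            delta_hat=float("nan"),
            beta0_hat=float("nan"),
            ir_hat=float("nan"),
            rss=float("inf"),
            converged=False,
            n_used=int(betas.size),
        )
    rss, _, x = best
    return SiteFit(
        probe_id=probe_id,
        delta_hat=float(x[0]),
        beta0_hat=float(x[1]),
        ir_hat=float(x[2]),
        rss=rss,
        converged=True,
        n_used=int(betas.size),
    )


def filter_sites(
    fits: Iterable[SiteFit], threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Probe ids whose fitted gain rate delta*IR meets the assay floor.

    Retains CpGs with ``delta_hat * ir_hat >= threshold`` (default 0.001,
    i.e. at least 1% DNAm gain per decade, the resolution of the beadarray
    assay).  Order-preserving and idempotent; unconverged fits never pass.
    """
    retained = []
    for fit in fits:
        if not fit.converged:
            continue
        if fit.rate_product >= threshold:
            retained.append(fit.probe_id)
    return retained


def _snap(value: float, choices: Sequence[float], log: bool) -> float:
    arr = np.asarray(choices, dtype=float)
    if log:
        dist = np.abs(np.log10(arr) - np.log10(max(value, 1e-300)))
    else:
        dist = np.abs(arr - value)
    return float(arr[int(np.argmin(dist))])


def consensus_rate(
    fits: Iterable[SiteFit], grid: FitGrid | None = None
) -> tuple[float, float]:
    """Modal (delta, IR) grid cell across retained site fits.

    Each site's continuous (delta_hat, ir_hat) is snapped to the nearest
    grid value — delta by nearest neighbour in log10 space (the delta grid
    is geometric), IR linearly — and the most occupied (delta, IR) cell is
    returned.  Ties are broken by the lowest summed RSS across the tied
    cells.  Since the true IR cannot be CpG-dependent, the modal cell is
    the cohort's single best-supported intrinsic rate.
    """
    grid = grid or FitGrid()
    counts: dict[tuple[float, float], int] = {}
    rss_sums: dict[tuple[float, float], float] = {}
    n = 0
    for fit in fits:
        if not fit.converged:
            continue
        cell = (
            _snap(fit.delta_hat, grid.delta_starts, log=True),
            _snap(fit.ir_hat, grid.ir_starts, log=False),
        )
        counts[cell] = counts.get(cell, 0) + 1
        rss_sums[cell] = rss_sums.get(cell, 0.0) + fit.rss
        n += 1
    if n == 0:
        raise ValueError("consensus_rate requires at least one converged fit")
    best_count = max(counts.values())
    tied = [cell for cell, c in counts.items() if c == best_count]
    winner = min(tied, key=lambda cell: rss_sums[cell])
    return winner


def refit_fixed_rate(
    matrix: pd.DataFrame,
    ages: Sequence[float],
    modal_ir: float,
    grid: FitGrid | None = None,
) -> pd.DataFrame:
    """Refit (delta_i, beta_i0) per probe with IR frozen at the modal value.

    ``matrix`` is probes x samples (rows restricted to the retained
    probes).  With t(s) = A(s) * modal_ir fixed, the two remaining
    parameters are well identified; the fit restarts from every
    (delta, beta0) grid pair.  Returns a DataFrame indexed by probe_id
    with columns ``delta``, ``beta0``, ``rss`` — the parameter table the
    clocks module consumes.
    """
    if modal_ir <= 0:
        raise ValueError("modal_ir must be positive")
    grid = grid or FitGrid()
    ages_arr = np.asarray(ages, dtype=float)
    lo = np.array([DELTA_BOUNDS[0], BETA0_BOUNDS[0]])
    hi = np.array([DELTA_BOUNDS[1], BETA0_BOUNDS[1]])
    rows = []
    for probe_id, row in matrix.iterrows():
        betas, t_ages = _clean_pairs(row.to_numpy(dtype=float), ages_arr)
        if betas.size < MIN_SAMPLES:
            raise ValueError(
                f"probe {probe_id}: need at least {MIN_SAMPLES} complete pairs"
            )
        t = t_ages * modal_ir

        def residuals(p: np.ndarray) -> np.ndarray:
            c = np.exp(t * np.log1p(-0.5 * p[0]))
            return (1.0 - (1.0 - p[1]) * c) - betas

        def jac(p: np.ndarray) -> np.ndarray:
            c = np.exp(t * np.log1p(-0.5 * p[0]))
            dd = (1.0 - p[1]) * c * t * (0.5 / (1.0 - 0.5 * p[0]))
            return np.column_stack([dd, c])

        best = None
        for d0 in grid.delta_starts:
            for b0 in grid.beta0_starts:
                x0 = np.clip(np.array([d0, b0]), lo, hi)
                res = least_squares(
                    residuals,
                    x0,
                    jac=jac,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale="jac",
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                    max_nfev=500,
                )
                if not res.success:
                    continue
                rss = float(2.0 * res.cost)
                if best is None or rss < best[0]:
                    best = (rss, res.x)
        if best is None:
            logger.warning("probe %s: fixed-rate refit did not converge", probe_id)
            continue
        rss, x = best
        rows.append(
            {"probe_id": probe_id, "delta": x[0], "beta0": x[1], "rss": rss}
        )
    return pd.DataFrame(rows).set_index("probe_id")


def fit_cohort(
    matrix: pd.DataFrame,
    ages: Sequence[float],
    grid: FitGrid | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CohortFit:
    """Full estimation pipeline: per-site fits, filter, consensus, refit.

    ``matrix`` is probes x samples with ``ages`` aligned to its columns.
    """
    grid = grid or FitGrid()
    ages_arr = np.asarray(ages, dtype=float)
    fits = []
    for i, (probe_id, row) in enumerate(matrix.iterrows()):
        fits.append(
            fit_site(row.to_numpy(dtype=float), ages_arr, grid, probe_id=str(probe_id))
        )
        if (i + 1) % 25 == 0:
            logger.info("fitted %d/%d sites", i + 1, len(matrix))
    retained = filter_sites(fits, threshold)
    retained_fits = [f for f in fits if f.probe_id in set(retained)]
    modal_delta, modal_ir = consensus_rate(retained_fits, grid)
    final = refit_fixed_rate(matrix.loc[retained], ages_arr, modal_ir, grid)
    return CohortFit(
        site_fits=tuple(fits),
        retained_probes=tuple(retained),
        modal_delta=modal_delta,
        modal_ir=modal_ir,
        final_params=final,
    )
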