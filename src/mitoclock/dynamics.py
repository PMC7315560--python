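"""Forward model of replication-coupled DNA methylation gain at a CpG dyad.

A CpG dyad (the pair of complementary strands at one locus) is in one of
three states: fully methylated (frequency ``M``), hemimethylated (``H``) or
unmethylated (``U``).  At each cell division a methylated strand is
maintained with probability ``mu`` and an unmethylated strand acquires de
novo methylation with probability ``delta_p`` (parent strand) or ``delta_d``
(daughter strand).  The strand-level methylation frequency
``m = M + H/2`` — the quantity a bisulfite beta value measures — then obeys
the linear recursion ``m_t = a + b * m_{t-1}`` with ``a = delta/2`` and
``b = (1 + mu - delta)/2``, which has the closed-form solution implemented
in :func:`trajectory_exact`.  For CpGs that start out unmethylated,
maintenance is close to perfect (``mu ~ 1``) and the trajectory reduces to

    beta_t = 1 - (1 - delta/2)**t + beta0 * (1 - delta/2)**t

(:func:`trajectory_approx`), whose first-order expansion in ``delta*t``
(:func:`first_order_beta`) is linear in the cumulative division count and
is the basis of the mitotic-age estimator in :mod:`mitoclock.clocks`.

Division count ``t`` is accepted as a non-negative real because downstream
fitting uses ``t = age * IR`` with a continuous division rate ``IR``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DyadState",
    "SiteKinetics",
    "dyad_step",
    "strand_recursion_coefficients",
    "trajectory_exact",
    "trajectory_approx",
    "first_order_beta",
]

_ATOL = 1e-12


def _check_fraction(value: float, name: str) -> None:
    if not (-_ATOL <= value <= 1.0 + _ATOL):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class DyadState:
    """Dyad-state frequencies: fully methylated, hemimethylated, unmethylated.

    Frequencies must be in [0, 1] and sum to 1 (within 1e-12).
    """

    M: float
    H: float
    U: float

    def __post_init__(self) -> None:
        for name in ("M", "H", "U"):
            _check_fraction(getattr(self, name), name)
        total = self.M + self.H + self.U
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dyad frequencies must sum to 1, got {total!r}")

    @property
    def m(self) -> float:
        """Strand-level methylation frequency ``M + H/2``."""
        return self.M + 0.5 * self.H

    @property
    def u(self) -> float:
        """Strand-level unmethylated frequency ``1 - m``."""
        return 1.0 - self.m


@dataclass(frozen=True)
class SiteKinetics:
    """Per-division methylation kinetics of one CpG site.

    Parameters
    ----------
    delta_p, delta_d
        De novo methylation probabilities on the parent and daughter
        strand, per division.
    mu
        Maintenance probability per division (1 - mu is the loss rate of
        a methylated strand).
    beta0
        Ground-state (fetal, division time 0) methylation fraction.
    """

    delta_p: float
    delta_d: float
    mu: float = 1.0
    beta0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_p", "delta_d", "mu", "beta0"):
            _check_fraction(getattr(self, name), name)
        if self.delta > 1.0 + _ATOL:
            raise ValueError(
                f"total de novo probability delta_p + delta_d must be <= 1, "
                f"got {self.delta!r}"
            )

    @classmethod
    def from_total(
        cls, delta: float, mu: float = 1.0, beta0: float = 0.0
    ) -> "SiteKinetics":
        """Build kinetics from the total de novo probability ``delta``.

        The split between strands is symmetric (delta_p = delta_d =
        delta/2); the strand-level trajectories depend only on the sum.
        """
        return cls(delta_p=delta / 2.0, delta_d=delta / 2.0, mu=mu, beta0=beta0)

    @property
    def delta(self) -> float:
        """Total de novo probability delta_p + delta_d."""
        return self.delta_p + self.delta_d


def dyad_step(state: DyadState, kin: SiteKinetics) -> DyadState:
    """Advance the dyad-state frequencies by one cell division.

    Both post-replication dyads inherit the strand composition of the
    parent dyad; maintenance acts on methylated parent strands and de novo
    methylation on unmethylated strands of either type, giving

        M_t = mu * m + delta_p * delta_d * u
        H_t = (1 - mu) * m + [delta_d (1 - delta_p) + delta_p (1 - delta_d)] * u

    with ``m = M + H/2`` and ``u = 1 - m`` of the input state.
    """
    m, u = state.m, state.u
    M_next = kin.mu * m + kin.delta_p * kin.delta_d * u
    H_next = (1.0 - kin.mu) * m + (
        kin.delta_d * (1.0 - kin.delta_p) + kin.delta_p * (1.0 - kin.delta_d)
    ) * u
    U_next = 1.0 - M_next - H_next
    return DyadState(M=M_next, H=H_next, U=max(U_next, 0.0))


def strand_recursion_coefficients(kin: SiteKinetics) -> tuple[float, float]:
    """Coefficients (a, b) of the strand-frequency recursion m_t = a + b m_{t-1}.

    a = delta/2 and b = (1 + mu - delta)/2; b < 1 whenever there is any
    methylation turnover (delta > 0 or mu < 1).
    """
    a = 0.5 * kin.delta
    b = 0.5 * (1.0 + kin.mu - kin.delta)
    return a, b


def trajectory_exact(kin: SiteKinetics, m0: float, t: float) -> float:
    """Closed-form strand methylation frequency after ``t`` divisions.

    Solves m_t = a + b m_{t-1} exactly:

        m_t = a/(1-b) + b**t * (m0 - a/(1-b))

    For b = 1 (delta = 0 and mu = 1, no turnover) the solution is the
    constant m0.  ``t`` may be any non-negative real.
    """
    _check_fraction(m0, "m0")
    if t < 0:
        raise ValueError("division count t must be non-negative")
    a, b = strand_recursion_coefficients(kin)
    one_minus_b = 0.5 * (1.0 + kin.delta - kin.mu)  # exact 1 - b
    if one_minus_b <= 0.0:
        return m0
    steady = a / one_minus_b
    # b**t via exp(t * log1p(-(1-b))) keeps precision for b close to 1
    if b > 0.0:
        bt = math.exp(t * math.log1p(-one_minus_b)) if t > 0 else 1.0
    else:
        bt = 1.0 if t == 0 else 0.0
    m_t = steady + bt * (m0 - steady)
    return float(min(max(m_t, 0.0), 1.0))


def trajectory_approx(delta, beta0, t):
    """Methylation beta value after ``t`` divisions under perfect maintenance.

        beta_t = 1 - (1 - delta/2)**t + beta0 * (1 - delta/2)**t

    This is :func:`trajectory_exact` with mu = 1; as t -> inf the site
    saturates at beta = 1.  Vectorised over any of the three arguments;
    ``t`` may be real-valued (t = age * IR in fitting).  delta = 0 is the
    degenerate no-gain case and returns beta0 for every t.
    """
    delta = np.asarray(delta, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(delta < 0) or np.any(delta > 1):
        raise ValueError("delta must lie in [0, 1]")
    if np.any((beta0 < 0) | (beta0 > 1)):
        raise ValueError("beta0 must lie in [0, 1]")
    if np.any(t < 0):
        raise ValueError("division count t must be non-negative")
    # (1 - delta/2)**t computed as exp(t * log1p(-delta/2)) for precision
    fac = np.exp(t * np.log1p(-0.5 * delta))
    out = 1.0 - (1.0 - beta0) * fac
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def first_order_beta(delta, beta0, tnsc):
    """First-order (in delta*t) methylation level at mitotic age ``tnsc``.

        beta = beta0 + (delta/2) * (1 - beta0) * TNSC

    capped at 1.  Linear in the cumulative division count below the cap;
    inverting this relation across a panel of CpGs is exactly the
    mitotic-age estimator :func:`mitoclock.clocks.estimate_tnsc`.
    """
    delta = np.asarray(delta, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    tnsc = np.asarray(tnsc, dtype=float)
    if np.any(tnsc < 0):
        raise ValueError("tnsc must be non-negative")
    out = beta0 + 0.5 * delta * (1.0 - beta0) * tnsc
    out = np.minimum(out, 1.0)
    return float(out) if out.ndim == 0 else out
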