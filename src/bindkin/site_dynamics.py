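"""Time-dependent availability of a binding site that builds and decays.

The central object is the total binding-site level ``B_total(t)``, which
rises toward an asymptote ``B_inf`` with rate constant ``ki`` and, once it
has settled (reached 95% of ``B_inf``), decays with rate constant
``k_minus_i``.  Two mechanistic pictures are supported:

* **Scenario 1** (``exp_species``): production/degradation of the
  site-containing species.  Buildup is a saturating exponential
  ``1 - exp(-ki*t)``; decay is a simple exponential.
* **Scenario 2** (``logistic_state``): gating of a binding-competent
  conformational state.  Both phases are logistic, with the curve pinned
  at 5% of its maximum at ``t = 0``.

Time is handled in the dimensionless variable ``tau = ki * t``, in which
the scenario-1 peak always sits at ``tau = 3`` (the normalized settling
time) and the scenario-2 peak at ``tau ~ 5.94``, independent of rates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scenario",
    "SiteTurnover",
    "ScenarioAnchors",
    "SiteTrajectory",
    "FunctionalWindow",
    "settling_time",
    "half_life",
    "btotal_scenario1",
    "btotal_scenario2",
    "site_trajectory",
    "functional_window",
    "BMAX_FRACTION",
    "XI_BAR_SCENARIO1",
    "TAU01",
    "XI_BAR_SCENARIO2",
    "TAU02",
    "DEFAULT_TAU_MAX",
    "DEFAULT_GRID_POINTS",
]

#: The settling convention: B_max is defined as 95% of the asymptote B_inf.
BMAX_FRACTION = 0.95

#: Normalized settling time for scenario 1 (3/ki in real time, by convention).
XI_BAR_SCENARIO1 = 3.0

#: Scenario-2 logistic buildup midpoint, fixed by B_total(0) = 5%: ln(19).
TAU01 = math.log(19.0)

#: Normalized settling time for scenario 2.
XI_BAR_SCENARIO2 = 3.0 + TAU01

#: Scenario-2 logistic decay midpoint.
TAU02 = 3.0 + XI_BAR_SCENARIO2

#: Default dimensionless window and grid density used by all figures-style
#: trajectories (uniform width tau = 12).
DEFAULT_TAU_MAX = 12.0
DEFAULT_GRID_POINTS = 1201


class Scenario(enum.Enum):
    """Mechanism generating binding-site buildup and decay."""

    EXP_SPECIES = 1
    LOGISTIC_STATE = 2


def _require_positive(value: float, name: str) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class SiteTurnover:
    """Buildup/decay law of the binding site.

    Parameters
    ----------
    ki : float
        Buildup rate constant (s^-1).
    k_minus_i : float
        Decay rate constant (s^-1).
    scenario : Scenario
        Which mechanistic picture applies.
    B_inf : float, default 1.0
        Asymptotic site level (M, or 1.0 in normalized mode).
    """

    ki: float
    k_minus_i: float
    scenario: Scenario = Scenario.EXP_SPECIES
    B_inf: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(self.ki, "ki")
        _require_positive(self.k_minus_i, "k_minus_i")
        _require_positive(self.B_inf, "B_inf")

    @property
    def gamma(self) -> float:
        """Ratio of decay to buildup rate, k_minus_i / ki."""
        return self.k_minus_i / self.ki


@dataclass(frozen=True)
class ScenarioAnchors:
    """Characteristic times of the site-availability curve.

    ``xi`` is the settling time in seconds; the remaining fields are
    dimensionless.  For scenario 1 ``xi_bar = 3`` by convention and the
    logistic midpoints are undefined (NaN).  For scenario 2 the buildup
    midpoint ``tau01 = ln 19`` follows from the 5% initial condition,
    ``xi_bar = 3 + tau01`` and ``tau02 = 3 + xi_bar``.
    """

    xi: float
    xi_bar: float
    tau01: float = float("nan")
    tau02: float = float("nan")

    @classmethod
    def for_turnover(cls, turnover: SiteTurnover) -> "ScenarioAnchors":
        xi = settling_time(turnover.ki)
        if turnover.scenario is Scenario.EXP_SPECIES:
            return cls(xi=xi, xi_bar=XI_BAR_SCENARIO1)
        return cls(xi=xi, xi_bar=XI_BAR_SCENARIO2, tau01=TAU01, tau02=TAU02)


@dataclass
class SiteTrajectory:
    """Sampled site-availability curve on a dimensionless time grid."""

    tau_grid: np.ndarray
    b_total: np.ndarray
    time_scale: float  # seconds per unit tau (= 1/ki)
    scenario: Scenario = Scenario.EXP_SPECIES

    @property
    def t_seconds(self) -> np.ndarray:
        return self.tau_grid * self.time_scale

    def argmax_tau(self) -> float:
        return float(self.tau_grid[int(np.argmax(self.b_total))])


@dataclass(frozen=True)
class FunctionalWindow:
    """Duration for which the site level stays >= 50% of its maximum."""

    lam: float  # seconds
    scenario: Scenario
    extrapolated: bool = False


def settling_time(ki: float) -> float:
    """Time for the saturating-exponential buildup to reach 95% of B_inf.

    Returns ``-ln(0.05)/ki``, approximately ``3/ki``.
    """
    _require_positive(ki, "ki")
    return -math.log(1.0 - BMAX_FRACTION) / ki


def half_life(k: float) -> float:
    """Half-life ``ln 2 / k`` of a first-order process (seconds)."""
    _require_positive(k, "k")
    return math.log(2.0) / k


def _check_tau(tau) -> np.ndarray:
    arr = np.asarray(tau, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("tau must be nonnegative")
    return arr


def btotal_scenario1(turnover: SiteTurnover, tau, *, rescale_decay: bool = False):
    """Normalized scenario-1 site level at dimensionless time ``tau``.

    Buildup ``(1 - exp(-tau))/0.95`` for ``tau < 3``, then exponential decay
    ``exp(-gamma*(tau - 3))`` with ``gamma = k_minus_i/ki``.  The buildup
    branch is expressed in units of ``B_max = 0.95*B_inf`` so its value at
    the settling time is exactly 1; the decay branch restarts from the full
    asymptote (a deliberate ~0.5% truncation jump at the switch).  Passing
    ``rescale_decay=True`` instead starts the decay from the buildup value
    at the switch, removing the jump.
    """
    arr = _check_tau(tau)
    gamma = turnover.gamma
    build = -np.expm1(-arr) / BMAX_FRACTION
    decay_amp = (-math.expm1(-XI_BAR_SCENARIO1) / BMAX_FRACTION) if rescale_decay else 1.0
    # clip the unused pre-settling part of the decay argument to avoid
    # spurious overflow inside np.where
    decay = decay_amp * np.exp(-gamma * np.maximum(arr - XI_BAR_SCENARIO1, 0.0))
    out = np.where(arr < XI_BAR_SCENARIO1, build, decay)
    return out if out.ndim else float(out)


def btotal_scenario2(turnover: SiteTurnover, tau,
                     anchors: ScenarioAnchors | None = None):
    """Scenario-2 site level (units of B_inf) at dimensionless time ``tau``.

    Logistic rise ``1/(1 + exp(-(tau - tau01)))`` for ``tau < xi_bar``, then
    a logistic fall.  For ``ki == k_minus_i`` the fall is the mirror-image
    logistic centred at ``tau02``; for unequal rates its steepness is scaled
    by ``gamma = k_minus_i/ki`` while keeping the curve continuous at the
    switch (an extrapolation beyond the equal-rates derivation, flagged as
    such by :func:`functional_window`).
    """
    arr = _check_tau(tau)
    if anchors is None:
        anchors = ScenarioAnchors.for_turnover(
            SiteTurnover(turnover.ki, turnover.k_minus_i, Scenario.LOGISTIC_STATE,
                         turnover.B_inf))
    gamma = turnover.gamma
    build = 1.0 / (1.0 + np.exp(-(arr - anchors.tau01)))
    # Decay argument gamma*(tau - xi_bar) - 3 equals (tau - tau02) when
    # gamma = 1 and keeps b(xi_bar) = 1/(1 + e^-3) for any gamma.
    decay_arg = gamma * np.maximum(arr - anchors.xi_bar, 0.0) - 3.0
    decay = 1.0 / (1.0 + np.exp(decay_arg))
    out = np.where(arr < anchors.xi_bar, build, decay)
    return out if out.ndim else float(out)


def site_trajectory(turnover: SiteTurnover,
                    tau_max: float = DEFAULT_TAU_MAX,
                    grid_points: int = DEFAULT_GRID_POINTS,
                    *, normalized: bool = True,
                    rescale_decay: bool = False) -> SiteTrajectory:
    """Sample the site-availability curve on a uniform dimensionless grid.

    In normalized mode the curve is expressed in units of its own maximum
    (scenario 1: B_max; scenario 2: the logistic peak level); otherwise it
    is multiplied by ``B_inf``.
    """
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    tau = np.linspace(0.0, tau_max, grid_points)
    if turnover.scenario is Scenario.EXP_SPECIES:
        b = btotal_scenario1(turnover, tau, rescale_decay=rescale_decay)
    else:
        b = btotal_scenario2(turnover, tau)
        if normalized:
            b = b * (1.0 + math.exp(-3.0))  # divide by logistic peak 1/(1+e^-3)
    if not normalized:
        scale = BMAX_FRACTION * turnover.B_inf \
            if turnover.scenario is Scenario.EXP_SPECIES else turnover.B_inf
        b = b * scale
    return SiteTrajectory(tau_grid=tau, b_total=b, time_scale=1.0 / turnover.ki,
                          scenario=turnover.scenario)


def functional_window(turnover: SiteTurnover) -> FunctionalWindow:
    """Duration Lambda (s) for which the site level stays >= 50% of maximum.

    Scenario 1: ``(3 - ln 2)/ki + ln 2/k_minus_i`` (buildup spends
    ``3 - ln 2`` dimensionless units above half level; decay one half-life).
    Scenario 2 with equal rates: ``2 ln 2 / ki``.  Scenario 2 with unequal
    rates has no closed form in the equal-rates derivation; the returned
    ``ln 2/ki + ln 2/k_minus_i`` is flagged as an extrapolation.
    """
    ki, kmi = turnover.ki, turnover.k_minus_i
    ln2 = math.log(2.0)
    if turnover.scenario is Scenario.EXP_SPECIES:
        lam = (XI_BAR_SCENARIO1 - ln2) / ki + ln2 / kmi
        return FunctionalWindow(lam=lam, scenario=turnover.scenario)
    if math.isclose(ki, kmi, rel_tol=1e-12):
        return FunctionalWindow(lam=2.0 * ln2 / ki, scenario=turnover.scenario)
    return FunctionalWindow(lam=ln2 / ki + ln2 / kmi, scenario=turnover.scenario,
                            extrapolated=True)
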