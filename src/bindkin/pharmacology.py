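"""Static occupancy algebra and kinetic-tuning analytics.

Hill-type fractional occupancy, its inverse (dose back-calculation),
competitive occupancy in the presence of an endogenous ligand, a
kinetic-tuning advisor that orders kon/koff optimization against the
binding site's own turnover rates, and summary statistics over tables of
published drug kinetics.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

from .occupancy import BindingKinetics, effective_koff, kon_ss, LigandDose
from .site_dynamics import SiteTurnover

__all__ = [
    "CompetitionContext",
    "DrugRecord",
    "DrugSetSummary",
    "TuningAdvisory",
    "TuningReport",
    "DIFFUSION_LIMIT_KON",
    "SLOW_KOFF_CUTOFF",
    "FAST_KON_CUTOFF",
    "SUB_NM_KD_CUTOFF",
    "hill_occupancy",
    "competitive_occupancy",
    "invert_hill",
    "tuning_report",
    "drugset_summary",
]

logger = logging.getLogger(__name__)

#: Diffusion-limited upper bound on kon; past this, occupancy gains must
#: come from concentration rather than on-rate.
DIFFUSION_LIMIT_KON = 1e9

#: Cutoffs used to bin marketed-drug kinetics: "slow" koff (half-life of
#: roughly 30 min or longer), "fast" kon, and sub-nanomolar affinity.
SLOW_KOFF_CUTOFF = 3.9e-4   # s^-1, strict <
FAST_KON_CUTOFF = 1e5       # M^-1 s^-1
SUB_NM_KD_CUTOFF = 1e-9     # M, strict <


def hill_occupancy(L: float, Kd: float) -> float:
    """Equilibrium fractional occupancy L/(L + Kd)."""
    if not (Kd > 0.0):
        raise ValueError(f"Kd must be positive, got {Kd!r}")
    if L < 0.0:
        raise ValueError(f"L must be nonnegative, got {L!r}")
    return L / (L + Kd)


def competitive_occupancy(L: float, Ki: float, Le: float, Ke: float) -> float:
    """Drug occupancy against a competing endogenous ligand.

    ``L/(L + Ki + Ki*Le/Ke)``: the apparent inhibitory constant is
    inflated by the endogenous occupancy pressure ``Le/Ke``.  Reduces to
    :func:`hill_occupancy` when ``Le = 0``.
    """
    if not (Ki > 0.0) or not (Ke > 0.0):
        raise ValueError("Ki and Ke must be positive")
    if L < 0.0 or Le < 0.0:
        raise ValueError("concentrations must be nonnegative")
    return L / (L + Ki + Ki * Le / Ke)


def invert_hill(occupancy: float, Kd: float) -> float:
    """Free ligand concentration producing a given fractional occupancy.

    Exact inverse of :func:`hill_occupancy`: ``Kd * occ/(1 - occ)``.
    """
    if not (0.0 < occupancy < 1.0):
        raise ValueError(f"occupancy must lie in (0, 1), got {occupancy!r}")
    if not (Kd > 0.0):
        raise ValueError(f"Kd must be positive, got {Kd!r}")
    return Kd * occupancy / (1.0 - occupancy)


@dataclass(frozen=True)
class CompetitionContext:
    """Concentrations and constants for competitive occupancy."""

    L: float   # free drug (M)
    Ki: float  # drug equilibrium constant (M)
    Le: float  # free endogenous ligand (M)
    Ke: float  # endogenous ligand equilibrium constant (M)

    def occupancy(self) -> float:
        return competitive_occupancy(self.L, self.Ki, self.Le, self.Ke)


class TuningAdvisory(enum.Enum):
    """Recommended next optimization step for a drug-target pair."""

    TUNED = "tuned"
    SPEED_KON_FIRST = "speed_kon_first"
    SLOW_KOFF_WITHIN_K_MINUS_I = "slow_koff_within_k_minus_i"
    CONCENTRATION_COMPENSATION_NEEDED = "concentration_compensation_needed"


@dataclass(frozen=True)
class TuningReport:
    """Kinetic-tuning assessment of a drug against its target turnover."""

    kon_ss: float
    kon_ratio: float          # kon / kon_ss
    hijacked: bool
    Kd_prime: float
    required_multiple: float  # n = L0/Kd' needed for the target occupancy
    compensation_multiple: float  # fold-increase in L0 standing in for kon
    advisory: TuningAdvisory


def tuning_report(kinetics: BindingKinetics, turnover: SiteTurnover,
                  dose: LigandDose, target_occupancy: float) -> TuningReport:
    """Order the kinetic optimization steps for a drug-target pair.

    The advisory follows a fixed decision table.  Below the steady-state
    on-rate (``kon < kon_ss = 10*ki/L0``) occupancy is on-rate limited and
    slowing koff is futile, so the first move is speeding kon — unless
    kon_ss exceeds the diffusion limit, in which case only raising the
    concentration can compensate.  At or above kon_ss, koff slower than
    the site decay rate ``k_minus_i`` buys nothing further (it is hijacked),
    so the pair is tuned; otherwise the remaining step is slowing koff
    down to ``k_minus_i``.
    """
    if not (0.0 < target_occupancy < 1.0):
        raise ValueError("target_occupancy must lie in (0, 1)")
    if not (dose.L0 > 0.0):
        raise ValueError("L0 must be positive")
    eff = effective_koff(kinetics, turnover.k_minus_i)
    kss = kon_ss(turnover.ki, dose.L0)
    ratio = kinetics.kon / kss
    n_required = target_occupancy / (1.0 - target_occupancy)

    if ratio >= 1.0:
        advisory = (TuningAdvisory.TUNED if eff.hijacked
                    else TuningAdvisory.SLOW_KOFF_WITHIN_K_MINUS_I)
    elif kss > DIFFUSION_LIMIT_KON:
        advisory = TuningAdvisory.CONCENTRATION_COMPENSATION_NEEDED
    else:
        advisory = TuningAdvisory.SPEED_KON_FIRST
    return TuningReport(kon_ss=kss, kon_ratio=ratio, hijacked=eff.hijacked,
                        Kd_prime=eff.Kd_prime,
                        required_multiple=n_required,
                        compensation_multiple=max(1.0, 1.0 / ratio),
                        advisory=advisory)


@dataclass(frozen=True)
class DrugRecord:
    """One published drug kinetics entry (kon, koff, complex half-life, Kd)."""

    name: str
    target: str
    kon: float      # M^-1 s^-1
    koff: float     # s^-1
    t_half: float   # min
    Kd: float       # M

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0 or self.Kd <= 0 or self.t_half <= 0:
            raise ValueError(f"{self.name}: rates and Kd must be positive")
        # Consistency is checked, not enforced: published tables round.
        t_half_calc = math.log(2.0) / self.koff / 60.0
        if abs(t_half_calc - self.t_half) > 0.10 * t_half_calc:
            logger.info("%s: printed t_half %.3g min vs ln2/koff %.3g min",
                        self.name, self.t_half, t_half_calc)
        kd_calc = self.koff / self.kon
        if abs(kd_calc - self.Kd) > 0.10 * kd_calc:
            logger.info("%s: printed Kd %.3g M vs koff/kon %.3g M",
                        self.name, self.Kd, kd_calc)


@dataclass(frozen=True)
class DrugSetSummary:
    """Kinetic-regime statistics over a set of drug records.

    ``kon_driven``: fast kon with non-slow koff (occupancy maintained by
    re-binding); ``koff_driven``: slow koff with slow kon (occupancy
    maintained by residence time).  Fractions are raw; the ``pct_*``
    properties round to the nearest integer for display.
    """

    n_records: int
    frac_kon_ge_1e5: float
    frac_koff_slow: float
    frac_kd_sub_nM: float
    frac_kon_driven: float
    frac_koff_driven: float

    def _pct(self, frac: float) -> int:
        return round(100.0 * frac)

    @property
    def pct_kon_ge_1e5(self) -> int:
        return self._pct(self.frac_kon_ge_1e5)

    @property
    def pct_koff_slow(self) -> int:
        return self._pct(self.frac_koff_slow)

    @property
    def pct_kd_sub_nM(self) -> int:
        return self._pct(self.frac_kd_sub_nM)

    @property
    def pct_kon_driven(self) -> int:
        return self._pct(self.frac_kon_driven)

    @property
    def pct_koff_driven(self) -> int:
        return self._pct(self.frac_koff_driven)


def drugset_summary(records: list[DrugRecord]) -> DrugSetSummary:
    """Count kinetic regimes across drug records.

    Inequalities are applied exactly as conventionally printed for these
    statistics: ``kon >= 1e5``, ``koff < 3.9e-4`` (strict), ``Kd < 1 nM``
    (strict), kon-driven = ``koff > 3.9e-4 and kon > 1e5``, koff-driven =
    ``koff < 3.9e-4 and kon < 1e5``.
    """
    if not records:
        raise ValueError("record list must be nonempty")
    n = len(records)
    fast_kon = sum(1 for r in records if r.kon >= FAST_KON_CUTOFF)
    slow_koff = sum(1 for r in records if r.koff < SLOW_KOFF_CUTOFF)
    sub_nm = sum(1 for r in records if r.Kd < SUB_NM_KD_CUTOFF)
    kon_driven = sum(1 for r in records
                     if r.koff > SLOW_KOFF_CUTOFF and r.kon > FAST_KON_CUTOFF)
    koff_driven = sum(1 for r in records
                      if r.koff < SLOW_KOFF_CUTOFF and r.kon < FAST_KON_CUTOFF)
    return DrugSetSummary(
        n_records=n,
        frac_kon_ge_1e5=fast_kon / n,
        frac_koff_slow=slow_koff / n,
        frac_kd_sub_nM=sub_nm / n,
        frac_kon_driven=kon_driven / n,
        frac_koff_driven=koff_driven / n,
    )
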