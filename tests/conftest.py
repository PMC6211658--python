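import numpy as np
import pytest
from hypothesis import settings

import bindkin as bk

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tau_grid():
    return np.linspace(0.0, 12.0, 1201)


def make_problem(kon, koff, ki, k_minus_i, L0, scenario=bk.Scenario.EXP_SPECIES):
    """Assemble the dimensional objects for one occupancy problem."""
    kinetics = bk.BindingKinetics(kon=kon, koff=koff)
    turnover = bk.SiteTurnover(ki=ki, k_minus_i=k_minus_i, scenario=scenario)
    eff = bk.effective_koff(kinetics, k_minus_i)
    dose = bk.LigandDose(L0=L0)
    return kinetics, eff, dose, turnover


@pytest.fixture
def pcsk9_wt_acidic():
    """wt PCSK9 at endosomal pH, with the measured effective koff' taken
    as reported (its published hijack floor, ln 2 / 5 min, sits below the
    nominal site decay rate used for the turnover)."""
    kinetics = bk.BindingKinetics(kon=4.73e5, koff=1.97e-3)
    eff = bk.EffectiveKinetics(kon=kinetics.kon, koff_prime=1.97e-3,
                               hijacked=False)
    turnover = bk.SiteTurnover(ki=1e-2, k_minus_i=1e-2)
    return kinetics, eff, bk.LigandDose(L0=40.5e-9), turnover
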