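"""Packaged reference tables and their validation.

Four small CSV tables ship with the package:

* ``table1`` — the turnover grid: binding-site buildup/decay rates spanning
  eight decades, with the functional window, buildup half-life and the
  steady-state on-rate ``kon_ss`` each row implies at ``L0 = Kd = 1 nM``.
* ``table2`` — surface-plasmon-resonance kinetics of wild-type and D374Y
  PCSK9 binding the LDL receptor at neutral and endosomal pH, with the
  hijack-corrected ``koff'`` and ``Kd'``.
* ``table3`` — hypothetical non-trappable hERG blockers: the blocker
  concentrations (as multiples of Kd and Kd') at which action-potential
  simulations predict pro-arrhythmic channel occupancy.
* ``table4`` — published kon/koff/Kd for 32 marketed drugs.

Numeric columns in tables 2-4 are inputs taken at face value; table 1 is
fully recomputable and :func:`validate_turnover_grid` checks every derived
cell at its printed precision.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .units import to_seconds

__all__ = ["FixtureTable", "load_fixture", "validate_turnover_grid",
           "pcsk9_condition", "FIXTURE_FILES", "FIXTURE_SHA256"]

FIXTURE_FILES = {
    "table1": "table1_turnover_grid.csv",
    "table2": "table2_pcsk9_kinetics.csv",
    "table3": "table3_herg_blockers.csv",
    "table4": "table4_marketed_drugs.csv",
}

FIXTURE_SHA256 = {
    "table1": "3afd5cfa335d75d72ce07ec84ccf32bb864482cfc2483525392a5c7fb014a842",
    "table2": "78d2ae42bfc5d966554edec8255d8dad43aaf66d7227209e55369d6b152f0e2d",
    "table3": "8e510d6083c8674286f348f837f6037686f0c83b9b788b40226291881444736d",
    "table4": "582974c5f0f8546ddca6734a29f51140cb5be50936393d88902adf7984480bfd",
}

_EXPECTED_ROWS = {"table1": 12, "table2": 4, "table3": 6, "table4": 32}

_PROVENANCE = {
    "table1": "turnover grid with derived kon_ss, half-life and window",
    "table2": "PCSK9/LDL-R binding kinetics by variant and pH",
    "table3": "hERG blocker pro-arrhythmic concentration thresholds",
    "table4": "published kinetics of 32 marketed drugs",
}

# Columns that must keep their printed text form so validation can honour
# the printed number of decimals.
_STRING_COLUMNS = {"table1": ["lam_printed", "thalf_printed"]}


@dataclass(frozen=True)
class FixtureTable:
    table_id: str
    frame: pd.DataFrame
    provenance: str


def _read_raw(table_id: str) -> bytes:
    ref = resources.files("bindkin.data").joinpath(FIXTURE_FILES[table_id])
    return ref.read_bytes()


def load_fixture(table_id: str) -> FixtureTable:
    """Load a packaged table, verifying checksum and row count."""
    if table_id not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture table {table_id!r}; "
                       f"known: {sorted(FIXTURE_FILES)}")
    raw = _read_raw(table_id)
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256[table_id]:
        raise ValueError(f"{table_id}: checksum mismatch ({digest}); "
                         "packaged fixture data has been altered")
    from io import BytesIO
    dtypes = {c: str for c in _STRING_COLUMNS.get(table_id, [])}
    frame = pd.read_csv(BytesIO(raw), dtype=dtypes)
    if len(frame) != _EXPECTED_ROWS[table_id]:
        raise ValueError(f"{table_id}: expected {_EXPECTED_ROWS[table_id]} "
                         f"rows, got {len(frame)}")
    return FixtureTable(table_id=table_id, frame=frame,
                        provenance=_PROVENANCE[table_id])


def _printed_decimals(text: str) -> int:
    text = text.strip()
    return len(text.split(".", 1)[1]) if "." in text else 0


def validate_turnover_grid() -> pd.DataFrame:
    """Recompute every derived cell of the turnover grid.

    For each row, ``kon_ss = 10*ki/L0`` (with ``L0 = Kd``), the buildup
    half-life ``ln 2/ki`` and the functional window
    ``(3 - ln 2)/ki + ln 2/k_minus_i`` are recomputed and compared with the
    printed cells after rounding to the printed number of decimals.  The
    printed kon_ss column is quoted to the next power of ten (a
    conservative "sufficient on-rate"), so the recomputed value is rounded
    up to a decade before comparison; for the equal-rate rows the two
    coincide exactly.  Raises ``ValueError`` on any mismatch; returns the
    comparison frame.
    """
    ln2 = math.log(2.0)
    tbl = load_fixture("table1").frame
    rows = []
    problems = []
    for _, r in tbl.iterrows():
        ki = float(r.ki_per_s)
        kmi = float(r.k_minus_i_per_s)
        L0 = float(r.kd_nM) * 1e-9
        thalf_s = ln2 / ki
        lam_s = (3.0 - ln2) / ki + ln2 / kmi
        konss = 10.0 * ki / L0

        thalf_printed = float(r.thalf_printed)
        thalf_unit = to_seconds(1.0, r.thalf_unit)
        thalf_check = round(thalf_s / thalf_unit, _printed_decimals(r.thalf_printed))
        lam_printed = float(r.lam_printed)
        lam_unit = to_seconds(1.0, r.lam_unit)
        lam_check = round(lam_s / lam_unit, _printed_decimals(r.lam_printed))
        konss_printed = None if pd.isna(r.konss_M_per_s) else float(r.konss_M_per_s)
        rows.append({"ki_per_s": ki, "k_minus_i_per_s": kmi,
                     "thalf_recomputed": thalf_check, "thalf_printed": thalf_printed,
                     "lam_recomputed": lam_check, "lam_printed": lam_printed,
                     "konss_recomputed": konss, "konss_printed": konss_printed})
        if thalf_check != thalf_printed:
            problems.append(f"ki={ki}: t_half {thalf_check} != {thalf_printed}")
        if lam_check != lam_printed:
            problems.append(f"ki={ki}: lambda {lam_check} != {lam_printed}")
        if konss_printed is not None:
            konss_decade = 10.0 ** math.ceil(math.log10(konss) - 1e-9)
            if not math.isclose(konss_decade, konss_printed, rel_tol=1e-9):
                problems.append(f"ki={ki}: kon_ss {konss} (decade "
                                f"{konss_decade}) != {konss_printed}")
    if problems:
        raise ValueError("turnover grid validation failed: " + "; ".join(problems))
    return pd.DataFrame(rows)


def pcsk9_condition(variant: str, ph: float) -> pd.Series:
    """Row of the PCSK9 kinetics table for a variant/pH condition."""
    tbl = load_fixture("table2").frame
    sel = tbl[(tbl.variant.str.lower() == variant.lower())
              & (tbl.ph == float(ph))]
    if len(sel) != 1:
        raise KeyError(f"unknown PCSK9 condition variant={variant!r}, ph={ph!r}; "
                       "choose variant in {wt, D374Y} and ph in {7.4, 5.3}")
    return sel.iloc[0]
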