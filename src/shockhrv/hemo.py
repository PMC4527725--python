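"""Derived hemodynamic and oxygen-transport variables from monitor/blood-gas data.

The "conventional formulae" of clinical hemodynamics, pinned down explicitly:

* BSA = 0.09 · BW^(2/3) m² (porcine coefficient, BW in kg)
* CI = CO / BSA;  SVI = 1000 · CI / HR
* SVRI = 79.92 · (MAP − CVP) / CI;  PVRI = 79.92 · (mPAP − PAWP) / CI
  (79.92 dyn·s·cm⁻⁵ per mmHg·min/L)
* CaO₂ = 1.34 · Hb · SaO₂ + 0.0031 · PaO₂ (and venous analogue)
* DO₂I = 10 · CI · CaO₂;  VO₂I = 10 · CI · (CaO₂ − CvO₂);  O₂ER = VO₂I / DO₂I
  (reverse Fick: consumption from the arterio-venous content difference)
* CO₂ gap = PvCO₂ − PaCO₂ (mixed-venous minus arterial; positive in shock)
* PPV = 100 · (PPmax − PPmin) / ((PPmax + PPmin) / 2), averaged over
  respiratory cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HemodynamicRecord",
    "FlowIndices",
    "OxygenTransport",
    "DerivedHemodynamics",
    "body_surface_area",
    "derive_flow_indices",
    "derive_oxygen_transport",
    "derive_all",
    "pulse_pressure_variation",
]

#: dyn·s·cm⁻⁵ per mmHg·min/L
RESISTANCE_CONVERSION = 79.92
#: mL O₂ carried per g hemoglobin at full saturation
HB_O2_CAPACITY = 1.34
#: mL O₂ dissolved per dL blood per mmHg
O2_SOLUBILITY = 0.0031


def _normalize_saturation(value: float, name: str) -> float:
    """Accept saturation as fraction or percent; normalize to fraction."""
    if value > 1.5:
        warnings.warn(f"{name} given as percent ({value}); converting to fraction")
        value = value / 100.0
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} out of range after normalization: {value}")
    return value


@dataclass
class HemodynamicRecord:
    """Measured monitor and blood-gas values for one animal at one time point."""

    hr: float  # beats/min
    co: float  # L/min
    bw: float  # kg
    map: float | None = None  # mmHg
    cvp: float | None = None
    mpap: float | None = None
    pawp: float | None = None
    hb: float | None = None  # g/dL
    sao2: float | None = None  # fraction (or percent, auto-detected)
    svo2: float | None = None
    pao2: float | None = None  # mmHg
    pvo2: float | None = None
    paco2: float | None = None
    pvco2: float | None = None
    ph: float | None = None
    hco3: float | None = None  # mmol/L
    be: float | None = None
    lactate: float | None = None
    potassium: float | None = None
    hematocrit: float | None = None  # %

    def __post_init__(self) -> None:
        for name in ("hr", "co", "bw"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hb is not None and self.hb <= 0:
            raise ValueError("hb must be positive")
        if self.sao2 is not None:
            self.sao2 = _normalize_saturation(self.sao2, "sao2")
        if self.svo2 is not None:
            self.svo2 = _normalize_saturation(self.svo2, "svo2")


def body_surface_area(bw: float) -> float:
    """Porcine body surface area, 0.09 · BW^(2/3) m²."""
    if bw <= 0:
        raise ValueError("body weight must be positive")
    return 0.09 * bw ** (2.0 / 3.0)


@dataclass(frozen=True)
class FlowIndices:
    bsa: float  # m²
    ci: float  # L/min/m²
    svi: float  # mL/beat/m²
    svri: float | None  # dyn·s·cm⁻⁵·m²; None if inputs missing or CI zero
    pvri: float | None


def derive_flow_indices(rec: HemodynamicRecord) -> FlowIndices:
    bsa = body_surface_area(rec.bw)
    ci = rec.co / bsa
    svi = 1000.0 * ci / rec.hr
    svri = pvri = None
    if ci > 0:
        if rec.map is not None and rec.cvp is not None:
            svri = RESISTANCE_CONVERSION * (rec.map - rec.cvp) / ci
        if rec.mpap is not None and rec.pawp is not None:
            pvri = RESISTANCE_CONVERSION * (rec.mpap - rec.pawp) / ci
    return FlowIndices(bsa, ci, svi, svri, pvri)


@dataclass(frozen=True)
class OxygenTransport:
    cao2: float  # mL O₂/dL
    cvo2: float
    do2i: float  # mL/min/m²
    vo2i: float
    o2er: float | None  # fraction; None when DO₂I is zero (undefined)
    co2gap: float | None  # mmHg


def oxygen_content(hb: float, saturation: float, po2: float) -> float:
    """Blood O₂ content in mL/dL: bound plus dissolved."""
    return HB_O2_CAPACITY * hb * saturation + O2_SOLUBILITY * po2


def derive_oxygen_transport(rec: HemodynamicRecord, ci: float) -> OxygenTransport:
    for name in ("hb", "sao2", "svo2", "pao2", "pvo2"):
        if getattr(rec, name) is None:
            raise ValueError(f"oxygen transport needs {name}")
    cao2 = oxygen_content(rec.hb, rec.sao2, rec.pao2)
    cvo2 = oxygen_content(rec.hb, rec.svo2, rec.pvo2)
    do2i = 10.0 * ci * cao2
    vo2i = 10.0 * ci * (cao2 - cvo2)
    o2er = vo2i / do2i if do2i > 0 else None
    co2gap = None
    if rec.pvco2 is not None and rec.paco2 is not None:
        co2gap = rec.pvco2 - rec.paco2
    return OxygenTransport(cao2, cvo2, do2i, vo2i, o2er, co2gap)


@dataclass(frozen=True)
class DerivedHemodynamics:
    flow: FlowIndices
    oxygen: OxygenTransport | None


def derive_all(rec: HemodynamicRecord) -> DerivedHemodynamics:
    """All derived indices computable from the record's populated fields."""
    flow = derive_flow_indices(rec)
    oxygen = None
    if all(getattr(rec, k) is not None for k in ("hb", "sao2", "svo2", "pao2", "pvo2")):
        oxygen = derive_oxygen_transport(rec, flow.ci)
    return DerivedHemodynamics(flow, oxygen)


def pulse_pressure_variation(pp_per_beat, resp_cycle_marks) -> float:
    """Respiratory pulse-pressure variation (%) from per-beat pulse pressures.

    ``resp_cycle_marks`` are beat indices opening each respiratory cycle; the
    cycle spans beats ``[m_k, m_{k+1})``.  Cycles with fewer than 3 beats are
    skipped with a warning; the reported PPV is the mean over usable cycles.
    """
    pp = np.asarray(pp_per_beat, dtype=float)
    marks = np.asarray(resp_cycle_marks, dtype=int)
    if len(marks) < 2:
        raise ValueError("need at least 2 cycle marks (one complete cycle)")
    values = []
    for a, b in zip(marks[:-1], marks[1:]):
        cycle = pp[a:b]
        if len(cycle) < 3:
            warnings.warn(f"respiratory cycle [{a}, {b}) has fewer than 3 beats; skipped")
            continue
        pmax, pmin = float(np.max(cycle)), float(np.min(cycle))
        denom = (pmax + pmin) / 2.0
        values.append(0.0 if denom == 0 else 100.0 * (pmax - pmin) / denom)
    if not values:
        raise ValueError("no complete respiratory cycle with >= 3 beats")
    return float(np.mean(values))
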