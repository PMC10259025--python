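"""Pressure-volume-loop forward model.

Given end-diastolic volume (EDV), end-systolic volume (ESV), the zero-pressure
volume V0 and end-systolic pressure Pes, this module computes the loop-derived
indices under a linear end-systolic pressure-volume relation through (V0, 0):

    Ees = Pes/(ESV - V0)          end-systolic elastance (contractility)
    Ea  = Pes/SV                  effective arterial elastance (afterload)
    EW  = Pes * SV                external work (rectangular loop area)
    PVA = EW + 0.5*Pes*(ESV - V0) pressure-volume area (EW + potential-energy
                                  triangle); proxy for myocardial O2 use
    Eff = EW/PVA                  ventricular mechanical efficiency
    EF  = SV/EDV                  ejection fraction

with SV = EDV - ESV.  Work and area stay in mmHg*mL; only the dimensionless
ratios are consumed downstream.

The module serves as the independent oracle for the coupling shortcut
EF = Eff/(2 - Eff): that identity is exact when V0 = 0 and
:func:`ef_shortcut_gap` quantifies its (positive) error when V0 > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coupling import ef_from_efficiency
from .errors import DegenerateLoopError, InvalidInputError

__all__ = ["PVLoopState", "PVQuantities", "pv_quantities", "ef_shortcut_gap"]


@dataclass(frozen=True)
class PVLoopState:
    """Volumes (mL) and end-systolic pressure (mmHg) defining one PV loop."""

    edv: float
    esv: float
    v0: float
    pes: float

    def __post_init__(self):
        if not self.v0 >= 0:
            raise InvalidInputError("v0", f"must be >= 0, got {self.v0}")
        if self.esv < self.v0:
            raise InvalidInputError("esv", f"must be >= v0 ({self.v0}), got {self.esv}")
        if not self.edv > self.esv:
            raise InvalidInputError("edv", f"must exceed esv ({self.esv}), got {self.edv}")
        if not self.pes > 0:
            raise InvalidInputError("pes", f"must be > 0, got {self.pes}")

    @property
    def sv(self) -> float:
        """Stroke volume EDV - ESV (mL)."""
        return self.edv - self.esv


@dataclass(frozen=True)
class PVQuantities:
    """Indices derived from one PV loop (elastances mmHg/mL, work mmHg*mL)."""

    ees: float
    ea: float
    ew: float
    pva: float
    eff: float
    ef: float


def pv_quantities(loop: PVLoopState) -> PVQuantities:
    """Compute elastances, work, pressure-volume area, efficiency and EF.

    Raises :class:`DegenerateLoopError` when ESV = V0 (the ESPVR slope is
    infinite and Ees undefined).
    """
    dead_volume = loop.esv - loop.v0
    if dead_volume == 0:
        raise DegenerateLoopError(
            f"esv equals v0 ({loop.v0} mL): end-systolic elastance is infinite"
        )
    sv = loop.sv
    ew = loop.pes * sv
    pva = ew + 0.5 * loop.pes * dead_volume
    return PVQuantities(
        ees=loop.pes / dead_volume,
        ea=loop.pes / sv,
        ew=ew,
        pva=pva,
        eff=ew / pva,
        ef=sv / loop.edv,
    )


def ef_shortcut_gap(loop: PVLoopState) -> float:
    """Error of the efficiency shortcut: ef_from_efficiency(Eff) - SV/EDV.

    Exactly zero when V0 = 0 (algebraic identity: with r = SV/(ESV - V0),
    Eff = 2r/(2r + 1) and Eff/(2 - Eff) = r/(r + 1) = SV/EDV).  Positive when
    V0 > 0: the shortcut then overestimates the volumetric ejection fraction.
    """
    q = pv_quantities(loop)
    return ef_from_efficiency(q.eff) - q.ef
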