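"""Closed-form wall shear stress (WSS) calculations for arterial blood flow.

Three methods are implemented, all grounded on τ = η·σ (stress = viscosity ×
shear rate at the wall), differing in the viscosity used and in how the wall
shear rate σ is obtained from the Doppler-measured maximal velocity:

``tN`` — theoretical Newtonian
    Blood as a homogeneous Newtonian fluid with a parabolic velocity
    profile (Vmax/Vm = 2), so σ = 4·Vmax/D and τt = ηb·4·Vmax/D with ηb
    the measured whole-blood viscosity.

``cN`` — corrected Newtonian
    Same Newtonian form but with the empirical small-artery
    centreline-to-mean velocity ratio Vmax/Vm ≈ 1.45, giving
    τc = η·(8/1.45)·Vmax/D ≈ η·5.5·Vmax/D. The viscosity may be the
    plasma viscosity ηp, the whole-blood viscosity ηb, or an apparent
    viscosity ηapp = 1.78·ηp.

``F`` — Fåhræus-type plug/sheath method
    Blood as a central red-cell plug moving at Vmax surrounded by a
    cell-free plasma sheath across which the velocity drops to zero at
    the wall. The wall stress is borne by plasma alone:
    τF = ηp·(4·Vmax/D)·f(Ht), with the hematocrit-dependent plug factor

        f(Ht) = (1 − Ht) / (1 − Ht·(1 − ln Ht)),

    which → 1 as Ht → 0 (plasma-only limit) and grows with hematocrit.
    The shear rate is directed against the flow; magnitudes are reported.

Units at the call boundary are the clinical ones (mm, mm/s, cP); all
arithmetic is done in SI (m, m/s, Pa·s) and WSS is returned in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from . import defaults
from .errors import DomainError

__all__ = [
    "HemodynamicRecord",
    "ViscosityModel",
    "WSSResult",
    "to_si",
    "wss_theoretical_newtonian",
    "apparent_viscosity",
    "wss_corrected_newtonian",
    "fahraeus_plug_factor",
    "fahraeus_shear_rate",
    "wss_fahraeus",
    "blood_viscosity_from_hematocrit",
    "wss_tn_from_hematocrit",
]


def _require_positive(value: float, name: str) -> None:
    if not (value > 0):
        raise DomainError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class HemodynamicRecord:
    """One animal × cardiac-phase measurement set.

    Parameters
    ----------
    animal_id : str
        Identifier carried through to results.
    sex : {"male", "female"}
    phase : {"diastole", "systole"}
    diameter_mm : float
        Vessel inner diameter D [mm].
    vmax_mm_s : float
        Maximal (centreline) blood velocity Vmax [mm/s].
    hematocrit : float
        Red-cell volume fraction Ht, in (0, 1).
    heart_rate_bpm : float, optional
        Pass-through metadata, not used in any calculation.
    """

    animal_id: str
    sex: str
    phase: str
    diameter_mm: float
    vmax_mm_s: float
    hematocrit: float
    heart_rate_bpm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.phase not in ("diastole", "systole"):
            raise DomainError(
                f"phase must be 'diastole' or 'systole', got {self.phase!r}"
            )
        _require_positive(self.diameter_mm, "diameter_mm")
        _require_positive(self.vmax_mm_s, "vmax_mm_s")
        if not (0.0 < self.hematocrit < 1.0):
            raise DomainError(
                f"hematocrit must be in (0, 1), got {self.hematocrit!r}"
            )

    @property
    def radius_mm(self) -> float:
        """Vessel inner radius R = D/2 [mm]."""
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class ViscosityModel:
    """Viscosity parameters of one animal group.

    ``eta_b_cp``/``eta_p_cp`` are the measured whole-blood and (pooled)
    plasma viscosities in cP. The remaining fields are the empirical
    constants of the corrected Newtonian method and the hematocrit →
    whole-blood-viscosity linear regression (Pa·s per hematocrit
    fraction).
    """

    eta_b_cp: float
    eta_p_cp: float
    correction_factor: float = defaults.APPARENT_VISCOSITY_FACTOR
    vmax_vm_ratio: float = defaults.VMAX_VM_RATIO
    regression_slope_pa_s: float = defaults.REGRESSION_SLOPE_PA_S
    regression_intercept_pa_s: float = defaults.REGRESSION_INTERCEPT_PA_S

    def __post_init__(self) -> None:
        _require_positive(self.eta_p_cp, "eta_p_cp")
        if self.eta_b_cp < self.eta_p_cp:
            raise DomainError(
                "whole-blood viscosity cannot be below plasma viscosity "
                f"(eta_b={self.eta_b_cp} cP < eta_p={self.eta_p_cp} cP)"
            )
        _require_positive(self.correction_factor, "correction_factor")
        if self.vmax_vm_ratio < 1.0:
            raise DomainError(
                f"vmax_vm_ratio must be >= 1, got {self.vmax_vm_ratio!r}"
            )

    @property
    def eta_app_cp(self) -> float:
        """Apparent viscosity ηapp = correction_factor × ηp [cP]."""
        return apparent_viscosity(self.eta_p_cp, self.correction_factor)


@dataclass(frozen=True)
class WSSResult:
    """Wall shear stress computed by one method for one record.

    ``wss_pa`` always equals ``viscosity_used_cp`` (converted to Pa·s)
    times ``shear_rate_per_s``; both WSS and shear rate are reported as
    positive magnitudes.
    """

    method: str                 # "tN" | "cN" | "F"
    viscosity_used_cp: float
    shear_rate_per_s: float
    wss_pa: float
    record_ref: str
    viscosity_variant: str = ""  # for cN: "plasma" | "blood" | "apparent"


def to_si(record: HemodynamicRecord, viscosity_cp: float) -> tuple[float, float, float]:
    """Convert (D [mm], Vmax [mm/s], η [cP]) to SI (m, m/s, Pa·s)."""
    _require_positive(viscosity_cp, "viscosity_cp")
    return (
        record.diameter_mm * defaults.MM_TO_M,
        record.vmax_mm_s * defaults.MM_TO_M,
        viscosity_cp * defaults.CP_TO_PA_S,
    )


def _make_result(
    record: HemodynamicRecord,
    method: str,
    viscosity_cp: float,
    shear_rate: float,
    variant: str = "",
) -> WSSResult:
    # WSS is constructed as η·σ so the consistency invariant holds exactly
    eta_pa_s = viscosity_cp * defaults.CP_TO_PA_S
    return WSSResult(
        method=method,
        viscosity_used_cp=viscosity_cp,
        shear_rate_per_s=shear_rate,
        wss_pa=eta_pa_s * shear_rate,
        record_ref=record.animal_id,
        viscosity_variant=variant,
    )


def newtonian_shear_rate(record: HemodynamicRecord) -> float:
    """Parabolic-profile wall shear rate σ = 4·Vmax/D [1/s]."""
    d_m, vmax_m_s, _ = to_si(record, 1.0)
    return 4.0 * vmax_m_s / d_m


def wss_theoretical_newtonian(record: HemodynamicRecord, eta_b_cp: float) -> WSSResult:
    """Theoretical Newtonian WSS τt = ηb·4·Vmax/D [Pa] (tN method)."""
    _require_positive(eta_b_cp, "eta_b_cp")
    return _make_result(record, "tN", eta_b_cp, newtonian_shear_rate(record))


def apparent_viscosity(
    eta_p_cp: float, correction_factor: float = defaults.APPARENT_VISCOSITY_FACTOR
) -> float:
    """Apparent viscosity ηapp = factor × ηp [cP], rounded to two decimals
    for tabulation (1.78 × 1.26 = 2.24; 1.78 × 1.27 = 2.26)."""
    _require_positive(eta_p_cp, "eta_p_cp")
    _require_positive(correction_factor, "correction_factor")
    return round(correction_factor * eta_p_cp, 2)


def wss_corrected_newtonian(
    record: HemodynamicRecord,
    eta_cp: float,
    vmax_vm_ratio: float = defaults.VMAX_VM_RATIO,
    *,
    exact_coefficient: bool = False,
    viscosity_variant: str = "",
) -> WSSResult:
    """Corrected Newtonian WSS τc = η·(8/ratio)·Vmax/D [Pa] (cN method).

    With the default ratio 1.45 the coefficient is the published rounded
    5.5; ``exact_coefficient=True`` uses 8/ratio un-rounded (5.5172 at
    1.45). ``eta_cp`` may be ηp, ηb or ηapp at the caller's choice.
    """
    _require_positive(eta_cp, "eta_cp")
    if not (1.0 <= vmax_vm_ratio <= 2.0):
        raise DomainError(
            f"vmax_vm_ratio must be in [1, 2], got {vmax_vm_ratio!r}"
        )
    if exact_coefficient or vmax_vm_ratio != defaults.VMAX_VM_RATIO:
        coefficient = 8.0 / vmax_vm_ratio
    else:
        coefficient = defaults.CORRECTED_N_COEFFICIENT
    d_m, vmax_m_s, _ = to_si(record, eta_cp)
    shear_rate = coefficient * vmax_m_s / d_m
    return _make_result(record, "cN", eta_cp, shear_rate, viscosity_variant)


def fahraeus_plug_factor(hematocrit: float) -> float:
    """Hematocrit-dependent plug/sheath factor f(Ht) of the F method.

    f(Ht) = (1 − Ht) / (1 − Ht·(1 − ln Ht)), taken positive. It is > 1
    on (0, 1), strictly increasing, tends to 1 as Ht → 0 (pure plasma)
    and diverges as Ht → 1 (vanishing sheath).
    """
    if not (0.0 < hematocrit < 1.0):
        raise DomainError(f"hematocrit must be in (0, 1), got {hematocrit!r}")
    return (1.0 - hematocrit) / (1.0 - hematocrit * (1.0 - math.log(hematocrit)))


def fahraeus_shear_rate(record: HemodynamicRecord) -> float:
    """Plug/sheath wall shear rate magnitude |σF| = (4·Vmax/D)·f(Ht) [1/s].

    The shear-rate vector points against the flow; the positive magnitude
    is returned, per the absolute-value reporting convention.
    """
    return newtonian_shear_rate(record) * fahraeus_plug_factor(record.hematocrit)


def wss_fahraeus(record: HemodynamicRecord, eta_p_cp: float) -> WSSResult:
    """F-method WSS τF = ηp·(4·Vmax/D)·f(Ht) [Pa].

    ``eta_p_cp`` is the plasma viscosity of the animal's group (plasma is
    pooled per group before measurement, so it is one scalar per group).
    """
    _require_positive(eta_p_cp, "eta_p_cp")
    return _make_result(record, "F", eta_p_cp, fahraeus_shear_rate(record))


def blood_viscosity_from_hematocrit(
    hematocrit: float, model: Optional[ViscosityModel] = None
) -> float:
    """Whole-blood viscosity ηb [cP] from the linear Ht regression.

    ηb [Pa·s] = slope·Ht + intercept with Ht a fraction; converted to cP
    on return (0.43 → 3.97 cP). Raises for hematocrits at or below the
    root of the line (≈ 0.115), where the fit predicts non-positive
    viscosity.
    """
    if not (0.0 < hematocrit < 1.0):
        raise DomainError(f"hematocrit must be in (0, 1), got {hematocrit!r}")
    slope = model.regression_slope_pa_s if model else defaults.REGRESSION_SLOPE_PA_S
    intercept = (
        model.regression_intercept_pa_s if model else defaults.REGRESSION_INTERCEPT_PA_S
    )
    eta_pa_s = slope * hematocrit + intercept
    if eta_pa_s <= 0.0:
        raise DomainError(
            f"regression predicts non-positive viscosity at Ht={hematocrit}"
        )
    return eta_pa_s / defaults.CP_TO_PA_S


def wss_tn_from_hematocrit(
    record: HemodynamicRecord, model: Optional[ViscosityModel] = None
) -> WSSResult:
    """tN-method WSS with the regression-implied viscosity:
    τt = (slope·Ht + intercept)·4·Vmax/D [Pa]."""
    eta_b_cp = blood_viscosity_from_hematocrit(record.hematocrit, model)
    return wss_theoretical_newtonian(record, eta_b_cp)
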