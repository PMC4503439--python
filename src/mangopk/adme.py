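"""Derived ADME quantities.

Tissue-to-plasma partitioning, equilibrium-dialysis protein binding,
unbound renal clearance, the fraction-unabsorbed correction, S9
metabolic stability and excretion recoveries. Each operator is a pure
function on one record; group summaries are assembled by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

__all__ = [
    "TISSUES",
    "TissueSample",
    "DialysisPair",
    "S9Result",
    "AdmeRecord",
    "TPRatio",
    "UnboundRenalClearance",
    "tissue_to_plasma",
    "protein_binding",
    "unbound_renal_clearance",
    "fraction_unabsorbed",
    "s9_disappearance",
    "excretion_percent",
    "MOUSE_GFR_ML_MIN_KG",
]

TISSUES = (
    "liver",
    "spleen",
    "stomach",
    "small_intestine",
    "large_intestine",
    "mesentery",
    "kidney",
    "fat",
    "muscle",
    "heart",
    "lung",
    "brain",
)

#: mouse glomerular filtration rate reference (creatinine clearance)
MOUSE_GFR_ML_MIN_KG = 14.0


@dataclass(frozen=True)
class TissueSample:
    """A tissue homogenate concentration with its paired plasma value.

    ``conc`` is the measured homogenate concentration; the homogenate is
    prepared by diluting the tissue with water (default 1 part tissue +
    4 parts water, i.e. dilution_factor 5), which tissue_to_plasma
    corrects for.
    """

    tissue: str
    time: float  # min after dose
    conc: float  # ug/mL homogenate
    paired_plasma_conc: float  # ug/mL
    dilution_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.conc < 0 or self.paired_plasma_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class DialysisPair:
    """Plasma-side / buffer-side concentrations at dialysis equilibrium."""

    plasma_side_conc: float  # ug/mL
    buffer_side_conc: float  # ug/mL
    spiked_conc: float  # ug/mL initially spiked into plasma

    def __post_init__(self) -> None:
        if self.buffer_side_conc < 0:
            raise ValueError("buffer-side concentration must be non-negative")
        if self.buffer_side_conc > self.plasma_side_conc:
            warnings.warn(
                "buffer-side exceeds plasma-side concentration; pair kept but "
                "binding will be negative",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class S9Result:
    """Remaining drug after a 30-min S9 incubation of a spiked sample."""

    tissue: str
    spiked_conc: float  # ug/mL
    remaining_conc: float  # ug/mL

    def __post_init__(self) -> None:
        if self.remaining_conc < 0:
            raise ValueError("remaining concentration must be non-negative")


@dataclass
class AdmeRecord:
    """Bundle of derived ADME metrics for reporting."""

    tp_ratio: Optional[float] = None
    bound_pct: Optional[float] = None
    fu: Optional[float] = None
    cl_r_fu: Optional[float] = None  # mL/min/kg
    f_unabs: Optional[float] = None
    disappearance_pct: Optional[float] = None


class TPRatio(NamedTuple):
    ratio: float
    high_affinity: bool  # ratio > 1


class UnboundRenalClearance(NamedTuple):
    value: float  # mL/min/kg
    below_gfr: bool  # filtration-only excretion plausible


def tissue_to_plasma(sample: TissueSample) -> TPRatio:
    """Tissue-to-plasma ratio, corrected for homogenate dilution.

    T/P = (homogenate conc x dilution factor) / plasma conc; a ratio
    above unity is tagged high-affinity.
    """
    if sample.paired_plasma_conc <= 0:
        raise ValueError("paired plasma concentration must be positive")
    ratio = sample.conc * sample.dilution_factor / sample.paired_plasma_conc
    return TPRatio(ratio=ratio, high_affinity=ratio > 1.0)


def protein_binding(pair: DialysisPair) -> tuple[float, float]:
    """(bound %, unbound fraction fu) from one dialysis pair.

    bound% = 100 (plasma - buffer)/plasma; fu = buffer/plasma, so
    fu = 1 - bound%/100 by construction.
    """
    if pair.plasma_side_conc <= 0:
        raise ValueError("plasma-side concentration must be positive")
    fu = pair.buffer_side_conc / pair.plasma_side_conc
    bound_pct = 100.0 * (1.0 - fu)
    return bound_pct, fu


def unbound_renal_clearance(
    cl_r: float, fu: float, gfr_reference: float = MOUSE_GFR_ML_MIN_KG
) -> UnboundRenalClearance:
    """Renal clearance of unbound drug, CL_R/fu, flagged against GFR.

    A value below the species GFR is consistent with excretion by
    glomerular filtration alone (no net secretion).
    """
    if not 0.0 < fu <= 1.0:
        raise ValueError("fu must be in (0, 1]")
    if cl_r < 0:
        raise ValueError("cl_r must be non-negative")
    value = cl_r / fu
    return UnboundRenalClearance(value=value, below_gfr=value < gfr_reference)


def fraction_unabsorbed(
    gi24_oral_frac: float,
    gi24_iv_frac: float,
    f_frac: float,
    method: str = "subtractive",
) -> float:
    """Fraction of the oral dose never absorbed, from 24-h GI recoveries.

    The oral GI recovery overstates non-absorption because absorbed drug
    can re-enter the gut (biliary/intestinal secretion); the IV GI
    recovery scaled by bioavailability estimates that post-absorptive
    share. Two correction variants:

    - "subtractive" (default): F_unabs = GI_oral - F x GI_iv
    - "normalized": the same numerator divided by (1 - F)

    All inputs are fractions of dose in [0, 1]. A result outside [0, 1]
    is flagged with a warning, not rejected.
    """
    for name, v in (
        ("gi24_oral_frac", gi24_oral_frac),
        ("gi24_iv_frac", gi24_iv_frac),
        ("f_frac", f_frac),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    f_unabs = gi24_oral_frac - f_frac * gi24_iv_frac
    if method == "normalized":
        f_unabs = f_unabs / (1.0 - f_frac) if f_frac < 1.0 else float("nan")
    elif method != "subtractive":
        raise ValueError(f"unknown method {method!r}")
    if not 0.0 <= f_unabs <= 1.0:
        warnings.warn(
            f"fraction unabsorbed {f_unabs:.4g} outside [0, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
    return f_unabs


def s9_disappearance(result: S9Result) -> float:
    """Percent of the spiked drug lost during the incubation.

    100 (1 - remaining/spiked); assay noise can push remaining above
    spiked, in which case the negative disappearance is clipped to 0
    with a warning.
    """
    if result.spiked_conc <= 0:
        raise ValueError("spiked concentration must be positive")
    pct = 100.0 * (1.0 - result.remaining_conc / result.spiked_conc)
    if pct < 0:
        warnings.warn(
            f"negative disappearance ({pct:.3g}%) clipped to 0 for {result.tissue}",
            RuntimeWarning,
            stacklevel=2,
        )
        pct = 0.0
    return pct


def excretion_percent(amount_excreted_ug: float, dose_amount_ug: float) -> float:
    """Amount excreted as a percentage of the administered amount."""
    if dose_amount_ug <= 0:
        raise ValueError("dose amount must be positive")
    if amount_excreted_ug < 0:
        raise ValueError("excreted amount must be non-negative")
    return 100.0 * amount_excreted_ug / dose_amount_ug
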