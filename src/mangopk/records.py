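"""Core data containers shared by the simulation, NCA and I/O stages.

Units follow the study conventions throughout: time in minutes,
concentration in ug/mL, dose in mg/kg, clearance in mL/min/kg,
volume in mL/kg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ProfileError

ROUTES = ("iv_bolus", "oral")

#: micrograms per milligram — converts mg/kg doses to ug/kg for
#: clearance in mL/min/kg against AUC in ug*min/mL.
UG_PER_MG = 1000.0


@dataclass(frozen=True)
class DoseEvent:
    """A single administration of drug to one subject."""

    subject_id: str
    route: str
    dose: float  # mg/kg
    body_weight_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose}")


@dataclass
class ConcProfile:
    """One subject's concentration-time series in a single matrix.

    Concentrations below the lower limit of quantitation (LLOQ) are
    censored: the ``censored`` flag is True and the stored value is NaN.
    Censored points are kept, never silently dropped.
    """

    subject_id: str
    times: np.ndarray  # min
    concs: np.ndarray  # ug/mL; NaN where censored
    censored: np.ndarray = None  # type: ignore[assignment]
    lloq: float = 1e-3  # ug/mL (1 ng/mL)
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.times.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (len(self.times) == len(self.concs) == len(self.censored)):
            raise ProfileError("times, concs and censored must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ProfileError("times must be strictly increasing")
        if len(self.times) and self.times[0] < 0:
            raise ProfileError("times must be non-negative")
        quant = ~self.censored
        if np.any(self.concs[quant] < 0):
            raise ProfileError("quantified concentrations must be non-negative")

    @property
    def quantifiable_mask(self) -> np.ndarray:
        return ~self.censored & np.isfinite(self.concs)

    @property
    def n_quantifiable(self) -> int:
        return int(self.quantifiable_mask.sum())

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations of the quantifiable points only."""
        m = self.quantifiable_mask
        return self.times[m], self.concs[m]


@dataclass
class ExcretionRecord:
    """24-h urinary and gastrointestinal recovery for one subject."""

    subject_id: str
    ae_0_24_pct: float  # % of dose excreted unchanged in urine, 0-24 h
    gi_24_pct: float  # % of dose in GI tract + feces at 24 h
    urine_amount_ug: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ae_0_24_pct < 0 or self.gi_24_pct < 0:
            raise ValueError("excretion percentages must be non-negative")


@dataclass
class NCAResult:
    """Full non-compartmental parameter set for one subject.

    Fields that depend on the terminal-slope fit are None when the
    terminal phase is not estimable; ``auc_last`` is always reported.
    """

    subject_id: str
    route: str
    dose: float  # mg/kg
    cmax: float  # ug/mL
    tmax: float  # min
    auc_last: float  # ug*min/mL
    auc_inf: Optional[float] = None
    auc_extrap_pct: Optional[float] = None
    aumc_inf: Optional[float] = None
    lambda_z: Optional[float] = None  # 1/min
    lambda_z_npoints: Optional[int] = None
    lambda_z_r2adj: Optional[float] = None
    t_half: Optional[float] = None  # min
    mrt: Optional[float] = None  # min (IV bolus)
    cl: Optional[float] = None  # mL/min/kg (IV)
    vss: Optional[float] = None  # mL/kg (IV)
    cl_r: Optional[float] = None  # mL/min/kg
    cl_nr: Optional[float] = None  # mL/min/kg
    f_pct: Optional[float] = None  # % (oral, when paired with IV)
    dose_normalized_auc: Optional[float] = None  # per mg/kg
    dose_normalized_cmax: Optional[float] = None  # per mg/kg

    _UNITS = {
        "cmax": "ug/mL",
        "tmax": "min",
        "auc_last": "ug*min/mL",
        "auc_inf": "ug*min/mL",
        "auc_extrap_pct": "%",
        "aumc_inf": "ug*min^2/mL",
        "lambda_z": "1/min",
        "lambda_z_npoints": "count",
        "lambda_z_r2adj": "",
        "t_half": "min",
        "mrt": "min",
        "cl": "mL/min/kg",
        "vss": "mL/kg",
        "cl_r": "mL/min/kg",
        "cl_nr": "mL/min/kg",
        "f_pct": "%",
        "dose_normalized_auc": "ug*min/mL per mg/kg",
        "dose_normalized_cmax": "ug/mL per mg/kg",
    }

    def to_tidy_rows(self) -> list[dict]:
        """Long-format rows: one per non-None parameter."""
        rows = []
        for name, units in self._UNITS.items():
            value = getattr(self, name)
            if value is None:
                continue
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "route": self.route,
                    "dose_mg_kg": self.dose,
                    "parameter": name,
                    "value": float(value),
                    "units": units,
                }
            )
        return rows
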