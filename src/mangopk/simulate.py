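"""Synthetic data generators for every input kind the pipeline consumes.

Plasma kinetics follow a linear two-compartment disposition model
parameterized by micro-constants (CL, V1, Q, V2), so every downstream
non-compartmental quantity has an analytic truth value:

    IV bolus:  C(t) = A e^(-alpha t) + B e^(-beta t)
    Oral:      first-order absorption (ka) into the same disposition
               model, dose scaled by the true bioavailability F.

Between-subject variability is log-normal and independent per
parameter; residual error is proportional; concentrations below the
LLOQ are censored (flagged, never dropped). All randomness flows from
the spec seed, so identical specs reproduce identical data.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .adme import DialysisPair, S9Result
from .biotransform import (
    BiotransformRule,
    ParentSpec,
    PeakRecord,
    build_rule_table,
    diagnostic_templates,
)
from .records import UG_PER_MG, ConcProfile, DoseEvent, ExcretionRecord

__all__ = [
    "IV_SCHEDULE",
    "ORAL_SCHEDULE",
    "PKPopulationSpec",
    "PeakListSpec",
    "simulate_iv_profiles",
    "simulate_oral_profiles",
    "simulate_excretion",
    "simulate_dialysis",
    "simulate_s9",
    "simulate_peaklist",
    "simulate_study",
    "iv_bolus_conc",
    "oral_conc",
    "disposition_exponents",
]

#: study sampling schedules (min)
IV_SCHEDULE = (0.0, 1.0, 5.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0, 360.0)
ORAL_SCHEDULE = (0.0, 5.0, 15.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0, 360.0)

#: relative perturbation applied to ka when it coincides with a
#: disposition exponent (degenerate closed form)
KA_DEGENERACY_EPS = 1e-6


class PKPopulationSpec(BaseModel):
    """Population PK spec with study-calibrated defaults.

    Defaults reproduce the study's IV summary: CL 31.4 mL/min/kg and
    Vss = V1 + V2 = 4304 mL/kg, split with Q chosen so the terminal
    half-life is ~227 min. Oral defaults: ka 0.03/min, F 0.0229.
    LLOQ is 1 ng/mL = 1e-3 ug/mL.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    cl: float = 31.4  # mL/min/kg
    v1: float = 1100.0  # mL/kg
    q: float = 15.0  # mL/min/kg (0 collapses to one compartment)
    v2: float = 3204.0  # mL/kg
    ka: float = 0.03  # 1/min (oral only)
    f_true: float = Field(0.0229, ge=0.0, le=1.0)
    fe_true: float = Field(0.00839, ge=0.0, le=1.0)
    gi_true: float = Field(0.0344, ge=0.0, le=1.0)
    omega: float = Field(0.25, ge=0.0)  # between-subject log-normal SD
    sigma_prop: float = Field(0.10, ge=0.0)  # proportional residual SD
    lloq: float = 1e-3  # ug/mL
    schedule: tuple[float, ...] = IV_SCHEDULE
    n_subjects: int = Field(9, ge=1)
    seed: int = 0

    @field_validator("cl", "v1", "v2", "ka", "lloq")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("must be positive")
        return v

    @field_validator("q")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be non-negative")
        return v

    @model_validator(mode="after")
    def _check_schedule(self) -> "PKPopulationSpec":
        sched = self.schedule
        if len(sched) == 0:
            raise ValueError("schedule must not be empty")
        if sched[0] != 0:
            raise ValueError("schedule must start at 0")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must be strictly increasing")
        return self


class PeakListSpec(BaseModel):
    """Spec for a synthetic centroided peak list around a parent ion."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    parent_mz: float = 411.21  # [M+H]+ Da
    parent_rt: float = 27.6  # min
    reactions: tuple[str, ...] = ()
    mz_noise_sd: float = Field(0.0, ge=0.0)  # Da
    #: RT offsets vs parent: uniform windows per polarity class (min)
    rt_offset_earlier: tuple[float, float] = (-12.0, -1.0)
    rt_offset_later: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    @field_validator("parent_mz")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("parent_mz must be positive")
        return v


def disposition_exponents(
    cl: float, v1: float, q: float, v2: float
) -> tuple[float, float, float, float]:
    """Micro-constants -> (k10, k21, alpha, beta) for the 2-cpt model."""
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return k10, k21, alpha, beta


def iv_bolus_conc(
    t: np.ndarray, dose: float, cl: float, v1: float, q: float, v2: float
) -> np.ndarray:
    """Noise-free bi-exponential plasma concentration after an IV bolus.

    dose in mg/kg; result in ug/mL. With q = 0 the model collapses to
    C(t) = (dose/V1) e^(-CL/V1 t).
    """
    if not dose > 0:
        raise ValueError("dose must be positive")
    t = np.asarray(t, dtype=float)
    c0 = dose * UG_PER_MG / v1
    _, k21, alpha, beta = disposition_exponents(cl, v1, q, v2)
    if alpha - beta < 1e-12 * alpha:
        return c0 * np.exp(-alpha * t)
    a_coef = c0 * (alpha - k21) / (alpha - beta)
    b_coef = c0 * (k21 - beta) / (alpha - beta)
    return a_coef * np.exp(-alpha * t) + b_coef * np.exp(-beta * t)


def oral_conc(
    t: np.ndarray,
    dose: float,
    f: float,
    ka: float,
    cl: float,
    v1: float,
    q: float,
    v2: float,
) -> np.ndarray:
    """First-order absorption into the two-compartment disposition model.

    Flip-flop kinetics (ka < beta) are permitted. If ka coincides with a
    disposition exponent the closed form is degenerate; ka is then
    perturbed by a relative KA_DEGENERACY_EPS and a warning is issued.
    """
    if not dose > 0:
        raise ValueError("dose must be positive")
    if not ka > 0:
        raise ValueError("ka must be positive")
    t = np.asarray(t, dtype=float)
    _, k21, alpha, beta = disposition_exponents(cl, v1, q, v2)
    scale = max(alpha, ka)
    while min(abs(ka - alpha), abs(ka - beta)) < 1e-9 * scale:
        warnings.warn(
            "ka coincides with a disposition exponent; perturbing ka by "
            f"{KA_DEGENERACY_EPS:g} (relative) to avoid the degenerate closed form",
            RuntimeWarning,
            stacklevel=2,
        )
        ka = ka * (1.0 + KA_DEGENERACY_EPS)
    pref = ka * f * dose * UG_PER_MG / v1
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    return pref * (
        ca * np.exp(-alpha * t) + cb * np.exp(-beta * t) + ck * np.exp(-ka * t)
    )


def _individual_params(
    spec: PKPopulationSpec, rng: np.random.Generator
) -> dict[str, float]:
    # independent log-normal deviates on CL, V1, Q, V2, ka
    draw = lambda base: base * math.exp(spec.omega * rng.standard_normal())  # noqa: E731
    return {
        "cl": draw(spec.cl),
        "v1": draw(spec.v1),
        "q": draw(spec.q) if spec.q > 0 else 0.0,
        "v2": draw(spec.v2),
        "ka": draw(spec.ka),
    }


def _observe(
    clean: np.ndarray, spec: PKPopulationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    obs = clean * (1.0 + spec.sigma_prop * rng.standard_normal(clean.shape))
    obs = np.clip(obs, 0.0, None)
    censored = obs < spec.lloq
    obs = np.where(censored, np.nan, obs)
    return obs, censored


def simulate_iv_profiles(
    spec: PKPopulationSpec, dose: float, prefix: str = "iv"
) -> list[ConcProfile]:
    """Simulate IV bolus plasma profiles for a population.

    Per-subject parameters are drawn log-normally around the spec
    values, proportional noise is applied, and values below the LLOQ
    are censored in place.
    """
    if not dose > 0:
        raise ValueError("dose must be positive")
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.schedule, dtype=float)
    profiles = []
    for i in range(spec.n_subjects):
        p = _individual_params(spec, rng)
        clean = iv_bolus_conc(times, dose, p["cl"], p["v1"], p["q"], p["v2"])
        obs, cens = _observe(clean, spec, rng)
        profiles.append(
            ConcProfile(
                subject_id=f"{prefix}{i + 1:02d}",
                times=times.copy(),
                concs=obs,
                censored=cens,
                lloq=spec.lloq,
            )
        )
    return profiles


def simulate_oral_profiles(
    spec: PKPopulationSpec, dose: float, prefix: str = "po"
) -> list[ConcProfile]:
    """Simulate oral plasma profiles (first-order absorption, dose x F)."""
    if not dose > 0:
        raise ValueError("dose must be positive")
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.schedule, dtype=float)
    profiles = []
    for i in range(spec.n_subjects):
        p = _individual_params(spec, rng)
        clean = oral_conc(
            times, dose, spec.f_true, p["ka"], p["cl"], p["v1"], p["q"], p["v2"]
        )
        obs, cens = _observe(clean, spec, rng)
        profiles.append(
            ConcProfile(
                subject_id=f"{prefix}{i + 1:02d}",
                times=times.copy(),
                concs=obs,
                censored=cens,
                lloq=spec.lloq,
            )
        )
    return profiles


def simulate_excretion(spec: PKPopulationSpec, prefix: str = "iv") -> list[ExcretionRecord]:
    """Per-subject 24-h urinary (Ae) and GI recoveries, % of dose.

    Values are drawn log-normally (SD = spec.omega) around the true
    fractions, so records are non-negative and exact at zero noise.
    """
    rng = np.random.default_rng(spec.seed + 1)
    records = []
    for i in range(spec.n_subjects):
        ae = 100.0 * spec.fe_true * math.exp(spec.omega * rng.standard_normal())
        gi = 100.0 * spec.gi_true * math.exp(spec.omega * rng.standard_normal())
        records.append(
            ExcretionRecord(subject_id=f"{prefix}{i + 1:02d}", ae_0_24_pct=ae, gi_24_pct=gi)
        )
    return records


def simulate_study(
    spec: PKPopulationSpec, dose: float, route: str = "iv_bolus", prefix: Optional[str] = None
) -> tuple[list[ConcProfile], list[DoseEvent], list[ExcretionRecord]]:
    """Convenience wrapper: profiles plus matching dose events and excretion."""
    if prefix is None:
        prefix = "iv" if route == "iv_bolus" else "po"
    if route == "iv_bolus":
        profiles = simulate_iv_profiles(spec, dose, prefix)
    elif route == "oral":
        profiles = simulate_oral_profiles(spec, dose, prefix)
    else:
        raise ValueError(f"unknown route {route!r}")
    doses = [DoseEvent(p.subject_id, route, dose) for p in profiles]
    excretion = simulate_excretion(spec, prefix)
    return profiles, doses, excretion


def simulate_dialysis(
    fu_true: float,
    noise_sd: float = 0.0,
    n: int = 3,
    seed: int = 0,
    spiked_conc: float = 1.0,
) -> list[DialysisPair]:
    """Equilibrium-dialysis pairs: buffer side = fu x plasma side.

    Noise is multiplicative log-normal (exp(noise_sd * z)) so both
    sides stay positive and zero noise is an exact identity.
    """
    if not 0.0 <= fu_true <= 1.0:
        raise ValueError("fu_true must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        plasma = spiked_conc
        buffer = fu_true * plasma * math.exp(noise_sd * rng.standard_normal())
        pairs.append(DialysisPair(plasma_side_conc=plasma, buffer_side_conc=buffer,
                                  spiked_conc=spiked_conc))
    return pairs


def simulate_s9(
    kdep: Mapping[str, float],
    t_inc: float = 30.0,
    spiked_conc: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[S9Result]:
    """S9 metabolic-stability results: remaining = spiked e^(-kdep t).

    kdep maps tissue name to a first-order depletion constant (1/min);
    kdep = 0 returns the spiked concentration unchanged. Proportional
    noise (1 + sd*z) is clipped at zero.
    """
    rng = np.random.default_rng(seed)
    results = []
    for tissue in kdep:
        k = kdep[tissue]
        if k < 0:
            raise ValueError(f"kdep must be non-negative ({tissue})")
        remaining = spiked_conc * math.exp(-k * t_inc)
        remaining *= max(1.0 + noise_sd * rng.standard_normal(), 0.0)
        results.append(
            S9Result(tissue=tissue, spiked_conc=spiked_conc, remaining_conc=remaining)
        )
    return results


def simulate_peaklist(
    spec: PeakListSpec, rules: Optional[Sequence[BiotransformRule]] = None
) -> list[PeakRecord]:
    """Synthetic peak list: the parent plus one peak per requested reaction.

    Each metabolite peak sits at parent_mz + rule shift (+ noise) and
    carries the rule's diagnostic neutral-loss fragments. Retention
    times are drawn earlier than the parent for every class except
    methylation, which elutes later.
    """
    rules = build_rule_table() if rules is None else list(rules)
    by_name = {r.name: r for r in rules}
    unknown = [r for r in spec.reactions if r not in by_name]
    if unknown:
        raise ValueError(f"unknown reactions: {unknown}")
    rng = np.random.default_rng(spec.seed)
    parent_spec = ParentSpec(parent_mz=spec.parent_mz, parent_rt=spec.parent_rt)

    def jitter(mz: float) -> float:
        return mz + spec.mz_noise_sd * rng.standard_normal()

    peaks = [
        PeakRecord(
            peak_id="parent",
            precursor_mz=jitter(spec.parent_mz),
            rt=spec.parent_rt,
            fragments=tuple(
                jitter(t) for t in diagnostic_templates(spec.parent_mz, None, parent_spec)
            ),
            sources=("plasma",),
        )
    ]
    for i, name in enumerate(spec.reactions):
        rule = by_name[name]
        mz_true = spec.parent_mz + rule.mono_shift
        lo, hi = (
            spec.rt_offset_later if rule.rt_direction == "later" else spec.rt_offset_earlier
        )
        rt = spec.parent_rt + rng.uniform(lo, hi)
        frags = tuple(
            jitter(t) for t in diagnostic_templates(mz_true, name, parent_spec)
        )
        peaks.append(
            PeakRecord(
                peak_id=f"S{i + 1}",
                precursor_mz=jitter(mz_true),
                rt=rt,
                fragments=frags,
                sources=("plasma",),
            )
        )
    return peaks
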