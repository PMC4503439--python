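"""Tentative metabolite identification by biotransformation mass shifts.

A metabolite peak is assigned to a reaction class when its precursor m/z
differs from the parent [M+H]+ by the monoisotopic mass of a known
elemental-composition change (e.g. +C6H8O6 for glucuronidation,
+CH2 for methylation). Supporting evidence comes from diagnostic
neutral losses in the product-ion list (the 56-Da prenyl loss of the
xanthone core, and glucuronide losses for conjugates) and from the
retention-time polarity shift expected for each class: every reaction
here increases polarity (earlier elution on reversed phase) except
methylation, which elutes later than the parent.

Mass shifts are recomputed from elemental formulas via pyteomics at
import time; they are never hard-coded literals. Nominal (integer) Da
shifts are kept for reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
from pyteomics.mass import calculate_mass

from .exceptions import DuplicatePeakIdError

__all__ = [
    "BiotransformRule",
    "PeakRecord",
    "MetaboliteAssignment",
    "ParentSpec",
    "build_rule_table",
    "match_peak",
    "fragment_evidence",
    "rt_consistency",
    "annotate_peaklist",
    "diagnostic_templates",
    "formula_shift",
    "load_reference_peaklist",
    "PRENYL_MASS",
    "GLUCURONIDE_MASS",
]

_FORMULA_RE = re.compile(r"^([+-])([A-Za-z0-9]+)$")


def formula_shift(delta: str) -> float:
    """Signed monoisotopic mass (Da) of a composition change like '+C6H8O6' or '-H2'."""
    m = _FORMULA_RE.match(delta)
    if m is None:
        raise ValueError(f"cannot parse composition change {delta!r}")
    sign = 1.0 if m.group(1) == "+" else -1.0
    return sign * calculate_mass(formula=m.group(2))


#: neutral-loss building blocks (monoisotopic Da)
PRENYL_MASS = calculate_mass(formula="C4H8")  # 56.0626, the xanthone prenyl loss
GLUCURONIDE_MASS = calculate_mass(formula="C6H8O6")  # 176.0321


@dataclass(frozen=True)
class BiotransformRule:
    """A named biotransformation with its composition and mass change."""

    name: str
    formula_delta: str  # e.g. "+C6H8O6"
    mono_shift: float  # signed Da, recomputed from formula_delta
    phase: str  # "I" or "II"
    rt_direction: str  # "earlier" or "later" than parent

    def __post_init__(self) -> None:
        expected = formula_shift(self.formula_delta)
        if abs(self.mono_shift - expected) > 1e-9:
            raise ValueError(
                f"mono_shift {self.mono_shift} inconsistent with "
                f"{self.formula_delta} ({expected})"
            )
        if self.rt_direction == "later" and self.name != "methylation":
            raise ValueError("only methylation elutes later than the parent")


_RULE_DEFS = (
    ("glucuronidation", "+C6H8O6", "II", "earlier"),
    ("bis_glucuronidation", "+C12H16O12", "II", "earlier"),
    ("dehydrogenation", "-H2", "I", "earlier"),
    ("hydrogenation", "+H2", "I", "earlier"),
    ("oxidation", "+O", "I", "earlier"),
    ("methylation", "+CH2", "I", "later"),
)


def build_rule_table() -> list[BiotransformRule]:
    """The six reaction classes with shifts recomputed from atomic masses."""
    return [
        BiotransformRule(name, delta, formula_shift(delta), phase, rt_dir)
        for name, delta, phase, rt_dir in _RULE_DEFS
    ]


@dataclass(frozen=True)
class ParentSpec:
    """Reference parent ion: m/z, retention time and neutral-loss units."""

    parent_mz: float = 411.21  # [M+H]+ in the identification acquisition
    parent_rt: float = 27.6  # min
    #: (name, Da, max multiplicity); prenyl C4H8 lost up to twice
    neutral_loss_units: tuple[tuple[str, float, int], ...] = (
        ("prenyl", PRENYL_MASS, 2),
    )

    def __post_init__(self) -> None:
        if not self.parent_mz > 0:
            raise ValueError("parent_mz must be positive")


@dataclass
class PeakRecord:
    """A centroided precursor with its product-ion list and source matrices."""

    peak_id: str
    precursor_mz: float  # Da, [M+H]+ convention
    rt: float  # min
    fragments: tuple[float, ...] = ()
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError("precursor_mz must be positive")
        self.fragments = tuple(float(f) for f in self.fragments)
        self.sources = tuple(self.sources)


@dataclass(frozen=True)
class MetaboliteAssignment:
    """One candidate annotation of a peak (mirrors one report row)."""

    peak_id: str
    rule: str  # rule name, "parent" or "unassigned"
    observed_shift: float  # Da vs parent
    mass_error: float  # observed_shift - rule mono_shift (Da)
    nominal_shift: int  # round(observed_shift)
    fragment_evidence: Optional[int] = None
    rt_consistent: Optional[bool] = None


def match_peak(
    peak: PeakRecord,
    parent: ParentSpec,
    rules: Optional[Sequence[BiotransformRule]] = None,
    tolerance_da: float = 0.5,
) -> list[MetaboliteAssignment]:
    """Candidate assignments for one peak, best (smallest |mass error|) first.

    A peak within tolerance of the parent m/z is labelled "parent"; a peak
    matching no rule is "unassigned" (a valid outcome, not an error).
    Ties within tolerance are all returned, never silently dropped.
    """
    if not tolerance_da > 0:
        raise ValueError("tolerance_da must be positive")
    rules = build_rule_table() if rules is None else list(rules)
    shift = peak.precursor_mz - parent.parent_mz
    nominal = int(round(shift))
    if abs(shift) <= tolerance_da:
        return [MetaboliteAssignment(peak.peak_id, "parent", shift, shift, nominal)]
    candidates = [
        MetaboliteAssignment(
            peak.peak_id, r.name, shift, shift - r.mono_shift, nominal
        )
        for r in rules
        if abs(shift - r.mono_shift) <= tolerance_da
    ]
    if not candidates:
        return [
            MetaboliteAssignment(peak.peak_id, "unassigned", shift, float("nan"), nominal)
        ]
    return sorted(candidates, key=lambda a: abs(a.mass_error))


def diagnostic_templates(
    precursor_mz: float, rule: Optional[str], parent: ParentSpec
) -> list[float]:
    """Expected product-ion m/z values for a precursor under a rule.

    All classes (and the parent itself) lose the prenyl unit once or
    twice; glucuronides additionally lose the glucuronide(s), followed by
    the aglycone-minus-prenyl cascade.
    """
    templates: list[float] = []
    for _, unit_mass, max_k in parent.neutral_loss_units:
        templates.extend(precursor_mz - k * unit_mass for k in range(1, max_k + 1))
    n_gluc = {"glucuronidation": 1, "bis_glucuronidation": 2}.get(rule or "", 0)
    for g in range(1, n_gluc + 1):
        aglycone = precursor_mz - g * GLUCURONIDE_MASS
        templates.append(aglycone)
        for _, unit_mass, max_k in parent.neutral_loss_units:
            templates.extend(aglycone - k * unit_mass for k in range(1, max_k + 1))
    return templates


def fragment_evidence(
    peak: PeakRecord,
    rule: Optional[str],
    parent: ParentSpec,
    tolerance_da: float = 0.5,
) -> int:
    """Count of observed product ions matching a diagnostic template.

    Each observed fragment is counted at most once; an empty fragment
    list yields 0.
    """
    templates = diagnostic_templates(peak.precursor_mz, rule, parent)
    count = 0
    for frag in peak.fragments:
        if any(abs(frag - t) <= tolerance_da for t in templates):
            count += 1
    return count


def rt_consistency(peak_rt: float, parent: ParentSpec, rule: BiotransformRule) -> bool:
    """Whether the observed retention shift matches the rule's polarity.

    "earlier" rules allow co-elution (equality); "later" (methylation)
    requires a strictly later retention time.
    """
    if rule.rt_direction == "later":
        return peak_rt > parent.parent_rt
    return peak_rt <= parent.parent_rt


def annotate_peaklist(
    peaks: Iterable[PeakRecord],
    parent: ParentSpec,
    rules: Optional[Sequence[BiotransformRule]] = None,
    tolerance_da: float = 0.5,
    fragment_tolerance_da: float = 0.5,
) -> pd.DataFrame:
    """Annotate a peak list: one row per peak, best assignment first.

    Columns mirror a tentative-identification report: assignment class,
    mass error (Da), nominal shift, diagnostic-fragment count and the
    retention-polarity flag. The RT flag is evidence, never a filter.
    Rows are ordered deterministically by retention time then m/z.
    """
    peaks = list(peaks)
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicatePeakIdError(f"duplicate peak_ids: {dupes}")
    rules = build_rule_table() if rules is None else list(rules)
    by_name = {r.name: r for r in rules}
    rows = []
    for peak in sorted(peaks, key=lambda p: (p.rt, p.precursor_mz)):
        best = match_peak(peak, parent, rules, tolerance_da)[0]
        rule_obj = by_name.get(best.rule)
        evidence = fragment_evidence(
            peak, best.rule if best.rule in by_name else None, parent,
            fragment_tolerance_da,
        )
        rt_ok = rt_consistency(peak.rt, parent, rule_obj) if rule_obj else None
        rows.append(
            {
                "peak_id": peak.peak_id,
                "precursor_mz": peak.precursor_mz,
                "rt_min": peak.rt,
                "assignment": best.rule,
                "mass_error_da": best.mass_error,
                "nominal_shift_da": best.nominal_shift,
                "fragment_evidence": evidence,
                "rt_consistent": rt_ok,
                "sources": ";".join(peak.sources),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "precursor_mz",
            "rt_min",
            "assignment",
            "mass_error_da",
            "nominal_shift_da",
            "fragment_evidence",
            "rt_consistent",
            "sources",
        ],
    )


def load_reference_peaklist() -> tuple[list[PeakRecord], ParentSpec]:
    """Bundled LC-MS/MS reference peak list for alpha-mangostin metabolites.

    Sixteen records (the parent plus 15 tentative metabolites) observed
    in mouse plasma, urine, feces, liver, small intestine and S9
    incubations, with precursor m/z, product ions and retention times.
    """
    from . import io as _io  # local import to avoid a cycle

    path = resources.files("mangopk.data") / "reference_peaklist.csv"
    with resources.as_file(path) as p:
        peaks = _io.read_peaklist_csv(p)
    return peaks, ParentSpec(parent_mz=411.21, parent_rt=27.6)
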