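"""Dose-context arithmetic: cumulative doses and interspecies scaling.

Small exact calculators that put an experimental dosing regimen in context:
the cumulative dose of a repeated daily exposure, conversion of a
per-person dietary intake to a per-kilogram dose, and allometric scaling of a
per-kilogram dose between species of different body mass.  Allometric scaling
follows three-quarter-power metabolic scaling of *total* dose, so the per-kg
dose scales by (w_from / w_to)^(1 - exponent) with exponent 0.75 by default.
"""

from __future__ import annotations


def cumulative_dose(daily_dose: float, days: float) -> float:
    """Cumulative dose (mass/kg-bw) of ``daily_dose`` given for ``days`` days."""
    if daily_dose < 0 or days < 0:
        raise ValueError("daily dose and days must be non-negative")
    return daily_dose * days


def per_kg_dose(total_daily: float, body_weight: float, ndigits: int | None = None) -> float:
    """Per-kilogram daily dose from a whole-body daily intake.

    ``ndigits`` optionally rounds for display (e.g. 2 decimals to match the
    convention of reporting 17 ug/person/day at 60 kg as 0.28 ug/kg/day).
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    value = total_daily / body_weight
    return round(value, ndigits) if ndigits is not None else value


def allometric_scale(dose_per_kg: float, weight_from: float, weight_to: float,
                     exponent: float = 0.75) -> float:
    """Scale a per-kg dose between body masses by metabolic-rate allometry."""
    if weight_from <= 0 or weight_to <= 0:
        raise ValueError("body weights must be positive")
    if not 0 < exponent <= 1:
        raise ValueError("exponent must be in (0, 1]")
    return dose_per_kg * (weight_from / weight_to) ** (1.0 - exponent)


def dose_context_report(
    daily_dose: float = 0.68,
    days: int = 10,
    dietary_intake: float = 17.0,
    human_weight: float = 60.0,
    mouse_weight: float = 0.030,
    exponent: float = 0.75,
) -> dict:
    """Bundle the standard dose-context quantities into one report.

    Defaults describe a 10-day gestational exposure window and the upper-bound
    dietary BaP intake for a 60-kg human scaled to a 30-g mouse.
    """
    human_per_kg = per_kg_dose(dietary_intake, human_weight)
    return {
        "cumulative_dose_mg_per_kg": cumulative_dose(daily_dose, days),
        "dietary_dose_ug_per_kg_day": round(human_per_kg, 2),
        "allometric_mouse_dose_ug_per_kg_day": round(
            allometric_scale(human_per_kg, human_weight, mouse_weight, exponent), 1
        ),
    }
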