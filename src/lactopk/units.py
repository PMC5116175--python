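"""Unit constants and conversions.

Internally everything is ng (amount), mL (volume) and hours (time), so
concentrations are natively ng/mL — the units of the assay data.
"""

LB_TO_G = 453.592
#: default milk density used to convert recorded milk weights to volumes (g/mL)
MILK_DENSITY_G_PER_ML = 1.03


def volume_from_weight(weight_value: float, unit: str = "g",
                       density_g_per_ml: float = MILK_DENSITY_G_PER_ML) -> float:
    """Convert a recorded milk weight to a volume in mL.

    Parameters
    ----------
    weight_value : recorded weight, ``>= 0``.
    unit : ``"g"``, ``"kg"`` or ``"lbs"``.
    density_g_per_ml : milk density; whole goat milk is ~1.03 g/mL.
    """
    if weight_value < 0:
        raise ValueError(f"weight must be non-negative, got {weight_value}")
    factors = {"g": 1.0, "kg": 1000.0, "lbs": LB_TO_G, "lb": LB_TO_G}
    try:
        grams = weight_value * factors[unit]
    except KeyError:
        raise ValueError(f"unknown weight unit {unit!r}; expected one of {sorted(factors)}") from None
    return grams / density_g_per_ml


def dose_ng(dose_mg_per_kg: float, body_weight_kg: float) -> float:
    """SC dose in ng from a mg/kg label dose and a body weight."""
    if dose_mg_per_kg <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and body weight must be positive")
    return dose_mg_per_kg * body_weight_kg * 1e6
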