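"""Human-equivalent-dose conversion and margin-of-exposure risk characterization.

An animal point of departure in mg/kg is scaled to a human-equivalent dose by
body-surface-area factors (FDA starting-dose guidance): divide by the species
divisor (6.2 for rat, i.e. multiply by 0.16), then multiply by the human Km
of 37 to express the dose in mg/m².  The margin of exposure is the ratio of
the human-equivalent PoD to the anticipated clinical exposure, classified
into green (>= 10-fold), yellow (3- to 10-fold) and red (< 3-fold) zones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SPECIES_TABLE",
    "KM_HUMAN",
    "HedConversion",
    "MoeAssessment",
    "MoeRangeProfile",
    "UnitError",
    "animal_to_hed",
    "compute_moe",
    "moe_range_profile",
]

#: body-surface-area divisors (animal mg/kg -> human mg/kg).  Only the rat
#: factor is printed in the source guidance excerpt used here; "human" is the
#: identity entry.  Other species can be passed explicitly via ``bsa_divisor``.
SPECIES_TABLE: dict[str, float] = {
    "rat": 6.2,
    "human": 1.0,
}

#: Km converting human mg/kg to mg/m²
KM_HUMAN = 37.0


class UnitError(ValueError):
    """Mismatched dose units (mg/kg vs mg/m²)."""


def _sig3(x: float) -> float:
    return float(f"{x:.3g}")


@dataclass
class HedConversion:
    """Animal PoD with its body-surface-area-scaled human equivalents.

    ``hed_mgkg``/``hed_mgm2`` carry the exact multiplicative chain.  The
    ``*_printed`` fields follow the conventional reporting arithmetic: mg/kg
    rounded to 2 decimals first, then multiplied by Km and given to 3
    significant figures.
    """

    pod_animal: float
    species: str = "rat"
    bsa_divisor: float = 6.2
    km_human: float = KM_HUMAN
    hed_mgkg: float = field(init=False)
    hed_mgm2: float = field(init=False)
    hed_mgkg_printed: float = field(init=False)
    hed_mgm2_printed: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.pod_animal > 0):
            raise ValueError(f"pod_animal must be > 0, got {self.pod_animal!r}")
        if not (self.bsa_divisor > 0 and self.km_human > 0):
            raise ValueError("bsa_divisor and km_human must be > 0")
        self.hed_mgkg = self.pod_animal / self.bsa_divisor
        self.hed_mgm2 = self.hed_mgkg * self.km_human
        self.hed_mgkg_printed = round(self.hed_mgkg, 2)
        self.hed_mgm2_printed = _sig3(self.hed_mgkg_printed * self.km_human)


def animal_to_hed(
    pod_animal: float,
    species: str = "rat",
    bsa_divisor: float | None = None,
    km_human: float = KM_HUMAN,
) -> HedConversion:
    """Scale an animal PoD (mg/kg) to human-equivalent mg/kg and mg/m²."""
    if bsa_divisor is None:
        if species not in SPECIES_TABLE:
            raise KeyError(
                f"unknown species {species!r}; available: {sorted(SPECIES_TABLE)} "
                "(or pass bsa_divisor explicitly)"
            )
        bsa_divisor = SPECIES_TABLE[species]
    return HedConversion(
        pod_animal=pod_animal, species=species, bsa_divisor=bsa_divisor, km_human=km_human
    )


@dataclass
class MoeAssessment:
    """Margin of exposure and its zone against the 3-/10-fold thresholds."""

    pod_hed: float
    exposure: float
    moe: float
    zone: str
    lower_threshold: float = 3.0
    upper_threshold: float = 10.0


def compute_moe(
    pod_hed: float,
    exposure: float,
    lower_threshold: float = 3.0,
    upper_threshold: float = 10.0,
    pod_units: str = "mg/m2",
    exposure_units: str = "mg/m2",
) -> MoeAssessment:
    """MOE = PoD / exposure with zone classification.

    Zones: green when MOE >= upper threshold, yellow when lower <= MOE <
    upper, red when MOE < lower.  Boundary values fall in the more favorable
    zone.
    """
    if pod_units != exposure_units:
        raise UnitError(f"PoD in {pod_units} cannot be compared to exposure in {exposure_units}")
    if not (pod_hed > 0):
        raise ValueError(f"pod_hed must be > 0, got {pod_hed!r}")
    if not (exposure > 0):
        raise ValueError(f"exposure must be > 0, got {exposure!r}")
    if not (0 < lower_threshold <= upper_threshold):
        raise ValueError("thresholds must satisfy 0 < lower <= upper")
    moe = pod_hed / exposure
    if moe >= upper_threshold:
        zone = "green"
    elif moe >= lower_threshold:
        zone = "yellow"
    else:
        zone = "red"
    return MoeAssessment(
        pod_hed=pod_hed, exposure=exposure, moe=moe, zone=zone,
        lower_threshold=lower_threshold, upper_threshold=upper_threshold,
    )


@dataclass
class MoeRangeProfile:
    """MOE at both ends of an exposure range plus the worst-case summary zone."""

    assessments: tuple
    summary_zone: str


def moe_range_profile(
    pod_hed: float,
    exposure_min: float,
    exposure_max: float,
    lower_threshold: float = 3.0,
    upper_threshold: float = 10.0,
) -> MoeRangeProfile:
    """Assess a clinical exposure range; the summary zone is the one at the
    maximum exposure (the smallest margin)."""
    if not (0 < exposure_min <= exposure_max):
        raise ValueError(
            f"need 0 < exposure_min <= exposure_max, got ({exposure_min!r}, {exposure_max!r})"
        )
    at_min = compute_moe(pod_hed, exposure_min, lower_threshold, upper_threshold)
    at_max = compute_moe(pod_hed, exposure_max, lower_threshold, upper_threshold)
    return MoeRangeProfile(assessments=(at_min, at_max), summary_zone=at_max.zone)
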