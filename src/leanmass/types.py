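"""Shared domain vocabulary: age-sex classes and table schemas."""

from __future__ import annotations

import enum


class AgeSexClass(str, enum.Enum):
    """The five age-sex classes recognised by the analysis."""

    ADULT_FEMALE = "adult_female"
    FLANGED_MALE = "flanged_male"
    UNFLANGED_MALE = "unflanged_male"
    ADOLESCENT = "adolescent"
    DEPENDENT = "dependent"


#: Canonical ordering used for design matrices, summaries and contrasts.
CLASS_ORDER: tuple[str, ...] = tuple(c.value for c in AgeSexClass)

SAMPLE_COLUMNS = ("sample_id", "individual_id", "date", "specific_gravity", "creatinine_mg_ml")
INDIVIDUAL_COLUMNS = ("individual_id", "age_sex_class")
TRUTH_COLUMNS = ("sample_id", "true_lean_mass", "hydration_factor", "assay_noise")
PHENOLOGY_COLUMNS = ("month", "stem_id", "dbh_cm", "fruiting")


def validate_class(name: str) -> str:
    """Return ``name`` if it is a known age-sex class, else raise."""
    from .errors import ConfigurationError

    if name not in CLASS_ORDER:
        raise ConfigurationError(
            f"unknown age-sex class {name!r}; expected one of {', '.join(CLASS_ORDER)}"
        )
    return name
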