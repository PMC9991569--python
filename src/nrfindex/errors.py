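"""Exception hierarchy shared across the package.

Every error a pipeline stage can raise derives from :class:`NRFError` so
callers can catch one base class; subclasses carry enough context (nutrient,
stratum, food, row) to make the message actionable.
"""

from __future__ import annotations


class NRFError(Exception):
    """Base class for all package errors."""


class MissingReferenceError(NRFError, LookupError):
    """No daily reference value covers the requested (nutrient, sex, age)."""

    def __init__(self, nutrient_id: str, sex: str | None = None, age_y: float | None = None):
        self.nutrient_id = nutrient_id
        self.sex = sex
        self.age_y = age_y
        stratum = "" if sex is None else f" for stratum (sex={sex}, age={age_y})"
        super().__init__(f"no reference value for nutrient {nutrient_id!r}{stratum}")


class AmbiguousReferenceError(NRFError):
    """Overlapping strata: more than one entry matches a lookup."""


class DomainError(NRFError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ZeroEnergyError(DomainError):
    """Per-100-kcal scoring requested for a food or diet with no energy."""

    def __init__(self, what: str):
        super().__init__(f"cannot express nutrients per 100 kcal: {what} has zero energy")


class UndefinedRatioError(DomainError):
    """Ratio-algorithm score requested when the LIM subscore is zero."""


class DegenerateDistributionError(DomainError):
    """Too few distinct values to form quartiles."""


class ReferentialIntegrityError(NRFError):
    """Recall records mention food ids absent from the composition table."""

    def __init__(self, missing_ids):
        self.missing_ids = sorted(set(missing_ids))
        super().__init__(f"unresolvable food ids in recalls: {self.missing_ids}")


class CollinearityError(NRFError):
    """Singular design matrix in a regression."""


class SchemaError(NRFError, ValueError):
    """An input table violates its declared schema."""


class ConvergenceError(NRFError):
    """A maximum-likelihood fit failed to converge (e.g. complete separation)."""
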