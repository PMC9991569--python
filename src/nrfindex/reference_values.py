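"""Daily reference values (DVs) for nutrients, stratified by sex and age.

The table serves two roles: it supplies the denominators of the NRF
subscores (the DV of each encouraged nutrient and the maximal reference
value, MRV, of each limited nutrient) and the denominators of the nutrient
adequacy ratio (NAR).  Values are configuration, not code: the bundled
``chinese_dri_2013.csv`` transcribes the Chinese dietary reference intakes
for adults (RNI where available, AI otherwise), the sodium maximal value,
and the saturated-fat limit expressed as an acceptable-macronutrient-
distribution fraction of energy.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import AmbiguousReferenceError, DomainError, MissingReferenceError, SchemaError

__all__ = [
    "ReferenceValueEntry",
    "ReferenceValueTable",
    "load_default_table",
    "KCAL_PER_G_FAT",
]

#: Atwater energy factor for fat, kcal per gram.
KCAL_PER_G_FAT = 9.0

_BASES = {"RNI", "AI", "AMDR_fraction_of_energy", "MRV"}
_SEXES = {"male", "female", "any"}


@dataclass(frozen=True)
class ReferenceValueEntry:
    """One daily reference value for one (nutrient, sex, age-range) stratum.

    ``value`` is an amount per day in the nutrient's canonical unit, except
    for basis ``AMDR_fraction_of_energy`` where it is a dimensionless
    fraction of daily energy (applies to saturated fat only).
    """

    nutrient_id: str
    sex: str  # male | female | any
    age_min_y: float
    age_max_y: float
    value: float
    basis: str  # RNI | AI | AMDR_fraction_of_energy | MRV
    unit: str = ""

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise SchemaError(f"unknown sex {self.sex!r} for {self.nutrient_id}")
        if self.basis not in _BASES:
            raise SchemaError(f"unknown basis {self.basis!r} for {self.nutrient_id}")
        if not self.value > 0:
            raise SchemaError(f"non-positive reference value for {self.nutrient_id}")
        if self.age_min_y > self.age_max_y:
            raise SchemaError(f"empty age interval for {self.nutrient_id}")
        if self.basis == "AMDR_fraction_of_energy" and not 0 < self.value < 1:
            raise SchemaError(
                f"AMDR fraction for {self.nutrient_id} must lie in (0, 1), got {self.value}"
            )

    def matches(self, sex: str, age_y: float) -> bool:
        sex_ok = self.sex == "any" or self.sex == sex
        return sex_ok and self.age_min_y <= age_y <= self.age_max_y


@dataclass
class ReferenceValueTable:
    """A collection of reference-value entries with unique-stratum lookup.

    ``energy_reference_kcal`` converts AMDR energy fractions to grams when a
    food-level (person-independent) score is wanted; the 2000 kcal default is
    the conventional fixed reference.
    """

    entries: list[ReferenceValueEntry] = field(default_factory=list)
    energy_reference_kcal: float = 2000.0

    def __post_init__(self) -> None:
        self._check_no_overlap()

    def _check_no_overlap(self) -> None:
        # Overlap for one nutrient and one concrete sex is a config error.
        by_nutrient: dict[str, list[ReferenceValueEntry]] = {}
        for e in self.entries:
            by_nutrient.setdefault(e.nutrient_id, []).append(e)
        for nutrient, group in by_nutrient.items():
            for sex in ("male", "female"):
                spans = sorted(
                    (e.age_min_y, e.age_max_y)
                    for e in group
                    if e.sex in (sex, "any")
                )
                for (lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
                    if lo2 <= hi1:
                        raise AmbiguousReferenceError(
                            f"overlapping age strata for nutrient {nutrient!r}, sex {sex}: "
                            f"[{lo1}, {hi1}] and [{lo2}, {_hi2}]"
                        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, energy_reference_kcal: float = 2000.0) -> "ReferenceValueTable":
        required = {"nutrient_id", "sex", "age_min", "age_max", "value", "basis"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"reference table missing columns: {sorted(missing)}")
        entries = [
            ReferenceValueEntry(
                nutrient_id=str(r.nutrient_id),
                sex=str(r.sex),
                age_min_y=float(r.age_min),
                age_max_y=float(r.age_max),
                value=float(r.value),
                basis=str(r.basis),
                unit=str(getattr(r, "unit", "")),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries=entries, energy_reference_kcal=energy_reference_kcal)

    @classmethod
    def from_csv(cls, path, energy_reference_kcal: float = 2000.0) -> "ReferenceValueTable":
        return cls.from_frame(pd.read_csv(path), energy_reference_kcal=energy_reference_kcal)

    # -- lookup ------------------------------------------------------------

    def lookup_dv(self, nutrient_id: str, sex: str, age_y: float) -> float:
        """Return the unique daily value for (nutrient, sex, age).

        Raises :class:`MissingReferenceError` if no entry covers the stratum
        and :class:`AmbiguousReferenceError` if more than one does.
        """
        hits = [
            e for e in self.entries
            if e.nutrient_id == nutrient_id and e.matches(sex, age_y)
        ]
        if not hits:
            raise MissingReferenceError(nutrient_id, sex, age_y)
        if len(hits) > 1:
            raise AmbiguousReferenceError(
                f"{len(hits)} entries match ({nutrient_id}, {sex}, {age_y})"
            )
        return hits[0].value

    def saturated_fat_limit_g(self, energy_kcal: float | None = None) -> float:
        """Daily saturated-fat limit in grams from the AMDR energy fraction.

        With ``energy_kcal`` absent the table's fixed reference energy is
        used, which makes food-level scores person-independent.
        """
        entry = next(
            (e for e in self.entries if e.basis == "AMDR_fraction_of_energy"),
            None,
        )
        if entry is None:
            raise MissingReferenceError("sat_fat")
        energy = self.energy_reference_kcal if energy_kcal is None else energy_kcal
        if not energy > 0:
            raise DomainError(f"energy must be positive, got {energy}")
        return entry.value * energy / KCAL_PER_G_FAT

    def resolve_dv_map(self, nutrient_ids: Iterable[str], sex: str, age_y: float) -> dict[str, float]:
        """Daily values for several nutrients at one stratum."""
        return {n: self.lookup_dv(n, sex, age_y) for n in nutrient_ids}

    def resolve_limit_map(
        self,
        sex: str,
        age_y: float,
        energy_kcal: float | None = None,
    ) -> dict[str, float]:
        """Maximal reference values for the two limit nutrients.

        Saturated fat comes from the AMDR fraction (grams/day); sodium is the
        MRV carried in the table (mg/day).
        """
        return {
            "sat_fat": self.saturated_fat_limit_g(energy_kcal),
            "sodium": self.lookup_dv("sodium", sex, age_y),
        }

    def covered_nutrients(self) -> set[str]:
        return {e.nutrient_id for e in self.entries}


def load_default_table(energy_reference_kcal: float = 2000.0) -> ReferenceValueTable:
    """Load the bundled adult Chinese dietary-reference-intake table."""
    ref = importlib.resources.files("nrfindex.data") / "chinese_dri_2013.csv"
    with importlib.resources.as_file(ref) as path:
        return ReferenceValueTable.from_csv(path, energy_reference_kcal=energy_reference_kcal)
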