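"""Nutrient-rich foods (NRF) index family: NRn and LIM subscores and totals.

An NRF score summarises the nutrient density of a food or whole diet per
reference amount (100 g or 100 kcal).  The positive subscore NRn sums, over
``n`` nutrients to encourage, the percentage of the daily value (DV) that the
reference amount supplies, each contribution capped (by default at 100 %DV).
The penalty subscore LIM sums, over the two nutrients to limit (saturated
fat and sodium), the uncapped percentage of the maximal reference value
(MRV).  Three algorithms combine the subscores::

    sum    NRFn.2 = NRn - LIM
    mean   NRFn.2 = NRn/n - LIM/2
    ratio  NRFn.2 = NRn / LIM          (undefined at LIM = 0)

Variants are written NRFn.2 with n encouraged nutrients and 2 limited ones;
the built-in presets cover n = 6, 9, 11 crossed with the three algorithms
and both reference amounts — the 18-variant grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, MissingReferenceError, UndefinedRatioError, ZeroEnergyError
from .reference_values import ReferenceValueTable

__all__ = [
    "FoodComposition",
    "NutrientProfileConfig",
    "NRFScore",
    "PRESETS",
    "variant_grid",
    "amounts_per_reference",
    "nr_subscore",
    "lim_subscore",
    "nrf_score",
    "score_food",
    "score_diet",
    "score_cohort",
]

FOOD_GROUPS = (
    "cereals", "vegetables", "fruits", "milk", "beans",
    "egg", "meat", "poultry", "fish", "snacks", "other",
)

LIMIT_NUTRIENTS = ("sat_fat", "sodium")

ENCOURAGE_6 = ("protein", "fibre", "vitamin_a", "vitamin_c", "calcium", "iron")
ENCOURAGE_9 = ENCOURAGE_6 + ("vitamin_e", "potassium", "magnesium")
ENCOURAGE_11 = ENCOURAGE_9 + ("vitamin_b12", "zinc")


@dataclass(frozen=True)
class FoodComposition:
    """Nutrients per 100 g edible portion plus energy density."""

    food_id: str
    name: str
    group: str
    energy_kcal_per_100g: float
    nutrients: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.energy_kcal_per_100g < 0:
            raise DomainError(f"negative energy for food {self.food_id}")
        bad = {k: v for k, v in self.nutrients.items() if v < 0}
        if bad:
            raise DomainError(f"negative nutrient amounts for food {self.food_id}: {bad}")


@dataclass(frozen=True)
class NutrientProfileConfig:
    """One member of the NRF family: which nutrients, reference, algorithm."""

    name: str
    encourage: tuple[str, ...]
    limit: tuple[str, ...] = LIMIT_NUTRIENTS
    reference_amount: str = "per_100kcal"  # per_100g | per_100kcal
    algorithm: str = "sum"  # sum | mean | ratio
    cap_percent_dv: float = 100.0

    def __post_init__(self) -> None:
        if set(self.encourage) & set(self.limit):
            raise DomainError("encourage and limit nutrient sets must be disjoint")
        if self.reference_amount not in ("per_100g", "per_100kcal"):
            raise DomainError(f"unknown reference amount {self.reference_amount!r}")
        if self.algorithm not in ("sum", "mean", "ratio"):
            raise DomainError(f"unknown algorithm {self.algorithm!r}")
        if len(self.limit) != 2:
            raise DomainError("the NRFn.2 family limits exactly two nutrients")

    @property
    def n(self) -> int:
        return len(self.encourage)


@dataclass(frozen=True)
class NRFScore:
    """Subscores and total of one variant applied to one food or diet."""

    config_name: str
    nr_subscore: float
    lim_subscore: float
    total: float
    reference_amount: str


def _preset(n: int, encourage: tuple[str, ...], algorithm: str, reference: str) -> NutrientProfileConfig:
    return NutrientProfileConfig(
        name=f"NRF{n}.2",
        encourage=encourage,
        algorithm=algorithm,
        reference_amount=reference,
    )


#: Canonical presets keyed by lower-case name (sum algorithm, per 100 kcal).
PRESETS: dict[str, NutrientProfileConfig] = {
    "nrf6.2": _preset(6, ENCOURAGE_6, "sum", "per_100kcal"),
    "nrf9.2": _preset(9, ENCOURAGE_9, "sum", "per_100kcal"),
    "nrf11.2": _preset(11, ENCOURAGE_11, "sum", "per_100kcal"),
}


def variant_grid(
    ns: Iterable[int] = (6, 9, 11),
    algorithms: Iterable[str] = ("sum", "mean", "ratio"),
    references: Iterable[str] = ("per_100kcal", "per_100g"),
) -> list[NutrientProfileConfig]:
    """The full NRF variant grid (default: 3 n-values x 3 algorithms x 2 refs)."""
    sets = {6: ENCOURAGE_6, 9: ENCOURAGE_9, 11: ENCOURAGE_11}
    grid = []
    for n in ns:
        for alg in algorithms:
            for ref in references:
                grid.append(replace(PRESETS[f"nrf{n}.2"], algorithm=alg, reference_amount=ref))
    return grid


def variant_label(config: NutrientProfileConfig) -> str:
    ref = "100kcal" if config.reference_amount == "per_100kcal" else "100g"
    return f"{config.name}/{config.algorithm}/{ref}"


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def amounts_per_reference(food: FoodComposition, reference_amount: str) -> dict[str, float]:
    """Express a food's nutrients per 100 g or per 100 kcal.

    Per 100 g is the composition table as-is; per 100 kcal rescales every
    amount by 100 / energy density, so foods at exactly 100 kcal/100 g are a
    fixed point.
    """
    if reference_amount == "per_100g":
        return dict(food.nutrients)
    if reference_amount == "per_100kcal":
        if food.energy_kcal_per_100g <= 0:
            raise ZeroEnergyError(f"food {food.food_id!r}")
        factor = 100.0 / food.energy_kcal_per_100g
        return {k: v * factor for k, v in food.nutrients.items()}
    raise DomainError(f"unknown reference amount {reference_amount!r}")


def nr_subscore(
    amounts: Mapping[str, float],
    config: NutrientProfileConfig,
    dv: Mapping[str, float],
) -> float:
    """NRn: capped percent-of-DV sum over the encouraged nutrients."""
    cap = config.cap_percent_dv / 100.0
    total = 0.0
    for nutrient in config.encourage:
        if nutrient not in dv:
            raise MissingReferenceError(nutrient)
        if dv[nutrient] <= 0:
            raise DomainError(f"non-positive DV for {nutrient}")
        total += min(amounts.get(nutrient, 0.0) / dv[nutrient], cap) * 100.0
    return total


def lim_subscore(
    amounts: Mapping[str, float],
    config: NutrientProfileConfig,
    mrv: Mapping[str, float],
) -> float:
    """LIM: uncapped percent-of-MRV sum over the limited nutrients."""
    total = 0.0
    for nutrient in config.limit:
        if nutrient not in mrv:
            raise MissingReferenceError(nutrient)
        if mrv[nutrient] <= 0:
            raise DomainError(f"non-positive MRV for {nutrient}")
        total += amounts.get(nutrient, 0.0) / mrv[nutrient] * 100.0
    return total


def nrf_score(nr: float, lim: float, config: NutrientProfileConfig) -> NRFScore:
    """Combine the subscores under the configured algorithm."""
    if nr < 0 or lim < 0:
        raise DomainError("subscores must be non-negative")
    if config.algorithm == "sum":
        total = nr - lim
    elif config.algorithm == "mean":
        total = nr / config.n - lim / len(config.limit)
    else:  # ratio
        if lim == 0:
            raise UndefinedRatioError(
                f"{config.name}: ratio algorithm undefined at LIM = 0"
            )
        total = nr / lim
    return NRFScore(
        config_name=config.name,
        nr_subscore=nr,
        lim_subscore=lim,
        total=total,
        reference_amount=config.reference_amount,
    )


def score_food(
    food: FoodComposition,
    config: NutrientProfileConfig,
    dv_table: ReferenceValueTable,
    sex: str = "male",
    age_y: float = 30.0,
) -> NRFScore:
    """Score one food: reference-amount conversion, subscores, algorithm.

    The (sex, age) stratum resolves DVs; the saturated-fat MRV uses the
    table's fixed reference energy so food scores are person-independent in
    the energy dimension.
    """
    amounts = amounts_per_reference(food, config.reference_amount)
    dv = dv_table.resolve_dv_map(config.encourage, sex, age_y)
    mrv = dv_table.resolve_limit_map(sex, age_y)
    return nrf_score(nr_subscore(amounts, config, dv), lim_subscore(amounts, config, mrv), config)


def score_diet(
    daily,
    config: NutrientProfileConfig,
    dv_table: ReferenceValueTable,
    sex: str = "male",
    age_y: float = 30.0,
    mode: str = "diet_level",
    food_table: Mapping[str, FoodComposition] | None = None,
) -> NRFScore:
    """Score a whole day's diet.

    ``diet_level`` (default) expresses the summed daily nutrients per
    reference amount of the total diet and applies the formulas once;
    ``energy_weighted_mean`` averages per-food scores weighted by each food's
    energy share and needs ``daily.foods`` plus a ``food_table``.
    """
    from .intake_mar import DailyIntake  # local import to avoid a cycle

    if not isinstance(daily, DailyIntake):
        raise DomainError("score_diet expects a DailyIntake")
    if mode == "diet_level":
        if config.reference_amount == "per_100kcal":
            if daily.energy_kcal <= 0:
                raise ZeroEnergyError(f"diet of participant {daily.participant_id!r}")
            factor = 100.0 / daily.energy_kcal
        else:
            if daily.total_grams <= 0:
                raise DomainError(f"diet of participant {daily.participant_id!r} has no mass")
            factor = 100.0 / daily.total_grams
        amounts = {k: v * factor for k, v in daily.nutrients.items()}
        dv = dv_table.resolve_dv_map(config.encourage, sex, age_y)
        mrv = dv_table.resolve_limit_map(sex, age_y)
        return nrf_score(
            nr_subscore(amounts, config, dv), lim_subscore(amounts, config, mrv), config
        )
    if mode == "energy_weighted_mean":
        if food_table is None or not daily.foods:
            raise DomainError("energy_weighted_mean mode needs per-food grams and a food table")
        energies = {}
        for fid, grams in daily.foods.items():
            if fid not in food_table:
                raise MissingReferenceError(fid)
            energies[fid] = grams / 100.0 * food_table[fid].energy_kcal_per_100g
        total_energy = sum(energies.values())
        if total_energy <= 0:
            raise ZeroEnergyError(f"diet of participant {daily.participant_id!r}")
        nr = lim = total = 0.0
        for fid, e in energies.items():
            w = e / total_energy
            s = score_food(food_table[fid], config, dv_table, sex, age_y)
            nr += w * s.nr_subscore
            lim += w * s.lim_subscore
            total += w * s.total
        return NRFScore(config.name, nr, lim, total, config.reference_amount)
    raise DomainError(f"unknown diet scoring mode {mode!r}")


# ---------------------------------------------------------------------------
# vectorised cohort scoring
# ---------------------------------------------------------------------------

def _dv_matrix(
    participants: pd.DataFrame,
    nutrients: tuple[str, ...],
    dv_table: ReferenceValueTable,
) -> np.ndarray:
    """Per-participant DV matrix (rows align with participants)."""
    cache: dict[tuple[str, float], list[float]] = {}
    rows = []
    for sex, age in zip(participants["sex"], participants["age"]):
        key = (sex, float(age))
        if key not in cache:
            cache[key] = [dv_table.lookup_dv(n, sex, float(age)) for n in nutrients]
        rows.append(cache[key])
    return np.asarray(rows, dtype=float)


def score_cohort(
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    config: NutrientProfileConfig,
    dv_table: ReferenceValueTable,
) -> pd.Series:
    """Diet-level NRF totals for every participant at once.

    ``intakes`` is indexed by participant id with columns ``energy_kcal``,
    ``total_grams`` and one column per nutrient; ``participants`` must carry
    ``participant_id``, ``sex`` and ``age``.
    """
    part = participants.set_index("participant_id").loc[intakes.index]
    if config.reference_amount == "per_100kcal":
        denom = intakes["energy_kcal"].to_numpy(float)
        if (denom <= 0).any():
            bad = intakes.index[denom <= 0].tolist()
            raise ZeroEnergyError(f"participants {bad}")
    else:
        denom = intakes["total_grams"].to_numpy(float)
        if (denom <= 0).any():
            raise DomainError("zero total grams in diet-level per-100 g scoring")
    factor = 100.0 / denom

    part_for_dv = part.reset_index()
    enc = np.column_stack([
        intakes[n].to_numpy(float) if n in intakes else np.zeros(len(intakes))
        for n in config.encourage
    ]) * factor[:, None]
    dv = _dv_matrix(part_for_dv, config.encourage, dv_table)
    cap = config.cap_percent_dv / 100.0
    nr = np.minimum(enc / dv, cap).sum(axis=1) * 100.0

    lim_amounts = np.column_stack([
        intakes[n].to_numpy(float) if n in intakes else np.zeros(len(intakes))
        for n in config.limit
    ]) * factor[:, None]
    satfat_mrv = dv_table.saturated_fat_limit_g()
    sodium_mrv = _dv_matrix(part_for_dv, ("sodium",), dv_table)[:, 0]
    mrv = np.column_stack([np.full(len(intakes), satfat_mrv), sodium_mrv])
    lim = (lim_amounts / mrv).sum(axis=1) * 100.0

    if config.algorithm == "sum":
        total = nr - lim
    elif config.algorithm == "mean":
        total = nr / config.n - lim / len(config.limit)
    else:
        if (lim == 0).any():
            raise UndefinedRatioError("ratio algorithm undefined for diets with LIM = 0")
        total = nr / lim
    return pd.Series(total, index=intakes.index, name=variant_label(config))
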