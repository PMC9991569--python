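"""24-h recall aggregation, energy-plausibility screening, and NAR/MAR.

Two non-consecutive 24-h recalls per participant are aggregated to mean
daily intakes (unweighted mean over the recall days present).  Participants
whose mean daily energy falls outside sex-specific plausibility bounds are
excluded before any scoring.  Nutrient adequacy is summarised by the
nutrient adequacy ratio NAR = min(intake / DRI, 1) for a fixed ten-nutrient
panel (energy, protein, vitamin A, vitamin C, Ca, Fe, P, thiamin,
riboflavin, niacin) and the mean adequacy ratio MAR = 100 x mean(NAR),
reported on a 0-100 percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, ReferentialIntegrityError
from .reference_values import ReferenceValueTable

__all__ = [
    "MAR_NUTRIENTS",
    "DEFAULT_ENERGY_BOUNDS",
    "RecallRecord",
    "DailyIntake",
    "MARResult",
    "aggregate_recalls",
    "intake_frame_to_daily",
    "exclude_implausible_energy",
    "nar",
    "mar",
    "mar_frame",
]

#: The fixed MAR panel, in canonical nutrient ids.
MAR_NUTRIENTS = (
    "energy", "protein", "vitamin_a", "vitamin_c", "calcium",
    "iron", "phosphorus", "vitamin_b1", "vitamin_b2", "niacin",
)

#: Conventional energy-plausibility screens, kcal/d (low, high) per sex.
DEFAULT_ENERGY_BOUNDS: dict[str, tuple[float, float]] = {
    "male": (800.0, 4200.0),
    "female": (500.0, 3500.0),
}


@dataclass(frozen=True)
class RecallRecord:
    participant_id: str
    day: int
    food_id: str
    grams: float

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise DomainError(f"negative grams for {self.participant_id}/{self.food_id}")


@dataclass
class DailyIntake:
    """Mean daily intake of one participant over their recall days."""

    participant_id: str
    energy_kcal: float
    total_grams: float
    nutrients: dict[str, float]
    food_groups: dict[str, float] = field(default_factory=dict)
    foods: dict[str, float] = field(default_factory=dict)  # mean grams per food


@dataclass(frozen=True)
class MARResult:
    participant_id: str
    nar: Mapping[str, float]
    mar: float  # percent, 0-100


def aggregate_recalls(recalls: pd.DataFrame, foods: pd.DataFrame) -> pd.DataFrame:
    """Aggregate recall records to mean daily intakes per participant.

    ``recalls`` needs columns participant_id, day, food_id, grams; ``foods``
    is the composition table indexed (or keyed) by food_id with
    ``energy_kcal_per_100g`` and one column per nutrient (amount per 100 g).
    Per-day nutrient totals are grams/100 x density, then averaged over the
    participant's recall days.  Returns a frame indexed by participant_id
    with energy_kcal, total_grams, nutrient columns and ``group_<g>`` mean
    grams per food group.
    """
    food_idx = foods.set_index("food_id") if "food_id" in foods.columns else foods
    unknown = set(recalls["food_id"]) - set(food_idx.index)
    if unknown:
        raise ReferentialIntegrityError(unknown)
    if (recalls["grams"] < 0).any():
        raise DomainError("negative grams in recall records")

    nutrient_cols = [
        c for c in food_idx.columns
        if c not in ("name", "group", "energy_kcal_per_100g")
    ]
    comp = food_idx[["energy_kcal_per_100g", *nutrient_cols]]

    merged = recalls.merge(
        comp, left_on="food_id", right_index=True, how="left", validate="m:1"
    )
    per100 = merged["grams"].to_numpy(float) / 100.0
    day_totals = pd.DataFrame(
        {
            "energy_kcal": per100 * merged["energy_kcal_per_100g"].to_numpy(float),
            "total_grams": merged["grams"].to_numpy(float),
            **{n: per100 * merged[n].to_numpy(float) for n in nutrient_cols},
        },
        index=pd.MultiIndex.from_frame(merged[["participant_id", "day"]]),
    )
    by_day = day_totals.groupby(level=["participant_id", "day"]).sum()
    daily = by_day.groupby(level="participant_id").mean()

    group_map = food_idx["group"] if "group" in food_idx.columns else None
    if group_map is not None:
        gframe = pd.DataFrame(
            {
                "participant_id": merged["participant_id"],
                "day": merged["day"],
                "group": merged["food_id"].map(group_map),
                "grams": merged["grams"],
            }
        )
        by_group = (
            gframe.pivot_table(
                index=["participant_id", "day"], columns="group",
                values="grams", aggfunc="sum", fill_value=0.0,
            )
            .groupby(level="participant_id")
            .mean()
        )
        by_group.columns = [f"group_{g}" for g in by_group.columns]
        daily = daily.join(by_group)
    return daily


def intake_frame_to_daily(
    intakes: pd.DataFrame,
    recalls: pd.DataFrame | None = None,
) -> dict[str, DailyIntake]:
    """Convert an aggregated intake frame to :class:`DailyIntake` objects."""
    nutrient_cols = [
        c for c in intakes.columns
        if c not in ("energy_kcal", "total_grams") and not c.startswith("group_")
    ]
    food_means: dict[str, dict[str, float]] = {}
    if recalls is not None:
        per_day = recalls.groupby(["participant_id", "day", "food_id"])["grams"].sum()
        n_days = recalls.groupby("participant_id")["day"].nunique()
        totals = per_day.groupby(["participant_id", "food_id"]).sum()
        for (pid, fid), grams in totals.items():
            food_means.setdefault(pid, {})[fid] = grams / n_days[pid]
    out = {}
    for pid, row in intakes.iterrows():
        out[pid] = DailyIntake(
            participant_id=pid,
            energy_kcal=float(row["energy_kcal"]),
            total_grams=float(row["total_grams"]),
            nutrients={n: float(row[n]) for n in nutrient_cols},
            food_groups={
                c.removeprefix("group_"): float(row[c])
                for c in intakes.columns if c.startswith("group_")
            },
            foods=food_means.get(pid, {}),
        )
    return out


def exclude_implausible_energy(
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition participants by energy plausibility.

    Returns ``(retained, excluded)``; ``excluded`` carries the offending
    energy and which bound was violated.  The partition is exhaustive and
    disjoint: every input participant lands in exactly one frame.
    """
    bounds = dict(DEFAULT_ENERGY_BOUNDS if bounds is None else bounds)
    for sex, (lo, hi) in bounds.items():
        if not (0 < lo < hi):
            raise DomainError(f"invalid energy bounds for {sex}: ({lo}, {hi})")
    sex = participants.set_index("participant_id")["sex"].loc[intakes.index]
    lo = sex.map({s: b[0] for s, b in bounds.items()}).to_numpy(float)
    hi = sex.map({s: b[1] for s, b in bounds.items()}).to_numpy(float)
    energy = intakes["energy_kcal"].to_numpy(float)
    keep = (energy >= lo) & (energy <= hi)
    retained = intakes.loc[keep]
    excluded = intakes.loc[~keep, ["energy_kcal"]].copy()
    excluded["violated_bound"] = np.where(energy[~keep] < lo[~keep], "low", "high")
    excluded["bound_value"] = np.where(energy[~keep] < lo[~keep], lo[~keep], hi[~keep])
    return retained, excluded


def nar(intake: float, dri: float) -> float:
    """Nutrient adequacy ratio: intake over reference, truncated at 1."""
    if dri <= 0:
        raise DomainError(f"DRI must be positive, got {dri}")
    if intake < 0:
        raise DomainError(f"intake must be non-negative, got {intake}")
    return min(intake / dri, 1.0)


def mar(
    intake: DailyIntake,
    dri_table: ReferenceValueTable,
    sex: str,
    age_y: float,
    scale: str = "percent",
) -> MARResult:
    """Mean adequacy ratio over the fixed ten-nutrient panel.

    Energy counts like any other panel nutrient, with its NAR capped at 1.
    ``scale="unit"`` reports on 0-1 instead of the default 0-100.
    """
    nars = {}
    for nutrient in MAR_NUTRIENTS:
        dri = dri_table.lookup_dv(nutrient, sex, age_y)
        amount = intake.energy_kcal if nutrient == "energy" else intake.nutrients.get(nutrient, 0.0)
        nars[nutrient] = nar(amount, dri)
    value = float(np.mean(list(nars.values())))
    if scale == "percent":
        value *= 100.0
    elif scale != "unit":
        raise DomainError(f"unknown MAR scale {scale!r}")
    return MARResult(participant_id=intake.participant_id, nar=nars, mar=value)


def mar_frame(
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    dri_table: ReferenceValueTable,
    scale: str = "percent",
) -> pd.DataFrame:
    """Vectorised NAR/MAR for a whole cohort.

    Returns a frame indexed like ``intakes`` with one ``nar_<nutrient>``
    column per panel nutrient and a ``mar`` column.
    """
    part = participants.set_index("participant_id").loc[intakes.index]
    cache: dict[tuple[str, float], np.ndarray] = {}
    dri_rows = []
    for s, a in zip(part["sex"], part["age"]):
        key = (s, float(a))
        if key not in cache:
            cache[key] = np.array(
                [dri_table.lookup_dv(n, s, float(a)) for n in MAR_NUTRIENTS]
            )
        dri_rows.append(cache[key])
    dri = np.vstack(dri_rows)
    amounts = np.column_stack([
        intakes["energy_kcal"].to_numpy(float) if n == "energy"
        else (intakes[n].to_numpy(float) if n in intakes else np.zeros(len(intakes)))
        for n in MAR_NUTRIENTS
    ])
    nars = np.minimum(amounts / dri, 1.0)
    out = pd.DataFrame(
        nars, index=intakes.index, columns=[f"nar_{n}" for n in MAR_NUTRIENTS]
    )
    out["mar"] = nars.mean(axis=1) * (100.0 if scale == "percent" else 1.0)
    return out
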