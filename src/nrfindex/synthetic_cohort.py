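"""Seeded synthetic dietary cohort with the structure the analysis assumes.

The generator emulates a cross-sectional adult cohort assessed by two
non-consecutive 24-h recalls against a mixed food supply: part
nutrient-dense (high encouraged-nutrient density per 100 kcal, low saturated
fat and sodium), part energy-dense (the reverse).  Each participant carries
a latent diet-quality trait (standard normal) that tilts food selection
toward nutrient-dense foods; overweight is simulated from a logistic model
on that trait, with the slope calibrated by root-finding so the Q4-vs-Q1
odds ratio across quartiles of the realised NRF9.2 (sum, per 100 kcal) score
matches the requested value in expectation.  A configurable fraction of
participants is planted with implausible energy intake so exclusion
bookkeeping can be verified exactly, and a MAR link scales the four
adequacy-panel nutrients that no NRF variant uses (phosphorus, thiamin,
riboflavin, niacin) so the computed mean adequacy ratio follows a linear
model in a chosen driver plus noise.

All randomness flows from one seed through named substreams, so any stage
can be regenerated stably and outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import DomainError
from .intake_mar import DEFAULT_ENERGY_BOUNDS, MAR_NUTRIENTS, mar_frame
from .nrf_scoring import PRESETS, score_cohort
from .reference_values import ReferenceValueTable, load_default_table

__all__ = [
    "GeneratorConfig",
    "CohortBundle",
    "generate_food_table",
    "generate_cohort",
    "generate_mar_link",
]

FOOD_GROUPS_DENSE = ("vegetables", "fruits", "milk", "beans", "egg", "fish")
FOOD_GROUPS_ENERGY = ("cereals", "snacks", "meat", "poultry")
ALL_GROUPS = FOOD_GROUPS_DENSE + FOOD_GROUPS_ENERGY

ENCOURAGE_NUTRIENTS = (
    "protein", "fibre", "vitamin_a", "vitamin_c", "vitamin_e", "vitamin_b12",
    "calcium", "iron", "magnesium", "potassium", "zinc",
)
#: Panel nutrients free for the MAR link (not used by any NRF variant).
MAR_FREE_NUTRIENTS = ("phosphorus", "vitamin_b1", "vitamin_b2", "niacin")
ALL_NUTRIENTS = ENCOURAGE_NUTRIENTS + MAR_FREE_NUTRIENTS + ("sat_fat", "sodium")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror the cohort the pipeline is meant to analyse: 656 adults
    aged 25-75, two recall days, roughly 6.7% implausible-energy records,
    and a protective planted Q4-vs-Q1 overweight odds ratio of 0.61.
    """

    n_participants: int = 656
    n_foods: int = 40
    seed: int = 0
    frac_nutrient_dense: float = 0.5
    latent_effect_or: float = 0.61
    recall_noise_cv: float = 0.25
    outlier_fraction: float = 0.067
    mar_noise_sd: float = 5.0
    mar_link_intercept: float = 72.0
    mar_link_slope: float = 8.0
    n_days: int = 2
    overweight_prevalence: float = 0.42
    pref_latent_weight: float = 0.9
    pref_idiosyncratic_sd: float = 1.0
    consume_prob: float = 0.6

    def __post_init__(self) -> None:
        for name in ("frac_nutrient_dense", "outlier_fraction", "consume_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")
        if self.n_participants < 8:
            raise DomainError("need at least 8 participants")
        if self.latent_effect_or <= 0:
            raise DomainError("latent_effect_or must be positive")


@dataclass
class CohortBundle:
    """Generated inputs plus the planted ground truth for recovery tests."""

    participants: pd.DataFrame
    recalls: pd.DataFrame
    food_table: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# food supply
# ---------------------------------------------------------------------------

def generate_food_table(
    config: GeneratorConfig,
    dv_table: ReferenceValueTable | None = None,
) -> pd.DataFrame:
    """A mixed nutrient-dense / energy-dense food composition table.

    Nutrient amounts are drawn as per-100-kcal fractions of an adult daily
    value and converted to per-100-g amounts through each food's energy
    density, so density type is expressed in the nutrient-per-energy sense
    that the NRF per-100 kcal scores measure.
    """
    if config.n_foods < 10:
        raise DomainError("need at least 10 foods to cover the food groups")
    dv_table = dv_table or load_default_table()
    rng = _streams(config.seed, ("foods",))["foods"]
    n = config.n_foods

    n_dense = int(round(config.frac_nutrient_dense * n))
    dense = np.zeros(n, dtype=bool)
    dense[rng.permutation(n)[:n_dense]] = True

    groups = np.empty(n, dtype=object)
    for i in range(n):
        pool = FOOD_GROUPS_DENSE if dense[i] else FOOD_GROUPS_ENERGY
        if rng.random() < 0.2:
            pool = ALL_GROUPS
        groups[i] = pool[rng.integers(len(pool))]
    if n >= len(ALL_GROUPS):  # guarantee every group appears
        slots = rng.permutation(n)[: len(ALL_GROUPS)]
        for slot, g in zip(slots, ALL_GROUPS):
            groups[slot] = g

    energy = np.where(
        dense,
        np.exp(rng.normal(np.log(80.0), 0.45, n)),
        np.exp(rng.normal(np.log(330.0), 0.35, n)),
    )
    energy = np.clip(energy, 20.0, 650.0)

    # reference adult DVs used only to shape realistic magnitudes
    dv = np.array([dv_table.lookup_dv(nt, "male", 30.0) for nt in ENCOURAGE_NUTRIENTS + MAR_FREE_NUTRIENTS])
    frac_mean = np.where(dense, 0.10, 0.025)
    frac = np.exp(
        rng.normal(0.0, 0.9, (n, len(dv)))
    ) * frac_mean[:, None]
    frac = np.clip(frac, 0.0, 0.6)
    per_100kcal = frac * dv[None, :]

    sat_fat = np.where(dense, rng.uniform(0.05, 0.45, n), rng.uniform(0.4, 2.2, n))
    sodium = np.where(dense, rng.uniform(10.0, 130.0, n), rng.uniform(80.0, 500.0, n))

    to_100g = energy[:, None] / 100.0
    data = {
        "food_id": [f"F{i:04d}" for i in range(n)],
        "name": [f"{'dense' if dense[i] else 'energy'}_food_{i:04d}" for i in range(n)],
        "group": groups,
        "energy_kcal_per_100g": np.round(energy, 2),
    }
    nutrient_cols = ENCOURAGE_NUTRIENTS + MAR_FREE_NUTRIENTS
    amounts_100g = per_100kcal * to_100g
    for j, nt in enumerate(nutrient_cols):
        data[nt] = np.round(amounts_100g[:, j], 5)
    data["sat_fat"] = np.round(sat_fat * energy / 100.0, 5)
    data["sodium"] = np.round(sodium * energy / 100.0, 4)
    table = pd.DataFrame(data)
    table.attrs["dense"] = dense
    return table


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _calibrate_outcome(
    latent: np.ndarray,
    quartile_of: np.ndarray,
    target_or: float,
    prevalence: float,
) -> tuple[float, float]:
    """Intercept and slope of P(overweight) = expit(a + b z).

    ``quartile_of`` holds integer quartile indices (0-3) of the realised
    diet score for the same participants.  The slope is root-found so the
    expected odds ratio between the top and bottom quartile groups equals
    ``target_or`` while the intercept keeps overall expected prevalence.
    """

    q1 = quartile_of == 0
    q4 = quartile_of == 3

    def alpha_for(beta: float) -> float:
        return brentq(
            lambda a: expit(a + beta * latent).mean() - prevalence, -20.0, 20.0
        )

    def log_or(beta: float) -> float:
        a = alpha_for(beta)
        p = expit(a + beta * latent)
        p1, p4 = p[q1].mean(), p[q4].mean()
        return float(np.log(p4 / (1 - p4)) - np.log(p1 / (1 - p1)))

    if abs(np.log(target_or)) < 1e-12:
        return alpha_for(0.0), 0.0
    beta = brentq(lambda b: log_or(b) - np.log(target_or), -12.0, 12.0)
    return alpha_for(beta), beta


def generate_cohort(
    config: GeneratorConfig,
    food_table: pd.DataFrame,
    dv_table: ReferenceValueTable | None = None,
) -> CohortBundle:
    """Participants, two-day recall records, and the planted ground truth."""
    dv_table = dv_table or load_default_table()
    streams = _streams(
        config.seed,
        ("foods", "latent", "prefs", "grams", "outcome", "anthro", "covariates", "mar"),
    )
    n, n_days = config.n_participants, config.n_days
    foods = food_table.reset_index(drop=True)
    n_foods = len(foods)
    energy_density = foods["energy_kcal_per_100g"].to_numpy(float)

    rng = streams["latent"]
    pid = np.array([f"P{i:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = rng.integers(25, 76, n)
    latent = rng.standard_normal(n)

    # food quality direction: above-median encouraged-nutrient density helps
    dense_attr = food_table.attrs.get("dense")
    if dense_attr is not None:
        quality = np.where(np.asarray(dense_attr), 1.0, -1.0)
    else:
        enc_density = (
            foods[list(ENCOURAGE_NUTRIENTS)].to_numpy(float).sum(axis=1)
            / energy_density
        )
        quality = np.where(enc_density > np.median(enc_density), 1.0, -1.0)

    rng = streams["prefs"]
    base = rng.normal(0.0, 0.5, n_foods)
    utility = (
        base[None, :]
        + config.pref_latent_weight * latent[:, None] * quality[None, :]
        + rng.normal(0.0, config.pref_idiosyncratic_sd, (n, n_foods))
    )
    weights = np.exp(utility - utility.max(axis=1, keepdims=True))
    weights /= weights.sum(axis=1, keepdims=True)

    rng = streams["grams"]
    # per-day availability mask; guarantee >= 3 foods a day
    mask = rng.random((n, n_days, n_foods)) < config.consume_prob
    for p in range(n):
        for d in range(n_days):
            if mask[p, d].sum() < 3:
                mask[p, d, np.argsort(weights[p])[-3:]] = True
    raw = weights[:, None, :] * mask * np.exp(rng.normal(0.0, 0.3, (n, n_days, n_foods)))

    bounds_lo = np.where(sex == "male", DEFAULT_ENERGY_BOUNDS["male"][0], DEFAULT_ENERGY_BOUNDS["female"][0])
    bounds_hi = np.where(sex == "male", DEFAULT_ENERGY_BOUNDS["male"][1], DEFAULT_ENERGY_BOUNDS["female"][1])
    target = np.where(
        sex == "male", rng.normal(2200.0, 320.0, n), rng.normal(1750.0, 280.0, n)
    )
    target = np.clip(target, bounds_lo + 150.0, bounds_hi - 150.0)
    day_target = target[:, None] * (1.0 + config.recall_noise_cv * rng.standard_normal((n, n_days)))
    day_target = np.clip(day_target, (bounds_lo + 50.0)[:, None], (bounds_hi - 50.0)[:, None])

    n_out = int(round(config.outlier_fraction * n))
    outlier_ids = rng.choice(n, size=n_out, replace=False)
    high = outlier_ids[: n_out // 2]
    low = outlier_ids[n_out // 2:]
    day_target[high] = (bounds_hi[high] * rng.uniform(1.15, 1.6, len(high)))[:, None]
    day_target[low] = (bounds_lo[low] * rng.uniform(0.4, 0.85, len(low)))[:, None]

    raw_energy = raw @ (energy_density / 100.0)
    grams = raw * (day_target / raw_energy)[:, :, None]

    # mean daily intakes (matrix route; the pipeline recomputes from recalls)
    nutrient_cols = [c for c in foods.columns if c not in ("food_id", "name", "group", "energy_kcal_per_100g")]
    comp = foods[nutrient_cols].to_numpy(float) / 100.0
    mean_grams = grams.mean(axis=1)
    intake = pd.DataFrame(mean_grams @ comp, columns=nutrient_cols, index=pid)
    intake.insert(0, "energy_kcal", mean_grams @ (energy_density / 100.0))
    intake.insert(1, "total_grams", mean_grams.sum(axis=1))
    intake.index.name = "participant_id"

    participants = pd.DataFrame({"participant_id": pid, "sex": sex, "age": age})
    score = score_cohort(intake, participants, PRESETS["nrf9.2"], dv_table)

    plausible = np.ones(n, dtype=bool)
    plausible[outlier_ids] = False
    sc = score.to_numpy()[plausible]
    cuts = np.percentile(sc, [25, 50, 75])
    q_idx = np.searchsorted(cuts, sc, side="left")  # value == cut -> lower quartile
    alpha, beta = _calibrate_outcome(
        latent[plausible], q_idx, config.latent_effect_or, config.overweight_prevalence
    )

    rng = streams["outcome"]
    p_overweight = expit(alpha + beta * latent)
    overweight = rng.random(n) < p_overweight

    rng = streams["anthro"]
    bmi = np.where(
        overweight,
        np.clip(rng.normal(26.5, 2.0, n), 24.05, 37.0),
        np.clip(rng.normal(21.3, 1.5, n), 18.55, 23.9),
    )
    under = (~overweight) & (rng.random(n) < 0.07)
    bmi = np.where(under, np.clip(rng.normal(17.8, 0.5, n), 16.0, 18.4), bmi)
    height = np.where(sex == "male", rng.normal(170.0, 5.5, n), rng.normal(158.0, 5.2, n))
    height = np.clip(height, 145.0, 195.0)
    weight = bmi * (height / 100.0) ** 2
    wc = 2.5 * bmi + np.where(sex == "male", 22.0, 18.0) + rng.normal(0.0, 4.5, n)
    wc = np.clip(wc, 55.0, 150.0)
    hc = np.clip(60.0 + 0.45 * wc + rng.normal(0.0, 3.0, n), 70.0, 160.0)

    rng = streams["covariates"]
    edu_latent = latent + rng.normal(0.0, 2.0, n)
    education_band = np.digitize(edu_latent, [-1.5, 1.5]) + 1
    income_band = np.digitize(latent * 0.3 + rng.normal(0.0, 2.5, n), [-1.2, 1.8]) + 1
    activity_band = rng.integers(1, 5, n)
    nap_frequency = np.clip(rng.poisson(2.0, n), 0, 7)
    smoking = (rng.random(n) < np.where(sex == "male", 0.40, 0.05)).astype(int)
    life_pressure = (rng.random(n) < 0.4).astype(int)
    grip_normal = (rng.random(n) < 0.85).astype(int)
    sedentary_h = np.round(np.clip(rng.normal(6.0, 2.0, n), 0.5, 16.0), 1)
    family_number = np.clip(1 + rng.poisson(2.0, n), 1, 8)

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "age": age,
            "weight_kg": np.round(weight, 1),
            "height_cm": np.round(height, 1),
            "wc_cm": np.round(wc, 1),
            "hc_cm": np.round(hc, 1),
            "education_band": education_band,
            "income_band": income_band,
            "activity_band": activity_band,
            "nap_frequency": nap_frequency,
            "smoking": smoking,
            "life_pressure": life_pressure,
            "grip_normal": grip_normal,
            "sedentary_h": sedentary_h,
            "family_number": family_number,
        }
    )

    p_idx, d_idx, f_idx = np.nonzero(grams > 1e-9)
    recalls = pd.DataFrame(
        {
            "participant_id": pid[p_idx],
            "day": d_idx + 1,
            "food_id": foods["food_id"].to_numpy()[f_idx],
            "grams": np.round(grams[p_idx, d_idx, f_idx], 1),
        }
    )

    truth = {
        "planted_outlier_ids": sorted(pid[outlier_ids].tolist()),
        "latent": pd.Series(latent, index=pid),
        "alpha": alpha,
        "beta": beta,
        "target_or": config.latent_effect_or,
        "overweight_planted": pd.Series(overweight.astype(int), index=pid),
        "config": config,
    }
    return CohortBundle(
        participants=participants, recalls=recalls, food_table=foods, truth=truth
    )


# ---------------------------------------------------------------------------
# MAR link
# ---------------------------------------------------------------------------

def generate_mar_link(
    config: GeneratorConfig,
    intakes: pd.DataFrame,
    participants: pd.DataFrame,
    dv_table: ReferenceValueTable | None = None,
    driver: np.ndarray | pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale the free panel nutrients so MAR follows a planted linear model.

    The target is ``intercept + slope * standardised(driver) + noise``,
    truncated to the achievable MAR range given the untouched panel
    nutrients.  Only phosphorus, thiamin, riboflavin and niacin are scaled —
    nutrients outside every NRF variant — so the link never feeds back into
    the scores being validated.  Returns the adjusted intake frame and the
    recomputed MAR (percent scale).
    """
    dv_table = dv_table or load_default_table()
    if rng is None:
        rng = _streams(config.seed, ("foods", "latent", "prefs", "grams", "outcome", "anthro", "covariates", "mar"))["mar"]
    if driver is None:
        raise DomainError("a driver vector (latent trait or diet score) is required")
    drv = np.asarray(pd.Series(driver).loc[intakes.index] if isinstance(driver, pd.Series) else driver, dtype=float)
    if len(drv) != len(intakes):
        raise DomainError("driver length must match the intake frame")
    sd = drv.std()
    drv_std = (drv - drv.mean()) / (sd if sd > 0 else 1.0)
    target = config.mar_link_intercept + config.mar_link_slope * drv_std
    target = np.clip(target + rng.normal(0.0, config.mar_noise_sd, len(drv)), 0.0, 100.0)

    nars = mar_frame(intakes, participants, dv_table)
    fixed = [n for n in MAR_NUTRIENTS if n not in MAR_FREE_NUTRIENTS]
    fixed_sum = nars[[f"nar_{n}" for n in fixed]].to_numpy(float).sum(axis=1)
    need = np.clip(target / 10.0 - fixed_sum, 0.0, len(MAR_FREE_NUTRIENTS) - 1e-9)

    part = participants.set_index("participant_id").loc[intakes.index]
    dri = np.column_stack([
        [dv_table.lookup_dv(nt, s, float(a)) for s, a in zip(part["sex"], part["age"])]
        for nt in MAR_FREE_NUTRIENTS
    ])
    ratios = intakes[list(MAR_FREE_NUTRIENTS)].to_numpy(float) / dri
    ratios = np.maximum(ratios, 1e-12)

    # solve sum_j min(s * r_j, 1) = need, vectorised bisection on log s
    lo = np.full(len(drv), -30.0)
    hi = np.full(len(drv), 30.0)
    for _ in range(80):
        mid = (lo + hi) / 2.0
        val = np.minimum(np.exp(mid)[:, None] * ratios, 1.0).sum(axis=1)
        go_up = val < need
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    scale = np.exp((lo + hi) / 2.0)

    adjusted = intakes.copy()
    adjusted[list(MAR_FREE_NUTRIENTS)] = ratios * scale[:, None] * dri
    mar = mar_frame(adjusted, participants, dv_table)["mar"]
    return adjusted, mar


def simulate_bundle(config: GeneratorConfig) -> CohortBundle:
    """Convenience one-call generator: food table then cohort."""
    dv_table = load_default_table()
    foods = generate_food_table(config, dv_table)
    return generate_cohort(config, foods, dv_table)
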