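"""FFQ nutrient estimation, eating-behavior scoring, body-composition indices.

Daily nutrient intake is estimated from a food-frequency questionnaire
(FFQ) over food groups plus cooking-method items:

    intake = portion size (g) x amount-category weight x weekly frequency / 7
             x per-gram nutrient density

with amount-category weights No = 0, "A little" = 0.5, Normal = 1,
Plenty = 1.5.  Estimated salt is adjusted by the household salt-taste
item (x1.15 if equal to restaurant food, x1.3 if saltier), with sodium
co-scaled.  53 nutrient items are produced (42 integrated directly from
per-gram densities, 11 derived: %energy shares, equivalents, group-tag
ratios) plus seven class-ratio variables (animal/vegetable/fish oil
ratios, saturated/mono/poly fatty-acid ratios, n-6/n-3 ratio).

The composition table bundled here is synthetic — 29 food groups and 10
cooking items with plausible magnitudes — because licensed national food
composition tables cannot be redistributed.  A user table in the same
delimited schema can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_WEIGHTS",
    "SALT_MULTIPLIERS",
    "DENSITY_NUTRIENTS",
    "NUTRIENTS",
    "RATIO_FIELDS",
    "FoodCompositionTable",
    "FFQRecord",
    "NutrientProfile",
    "BehaviorRecord",
    "BodyComposition",
    "estimate_nutrient_intake",
    "adjust_salt",
    "score_eating_behavior",
    "compute_body_indices",
    "profiles_to_frame",
    "BEHAVIOR_CATEGORIES",
    "default_scale_map",
]

CATEGORY_WEIGHTS = {"No": 0.0, "A little": 0.5, "Normal": 1.0, "Plenty": 1.5}
SALT_MULTIPLIERS = {"lighter": 1.0, "equal": 1.15, "saltier": 1.3}

#: nutrient items integrated directly from per-gram densities
DENSITY_NUTRIENTS = [
    "energy_kcal", "water_g", "protein_g", "lipid_g", "fa_total_g",
    "saturated_fa_g", "cholesterol_mg", "monounsaturated_fa_g",
    "polyunsaturated_fa_g", "n3_polyunsaturated_fa_g",
    "n6_polyunsaturated_fa_g", "carbohydrate_g",
    "dietary_fiber_soluble_g", "dietary_fiber_insoluble_g",
    "retinol_ug", "alpha_carotene_ug", "beta_carotene_ug",
    "cryptoxanthin_ug", "vitamin_d_ug",
    "alpha_tocopherol_mg", "beta_tocopherol_mg", "gamma_tocopherol_mg",
    "delta_tocopherol_mg", "vitamin_k_ug", "vitamin_b1_mg", "vitamin_b2_mg",
    "niacin_mg", "vitamin_b6_mg", "vitamin_b12_ug", "folic_acid_ug",
    "pantothenic_acid_mg", "vitamin_c_mg", "mineral_g", "sodium_mg",
    "potassium_mg", "calcium_mg", "magnesium_mg", "phosphorus_mg",
    "iron_mg", "zinc_mg", "copper_mg", "manganese_mg",
]

#: items derived from the integrated ones (shares, equivalents, tag ratios)
DERIVED_NUTRIENTS = [
    "grain_pct_energy", "protein_pct_energy", "lipid_pct_energy",
    "carbohydrate_pct_energy", "animal_protein_ratio_pct",
    "deep_yellow_vegetable_ratio", "dietary_fiber_total_g",
    "beta_carotene_equivalent_ug", "retinol_equivalent_ug",
    "tocopherol_equivalent_mg", "salt_g",
]

#: the 53 estimated nutrient items
NUTRIENTS = DENSITY_NUTRIENTS + DERIVED_NUTRIENTS

RATIO_FIELDS = [
    "animal_oil_ratio", "vegetable_oil_ratio", "fish_oil_ratio",
    "saturated_fa_ratio", "monounsaturated_fa_ratio",
    "polyunsaturated_fa_ratio", "n6_n3_fa_ratio",
]

_TAG_COLUMNS = [
    "portion_size_g", "oil_class", "is_cooking", "is_grain",
    "is_vegetable", "is_deep_yellow_vegetable", "is_animal_protein",
]


class FoodCompositionTable:
    """Per-food-group portion sizes, class tags, and per-gram densities.

    Backed by a DataFrame indexed by food-group/cooking-item name with the
    tag columns ``portion_size_g``, ``oil_class`` (animal/vegetable/fish/
    none), ``is_cooking``, ``is_grain``, ``is_vegetable``,
    ``is_deep_yellow_vegetable``, ``is_animal_protein`` followed by one
    per-gram density column for each integrated nutrient.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _TAG_COLUMNS + DENSITY_NUTRIENTS if c not in frame.columns]
        if missing:
            raise ValueError(f"composition table missing columns: {missing}")
        if (frame["portion_size_g"] <= 0).any():
            bad = frame.index[frame["portion_size_g"] <= 0].tolist()
            raise ValueError(f"non-positive portion sizes: {bad}")
        dens = frame[DENSITY_NUTRIENTS].to_numpy(float)
        if (dens < 0).any():
            raise ValueError("negative nutrient densities")
        bad_oil = set(frame["oil_class"]) - {"animal", "vegetable", "fish", "none"}
        if bad_oil:
            raise ValueError(f"unknown oil classes: {sorted(bad_oil)}")
        self.frame = frame

    @property
    def food_groups(self) -> list[str]:
        return self.frame.index[~self.frame["is_cooking"].astype(bool)].tolist()

    @property
    def cooking_items(self) -> list[str]:
        return self.frame.index[self.frame["is_cooking"].astype(bool)].tolist()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="item")

    @classmethod
    def from_csv(cls, path) -> "FoodCompositionTable":
        return cls(pd.read_csv(path, index_col="item"))

    @classmethod
    def default(cls) -> "FoodCompositionTable":
        return _build_default_table()


# ---------------------------------------------------------------------------
# synthetic default composition table
# ---------------------------------------------------------------------------

# group: (portion g, kcal/100g, protein, lipid, carb g/100g, oil_class, tags)
# tags: g=grain v=vegetable y=deep-yellow a=animal-protein
_GROUPS: dict[str, tuple[float, float, float, float, float, str, str]] = {
    "rice":                    (150, 156,  2.5,  0.3, 36.0, "none", "g"),
    "bread":                   ( 60, 260,  9.0,  4.0, 47.0, "none", "g"),
    "noodles":                 (200, 130,  5.0,  0.8, 26.0, "none", "g"),
    "potatoes":                ( 80,  76,  1.8,  0.1, 17.5, "none", ""),
    "sugar_sweeteners":        ( 10, 390,  0.0,  0.0, 99.0, "none", ""),
    "confectionery":           ( 50, 420,  6.0, 18.0, 58.0, "vegetable", ""),
    "beans_soy":               ( 60, 140, 10.0,  7.0,  8.0, "vegetable", ""),
    "fish_shellfish":          ( 80, 130, 20.0,  5.0,  0.5, "fish", "a"),
    "small_fish":              ( 15, 300, 40.0, 10.0,  1.0, "fish", "a"),
    "fish_paste":              ( 40, 100, 12.0,  1.5,  9.5, "fish", "a"),
    "meat":                    ( 80, 220, 18.0, 16.0,  0.3, "animal", "a"),
    "processed_meat":          ( 30, 300, 14.0, 27.0,  2.5, "animal", "a"),
    "eggs":                    ( 50, 150, 12.0, 10.5,  0.4, "animal", "a"),
    "milk":                    (200,  65,  3.3,  3.8,  4.8, "animal", "a"),
    "dairy_products":          ( 80, 180,  9.0, 13.0,  5.0, "animal", "a"),
    "green_yellow_vegetables": ( 70,  30,  1.7,  0.2,  6.5, "none", "vy"),
    "other_vegetables":        ( 80,  22,  1.2,  0.1,  4.8, "none", "v"),
    "pickles":                 ( 20,  30,  1.5,  0.1,  6.0, "none", "v"),
    "fruits":                  (100,  55,  0.7,  0.2, 14.0, "none", ""),
    "citrus_fruits":           ( 80,  45,  0.8,  0.1, 11.0, "none", ""),
    "mushrooms":               ( 30,  18,  2.5,  0.3,  5.0, "none", ""),
    "seaweed":                 (  5, 140, 12.0,  2.0, 41.0, "none", ""),
    "fats_oils":               ( 10, 890,  0.0, 97.0,  0.2, "vegetable", ""),
    "butter":                  (  8, 730,  0.6, 81.0,  0.2, "animal", ""),
    "mayonnaise_dressing":     ( 12, 670,  1.5, 72.0,  3.5, "vegetable", ""),
    "sweet_beverages":         (200,  45,  0.0,  0.0, 11.0, "none", ""),
    "alcohol":                 (180,  70,  0.4,  0.0,  4.0, "none", ""),
    "miso_soup":               (150,  35,  2.5,  1.2,  4.5, "none", ""),
    "seasonings":              ( 15,  90,  4.0,  1.0, 15.0, "none", ""),
}

# cooking items: per-occasion grams of the seasoning/oil they add
_COOKING: dict[str, tuple[float, float, float, float, float, str]] = {
    # name: (grams/occasion, kcal/100g, protein, lipid, carb, oil_class)
    "boiled":         ( 2.0,  20, 0.5,  0.1,  4.0, "none"),
    "deep_fried":     (10.0, 890, 0.0, 97.0,  0.2, "vegetable"),
    "stir_fried":     ( 5.0, 890, 0.0, 97.0,  0.2, "vegetable"),
    "grilled":        ( 2.0, 120, 2.0,  1.0, 22.0, "none"),
    "steamed":        ( 1.0,  10, 0.3,  0.0,  2.0, "none"),
    "simmered":       ( 5.0, 110, 2.0,  0.5, 22.0, "none"),
    "soup":           ( 8.0,  40, 2.5,  0.5,  5.5, "none"),
    "raw_salad":      ( 6.0, 400, 1.0, 40.0,  8.0, "vegetable"),
    "dressed":        ( 5.0, 180, 3.0,  6.0, 26.0, "none"),
    "sweet_simmered": ( 6.0, 350, 0.5,  0.2, 85.0, "none"),
}

# fatty-acid split of lipid (sat, mono, poly fractions of FA total)
# and n-3 fraction of polyunsaturated FA, per oil class
_FA_SPLIT = {
    "animal":    (0.45, 0.40, 0.15, 0.20),
    "vegetable": (0.15, 0.40, 0.45, 0.12),
    "fish":      (0.25, 0.30, 0.45, 0.80),
    "none":      (0.30, 0.40, 0.30, 0.20),
}

# micronutrient per-100g typical densities and class boosts
_MICRO_BASE = {
    "cholesterol_mg": 5.0, "retinol_ug": 5.0, "alpha_carotene_ug": 10.0,
    "beta_carotene_ug": 40.0, "cryptoxanthin_ug": 10.0, "vitamin_d_ug": 0.1,
    "alpha_tocopherol_mg": 0.4, "beta_tocopherol_mg": 0.05,
    "gamma_tocopherol_mg": 0.3, "delta_tocopherol_mg": 0.1,
    "vitamin_k_ug": 8.0, "vitamin_b1_mg": 0.06, "vitamin_b2_mg": 0.08,
    "niacin_mg": 1.2, "vitamin_b6_mg": 0.1, "vitamin_b12_ug": 0.1,
    "folic_acid_ug": 25.0, "pantothenic_acid_mg": 0.5, "vitamin_c_mg": 5.0,
    "sodium_mg": 120.0, "potassium_mg": 180.0, "calcium_mg": 25.0,
    "magnesium_mg": 20.0, "phosphorus_mg": 80.0, "iron_mg": 0.7,
    "zinc_mg": 0.8, "copper_mg": 0.1, "manganese_mg": 0.2,
    "dietary_fiber_soluble_g": 0.3, "dietary_fiber_insoluble_g": 0.8,
}

_BOOSTS: list[tuple[str, tuple[str, ...], float]] = [
    ("vitamin_b12_ug",   ("fish_shellfish", "small_fish", "meat", "eggs", "milk", "dairy_products"), 20.0),
    ("vitamin_d_ug",     ("fish_shellfish", "small_fish", "eggs"), 60.0),
    ("retinol_ug",       ("eggs", "butter", "meat", "dairy_products"), 30.0),
    ("beta_carotene_ug", ("green_yellow_vegetables",), 80.0),
    ("alpha_carotene_ug", ("green_yellow_vegetables",), 40.0),
    ("cryptoxanthin_ug", ("citrus_fruits",), 40.0),
    ("vitamin_c_mg",     ("fruits", "citrus_fruits", "green_yellow_vegetables", "other_vegetables", "potatoes"), 8.0),
    ("calcium_mg",       ("milk", "dairy_products", "small_fish", "seaweed"), 8.0),
    ("iron_mg",          ("meat", "beans_soy", "seaweed", "small_fish"), 4.0),
    ("cholesterol_mg",   ("eggs",), 80.0),
    ("cholesterol_mg",   ("meat", "processed_meat", "fish_shellfish", "butter"), 15.0),
    ("sodium_mg",        ("pickles", "seasonings", "miso_soup", "processed_meat", "fish_paste", "soup", "dressed"), 12.0),
    ("folic_acid_ug",    ("green_yellow_vegetables", "beans_soy"), 5.0),
    ("vitamin_b1_mg",    ("meat", "beans_soy"), 6.0),
    ("niacin_mg",        ("fish_shellfish", "meat", "mushrooms"), 5.0),
    ("vitamin_k_ug",     ("green_yellow_vegetables", "beans_soy", "seaweed"), 10.0),
    ("alpha_tocopherol_mg", ("fats_oils", "mayonnaise_dressing", "small_fish"), 15.0),
    ("gamma_tocopherol_mg", ("fats_oils", "beans_soy", "mayonnaise_dressing"), 12.0),
    ("dietary_fiber_soluble_g", ("seaweed", "fruits", "beans_soy"), 4.0),
    ("dietary_fiber_insoluble_g", ("green_yellow_vegetables", "other_vegetables", "beans_soy", "mushrooms", "seaweed"), 4.0),
    ("potassium_mg",     ("potatoes", "fruits", "green_yellow_vegetables", "beans_soy"), 2.5),
]


def _build_default_table() -> FoodCompositionTable:
    rows = {}
    rng = np.random.default_rng(20130515)  # fixed: the table is a constant
    items = {**_GROUPS}
    for name, (g, kcal, pro, lip, carb, oil) in _COOKING.items():
        items[name] = (g, kcal, pro, lip, carb, oil, "cook")
    for name, (portion, kcal, pro, lip, carb, oil, tags) in items.items():
        row = {
            "portion_size_g": portion,
            "oil_class": oil,
            "is_cooking": tags == "cook",
            "is_grain": "g" in tags and tags != "cook",
            "is_vegetable": "v" in tags,
            "is_deep_yellow_vegetable": "y" in tags,
            "is_animal_protein": "a" in tags,
        }
        per100 = {
            "energy_kcal": kcal, "protein_g": pro, "lipid_g": lip,
            "carbohydrate_g": carb, "mineral_g": 1.0,
        }
        fa_total = 0.95 * lip
        sat, mono, poly, n3f = _FA_SPLIT[oil]
        per100.update(
            fa_total_g=fa_total, saturated_fa_g=sat * fa_total,
            monounsaturated_fa_g=mono * fa_total,
            polyunsaturated_fa_g=poly * fa_total,
            n3_polyunsaturated_fa_g=n3f * poly * fa_total,
            n6_polyunsaturated_fa_g=(1 - n3f) * poly * fa_total,
        )
        for micro, base in _MICRO_BASE.items():
            boost = 1.0
            for target, names, factor in _BOOSTS:
                if target == micro and name in names:
                    boost *= factor
            jitter = rng.lognormal(0.0, 0.25)
            per100[micro] = base * boost * jitter
        per100["water_g"] = max(0.0, 100.0 - pro - lip - carb - 1.0)
        rows[name] = {**row, **{k: v / 100.0 for k, v in per100.items()}}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "item"
    return FoodCompositionTable(frame[_TAG_COLUMNS + DENSITY_NUTRIENTS])


# ---------------------------------------------------------------------------
# FFQ records and intake estimation
# ---------------------------------------------------------------------------

@dataclass
class FFQRecord:
    """One subject's food-frequency questionnaire responses."""

    subject_id: str
    amounts: dict[str, str]            # food group -> amount category
    frequencies: dict[str, float]      # food group -> times/week
    cooking: dict[str, float] = field(default_factory=dict)  # type -> times/week
    salt_taste: str = "lighter"

    def __post_init__(self) -> None:
        bad_cat = {g: c for g, c in self.amounts.items() if c not in CATEGORY_WEIGHTS}
        if bad_cat:
            raise ValueError(f"unknown amount categories: {bad_cat}")
        for src in (self.frequencies, self.cooking):
            for k, f in src.items():
                if not np.isfinite(f) or f < 0:
                    raise ValueError(f"invalid weekly frequency for {k!r}: {f}")
        if self.salt_taste not in SALT_MULTIPLIERS:
            raise ValueError(f"unknown salt-taste category {self.salt_taste!r}")


@dataclass
class NutrientProfile:
    """Estimated daily intakes (53 items) plus the seven class ratios."""

    subject_id: str
    intakes: pd.Series   # indexed by NUTRIENTS
    ratios: pd.Series    # indexed by RATIO_FIELDS

    def __post_init__(self) -> None:
        if (self.intakes < -1e-12).any():
            raise ValueError("negative nutrient intake")
        bounded = self.ratios.drop("n6_n3_fa_ratio")
        if ((bounded < -1e-12) | (bounded > 1 + 1e-12)).any():
            raise ValueError("class ratio outside [0, 1]")
        if self.ratios["n6_n3_fa_ratio"] < -1e-12:
            raise ValueError("negative n-6/n-3 ratio")

    def to_series(self) -> pd.Series:
        s = pd.concat([self.intakes, self.ratios])
        s.name = self.subject_id
        return s


def adjust_salt(base_salt_g: float, taste: str) -> float:
    """Scale estimated salt by the household salt-taste multiplier."""
    if base_salt_g < 0:
        raise ValueError("base salt must be >= 0")
    try:
        return base_salt_g * SALT_MULTIPLIERS[taste]
    except KeyError:
        raise ValueError(f"unknown salt-taste category {taste!r}") from None


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def estimate_nutrient_intake(
    record: FFQRecord, table: FoodCompositionTable
) -> NutrientProfile:
    """Estimate one subject's daily nutrient profile from FFQ responses."""
    frame = table.frame
    unknown = [g for g in record.frequencies if g not in frame.index]
    unknown += [c for c in record.cooking if c not in frame.index]
    if unknown:
        raise KeyError(f"food groups absent from composition table: {unknown}")

    grams = pd.Series(0.0, index=frame.index)
    for group, freq in record.frequencies.items():
        weight = CATEGORY_WEIGHTS[record.amounts.get(group, "Normal")]
        grams[group] = frame.at[group, "portion_size_g"] * weight * freq / 7.0
    for item, freq in record.cooking.items():
        grams[item] = frame.at[item, "portion_size_g"] * freq / 7.0

    dens = frame[DENSITY_NUTRIENTS]
    intakes = pd.Series(grams.to_numpy() @ dens.to_numpy(float), index=DENSITY_NUTRIENTS)

    energy = intakes["energy_kcal"]
    grain_energy = float(
        grams[frame["is_grain"]] @ dens.loc[frame["is_grain"], "energy_kcal"]
    )
    animal_protein = float(
        grams[frame["is_animal_protein"]]
        @ dens.loc[frame["is_animal_protein"], "protein_g"]
    )
    veg_g = float(grams[frame["is_vegetable"]].sum())
    dyv_g = float(grams[frame["is_deep_yellow_vegetable"]].sum())

    salt_factor = SALT_MULTIPLIERS[record.salt_taste]
    sodium = intakes["sodium_mg"] * salt_factor
    intakes["sodium_mg"] = sodium

    derived = {
        # Atwater shares of total energy from the table's own energy column
        "grain_pct_energy": _ratio(grain_energy, energy) * 100.0,
        "protein_pct_energy": _ratio(4.0 * intakes["protein_g"], energy) * 100.0,
        "lipid_pct_energy": _ratio(9.0 * intakes["lipid_g"], energy) * 100.0,
        "carbohydrate_pct_energy": _ratio(4.0 * intakes["carbohydrate_g"], energy) * 100.0,
        "animal_protein_ratio_pct": _ratio(animal_protein, intakes["protein_g"]) * 100.0,
        "deep_yellow_vegetable_ratio": _ratio(dyv_g, veg_g),
        "dietary_fiber_total_g": intakes["dietary_fiber_soluble_g"]
        + intakes["dietary_fiber_insoluble_g"],
        "beta_carotene_equivalent_ug": intakes["beta_carotene_ug"]
        + 0.5 * intakes["alpha_carotene_ug"] + 0.5 * intakes["cryptoxanthin_ug"],
        "tocopherol_equivalent_mg": intakes["alpha_tocopherol_mg"]
        + 0.4 * intakes["beta_tocopherol_mg"] + 0.1 * intakes["gamma_tocopherol_mg"]
        + 0.01 * intakes["delta_tocopherol_mg"],
        "salt_g": sodium * 2.54 / 1000.0,  # NaCl equivalent of (scaled) sodium
    }
    derived["retinol_equivalent_ug"] = (
        intakes["retinol_ug"] + derived["beta_carotene_equivalent_ug"] / 12.0
    )
    all_intakes = pd.concat([intakes, pd.Series(derived)])[NUTRIENTS]

    oil = {"animal": 0.0, "vegetable": 0.0, "fish": 0.0}
    lip_dens = dens["lipid_g"].to_numpy(float)
    for cls in oil:
        mask = (frame["oil_class"] == cls).to_numpy()
        oil[cls] = float(grams.to_numpy()[mask] @ lip_dens[mask])
    total_oil = sum(oil.values())
    fa_total = intakes["fa_total_g"]
    ratios = pd.Series(
        {
            "animal_oil_ratio": _ratio(oil["animal"], total_oil),
            "vegetable_oil_ratio": _ratio(oil["vegetable"], total_oil),
            "fish_oil_ratio": _ratio(oil["fish"], total_oil),
            "saturated_fa_ratio": _ratio(intakes["saturated_fa_g"], fa_total),
            "monounsaturated_fa_ratio": _ratio(intakes["monounsaturated_fa_g"], fa_total),
            "polyunsaturated_fa_ratio": _ratio(intakes["polyunsaturated_fa_g"], fa_total),
            "n6_n3_fa_ratio": _ratio(
                intakes["n6_polyunsaturated_fa_g"], intakes["n3_polyunsaturated_fa_g"]
            ),
        }
    )[RATIO_FIELDS]
    return NutrientProfile(record.subject_id, all_intakes, ratios)


def profiles_to_frame(profiles: list[NutrientProfile]) -> pd.DataFrame:
    """Stack profiles into an (n_subjects x 60) analysis matrix."""
    return pd.DataFrame([p.to_series() for p in profiles])


# ---------------------------------------------------------------------------
# eating behavior
# ---------------------------------------------------------------------------

BEHAVIOR_CATEGORIES = [
    "recognition_of_weight", "external_eating", "emotional_eating",
    "sense_of_hunger", "eating_style", "food_preference",
    "regularity_of_habits",
]

N_BEHAVIOR_ITEMS = 55


def default_scale_map() -> list[str]:
    """Item -> category assignment: near-even split of the 55 items
    (8,8,8,8,8,8,7).  The published item sets live in a supplementary
    source not reproduced here, so the map is configurable."""
    sizes = [8, 8, 8, 8, 8, 8, 7]
    out: list[str] = []
    for cat, size in zip(BEHAVIOR_CATEGORIES, sizes):
        out.extend([cat] * size)
    return out


@dataclass
class BehaviorRecord:
    """55 four-point eating-behavior items with their category map."""

    subject_id: str
    responses: dict[int, int]                 # item index (0-54) -> 1..4
    scale_map: list[str] = field(default_factory=default_scale_map)

    def __post_init__(self) -> None:
        if len(self.scale_map) != N_BEHAVIOR_ITEMS:
            raise ValueError("scale map must assign all 55 items")
        if set(self.scale_map) - set(BEHAVIOR_CATEGORIES):
            raise ValueError("scale map contains unknown categories")
        bad = {i: r for i, r in self.responses.items() if r not in (1, 2, 3, 4)}
        if bad:
            raise ValueError(f"responses outside the 1-4 scale: {bad}")


def score_eating_behavior(record: BehaviorRecord) -> pd.Series:
    """Per-category sum scores plus the total over all 55 items.

    Missing items are rejected (no imputation)."""
    missing = [i for i in range(N_BEHAVIOR_ITEMS) if i not in record.responses]
    if missing:
        raise ValueError(f"unanswered behavior items: {missing}")
    scores = dict.fromkeys(BEHAVIOR_CATEGORIES, 0)
    for i in range(N_BEHAVIOR_ITEMS):
        scores[record.scale_map[i]] += record.responses[i]
    scores["total"] = sum(record.responses[i] for i in range(N_BEHAVIOR_ITEMS))
    out = pd.Series(scores, dtype=float)
    out.name = record.subject_id
    return out


# ---------------------------------------------------------------------------
# body composition
# ---------------------------------------------------------------------------

@dataclass
class BodyComposition:
    """Measured body composition with derived indices.

    FFMI (fat-free mass / height^2) and FMI (fat mass / height^2) sum to
    the BMI exactly because fat mass + fat-free mass = weight.
    """

    subject_id: str
    weight_kg: float
    height_m: float
    fat_mass_kg: float
    fat_free_mass_kg: float | None = None
    muscle_mass_kg: float | None = None
    bmi: float | None = None
    fat_pct: float | None = None
    ffmi: float | None = None
    fmi: float | None = None

    def __post_init__(self) -> None:
        if self.fat_free_mass_kg is None:
            self.fat_free_mass_kg = self.weight_kg - self.fat_mass_kg
        elif abs(self.fat_mass_kg + self.fat_free_mass_kg - self.weight_kg) > 1e-9:
            raise ValueError("fat mass + fat-free mass must equal weight")
        if self.muscle_mass_kg is None:
            self.muscle_mass_kg = self.fat_free_mass_kg

    def to_series(self) -> pd.Series:
        s = pd.Series(
            {
                "weight_kg": self.weight_kg, "height_m": self.height_m,
                "fat_mass_kg": self.fat_mass_kg,
                "fat_free_mass_kg": self.fat_free_mass_kg,
                "muscle_mass_kg": self.muscle_mass_kg,
                "bmi": self.bmi, "fat_pct": self.fat_pct,
                "ffmi": self.ffmi, "fmi": self.fmi,
            }
        )
        s.name = self.subject_id
        return s


def compute_body_indices(raw: BodyComposition) -> BodyComposition:
    """Fill BMI, body fat %, FFMI and FMI from the measured fields."""
    if raw.height_m <= 0 or raw.weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    h2 = raw.height_m**2
    raw.bmi = raw.weight_kg / h2
    raw.fat_pct = 100.0 * raw.fat_mass_kg / raw.weight_kg
    raw.ffmi = raw.fat_free_mass_kg / h2
    raw.fmi = raw.fat_mass_kg / h2
    return raw
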