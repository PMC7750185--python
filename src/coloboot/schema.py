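"""Variable vocabularies for the colostrum-sample table.

The analysis table has one row per colostrum sample.  Thirteen modelling
variables are available as fixed effects: the 3-level collection source, one
continuous variable (days between calving-pen clean-outs) and eleven
management practices recorded by farmer questionnaire.  Management practices
that are undefined for a sample — e.g. the feeding-equipment cleaning method
for a sample collected straight from the cow's teat — carry the structural
level ``"Not applicable"``.

Reference levels are fixed so that coefficients read as contrasts against the
hygienic/default practice: ``"Cows teat"`` for the collection source,
``"Not applicable"`` (i.e. teat-collected) for the milking system, ``"Water"``
for cleaning methods, ``"Each use"``/``"Each calf"`` for cleaning frequencies
and ``"No"`` for binary practices.

Level frequencies are the observed per-sample percentages of the 56-farm
study population and drive the synthetic-data generator's defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

NOT_APPLICABLE = "Not applicable"

#: raw collection points as recorded on the submission form
COLLECTION_POINTS = (
    "Cows teat",
    "Colostrum collection bucket",
    "Feeding teat",
    "Esophageal tube",
)

#: modelling variable: where in the harvest/feed chain the sample was drawn
COLLECTION_SOURCE_MAP = {
    "Cows teat": "Cows teat",
    "Colostrum collection bucket": "Collection equipment",
    "Feeding teat": "Feeding equipment",
    "Esophageal tube": "Feeding equipment",
}

#: structural-applicability rules: when a variable is forced to Not applicable
NA_WHEN_TEAT = "teat"            # undefined for teat-collected samples
NA_WHEN_NO_FEEDING = "teat_or_bucket"  # undefined unless sample passed feeding kit


@dataclass(frozen=True)
class Variable:
    """One modelling covariate: its kind, level vocabulary and reference."""

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] = ()
    reference: str | None = None
    na_rule: str | None = None
    #: observed marginal per-sample frequencies (proportions, incl. the
    #: structural Not-applicable share); generator default
    freqs: dict[str, float] = field(default_factory=dict)
    #: raw levels remapped during releveling (coarsened cleaning frequencies)
    relevel: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if self.reference not in self.levels:
                raise ValueError(
                    f"{self.name}: reference {self.reference!r} not in levels"
                )
            if self.freqs and set(self.freqs) != set(self.levels):
                raise ValueError(f"{self.name}: freqs/levels mismatch")

    @property
    def nonref_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


_CLEAN_METHOD_LEVELS = (
    "Water",
    "Hypochlorite",
    "Parlor wash",
    "Peracetic acid",
    "Soap",
    NOT_APPLICABLE,
)

VARIABLES: tuple[Variable, ...] = (
    Variable(
        "collection_source",
        "categorical",
        ("Cows teat", "Collection equipment", "Feeding equipment"),
        reference="Cows teat",
        freqs={
            "Cows teat": 0.178,
            "Collection equipment": 0.363,
            "Feeding equipment": 0.440,
        },
    ),
    Variable("days_calving_pen_cleanout", "continuous"),
    Variable(
        "premilking_teat_disinfection",
        "categorical",
        ("No", "Yes"),
        reference="No",
        freqs={"No": 0.174, "Yes": 0.826},
    ),
    Variable(
        "teat_dry_wiped",
        "categorical",
        ("No", "Yes"),
        reference="No",
        freqs={"No": 0.177, "Yes": 0.823},
    ),
    Variable(
        "milking_system",
        "categorical",
        (NOT_APPLICABLE, "Parlor", "Robot"),
        reference=NOT_APPLICABLE,  # teat-collected samples use no machine
        na_rule=NA_WHEN_TEAT,
        freqs={"Parlor": 0.670, "Robot": 0.152, NOT_APPLICABLE: 0.178},
    ),
    Variable(
        "collection_cleaning_freq",
        "categorical",
        ("Each use", "Less than each use", NOT_APPLICABLE),
        reference="Each use",
        na_rule=NA_WHEN_TEAT,
        freqs={"Each use": 0.210, "Less than each use": 0.612, NOT_APPLICABLE: 0.178},
        relevel={"Daily": "Less than each use", "Less than daily": "Less than each use"},
    ),
    Variable(
        "collection_cleaning_method",
        "categorical",
        _CLEAN_METHOD_LEVELS,
        reference="Water",
        na_rule=NA_WHEN_TEAT,
        freqs={
            "Water": 0.241,
            "Hypochlorite": 0.165,
            "Parlor wash": 0.287,
            "Peracetic acid": 0.095,
            "Soap": 0.037,
            NOT_APPLICABLE: 0.178,
        },
    ),
    Variable(
        "collection_hot_water",
        "categorical",
        ("No", "Yes", NOT_APPLICABLE),
        reference="No",
        na_rule=NA_WHEN_TEAT,
        freqs={"No": 0.381, "Yes": 0.442, NOT_APPLICABLE: 0.178},
    ),
    Variable(
        "feeding_cleaning_freq",
        "categorical",
        ("Each calf", "Less than each calf", NOT_APPLICABLE),
        reference="Each calf",
        na_rule=NA_WHEN_NO_FEEDING,
        freqs={"Each calf": 0.311, "Less than each calf": 0.149, NOT_APPLICABLE: 0.540},
        relevel={"Daily": "Less than each calf", "Less than daily": "Less than each calf"},
    ),
    Variable(
        "feeding_cleaning_method",
        "categorical",
        _CLEAN_METHOD_LEVELS,
        reference="Water",
        na_rule=NA_WHEN_NO_FEEDING,
        freqs={
            "Water": 0.104,
            "Hypochlorite": 0.137,
            "Parlor wash": 0.073,
            "Peracetic acid": 0.073,
            "Soap": 0.073,
            NOT_APPLICABLE: 0.540,
        },
    ),
    Variable(
        "feeding_hot_water",
        "categorical",
        ("No", "Yes", NOT_APPLICABLE),
        reference="No",
        na_rule=NA_WHEN_NO_FEEDING,
        freqs={"No": 0.149, "Yes": 0.311, NOT_APPLICABLE: 0.540},
    ),
    Variable(
        "colostrum_frozen",
        "categorical",
        ("No", "Yes", NOT_APPLICABLE),
        reference="No",
        na_rule=NA_WHEN_TEAT,
        freqs={"No": 0.780, "Yes": 0.043, NOT_APPLICABLE: 0.178},
    ),
    Variable(
        "pasteuriser_used",
        "categorical",
        ("No", "Yes", NOT_APPLICABLE),
        reference="No",
        na_rule=NA_WHEN_TEAT,
        freqs={"No": 0.789, "Yes": 0.034, NOT_APPLICABLE: 0.178},
    ),
)

VARIABLES_BY_NAME: dict[str, Variable] = {v.name: v for v in VARIABLES}

#: sample-level frequencies of the raw collection point (generator default)
COLLECTION_POINT_FREQS = {
    "Cows teat": 0.178,
    "Colostrum collection bucket": 0.363,
    "Feeding teat": 0.244,
    "Esophageal tube": 0.216,
}

MODEL_TERMS: tuple[str, ...] = tuple(v.name for v in VARIABLES)
CONTINUOUS_TERMS: tuple[str, ...] = tuple(
    v.name for v in VARIABLES if v.kind == "continuous"
)

#: columns every raw sample CSV must carry
RAW_COLUMNS = (
    ["farm_id", "cow_id", "collection_point"]
    + [v.name for v in VARIABLES if v.name != "collection_source"]
    + ["tbc", "cc"]
)


def term_label(term: str, level: str | None) -> str:
    """Canonical ``variable:Level`` key used for effects and coefficients."""
    return term if level is None else f"{term}:{level}"


def parse_term_label(label: str) -> tuple[str, str | None]:
    if ":" in label:
        term, level = label.split(":", 1)
        return term, level
    return label, None


def schema_dict() -> dict:
    """Machine-readable description of the sample-table schema."""
    return {
        "collection_points": list(COLLECTION_POINTS),
        "collection_source_map": dict(COLLECTION_SOURCE_MAP),
        "variables": [
            {
                "name": v.name,
                "kind": v.kind,
                "levels": list(v.levels),
                "reference": v.reference,
                "na_rule": v.na_rule,
                "frequencies": dict(v.freqs),
                "relevel": dict(v.relevel),
            }
            for v in VARIABLES
        ],
        "raw_columns": list(RAW_COLUMNS),
    }


def write_schema_json(path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(schema_dict(), fh, indent=2)
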