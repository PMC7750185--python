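"""Synthetic herd-data generator with known ground truth.

Emulates a multi-farm colostrum bacteriology study: farms carry management
practices (cleaning chemistry, hot-water use, milking system, ...) that are
farm-level properties shared by all of a farm's samples, while the collection
point varies sample by sample.  Log-scale outcomes follow the random-intercept
linear model

    y_ij = mu + x_ij' beta + U_j + eps_ij,
    U_j ~ N(0, theta_U),  eps_ij ~ N(0, theta_eps),

and counts are produced as ``max(0, round(exp(y) - 1))`` so that the analysis
transform ``ln(x + 1)`` inverts the generator up to integer rounding.
Coliform counts are generated the same way from their own intercept and farm
effects and are additionally replaced by structural zeros with probability
``cc_zero_prob``, reproducing the observed excess of zero coliform counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import (
    COLLECTION_POINT_FREQS,
    COLLECTION_SOURCE_MAP,
    NOT_APPLICABLE,
    NA_WHEN_NO_FEEDING,
    NA_WHEN_TEAT,
    VARIABLES,
    VARIABLES_BY_NAME,
    parse_term_label,
    term_label,
)

#: realistic default effect sizes (log cfu/ml) for the management practices
#: most strongly associated with total bacterial counts in a 56-farm GB study
DEFAULT_TRUE_EFFECTS: dict[str, float] = {
    "milking_system:Parlor": 2.06,
    "milking_system:Robot": 3.38,
    "collection_source:Feeding equipment": 2.36,
    "feeding_hot_water:Yes": -2.54,
    "collection_cleaning_method:Hypochlorite": -1.60,
    "collection_cleaning_method:Peracetic acid": -2.04,
    "collection_cleaning_freq:Less than each use": 1.75,
    "teat_dry_wiped:Yes": -1.97,
    "pasteuriser_used:Yes": -3.79,
}

#: range (days) of calving-pen clean-out intervals observed across farms
DAYS_CLEANOUT_RANGE = (3.5, 90.0)


def _uniform_sd(lo: float, hi: float) -> float:
    return (hi - lo) / np.sqrt(12.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generative parameters for one synthetic study.

    Defaults mimic the study dimensions (56 farms, 6 samples each) and give a
    marginal log-TBC standard deviation of ~3.3 log cfu/ml.
    """

    n_farms: int = 56
    samples_per_farm: int = 6
    mu: float = 6.3          # log-TBC intercept (teat-collected baseline)
    mu_cc: float = 1.0       # log-CC intercept
    true_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS)
    )
    true_effects_cc: dict[str, float] | None = None  # None -> reuse true_effects
    theta_U: float = 2.0     # between-farm variance, log scale
    theta_eps: float = 4.0   # residual variance, log scale
    level_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    collection_point_freqs: dict[str, float] = field(
        default_factory=lambda: dict(COLLECTION_POINT_FREQS)
    )
    cc_zero_prob: float = 0.40
    #: "farm": management practices shared by all of a farm's samples
    #: (questionnaire protocols are farm properties); "sample": drawn
    #: independently per sample (covariates then carry no chance herd-level
    #: confounding with the farm random effects).
    covariate_sharing: str = "farm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariate_sharing not in ("farm", "sample"):
            raise ValueError("covariate_sharing must be 'farm' or 'sample'")
        if self.n_farms < 2:
            raise ValueError("n_farms must be >= 2 (farm variance unidentifiable)")
        if self.samples_per_farm < 1:
            raise ValueError("samples_per_farm must be >= 1")
        if self.theta_U < 0 or self.theta_eps < 0:
            raise ValueError("variances must be >= 0")
        if not 0.0 <= self.cc_zero_prob <= 1.0:
            raise ValueError("cc_zero_prob must lie in [0, 1]")
        for name, freqs in self.effective_level_freqs().items():
            total = sum(freqs.values())
            if any(p < 0 for p in freqs.values()):
                raise ValueError(f"{name}: negative probability")
            if abs(total - 1.0) > 5e-3:
                raise ValueError(f"{name}: probabilities sum to {total}, not 1")
        cp_total = sum(self.collection_point_freqs.values())
        if abs(cp_total - 1.0) > 5e-3:
            raise ValueError("collection point probabilities must sum to 1")
        for key in self.all_true_effects():
            term, level = parse_term_label(key)
            var = VARIABLES_BY_NAME.get(term)
            if var is None:
                raise ValueError(f"true effect refers to unknown variable: {key}")
            if var.kind == "categorical":
                if level is None or level not in var.levels:
                    raise ValueError(f"true effect refers to unknown level: {key}")
                if level == var.reference:
                    raise ValueError(f"reference level cannot carry an effect: {key}")
            elif level is not None:
                raise ValueError(f"continuous effect must be keyed by name: {key}")

    def effective_level_freqs(self) -> dict[str, dict[str, float]]:
        """Marginal level frequencies per variable, config overrides applied.

        Values are printed to one decimal of a percent, so each vector is
        re-normalised before use.
        """
        out: dict[str, dict[str, float]] = {}
        for var in VARIABLES:
            if var.kind != "categorical" or var.name == "collection_source":
                continue
            freqs = dict(self.level_freqs.get(var.name, var.freqs))
            out[var.name] = freqs
        return out

    def all_true_effects(self) -> dict[str, float]:
        eff = dict(self.true_effects)
        if self.true_effects_cc is not None:
            eff.update(self.true_effects_cc)
        return eff


def true_effect_table(config: SimulationConfig, outcome: str = "tbc") -> dict[str, float]:
    """Full per-level coefficient table used by the generator, with reference
    levels carrying 0 by construction."""
    effects = (
        dict(config.true_effects)
        if outcome == "tbc" or config.true_effects_cc is None
        else dict(config.true_effects_cc)
    )
    table: dict[str, float] = {}
    for var in VARIABLES:
        if var.kind == "continuous":
            table[var.name] = float(effects.get(var.name, 0.0))
            continue
        for level in var.levels:
            key = term_label(var.name, level)
            table[key] = 0.0 if level == var.reference else float(effects.get(key, 0.0))
    return table


def _normalized(freqs: dict[str, float]) -> tuple[list[str], np.ndarray]:
    levels = list(freqs)
    p = np.array([freqs[l] for l in levels], dtype=float)
    return levels, p / p.sum()


def _conditional_freqs(var, freqs: dict[str, float]) -> tuple[list[str], np.ndarray]:
    """Frequencies among applicable samples: drop the structural NA share and
    renormalise, giving the practice mix of farms where the variable applies."""
    applicable = {l: p for l, p in freqs.items() if l != NOT_APPLICABLE}
    return _normalized(applicable)


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Draw one synthetic study as a raw sample table.

    Management practices are drawn once per farm from the applicable-level
    frequency mix; the collection point is drawn per sample; structural
    applicability is then enforced record by record, which in expectation
    reproduces the marginal level frequencies (including the Not-applicable
    shares) of the study population.
    """
    rng = np.random.default_rng(config.seed)
    n_farms, m = config.n_farms, config.samples_per_farm

    farm_ids = [f"F{j + 1:03d}" for j in range(n_farms)]
    level_freqs = config.effective_level_freqs()

    farm_practice: dict[str, list[str]] = {}
    for var in VARIABLES:
        if var.kind != "categorical" or var.name == "collection_source":
            continue
        levels, p = _conditional_freqs(var, level_freqs[var.name])
        farm_practice[var.name] = list(rng.choice(levels, size=n_farms, p=p))
    lo, hi = DAYS_CLEANOUT_RANGE
    farm_days = rng.uniform(lo, hi, size=n_farms)

    cp_levels, cp_p = _normalized(config.collection_point_freqs)

    farm_u_tbc = rng.normal(0.0, np.sqrt(config.theta_U), size=n_farms)
    farm_u_cc = rng.normal(0.0, np.sqrt(config.theta_U), size=n_farms)

    effects_tbc = true_effect_table(config, "tbc")
    effects_cc = true_effect_table(config, "cc")
    days_sd = _uniform_sd(lo, hi)
    days_mean = 0.5 * (lo + hi)

    rows = []
    for j in range(n_farms):
        points = rng.choice(cp_levels, size=m, p=cp_p)
        if config.covariate_sharing == "sample":
            sample_practice = {}
            for name in farm_practice:
                lv, pr = _conditional_freqs(
                    VARIABLES_BY_NAME[name], level_freqs[name]
                )
                sample_practice[name] = list(rng.choice(lv, size=m, p=pr))
            sample_days = rng.uniform(lo, hi, size=m)
        eps_tbc = rng.normal(0.0, np.sqrt(config.theta_eps), size=m)
        eps_cc = rng.normal(0.0, np.sqrt(config.theta_eps), size=m)
        zero_draws = rng.random(size=m)
        for i in range(m):
            per_sample = config.covariate_sharing == "sample"
            days_i = sample_days[i] if per_sample else farm_days[j]
            rec: dict = {
                "farm_id": farm_ids[j],
                "cow_id": f"{farm_ids[j]}-C{i + 1}",
                "collection_point": points[i],
                "days_calving_pen_cleanout": days_i,
            }
            for name, practice in farm_practice.items():
                rec[name] = sample_practice[name][i] if per_sample else practice[j]
            rec = _apply_structural_na_fast(rec)
            rec["collection_source"] = COLLECTION_SOURCE_MAP[points[i]]

            days_z = (days_i - days_mean) / days_sd
            lp_tbc = config.mu + days_z * effects_tbc["days_calving_pen_cleanout"]
            lp_cc = config.mu_cc + days_z * effects_cc["days_calving_pen_cleanout"]
            for var in VARIABLES:
                if var.kind != "categorical":
                    continue
                key = term_label(var.name, rec[var.name])
                lp_tbc += effects_tbc[key]
                lp_cc += effects_cc[key]

            y_tbc = lp_tbc + farm_u_tbc[j] + eps_tbc[i]
            y_cc = lp_cc + farm_u_cc[j] + eps_cc[i]
            rec["latent_log_tbc"] = y_tbc
            rec["latent_log_cc"] = y_cc
            rec["tbc"] = max(0, round(np.exp(y_tbc) - 1.0))
            cc = max(0, round(np.exp(y_cc) - 1.0))
            if zero_draws[i] < config.cc_zero_prob:
                cc = 0
            rec["cc"] = cc
            rows.append(rec)

    df = pd.DataFrame(rows)
    df = df.drop(columns=["collection_source"])  # derived during preprocessing
    return df


def _apply_structural_na_fast(rec: dict) -> dict:
    point = rec["collection_point"]
    teat = point == "Cows teat"
    bucket = point == "Colostrum collection bucket"
    for var in VARIABLES:
        if var.na_rule is None:
            continue
        if (var.na_rule == NA_WHEN_TEAT and teat) or (
            var.na_rule == NA_WHEN_NO_FEEDING and (teat or bucket)
        ):
            rec[var.name] = NOT_APPLICABLE
    return rec


def ground_truth_sidecar(config: SimulationConfig) -> dict:
    """JSON-serialisable ground truth for a generated dataset."""
    return {
        "seed": config.seed,
        "n_farms": config.n_farms,
        "samples_per_farm": config.samples_per_farm,
        "mu": config.mu,
        "mu_cc": config.mu_cc,
        "theta_U": config.theta_U,
        "theta_eps": config.theta_eps,
        "cc_zero_prob": config.cc_zero_prob,
        "true_effects_tbc": true_effect_table(config, "tbc"),
        "true_effects_cc": true_effect_table(config, "cc"),
    }


def write_simulation(config: SimulationConfig, csv_path, truth_path=None) -> pd.DataFrame:
    df = generate_dataset(config)
    out = df.drop(columns=["latent_log_tbc", "latent_log_cc"])
    out.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(ground_truth_sidecar(config), fh, indent=2)
    return df
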