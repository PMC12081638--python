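"""Bliss-independence synergy scoring and classification.

Under Bliss independence two agents act on independent cell subpopulations,
so the expected combination viability is the product of the single-agent
viabilities, Y_AB(E) = Y_A * Y_B. The synergy score is the ratio of expected
to observed combination viability, Y_AB(E) / Y_AB(O): a score of 1 means the
agents act independently, a score above 1 means the combination leaves fewer
viable cells than independence predicts.

Per-experiment scores are classified as:

* ``not synergistic`` — score < 2
* ``synergistic``     — 2 <= score <= 5
* ``strongly synergistic`` — score > 5

A combination (across independent experiments) is called synergistic only
when a strict majority of experiments score above 2 (2 of 3 in the standard
triplicate design), and strongly synergistic when additionally the median
score exceeds 5. The aggregate score is reported as the median with the
(min, max) range across experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plates import ViabilityTable

__all__ = [
    "NOT_SYNERGISTIC",
    "SYNERGISTIC",
    "STRONGLY_SYNERGISTIC",
    "MonotherapyPair",
    "SynergyResult",
    "bliss_expected",
    "synergy_score",
    "classify_experiment",
    "classify_combination",
    "combination_synergy",
    "radiation_combo_bliss",
    "results_to_frame",
]

NOT_SYNERGISTIC = "not synergistic"
SYNERGISTIC = "synergistic"
STRONGLY_SYNERGISTIC = "strongly synergistic"

#: default per-experiment classification boundaries (lower, upper)
DEFAULT_THRESHOLDS = (2.0, 5.0)
#: floor applied to observed viability before division, so near-complete
#: eradication yields a large finite score instead of a division by ~0
OBSERVED_FLOOR = 1e-4


@dataclass(frozen=True)
class MonotherapyPair:
    """Single-agent viability fractions Y_A and Y_B."""

    y_a: float
    y_b: float

    def __post_init__(self):
        if self.y_a < 0 or self.y_b < 0:
            raise ValueError("monotherapy viabilities must be >= 0")


@dataclass
class SynergyResult:
    """Scores for one agent-dose combination across independent experiments."""

    combination: str
    y_expected: float  # median across experiments
    y_observed: float  # median across experiments
    score: float  # median per-experiment score
    per_experiment_scores: list[float]
    score_range: tuple[float, float]  # (min, max) across experiments
    combination_label: str
    n_experiments: int
    floored: bool = False
    per_experiment: pd.DataFrame | None = field(default=None, repr=False)


def bliss_expected(pair: MonotherapyPair | tuple[float, float]) -> float:
    """Expected combination viability under Bliss independence: Y_A * Y_B."""
    if not isinstance(pair, MonotherapyPair):
        pair = MonotherapyPair(*pair)
    return pair.y_a * pair.y_b


def synergy_score(
    y_expected: float, y_observed: float, floor: float = OBSERVED_FLOOR
) -> float:
    """Synergy score: expected viability divided by observed viability.

    Observed viabilities at or below ``floor`` are floored (with a warning)
    to keep the ratio finite when the combination kills essentially all cells.
    """
    if y_expected < 0:
        raise ValueError("expected viability must be >= 0")
    if y_observed <= floor:
        warnings.warn(
            f"observed viability {y_observed:.3g} floored at {floor:g} before division",
            stacklevel=2,
        )
        y_observed = floor
    return y_expected / y_observed


def classify_experiment(
    score: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Per-experiment label from the score and the (2, 5) boundaries.

    Scores in the closed interval [lower, upper] are ``synergistic``; strictly
    above the upper boundary is ``strongly synergistic``.
    """
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    lower, upper = thresholds
    if score < lower:
        return NOT_SYNERGISTIC
    if score <= upper:
        return SYNERGISTIC
    return STRONGLY_SYNERGISTIC


def classify_combination(
    per_experiment_scores: list[float],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> tuple[str, dict]:
    """Replication-aware combination label plus evidence counts.

    A combination qualifies as synergistic when the number of experiments
    with score strictly greater than the lower threshold reaches a strict
    majority, ceil((n+1)/2) — which is the 2-of-3 rule for the standard
    triplicate design. It is promoted to strongly synergistic when the median
    score additionally exceeds the upper threshold.
    """
    scores = [float(s) for s in per_experiment_scores]
    if not scores:
        raise ValueError("at least one per-experiment score is required")
    for s in scores:
        if not math.isfinite(s):
            raise ValueError(f"scores must be finite, got {s}")
    lower, upper = thresholds
    n = len(scores)
    required = math.ceil((n + 1) / 2)
    qualifying = sum(s > lower for s in scores)
    median = float(np.median(scores))

    if qualifying >= required:
        label = STRONGLY_SYNERGISTIC if median > upper else SYNERGISTIC
    else:
        label = NOT_SYNERGISTIC
    evidence = {
        "n_experiments": n,
        "n_qualifying": qualifying,
        "n_required": required,
        "median_score": median,
    }
    return label, evidence


def _combo_conditions(wells: pd.DataFrame, col_a: str, col_b: str) -> list[tuple[float, float]]:
    combo = wells[(wells[col_a] > 0) & (wells[col_b] > 0)]
    pairs = combo[[col_a, col_b]].drop_duplicates().itertuples(index=False)
    return sorted((float(a), float(b)) for a, b in pairs)


def combination_synergy(
    viability: ViabilityTable,
    agent_a: str = "drug_a_conc_uM",
    agent_b: str = "drug_b_conc_uM",
    floor: float = OBSERVED_FLOOR,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    unit_a: str = "uM",
    unit_b: str = "uM",
) -> list[SynergyResult]:
    """Score every (dose A > 0, dose B > 0) combination in a viability table.

    For each combination and each experiment the monotherapy viabilities are
    the mean viabilities of the matching single-agent conditions of that
    experiment; a missing monotherapy condition raises an error naming it.
    """
    wells = viability.wells
    for col in (agent_a, agent_b):
        if col not in wells.columns:
            raise KeyError(f"viability table has no column '{col}'")

    zero_other = {c: 0.0 for c in viability.condition_columns}

    results = []
    for dose_a, dose_b in _combo_conditions(wells, agent_a, agent_b):
        rows = []
        floored = False
        for exp in viability.experiments:
            def cond_mean(**kw):
                full = dict(zero_other)
                full.update(kw)
                return viability.condition_mean(
                    drug_a_conc_uM=full.get("drug_a_conc_uM", 0.0),
                    drug_b_conc_uM=full.get("drug_b_conc_uM", 0.0),
                    dose_Gy=full.get("dose_Gy", 0.0),
                    experiment_id=exp,
                )

            try:
                y_a = cond_mean(**{agent_a: dose_a})
            except KeyError:
                raise KeyError(
                    f"missing monotherapy condition {agent_a}={dose_a} in experiment {exp}"
                ) from None
            try:
                y_b = cond_mean(**{agent_b: dose_b})
            except KeyError:
                raise KeyError(
                    f"missing monotherapy condition {agent_b}={dose_b} in experiment {exp}"
                ) from None
            y_obs = cond_mean(**{agent_a: dose_a, agent_b: dose_b})

            y_exp = bliss_expected((y_a, y_b))
            if y_obs <= floor:
                floored = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score = synergy_score(y_exp, y_obs, floor=floor)
            rows.append(
                {
                    "experiment_id": exp,
                    "y_a": y_a,
                    "y_b": y_b,
                    "y_expected": y_exp,
                    "y_observed": y_obs,
                    "score": score,
                    "experiment_label": classify_experiment(score, thresholds),
                }
            )

        per_exp = pd.DataFrame(rows)
        scores = per_exp["score"].tolist()
        label, _ = classify_combination(scores, thresholds)
        results.append(
            SynergyResult(
                combination=f"{dose_a:g} {unit_a} + {dose_b:g} {unit_b}",
                y_expected=float(per_exp["y_expected"].median()),
                y_observed=float(per_exp["y_observed"].median()),
                score=float(np.median(scores)),
                per_experiment_scores=scores,
                score_range=(float(min(scores)), float(max(scores))),
                combination_label=label,
                n_experiments=len(scores),
                floored=floored,
                per_experiment=per_exp,
            )
        )
    return results


def radiation_combo_bliss(
    viability: ViabilityTable,
    drug: str = "drug_a_conc_uM",
    floor: float = OBSERVED_FLOOR,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[SynergyResult]:
    """Bliss scoring treating the radiation dose (Gy) as agent B.

    Requires the (drug, 0 Gy), (0 drug, Gy), (drug, Gy) and (0 drug, 0 Gy)
    conditions; Y_expected = Y_drug,0Gy x Y_0drug,Gy.
    """
    return combination_synergy(
        viability,
        agent_a=drug,
        agent_b="dose_Gy",
        floor=floor,
        thresholds=thresholds,
        unit_b="Gy",
    )


def results_to_frame(results: list[SynergyResult]) -> pd.DataFrame:
    """Tidy CSV-ready frame: one row per combination per experiment."""
    frames = []
    for res in results:
        frame = res.per_experiment.copy()
        frame.insert(0, "combination", res.combination)
        frame["combination_label"] = res.combination_label
        frame["median_score"] = res.score
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
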