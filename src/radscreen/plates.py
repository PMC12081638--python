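"""Plate reading and viability normalization.

Raw luminescence (an ATP proxy such as CellTiter-Glo) is converted to a
viability fraction by dividing each well by the mean signal of the matched
solvent-only control wells of the same plate, experiment and solvent.
Viabilities are deliberately NOT clipped at 1 — wells can outgrow controls,
and clipping would bias downstream Bliss expectations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "read_plate", "normalize_viability", "ViabilityTable"]

REQUIRED_COLUMNS = [
    "plate_id",
    "well",
    "drug_a_conc_uM",
    "drug_b_conc_uM",
    "dose_Gy",
    "solvent",
    "raw_signal",
    "experiment_id",
]

#: maximum tolerated solvent fraction (%) before a warning is issued
SOLVENT_LIMITS_PCT = {"DMSO": 1.0, "Tween-20": 0.3}

CONDITION_COLUMNS = ["drug_a_conc_uM", "drug_b_conc_uM", "dose_Gy"]


class SchemaError(ValueError):
    """A plate file does not match the expected column schema."""


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate CSV into a well table.

    The file must contain :data:`REQUIRED_COLUMNS`; any extra columns are
    preserved as metadata. Raises :class:`SchemaError` naming missing columns
    and a parse error with the row number for non-numeric signals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plate file not found: {path}")
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"plate file {path} is missing required columns: {missing}")
    if table.empty:
        warnings.warn(f"plate file {path} contains no wells", stacklevel=2)
        return table

    signals = pd.to_numeric(table["raw_signal"], errors="coerce")
    bad = table.index[signals.isna()]
    if len(bad):
        raise ValueError(
            f"non-numeric raw_signal in {path} at row {int(bad[0]) + 2} "  # +2: header + 1-based
            f"(value {table.loc[bad[0], 'raw_signal']!r})"
        )
    if (signals < 0).any():
        raise ValueError(f"negative raw_signal values in {path}")
    table["raw_signal"] = signals.astype(float)
    for col in CONDITION_COLUMNS:
        table[col] = pd.to_numeric(table[col])

    _check_solvent_limits(table)
    return table


def _check_solvent_limits(table: pd.DataFrame) -> None:
    # solvent fractions are a plausibility check, not a hard constraint
    if "solvent_pct" not in table.columns:
        return
    for solvent, limit in SOLVENT_LIMITS_PCT.items():
        over = table[(table["solvent"] == solvent) & (table["solvent_pct"] > limit)]
        if not over.empty:
            warnings.warn(
                f"{len(over)} wells exceed the {limit}% {solvent} solvent limit",
                stacklevel=3,
            )


@dataclass
class ViabilityTable:
    """Per-well viability fractions plus condition-level summaries.

    ``wells`` carries one row per well with a ``viability`` column appended to
    the raw record. Conditions are keyed by the treatment columns
    (drug concentrations in µM and radiation dose in Gy).
    """

    wells: pd.DataFrame
    condition_columns: list[str] = field(default_factory=lambda: list(CONDITION_COLUMNS))

    def summary(self) -> pd.DataFrame:
        """Mean viability and well count per condition per experiment."""
        grouped = self.wells.groupby(self.condition_columns + ["experiment_id"])
        out = grouped["viability"].agg(["mean", "count"]).reset_index()
        return out.rename(columns={"mean": "mean_viability", "count": "n_wells"})

    def condition_mean(
        self,
        drug_a_conc_uM: float = 0.0,
        drug_b_conc_uM: float = 0.0,
        dose_Gy: float = 0.0,
        experiment_id: str | None = None,
    ) -> float:
        """Mean viability of one condition (optionally within one experiment)."""
        sel = self.wells
        for col, val in zip(
            self.condition_columns, (drug_a_conc_uM, drug_b_conc_uM, dose_Gy)
        ):
            sel = sel[np.isclose(sel[col], val)]
        if experiment_id is not None:
            sel = sel[sel["experiment_id"] == experiment_id]
        if sel.empty:
            raise KeyError(
                f"no wells for condition drug_a={drug_a_conc_uM}, "
                f"drug_b={drug_b_conc_uM}, dose={dose_Gy}, experiment={experiment_id}"
            )
        return float(sel["viability"].mean())

    @property
    def experiments(self) -> list[str]:
        return sorted(self.wells["experiment_id"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.wells.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        self.summary().to_json(path, orient="records", indent=2)


def _default_control_mask(wells: pd.DataFrame) -> pd.Series:
    """Solvent-only wells: every treatment column is zero."""
    mask = pd.Series(True, index=wells.index)
    for col in CONDITION_COLUMNS:
        mask &= wells[col] == 0
    return mask


def normalize_viability(
    wells: pd.DataFrame,
    control_selector=None,
    match_columns: tuple[str, ...] = ("plate_id", "experiment_id", "solvent"),
) -> ViabilityTable:
    """Normalize raw signals to matched solvent-only controls.

    ``viability(well) = raw_signal / mean(raw_signal of control wells)`` with
    controls matched within the same plate, experiment and solvent. The
    default ``control_selector`` picks wells with no drug and no radiation;
    pass a predicate ``f(wells) -> boolean Series`` to override.

    Raises if any plate group lacks control wells (listing the plates) or has
    a non-positive control mean.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in wells.columns]
    if missing:
        raise SchemaError(f"well table is missing required columns: {missing}")
    if wells.empty:
        raise ValueError("cannot normalize an empty well table")

    mask = (control_selector or _default_control_mask)(wells)
    mask = pd.Series(np.asarray(mask, dtype=bool), index=wells.index)

    out = wells.copy()
    out["is_control"] = mask

    group_keys = [k for k in match_columns if k in wells.columns]
    control_means = (
        out[out["is_control"]].groupby(group_keys)["raw_signal"].mean().rename("control_mean")
    )

    groups = out.groupby(group_keys).size().index
    no_controls = [key for key in groups if key not in control_means.index]
    if no_controls:
        raise ValueError(
            "no control wells for plate groups "
            + ", ".join(str(dict(zip(group_keys, k if isinstance(k, tuple) else (k,)))) for k in no_controls)
        )
    bad = control_means[control_means <= 0]
    if not bad.empty:
        raise ValueError(f"control mean signal <= 0 for groups: {list(bad.index)}")

    out = out.join(control_means, on=group_keys)
    out["viability"] = out["raw_signal"] / out["control_mean"]
    out = out.drop(columns=["control_mean"])
    out.attrs = dict(wells.attrs)
    return ViabilityTable(wells=out)
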