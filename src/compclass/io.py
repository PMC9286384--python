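"""CSV/JSON file formats and validation.

All tabular data is CSV (UTF-8, declared headers); configuration and
parameter vectors are JSON. Loaders report malformed rows by line number;
writers round-trip to full precision.

Formats
-------
items.csv
    item_id, subordinate, superordinate, expectation_level,
    log_freq_ratio, sub_is_basic
counts.csv
    task (cc | endorse), item_id, polarity, explicit_class
    (blank for cc rows), count (n_sub for cc, n_yes for endorse), n_total
theta.json
    {alpha1, alpha2, class_params: {variant, beta00, beta01, beta1},
     categories: [{item_id, sub_mean, sub_sd}, ...]}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dataclasses import asdict, dataclass, field

from .bda import AISSettings, BehavioralDataset, DataValidationError, ParameterVector
from .class_priors import EXPECTATION_LEVELS, ClassPriorParams, ItemMeta
from .grids import DEFAULT_COSTS, DEFAULT_ENDORSE_COSTS, DegreeGrid

__all__ = [
    "RunConfig",
    "load_items",
    "write_items",
    "load_counts",
    "write_counts",
    "load_theta",
    "write_theta",
    "write_posterior",
    "write_predictions",
    "write_comparison",
]

ITEM_COLUMNS = [
    "item_id",
    "subordinate",
    "superordinate",
    "expectation_level",
    "log_freq_ratio",
    "sub_is_basic",
]
COUNT_COLUMNS = ["task", "item_id", "polarity", "explicit_class", "count", "n_total"]


@dataclass
class RunConfig:
    """One bundle of analysis settings, serializable to JSON.

    Stage seeds are derived from the global seed by fixed offsets so that
    every stochastic entry point is explicitly and reproducibly seeded.
    """

    grid_bounds: tuple[float, float] = (-5.0, 5.0)
    grid_points: int = 201
    costs: tuple[float, float, float] = DEFAULT_COSTS
    endorse_costs: tuple[float, float, float] = DEFAULT_ENDORSE_COSTS
    variant: str = "basic_freq"
    n_chains: int = 3
    n_iter: int = 20_000
    burn_frac: float = 0.5
    ais: AISSettings = field(default_factory=AISSettings)
    seed: int = 0
    out_dir: str = "."

    _STAGE_OFFSETS = {"design": 11, "simulate": 23, "mcmc": 37, "ais": 53}

    def grid(self) -> DegreeGrid:
        return DegreeGrid.default(*self.grid_bounds, self.grid_points)

    def stage_seed(self, stage: str) -> int:
        return self.seed + self._STAGE_OFFSETS[stage]

    def to_json(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "ais" in d and isinstance(d["ais"], dict):
            d["ais"] = AISSettings(**d["ais"])
        for key in ("grid_bounds", "costs", "endorse_costs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")


def load_items(path) -> list[ItemMeta]:
    """Read item metadata; raises with the offending line on bad rows."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ITEM_COLUMNS, path)
    items, seen = [], set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["item_id"] in seen:
            raise DataValidationError(f"{path} line {line}: duplicate item_id {row['item_id']!r}")
        seen.add(row["item_id"])
        if row["expectation_level"] not in EXPECTATION_LEVELS:
            raise DataValidationError(
                f"{path} line {line}: bad expectation_level {row['expectation_level']!r}"
            )
        try:
            items.append(
                ItemMeta(
                    item_id=str(row["item_id"]),
                    subordinate_label=str(row["subordinate"]),
                    superordinate_label=str(row["superordinate"]),
                    expectation_level=str(row["expectation_level"]),
                    log_freq_ratio=float(row["log_freq_ratio"]),
                    sub_is_basic=_parse_bool(row["sub_is_basic"], path, line),
                )
            )
        except (TypeError, ValueError) as err:
            raise DataValidationError(f"{path} line {line}: {err}") from err
    return items


def _parse_bool(v, path, line) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise DataValidationError(f"{path} line {line}: bad boolean {v!r}")


def write_items(items: Sequence[ItemMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "item_id": it.item_id,
                "subordinate": it.subordinate_label,
                "superordinate": it.superordinate_label,
                "expectation_level": it.expectation_level,
                "log_freq_ratio": repr(it.log_freq_ratio),
                "sub_is_basic": it.sub_is_basic,
            }
            for it in items
        ],
        columns=ITEM_COLUMNS,
    ).to_csv(path, index=False)


def load_counts(path, items: Sequence[ItemMeta]) -> BehavioralDataset:
    """Read a combined counts table for both tasks into a dataset."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["task", "item_id", "polarity", "count", "n_total"], path)
    known = {it.item_id for it in items}
    cc_rows, en_rows = [], []
    for i, row in df.iterrows():
        line = i + 2
        if row["item_id"] not in known:
            raise DataValidationError(f"{path} line {line}: unknown item_id {row['item_id']!r}")
        try:
            count, total = int(row["count"]), int(row["n_total"])
        except (TypeError, ValueError) as err:
            raise DataValidationError(f"{path} line {line}: non-integer counts") from err
        if not (0 <= count <= total):
            raise DataValidationError(f"{path} line {line}: need 0 <= count <= n_total")
        if row["task"] == "cc":
            cc_rows.append(
                {"item_id": row["item_id"], "polarity": row["polarity"],
                 "n_sub": count, "n_total": total}
            )
        elif row["task"] == "endorse":
            explicit = row.get("explicit_class", "super")
            if pd.isna(explicit) or explicit == "":
                explicit = "super"
            en_rows.append(
                {"item_id": row["item_id"], "polarity": row["polarity"],
                 "explicit_class": explicit, "n_yes": count, "n_total": total}
            )
        else:
            raise DataValidationError(f"{path} line {line}: bad task {row['task']!r}")
    cols_cc = ["item_id", "polarity", "n_sub", "n_total"]
    cols_en = ["item_id", "polarity", "explicit_class", "n_yes", "n_total"]
    try:
        return BehavioralDataset(
            items=list(items),
            cc_counts=pd.DataFrame(cc_rows, columns=cols_cc),
            endorse_counts=pd.DataFrame(en_rows, columns=cols_en),
        )
    except DataValidationError as err:
        raise DataValidationError(f"{path}: {err}") from err


def write_counts(data: BehavioralDataset, path) -> None:
    rows = [
        {"task": "cc", "item_id": r["item_id"], "polarity": r["polarity"],
         "explicit_class": "", "count": r["n_sub"], "n_total": r["n_total"]}
        for _, r in data.cc_counts.iterrows()
    ] + [
        {"task": "endorse", "item_id": r["item_id"], "polarity": r["polarity"],
         "explicit_class": r["explicit_class"], "count": r["n_yes"], "n_total": r["n_total"]}
        for _, r in data.endorse_counts.iterrows()
    ]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, index=False)


def write_theta(theta: ParameterVector, items: Sequence[ItemMeta], path) -> None:
    payload = {
        "alpha1": theta.alpha1,
        "alpha2": theta.alpha2,
        "class_params": {
            "variant": theta.class_params.variant,
            "beta00": theta.class_params.beta00,
            "beta01": theta.class_params.beta01,
            "beta1": theta.class_params.beta1,
        },
        "categories": [
            {"item_id": it.item_id, "sub_mean": float(m), "sub_sd": float(s)}
            for it, m, s in zip(items, theta.sub_mean, theta.sub_sd)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_theta(path, items: Sequence[ItemMeta]) -> ParameterVector:
    payload = json.loads(Path(path).read_text())
    by_id = {c["item_id"]: c for c in payload["categories"]}
    missing = [it.item_id for it in items if it.item_id not in by_id]
    if missing:
        raise DataValidationError(f"{path}: no degree-prior entry for items {missing[:5]}")
    return ParameterVector(
        alpha1=float(payload["alpha1"]),
        alpha2=float(payload["alpha2"]),
        sub_mean=np.array([by_id[it.item_id]["sub_mean"] for it in items]),
        sub_sd=np.array([by_id[it.item_id]["sub_sd"] for it in items]),
        class_params=ClassPriorParams(**payload["class_params"]),
    )


def write_posterior(summaries: pd.DataFrame, path) -> None:
    """Posterior CSV: parameter, mean, ci_low, ci_high."""
    summaries.to_csv(path, index=False)


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, index=False)


def write_comparison(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
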