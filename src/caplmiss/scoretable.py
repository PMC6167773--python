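"""Raw protocol values -> component points via a pluggable scoring table.

The official battery manual maps raw protocol results to points through
age- and gender-specific lookup tables.  Those tables are not part of
this package; instead a synthetic stand-in is shipped as an editable
JSON config: per component a monotone piecewise-linear band from a
"zero-points" anchor (lo) to a "full-points" anchor (hi), optionally
gender-adjusted.  hi < lo encodes components where less is better
(waist circumference, screen time).  Points are clipped to
[0, component max]; a missing raw value yields a missing point value.

Two composite rules exist:

* steps — the pedometer component is the mean of steps over *valid*
  days (wear time >= ``wear_min_h``, default 10 h); at least
  ``min_valid_days`` (default 3) valid days are required, otherwise the
  component is missing.  The daily mean is then banded linearly.
* screen — weekday and weekend hours are combined as a time-weighted
  daily average (5*wk + 2*we)/7 before banding (decreasing).

The band thresholds and the valid-day rule are configuration, not
claims about the official instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .battery import BatterySpec, DEFAULT_BATTERY


@dataclass(frozen=True)
class ScoringTable:
    """Monotone raw->points mapping for every battery component."""

    components: dict[str, dict]
    wear_min_h: float = 10.0
    min_valid_days: int = 3
    name: str = "scoring table"

    def band(self, component: str, gender: str | None = None) -> tuple[float, float]:
        entry = self.components[component]
        if "by_gender" in entry:
            g = entry["by_gender"].get(gender)
            if g is None:
                # unknown gender label: use the mean band
                los = [b["lo"] for b in entry["by_gender"].values()]
                his = [b["hi"] for b in entry["by_gender"].values()]
                return float(np.mean(los)), float(np.mean(his))
            return float(g["lo"]), float(g["hi"])
        return float(entry["lo"]), float(entry["hi"])


def load_scoring_table(path: str | Path | None = None) -> ScoringTable:
    """Load a scoring table from JSON; default is the shipped stand-in."""
    if path is None:
        text = resources.files("caplmiss.data").joinpath("scoring_table.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    rule = payload.get("steps_rule", {})
    return ScoringTable(
        components=payload["components"],
        wear_min_h=float(rule.get("wear_min_h", 10.0)),
        min_valid_days=int(rule.get("min_valid_days", 3)),
        name=payload.get("name", "scoring table"),
    )


DEFAULT_SCORING_TABLE = load_scoring_table()


def _linear_points(x: pd.Series, lo: float, hi: float, mx: float) -> pd.Series:
    if hi == lo:
        raise ValueError("degenerate band: lo == hi")
    frac = (x - lo) / (hi - lo)
    return (frac.clip(0.0, 1.0) * mx).where(x.notna())


def _steps_component(cohort: pd.DataFrame, table: ScoringTable, lo: float, hi: float,
                     mx: float) -> pd.Series:
    steps = cohort[[f"steps_d{i}" for i in range(1, 8)]].to_numpy(dtype=float)
    wear = cohort[[f"wear_d{i}" for i in range(1, 8)]].to_numpy(dtype=float)
    valid = (~np.isnan(steps)) & (~np.isnan(wear)) & (wear >= table.wear_min_h)
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_steps = np.where(
            n_valid > 0,
            np.nansum(np.where(valid, steps, 0.0), axis=1) / np.maximum(n_valid, 1),
            np.nan,
        )
    mean_steps = np.where(n_valid >= table.min_valid_days, mean_steps, np.nan)
    frac = np.clip((mean_steps - lo) / (hi - lo), 0.0, 1.0)
    return pd.Series(frac * mx, index=cohort.index)


def raw_to_points(
    cohort: pd.DataFrame,
    table: ScoringTable = DEFAULT_SCORING_TABLE,
    battery: BatterySpec = DEFAULT_BATTERY,
) -> pd.DataFrame:
    """Map raw protocol values to the 25 component point values.

    Missingness propagates: a missing raw input yields a missing
    component.  Output values lie in [0, component max].
    """
    unknown = set(table.components) - set(battery.component_names)
    if unknown:
        raise KeyError(f"scoring table has unknown components: {sorted(unknown)}")
    missing = set(battery.component_names) - set(table.components)
    if missing:
        raise KeyError(f"scoring table lacks components: {sorted(missing)}")

    gender = cohort["gender"] if "gender" in cohort.columns else pd.Series(index=cohort.index, dtype=object)
    out = pd.DataFrame(index=cohort.index)
    for comp in battery.component_names:
        entry = table.components[comp]
        mx = battery.component_max[comp]
        kind = entry.get("kind", "linear")
        if kind == "steps":
            out[comp] = _steps_component(cohort, table, float(entry["lo"]), float(entry["hi"]), mx)
        elif kind == "screen":
            daily = (5.0 * cohort["screen_wk_h"] + 2.0 * cohort["screen_we_h"]) / 7.0
            out[comp] = _linear_points(daily, float(entry["lo"]), float(entry["hi"]), mx)
        elif kind == "absdev":
            x = cohort[entry["source"]]
            dev = (x - float(entry["center"])).abs()
            out[comp] = _linear_points(dev, float(entry["zero_at"]), 0.0, mx)
        elif kind == "linear":
            x = cohort[entry["source"]].astype(float)
            if "by_gender" in entry:
                pts = pd.Series(np.nan, index=cohort.index)
                for g in gender.dropna().unique():
                    sel = gender == g
                    lo, hi = table.band(comp, g)
                    pts.loc[sel] = _linear_points(x.loc[sel], lo, hi, mx)
                out[comp] = pts
            else:
                out[comp] = _linear_points(x, float(entry["lo"]), float(entry["hi"]), mx)
        else:
            raise ValueError(f"unknown scoring kind {kind!r} for {comp!r}")
    return out
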