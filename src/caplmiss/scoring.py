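"""Domain and overall scoring with missing-component re-weighting.

The battery tolerates limited missing data by re-weighting: if exactly
one component of a domain is missing, the sum of the present components
is rescaled to the full raw maximum (e.g. six Physical Competence
protocols summing to s out of 152 become s * 160 / 152) before the
domain divisor is applied.  Likewise, if exactly one whole domain is
missing, the sum of the present domain scores is rescaled to 100.  Two
or more missing components void the domain; two or more missing domains
void the overall score.  The component-level and domain-level allowances
stack, so a child can carry one missing component in each of several
domains plus one fully missing domain and still receive an overall
score.

An optional switch suspends the allowance for Daily Behaviour so that
children missing pedometer step counts receive no Daily Behaviour score,
which is the conservative alternative for the component with by far the
most missing data.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .battery import BatterySpec, DomainSpec, DEFAULT_BATTERY

DOMAIN_COLUMNS = ["pc", "db", "ku", "mc"]
OVERALL_COLUMN = "overall"


def reweighted_sum(present_values: Iterable[float], present_max: float, raw_max: float) -> float:
    """Rescale the sum of the present component points to the full raw maximum.

    Parameters
    ----------
    present_values : iterable of float
        Points of the components that were observed.
    present_max : float
        Sum of the maxima of the observed components; must be > 0.
    raw_max : float
        Sum of the maxima of all components in the domain.

    Returns
    -------
    float
        ``sum(present_values) * raw_max / present_max``.
    """
    if present_max <= 0:
        raise ValueError("present_max must be > 0")
    values = list(present_values)
    if any(v < 0 for v in values):
        raise ValueError("component points must be non-negative")
    return float(sum(values)) * float(raw_max) / float(present_max)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v)


def score_domain(
    components: dict[str, float],
    spec: DomainSpec,
    allow_reweight: bool = True,
) -> float:
    """Score one domain from its component points.

    With no missing component the score is the plain sum divided by the
    domain divisor.  With exactly one missing component and the
    allowance enabled, the present sum is re-weighted to the raw maximum
    first.  Otherwise the domain score is missing (NaN).
    """
    unknown = set(components) - set(spec.components)
    if unknown:
        raise KeyError(f"unknown components for domain {spec.name!r}: {sorted(unknown)}")
    present: list[float] = []
    present_max = 0.0
    n_missing = 0
    for name, mx in spec.components.items():
        v = components.get(name)
        if _is_missing(v):
            n_missing += 1
            continue
        v = float(v)
        if v < 0 or v > mx:
            raise ValueError(f"component {name!r} value {v} outside [0, {mx}]")
        present.append(v)
        present_max += mx
    if n_missing == 0:
        return sum(present) / spec.divisor
    if n_missing == 1 and allow_reweight:
        return reweighted_sum(present, present_max, spec.raw_max) / spec.divisor
    return float("nan")


def score_overall(
    domains: dict[str, float],
    battery: BatterySpec = DEFAULT_BATTERY,
    allow_reweight: bool = True,
) -> float:
    """Combine domain scores into the overall score (out of 100).

    Exactly one missing domain is tolerated (with the allowance on) by
    rescaling the present sum to the overall maximum; two or more
    missing domains yield a missing overall score.
    """
    present_sum = 0.0
    present_max = 0.0
    n_missing = 0
    for name, dom in battery.domains.items():
        v = domains.get(name)
        if _is_missing(v):
            n_missing += 1
            continue
        v = float(v)
        if v < 0 or v > dom.domain_max + 1e-9:
            raise ValueError(f"domain {name!r} score {v} outside [0, {dom.domain_max}]")
        present_sum += v
        present_max += dom.domain_max
    if n_missing == 0:
        return present_sum
    if n_missing == 1 and allow_reweight:
        return present_sum * battery.overall_max / present_max
    return float("nan")


def score_cohort(
    component_table: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    battery: BatterySpec = DEFAULT_BATTERY,
    allow_reweight: bool = True,
    db_reweight: bool = True,
) -> pd.DataFrame:
    """Score a cohort into the 32-variable analysis subset.

    Parameters
    ----------
    component_table : DataFrame
        One row per child, one column per battery component (points or
        NaN); the index identifies the child.
    demographics : DataFrame, optional
        Must provide ``age`` and ``gender`` aligned to the same index.
    battery : BatterySpec
        Component maxima, divisors, domain structure.
    allow_reweight : bool
        Enable the single-missing-component / single-missing-domain
        allowances.
    db_reweight : bool
        When False, suspend the allowance for the Daily Behaviour
        domain only (children missing a Daily Behaviour component get a
        missing domain score).

    Returns
    -------
    DataFrame
        Columns: age, gender, the 25 components, the four domain scores
        and the overall score — 32 variables per child.
    """
    if component_table.index.has_duplicates:
        raise ValueError("duplicate child identifiers in component table")
    missing_cols = set(battery.component_names) - set(component_table.columns)
    if missing_cols:
        raise KeyError(f"component table lacks columns: {sorted(missing_cols)}")

    out = pd.DataFrame(index=component_table.index)
    if demographics is not None:
        out["age"] = demographics.reindex(component_table.index)["age"].astype(float)
        out["gender"] = demographics.reindex(component_table.index)["gender"]
    else:
        out["age"] = np.nan
        out["gender"] = pd.NA
    for comp in battery.component_names:
        out[comp] = component_table[comp].astype(float)

    for dname, dom in battery.domains.items():
        allow = allow_reweight and (db_reweight or dname != "db")
        vals = component_table[list(dom.components)]
        out[dname] = [
            score_domain(row.to_dict(), dom, allow_reweight=allow)
            for _, row in vals.iterrows()
        ]
    out[OVERALL_COLUMN] = [
        score_overall({d: row[d] for d in battery.domains}, battery, allow_reweight)
        for _, row in out.iterrows()
    ]
    return out
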