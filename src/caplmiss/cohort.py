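"""Synthetic cohort generator for a CAPL-like field study.

Generates complete per-child records for a multi-site cross-sectional
study of 8- to 12-year-old children: demographics (site, age, gender,
grade, height, weight), fitness protocols (shuttle-run laps, grip
strength, plank hold, BMI z-score, waist circumference, sit-and-reach,
agility course), seven days of pedometer steps and wear time,
self-reported MVPA days and screen time, and component-level
questionnaire values for the knowledge and motivation domains.

Two correlated latent factors drive the covariance structure: a
"fitness" factor loading on the physical-competence protocols and an
"activity" factor loading on steps, MVPA and (negatively) screen time.
Sites carry activity offsets so that site membership predicts activity
level; the offsets are aligned with the default missingness mechanism's
site groups, which makes complete-case summaries of pedometer variables
biased and gives imputation something real to correct.

Questionnaire component-level values are generated directly (no item
level) on a 0-10 scale; their per-component means are calibrated so
that the shipped scoring bands reproduce realistic point distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_SITES = 11
SITES = [f"site_{i:02d}" for i in range(1, N_SITES + 1)]

# Site weights by missingness group: 3 high-missing sites (total 0.16),
# 4 mid (0.28), 4 low (0.56).  With group step-missing rates
# 69.2/38.2/21.4% this yields an overall rate of ~33.8%.
SITE_GROUPS = {
    "high": SITES[:3],
    "mid": SITES[3:7],
    "low": SITES[7:],
}
DEFAULT_SITE_WEIGHTS = [0.16 / 3] * 3 + [0.28 / 4] * 4 + [0.56 / 4] * 4

# Activity-factor offset per missingness group: high-missing sites are
# more active on average, so their (mostly unobserved) step counts are
# above the cohort mean.
SITE_ACTIVITY_OFFSET = {"high": 0.6, "mid": 0.1, "low": -0.35}

KU_COMPONENTS = [
    "comprehension", "pa_guideline", "screen_guideline", "crf_def",
    "strength_def", "healthy_meaning", "safety_gear", "improve_skill",
    "better_shape", "leisure_pref",
]
MC_COMPONENTS = [
    "activity_vs_peers", "skill_vs_peers", "benefits_barriers",
    "csappa_predilection", "csappa_adequacy",
]

# Target mean fraction of each questionnaire component's maximum,
# calibrated to published cohort summaries; raw values live on a 0-10
# scale and the shipped scoring table maps them linearly to points.
_KU_TARGET_FRACTION = {
    "comprehension": 0.72, "pa_guideline": 0.64, "screen_guideline": 0.14,
    "crf_def": 0.58, "strength_def": 0.76, "healthy_meaning": 0.80,
    "safety_gear": 0.34, "improve_skill": 0.51, "better_shape": 0.81,
    "leisure_pref": 0.74,
}
_MC_TARGET_FRACTION = {
    "activity_vs_peers": 0.72, "skill_vs_peers": 0.67,
    "benefits_barriers": 0.40, "csappa_predilection": 0.81,
    "csappa_adequacy": 0.78,
}

DAY_COLUMNS = [f"steps_d{i}" for i in range(1, 8)] + [f"wear_d{i}" for i in range(1, 8)]

RAW_COLUMNS = (
    ["child_id", "site", "age", "gender", "grade", "height", "weight",
     "pacer_laps", "grip_kg", "plank_s", "bmi_z", "waist_cm", "sitreach_cm",
     "camsa_raw"]
    + [f"steps_d{i}" for i in range(1, 8)]
    + [f"wear_d{i}" for i in range(1, 8)]
    + ["mvpa_days", "screen_wk_h", "screen_we_h"]
    + [f"ku_{c}" for c in KU_COMPONENTS]
    + [f"mc_{c}" for c in MC_COMPONENTS]
)


@dataclass
class CohortParams:
    """Tunable parameters of the cohort generator.

    The defaults describe an 11-site study with latent fitness/activity
    correlation 0.6 and site-level activity offsets tied to the default
    missingness groups.
    """

    n: int = 10_000
    site_weights: list[float] = field(default_factory=lambda: list(DEFAULT_SITE_WEIGHTS))
    latent_rho: float = 0.6          # corr(fitness, activity)
    steps_per_sd: float = 2200.0     # step-count loading on activity
    steps_mean: float = 10_000.0
    site_activity_offsets: dict[str, float] = field(
        default_factory=lambda: dict(SITE_ACTIVITY_OFFSET)
    )


def _site_offsets(params: CohortParams) -> dict[str, float]:
    off = {}
    for group, sites in SITE_GROUPS.items():
        for s in sites:
            off[s] = params.site_activity_offsets.get(group, 0.0)
    return off


def generate_cohort(params: CohortParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a complete cohort table (no missing cells).

    Deterministic given (params, seed).  Returns one row per child with
    the full raw-variable schema; ``child_id`` is the index.
    """
    params = params or CohortParams()
    if params.n < 0:
        raise ValueError("n must be >= 0")
    w = np.asarray(params.site_weights, dtype=float)
    if len(w) != N_SITES or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("site_weights must be 11 non-negative weights with positive sum")
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    n = params.n

    site = rng.choice(SITES, size=n, p=w)
    age = rng.uniform(8.0, 12.0, size=n)
    gender = rng.choice(["girl", "boy"], size=n)
    # grade derived from age with classroom-assignment noise, clipped 3-7
    grade = np.clip(
        np.floor(age).astype(int) - 5 + rng.choice([-1, 0, 1], size=n, p=[0.1, 0.8, 0.1]),
        3, 7,
    )

    # correlated latent factors
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    fitness = z1
    rho = params.latent_rho
    offsets = _site_offsets(params)
    activity = rho * z1 + np.sqrt(1 - rho**2) * z2 + np.array([offsets[s] for s in site])

    boy = (gender == "boy").astype(float)

    # anthropometrics: simple growth trends + noise
    height = 120 + 6.5 * (age - 8) + 2.0 * boy + rng.normal(0, 6, n)
    bmi_z = rng.normal(0.2, 0.8, n) - 0.15 * fitness
    bmi = 16.5 + 0.55 * (age - 8) + 1.6 * bmi_z
    weight = bmi * (height / 100) ** 2 + rng.normal(0, 1.0, n)
    waist = 55 + 1.4 * (age - 8) + 4.2 * bmi_z + rng.normal(0, 3, n)

    # fitness protocols
    pacer = np.clip(35 + 12 * fitness + 2.5 * (age - 10) + 3 * boy + rng.normal(0, 6, n), 0, None)
    grip = np.clip(24 + 5 * fitness + 2.8 * (age - 10) + 1.5 * boy + rng.normal(0, 4, n), 2, None)
    plank = np.clip(55 + 22 * fitness + rng.normal(0, 18, n), 0, None)
    sitreach = 21 + 5 * fitness - 2.0 * boy + rng.normal(0, 8, n)
    camsa = np.clip(22 + 2.6 * fitness + 0.8 * (age - 10) + rng.normal(0, 3, n), 0, 28)

    # pedometer week: child-level mean steps from activity, day noise
    child_steps = params.steps_mean + params.steps_per_sd * activity + rng.normal(0, 1200, n)
    steps_days = np.clip(
        child_steps[:, None] + rng.normal(0, 1500, (n, 7)), 0, None
    ).round()
    wear_days = np.clip(11.5 + rng.normal(0, 1.6, (n, 7)), 0, 16)

    mvpa = np.clip(np.round(5.0 + 1.3 * activity + rng.normal(0, 1.2, n)), 0, 7).astype(int)
    screen_wk = np.clip(2.2 - 0.35 * activity + rng.normal(0, 1.0, n), 0, 12)
    screen_we = np.clip(3.2 - 0.35 * activity + rng.normal(0, 1.3, n), 0, 14)

    data: dict[str, np.ndarray] = {
        "site": site,
        "age": age,
        "gender": gender,
        "grade": grade,
        "height": height,
        "weight": weight,
        "pacer_laps": pacer.round(),
        "grip_kg": grip,
        "plank_s": plank,
        "bmi_z": bmi_z,
        "waist_cm": waist,
        "sitreach_cm": sitreach,
        "camsa_raw": camsa,
    }
    for i in range(7):
        data[f"steps_d{i + 1}"] = steps_days[:, i]
    for i in range(7):
        data[f"wear_d{i + 1}"] = wear_days[:, i]
    data["mvpa_days"] = mvpa
    data["screen_wk_h"] = screen_wk
    data["screen_we_h"] = screen_we

    # questionnaire component-level values on a 0-10 scale, loading on a
    # knowledge / motivation latent each correlated with activity
    knowledge = 0.3 * activity + np.sqrt(1 - 0.3**2) * rng.standard_normal(n)
    motivation = 0.5 * activity + np.sqrt(1 - 0.5**2) * rng.standard_normal(n)
    for comp, frac in _KU_TARGET_FRACTION.items():
        data[f"ku_{comp}"] = np.clip(10 * frac + 1.5 * knowledge + rng.normal(0, 1.5, n), 0, 10)
    for comp, frac in _MC_TARGET_FRACTION.items():
        data[f"mc_{comp}"] = np.clip(10 * frac + 1.8 * motivation + rng.normal(0, 1.2, n), 0, 10)

    df = pd.DataFrame(data, index=pd.Index([f"c{i:06d}" for i in range(n)], name="child_id"))
    if n == 0:
        # preserve full column schema in the empty case
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in RAW_COLUMNS[1:]})
        df.index.name = "child_id"
    return df[RAW_COLUMNS[1:]]
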