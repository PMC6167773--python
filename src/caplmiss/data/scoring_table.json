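{
  "name": "synthetic piecewise-linear scoring bands (stand-in, not the official manual tables)",
  "steps_rule": {"wear_min_h": 10.0, "min_valid_days": 3},
  "components": {
    "pacer": {"kind": "linear", "source": "pacer_laps",
              "by_gender": {"boy": {"lo": 0, "hi": 80}, "girl": {"lo": 0, "hi": 70}}},
    "camsa": {"kind": "linear", "source": "camsa_raw", "lo": 4, "hi": 28},
    "grip": {"kind": "linear", "source": "grip_kg",
             "by_gender": {"boy": {"lo": 5, "hi": 45}, "girl": {"lo": 5, "hi": 40}}},
    "plank": {"kind": "linear", "source": "plank_s", "lo": 0, "hi": 120},
    "bmi_z": {"kind": "absdev", "source": "bmi_z", "center": 0.0, "zero_at": 3.0},
    "waist": {"kind": "linear", "source": "waist_cm", "lo": 90, "hi": 50},
    "sitreach": {"kind": "linear", "source": "sitreach_cm", "lo": -10, "hi": 40},
    "steps": {"kind": "steps", "lo": 2000, "hi": 18000},
    "screen": {"kind": "screen", "lo": 6.0, "hi": 0.5},
    "mvpa": {"kind": "linear", "source": "mvpa_days", "lo": 0, "hi": 7},
    "comprehension": {"kind": "linear", "source": "ku_comprehension", "lo": 0, "hi": 10},
    "pa_guideline": {"kind": "linear", "source": "ku_pa_guideline", "lo": 0, "hi": 10},
    "screen_guideline": {"kind": "linear", "source": "ku_screen_guideline", "lo": 0, "hi": 10},
    "crf_def": {"kind": "linear", "source": "ku_crf_def", "lo": 0, "hi": 10},
    "strength_def": {"kind": "linear", "source": "ku_strength_def", "lo": 0, "hi": 10},
    "healthy_meaning": {"kind": "linear", "source": "ku_healthy_meaning", "lo": 0, "hi": 10},
    "safety_gear": {"kind": "linear", "source": "ku_safety_gear", "lo": 0, "hi": 10},
    "improve_skill": {"kind": "linear", "source": "ku_improve_skill", "lo": 0, "hi": 10},
    "better_shape": {"kind": "linear", "source": "ku_better_shape", "lo": 0, "hi": 10},
    "leisure_pref": {"kind": "linear", "source": "ku_leisure_pref", "lo": 0, "hi": 10},
    "activity_vs_peers": {"kind": "linear", "source": "mc_activity_vs_peers", "lo": 0, "hi": 10},
    "skill_vs_peers": {"kind": "linear", "source": "mc_skill_vs_peers", "lo": 0, "hi": 10},
    "benefits_barriers": {"kind": "linear", "source": "mc_benefits_barriers", "lo": 0, "hi": 10},
    "csappa_predilection": {"kind": "linear", "source": "mc_csappa_predilection", "lo": 0, "hi": 10},
    "csappa_adequacy": {"kind": "linear", "source": "mc_csappa_adequacy", "lo": 0, "hi": 10}
  }
}
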