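{
  "name": "CAPL (25-component battery)",
  "domains": {
    "pc": {
      "label": "Physical Competence",
      "divisor": 5,
      "components": {
        "pacer": 42,
        "camsa": 42,
        "grip": 17,
        "plank": 17,
        "bmi_z": 17,
        "waist": 17,
        "sitreach": 8
      }
    },
    "db": {
      "label": "Daily Behaviour",
      "divisor": 1,
      "components": {
        "steps": 21,
        "screen": 8,
        "mvpa": 3
      }
    },
    "ku": {
      "label": "Knowledge and Understanding",
      "divisor": 1,
      "components": {
        "comprehension": 5,
        "pa_guideline": 1,
        "screen_guideline": 1,
        "crf_def": 1,
        "strength_def": 1,
        "healthy_meaning": 5,
        "safety_gear": 1,
        "improve_skill": 1,
        "better_shape": 1,
        "leisure_pref": 1
      }
    },
    "mc": {
      "label": "Motivation and Confidence",
      "divisor": 1,
      "components": {
        "activity_vs_peers": 1,
        "skill_vs_peers": 1,
        "benefits_barriers": 4,
        "csappa_predilection": 6,
        "csappa_adequacy": 6
      }
    }
  }
}
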