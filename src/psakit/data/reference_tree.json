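{
  "version": "psa-reference-1.0",
  "metadata": {
    "description": "Reference Personal Support Algorithm tree. Encodes the published narrative structure: root split on the Self-Reliance Index; IADL difficulty separates Group 1 into 1A/1B/1C; the ADL Short scale stratifies impaired patients into low / moderate / high ADL impairment; dressing upper body plus decision making or great IADL difficulty differentiate the low branch; cognitive impairment, unstable health, and bladder incontinence differentiate the moderate branch; late-loss ADL (eating) with bowel incontinence, or communication difficulty with caregiver distress, identify the highest-need group. Cut-points are configurable data, not code.",
    "cut_point_notes": {
      "low_adl_impairment": "adl_short <= 2",
      "high_adl_impairment": "adl_short >= 10",
      "any_difficulty_decision_making": "decision_making >= 1",
      "great_iadl_difficulty": "iadl_difficulty >= 5",
      "cognitive_impairment": "cps >= 3",
      "weekly_incontinence": "code >= 2",
      "supervision_or_physical_help": "code >= 2",
      "communication_difficulty": "making_self_understood >= 2"
    }
  },
  "root": "root",
  "nodes": [
    {"id": "root", "variable": "self_reliance_impaired", "cuts": [1], "children": ["g1_iadl", "imp_adl"]},
    {"id": "g1_iadl", "variable": "iadl_difficulty", "cuts": [2], "children": ["leaf_1a", "g1_iadl2"]},
    {"id": "g1_iadl2", "variable": "iadl_difficulty", "cuts": [5], "children": ["leaf_1b", "leaf_1c"]},
    {"id": "imp_adl", "variable": "adl_short", "cuts": [3], "children": ["low_dress", "midhigh"]},
    {"id": "midhigh", "variable": "adl_short", "cuts": [10], "children": ["mid_cog", "high_bowel"]},
    {"id": "low_dress", "variable": "dressing_upper", "cuts": [2], "children": ["leaf_2_low", "low_dm"]},
    {"id": "low_dm", "variable": "decision_making", "cuts": [1], "children": ["low_iadl", "leaf_3_dm"]},
    {"id": "low_iadl", "variable": "iadl_difficulty", "cuts": [5], "children": ["leaf_2_dress", "leaf_3_iadl"]},
    {"id": "mid_cog", "variable": "cps", "cuts": [3], "children": ["mid_bladder", "mid_unstable"]},
    {"id": "mid_bladder", "variable": "bladder_incontinence", "cuts": [2], "children": ["leaf_3_mid", "leaf_4_bladder"]},
    {"id": "mid_unstable", "variable": "unstable_conditions", "cuts": [1], "children": ["leaf_4_cog", "leaf_5_unstable"]},
    {"id": "high_bowel", "variable": "bowel_incontinence", "cuts": [2], "children": ["high_comm_a", "high_eat"]},
    {"id": "high_eat", "variable": "eating", "cuts": [2], "children": ["high_comm_b", "leaf_6_lateloss"]},
    {"id": "high_comm_a", "variable": "making_self_understood", "cuts": [2], "children": ["leaf_5_a", "high_cgd_a"]},
    {"id": "high_cgd_a", "variable": "caregiver_distress", "cuts": [1], "children": ["leaf_5_a2", "leaf_6_comm_a"]},
    {"id": "high_comm_b", "variable": "making_self_understood", "cuts": [2], "children": ["leaf_5_b", "high_cgd_b"]},
    {"id": "high_cgd_b", "variable": "caregiver_distress", "cuts": [1], "children": ["leaf_5_b2", "leaf_6_comm_b"]},
    {"id": "leaf_1a", "group": "1A"},
    {"id": "leaf_1b", "group": "1B"},
    {"id": "leaf_1c", "group": "1C"},
    {"id": "leaf_2_low", "group": "2"},
    {"id": "leaf_2_dress", "group": "2"},
    {"id": "leaf_3_dm", "group": "3"},
    {"id": "leaf_3_iadl", "group": "3"},
    {"id": "leaf_3_mid", "group": "3"},
    {"id": "leaf_4_bladder", "group": "4"},
    {"id": "leaf_4_cog", "group": "4"},
    {"id": "leaf_5_unstable", "group": "5"},
    {"id": "leaf_5_a", "group": "5"},
    {"id": "leaf_5_a2", "group": "5"},
    {"id": "leaf_5_b", "group": "5"},
    {"id": "leaf_5_b2", "group": "5"},
    {"id": "leaf_6_lateloss", "group": "6"},
    {"id": "leaf_6_comm_a", "group": "6"},
    {"id": "leaf_6_comm_b", "group": "6"}
  ]
}
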