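{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "plgarelease dataset CSV pair",
  "description": "Column contracts for the two input CSVs (UTF-8, '.' decimal separator, headers case-insensitive and order-free). DLC/EE and cumulative release are fractions in [0,1]; release values up to 1.1 are tolerated on input and clipped.",
  "properties": {
    "features.csv": {
      "description": "One row per formulation.",
      "required": [
        "formulation_id", "drug_id", "polymer_mw", "la_ga",
        "initial_dm_ratio", "drug_mw", "drug_tpsa", "drug_logp",
        "particle_size", "dlc", "ee", "se", "agitation_rpm",
        "polymer_concentration", "acid_endcap"
      ],
      "properties": {
        "formulation_id": {"type": "string", "description": "unique key"},
        "drug_id": {"type": "string", "description": "grouping key for LODO"},
        "polymer_mw": {"type": "number", "exclusiveMinimum": 0, "description": "PLGA molecular weight, kDa; ranges encoded as midpoints"},
        "la_ga": {"type": "number", "exclusiveMinimum": 0, "description": "LA:GA molar ratio; 50:50 encoded 1.0, 75:25 encoded 3.0"},
        "initial_dm_ratio": {"type": "number", "exclusiveMinimum": 0, "description": "initial drug-to-polymer mass ratio"},
        "drug_mw": {"type": "number", "exclusiveMinimum": 0, "description": "drug molecular weight, Da"},
        "drug_tpsa": {"type": "number", "minimum": 0, "description": "topological polar surface area, A^2"},
        "drug_logp": {"type": "number", "description": "octanol-water partition coefficient"},
        "particle_size": {"type": "number", "exclusiveMinimum": 0, "description": "microsphere diameter, um"},
        "dlc": {"type": "number", "minimum": 0, "maximum": 1, "description": "drug loading capacity, mass fraction (percent inputs must be divided by 100)"},
        "ee": {"type": "number", "minimum": 0, "maximum": 1, "description": "encapsulation efficiency, fraction"},
        "se": {"type": "number", "minimum": 0, "description": "solubility enhancer concentration in the release medium, % w/v"},
        "agitation_rpm": {"type": "number", "minimum": 0, "description": "in vitro agitation rate, rpm"},
        "polymer_concentration": {"type": "number", "exclusiveMinimum": 0, "maximum": 1, "description": "polymer weight fraction of the organic phase"},
        "acid_endcap": {"type": "integer", "enum": [0, 1], "description": "1 = acid-terminated PLGA, 0 = ester-terminated"},
        "slow_release": {"type": "integer", "enum": [0, 1], "description": "optional; ignored on read (labels are recomputed from the profiles)"}
      }
    },
    "profiles.csv": {
      "description": "Long format: one row per release observation; >= 2 observations per formulation, strictly increasing times.",
      "required": ["formulation_id", "time_days", "cumulative_release"],
      "properties": {
        "formulation_id": {"type": "string", "description": "must exist in features.csv"},
        "time_days": {"type": "number", "minimum": 0, "description": "time in days (72 h = 3.0)"},
        "cumulative_release": {"type": "number", "minimum": 0, "maximum": 1.1, "description": "cumulative release fraction; clipped to [0,1] on read"}
      }
    }
  }
}
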