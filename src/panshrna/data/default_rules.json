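{
  "name": "panshrna-default-rules",
  "version": "1.0",
  "comment": "Soft, weighted shRNA design rules. All weights overridable; a weight of -Infinity (JSON string '-inf') turns a rule into a hard filter.",
  "coverage_bonus_per_isoform": 1.0,
  "rules": [
    {
      "name": "gc_range",
      "kind": "range-penalty",
      "weight": -2.0,
      "params": {"min_pct": 30.0, "max_pct": 52.0}
    },
    {
      "name": "homopolymer_run",
      "kind": "motif-penalty",
      "weight": -1.0,
      "params": {"run_threshold": 4}
    },
    {
      "name": "guide_5p_au",
      "kind": "position-bonus",
      "weight": 1.0,
      "params": {"strand": "guide", "positions": [1, 2], "bases": ["A", "T"]}
    },
    {
      "name": "type_iis_sites",
      "kind": "cloning-incompatibility",
      "weight": -10.0,
      "params": {"motifs": ["CGTCTC", "GAAGAC"], "both_strands": true}
    }
  ]
}
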