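{
  "name": "mir30-short-default",
  "comment": "Synthetic default: a shortened miR-30-style scaffold (canonical miR-30 arm context and loop) with Golden Gate overhangs chosen by this package. Not a transcription of any published construct; supply your own BackboneSpec for bit-exact cloning.",
  "flank5": "AGGCTGCTGTTGACAGTGAGCG",
  "loop": "TAGTGAAGCCACAGATGTA",
  "flank3": "TGCCTACTGCCTCGGAGCCT",
  "enzyme_name": "Esp3I",
  "enzyme_site": "CGTCTC",
  "overhang_length": 4,
  "upstream_overhang": "AGGC",
  "downstream_overhang": "GCCT",
  "multimer_junctions": [["GCCT", "AGGC"]]
}
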