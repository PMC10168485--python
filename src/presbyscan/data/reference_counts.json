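{
  "validation_calls": {
    "correct": 357,
    "total": 377
  },
  "deafness_gene_list_components": {
    "human_only": 72,
    "human_and_mouse": 122,
    "mouse_only_human_orthologues": 540
  }
}
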