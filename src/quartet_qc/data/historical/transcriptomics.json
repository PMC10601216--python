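{
  "omics": "transcriptomics",
  "scores": [
    0.44716059910383565,
    0.3874473172671834,
    0.3565199417302626,
    0.3276987561639264,
    0.31572536346963614,
    0.22726204251598703,
    0.26511879161651936,
    0.271507519457236,
    0.19824754031832456,
    0.21756802233349448,
    0.21911504927387587,
    0.16413046568606654,
    0.1959907094189876,
    0.17512273864358363,
    0.16035416805980254,
    0.11529811261676211,
    0.08699150397159774,
    0.12185308233037462,
    0.09857647771561769,
    0.08255215147329675
  ],
  "version": "sim-2024.1"
}
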