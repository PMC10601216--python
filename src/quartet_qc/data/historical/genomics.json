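{
  "omics": "genomics",
  "scores": [
    0.9986163624351373,
    0.9871171167808865,
    0.9828426188744379,
    0.9665066676792232,
    0.9601067438763841,
    0.9500112000030159,
    0.9484437661229123,
    0.927134969938286,
    0.9228067403791193,
    0.9191904864368472,
    0.9061373965384829,
    0.8931562808865566,
    0.8916243200902211,
    0.8737655288095696,
    0.8794652101168589,
    0.8600375984617163,
    0.8569650024350879,
    0.8529240667486709,
    0.847653652377231,
    0.828452006864027
  ],
  "version": "sim-2024.1"
}
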