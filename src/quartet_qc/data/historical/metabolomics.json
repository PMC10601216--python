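{
  "omics": "metabolomics",
  "scores": [
    0.7646942826175421,
    0.7290168269842029,
    0.7090789761718794,
    0.6880777672184707,
    0.669879532183372,
    0.5943937371290962,
    0.625701451890517,
    0.6329000899031874,
    0.5404299255017506,
    0.5523738812203296,
    0.557513492256085,
    0.48090683115875205,
    0.5052007256126472,
    0.4640192340537439,
    0.44570248210197205,
    0.38630536010460453,
    0.3268544862004878,
    0.36838106433211276,
    0.3124801631337038,
    0.2914852280250965
  ],
  "version": "sim-2024.1"
}
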