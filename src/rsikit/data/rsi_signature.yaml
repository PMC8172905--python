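# Ten-gene radiosensitivity index (RSI): per-gene linear coefficients applied
# to within-sample ranks (highest expression -> rank 10). Lower RSI means
# higher predicted radiosensitivity (RSI proxies SF2).
name: RSI
genes:
  AR: -0.0098009
  JUN: 0.0128283
  STAT1: 0.0254552
  PRKCB: -0.0017589
  RELA: -0.0038171
  ABL1: 0.1070213
  SUMO1: -0.0002509
  CDK1: -0.0092431
  HDAC1: -0.0204469
  IRF1: -0.0441683
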