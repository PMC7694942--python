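{
 "score_scale": 1.0,
 "purity_intercept": 0.6049872018,
 "purity_slope": 0.0001467884
}
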