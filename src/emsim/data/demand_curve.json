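{
 "resolution_s": 900,
 "weights": [
  0.003402,
  0.003411,
  0.003422,
  0.003436,
  0.003454,
  0.003476,
  0.003504,
  0.003538,
  0.003581,
  0.003634,
  0.0037,
  0.003782,
  0.003883,
  0.004007,
  0.004158,
  0.004342,
  0.004563,
  0.004827,
  0.005138,
  0.0055,
  0.005916,
  0.006385,
  0.006903,
  0.007465,
  0.00806,
  0.008677,
  0.009302,
  0.009922,
  0.010525,
  0.011101,
  0.011644,
  0.012152,
  0.012623,
  0.013057,
  0.013456,
  0.013819,
  0.014145,
  0.014432,
  0.014677,
  0.014878,
  0.01503,
  0.015133,
  0.015187,
  0.015194,
  0.015158,
  0.015088,
  0.01499,
  0.014874,
  0.014749,
  0.014623,
  0.014503,
  0.014395,
  0.014303,
  0.01423,
  0.014178,
  0.014147,
  0.014137,
  0.01415,
  0.014183,
  0.014234,
  0.0143,
  0.014376,
  0.014456,
  0.01453,
  0.014589,
  0.014624,
  0.014625,
  0.014587,
  0.014504,
  0.014375,
  0.014202,
  0.01399,
  0.013744,
  0.013472,
  0.01318,
  0.012875,
  0.012559,
  0.012237,
  0.011907,
  0.011571,
  0.011227,
  0.010874,
  0.010511,
  0.010139,
  0.009757,
  0.009369,
  0.008976,
  0.008582,
  0.00819,
  0.007805,
  0.007429,
  0.007066,
  0.006719,
  0.00639,
  0.006082,
  0.005795
 ]
}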