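{
 "beta12": 6768.0,
 "beta11": 345600.0,
 "beta21": 100800.0,
 "alpha12": 1353600.0,
 "alpha21": 734400.0,
 "gamma": 2.0,
 "k12": 3600000000.0,
 "k21": 13000000.0,
 "lambda1": 1.08,
 "lambda2": 0.8,
 "mu1": 0.3,
 "mu2": 0.3,
 "K": 1000000.0
}
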