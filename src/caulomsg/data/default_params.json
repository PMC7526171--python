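{
 "k_s_cdG": 33.5,
 "k_d_cdG": 100.0,
 "K1": 0.5,
 "Km1": 1500.0,
 "Km2": 0.06,
 "DgcB": 0.7,
 "basalPDE": 0.2,
 "k_s_ppGpp": 170.0,
 "k_d_ppGpp": 160.0,
 "K2": 75.0,
 "K3": 10.0,
 "K_SpoT": 4.0,
 "Km3": 1000.0,
 "Km4": 2000.0,
 "K4": 75.63,
 "eps": 0.1,
 "k_s_GTP": 1500.0,
 "k_d_GTP": 100.0,
 "EI_T": 10.0,
 "NPr_T": 30.0,
 "EIIA_T": 30.0,
 "k1": 52.4,
 "k_1": 67.2,
 "k2": 12000.0,
 "k3": 3700.0,
 "Kd1": 350.0,
 "Kd2": 670.0
}
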