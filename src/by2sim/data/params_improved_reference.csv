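# by2sim 0.1.0
# seed: none
# variant: improved
parameter,value,min,max,ci_halfwidth_90
kd,5.44e-4,0.0,0.01,6.2e-5
mu_m,0.162,0.0,10.0,0.17
mu_mA,0.578,0.0,10.0,0.48
mu_mP,2.1e-5,0.0,10.0,0.37
K_S,72.53,0.0,100.0,73.4
K_IS,100.0,0.0,100.0,73.3
K_A,0.221,0.0,1.0,0.22
K_IA,0.221,0.0,1.0,0.065
K_N,0.835,0.0,5.0,0.25
K_IN,1.0,0.0,5.0,0.06
K_F,1.108,0.0,30.0,0.71
K_IF,1.404,0.0,30.0,0.51
K_G,18.0,0.0,30.0,17.1
K_IG,18.0,0.0,30.0,12.0
alpha,0.396,0.0,1.0,0.24
mu_A,6.9e-3,0.0,1.0,1.9e-3
mu_N,1.71e-2,0.0,1.0,2.7e-2
mu_F,8.34e-2,0.0,1.0,2.9e-2
mu_G,0.273,0.0,1.0,0.26
mu_P,2.68e-2,0.0,1.0,3.2e-3
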