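# by2sim 0.1.0
# seed: none
# variant: initial
parameter,value,min,max,ci_halfwidth_90
kd,6.62e-4,0.0,0.1,5.8e-5
mu_m,9.47,0.0,10.0,0.06
K_S,17.64,0.0,100.0,3.5
K_IS,17.64,0.0,100.0,3.4
K_A,0.796,0.0,1.0,0.040
K_IA,0.797,0.0,1.0,0.024
K_N,0.133,0.0,5.0,0.057
K_IN,0.135,0.0,5.0,0.097
mu_S,2.235e-1,0.0,1.0,4.65e-2
mu_A,4.863e-3,0.0,1.0,6.34e-4
mu_N,3.013e-2,0.0,1.0,2.49e-3
mu_P,2.883e-2,0.0,1.0,2.36e-3
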