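MOL,d_P_nm,d_p_nm,n_p_o,D_m2s,theta_star,theta,V_tot_nm3,delta_p_nm,SAS_p_nm2,delta_P_nm,SAS_P_nm2,n_p_e
IONP,8.13,1.97,4,1.91E-09,0.31,0.37,200.75,0.50,21.64,0.33,140.47,2.66
IONP,8.13,1.97,8,1.33E-09,0.57,0.85,180.90,0.50,21.64,0.33,140.47,10.06
IONP,8.13,1.27,16,1.46E-09,0.52,0.73,193.59,0.46,12.61,0.33,140.47,16.16
IONP,11.04,1.27,36,1.62E-09,0.44,0.59,351.63,0.46,12.61,0.33,194.00,24.47
IONP,11.04,1.97,20,1.37E-09,0.56,0.81,313.15,0.50,21.64,0.33,194.00,17.74
IONP,11.04,1.27,66,6.63E-10,0.88,2.09,300.98,0.46,12.61,0.33,194.00,97.30
1AKI,11.04,,2,2.06E-09,0.24,0.28,375.71,0.32,67.36,0.33,194.00,1.95
1AKI,11.04,,3,1.93E-09,0.30,0.36,357.35,0.32,67.36,0.33,194.00,3.08
1AKI,11.04,,9,1.44E-09,0.52,0.74,247.23,0.32,67.36,0.33,194.00,5.66
1UBQ,11.04,,7,1.96E-09,0.29,0.34,338.10,0.31,48.19,0.33,194.00,3.48
1UBQ,11.04,,9,1.55E-09,0.47,0.64,316.87,0.31,48.19,0.33,194.00,9.38
1UBQ,11.04,,12,1.38E-09,0.55,0.81,285.02,0.31,48.19,0.33,194.00,11.14
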