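lake_code,genotype_ratio,pi,ho_all,he_all,n_polymorphic,ho_neutral,he_neutral,n_polymorphic_neutral,del_proportion,load_ratio,mean_del_maf,n_fixed_del
CA,0.88,0.00107,0.24,0.17,2454,0.16,0.13,2454,0.57,1.15,0.15,0
HA,0.87,0.000956,0.21,0.15,2596,0.13,0.11,2596,0.56,1.07,0.13,0
MG,0.90,0.00101,0.24,0.16,2425,0.15,0.12,2425,0.54,1.11,0.13,0
KI,0.84,0.00121,0.25,0.19,2936,0.18,0.17,2936,0.58,0.98,0.14,0
PA,0.86,0.00129,0.27,0.20,3412,0.20,0.18,3412,0.60,0.88,0.13,0
CE,0.86,0.00128,0.26,0.20,3145,0.19,0.18,3145,0.59,0.94,0.13,0
AC,0.88,0.00130,0.27,0.21,3449,0.20,0.18,3449,0.67,0.97,0.13,0
CY,0.90,0.00135,0.27,0.21,3534,0.21,0.19,3534,0.64,0.90,0.13,0
BS,0.89,0.00136,0.29,0.22,3543,0.22,0.19,3543,0.67,0.95,0.14,0
MI,0.91,0.00131,0.29,0.21,2979,0.22,0.19,2979,0.58,0.96,0.14,0
BO,0.89,0.00111,0.25,0.17,2569,0.17,0.14,2569,0.58,1.12,0.14,0
MA,0.92,0.00125,0.28,0.20,2962,0.20,0.17,2962,0.56,0.94,0.14,0
TU,0.86,0.00113,0.26,0.17,2549,0.18,0.14,2549,0.69,1.35,0.24,3
GR,0.85,0.00137,0.28,0.22,3608,0.21,0.20,3608,0.67,0.93,0.14,0
PM,0.87,0.00149,0.31,0.24,3610,0.25,0.22,3610,0.72,0.99,0.23,3
TZ,0.87,0.00145,0.30,0.23,3440,0.24,0.21,3440,0.71,1.03,0.23,2
CR,0.87,0.00137,0.28,0.22,3520,0.21,0.20,3520,0.66,0.94,0.14,0
PB,0.90,0.00128,0.28,0.20,3087,0.21,0.18,3087,0.58,0.94,0.13,0
AL,0.90,0.00136,0.28,0.22,3326,0.22,0.20,3326,0.61,0.91,0.14,0
OF,0.87,0.00127,0.27,0.20,3046,0.20,0.18,3046,0.54,0.88,0.14,0
WA,0.85,0.00143,0.30,0.23,3462,0.24,0.21,3462,0.73,1.04,0.23,3
ES,0.87,0.00125,0.26,0.20,3415,0.19,0.17,3415,0.62,0.90,0.12,0
PO,0.89,0.00143,0.29,0.23,3610,0.22,0.21,3610,0.72,0.99,0.22,1
MZ,0.87,0.00129,0.29,0.20,3603,0.22,0.18,3603,0.64,0.88,0.13,0
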