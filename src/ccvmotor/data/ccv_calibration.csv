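# Timing calibration for the 15 plosive-plosive analysis CCVs.
# tau_norm_mean reproduces the measured subgroup means of the normalized
# consonantal transition tau' (0.373 / 0.390 / 0.413); per-CCV means are
# not published, so subgroup means are assigned uniformly within subgroup.
# tau_norm_sd back-solved from the printed group standard errors.
ccv,tau_norm_mean,tau_norm_sd,T_mean,T_sd
bda,0.373,0.065,0.49,0.05
bga,0.373,0.065,0.49,0.05
dga,0.373,0.065,0.49,0.05
dba,0.39,0.065,0.49,0.05
gba,0.39,0.065,0.49,0.05
gda,0.39,0.065,0.49,0.05
bpa,0.413,0.065,0.49,0.05
bta,0.413,0.065,0.49,0.05
bca,0.413,0.065,0.49,0.05
dpa,0.413,0.065,0.49,0.05
dta,0.413,0.065,0.49,0.05
dca,0.413,0.065,0.49,0.05
gpa,0.413,0.065,0.49,0.05
gta,0.413,0.065,0.49,0.05
gca,0.413,0.065,0.49,0.05
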