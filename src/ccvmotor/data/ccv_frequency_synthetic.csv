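# SYNTHETIC intra-word frequency table (appearances per million words).
# Plausible stand-in values, NOT corpus-mined: plosive-plosive clusters
# homogeneously low (bta high, dta/gta medium), fricative-containing
# clusters higher and more variable. Deterministic (seed 20260929).
ccv,f
bda,2.2
bga,4.8
bpa,3.2
bta,60.0
bca,0.2
bsa,106.2
bfa,29.0
bja,251.0
dba,4.2
dga,1.9
dpa,2.1
dta,15.0
dca,4.1
dsa,8.1
dfa,733.9
dja,17.6
gba,1.9
gda,5.6
gpa,5.4
gta,12.0
gca,2.8
gsa,9.2
gfa,6.0
gja,3.3
pba,4.6
pda,5.9
pga,3.4
pta,1.3
pca,3.0
psa,1781.4
pfa,10.2
pja,17.5
tba,2.7
tda,0.4
tga,1.7
tpa,5.4
tca,4.0
tsa,2.4
tfa,50.6
tja,61.5
cba,1.9
cda,3.6
cga,0.7
cpa,1.4
cta,3.5
csa,15.1
cfa,2307.6
cja,298.5
sba,2.3
sda,29.3
sga,2.2
spa,348.8
sta,51.6
sca,15.9
sfa,29.7
sja,216.3
fba,19.8
fda,1060.6
fga,10.8
fpa,401.2
fta,219.3
fca,3.4
fsa,945.4
fja,42.7
jba,35.9
jda,1202.0
jga,1035.8
jpa,1373.3
jta,16.5
jca,3056.4
jsa,3.6
jfa,1170.0
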