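trait,source,df,mean_square,pct_ss
IOD15F,ENV,2,1868.3,1.19
IOD15F,REP(ENV),6,83.8,0.16
IOD15F,GEN,31,8931.1,88.36
IOD15F,ENV:GEN,62,432.5,8.56
IOD15F,PC1,32,788.36,94.1
IOD15F,PC2,30,52.88,5.9
IOD15F,Residuals,186,29.1,1.73
IOD21F,ENV,2,948.3,0.48
IOD21F,REP(ENV),6,73.2,0.11
IOD21F,GEN,31,11748.5,91.71
IOD21F,ENV:GEN,62,359.9,5.62
IOD21F,PC1,32,652.33,93.6
IOD21F,PC2,30,47.95,6.4
IOD21F,Residuals,186,44.4,2.08
IOD15L,ENV,2,1558.7,0.93
IOD15L,REP(ENV),6,187.4,0.34
IOD15L,GEN,31,9633.3,89.54
IOD15L,ENV:GEN,62,305.6,5.68
IOD15L,PC1,32,401.76,67.9
IOD15L,PC2,30,203.0,32.1
IOD15L,Residuals,186,62.9,3.51
IOD21L,ENV,2,56.6,0.02
IOD21L,REP(ENV),6,184.1,0.24
IOD21L,GEN,31,13860.3,94.46
IOD21L,ENV:GEN,62,163.3,2.23
IOD21L,PC1,32,191.5,60.5
IOD21L,PC2,30,133.31,39.5
IOD21L,Residuals,186,74.5,3.05
PYLP,ENV,2,487.43,46.0
PYLP,REP(ENV),6,1.25,0.36
PYLP,GEN,31,14.59,21.34
PYLP,ENV:GEN,62,5.75,16.81
PYLP,PC1,32,9.73,87.4
PYLP,PC2,30,1.5,12.6
PYLP,Residuals,186,1.76,15.49
HPW,ENV,2,7173.0,19.38
HPW,REP(ENV),6,190.2,1.54
HPW,GEN,31,1320.3,55.29
HPW,ENV:GEN,62,145.2,12.16
HPW,PC1,32,217.79,77.4
HPW,PC2,30,67.86,22.6
HPW,Residuals,186,46.3,11.63
HKW,ENV,2,798.75,9.02
HKW,REP(ENV),6,61.89,2.1
HKW,GEN,31,305.29,53.41
HKW,ENV:GEN,62,41.41,14.49
HKW,PC1,32,54.7,68.2
HKW,PC2,30,27.24,31.8
HKW,Residuals,186,20.0,20.99
SP,ENV,2,5036.4,35.45
SP,REP(ENV),6,91.7,1.94
SP,GEN,31,352.3,38.44
SP,ENV:GEN,62,52.0,11.34
SP,PC1,32,83.01,82.4
SP,PC2,30,18.85,17.6
SP,Residuals,186,19.6,12.83
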