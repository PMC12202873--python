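label,source,sink,lag,p_value,rho,persistence
a,media_shootings,media_laws,1,<0.001,0.094,1.00
b,media_laws,media_crime,0,<0.001,0.100,1.00
c,media_shootings,media_crime,1,0.001,0.083,1.00
d,media_crime,media_shootings,0,0.001,0.071,1.00
e,media_laws,tweets_pro,2,<0.001,-0.069,1.00
f,background_checks,media_crime,1,<0.001,0.105,1.00
g,tweets_anti,media_crime,2,0.009,0.048,0.57
h,media_crime,background_checks,7,<0.001,-0.075,0.40
i,media_crime,background_checks,6,0.035,0.054,0.33
j,tweets_anti,background_checks,1,0.092,0.048,0.53
k,media_laws,background_checks,1,<0.001,0.084,1.00
l,background_checks,media_laws,1,<0.001,0.099,0.67
m,background_checks,tweets_anti,2,0.001,0.059,0.97
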