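variable,category,group,band,count
smoking,daily,patient,b18_44,62
smoking,daily,control,b18_44,254
smoking,daily,patient,b45_54,103
smoking,daily,control,b45_54,148
smoking,occasional,patient,b18_44,10
smoking,occasional,control,b18_44,112
smoking,occasional,patient,b45_54,16
smoking,occasional,control,b45_54,33
smoking,ex_smoker,patient,b18_44,17
smoking,ex_smoker,control,b18_44,344
smoking,ex_smoker,patient,b45_54,48
smoking,ex_smoker,control,b45_54,133
smoking,never,patient,b18_44,44
smoking,never,control,b18_44,539
smoking,never,patient,b45_54,38
smoking,never,control,b45_54,206
bmi,lt25,patient,b18_44,53
bmi,lt25,control,b18_44,740
bmi,lt25,patient,b45_54,45
bmi,lt25,control,b45_54,197
bmi,b25_29_9,patient,b18_44,45
bmi,b25_29_9,control,b18_44,352
bmi,b25_29_9,patient,b45_54,74
bmi,b25_29_9,control,b45_54,202
bmi,ge30,patient,b18_44,32
bmi,ge30,control,b18_44,159
bmi,ge30,patient,b45_54,76
bmi,ge30,control,b45_54,122
exercise,ge4_per_week,patient,b18_44,16
exercise,ge4_per_week,control,b18_44,189
exercise,ge4_per_week,patient,b45_54,15
exercise,ge4_per_week,control,b45_54,66
exercise,w2_3_per_week,patient,b18_44,24
exercise,w2_3_per_week,control,b18_44,344
exercise,w2_3_per_week,patient,b45_54,32
exercise,w2_3_per_week,control,b45_54,99
exercise,once_per_week,patient,b18_44,18
exercise,once_per_week,control,b18_44,152
exercise,once_per_week,patient,b45_54,23
exercise,once_per_week,control,b45_54,68
exercise,m2_3_per_month,patient,b18_44,17
exercise,m2_3_per_month,control,b18_44,158
exercise,m2_3_per_month,patient,b45_54,16
exercise,m2_3_per_month,control,b45_54,48
exercise,rare_or_none,patient,b18_44,52
exercise,rare_or_none,control,b18_44,406
exercise,rare_or_none,patient,b45_54,103
exercise,rare_or_none,control,b45_54,238
vegetables,ge6_days,patient,b18_44,51
vegetables,ge6_days,control,b18_44,537
vegetables,ge6_days,patient,b45_54,87
vegetables,ge6_days,control,b45_54,226
vegetables,lt6_days,patient,b18_44,78
vegetables,lt6_days,control,b18_44,721
vegetables,lt6_days,patient,b45_54,112
vegetables,lt6_days,control,b45_54,294
salting,before_tasting,patient,b18_44,9
salting,before_tasting,control,b18_44,66
salting,before_tasting,patient,b45_54,19
salting,before_tasting,control,b45_54,15
salting,when_needed,patient,b18_44,86
salting,when_needed,control,b18_44,782
salting,when_needed,patient,b45_54,118
salting,when_needed,control,b45_54,346
salting,never,patient,b18_44,36
salting,never,control,b18_44,411
salting,never,patient,b45_54,55
salting,never,control,b45_54,163
alcohol_freq,ge2_per_week,patient,b18_44,26
alcohol_freq,ge2_per_week,control,b18_44,232
alcohol_freq,ge2_per_week,patient,b45_54,54
alcohol_freq,ge2_per_week,control,b45_54,92
alcohol_freq,once_per_week,patient,b18_44,20
alcohol_freq,once_per_week,control,b18_44,206
alcohol_freq,once_per_week,patient,b45_54,33
alcohol_freq,once_per_week,control,b45_54,73
alcohol_freq,m2_3_per_month,patient,b18_44,34
alcohol_freq,m2_3_per_month,control,b18_44,334
alcohol_freq,m2_3_per_month,patient,b45_54,38
alcohol_freq,m2_3_per_month,control,b45_54,145
alcohol_freq,few_per_year,patient,b18_44,38
alcohol_freq,few_per_year,control,b18_44,379
alcohol_freq,few_per_year,patient,b45_54,51
alcohol_freq,few_per_year,control,b45_54,170
alcohol_freq,none,patient,b18_44,13
alcohol_freq,none,control,b18_44,101
alcohol_freq,none,patient,b45_54,25
alcohol_freq,none,control,b45_54,42
alcohol_7d,excess,patient,b18_44,23
alcohol_7d,excess,control,b18_44,174
alcohol_7d,excess,patient,b45_54,20
alcohol_7d,excess,control,b45_54,64
alcohol_7d,no_excess,patient,b18_44,103
alcohol_7d,no_excess,control,b18_44,1075
alcohol_7d,no_excess,patient,b45_54,171
alcohol_7d,no_excess,control,b45_54,454
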