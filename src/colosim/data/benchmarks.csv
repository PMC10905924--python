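metric,sex,age_lo,age_hi,value
early_adenoma_prevalence,male,40,45,10.340638103274241
advanced_adenoma_prevalence,male,40,45,2.647041116337371
early_adenoma_prevalence,male,45,50,12.744703497733449
advanced_adenoma_prevalence,male,45,50,3.7015818773254892
early_adenoma_prevalence,male,50,55,15.477969824281477
advanced_adenoma_prevalence,male,50,55,4.9934929788629301
early_adenoma_prevalence,male,55,60,18.489990264373464
advanced_adenoma_prevalence,male,55,60,6.5519132924514416
early_adenoma_prevalence,male,60,65,21.697106993433774
advanced_adenoma_prevalence,male,60,65,8.4000000000000004
early_adenoma_prevalence,male,65,70,24.989438866293533
advanced_adenoma_prevalence,male,65,70,10.55202933783349
early_adenoma_prevalence,male,70,75,28.244885766126636
advanced_adenoma_prevalence,male,70,75,13.011427682930176
early_adenoma_prevalence,male,75,80,31.346693437757413
advanced_adenoma_prevalence,male,75,80,15.770278513844097
early_adenoma_prevalence,female,40,45,6.8937587355161618
advanced_adenoma_prevalence,female,40,45,1.7646940775582474
early_adenoma_prevalence,female,45,50,8.4964689984889645
advanced_adenoma_prevalence,female,45,50,2.4677212515503264
early_adenoma_prevalence,female,50,55,10.318646549520984
advanced_adenoma_prevalence,female,50,55,3.3289953192419537
early_adenoma_prevalence,female,55,60,12.326660176248978
advanced_adenoma_prevalence,female,55,60,4.3679421949676289
early_adenoma_prevalence,female,60,65,14.464737995622517
advanced_adenoma_prevalence,female,60,65,5.6000000000000005
early_adenoma_prevalence,female,65,70,16.659625910862356
advanced_adenoma_prevalence,female,65,70,7.0346862252223277
early_adenoma_prevalence,female,70,75,18.829923844084426
advanced_adenoma_prevalence,female,70,75,8.6742851219534511
early_adenoma_prevalence,female,75,80,20.897795625171611
advanced_adenoma_prevalence,female,75,80,10.513519009229398
crc_incidence,male,30,35,25.422978671236415
crc_mortality,male,30,35,0
crc_incidence,male,35,40,51.364366454001789
crc_mortality,male,35,40,3.8823007492268808
crc_incidence,male,40,45,64.566285029888604
crc_mortality,male,40,45,22.527705602408762
crc_incidence,male,45,50,80.170448269543826
crc_mortality,male,45,50,28.4375117832375
crc_incidence,male,50,55,98.086173172292476
crc_mortality,male,50,55,35.491668542629178
crc_incidence,male,55,60,117.94299454495381
crc_mortality,male,55,60,43.688672599967617
crc_incidence,male,60,65,139.04474463883912
crc_mortality,male,60,65,52.905630039254447
crc_incidence,male,65,70,160.39456937898629
crc_mortality,male,65,70,62.867529948816838
crc_incidence,male,70,75,180.81681177499095
crc_mortality,male,70,75,73.143865655383124
crc_incidence,male,75,80,199.16480081619994
crc_mortality,male,75,80,83.18922126603357
crc_incidence,male,80,85,214.55533173104192
crc_mortality,male,80,85,92.431274039533619
crc_incidence,male,85,90,226.54350526281101
crc_mortality,male,85,90,100.38698274346054
crc_incidence,male,90,101,235.97998557715133
crc_mortality,male,90,101,107.44438802659333
crc_incidence,female,30,35,16.954701281810394
crc_mortality,female,30,35,0
crc_incidence,female,35,40,34.24451018336292
crc_mortality,female,35,40,2.5908852691707356
crc_incidence,female,40,45,43.047078751686627
crc_mortality,female,40,45,15.019545521965174
crc_incidence,female,45,50,53.452255917387646
crc_mortality,female,45,50,18.960380263585769
crc_incidence,female,50,55,65.400427329955022
crc_mortality,female,50,55,23.664993324640619
crc_incidence,female,55,60,78.645887457267946
crc_mortality,female,55,60,29.133082369754973
crc_incidence,female,60,65,92.726213230362873
crc_mortality,female,60,65,35.283816787531727
crc_incidence,female,65,70,106.97866878979244
crc_mortality,female,65,70,41.935393663201502
crc_incidence,female,70,75,120.62077731991174
crc_mortality,female,70,75,48.802616505199204
crc_incidence,female,75,80,132.88771561247557
crc_mortality,female,75,80,55.523384532880186
crc_incidence,female,80,85,143.18720743148896
crc_mortality,female,80,85,61.716207131438523
crc_incidence,female,85,90,151.21458663725045
crc_mortality,female,85,90,67.055762047252259
crc_incidence,female,90,101,157.96027885129973
crc_mortality,female,90,101,72.164636798858226
rectal_fraction,all,0,101,0.29999999999999999
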