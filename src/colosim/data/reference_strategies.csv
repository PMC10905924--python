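# Externally reported per-1000 outcomes for efficient organized CRC screening
# strategies (main analysis: trial participation, surveillance enabled).
# Values as printed: integer per-1000 counts, harms to 2 dp, ratios to 1 dp.
# efficiency_ratio is empty for each category's default strategy.
category,start_age,stop_age,interval,colonoscopies,non_col_tests,reduced_crc_cases,reduced_crc_deaths,lyg,col_deaths,years_lost_cols,efficiency_ratio,additional_cols_per_lyg,near_efficient
FIT,50,70,3,920,6015,13,7,83,0.04,0.67,,10.5,0
FIT,45,70,3,1068,7542,16,8,98,0.03,0.71,9.6,10.4,0
FIT,40,70,3,1202,9064,17,8,105,0.05,1.05,12.7,11.0,1
FIT,45,70,2,1344,10342,19,9,114,0.06,1.27,13.7,11.4,1
FIT,40,70,2,1522,12444,20,9,126,0.05,1.09,13.8,11.7,0
FIT,40,75,2,1685,13954,21,10,133,0.06,1.22,15.4,12.3,0
FIT,40,80,2,1812,15196,21,11,136,0.06,1.25,16.8,13.0,0
FIT,40,70,1,2232,20461,23,11,145,0.09,2.26,21.1,15.1,1
FIT,40,75,1,2476,22938,24,12,151,0.10,2.25,22.7,16.1,0
FIT,40,80,1,2670,24963,24,12,155,0.10,2.23,24.2,16.9,0
NCPCS,50,70,3,1880,5585,19,8,93,0.07,1.32,,19.6,0
NCPCS,40,70,3,2542,8294,22,9,119,0.10,2.35,26.0,21.0,0
NCPCS,40,70,2,3107,10553,24,10,130,0.12,2.66,33.3,23.5,0
NCPCS,40,70,1,4107,14715,25,11,141,0.13,3.23,46.3,28.7,0
NCPCS,40,75,1,4565,16440,26,12,145,0.15,3.32,51.7,31.1,0
NCPCS,40,80,1,4930,17855,27,12,148,0.16,3.41,56.0,33.0,0
RS,50,70,3,2564,4992,22,10,114,0.08,1.47,,22.1,0
RS,45,70,3,3054,6220,24,10,128,0.12,2.53,34.7,23.5,0
RS,40,70,3,3539,7475,24,10,138,0.11,2.60,40.6,25.3,0
RS,40,75,3,3928,8346,26,11,145,0.12,2.83,44.1,26.8,0
RS,40,75,2,4543,9899,26,12,151,0.14,3.50,53.5,29.8,0
RS,40,80,2,4903,10748,27,12,152,0.14,3.39,60.4,31.9,0
RS,40,80,1,5901,13325,27,12,154,0.20,4.73,83.1,38.0,0
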