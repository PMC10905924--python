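adenoma_risk:
  edges:
  - 0
  - 20
  - 30
  - 40
  - 45
  - 50
  - 55
  - 60
  - 65
  - 70
  - 75
  - 80
  - 101
  female:
  - 0.0
  - 0.002050825711451158
  - 0.004101651422902316
  - 0.008203302845804632
  - 0.007664261053204565
  - 0.00813975720686528
  - 0.009126087480961933
  - 0.009737204871308717
  - 0.010405544935290749
  - 0.010530788040503928
  - 0.010692591382612117
  - 0.009623332244350906
  male:
  - 0.0
  - 0.0031485203729830543
  - 0.006297040745966109
  - 0.012594081491932217
  - 0.01139176599642944
  - 0.012794421650633745
  - 0.01419774997341124
  - 0.015261064125376355
  - 0.01631068553879819
  - 0.016666472930527317
  - 0.01721785286570693
  - 0.015496067579136234
aggressive_fraction: 0.12684527548474173
min_genesis_age: 20
p_advanced_to_preclinical: 0.18
p_early_to_advanced: 0.18
p_early_to_advanced_indolent: 0.023783885038158765
p_growth: 0.12
rectal_fraction: 0.3
serrated_risk:
  edges:
  - 0
  - 20
  - 30
  - 40
  - 45
  - 50
  - 55
  - 60
  - 65
  - 70
  - 75
  - 80
  - 101
  female:
  - 0.0
  - 0.0
  - 8.984873680169205e-06
  - 1.796974736033841e-05
  - 3.593949472067682e-05
  - 5.3909242081015236e-05
  - 8.984873680169204e-05
  - 0.00013477310520253804
  - 0.0001796974736033841
  - 0.00022462184200423008
  - 0.0002695462104050761
  - 0.0002695462104050761
  male:
  - 0.0
  - 0.0
  - 1.0570439623728477e-05
  - 2.1140879247456954e-05
  - 4.228175849491391e-05
  - 6.342263774237088e-05
  - 0.00010570439623728475
  - 0.00015855659435592715
  - 0.0002114087924745695
  - 0.00026426099059321194
  - 0.0003171131887118543
  - 0.0003171131887118543
sojourn_mean: 4.5
stage_dist_screen:
- 0.45
- 0.3
- 0.17
- 0.08
stage_dist_symptomatic:
- 0.18
- 0.27
- 0.32
- 0.23
survival_rate:
- 0.0021606733195366967
- 0.008642693278146787
- 0.03457077311258715
- 0.17285386556293575
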