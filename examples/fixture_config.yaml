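n_individuals: 12
loci:
- name: '2004'
  alleles:
  - 120
  - 122
  - 124
  - 126
  - 128
  - 130
  frequencies:
  - 0.3
  - 0.25
  - 0.2
  - 0.15
  - 0.06
  - 0.04
- name: CXX119
  alleles:
  - 130
  - 132
  - 134
  - 136
  - 138
  - 140
  frequencies:
  - 0.28
  - 0.24
  - 0.2
  - 0.14
  - 0.08
  - 0.06
- name: CXX173
  alleles:
  - 140
  - 142
  - 144
  - 146
  - 148
  frequencies:
  - 0.35
  - 0.25
  - 0.18
  - 0.12
  - 0.1
- name: FH2001
  alleles:
  - 150
  - 152
  - 154
  - 156
  - 158
  - 160
  frequencies:
  - 0.25
  - 0.22
  - 0.18
  - 0.15
  - 0.12
  - 0.08
- name: FH2054
  alleles:
  - 160
  - 162
  - 164
  - 166
  - 168
  - 170
  - 172
  frequencies:
  - 0.3
  - 0.22
  - 0.18
  - 0.12
  - 0.08
  - 0.06
  - 0.04
- name: FH2088
  alleles:
  - 170
  - 172
  - 174
  - 176
  - 178
  frequencies:
  - 0.26
  - 0.24
  - 0.2
  - 0.16
  - 0.14
- name: FH2137
  alleles:
  - 180
  - 182
  - 184
  - 186
  - 188
  - 190
  - 192
  - 194
  frequencies:
  - 0.22
  - 0.2
  - 0.18
  - 0.14
  - 0.1
  - 0.08
  - 0.05
  - 0.03
- name: FH2611
  alleles:
  - 190
  - 192
  - 194
  - 196
  - 198
  frequencies:
  - 0.3
  - 0.26
  - 0.22
  - 0.12
  - 0.1
- name: FH2670
  alleles:
  - 200
  - 202
  - 204
  - 206
  - 208
  - 210
  frequencies:
  - 0.28
  - 0.22
  - 0.18
  - 0.14
  - 0.1
  - 0.08
- name: FH3725
  alleles:
  - 210
  - 212
  - 214
  - 216
  - 218
  - 220
  frequencies:
  - 0.32
  - 0.24
  - 0.16
  - 0.12
  - 0.09
  - 0.07
dropout_rate: 0.1
false_allele_rate: 0.01
locus_failure_rate: 0.05
n_replicates: 3
seasons:
- label: winter
  week_start: 1
  week_end: 9
  scat_age_max_days: 14
- label: summer
  week_start: 17
  week_end: 27
  scat_age_max_days: 7
- label: fall
  week_start: 40
  week_end: 48
  scat_age_max_days: 14
diet_base:
  winter:
    deer: 0.45
    wild_pig: 0.05
    rabbit: 0.18
    small_mammal: 0.55
    other_mammal: 0.1
    bird: 0.04
    insect: 0.02
    blackberry: 0.005
    persimmon: 0.02
    other_fruit_vegetation: 0.28
    other: 0.05
  summer:
    deer: 0.1
    wild_pig: 0.05
    rabbit: 0.15
    small_mammal: 0.3
    other_mammal: 0.08
    bird: 0.05
    insect: 0.15
    blackberry: 0.15
    persimmon: 0.005
    other_fruit_vegetation: 0.45
    other: 0.06
  fall:
    deer: 0.4
    wild_pig: 0.07
    rabbit: 0.13
    small_mammal: 0.35
    other_mammal: 0.09
    bird: 0.04
    insect: 0.06
    blackberry: 0.01
    persimmon: 0.2
    other_fruit_vegetation: 0.28
    other: 0.05
pulses:
- resource: fawn
  item: deer
  peak_week: 19
  sd_weeks: 1.5
  height: 10.0
  vulnerability_weeks: 3
  effect_scale: 2.0
- resource: blackberry
  item: blackberry
  peak_week: 24
  sd_weeks: 1.2
  height: 50.0
  vulnerability_weeks: 0
  effect_scale: 1.0
- resource: persimmon
  item: persimmon
  peak_week: 42
  sd_weeks: 2.0
  height: 30.0
  vulnerability_weeks: 0
  effect_scale: 1.0
pulse_effect: 3.0
diet_consistency: 1.0
scats_per_individual_per_season: 2.0
hair_width_params:
  fawn_mean: 55.0
  fawn_sd: 8.0
  adult_mean: 105.0
  adult_sd: 10.0
fawn_fraction_peak: 0.85
n_transects: 10
transect_length_km: 1.6
home_scatter_km: 0.5
study_start: '2020-01-06'
n_weeks: 52
seed: 0
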