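# Full-NPK treatment on a humid rainforest-transition site.
# Site supply values are control-plot uptakes (with omission-plot extras);
# fertilizer amounts accept unit-tagged strings or bare numbers in g m-2.
parameters:
  K_NI: 6.1
  KMAX: 4
  TSUM_NPKI: 272

site_supply:
  base_N: "194.2 kg N ha-1"
  base_P: "19.9 kg P ha-1"
  base_K: "88.0 kg K ha-1"
  extra_N: "62.7 kg N ha-1"
  extra_P: "11.5 kg P ha-1"
  extra_K: "7.2 kg K ha-1"

fertilizer:
  - {day: 30, N: "150 kg/ha", P: "100 kg/ha", K: "150 kg/ha"}
  - {day: 90, N: "150 kg/ha", K: "150 kg/ha"}

scenario:
  name: full-npk
  season_length: 420
  planting_date: "2016-05-24"
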