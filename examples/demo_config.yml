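# Scaled-down study configuration: two stations per isohyet zone with their
# long-term mean annual rainfall, 20 synthetic seasons each, both soils and
# both cultivars (8 x 20 x 2 x 2 = 640 runs).
sites:
  - {name: Nara, latitude: 15.2, isohyet_zone: "400-600", target_annual_rainfall: 426, n_seasons: 20}
  - {name: Mopti, latitude: 14.5, isohyet_zone: "400-600", target_annual_rainfall: 492, n_seasons: 20}
  - {name: Segou, latitude: 13.4, isohyet_zone: "600-800", target_annual_rainfall: 661, n_seasons: 20}
  - {name: Kolokani, latitude: 13.6, isohyet_zone: "600-800", target_annual_rainfall: 753, n_seasons: 20}
  - {name: Samanko, latitude: 12.5, isohyet_zone: "800-1000", target_annual_rainfall: 920, n_seasons: 20}
  - {name: Kita, latitude: 13.1, isohyet_zone: "800-1000", target_annual_rainfall: 986, n_seasons: 20}
  - {name: Kangaba, latitude: 11.9, isohyet_zone: ">1000", target_annual_rainfall: 1040, n_seasons: 20}
  - {name: Sikasso, latitude: 11.4, isohyet_zone: ">1000", target_annual_rainfall: 1170, n_seasons: 20}
soils: [low_swhc, high_swhc]
cultivars: [CSM63E, CSM335]
seed: 11
k_scenarios: 3
cluster_method: kmeans
output_dir: scratch/demo_run
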