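# Self-contained demo study: every stage simulates its inputs from the seed.
seed: 1
output_dir: results/demo
stages:
  splice:
    simulate: {psi: 0.945, depth_per_junction: 10000, n_transcripts: 10000}
    min_reads: 3
  tfl:
    simulate:
      groups: {WT: 1.06, HOM: 0.96}
      n_profiles_per_group: 2
      n_sarcomeres: 5
      sl: 2.6
      sigma: 0.15
      bump_rel_amp: 0.15
      noise_sd: 0.0
    mask_fraction: 0.5
  mech:
    simulate:
      groups:
        WT:  {p0min: 2.0, p0max: 20.0, fhalf: 45.0, k: 8.0}
        HOM: {p0min: 2.0, p0max: 12.0, fhalf: 50.0, k: 8.0}
      muscle: edl
      n_per_group: 3
      noise_sd: 0.3
  morph:
    simulate:
      n_samples: 2
      n_per_sample: 80
      groups:
        WT:  {feret_mean: 40.0, feret_sd: 8.0, type_probs: [0.01, 0.12, 0.23, 0.64]}
        HOM: {feret_mean: 32.0, feret_sd: 8.0, type_probs: [0.06, 0.23, 0.25, 0.46]}
    min_area: 300.0
    edges: [0, 10, 20, 30, 40, 50, 60, 80]
  survival:
    records:
      - {animal_id: m01, genotype: HOM, time_days: 110, event: true}
      - {animal_id: m02, genotype: HOM, time_days: 128, event: true}
      - {animal_id: m03, genotype: HOM, time_days: 136, event: true}
      - {animal_id: m04, genotype: HOM, time_days: 150, event: true}
      - {animal_id: m05, genotype: HOM, time_days: 164, event: false}
      - {animal_id: m06, genotype: WT, time_days: 200, event: false}
      - {animal_id: m07, genotype: WT, time_days: 210, event: false}
      - {animal_id: m08, genotype: WT, time_days: 220, event: false}
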