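# Demo: synthetic 4x4 lattice, 6 years, 2 survey instruments, full pipeline.
# Run with:  caresae run examples/demo_config.yaml
output_dir: demo_output
seed: 12345
simulate:
  n_rows: 4
  n_cols: 4
  years: [2014, 2015, 2016, 2017, 2018, 2019]
  surveys:
    - survey_id: spa_2015
      year: 2015
      fractions: {hospital/public: 1.0, health_center/public: 0.5, clinic/private: 0.35}
      offset: 0.25
    - survey_id: sdi_2018
      year: 2018
      fractions: {hospital/public: 1.0, health_center/public: 0.6, clinic/private: 0.25}
      offset: -0.25
metrics: [readiness, process_quality]
model_ids: [1, 2, 3, 4, 5, 6, 7]
years: [2014, 2015, 2016, 2017, 2018, 2019]
run_cv: true
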