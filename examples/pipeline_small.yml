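# Pipeline settings for the bundled two-species scenario. Model settings
# keep the conventional SDM protocol defaults; evaluation repetitions and
# contrast-sample sizes are reduced for a quick demonstration run (all
# overrides are echoed into the output manifest).
climate_dir: scenario_out
occurrences_csv: scenario_out/occurrences.csv
fossils_csv: scenario_out/fossils.csv
out_dir: pipeline_out
n_background: 500
n_pseudoabsence: 500
n_reps: 10
seed: 0
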