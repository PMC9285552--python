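# Demo pipeline run: 2 Latin squares x 3 cows x 3 diets, 4 AMS visits
# and 4 head-box measurements per cow-diet. Completes in seconds.
#   entch4 run --config configs/demo.yaml --out demo_out
seed: 20210930
out_dir: demo_out
n_squares: 2
cows_per_square: 3
visits_per_cow_diet: 4
visit_duration_s: 420
headbox_reps: 4
co2_threshold_ppm: 500.0
min_retained_s: 60
equation: eq2
recovery_correction: false
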