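# End-to-end demo: simulate 8 toy counties over four years, filter and
# aggregate posts, validate internet streams against the clinical stream,
# and map intensity.  Run:  aerosurv run --config examples/demo.yaml --seed 1
seed: 1
out_dir: run
simulate:
  n_regions: 8
  n_days: 1461
  start_date: "2016-01-01"
thresholds:
  min_ed_per_100k: 450
  min_posts_per_100k: 80
  min_population: 500000
exclude_ranges: []
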