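# Demo pipeline configuration: two synthetic streamlined genomes and one
# simulated 4:1 read set.  Run with:
#   streamline-scan run examples/demo-config.yaml
# Completes in well under a minute on one CPU; outputs land in demo-out/.
seed: 3
output_dir: demo-out
genomes:
  - id: GA
    synth: {length: 100000, gc: 0.627, seed: 101}
  - id: GB
    synth: {length: 100000, gc: 0.639, seed: 202}
reads:
  - id: meta
    simulate:
      members:
        - {genome: GA, abundance: 0.8}
        - {genome: GB, abundance: 0.2}
      read_count: 5000
      read_length: 100
      seed: 7
# Stage thresholds (defaults shown; uncomment to override)
# recruitment: {mode: abs_len, min_identity: 95.0, min_len: 50, k: 13}
# ani: {fragment_len: 1020, min_identity: 30.0, min_coverage: 0.7, k: 11}
# islands: {window: 10000, step: 1000, ratio_threshold: 0.2, merge_gap: 2000, min_len: 5000}
# spacers: {policy: clamp}
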