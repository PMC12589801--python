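# Study configuration mirroring the published four-condition boron comparison.
# Load with pbct_microdose.load_study_config(); conditions default to the
# table2 presets for the listed beams.
beams: [70, 190]
master_seed: 1
n_events: 20000
n_repeats: 10
n_calibration_events: 1500
repeat_jitter_cv: 0.08   # used by depth scans; boron-study presets carry their own
output_dir: out
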