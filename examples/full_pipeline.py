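"""Run the full replicated pipeline end to end at desk scale.

Sweeps window sizes, trains one model per (window, replicate), averages
replicate error maps, selects the window size with the lowest improv
("test") reconstruction error, and runs the ROI group comparison (robust
summaries of log-MSE, Welch's t / Mann-Whitney / permutation, Cohen's d
and Cliff's delta) at the selected window.
"""

import nirsae as na

config = na.PipelineConfig(
    cohort=na.CohortConfig(n_group_a=6, n_group_b=4, seed=2),
    window_candidates=(15, 20),
    stride=30,
    train=na.TrainConfig(epochs=20),
    n_replicates=2,
    n_permutations=5000,
    master_seed=7,
)
report = na.run_pipeline(config)

print(report.sweep.to_frame().to_string(index=False))
print(f"selected window size: {report.selected_window}")
print("\ntop channels on improv:")
print(report.channel_ranking.head(3).to_string(index=False))
print()
print(report.comparison.to_text())
# With the default planted effect the ROI (channels 1 and 15) should top the
# ranking and the p90 log-MSE summary should separate the groups; on a null
# cohort (burst_rate=0, variance_inflation=1) all nine p-values are uniform.
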