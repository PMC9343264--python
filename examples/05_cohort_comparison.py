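"""Outcome-group comparison with the sampling-frequency sweep.

Runs the full pipeline on a reduced synthetic cohort (10 vs 24 patients, 6 h
records to keep this example quick), prints the headline comparisons (index
medians per group, Mann-Whitney p, AUC with 95% CI), and shows where on the
(interval x method) grid SV discriminates best.  A p-value surface plot in
the style of a sampling-frequency sweep figure is written next to the other
outputs.
"""

from bpvar import RunConfig, run_pipeline
from bpvar.plots import plot_frequency_sweep
from bpvar.synthetic import SynthConfig

cfg = RunConfig(
    out_dir="scratch/example05",
    synth=SynthConfig(duration_h=6.0, truncation_probs=(1, 0, 0)),
    seed=3,
)
bundle = run_pipeline(cfg)

cols = ["statistic", "median_favorable", "median_unfavorable", "p_value", "auc"]
print(bundle["comparisons"][cols].round(3).to_string(index=False))

sweep = bundle["frequency_sweep"]
sv = sweep[sweep["index"] == "sv"]
best = sv.loc[sv.p_value.idxmin()]
print(
    f"\nbest SV cell: {best.interval_s:.0f} s / {best.method} "
    f"(p = {best.p_value:.4f}, AUC = {best.auc:.2f})"
)
plot_frequency_sweep(sweep, path="scratch/example05/frequency_sweep.png")
print("wrote scratch/example05/ (tidy CSVs, run log, sweep figure)")
print("Higher midrange-band variability in the unfavorable group is best seen")
print("after averaging over bins whose Nyquist rate covers that band.")
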