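"""Score osmotic-swelling assays for burst frequency, timing and position.

Immersion in water swells the follicle until the basement membrane
breaches. This example generates swelling time-lapse series for four
genotype presets, detects bursts from frame-to-frame area drops (or the
breach-marker channel), classifies each breach along the A-P axis, and
prints the cohort table.
"""

from follimech import GeneratorConfig, cohort_stats, detect_burst, make_swelling_series

config = GeneratorConfig(seed=5)
N = 12  # follicles per cohort

events, series = {}, {}
for genotype in ("WT", "fat2", "collagenase", "EHBP1-OE"):
    sers = [make_swelling_series(genotype, config, stage=7, salt=i)
            for i in range(N)]
    events[genotype] = [detect_burst(s) for s in sers]
    series[genotype] = sers

table = cohort_stats(events, series)
cols = ["group", "burst_percent", "median_burst_time_s",
        "n_pole", "n_terminal", "n_central", "mean_aspect_ratio_before"]
print(table[cols].to_string(index=False))

print("\nCollagenase-digested membranes burst at the first frame after "
      "immersion; EHBP1 overexpression (extra Collagen IV fibrils) fully "
      "resists bursting; wild-type follicles fail preferentially at the "
      "poles, where the basement membrane is softest.")
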