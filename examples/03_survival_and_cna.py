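"""Melanoma-free survival and copy-number burden.

Simulates a control and a UV-accelerated group of exponential survival
times with right-censoring, compares them with the Gehan-Breslow-
Wilcoxon weighted log-rank test, and quantifies copy-number burden as
the fraction of the segmented genome footprint beyond the |log2| >= 0.2,
>= 5 bins threshold.
"""

from uvsig.cna import filter_segments, genome_altered_fraction
from uvsig.stats import gehan_breslow_wilcoxon, km_estimate
from uvsig.synthetic import ClinicalConfig, simulate_clinical

cfg = ClinicalConfig(
    seed=5,
    survival_groups={
        "control": (20, 60.0, 80.0),  # n, exponential scale (wk), horizon
        "uvb": (20, 20.0, 80.0),
    },
    n_samples=6,
    altered_fraction=0.25,
)
segments, records, truth = simulate_clinical(cfg)

curves = km_estimate(records)
for group, curve in curves.items():
    median = curve[curve["survival"] <= 0.5]["time"].min()
    print(f"{group}: Kaplan-Meier median survival {median:.1f} weeks")

chi2, p = gehan_breslow_wilcoxon(
    [r for r in records if r.group == "control"],
    [r for r in records if r.group == "uvb"],
)
print(f"Gehan-Breslow-Wilcoxon: chi2 = {chi2:.2f}, p = {p:.2e}")
print("(the at-risk weighting emphasises the early separation UV causes)\n")

for sid, segs in segments.items():
    altered = filter_segments(segs, log2_threshold=0.2, min_bins=5)
    frac = genome_altered_fraction(segs, altered)
    print(f"{sid}: altered genome fraction {frac[sid]:.3f} "
          f"({len(altered)}/{len(segs)} segments pass)")
print(f"\nplanted fraction was {cfg.altered_fraction}; the generator tiles")
print("segments so the recovered fraction matches it exactly.")
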