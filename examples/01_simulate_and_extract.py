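"""Simulate a UV-exposure cohort and extract its mutational signatures.

Generates 20 tumors from a UVB-like + flat background mixture (three
exposure groups, as in a cohort of unexposed, UVA- and UVB-irradiated
mice), runs ensemble-consensus calling, dipyrimidine collapsing and
SBS96 classification, then de novo NMF extraction with bootstrap rank
selection and NNLS activity attribution.
"""

import numpy as np

from uvsig.comparison import cosine_similarity
from uvsig.signatures import attribute_activities, extract_with_stability
from uvsig.spectrum import build_sbs96
from uvsig.synthetic import SimulationConfig, generate_reference, simulate_catalog
from uvsig.variants import (
    build_consensus,
    classify_events,
    collapse_dinucleotide_events,
)

cfg = SimulationConfig(seed=7, n_samples=20, dinucleotide_rate=0.03)
bundle = generate_reference(cfg)
callsets, truth = simulate_catalog(bundle, cfg)

consensus = build_consensus(list(callsets.values()))
events = classify_events(collapse_dinucleotide_events(consensus, bundle), bundle)
catalog = build_sbs96(events)
print(f"consensus calls: {len(consensus)}, collapsed events: {len(events)}")
print(f"catalog: {len(catalog.sample_ids)} samples x 96 channels, "
      f"{catalog.counts.sum()} SNVs")

signatures, report = extract_with_stability(
    catalog, rank_range=range(1, 5), n_bootstrap=30, seed=7
)
print("\nrank selection (stability = mean bootstrap silhouette; a rank is")
print("admissible when its error reaches the Poisson noise floor):")
print(report.metrics[["stability", "reconstruction_error"]].round(3))
print(f"selected rank: {report.selected_rank}")

for j, label in enumerate(signatures.labels):
    cos = [
        cosine_similarity(signatures.profiles[:, j], truth.signatures[:, k])
        for k in range(truth.signatures.shape[1])
    ]
    k = int(np.argmax(cos))
    print(f"{label}: cosine {cos[k]:.3f} to planted "
          f"'{truth.signature_names[k]}' profile")

activities = attribute_activities(catalog, signatures)
print("\nper-group mean activity (mutations attributed per signature):")
frame = activities.to_frame()
frame["group"] = [truth.sample_groups[s] for s in frame.index]
print(frame.groupby("group").mean().round(1))
print("\nUVB-exposed tumors carry an order of magnitude more UVB-signature")
print("activity than unexposed ones; the background is uniform across groups.")
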