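import numpy as np
import pytest

from uvsig.synthetic import SimulationConfig, generate_reference, simulate_catalog
from uvsig.variants import (
    build_consensus,
    classify_events,
    collapse_dinucleotide_events,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across test modules: reference
    bundle, per-caller call sets, ground truth, and the classified
    consensus event stream."""
    cfg = SimulationConfig(
        seed=5,
        n_samples=6,
        reference_length_bp=100_000,
        signature_spec=[("uvb_like", 150.0), ("flat", 60.0)],
        dinucleotide_rate=0.05,
        strand_bias_rho=3.0,
        caller_dropout=0.02,
        caller_false_positives=4,
    )
    bundle = generate_reference(cfg)
    callsets, truth = simulate_catalog(bundle, cfg)
    consensus = build_consensus(list(callsets.values()))
    events = classify_events(
        collapse_dinucleotide_events(consensus, bundle), bundle
    )
    return {
        "config": cfg,
        "bundle": bundle,
        "callsets": callsets,
        "truth": truth,
        "consensus": consensus,
        "events": events,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
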