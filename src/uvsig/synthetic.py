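"""Synthetic data generation for end-to-end pipeline testing.

Emulates the statistical structure of a UV-exposure melanoma sequencing
study without any raw reads: a random reference with stranded gene
models, multi-sample SNV catalogs drawn from a mixture of a UVB-like
signature (C>T concentrated at 5'-T dipyrimidines, biased toward the
untranscribed strand, with CC>TT dinucleotide events) and a flat
background signature, per-caller call sets with dropout and private
false positives to exercise consensus filtering, plus copy-number
segments with a planted altered fraction and two-group exponential
survival times.

Every generator is deterministic under its seed, and the module records
the ground truth (true signatures, activities, per-event provenance) so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cna import CnaSegment
from .sbs import (
    CHANNEL_INDEX,
    CHANNELS,
    COMPLEMENT,
    PYRIMIDINES,
    pyrimidine_context,
)
from .stats import SurvivalRecord
from .variants import VariantCall

CALLER_IDS = ("varscan2", "mutect2", "strelka2")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort."""

    seed: int = 0
    reference_length_bp: int = 200_000
    gc_fraction: float = 0.42
    n_genes: int = 40
    n_samples: int = 30
    #: (signature kind or 96-profile, mean mutations per sample) pairs
    signature_spec: list = field(
        default_factory=lambda: [("uvb_like", 300.0), ("flat", 100.0)]
    )
    #: shape of the per-sample Gamma activity distribution (CV = shape**-0.5)
    activity_shape: float = 4.0
    #: exposure groups: name -> (fraction of samples, per-signature activity
    #: multipliers).  The default mirrors a cohort of unexposed, UVA- and
    #: UVB-exposed tumors: the first (UVB-like) signature is nearly absent
    #: outside the UVB group while the background signature is uniform, and
    #: the multipliers average to 1 so configured means are cohort-wide
    #: expectations.  None disables grouping (all samples share the means).
    group_spec: dict | None = field(
        default_factory=lambda: {
            "no_uv": (1 / 3, [0.05, 1.0]),
            "uva": (1 / 3, [0.05, 1.0]),
            "uvb": (1 / 3, [2.9, 1.0]),
        }
    )
    #: untranscribed:transcribed odds for genic C>T events
    strand_bias_rho: float = 1.0
    #: fraction of C>T events emitted as CC>TT dinucleotide pairs
    dinucleotide_rate: float = 0.0
    #: per-caller probability that a true variant is missed
    caller_dropout: float = 0.0
    #: private false positives per caller per sample
    caller_false_positives: int = 0
    chrom_name: str = "chr1"

    def __post_init__(self):
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must be in (0, 1)")
        if not (0 <= self.dinucleotide_rate < 1):
            raise ValueError("dinucleotide_rate must be in [0, 1)")
        if self.strand_bias_rho < 1:
            raise ValueError("strand_bias_rho must be >= 1")
        if any(mean < 0 for _, mean in self.signature_spec):
            raise ValueError("mean activities must be >= 0")


@dataclass
class ReferenceBundle:
    """Reference sequence with gene annotation and capture regions."""

    sequence: dict[str, str]
    genes: list[tuple[str, int, int, str, str]]  # chrom,start,end,name,strand
    capture_regions: list[tuple[str, int, int]]

    def __getitem__(self, chrom):
        return self.sequence[chrom]


@dataclass
class GroundTruth:
    signatures: np.ndarray  # 96 x K
    signature_names: list[str]
    activities: np.ndarray  # n_samples x K realized SNV counts
    sample_ids: list[str]
    sample_groups: dict[str, str] = field(default_factory=dict)
    event_provenance: list[dict] = field(default_factory=list)
    n_dinucleotide: int = 0


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Random reference at the requested GC with non-overlapping genes.

    Genes alternate between + and - strands, cover roughly half of the
    sequence, and the whole chromosome forms a single capture region.
    """
    if config.reference_length_bp < 10_000:
        raise ValueError("reference must be at least 10 kb")
    rng = np.random.default_rng(config.seed)
    L = config.reference_length_bp
    p_gc = config.gc_fraction
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=L, p=probs))

    slot = L // max(config.n_genes, 1)
    gene_len = slot // 2
    if gene_len < 100:
        raise ValueError(
            f"{config.n_genes} genes do not fit in {L} bp (min 100 bp each)"
        )
    genes = []
    for i in range(config.n_genes):
        start = i * slot + slot // 4
        genes.append(
            (
                config.chrom_name,
                start,
                start + gene_len,
                f"gene{i + 1:03d}",
                "+" if i % 2 == 0 else "-",
            )
        )
    capture = [(config.chrom_name, 0, L)]
    return ReferenceBundle({config.chrom_name: seq}, genes, capture)


def make_signatures(kind: str = "uvb_like", profile=None) -> np.ndarray:
    """A 96-channel signature profile, normalized to sum 1.

    ``uvb_like`` concentrates mass on C>T at dipyrimidine contexts with
    the 5'-T preference TCT > TCC > TCA > TCG, with minor mass spread
    over the remaining channels.  ``flat`` is uniform.  ``custom`` takes
    a non-negative 96-vector.
    """
    if kind == "flat":
        return np.full(96, 1.0 / 96)
    if kind == "custom":
        p = np.asarray(profile, dtype=float)
        if p.shape != (96,):
            raise ValueError("custom profile must be a 96-vector")
        if (p < 0).any():
            raise ValueError("custom profile must be non-negative")
        if p.sum() <= 0:
            raise ValueError("custom profile must have positive mass")
        return p / p.sum()
    if kind != "uvb_like":
        raise ValueError(f"unknown signature kind {kind!r}")
    # C>T mass ordered by 5' base T > C > others, 3' base T > C > A > G
    weights = {"TCT": 30.0, "TCC": 22.0, "TCA": 15.0, "TCG": 8.0,
               "CCT": 12.0, "CCC": 8.0, "CCA": 5.0, "CCG": 2.0}
    p = np.zeros(96)
    for j, (cls, ctx) in enumerate(CHANNELS):
        if cls == "C>T":
            p[j] = weights.get(ctx, 0.6)
        else:
            p[j] = 0.08  # faint non-C>T floor so no channel is impossible
    return p / p.sum()


def _resolve_spec(signature_spec):
    names, profiles, means = [], [], []
    for i, (sig, mean) in enumerate(signature_spec):
        if isinstance(sig, str):
            names.append(sig if sig not in names else f"{sig}_{i}")
            profiles.append(make_signatures(sig))
        else:
            names.append(f"custom_{i}")
            profiles.append(make_signatures("custom", profile=sig))
        means.append(float(mean))
    return names, np.column_stack(profiles), np.asarray(means)


class _SiteIndex:
    """Positions of every pyrimidine-centric trinucleotide context and of
    CC dinucleotide sites (both strands), for mutation placement."""

    def __init__(self, bundle: ReferenceBundle, chrom: str):
        seq = bundle.sequence[chrom]
        self.chrom = chrom
        self.by_context: dict[str, list[int]] = {}
        self.cc_sites: list[tuple[int, str]] = []  # (leftmost pos0, pyr strand)
        for p in range(1, len(seq) - 1):
            tri = seq[p - 1 : p + 2]
            if "N" in tri:
                continue
            self.by_context.setdefault(pyrimidine_context(tri), []).append(p)
        for p in range(1, len(seq) - 2):
            if seq[p] == "C" and seq[p + 1] == "C":
                self.cc_sites.append((p, "+"))
            elif seq[p] == "G" and seq[p + 1] == "G":
                self.cc_sites.append((p, "-"))
        # gene lookup for strand-bias placement
        self.gene_strand: dict[int, str] = {}
        multi = set()
        for gchrom, start, end, _, strand in bundle.genes:
            if gchrom != chrom:
                continue
            for p in range(start, end):
                if p in self.gene_strand and self.gene_strand[p] != strand:
                    multi.add(p)
                self.gene_strand[p] = strand
        for p in multi:
            del self.gene_strand[p]


def _alleles_for(seq: str, pos0: int, cls: str) -> tuple[str, str]:
    """Reference and alternate allele (+ strand) for a class at a site."""
    ref = seq[pos0]
    alt_pyr = cls[2]
    if ref in PYRIMIDINES:
        return ref, alt_pyr
    return ref, COMPLEMENT[alt_pyr]


def simulate_catalog(
    bundle: ReferenceBundle, config: SimulationConfig
) -> tuple[dict[str, list[VariantCall]], GroundTruth]:
    """Draw a multi-sample SNV catalog from the configured mixture.

    Per sample, the activity of each signature is Gamma-distributed
    around its configured mean and the realized mutation count is
    Poisson.  Each mutation's channel is drawn from its signature and
    placed uniformly over reference sites with the matching trinucleotide
    context (collisions redrawn).  Genic C>T events are accepted on the
    untranscribed vs transcribed strand with odds rho; a configured
    fraction of C>T events is emitted as CC>TT adjacent pairs.  Returns
    per-caller call sets (with dropout and private false positives) and
    the ground truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.chrom_name
    seq = bundle.sequence[chrom]
    index = _SiteIndex(bundle, chrom)
    names, profiles, means = _resolve_spec(config.signature_spec)
    for j, (cls, ctx) in enumerate(CHANNELS):
        if profiles[j].sum() > 0 and ctx not in index.by_context:
            raise ValueError(f"context {ctx} absent from the reference")
    k = len(names)
    shape = config.activity_shape

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    activities = np.zeros((config.n_samples, k), dtype=int)

    # deterministic round-robin assignment of samples to exposure groups
    groups: dict[str, str] = {}
    multipliers: dict[str, np.ndarray] = {}
    if config.group_spec:
        gnames, counts = [], []
        for gname, (frac, mult) in config.group_spec.items():
            gnames.append(gname)
            counts.append(frac)
            m = np.asarray(mult, dtype=float)
            if m.shape != (k,):
                raise ValueError(
                    f"group {gname!r} needs one multiplier per signature"
                )
            multipliers[gname] = m
        alloc = np.floor(
            np.cumsum(counts) / sum(counts) * config.n_samples
        ).astype(int)
        bounds = np.concatenate([[0], alloc])
        for gi, gname in enumerate(gnames):
            for i in range(bounds[gi], bounds[gi + 1]):
                groups[sample_ids[i]] = gname
    truth = GroundTruth(profiles, names, activities, sample_ids, groups)
    true_calls: dict[str, list[VariantCall]] = {}

    for i, sid in enumerate(sample_ids):
        used: set[int] = set()
        calls: list[VariantCall] = []
        gmult = multipliers.get(groups.get(sid), np.ones(k))
        for ksig in range(k):
            mean = means[ksig] * gmult[ksig]
            lam = rng.gamma(shape, mean / shape) if mean > 0 else 0.0
            n_mut = rng.poisson(lam)
            placed = 0
            while placed < n_mut:
                j = rng.choice(96, p=profiles[:, ksig])
                cls, ctx = CHANNELS[j]
                make_dinuc = (
                    cls == "C>T"
                    and config.dinucleotide_rate > 0
                    and rng.random() < config.dinucleotide_rate
                    and len(index.cc_sites)
                )
                if make_dinuc:
                    pos0, strand = index.cc_sites[rng.integers(len(index.cc_sites))]
                    if pos0 in used or pos0 + 1 in used:
                        continue
                    used.update((pos0, pos0 + 1))
                    ref_pair = seq[pos0 : pos0 + 2]
                    alt_pair = "TT" if strand == "+" else "AA"
                    for off in range(2):
                        calls.append(
                            VariantCall(
                                sid, chrom, pos0 + off + 1,
                                ref_pair[off], alt_pair[off],
                            )
                        )
                    truth.event_provenance.append(
                        {"sample": sid, "pos0": pos0, "signature": names[ksig],
                         "kind": "dinucleotide"}
                    )
                    truth.n_dinucleotide += 1
                    placed += 1
                    continue
                sites = index.by_context[ctx]
                pos0 = sites[rng.integers(len(sites))]
                if pos0 in used or pos0 - 1 in used or pos0 + 1 in used:
                    continue
                if cls == "C>T" and config.strand_bias_rho > 1:
                    gstrand = index.gene_strand.get(pos0)
                    if gstrand is not None:
                        pyr_strand = "+" if seq[pos0] in PYRIMIDINES else "-"
                        label = (
                            "untranscribed" if pyr_strand == gstrand
                            else "transcribed"
                        )
                        if label == "transcribed" and (
                            rng.random() >= 1.0 / config.strand_bias_rho
                        ):
                            continue  # redraw: thins transcribed to odds 1:rho
                used.add(pos0)
                ref, alt = _alleles_for(seq, pos0, cls)
                calls.append(VariantCall(sid, chrom, pos0 + 1, ref, alt))
                truth.event_provenance.append(
                    {"sample": sid, "pos0": pos0, "signature": names[ksig],
                     "kind": "snv", "channel": j}
                )
                activities[i, ksig] += 1
                placed += 1
        true_calls[sid] = calls

    callsets = emit_caller_sets(true_calls, bundle, config, rng)
    return callsets, truth


def emit_caller_sets(
    true_calls: dict[str, list[VariantCall]],
    bundle: ReferenceBundle,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[VariantCall]]:
    """Per-caller call sets with dropout and private false positives.

    Every true variant is independently missing from each caller with
    probability ``caller_dropout``; each caller additionally reports
    ``caller_false_positives`` private random SNVs per sample, which the
    three-way consensus removes.
    """
    chrom = config.chrom_name
    seq = bundle.sequence[chrom]
    truth_keys = {
        v.key[1:] for calls in true_calls.values() for v in calls
    }
    callsets: dict[str, list[VariantCall]] = {c: [] for c in CALLER_IDS}
    for sid, calls in true_calls.items():
        for caller in CALLER_IDS:
            for v in calls:
                if rng.random() >= config.caller_dropout:
                    callsets[caller].append(
                        VariantCall(
                            v.sample_id, v.chrom, v.pos, v.ref, v.alt,
                            caller_id=caller,
                        )
                    )
            fp = 0
            while fp < config.caller_false_positives:
                pos0 = int(rng.integers(1, len(seq) - 1))
                ref = seq[pos0]
                alt = "ACGT"[rng.integers(4)]
                if alt == ref or (chrom, pos0 + 1, ref, alt) in truth_keys:
                    continue
                callsets[caller].append(
                    VariantCall(sid, chrom, pos0 + 1, ref, alt, caller_id=caller)
                )
                fp += 1
    return callsets


@dataclass
class ClinicalConfig:
    """Parameters for the clinical-arm simulation."""

    seed: int = 0
    #: group -> (n_subjects, exponential scale in weeks, censor horizon)
    survival_groups: dict = field(
        default_factory=lambda: {
            "control": (20, 60.0, 80.0),
            "uvb": (20, 25.0, 80.0),
        }
    )
    n_samples: int = 10
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 100_000_000})
    segments_per_chrom: int = 20
    altered_fraction: float = 0.25
    altered_log2: float = 0.5
    neutral_log2: float = 0.0
    bins_per_segment: int = 20


def simulate_clinical(
    config: ClinicalConfig,
) -> tuple[dict[str, list[CnaSegment]], list[SurvivalRecord], dict]:
    """CNA segments with a planted altered fraction plus survival times.

    Segments tile each chromosome evenly; the first ``round(fraction *
    n)`` segments per chromosome carry the altered log2 ratio, so the
    realized altered fraction equals the planted one by construction.
    Survival times are exponential per group with right-censoring at a
    fixed horizon.
    """
    if not (0 <= config.altered_fraction <= 1):
        raise ValueError("altered fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 2)
    segments: dict[str, list[CnaSegment]] = {}
    planted: dict[str, float] = {}
    for i in range(config.n_samples):
        sid = f"S{i + 1:03d}"
        segs = []
        for chrom, size in config.chrom_sizes.items():
            n = config.segments_per_chrom
            edges = np.linspace(0, size, n + 1).astype(int)
            n_alt = round(config.altered_fraction * n)
            order = rng.permutation(n)
            for j in range(n):
                log2 = (
                    config.altered_log2 * (1 if rng.random() < 0.5 else -1)
                    if order[j] < n_alt
                    else config.neutral_log2
                )
                segs.append(
                    CnaSegment(
                        sid, chrom, int(edges[j]), int(edges[j + 1]),
                        log2, config.bins_per_segment,
                    )
                )
        segments[sid] = segs
        planted[sid] = config.altered_fraction

    records = []
    true_scales = {}
    for group, (n, scale, horizon) in config.survival_groups.items():
        true_scales[group] = scale
        times = rng.exponential(scale, size=n)
        for j, t in enumerate(times):
            observed = t <= horizon
            records.append(
                SurvivalRecord(
                    subject_id=f"{group}_{j + 1:02d}",
                    time=float(min(t, horizon)),
                    event=bool(observed),
                    group=group,
                )
            )
    truth = {"planted_fraction": planted, "survival_scales": true_scales}
    return segments, records, truth
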