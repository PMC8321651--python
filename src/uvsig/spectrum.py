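"""Trinucleotide mutation spectra and transcriptional strand bias.

Builds samples x 96 SBS96 catalogs from classified mutation events,
tallies the six substitution classes (plus the C>T-at-CpG sub-class),
normalizes spectra to the trinucleotide composition of a region set, and
tests transcribed-versus-untranscribed strand asymmetry with an exact
conditional binomial test (the standard two-count Poisson rate test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .sbs import (
    CHANNEL_INDEX,
    CHANNEL_LABELS,
    CHANNELS,
    PYRIMIDINE_CONTEXTS,
    PYRIMIDINES,
    fetch,
    pyrimidine_context,
)
from .variants import MutationEvent


@dataclass
class Sbs96Catalog:
    """Samples x 96 non-negative count matrix in the frozen channel order."""

    sample_ids: list[str]
    counts: np.ndarray  # shape (n_samples, 96), integer

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), 96):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x 96 channels"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """COSMIC layout: channels as rows, samples as columns."""
        df = pd.DataFrame(
            self.counts.T, index=list(CHANNEL_LABELS), columns=self.sample_ids
        )
        df.index.name = "MutationType"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Sbs96Catalog":
        if list(df.index) != list(CHANNEL_LABELS):
            raise ValueError(
                "catalog rows are not in the canonical SBS96 channel order"
            )
        return cls(list(df.columns), df.to_numpy().T)

    def pooled(self) -> np.ndarray:
        """96-vector of counts summed over samples."""
        return self.counts.sum(axis=0)


def build_sbs96(events: Iterable[MutationEvent]) -> Sbs96Catalog:
    """Tally classified SNV events into the canonical 96-channel order.

    Dinucleotide and indel events are excluded; sample order follows
    first appearance in the event stream.
    """
    samples: list[str] = []
    index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for e in events:
        if e.sample_id not in index:
            index[e.sample_id] = len(samples)
            samples.append(e.sample_id)
            rows.append(np.zeros(96, dtype=int))
        if e.event_kind != "snv":
            continue
        if e.snv_class is None or e.context is None:
            raise RuntimeError(
                f"unclassified snv event at {e.chrom}:{e.start}; "
                "run classification first"
            )
        rows[index[e.sample_id]][CHANNEL_INDEX[(e.snv_class, e.context)]] += 1
    return Sbs96Catalog(samples, np.vstack(rows) if rows else np.zeros((0, 96), int))


MUT_TYPE_COLUMNS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G", "C>T at CpG"]


def count_mutation_types(events: Iterable[MutationEvent]) -> pd.DataFrame:
    """Per-sample occurrences of the 6 classes plus the C>T-at-CpG sub-tally.

    Returns a frame with absolute counts, per-class frequencies (class
    count / total SNVs) and a ``defined`` flag that is False for samples
    with zero SNVs (whose frequencies are left at 0 rather than NaN).
    """
    counts: dict[str, dict[str, int]] = {}
    for e in events:
        row = counts.setdefault(e.sample_id, {c: 0 for c in MUT_TYPE_COLUMNS})
        if e.event_kind != "snv" or e.snv_class is None:
            continue
        row[e.snv_class] += 1
        if e.snv_class == "C>T" and e.at_cpg:
            row["C>T at CpG"] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df.reindex(columns=MUT_TYPE_COLUMNS, fill_value=0)
    total = df[list(MUT_TYPE_COLUMNS[:6])].sum(axis=1)
    df["total_snv"] = total
    df["defined"] = total > 0
    for c in MUT_TYPE_COLUMNS:
        df[f"freq {c}"] = np.where(total > 0, df[c] / total.replace(0, 1), 0.0)
    df.index.name = "sample"
    return df.sort_index()


def trinucleotide_frequencies(
    reference, regions: Sequence[tuple[str, int, int]]
) -> dict[str, int]:
    """Occurrences of the 32 pyrimidine-centric 3-mers within a region set.

    Regions are (chrom, start, end) 0-based half-open.  Both strands are
    aggregated through complementation: a purine-centered trinucleotide
    counts toward its reverse complement.  Windows containing N are
    skipped.
    """
    if not regions:
        raise ValueError("region set is empty")
    counts = {ctx: 0 for ctx in PYRIMIDINE_CONTEXTS}
    for chrom, start, end in regions:
        # widen by 1 so 3-mers centered on region edges are included
        lo = max(start - 1, 0)
        seq = fetch(reference, chrom, lo, end + 1)
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if "N" in tri:
                continue
            counts[pyrimidine_context(tri)] += 1
    return counts


def normalize_spectrum(
    catalog: Sbs96Catalog,
    reference,
    regions: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Normalize a catalog to trinucleotide occurrences in a region set.

    rate(channel) = count(channel) * 1e6 / occurrences(context), i.e.
    mutations per million available trinucleotide sites, comparable
    across contexts of unequal genomic frequency.
    """
    occ = trinucleotide_frequencies(reference, regions)
    denom = np.empty(96)
    for j, (cls, ctx) in enumerate(CHANNELS):
        n = occ[ctx]
        if n == 0:
            if catalog.counts[:, j].sum() > 0:
                raise ValueError(
                    f"context {ctx} absent from regions but channel "
                    f"{CHANNEL_LABELS[j]} has counts"
                )
            denom[j] = np.nan
        else:
            denom[j] = n
    rates = catalog.counts * 1e6 / denom
    rates = np.nan_to_num(rates, nan=0.0)
    return pd.DataFrame(
        rates, index=catalog.sample_ids, columns=list(CHANNEL_LABELS)
    )


class GeneIndex:
    """Stranded gene intervals with fast point overlap queries."""

    def __init__(self, genes: Iterable[tuple[str, int, int, str, str]]):
        """genes: (chrom, start, end, name, strand) with 0-based half-open
        coordinates and strand '+' or '-'."""
        self.trees: dict[str, IntervalTree] = {}
        for chrom, start, end, name, strand in genes:
            if strand not in ("+", "-"):
                raise ValueError(f"malformed strand {strand!r} for gene {name}")
            self.trees.setdefault(chrom, IntervalTree()).addi(
                start, end, (name, strand)
            )

    def overlapping(self, chrom: str, pos0: int) -> list[tuple[str, str]]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos0]]


def assign_transcriptional_strand(
    event: MutationEvent, genes: GeneIndex
) -> MutationEvent:
    """Label an event transcribed / untranscribed / unknown.

    The pyrimidine of the mutated pair sits on the reference (+) strand
    when the reference base is C or T, else on the (-) strand.  For a
    gene on strand s, the template (transcribed) strand is the opposite
    of s: a pyrimidine on the gene's coding strand is untranscribed, on
    the template strand transcribed.  Intergenic events and events in
    regions covered by genes on both strands are labeled unknown.  Also
    fills the event's gene label when a single gene overlaps.
    """
    hits = genes.overlapping(event.chrom, event.start - 1)
    strands = {s for _, s in hits}
    if not hits:
        event.strand_label = "unknown"
        return event
    if len(strands) > 1:
        event.strand_label = "unknown"
        event.gene = hits[0][0]
        return event
    event.gene = hits[0][0]
    if event.event_kind != "snv":
        event.strand_label = "unknown"
        return event
    gene_strand = strands.pop()
    pyr_strand = "+" if event.ref_allele.upper() in PYRIMIDINES else "-"
    # template strand is the complement of the gene (coding) strand
    event.strand_label = (
        "untranscribed" if pyr_strand == gene_strand else "transcribed"
    )
    return event


def strand_resolved_counts(
    events: Iterable[MutationEvent],
) -> tuple[pd.DataFrame, int]:
    """Per-class transcribed/untranscribed tallies, pooled over samples.

    Returns (frame indexed by the 6 classes with columns transcribed /
    untranscribed, number of strand-unknown SNV events).
    """
    from .sbs import SNV_CLASSES

    tallies = pd.DataFrame(
        0, index=list(SNV_CLASSES), columns=["transcribed", "untranscribed"]
    )
    excluded = 0
    for e in events:
        if e.event_kind != "snv" or e.snv_class is None:
            continue
        if e.strand_label in ("transcribed", "untranscribed"):
            tallies.loc[e.snv_class, e.strand_label] += 1
        else:
            excluded += 1
    return tallies, excluded


@dataclass
class StrandBiasResult:
    """Exact two-sided test of transcribed vs untranscribed counts."""

    snv_class: str
    transcribed: int
    untranscribed: int
    log2_ratio: float
    p_value: float
    testable: bool = True


def strand_bias_test(
    transcribed: int, untranscribed: int, snv_class: str = ""
) -> StrandBiasResult:
    """Exact conditional binomial test of strand symmetry.

    Under the null each event falls on either strand with probability
    1/2; conditioning on the total, the transcribed count is
    Binomial(n, 1/2) and the two-sided p-value sums all outcomes with
    likelihood no greater than the observed one (minimum-likelihood
    rule).  This is the standard exact comparison of two Poisson rates.
    Zero counts get a +0.5 continuity adjustment in the reported log2
    ratio only; raw counts are retained.
    """
    if transcribed < 0 or untranscribed < 0:
        raise ValueError("counts must be non-negative")
    n = transcribed + untranscribed
    if n == 0:
        return StrandBiasResult(snv_class, 0, 0, 0.0, 1.0, testable=False)
    t, u = float(transcribed), float(untranscribed)
    if t == 0 or u == 0:
        t, u = t + 0.5, u + 0.5
    log2_ratio = float(np.log2(t / u))
    p = stats.binomtest(transcribed, n, 0.5).pvalue
    return StrandBiasResult(snv_class, transcribed, untranscribed, log2_ratio, float(p))


def strand_bias_table(tallies: pd.DataFrame) -> pd.DataFrame:
    """Run the strand-bias test for each substitution class."""
    rows = []
    for cls, row in tallies.iterrows():
        r = strand_bias_test(int(row["transcribed"]), int(row["untranscribed"]), cls)
        rows.append(
            {
                "class": cls,
                "transcribed": r.transcribed,
                "untranscribed": r.untranscribed,
                "log2_ratio": r.log2_ratio,
                "p_value": r.p_value,
                "testable": r.testable,
            }
        )
    return pd.DataFrame(rows)
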