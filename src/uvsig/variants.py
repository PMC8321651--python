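"""Consensus somatic call sets, event collapsing, burden and recurrence.

Ensemble variant calling retains only variants reported by every caller
and absent from a known-polymorphism exclusion list.  Adjacent same-sample
SNV pairs (the CC>TT products of cyclobutane pyrimidine dimers) are
collapsed into single dinucleotide events so that one photolesion counts
as one mutational event in burden arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sbs import PYRIMIDINES, fetch, pyrimidine_context, pyrimidine_substitution

log = logging.getLogger(__name__)

_VALID_KINDS = ("snv", "insertion", "deletion")


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (empty inputs, bad sizes)."""


@dataclass(frozen=True, order=True)
class VariantCall:
    """One somatic variant as reported by a single caller."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_kind: str = "snv"
    caller_id: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.variant_kind not in _VALID_KINDS:
            raise ValueError(f"unknown variant kind {self.variant_kind!r}")
        if self.variant_kind == "snv" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(
                f"snv must have single-base alleles: {self.ref}>{self.alt}"
            )

    @property
    def key(self) -> tuple:
        """Identity key used for consensus and exclusion matching."""
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MutationEvent:
    """One collapsed somatic event (SNV, dinucleotide or indel)."""

    sample_id: str
    chrom: str
    start: int  # 1-based, leftmost substituted base
    ref_allele: str
    alt_allele: str
    event_kind: str  # snv | dinucleotide | indel
    snv_class: str | None = None  # one of the 6 pyrimidine-centric classes
    context: str | None = None  # pyrimidine-centered trinucleotide
    at_cpg: bool = False
    strand_label: str = "unknown"  # transcribed | untranscribed | unknown
    gene: str | None = None

    def as_record(self) -> dict:
        return {
            "sample": self.sample_id,
            "chrom": self.chrom,
            "start": self.start,
            "ref": self.ref_allele,
            "alt": self.alt_allele,
            "kind": self.event_kind,
            "class": self.snv_class or "",
            "context": self.context or "",
            "at_cpg": self.at_cpg,
            "strand": self.strand_label,
            "gene": self.gene or "",
        }


def build_consensus(
    callsets: Sequence[Iterable[VariantCall]],
    exclusion_set: Iterable[tuple] = (),
) -> list[VariantCall]:
    """Intersect per-caller call sets and drop known polymorphisms.

    A variant is retained only when its (sample, chrom, pos, ref, alt)
    key appears in every supplied call set and not in ``exclusion_set``.
    The representative record is taken from the first call set; output is
    sorted by (sample, chrom, pos).
    """
    if not callsets:
        raise ConfigurationError("at least one call set is required")
    excluded = set()
    for key in exclusion_set:
        if len(key) not in (4, 5):
            raise ValueError(f"malformed exclusion key: {key!r}")
        excluded.add(tuple(key))

    first, *rest = [ {v.key: v for v in cs} for cs in callsets ]
    keys = set(first)
    for other in rest:
        keys &= set(other)
    # exclusion keys may carry the sample (5 fields) or be site-level (4)
    kept = [
        v
        for k, v in first.items()
        if k in keys and k not in excluded and k[1:] not in excluded
    ]
    return sorted(kept, key=lambda v: (v.sample_id, v.chrom, v.pos))


def collapse_dinucleotide_events(
    variants: Iterable[VariantCall], reference=None
) -> list[MutationEvent]:
    """Merge adjacent same-sample SNV pairs into dinucleotide events.

    SNVs at positions (pos, pos+1) on the same sample and chromosome
    become a single ``dinucleotide`` event; runs of three or more
    adjacent SNVs merge left-to-right greedily into pairs.  Indels pass
    through unchanged as ``indel`` events.
    """
    snvs, others = [], []
    for v in variants:
        (snvs if v.variant_kind == "snv" else others).append(v)
    snvs.sort(key=lambda v: (v.sample_id, v.chrom, v.pos))

    events: list[MutationEvent] = []
    i = 0
    while i < len(snvs):
        a = snvs[i]
        if reference is not None:
            chrom_len = len(reference[a.chrom])
            if a.pos > chrom_len:
                raise IndexError(
                    f"{a.chrom}:{a.pos} beyond reference length {chrom_len}"
                )
        if (
            i + 1 < len(snvs)
            and snvs[i + 1].sample_id == a.sample_id
            and snvs[i + 1].chrom == a.chrom
            and snvs[i + 1].pos == a.pos + 1
        ):
            b = snvs[i + 1]
            events.append(
                MutationEvent(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    start=a.pos,
                    ref_allele=a.ref + b.ref,
                    alt_allele=a.alt + b.alt,
                    event_kind="dinucleotide",
                )
            )
            i += 2
        else:
            events.append(
                MutationEvent(
                    sample_id=a.sample_id,
                    chrom=a.chrom,
                    start=a.pos,
                    ref_allele=a.ref,
                    alt_allele=a.alt,
                    event_kind="snv",
                )
            )
            i += 1
    for v in others:
        events.append(
            MutationEvent(
                sample_id=v.sample_id,
                chrom=v.chrom,
                start=v.pos,
                ref_allele=v.ref,
                alt_allele=v.alt,
                event_kind="indel",
            )
        )
    events.sort(key=lambda e: (e.sample_id, e.chrom, e.start))
    return events


def classify_snv(event: MutationEvent, reference) -> MutationEvent | None:
    """Fill in pyrimidine-centric class, trinucleotide context and CpG flag.

    A purine reference base is mapped through the reverse complement, so
    a G>A in 5'-AGA-3' is classified as C>T in context TCT.  ``at_cpg``
    is true iff the mutated cytosine is immediately followed by G on the
    pyrimidine-bearing strand.  Events whose context contains an
    ambiguous base are logged and returned as ``None``.
    """
    if event.event_kind != "snv":
        raise ValueError("classification applies to snv events only")
    pos0 = event.start - 1  # to 0-based
    if pos0 < 1:
        raise IndexError(
            f"cannot resolve flanks for {event.chrom}:{event.start}"
        )
    trinuc = fetch(reference, event.chrom, pos0 - 1, pos0 + 2)
    if len(trinuc) != 3:
        raise IndexError(
            f"cannot resolve flanks for {event.chrom}:{event.start}"
        )
    if trinuc[1] != event.ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {event.chrom}:{event.start}: "
            f"expected {event.ref_allele}, found {trinuc[1]}"
        )
    if "N" in trinuc:
        log.warning(
            "ambiguous context %s at %s:%d; event excluded from context analyses",
            trinuc, event.chrom, event.start,
        )
        return None
    cls = pyrimidine_substitution(event.ref_allele, event.alt_allele)
    ctx = pyrimidine_context(trinuc)
    at_cpg = cls.startswith("C") and ctx[2] == "G"
    return replace(event, snv_class=cls, context=ctx, at_cpg=at_cpg)


def classify_events(events: Iterable[MutationEvent], reference) -> list[MutationEvent]:
    """Classify every SNV event; dinucleotides and indels pass through."""
    out = []
    for e in events:
        if e.event_kind == "snv":
            c = classify_snv(e, reference)
            if c is not None:
                out.append(c)
        else:
            out.append(e)
    return out


def burden_per_mb(
    events: Iterable[MutationEvent],
    capture_size_bp: int,
    kind_filter: str | Sequence[str] = ("snv", "dinucleotide"),
) -> pd.Series:
    """Per-sample mutational burden in events per megabase of capture.

    Each dinucleotide event contributes one to the SNV burden, matching
    the convention of counting a dipyrimidine substitution as a single
    event.
    """
    if capture_size_bp <= 0:
        raise ConfigurationError("capture_size_bp must be positive")
    kinds = {kind_filter} if isinstance(kind_filter, str) else set(kind_filter)
    counts: dict[str, int] = {}
    for e in events:
        counts.setdefault(e.sample_id, 0)
        if e.event_kind in kinds:
            counts[e.sample_id] += 1
    burden = pd.Series(counts, dtype=float) * 1e6 / capture_size_bp
    burden.index.name = "sample"
    return burden.sort_index()


@dataclass
class RecurrenceTable:
    """Genes recurrently altered across the cohort (OncoPrint-style)."""

    cohort_size: int
    min_samples: int
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # table columns: gene, sample, kinds (comma-joined), plus per-gene
    # summary in `summary`: altered_samples, frequency

    @property
    def summary(self) -> pd.DataFrame:
        if self.table.empty:
            return pd.DataFrame(columns=["gene", "altered_samples", "frequency"])
        g = (
            self.table.groupby("gene")["sample"]
            .nunique()
            .rename("altered_samples")
            .reset_index()
        )
        g["frequency"] = g["altered_samples"] / self.cohort_size
        return g.sort_values(
            ["altered_samples", "gene"], ascending=[False, True]
        ).reset_index(drop=True)


def gene_recurrence(
    annotated_events: Iterable[MutationEvent],
    cohort_size: int,
    min_samples: int = 3,
) -> RecurrenceTable:
    """Tally genes altered in at least ``min_samples`` distinct samples.

    Multiple events in the same gene and sample count once toward
    recurrence; intergenic events (gene missing or "intergenic") are
    ignored.
    """
    rows = []
    samples = set()
    for e in annotated_events:
        samples.add(e.sample_id)
        gene = e.gene
        if not gene or gene == "intergenic":
            continue
        rows.append({"gene": gene, "sample": e.sample_id, "kind": e.event_kind})
    if cohort_size < len(samples):
        raise ConfigurationError(
            f"cohort_size {cohort_size} < {len(samples)} distinct samples seen"
        )
    if not rows:
        return RecurrenceTable(cohort_size, min_samples)
    df = pd.DataFrame(rows)
    per = (
        df.groupby(["gene", "sample"])["kind"]
        .apply(lambda k: ",".join(sorted(set(k))))
        .rename("kinds")
        .reset_index()
    )
    keep = per.groupby("gene")["sample"].nunique()
    keep = set(keep[keep >= min_samples].index)
    per = per[per["gene"].isin(keep)].reset_index(drop=True)
    return RecurrenceTable(cohort_size, min_samples, per)


def events_to_frame(events: Iterable[MutationEvent]) -> pd.DataFrame:
    """Tabulate events for TSV output."""
    return pd.DataFrame([e.as_record() for e in events])


def events_from_frame(df: pd.DataFrame) -> list[MutationEvent]:
    """Rebuild events from the tabular representation."""
    out = []
    for row in df.to_dict("records"):
        out.append(
            MutationEvent(
                sample_id=str(row["sample"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                event_kind=str(row["kind"]),
                snv_class=str(row["class"]) if row.get("class") else None,
                context=str(row["context"]) if row.get("context") else None,
                at_cpg=bool(row.get("at_cpg", False)),
                strand_label=str(row.get("strand", "unknown") or "unknown"),
                gene=str(row["gene"]) if row.get("gene") else None,
            )
        )
    return out
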