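"""Copy-number segment filtering and altered-genome fraction.

Segments (from an upstream segmentation such as CNVkit's) are reduced to
reportable copy-number alterations by an absolute log2-ratio threshold
and a minimum supporting-bin count; per-sample CNA burden is the
footprint of altered segments divided by the total segmented footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class CnaSegment:
    """Genomic interval (0-based half-open) with log2 copy ratio."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_bins: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def direction(self) -> str:
        if self.log2_ratio > 0:
            return "gain"
        if self.log2_ratio < 0:
            return "loss"
        return "neutral"


def validate_segments(segments: Sequence[CnaSegment]) -> None:
    """Reject overlapping segments within a sample and chromosome."""
    by_key: dict[tuple, list[CnaSegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    offenders = []
    for segs in by_key.values():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                offenders.append((a, b))
    if offenders:
        msg = "; ".join(
            f"{a.sample_id} {a.chrom}:{a.start}-{a.end} overlaps "
            f"{b.chrom}:{b.start}-{b.end}"
            for a, b in offenders[:5]
        )
        raise ValueError(f"overlapping segments: {msg}")


def filter_segments(
    segments: Sequence[CnaSegment],
    log2_threshold: float = 0.2,
    min_bins: int = 5,
    include_sex_chroms: bool = True,
) -> list[CnaSegment]:
    """Retain segments with |log2| >= threshold and enough supporting bins.

    The threshold is inclusive: a segment exactly at the boundary is
    reported.  Sex chromosomes (chrX/chrY/X/Y) can be excluded.
    """
    validate_segments(segments)
    out = []
    for s in segments:
        if not include_sex_chroms and s.chrom.lstrip("chr") in ("X", "Y"):
            continue
        if abs(s.log2_ratio) >= log2_threshold and s.n_bins >= min_bins:
            out.append(s)
    return out


def genome_altered_fraction(
    all_segments: Sequence[CnaSegment],
    altered_segments: Sequence[CnaSegment],
) -> pd.Series:
    """Per-sample fraction of the segmented footprint that is altered.

    Altered footprint / total footprint per sample, in [0, 1].  Samples
    with zero total footprint are reported as NaN (undefined).
    """
    altered_keys = {
        (s.sample_id, s.chrom, s.start, s.end) for s in altered_segments
    }
    all_keys = {(s.sample_id, s.chrom, s.start, s.end) for s in all_segments}
    if not altered_keys <= all_keys:
        raise ValueError("altered segments must be a subset of all segments")
    total: dict[str, int] = {}
    altered: dict[str, int] = {}
    for s in all_segments:
        total[s.sample_id] = total.get(s.sample_id, 0) + s.length
        altered.setdefault(s.sample_id, 0)
    for s in altered_segments:
        altered[s.sample_id] += s.length
    frac = pd.Series(
        {
            k: (altered[k] / total[k]) if total[k] > 0 else float("nan")
            for k in total
        }
    )
    frac.index.name = "sample"
    return frac.sort_index()


def segments_from_frame(df: pd.DataFrame, sample_id: str | None = None) -> list[CnaSegment]:
    """Build segments from a generic TSV or a CNVkit ``.cns``-style table.

    Accepted column spellings: chromosome|chrom, start, end, log2|log2_ratio,
    probes|n_bins, plus an optional sample column when ``sample_id`` is
    not given.
    """
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise KeyError(f"none of {names} found in segment table")

    chrom_c = pick("chromosome", "chrom")
    log2_c = pick("log2", "log2_ratio")
    bins_c = pick("probes", "n_bins", "bins")
    sample_c = cols.get("sample") or cols.get("sample_id")
    out = []
    for row in df.to_dict("records"):
        sid = sample_id if sample_id is not None else str(row[sample_c])
        out.append(
            CnaSegment(
                sample_id=sid,
                chrom=str(row[chrom_c]),
                start=int(row[cols["start"]]),
                end=int(row[cols["end"]]),
                log2_ratio=float(row[log2_c]),
                n_bins=int(row[bins_c]),
            )
        )
    return out


def segments_to_frame(segments: Iterable[CnaSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample_id,
                "chromosome": s.chrom,
                "start": s.start,
                "end": s.end,
                "log2": s.log2_ratio,
                "probes": s.n_bins,
                "direction": s.direction,
            }
            for s in segments
        ]
    )
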