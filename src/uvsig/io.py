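"""Readers and writers for the pipeline's file formats.

VCF I/O goes through pysam, FASTA writing through Biopython, FASTA
random access through pyfaidx; tabular artifacts are TSV via pandas.
Coordinates are 1-based in VCF and GFF3, 0-based half-open in BED and
internally.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .variants import MutationEvent, VariantCall, events_to_frame


# ---------------------------------------------------------------- FASTA

def write_fasta(sequence: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sequence.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def open_fasta(path):
    import pyfaidx

    return pyfaidx.Fasta(str(path))


# ------------------------------------------------------------------ BED

def write_genes_bed(
    genes: Iterable[tuple[str, int, int, str, str]], path
) -> None:
    """(chrom, start, end, name, strand) records to 6-column BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in genes:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_genes_bed(path) -> list[tuple[str, int, int, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"BED gene records need 6 columns: {line!r}")
            out.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return out


def read_genes_gff3(path) -> list[tuple[str, int, int, str, str]]:
    """Gene features from a GFF3 file (1-based closed -> 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            name = next(
                (
                    kv.split("=", 1)[1]
                    for kv in f[8].split(";")
                    if kv.startswith(("ID=", "Name="))
                ),
                f"{f[0]}:{f[3]}",
            )
            out.append((f[0], int(f[3]) - 1, int(f[4]), name, f[6]))
    return out


def read_genes(path) -> list[tuple[str, int, int, str, str]]:
    """Dialect chosen by extension: .bed -> BED, .gff/.gff3 -> GFF3."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_genes_bed(path)
    if suffix in (".gff", ".gff3"):
        return read_genes_gff3(path)
    raise ValueError(f"unrecognized gene annotation format: {path}")


def write_regions_bed(regions: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_regions_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ------------------------------------------------------------------ VCF

def write_vcf(
    calls: Sequence[VariantCall],
    path,
    contig_lengths: dict[str, int],
) -> None:
    """Minimal single- or multi-sample VCF (uncompressed)."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    samples = sorted({c.sample_id for c in calls})
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.sample_id)):
            rec = vf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
            )
            for s in samples:
                rec.samples[s]["GT"] = (0, 1) if s == c.sample_id else (0, 0)
            vf.write(rec)


def read_vcf_calls(
    path, caller_id: str = "", sample_id: str | None = None
) -> list[VariantCall]:
    """Read somatic calls from a VCF.

    Multi-allelic records are split into biallelic calls.  The sample is
    taken from genotyped header samples (carriers of an alternate
    allele); for sample-less VCFs ``sample_id`` (or the file stem) is
    used.
    """
    out = []
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                if alt in ("<NON_REF>", "*"):
                    continue
                kind = (
                    "snv"
                    if len(rec.ref) == 1 and len(alt) == 1
                    else ("insertion" if len(alt) > len(rec.ref) else "deletion")
                )
                if header_samples:
                    carriers = [
                        s
                        for s in header_samples
                        if any(
                            a is not None and a > 0
                            for a in (rec.samples[s].get("GT") or ())
                        )
                    ]
                else:
                    carriers = [sample_id or Path(path).stem]
                for s in carriers:
                    out.append(
                        VariantCall(
                            sample_id=s,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            variant_kind=kind,
                            caller_id=caller_id,
                        )
                    )
    return out


def read_exclusion_list(path) -> set[tuple]:
    """Known-variant keys from a VCF or a TSV (chrom, pos, ref, alt)."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        keys = set()
        with pysam.VariantFile(p) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    keys.add((rec.chrom, rec.pos, rec.ref, alt))
        return keys
    df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    return {
        (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))
        for r in df.to_dict("records")
    }


# ------------------------------------------------------------ calls TSV

def read_calls_tsv(path) -> list[VariantCall]:
    """Tabular call set with columns sample, chrom, pos, ref, alt[, caller]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.to_dict("records"):
        ref, alt = str(r["ref"]), str(r["alt"])
        kind = (
            "snv"
            if len(ref) == 1 and len(alt) == 1
            else ("insertion" if len(alt) > len(ref) else "deletion")
        )
        out.append(
            VariantCall(
                sample_id=str(r["sample"]),
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                ref=ref,
                alt=alt,
                variant_kind=kind,
                caller_id=str(r.get("caller", "")),
            )
        )
    return out


def write_calls_tsv(calls: Sequence[VariantCall], path) -> None:
    pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "caller": c.caller_id,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- events TSV

def write_events_tsv(events: Sequence[MutationEvent], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[MutationEvent]:
    from .variants import events_from_frame

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    return events_from_frame(df)


# --------------------------------------------------------- catalogs TSV

def write_catalog_tsv(catalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t")


def read_catalog_tsv(path):
    from .spectrum import Sbs96Catalog

    df = pd.read_csv(path, sep="\t", index_col=0)
    return Sbs96Catalog.from_frame(df)


def write_signatures_tsv(signatures, path) -> None:
    signatures.to_frame().to_csv(path, sep="\t")


def read_signatures_tsv(path):
    from .signatures import SignatureMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix.from_frame(df)


def read_reference_catalog_tsv(path) -> pd.DataFrame:
    """COSMIC-format tabular signature catalog (channels x signatures)."""
    from .sbs import CHANNEL_LABELS

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNEL_LABELS):
        raise ValueError(
            f"{path}: rows are not in the canonical SBS96 channel order"
        )
    return df
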