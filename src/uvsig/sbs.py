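"""SBS96 channel conventions and small sequence helpers.

The 96-channel single-base-substitution classification crosses the six
pyrimidine-centric substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
with the 16 combinations of 5' and 3' flanking bases.  Channel order is
frozen to the COSMIC convention: classes in the order above, contexts
alphabetical within each class.  All substitutions are reported on the
pyrimidine-bearing strand; a purine reference base is mapped through the
reverse complement.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")

#: The six pyrimidine-centric substitution classes, COSMIC order.
SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 32 pyrimidine-centric trinucleotides (middle base C or T).
PYRIMIDINE_CONTEXTS = tuple(
    f5 + mid + f3 for mid in PYRIMIDINES for f5 in BASES for f3 in BASES
)

#: Frozen SBS96 channel order: (class, context) pairs.
CHANNELS = tuple(
    (cls, f5 + cls[0] + f3)
    for cls in SNV_CLASSES
    for f5 in BASES
    for f3 in BASES
)

#: Channel -> row index in the canonical order.
CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}

#: Human-readable channel labels, e.g. ``A[C>T]G``.
CHANNEL_LABELS = tuple(f"{ctx[0]}[{cls}]{ctx[2]}" for cls, ctx in CHANNELS)

LABEL_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def pyrimidine_context(trinuc: str) -> str:
    """Map a trinucleotide onto its pyrimidine-centric representation.

    If the middle base is a purine the reverse complement is returned,
    otherwise the (upper-cased) input itself.
    """
    trinuc = trinuc.upper()
    if len(trinuc) != 3:
        raise ValueError(f"expected a trinucleotide, got {trinuc!r}")
    return trinuc if trinuc[1] in PYRIMIDINES else revcomp(trinuc)


def pyrimidine_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-centric class string for a single-base substitution."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref equals alt")
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}"
    return f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"


def parse_channel_label(label: str) -> tuple[str, str]:
    """Parse ``A[C>T]G`` into the (class, context) pair."""
    if len(label) != 7 or label[1] != "[" or label[5] != "]":
        raise ValueError(f"malformed SBS96 channel label: {label!r}")
    cls = label[2:5]
    ctx = label[0] + cls[0] + label[6]
    if (cls, ctx) not in CHANNEL_INDEX:
        raise ValueError(f"unknown SBS96 channel: {label!r}")
    return cls, ctx


def fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence ``[start, end)`` (0-based half-open).

    Accepts a ``pyfaidx.Fasta``, any mapping of chromosome name to
    string, or any object whose ``[chrom][start:end]`` slice yields a
    sequence-like object with a string representation.
    """
    seg = reference[chrom][start:end]
    seq = seg if isinstance(seg, str) else str(seg)
    return seq.upper()
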