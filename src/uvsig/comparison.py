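"""Signature comparison: cosine similarity, empirical permutation
p-values, reference-catalog matching and cross-extractor correlation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

#: Exhaustive enumeration is auto-selected when length! is at most this.
EXHAUSTIVE_LIMIT = 5040  # 7!


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative spectra.

    dot(a, b) / (|a| |b|); invariant to positive rescaling of either
    argument, in [0, 1] for non-negative inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SimilarityResult:
    cosine: float
    p_empirical: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def cosine_permutation_pvalue(
    a,
    b,
    n_permutations: int = 1_000_000,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> SimilarityResult:
    """Empirical p-value for an observed cosine similarity.

    The entries of the second vector are permuted; the p-value is
    (1 + #{permuted cosine >= observed}) / (n + 1), never exactly zero.
    When the vector is short enough (length! <= 5040) and ``exhaustive``
    is not False, all permutations are enumerated and the exact tail
    fraction #{cosine >= observed} / length! is returned instead.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    observed = cosine_similarity(a, b)
    m = len(b)
    if exhaustive is None:
        exhaustive = math.factorial(m) <= EXHAUSTIVE_LIMIT
    if exhaustive and math.factorial(m) > EXHAUSTIVE_LIMIT:
        raise ValueError(f"exhaustive enumeration infeasible for length {m}")

    tol = 1e-12
    if exhaustive:
        total = math.factorial(m)
        hits = sum(
            1
            for perm in permutations(b)
            if cosine_similarity(a, np.asarray(perm)) >= observed - tol
        )
        return SimilarityResult(observed, hits / total, total, None, True)

    rng = np.random.default_rng(seed)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    hits = 0
    batch = 20_000
    left = n_permutations
    while left > 0:
        k = min(batch, left)
        idx = np.argsort(rng.random((k, m)), axis=1)
        cos = (b[idx] @ a) / (na * nb)
        hits += int(np.sum(cos >= observed - tol))
        left -= k
    p = (1 + hits) / (n_permutations + 1)
    return SimilarityResult(observed, p, n_permutations, seed, False)


def match_to_catalog(
    signatures,
    reference: pd.DataFrame,
    n_permutations: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cosine-match extracted signatures against a named reference catalog.

    ``reference`` is a channels x M frame in the frozen SBS96 row order
    (validated against the canonical labels).  Returns the full K x M
    cosine matrix and a per-signature best-match table; when
    ``n_permutations`` > 0 an empirical p accompanies each best match.
    """
    from .sbs import CHANNEL_LABELS
    from .signatures import SignatureMatrix

    if isinstance(signatures, SignatureMatrix):
        sig_df = signatures.to_frame()
    else:
        sig_df = signatures
    if list(reference.index) != list(CHANNEL_LABELS):
        raise ValueError(
            "reference catalog rows are not in the canonical SBS96 order"
        )
    if list(sig_df.index) != list(CHANNEL_LABELS):
        raise ValueError("signature rows are not in the canonical SBS96 order")

    sim = pd.DataFrame(
        [
            [
                cosine_similarity(sig_df[s].to_numpy(), reference[r].to_numpy())
                for r in reference.columns
            ]
            for s in sig_df.columns
        ],
        index=sig_df.columns,
        columns=reference.columns,
    )
    rows = []
    for s in sim.index:
        best = sim.loc[s].idxmax()
        row = {"signature": s, "best_match": best, "cosine": sim.loc[s, best]}
        if n_permutations > 0:
            row["p_empirical"] = cosine_permutation_pvalue(
                sig_df[s].to_numpy(),
                reference[best].to_numpy(),
                n_permutations=n_permutations,
                seed=seed,
                exhaustive=False,
            ).p_empirical
        rows.append(row)
    return sim, pd.DataFrame(rows)


def cross_method_correlation(signature_sets: dict) -> pd.DataFrame:
    """Pearson correlation between signatures from different extractions.

    ``signature_sets`` maps a configuration name to a SignatureMatrix or
    channels x K frame; all must share the SBS96 channel order.  Signed
    correlations expose concordance (positive) vs discordance (negative)
    between extractor variants.  Constant profiles yield NaN and are
    flagged by a warning.
    """
    from .sbs import CHANNEL_LABELS
    from .signatures import SignatureMatrix

    cols = {}
    for name, sigs in signature_sets.items():
        df = sigs.to_frame() if isinstance(sigs, SignatureMatrix) else sigs
        if list(df.index) != list(CHANNEL_LABELS):
            raise ValueError(f"set {name!r} not in the canonical SBS96 order")
        for c in df.columns:
            cols[f"{name}:{c}"] = df[c].to_numpy()
    frame = pd.DataFrame(cols)
    if (frame.std(axis=0) == 0).any():
        import warnings

        warnings.warn("constant profile(s): correlation undefined (NaN)")
    return frame.corr(method="pearson")
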