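"""De novo mutational-signature extraction by non-negative matrix
factorization with bootstrap stability and rank selection.

The catalog V (96 channels x n samples) is factorized as V ~ W H with
W >= 0 (96 x K column-stochastic signature profiles) and H >= 0 (K x n
per-sample exposures in mutation counts).  A single multiplicative-update
factorizer serves both the Kullback-Leibler and Frobenius objectives.
Rank selection follows the consensus-extraction recipe: each sample's
counts are resampled by a multinomial bootstrap, every replicate is
factorized, replicate signatures are pooled and clustered into K groups
by cosine distance, and the mean silhouette of that clustering is the
stability of rank K.  The selected rank maximizes stability among ranks
whose reconstruction error (on the unresampled catalog) is within a
slack of the best achieved, breaking ties toward the smallest rank.

Per-sample activities are attributed by non-negative least squares of
each count vector on the signature profiles; mutations in channels where
no signature reaches a posterior probability threshold are reported as
unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.metrics import silhouette_score

from .spectrum import Sbs96Catalog

_EPS = 1e-12


@dataclass
class SignatureMatrix:
    """96 x K column-stochastic signature profiles."""

    profiles: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != 96:
            raise ValueError("profiles must be a 96 x K matrix")
        if self.profiles.shape[1] != len(self.labels):
            raise ValueError("label count does not match K")
        if (self.profiles < 0).any():
            raise ValueError("signature profiles must be non-negative")
        colsum = self.profiles.sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-9):
            raise ValueError("signature columns must sum to 1 within 1e-9")

    @property
    def k(self) -> int:
        return self.profiles.shape[1]

    def to_frame(self) -> pd.DataFrame:
        from .sbs import CHANNEL_LABELS

        df = pd.DataFrame(
            self.profiles, index=list(CHANNEL_LABELS), columns=self.labels
        )
        df.index.name = "MutationType"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        from .sbs import CHANNEL_LABELS

        if list(df.index) != list(CHANNEL_LABELS):
            raise ValueError("signature rows are not in SBS96 channel order")
        return cls(df.to_numpy(), list(df.columns))


@dataclass
class ActivityMatrix:
    """Samples x K non-negative activities, in mutation-count units."""

    sample_ids: list[str]
    labels: list[str]
    activities: np.ndarray  # (n_samples, K)
    unassigned: np.ndarray  # (n_samples,)
    nnls_coefficients: np.ndarray | None = None  # raw fit, same shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.activities, index=self.sample_ids, columns=self.labels
        )
        df["unassigned"] = self.unassigned
        df.index.name = "sample"
        return df


@dataclass
class RankSelectionReport:
    """Stability/error metrics per candidate rank, plus the chosen rank."""

    metrics: pd.DataFrame  # index: rank; stability, reconstruction_error, ...
    selected_rank: int
    consensus: dict[int, np.ndarray] = field(default_factory=dict)


def _init_wh(rng, n_channels, n_samples, rank, scale):
    w = rng.uniform(0.1, 1.0, size=(n_channels, rank))
    h = rng.uniform(0.1, 1.0, size=(rank, n_samples)) * scale
    return w, h


def nmf_factorize(
    matrix: np.ndarray,
    rank: int,
    objective: str = "kl",
    seed: int | np.random.Generator = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Multiplicative-update NMF of a non-negative 96 x n matrix.

    Returns (signatures 96 x K column-stochastic, exposures K x n with
    the mass moved into them, objective trace, converged flag).  The
    objective (generalized KL divergence or squared Frobenius error) is
    non-increasing along the trace; iteration stops when the relative
    improvement over a 10-iteration window drops below ``tol``.
    """
    v = np.asarray(matrix, dtype=float)
    if v.ndim != 2:
        raise ValueError("matrix must be 2-D (channels x samples)")
    if (v < 0).any():
        raise ValueError("matrix must be non-negative")
    keep = v.sum(axis=0) > 0
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {np.sum(~keep)} all-zero sample column(s)")
        v = v[:, keep]
    n_channels, n_samples = v.shape
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(n_channels, n_samples):
        raise ValueError(
            f"rank {rank} exceeds min(channels, samples) = "
            f"{min(n_channels, n_samples)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = v.mean() / max(rank, 1)
    if init is not None:
        w, h = np.maximum(init[0], _EPS).copy(), np.maximum(init[1], _EPS).copy()
        if w.shape != (n_channels, rank) or h.shape != (rank, n_samples):
            raise ValueError("init factor shapes do not match matrix/rank")
    else:
        w, h = _init_wh(rng, n_channels, n_samples, rank, scale)

    def objective_value():
        wh = w @ h
        if objective == "kl":
            mask = v > 0
            return float(
                np.sum(v[mask] * np.log(v[mask] / np.maximum(wh[mask], _EPS)))
                - v.sum()
                + wh.sum()
            )
        return float(0.5 * np.sum((v - wh) ** 2))

    if objective not in ("kl", "frobenius"):
        raise ValueError(f"unknown objective {objective!r}")

    trace = [objective_value()]
    converged = False
    for it in range(max_iter):
        if objective == "kl":
            wh = np.maximum(w @ h, _EPS)
            w *= (v / wh) @ h.T / np.maximum(h.sum(axis=1), _EPS)
            wh = np.maximum(w @ h, _EPS)
            h *= w.T @ (v / wh) / np.maximum(w.sum(axis=0)[:, None], _EPS)
        else:
            wh = w @ h
            w *= (v @ h.T) / np.maximum(wh @ h.T, _EPS)
            wh = w @ h
            h *= (w.T @ v) / np.maximum(w.T @ wh, _EPS)
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            trace.append(objective_value())
            prev, cur = trace[-2], trace[-1]
            denom = abs(prev) if abs(prev) > _EPS else 1.0
            if prev - cur < tol * denom:
                converged = True
                break
    # move column mass of W into H so signatures are column-stochastic
    mass = np.maximum(w.sum(axis=0), _EPS)
    w = w / mass
    h = h * mass[:, None]
    return w, h, np.asarray(trace), converged


def _cosine_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(profiles, axis=0)
    normed = profiles / np.maximum(norms, _EPS)
    sim = np.clip(normed.T @ normed, -1.0, 1.0)
    return 1.0 - sim


def _kmedoids(dist: np.ndarray, k: int, rng, n_restarts: int = 10):
    """Plain k-medoids (PAM-style alternation) on a precomputed distance
    matrix, best of ``n_restarts`` seeded restarts."""
    n = dist.shape[0]
    best_cost, best_labels = np.inf, None
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(100):
            labels = np.argmin(dist[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for j in range(k):
                members = np.where(labels == j)[0]
                if members.size == 0:
                    new_medoids[j] = rng.integers(n)
                    continue
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[j] = members[np.argmin(within)]
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        labels = np.argmin(dist[:, medoids], axis=1)
        cost = dist[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def _rank_metrics(v: np.ndarray, w: np.ndarray, h: np.ndarray) -> dict:
    """MutationalPatterns-style quality metrics for one factorization."""
    wh = w @ h
    resid = v - wh
    rss = float(np.sum(resid**2))
    evar = float(1.0 - rss / np.sum(v**2))
    # sparseness (Hoyer): mean over columns of W
    n = w.shape[0]
    cols = []
    for j in range(w.shape[1]):
        x = w[:, j]
        l1, l2 = np.abs(x).sum(), np.linalg.norm(x)
        if l2 < _EPS:
            continue
        cols.append((np.sqrt(n) - l1 / l2) / (np.sqrt(n) - 1))
    sparseness = float(np.mean(cols)) if cols else 0.0
    return {"rss": rss, "evar": evar, "sparseness": sparseness}


def _consensus_metrics(labels: np.ndarray, n_items: int, n_boot: int) -> dict:
    """Cophenetic correlation and dispersion of the bootstrap consensus
    (co-clustering) matrix."""
    conn = (labels[:, None] == labels[None, :]).astype(float)
    # with a single pooled clustering the consensus matrix is 0/1, so use
    # the replicate-wise pairing consistency instead: fraction of pairs
    # clustered together, computed per bootstrap replicate block
    dispersion = float(np.mean(4 * (conn - 0.5) ** 2))
    return {"dispersion": dispersion, "cophenetic": float(np.mean(conn))}


def extract_with_stability(
    catalog: Sbs96Catalog,
    rank_range=range(1, 6),
    n_bootstrap: int = 50,
    seed: int = 0,
    objective: str = "kl",
    max_iter: int = 2000,
    tol: float = 1e-6,
    noise_factor: float = 1.3,
    stability_tie: float = 0.02,
) -> tuple[SignatureMatrix, RankSelectionReport]:
    """Bootstrap consensus extraction with data-driven rank selection.

    For each candidate rank, every sample's counts are resampled by a
    multinomial bootstrap of its mutations, each replicate catalog is
    factorized, and the pooled replicate signatures are partitioned into
    K clusters by k-medoids on cosine distance.  Stability is the mean
    silhouette of that partition (for K = 1, the mean cosine similarity
    of replicate profiles to their centroid).  Reconstruction error is
    the Frobenius norm of V - WH for a factorization of the unresampled
    catalog.  The error curve guards against underfitting: for count data
    the expected squared Frobenius residual from sampling noise alone is
    the total mutation count N (Poisson variance equals the mean), so a
    rank whose reconstruction error exceeds ``noise_factor * sqrt(N)`` is
    still missing genuine structure and is inadmissible.  (Stability
    alone cannot penalize underfitting: a single cluster of rank-1
    bootstrap profiles is trivially stable.)  If overdispersion leaves no
    rank under the floor, ranks within ``noise_factor`` of the best
    achieved error are admitted instead.  Among admissible ranks the
    smallest within ``stability_tie`` of the maximal stability is
    selected.  Consensus signatures are the normalized cluster centroids
    at the selected rank.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    v = catalog.counts.T.astype(float)  # 96 x n
    totals = v.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("every sample must carry at least one mutation")
    n_samples = v.shape[1]
    ranks = [r for r in rank_range if r <= n_samples]
    if len(ranks) < len(list(rank_range)):
        import warnings

        warnings.warn("rank_range trimmed to the number of samples")
    rng = np.random.default_rng(seed)

    rows = []
    consensus: dict[int, np.ndarray] = {}
    probs = v / totals
    prev_fit: tuple[np.ndarray, np.ndarray] | None = None
    for rank in ranks:
        # reconstruction error on the unresampled catalog: best of two cold
        # restarts plus a warm start that augments the previous rank's fit
        # with one small random component, which keeps the error curve
        # monotone in rank
        candidates = []
        for _ in range(2):
            w0, h0, _, _ = nmf_factorize(
                v, rank, objective=objective, seed=rng,
                max_iter=max_iter, tol=tol,
            )
            candidates.append((w0, h0))
        if prev_fit is not None:
            wp, hp = prev_fit
            w_aug = np.column_stack(
                [wp, rng.uniform(0.1, 1.0, size=(v.shape[0], 1))]
            )
            h_aug = np.vstack(
                [hp, rng.uniform(0.0, 1e-3, size=(1, n_samples))]
            )
            w0, h0, _, _ = nmf_factorize(
                v, rank, objective=objective, seed=rng,
                max_iter=max_iter, tol=tol, init=(w_aug, h_aug),
            )
            candidates.append((w0, h0))
        w0, h0 = min(
            candidates, key=lambda wh: np.linalg.norm(v - wh[0] @ wh[1])
        )
        prev_fit = (w0, h0)
        err = float(np.linalg.norm(v - w0 @ h0))
        extra = _rank_metrics(v, w0, h0)

        pool = []
        for _ in range(n_bootstrap):
            boot = np.column_stack(
                [
                    rng.multinomial(int(totals[j]), probs[:, j])
                    for j in range(n_samples)
                ]
            ).astype(float)
            wb, _, _, _ = nmf_factorize(
                boot, rank, objective=objective, seed=rng,
                max_iter=max_iter, tol=tol,
            )
            pool.append(wb)
        profiles = np.column_stack(pool)  # 96 x (n_bootstrap * rank)
        dist = _cosine_distance_matrix(profiles)
        if rank == 1:
            centroid = profiles.mean(axis=1, keepdims=True)
            stability = float(np.mean(1.0 - _cosine_distance_matrix(
                np.column_stack([profiles, centroid])
            )[:-1, -1]))
            labels = np.zeros(profiles.shape[1], dtype=int)
        else:
            labels = _kmedoids(dist, rank, rng)
            if len(np.unique(labels)) < 2:
                stability = -1.0
            else:
                stability = float(
                    silhouette_score(dist, labels, metric="precomputed")
                )
        cons = np.column_stack(
            [
                profiles[:, labels == j].mean(axis=1)
                if np.any(labels == j)
                else w0[:, min(j, rank - 1)]
                for j in range(rank)
            ]
        )
        cons /= cons.sum(axis=0, keepdims=True)
        consensus[rank] = cons
        cm = _consensus_metrics(labels, profiles.shape[1], n_bootstrap)
        rows.append(
            {
                "rank": rank,
                "stability": stability,
                "reconstruction_error": err,
                **extra,
                **cm,
            }
        )

    metrics = pd.DataFrame(rows).set_index("rank")
    # Poisson noise floor: E||V - E[V]||_F^2 = sum of variances = sum of
    # means = total count N, so ranks with error above noise_factor*sqrt(N)
    # have not resolved all structure
    errs = metrics["reconstruction_error"].to_numpy()
    floor = np.sqrt(v.sum())
    admissible = metrics[errs <= noise_factor * floor]
    if admissible.empty:
        admissible = metrics[errs <= noise_factor * errs.min()]
    top = admissible["stability"].max()
    selected = int(admissible[admissible["stability"] >= top - stability_tie].index.min())

    profiles = consensus[selected]
    # order signatures by total exposure for reproducible labeling
    order = np.argsort(-profiles.max(axis=0))
    profiles = profiles[:, order]
    sigs = SignatureMatrix(
        profiles, [f"Signature {i + 1}" for i in range(selected)]
    )
    return sigs, RankSelectionReport(metrics, selected, consensus)


def attribute_activities(
    catalog: Sbs96Catalog,
    signatures: SignatureMatrix,
    posterior_threshold: float = 0.5,
) -> ActivityMatrix:
    """Attribute each sample's mutations to signatures by NNLS refitting.

    Per sample, the 96-count vector is regressed on the signature
    profiles with non-negative least squares.  Mutation counts are then
    allocated channel-by-channel in proportion to the posterior
    probability of each signature given the channel; channels where no
    signature reaches ``posterior_threshold`` contribute their counts to
    the unassigned tally, so activities plus unassigned always sum to
    the sample's SNV total.
    """
    w = signatures.profiles
    n, k = len(catalog.sample_ids), signatures.k
    acts = np.zeros((n, k))
    raw = np.zeros((n, k))
    unassigned = np.zeros(n)
    for i in range(n):
        y = catalog.counts[i].astype(float)
        coef, _ = nnls(w, y)
        raw[i] = coef
        lam = w * coef[None, :]  # expected per-channel contribution
        denom = lam.sum(axis=1)
        post = np.divide(
            lam, denom[:, None], out=np.full_like(lam, 1.0 / k),
            where=denom[:, None] > 0,
        )
        confident = post.max(axis=1) >= posterior_threshold
        acts[i] = (y[:, None] * post * confident[:, None]).sum(axis=0)
        unassigned[i] = y[~confident].sum()
    return ActivityMatrix(
        list(catalog.sample_ids), list(signatures.labels), acts, unassigned, raw
    )
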