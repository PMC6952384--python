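"""Transcriptional subgroup discovery.

Top-variable gene selection, k-medoids (PAM, deterministic BUILD + SWAP),
per-sample silhouette widths, silhouette-based model selection over a k
range, negative-silhouette "core sample" filtering, and subsampled
consensus clustering with the CDF-area summary.

The default sample dissimilarity is 1 - Pearson correlation between sample
profiles over the selected genes — the transcriptomics convention, and
scale-free once genes are standardised.  Euclidean distance is available
as an alternative.  All tie-breaks resolve to the smaller index / smaller
k so repeated runs are identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances and gene selection
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities with zero diagonal."""

    values: np.ndarray
    sample_ids: pd.Index
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.sample_ids = pd.Index(self.sample_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def sample_distances(m: ExpressionMatrix, metric: str = "pearson") -> DistanceMatrix:
    """Pairwise sample dissimilarities over the matrix's genes."""
    x = m.values.to_numpy()
    if metric in ("pearson", "one-minus-pearson"):
        d = 1.0 - np.corrcoef(x, rowvar=False)
        metric = "one-minus-pearson"
    elif metric == "euclidean":
        sq = (x ** 2).sum(axis=0)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x.T @ x)
        d = np.sqrt(np.clip(d2, 0.0, None))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, m.sample_ids, metric)


def top_variable_genes(m: ExpressionMatrix, n: int = 1000) -> ExpressionMatrix:
    """Keep the ``n`` genes with the largest variance across samples.

    Ties are broken by gene-ID sort order so the selection is reproducible.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > m.n_genes:
        raise ValueError(f"requested {n} genes but matrix has {m.n_genes}")
    var = m.values.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "gene": var.index}).sort_values(
        ["var", "gene"], ascending=[False, True], kind="mergesort"
    )
    keep = order.index[:n]
    return m.subset_genes(keep)


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    k: int
    assignment: pd.Series            # per-sample label in 1..k
    medoids: list                    # sample IDs, one per cluster, cluster c = medoids[c-1]
    silhouette: pd.Series
    mean_silhouette: float
    core_mask: pd.Series             # silhouette >= 0
    total_cost: float = field(default=np.nan)


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    nearest = d[:, first].copy()
    while len(medoids) < k:
        best_gain, best_c = -np.inf, None
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(nearest - d[:, c], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_c = gain, c
        medoids.append(best_c)
        nearest = np.minimum(nearest, d[:, best_c])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    n = d.shape[0]
    medoids = sorted(medoids)

    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_cost, best_pair = current, None
        for mi, m_old in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1:]
            for h in range(n):
                if h in medoids:
                    continue
                c = cost(others + [h])
                if c < best_cost - 1e-12:
                    best_cost, best_pair = c, (mi, h)
        if best_pair is not None:
            mi, h = best_pair
            medoids[mi] = h
            medoids = sorted(medoids)
            current = best_cost
            improved = True
    return medoids


def _pam_exhaustive(d: np.ndarray, k: int) -> list[int]:
    """Globally optimal medoid set by enumeration (tiny instances only).

    Ties resolve to the lexicographically smallest medoid set.
    """
    import itertools

    n = d.shape[0]
    best_cost, best = np.inf, None
    for medoids in itertools.combinations(range(n), k):
        cost = d[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, medoids
    return list(best)


#: enumeration bound: below this many candidate medoid sets the solver is
#: exact; larger problems use the classic BUILD + SWAP heuristic
_EXACT_LIMIT = 3000


def pam_kmedoids(d: DistanceMatrix, k: int, seed: int | None = None) -> ClusterResult:
    """k-medoids partitioning (PAM).

    Tiny instances (fewer than ~3000 candidate medoid sets) are solved
    exactly by enumeration; larger ones use the classic greedy BUILD phase
    followed by best-improvement SWAP until no swap lowers the total cost.
    Deterministic given the distance matrix (``seed`` is accepted for API
    symmetry but unused).  Samples are assigned to the nearest medoid,
    ties to the lowest-index medoid; cluster labels 1..k follow medoid
    index order.
    """
    n = d.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    dm = d.values
    from math import comb

    if comb(n, k) <= _EXACT_LIMIT:
        medoids = _pam_exhaustive(dm, k)
    else:
        medoids = _pam_build(dm, k)
        if k < n:
            medoids = _pam_swap(dm, medoids)
    medoids = sorted(medoids)
    assign_idx = np.argmin(dm[:, medoids], axis=1)       # argmin ties -> lowest medoid
    assignment = pd.Series(assign_idx + 1, index=d.sample_ids, name="cluster")
    total_cost = float(dm[np.arange(n), np.asarray(medoids)[assign_idx]].sum())
    sil = (
        silhouette_widths(d, assignment)
        if k >= 2
        else pd.Series(0.0, index=d.sample_ids, name="silhouette")
    )
    return ClusterResult(
        k=k,
        assignment=assignment,
        medoids=[d.sample_ids[m] for m in medoids],
        silhouette=sil,
        mean_silhouette=float(sil.mean()),
        core_mask=sil >= 0,
        total_cost=total_cost,
    )


def silhouette_widths(d: DistanceMatrix, assignment: pd.Series) -> pd.Series:
    """Per-sample silhouette width s(i) = (b - a) / max(a, b).

    a(i): mean dissimilarity to the sample's own cluster (self excluded);
    b(i): smallest mean dissimilarity to any other cluster.  Members of
    singleton clusters get s(i) = 0 by convention.
    """
    assignment = pd.Series(assignment).reindex(d.sample_ids)
    labels = assignment.to_numpy()
    unique = np.unique(labels)
    if len(unique) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    dm = d.values
    n = d.n
    s = np.zeros(n)
    masks = {c: labels == c for c in unique}
    for i in range(n):
        own = masks[labels[i]].copy()
        if own.sum() == 1:
            s[i] = 0.0
            continue
        own[i] = False
        a = dm[i, own].mean()
        b = min(dm[i, masks[c]].mean() for c in unique if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return pd.Series(s, index=d.sample_ids, name="silhouette")


# ---------------------------------------------------------------------------
# model selection and core filtering
# ---------------------------------------------------------------------------


@dataclass
class KSelection:
    best_k: int
    mean_silhouettes: dict[int, float]
    results: dict[int, ClusterResult]
    no_structure: bool              # all mean widths below the structure floor


def select_k_by_silhouette(
    m: ExpressionMatrix,
    k_min: int = 2,
    k_max: int = 10,
    metric: str = "pearson",
    seed: int | None = None,
    structure_floor: float = 0.05,
) -> KSelection:
    """Run PAM for each k in [k_min, k_max]; pick the highest mean silhouette.

    Ties go to the smaller k.  If no k reaches ``structure_floor`` the
    selection is flagged as showing no structure.
    """
    if k_max >= m.n_samples:
        raise ValueError("k_max must be below the sample count")
    d = sample_distances(m, metric)
    results: dict[int, ClusterResult] = {}
    means: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        res = pam_kmedoids(d, k, seed=seed)
        results[k] = res
        means[k] = res.mean_silhouette
    best_k = max(sorted(means), key=lambda k: (means[k], -k))
    no_structure = max(means.values()) < structure_floor
    if no_structure:
        logger.warning("no cluster structure detected (max mean silhouette %.3f)", max(means.values()))
    return KSelection(best_k, means, results, no_structure)


def filter_core_samples(r: ClusterResult) -> tuple[list, list]:
    """Split samples into core (silhouette >= 0) and excluded (negative).

    The exclusion list is logged with the offending widths; raises when no
    sample survives.
    """
    retained = list(r.silhouette.index[r.silhouette >= 0])
    excluded = list(r.silhouette.index[r.silhouette < 0])
    if not retained:
        raise ValueError("no core samples: all silhouette widths are negative")
    for sample in excluded:
        logger.info("excluding %s (silhouette %.3f)", sample, r.silhouette[sample])
    return retained, excluded


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]   # per-k co-clustering frequencies
    cdf_grid: np.ndarray                 # 101 points in [0, 1]
    cdf: dict[int, np.ndarray]
    area: dict[int, float]               # trapezoid area under the CDF
    delta_area: dict[int, float]         # relative change in area vs previous k
    selected_k: int                      # argmax raw area (see class docstring)
    never_cosampled: dict[int, int]      # per-k count of pairs never co-subsampled

    # NOTE: the raw CDF area typically grows with k; the per-k *change* in
    # area (``delta_area``) is the conventional selector and is reported
    # alongside.  ``selected_k`` follows the raw-area criterion.


def consensus_cluster(
    m: ExpressionMatrix,
    k_min: int = 2,
    k_max: int = 10,
    reps: int = 100,
    subsample_frac: float = 0.8,
    metric: str = "pearson",
    seed: int | None = None,
) -> ConsensusResult:
    """Subsampled consensus clustering over a range of k.

    RNG protocol (documented so runs can be reproduced exactly): a single
    ``numpy.random.default_rng(seed)`` stream drives all subsampling; for
    each k in ascending order and each repetition, ``ceil(frac * n)``
    samples are drawn without replacement via ``rng.choice`` and clustered
    with PAM.  consensus(i, j) = co-cluster count / co-subsample count;
    pairs never co-sampled score 0 and are counted in ``never_cosampled``.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    n = m.n_samples
    sub_n = int(np.ceil(subsample_frac * n))
    if sub_n <= k_max:
        raise ValueError(f"subsample of {sub_n} too small for k_max={k_max}")
    d_full = sample_distances(m, metric)
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 101)
    consensus, cdfs, areas, never = {}, {}, {}, {}
    for k in range(k_min, k_max + 1):
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(reps):
            idx = np.sort(rng.choice(n, size=sub_n, replace=False))
            sub = DistanceMatrix(d_full.values[np.ix_(idx, idx)], d_full.sample_ids[idx], d_full.metric)
            labels = pam_kmedoids(sub, k).assignment.to_numpy()
            co_sample[np.ix_(idx, idx)] += 1.0
            same = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(co_sample > 0, co_cluster / np.where(co_sample > 0, co_sample, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        iu = np.triu_indices(n, k=1)
        never[k] = int((co_sample[iu] == 0).sum())
        entries = cons[iu]
        cdf = np.array([(entries <= g).mean() for g in grid])
        consensus[k] = pd.DataFrame(cons, index=m.sample_ids, columns=m.sample_ids)
        cdfs[k] = cdf
        areas[k] = float(np.trapezoid(cdf, grid))
    ks = sorted(areas)
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else np.nan
    selected = max(ks, key=lambda k: (areas[k], -k))
    return ConsensusResult(consensus, grid, cdfs, areas, delta, selected, never)
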