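"""Gene-set analysis: GMT I/O, permutation pre-ranked GSEA, and GSVA.

Two complementary scoring schemes are provided.  ``gsea_preranked`` runs the
weighted Kolmogorov–Smirnov-style running-sum statistic over a ranked gene
list (here typically the per-subgroup shrunken-centroid scores of the
classifier), with a gene-label permutation null, sign-stratified NES
normalisation and FDR.  ``gsva_scores`` converts a gene-by-sample matrix
into a set-by-sample matrix of per-sample enrichment scores via the
kernel-CDF / symmetric-rank random-walk procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gene set collections / GMT format
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions

    def filter_to_universe(
        self, universe, min_size: int = 5, max_size: int = 500
    ) -> "GeneSetCollection":
        """Restrict members to ``universe``; drop sets outside the size window."""
        universe = set(universe)
        kept: dict[str, list[str]] = {}
        desc: dict[str, str] = {}
        for name, members in self.sets.items():
            filtered = [g for g in members if g in universe]
            if min_size <= len(filtered) <= max_size:
                kept[name] = filtered
                desc[name] = self.descriptions.get(name, "")
            else:
                logger.info(
                    "excluding gene set %s (%d members in universe, window [%d, %d])",
                    name, len(filtered), min_size, max_size,
                )
        return GeneSetCollection(kept, desc)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (needs name, description, >=1 member)")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: malformed GMT line {lineno} (no members)")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------


def _order_by_score(scores: pd.Series) -> pd.Series:
    """Sort genes by score descending, ties broken by gene ID ascending."""
    frame = pd.DataFrame({"score": scores.astype(float)})
    frame["gene"] = frame.index
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return frame["score"]


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n_genes: int):
    """Enrichment score of a hit-position set in O(|S| log |S|).

    ``positions`` are 0-based indices into the ranked list; ``weights`` the
    (already exponentiated) hit increments at those positions.  Misses
    decrement by 1/(N - |S|).  Returns (ES, index of the extreme position).
    The extreme with the larger absolute running-sum deviation wins; on an
    exact tie the positive one is reported.
    """
    m = positions.size
    order = np.argsort(positions, kind="mergesort")
    pos = positions[order]
    w = weights[order]
    total = w.sum()
    if total <= 0:
        # degenerate all-zero weights inside the set: fall back to equal hits
        w = np.ones(m)
        total = float(m)
    miss_dec = 1.0 / (n_genes - m)
    cum_hits = np.cumsum(w) / total
    # misses strictly before each hit position: pos_j - j  (0-based)
    misses_before = pos - np.arange(m)
    after = cum_hits - (misses_before + 0.0) * miss_dec          # value just after each hit
    before = np.concatenate(([0.0], cum_hits[:-1])) - misses_before * miss_dec
    # candidate minima: value just before each hit (deepest point preceding it)
    max_dev = after.max()
    min_dev = min(before.min(), after[-1] - (n_genes - 1 - pos[-1]) * miss_dec)
    if max_dev >= -min_dev:
        es = float(max_dev)
        extreme = int(pos[int(np.argmax(after))])
    else:
        es = float(min_dev)
        candidates = np.concatenate((before, [after[-1] - (n_genes - 1 - pos[-1]) * miss_dec]))
        idx = int(np.argmin(candidates))
        extreme = int(pos[idx]) - 1 if idx < m else n_genes - 1
    return es, extreme


def gsea_preranked(
    scores: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
    max_size: int = 500,
    fdr_method: str = "gsea",
) -> pd.DataFrame:
    """Permutation-based pre-ranked GSEA.

    Genes are ordered by ``scores`` descending; a set's running sum gains
    ``|score|^weight`` (normalised) at members and loses 1/(N-|S|) at
    non-members; ES is the signed extreme deviation.  The null distribution
    comes from ``n_perm`` random placements of the set members in the list
    (gene-label permutation).  ``p = (1 + #direction-consistent perm ES at
    least as extreme) / (n_perm + 1)``; NES divides ES by the mean same-sign
    permutation ES; FDR is the sign-stratified NES-based convention
    (``fdr_method="bh"`` applies plain Benjamini–Hochberg instead).

    Returns a DataFrame indexed by set name with columns
    ``es, nes, pval, qval, size, leading_edge``.
    """
    scores = pd.Series(scores, dtype=float)
    if scores.empty:
        raise ValueError("empty ranking")
    if (scores == 0).all():
        raise ValueError("degenerate ranking: all gene scores are zero")
    ranked = _order_by_score(scores)
    genes = ranked.index.to_numpy()
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    abs_w = np.abs(ranked.to_numpy()) ** weight

    usable = sets.filter_to_universe(genes, min_size=min_size, max_size=max_size)
    if len(usable) == 0:
        raise ValueError("no gene sets within the size window on this ranking")

    rng = np.random.default_rng(seed)
    records = []
    perm_es_all: list[np.ndarray] = []
    for name, members in usable:
        positions = np.array(sorted(gene_pos[g] for g in members))
        m = positions.size
        if m >= n_genes:
            raise ValueError(f"gene set {name!r} covers the whole universe")
        es, extreme = _es_from_positions(positions, abs_w[positions], n_genes)
        perm_es = np.empty(n_perm)
        for p_i in range(n_perm):
            perm_pos = rng.choice(n_genes, size=m, replace=False)
            perm_es[p_i], _ = _es_from_positions(perm_pos, abs_w[perm_pos], n_genes)
        # nominal p against the same-sign portion of the permutation null
        # (sign-stratified, so null sets are calibrated at level alpha)
        if es >= 0:
            same_sign = perm_es[perm_es >= 0]
            pval = (1 + int((same_sign >= es).sum())) / (1 + same_sign.size)
        else:
            same_sign = perm_es[perm_es < 0]
            pval = (1 + int((same_sign <= es).sum())) / (1 + same_sign.size)
        nes = es / np.abs(same_sign).mean() if same_sign.size else np.nan
        if es >= 0:
            lead = [g for g in members if gene_pos[g] <= extreme]
        else:
            lead = [g for g in members if gene_pos[g] >= extreme]
        records.append({"name": name, "es": es, "nes": nes, "pval": pval,
                        "size": m, "leading_edge": lead})
        perm_es_all.append(perm_es)

    result = pd.DataFrame(records).set_index("name")
    result["qval"] = _gsea_fdr(result, perm_es_all) if fdr_method == "gsea" else _bh(result["pval"].to_numpy())
    return result[["es", "nes", "pval", "qval", "size", "leading_edge"]]


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _gsea_fdr(result: pd.DataFrame, perm_es_all: list[np.ndarray]) -> np.ndarray:
    """Sign-stratified NES-based FDR as in canonical GSEA."""
    # normalise each set's permutation ES by that set's same-sign mean
    norm_perm: list[np.ndarray] = []
    for perm_es in perm_es_all:
        pos_mean = perm_es[perm_es > 0].mean() if (perm_es > 0).any() else np.nan
        neg_mean = np.abs(perm_es[perm_es < 0]).mean() if (perm_es < 0).any() else np.nan
        scaled = np.where(perm_es >= 0, perm_es / pos_mean, perm_es / neg_mean)
        norm_perm.append(scaled[np.isfinite(scaled)])
    all_perm = np.concatenate(norm_perm)
    obs = result["nes"].to_numpy()
    qvals = np.empty(len(obs))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            qvals[i] = 1.0
            continue
        if nes >= 0:
            denom_perm = (all_perm >= 0).sum()
            num = (all_perm >= nes).sum() / denom_perm if denom_perm else 1.0
            obs_pos = obs[np.isfinite(obs) & (obs >= 0)]
            den = (obs_pos >= nes).sum() / obs_pos.size if obs_pos.size else 1.0
        else:
            denom_perm = (all_perm < 0).sum()
            num = (all_perm <= nes).sum() / denom_perm if denom_perm else 1.0
            obs_neg = obs[np.isfinite(obs) & (obs < 0)]
            den = (obs_neg <= nes).sum() / obs_neg.size if obs_neg.size else 1.0
        qvals[i] = min(1.0, num / den) if den > 0 else 1.0
    return qvals


def rank_from_classifier(ranking, subgroup) -> pd.Series:
    """Per-gene ranking scores for one subgroup from a fitted classifier.

    The score of a gene is its signed shrunken centroid contrast d' for the
    requested subgroup; genes shrunk to zero (non-survivors) score 0.  The
    resulting vector is the input to :func:`gsea_preranked`.
    """
    scores = ranking.shrunken_scores
    if subgroup not in scores.columns:
        raise KeyError(f"unknown subgroup {subgroup!r}; have {list(scores.columns)}")
    return scores[subgroup].copy()


# ---------------------------------------------------------------------------
# GSVA
# ---------------------------------------------------------------------------


def _kernel_cdf(x: np.ndarray, bandwidth_factor: float = 4.0, chunk: int = 256) -> np.ndarray:
    """Gaussian-kernel smoothed empirical CDF of each gene across samples.

    For gene i and sample j: ``z_ij = mean_k Phi((x_ij - x_ik) / h_i)`` with
    bandwidth ``h_i = sd_i / bandwidth_factor`` (sample SD).
    """
    n_genes, n_samples = x.shape
    sd = x.std(axis=1, ddof=1)
    h = sd / bandwidth_factor
    z = np.empty_like(x)
    for start in range(0, n_genes, chunk):
        stop = min(start + chunk, n_genes)
        block = x[start:stop]
        diff = (block[:, :, None] - block[:, None, :]) / h[start:stop, None, None]
        z[start:stop] = norm.cdf(diff).mean(axis=2)
    return z


def gsva_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    kernel: str = "gaussian",
    min_size: int = 5,
    max_size: int = 500,
    method: str = "diff",
) -> pd.DataFrame:
    """Per-sample gene-set variation scores (set-by-sample matrix).

    Procedure: (1) Gaussian-kernel CDF of each gene across samples
    (bandwidth = sample SD / 4); (2) per sample, genes are ordered by the
    CDF value descending and rescored symmetrically around the list middle,
    ``r = |N/2 - rank|``; (3) per set and sample, a weighted KS random walk
    over the ordered genes with hit weight ``r^tau``; (4) the score is the
    difference between the maximum positive and maximum negative deviation
    (``method="diff"``, the default) or the single largest absolute
    deviation (``method="maxdev"``).
    """
    if kernel != "gaussian":
        raise ValueError("only the gaussian kernel is implemented")
    if m.n_samples < 3:
        raise ValueError("GSVA needs at least 3 samples")
    values = m.values
    variable = values.std(axis=1, ddof=1) > 0
    if not variable.all():
        logger.warning("dropping %d constant gene rows for GSVA", int((~variable).sum()))
        values = values.loc[variable]
    genes = values.index.to_numpy()
    n_genes, n_samples = values.shape

    usable = sets.filter_to_universe(genes, min_size=min_size, max_size=max_size)
    if len(usable) == 0:
        raise ValueError("no usable gene sets for GSVA")

    z = _kernel_cdf(values.to_numpy())
    # per sample: rank 1 = largest kernel-CDF value; ties broken by gene order
    order = np.argsort(-z, axis=0, kind="mergesort")       # genes ordered per sample
    rank = np.empty_like(order)
    rows = np.arange(n_genes)
    for j in range(n_samples):
        rank[order[:, j], j] = rows                         # 0-based position in ordering
    sym = np.abs(n_genes / 2.0 - (rank + 1))                # symmetric rank statistic

    gene_idx = {g: i for i, g in enumerate(genes)}
    out = pd.DataFrame(index=list(usable.sets), columns=m.sample_ids, dtype=float)
    for name, members in usable:
        idx = np.array([gene_idx[g] for g in members])
        for j in range(n_samples):
            positions = rank[idx, j]
            weights = sym[idx, j] ** tau
            out.loc[name, m.sample_ids[j]] = _gsva_walk(positions, weights, n_genes, method)
    return out


def _gsva_walk(positions: np.ndarray, weights: np.ndarray, n_genes: int, method: str) -> float:
    """Deviation statistic of the weighted KS walk for one set and sample."""
    m = positions.size
    order = np.argsort(positions, kind="mergesort")
    pos = positions[order]
    w = weights[order]
    total = w.sum()
    if total <= 0:
        w = np.ones(m)
        total = float(m)
    miss_dec = 1.0 / (n_genes - m)
    cum_hits = np.cumsum(w) / total
    misses_before = pos - np.arange(m)
    after = cum_hits - misses_before * miss_dec
    before = np.concatenate(([0.0], cum_hits[:-1])) - misses_before * miss_dec
    tail = after[-1] - (n_genes - 1 - pos[-1]) * miss_dec
    max_dev = max(float(after.max()), 0.0)
    min_dev = min(float(before.min()), float(tail), 0.0)
    if method == "diff":
        return max_dev + min_dev          # max positive minus magnitude of max negative
    if method == "maxdev":
        return max_dev if max_dev >= -min_dev else min_dev
    raise ValueError(f"unknown GSVA method {method!r}")
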