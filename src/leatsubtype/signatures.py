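"""Subgroup signature genes via the nearest-shrunken-centroid classifier.

The NSC estimator standardises each gene's class-centroid contrast,
soft-thresholds it by Delta, and classifies samples by the shrunken
discriminant.  Cross-validated refitting yields a per-gene average rank
(the GSEA input), one-vs-rest Welch t-tests with Benjamini–Hochberg
adjustment provide per-gene FDR, and the class discriminants give every
sample an affiliation likelihood over the subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix
from .enrichment import _bh

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# NSC model
# ---------------------------------------------------------------------------


@dataclass
class NSCModel:
    """Fitted nearest-shrunken-centroid classifier.

    ``d`` holds the standardized contrasts d_ik, ``d_shrunk`` their
    soft-thresholded counterparts d'_ik = sign(d) * max(|d| - Delta, 0).
    Shrunken class centroids are reconstructed from d'.
    """

    classes: list
    genes: pd.Index
    overall_centroid: pd.Series
    pooled_sd: pd.Series
    s0: float
    m_k: pd.Series                       # per-class standardization factor
    priors: pd.Series
    d: pd.DataFrame                      # genes x classes
    d_shrunk: pd.DataFrame
    delta: float
    shrunken_centroids: pd.DataFrame = field(repr=False)

    @property
    def survivors(self) -> pd.Index:
        return self.genes[(self.d_shrunk != 0).any(axis=1)]

    def discriminants(self, m: ExpressionMatrix) -> pd.DataFrame:
        """Per-sample, per-class score delta_k(x); smaller is closer."""
        if not m.gene_ids.equals(self.genes):
            if set(m.gene_ids) >= set(self.genes):
                m = m.subset_genes(self.genes)
            else:
                raise ValueError("matrix genes do not cover the model's genes")
        x = m.values.to_numpy()
        denom = (self.pooled_sd.to_numpy() + self.s0) ** 2
        out = np.empty((m.n_samples, len(self.classes)))
        for ci, c in enumerate(self.classes):
            diff = x - self.shrunken_centroids[c].to_numpy()[:, None]
            out[:, ci] = (diff ** 2 / denom[:, None]).sum(axis=0) - 2.0 * np.log(self.priors[c])
        return pd.DataFrame(out, index=m.sample_ids, columns=self.classes)

    def predict(self, m: ExpressionMatrix) -> pd.Series:
        disc = self.discriminants(m)
        # argmin with ties to the first class in sorted order
        idx = np.argmin(disc.to_numpy(), axis=1)
        return pd.Series([self.classes[i] for i in idx], index=disc.index, name="predicted")


def nsc_fit(m: ExpressionMatrix, labels: pd.Series, delta: float = 0.0) -> NSCModel:
    """Fit the NSC model at shrinkage threshold ``delta``.

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)) with pooled within-class
    SD s_i, offset s0 = median(s_i) and m_k = sqrt(1/n_k + 1/n); class
    priors are the empirical frequencies.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    labels = pd.Series(labels).reindex(m.sample_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"classes with fewer than 2 samples: {sorted(counts[counts < 2].index)}")

    x = m.values
    n = m.n_samples
    overall = x.mean(axis=1)
    centroids = pd.DataFrame({c: x.loc[:, (labels == c).to_numpy()].mean(axis=1) for c in classes})
    ss_within = sum(
        ((x.loc[:, (labels == c).to_numpy()].sub(centroids[c], axis=0)) ** 2).sum(axis=1)
        for c in classes
    )
    pooled_sd = np.sqrt(ss_within / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    m_k = pd.Series({c: np.sqrt(1.0 / counts[c] + 1.0 / n) for c in classes})
    denom = pooled_sd + s0
    d = centroids.sub(overall, axis=0).div(denom, axis=0) / m_k
    d_shrunk = np.sign(d) * np.maximum(d.abs() - delta, 0.0)
    shrunken = d_shrunk.mul(denom, axis=0) * m_k
    shrunken = shrunken.add(overall, axis=0)
    priors = (counts / n).reindex(classes)
    return NSCModel(
        classes=classes, genes=m.gene_ids, overall_centroid=overall,
        pooled_sd=pooled_sd, s0=s0, m_k=m_k, priors=priors,
        d=d, d_shrunk=d_shrunk, delta=float(delta), shrunken_centroids=shrunken,
    )


def _reshrink(model: NSCModel, delta: float) -> NSCModel:
    """Re-threshold a fitted model at a different Delta (cheap)."""
    d_shrunk = np.sign(model.d) * np.maximum(model.d.abs() - delta, 0.0)
    denom = model.pooled_sd + model.s0
    shrunken = d_shrunk.mul(denom, axis=0) * model.m_k
    shrunken = shrunken.add(model.overall_centroid, axis=0)
    return NSCModel(
        classes=model.classes, genes=model.genes,
        overall_centroid=model.overall_centroid, pooled_sd=model.pooled_sd,
        s0=model.s0, m_k=model.m_k, priors=model.priors, d=model.d,
        d_shrunk=d_shrunk, delta=float(delta), shrunken_centroids=shrunken,
    )


# ---------------------------------------------------------------------------
# cross-validated gene ranking
# ---------------------------------------------------------------------------


@dataclass
class GeneRanking:
    """Average cross-validation gene ranks plus the full-data refit.

    ``avg_rank`` averages a gene's rank (1 = strongest, by max-class |d'|)
    over the folds in which it survived the selected threshold; genes that
    never survive carry the sentinel rank ``n_genes + 1``.

    Two thresholds attain the minimal CV misclassification: the *sparsest*
    (``selected_delta``, ties to larger Delta — the reported classifier)
    and the *most inclusive* (``ranking_delta``, ties to smaller Delta).
    ``shrunken_scores`` holds the full-data per-class d' at
    ``ranking_delta`` and is the pre-ranked GSEA input; a near-empty score
    vector would make the permutation null degenerate, which is why the
    inclusive threshold feeds enrichment.
    """

    avg_rank: pd.Series
    shrunken_scores: pd.DataFrame
    n_folds: int
    delta_grid: np.ndarray
    selected_delta: float
    ranking_delta: float
    cv_accuracy: float
    cv_errors: pd.Series                 # per-Delta misclassification counts


def nsc_cv_rank(
    m: ExpressionMatrix,
    labels: pd.Series,
    n_folds: int = 5,
    delta_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> GeneRanking:
    """Stratified-CV threshold selection and per-gene average ranks.

    Per fold the NSC model is fitted on the training split over the Delta
    grid; the grid value minimising total CV misclassification is selected
    (ties to the larger Delta, i.e. fewer genes).  Within each fold the
    surviving genes are ranked globally by max-class |d'| descending.
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    counts = labels.value_counts()
    min_class = int(counts.min())
    if min_class < n_folds:
        logger.warning("reducing folds from %d to %d (smallest class)", n_folds, min_class)
        n_folds = min_class
    if n_folds < 2:
        raise ValueError("need at least 2 usable folds")

    full = nsc_fit(m, labels, delta=0.0)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(full.d.abs().to_numpy().max()), 30)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise ValueError("empty Delta grid")

    if n_folds == m.n_samples:
        splitter = ((np.setdiff1d(np.arange(m.n_samples), [i]), np.array([i]))
                    for i in range(m.n_samples))
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splitter = skf.split(np.zeros(m.n_samples), labels.to_numpy())

    errors = np.zeros(delta_grid.size)
    fold_models: list[NSCModel] = []
    fold_tests: list[np.ndarray] = []
    for train_idx, test_idx in splitter:
        train = m.subset_samples(m.sample_ids[train_idx])
        test = m.subset_samples(m.sample_ids[test_idx])
        base = nsc_fit(train, labels.iloc[train_idx], delta=0.0)
        fold_models.append(base)
        fold_tests.append(test_idx)
        truth = labels.iloc[test_idx].to_numpy()
        for di, delta in enumerate(delta_grid):
            pred = _reshrink(base, delta).predict(test).to_numpy()
            errors[di] += int((pred != truth).sum())

    best_err = errors.min()
    selected_delta = float(delta_grid[np.flatnonzero(errors == best_err).max()])
    ranking_delta = float(delta_grid[np.flatnonzero(errors == best_err).min()])

    rank_sum = pd.Series(0.0, index=m.gene_ids)
    rank_n = pd.Series(0, index=m.gene_ids)
    correct = 0
    for base, test_idx in zip(fold_models, fold_tests):
        model = _reshrink(base, selected_delta)
        strength = model.d_shrunk.abs().max(axis=1)
        surv = strength[strength > 0]
        order = pd.DataFrame({"s": surv, "gene": surv.index}).sort_values(
            ["s", "gene"], ascending=[False, True], kind="mergesort"
        )
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index, dtype=float)
        rank_sum.loc[ranks.index] += ranks
        rank_n.loc[ranks.index] += 1
        test = m.subset_samples(m.sample_ids[test_idx])
        pred = model.predict(test).to_numpy()
        correct += int((pred == labels.iloc[test_idx].to_numpy()).sum())

    sentinel = float(m.n_genes + 1)
    avg_rank = pd.Series(sentinel, index=m.gene_ids, name="avg_rank")
    seen = rank_n > 0
    avg_rank[seen] = rank_sum[seen] / rank_n[seen]

    final = _reshrink(full, ranking_delta)
    return GeneRanking(
        avg_rank=avg_rank,
        shrunken_scores=final.d_shrunk.copy(),
        n_folds=n_folds,
        delta_grid=delta_grid,
        selected_delta=selected_delta,
        ranking_delta=ranking_delta,
        cv_accuracy=correct / m.n_samples,
        cv_errors=pd.Series(errors, index=delta_grid),
    )


# ---------------------------------------------------------------------------
# differential expression and affiliation scores
# ---------------------------------------------------------------------------


def pairwise_de(m: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """One-vs-rest Welch t-test per gene per subgroup, BH within subgroup.

    Genes with zero variance in both groups get p = 1 by convention.
    Returns a tidy frame with columns gene, subgroup, t, pval, qval.
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every subgroup needs at least 2 samples")
    frames = []
    x = m.values.to_numpy()
    for c in sorted(labels.unique()):
        in_c = (labels == c).to_numpy()
        t, p = stats.ttest_ind(x[:, in_c], x[:, ~in_c], axis=1, equal_var=False)
        flat = ~np.isfinite(t)
        if flat.any():
            logger.warning("%d zero-variance genes in subgroup %s: p set to 1", int(flat.sum()), c)
            t = np.where(flat, 0.0, t)
            p = np.where(flat, 1.0, p)
        q = _bh(np.asarray(p))
        frames.append(pd.DataFrame({
            "gene": m.gene_ids, "subgroup": c, "t": t, "pval": p, "qval": q,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class SubclassScores:
    """Per-sample subgroup affiliation and per-gene subclass scores."""

    affiliation: pd.DataFrame        # samples x subgroups, rows sum to 1
    gene_scores: pd.DataFrame        # gene, subgroup (best class), score, qval, neg_log10_fdr


def subclass_scores(
    model: NSCModel,
    m: ExpressionMatrix,
    de: pd.DataFrame | None = None,
) -> SubclassScores:
    """Affiliation likelihood = softmax over -0.5 * delta_k(x).

    Each gene's subclass score is its shrunken contrast d' for the class
    where |d'| is largest; when a :func:`pairwise_de` table is supplied the
    matching q-value (and -log10 FDR) is attached for scatter plotting.
    """
    disc = model.discriminants(m)
    logits = -0.5 * disc.to_numpy()
    logits -= logits.max(axis=1, keepdims=True)
    prob = np.exp(logits)
    prob /= prob.sum(axis=1, keepdims=True)
    affiliation = pd.DataFrame(prob, index=disc.index, columns=disc.columns)

    best_pos = model.d_shrunk.abs().to_numpy().argmax(axis=1)
    best_class = [model.classes[i] for i in best_pos]
    score = model.d_shrunk.to_numpy()[np.arange(len(model.genes)), best_pos]
    genes = pd.DataFrame({"gene": model.genes, "subgroup": best_class, "score": score})
    if de is not None:
        genes = genes.merge(de[["gene", "subgroup", "qval"]], on=["gene", "subgroup"], how="left")
        with np.errstate(divide="ignore"):
            genes["neg_log10_fdr"] = -np.log10(genes["qval"])
    return SubclassScores(affiliation=affiliation, gene_scores=genes)
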